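"""Phylogenetic null models for community assembly inference.

The central quantities:

* ``MNTD`` — abundance-weighted mean distance from each taxon in a sample
  to its nearest relative in the same sample; ``ses.MNTD`` standardizes it
  against a tip-label-shuffling null.
* ``betaMNTD`` — between-sample analogue: for each taxon, distance to its
  nearest relative in the *other* sample, abundance-weighted and averaged
  over both directions.
* ``betaNTI`` — (observed betaMNTD - null mean) / null sd under tip-label
  shuffles of the whole tree.  |betaNTI| > 2 indicates deterministic
  assembly (variable selection if > 2, homogeneous selection if < -2).
* ``RC-bray`` — Bray-Curtis-based Raup-Crick metric: the rescaled rank of
  the observed dissimilarity within a null that preserves each sample's
  richness and read total while drawing taxa by occupancy and reads by
  pool abundance.  Within |betaNTI| <= 2 it separates dispersal limitation
  (> 0.95), homogenizing dispersal (< -0.95), and drift (between).

The null scheme is "taxa labels": one random permutation of all tree tips
per draw, shared by every sample (so identical communities yield a
degenerate null, which is flagged as undefined rather than crashing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import mantel as _skbio_mantel

from commeco.io import CountMatrix, SampleGroups, ValidationError, align_counts_to_tree

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)
DETERMINISTIC = PROCESS_LABELS[:2]
STOCHASTIC = PROCESS_LABELS[2:]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def patristic_matrix(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    """Tip-to-tip patristic distances ordered as ``taxa``."""
    dm = tree.tip_tip_distances()
    return dm.filter(taxa).data


# ---------------------------------------------------------------------------
# MNTD / ses.MNTD
# ---------------------------------------------------------------------------

def mntd(abundances, dist: np.ndarray, abundance_weighted: bool = True) -> float:
    """Mean nearest taxon distance within one sample.

    ``abundances`` is a vector over the taxa indexing ``dist``; taxa with
    zero abundance are absent.  Weighted form uses relative abundances,
    unweighted uses 1/S.
    """
    ab = np.asarray(abundances, dtype=float)
    present = np.flatnonzero(ab > 0)
    if len(present) < 2:
        raise ValidationError("MNTD needs >= 2 taxa present")
    sub = dist[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if abundance_weighted:
        w = ab[present] / ab[present].sum()
    else:
        w = np.full(len(present), 1.0 / len(present))
    return float(w @ nearest)


@dataclass
class SesMntdTable:
    """Per-sample ses.MNTD records; ``undefined`` flags samples whose null
    distribution was degenerate (sd = 0)."""

    table: pd.DataFrame  # mntd_obs, null_mean, null_sd, ses_mntd, nti, undefined


def ses_mntd(counts: CountMatrix, tree: TreeNode, n_null: int = 999,
             seed: int = 0, abundance_weighted: bool = True) -> SesMntdTable:
    """Standard effect size of MNTD under tip-label shuffles.

    ses = (obs - null mean) / null sd over ``n_null`` random permutations
    of the taxa across all tree tips; NTI is its negative.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    counts = align_counts_to_tree(counts, tree)
    D = patristic_matrix(tree, counts.taxon_ids)
    X = counts.counts()
    rng = np.random.default_rng(seed)
    n_taxa = X.shape[1]

    obs = np.array([mntd(row, D, abundance_weighted) for row in X])
    nulls = np.empty((n_null, X.shape[0]))
    for d in range(n_null):
        perm = rng.permutation(n_taxa)
        for s, row in enumerate(X):
            present = np.flatnonzero(row > 0)
            idx = perm[present]
            sub = D[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, np.inf)
            nearest = sub.min(axis=1)
            if abundance_weighted:
                w = row[present] / row[present].sum()
            else:
                w = np.full(len(present), 1.0 / len(present))
            nulls[d, s] = w @ nearest
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    undefined = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(undefined, np.nan, (obs - mean) / sd)
    table = pd.DataFrame({
        "mntd_obs": obs, "null_mean": mean, "null_sd": sd,
        "ses_mntd": ses, "nti": -ses, "undefined": undefined,
    }, index=counts.sample_ids)
    return SesMntdTable(table)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _pair_beta_mntd(idx_k, w_k, idx_m, w_m, D) -> float:
    sub = D[np.ix_(idx_k, idx_m)]
    return 0.5 * float(w_k @ sub.min(axis=1) + w_m @ sub.min(axis=0))


def _sample_profiles(counts: CountMatrix, abundance_weighted: bool):
    X = counts.counts()
    profiles = []
    for row in X:
        present = np.flatnonzero(row > 0)
        if len(present) == 0:
            raise ValidationError("empty sample in betaMNTD")
        if abundance_weighted:
            w = row[present] / row[present].sum()
        else:
            w = np.full(len(present), 1.0 / len(present))
        profiles.append((present, w))
    return profiles


def beta_mntd(counts: CountMatrix, tree: TreeNode,
              abundance_weighted: bool = True) -> DistanceMatrix:
    """Between-sample mean nearest taxon distance.

    betaMNTD(k, m) = 1/2 [ sum_i f_ik min_{j in m} d(i, j)
                         + sum_j f_jm min_{i in k} d(i, j) ].
    A taxon present in both samples is its own nearest neighbour (d = 0).
    """
    counts = align_counts_to_tree(counts, tree)
    D = patristic_matrix(tree, counts.taxon_ids)
    profiles = _sample_profiles(counts, abundance_weighted)
    n = len(profiles)
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(k + 1, n):
            ik, wk = profiles[k]
            im, wm = profiles[m]
            out[k, m] = out[m, k] = _pair_beta_mntd(ik, wk, im, wm, D)
    return DistanceMatrix(out, ids=counts.sample_ids)


@dataclass
class BetaNtiResult:
    """Pairwise betaNTI with its ingredients; undefined pairs (degenerate
    null, sd = 0) are NaN in ``bnti`` and True in ``undefined``."""

    bnti: pd.DataFrame
    beta_mntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    undefined: pd.DataFrame


def beta_nti(counts: CountMatrix, tree: TreeNode, n_null: int = 999,
             seed: int = 0, abundance_weighted: bool = True) -> BetaNtiResult:
    """betaNTI: standardized effect size of betaMNTD.

    Each null draw applies one tip-label permutation of the whole tree to
    *both* samples of every pair, then recomputes betaMNTD; betaNTI =
    (obs - null mean) / null sd.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    counts = align_counts_to_tree(counts, tree)
    D = patristic_matrix(tree, counts.taxon_ids)
    profiles = _sample_profiles(counts, abundance_weighted)
    ids = counts.sample_ids
    n = len(profiles)
    rng = np.random.default_rng(seed)
    n_taxa = D.shape[0]

    pairs = [(k, m) for k in range(n) for m in range(k + 1, n)]
    obs = np.array([
        _pair_beta_mntd(profiles[k][0], profiles[k][1],
                        profiles[m][0], profiles[m][1], D)
        for k, m in pairs
    ])
    nulls = np.empty((n_null, len(pairs)))
    for d in range(n_null):
        perm = rng.permutation(n_taxa)
        for p, (k, m) in enumerate(pairs):
            ik, wk = profiles[k]
            im, wm = profiles[m]
            nulls[d, p] = _pair_beta_mntd(perm[ik], wk, perm[im], wm, D)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    undef = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    if undef.any():
        warnings.warn(
            f"{undef.sum()} sample pair(s) have a degenerate betaMNTD null "
            "(identical communities?); betaNTI flagged undefined",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(undef, np.nan, (obs - mean) / sd)

    def _square(vec, fill=0.0):
        M = np.full((n, n), fill, dtype=float)
        for p, (k, m) in enumerate(pairs):
            M[k, m] = M[m, k] = vec[p]
        return pd.DataFrame(M, index=ids, columns=ids)

    return BetaNtiResult(
        bnti=_square(bnti, np.nan).where(~np.eye(n, dtype=bool), 0.0),
        beta_mntd_obs=_square(obs),
        null_mean=_square(mean),
        null_sd=_square(sd),
        undefined=_square(undef.astype(float)).astype(bool)
        & ~np.eye(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# RC-bray
# ---------------------------------------------------------------------------

def _bray_curtis_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.abs(A - B).sum(axis=1) / (A + B).sum(axis=1)


def rc_bray(counts: CountMatrix, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick metric on [-1, 1].

    Null communities preserve each sample's observed richness and read
    total: richness taxa are drawn without replacement with probability
    proportional to occupancy (fraction of samples containing the taxon);
    each drawn taxon receives one read and the remaining reads are allotted
    multinomially with probability proportional to metacommunity relative
    abundance.  RC = 2 * ((#null BC below observed + half the ties) /
    n_null - 0.5).  Null draws are generated once per sample and shared
    across the pairs that involve it.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    X = counts.counts()
    n_samples, n_taxa = X.shape
    if (X.sum(axis=0) > 0).sum() < 2:
        raise ValidationError("RC-bray needs >= 2 taxa in the metacommunity")
    occupancy = (X > 0).sum(axis=0).astype(float)
    pool_ab = X.sum(axis=0).astype(float)
    rng = np.random.default_rng(seed)

    # successive occupancy-weighted sampling without replacement, drawn for
    # all null replicates at once via Gumbel top-k (Efraimidis-Spirakis)
    with np.errstate(divide="ignore"):
        log_occ = np.log(occupancy)
    null_counts = []
    for s in range(n_samples):
        richness = int((X[s] > 0).sum())
        depth = int(X[s].sum())
        keys = log_occ + rng.gumbel(size=(n_null, n_taxa))
        chosen_all = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
        draws = np.zeros((n_null, n_taxa), dtype=np.int64)
        extra = depth - richness
        for d in range(n_null):
            chosen = chosen_all[d]
            draws[d, chosen] = 1
            if extra > 0:
                p = pool_ab[chosen] / pool_ab[chosen].sum()
                draws[d, chosen] += rng.multinomial(extra, p)
        null_counts.append(draws)

    out = np.zeros((n_samples, n_samples))
    for k in range(n_samples):
        for m in range(k + 1, n_samples):
            obs = np.abs(X[k] - X[m]).sum() / (X[k] + X[m]).sum()
            null_bc = _bray_curtis_rows(null_counts[k], null_counts[m])
            below = (null_bc < obs - 1e-12).sum()
            ties = (np.abs(null_bc - obs) <= 1e-12).sum()
            rc = (below + 0.5 * ties) / n_null
            out[k, m] = out[m, k] = 2.0 * (rc - 0.5)
    return pd.DataFrame(out, index=counts.sample_ids, columns=counts.sample_ids)


# ---------------------------------------------------------------------------
# classification and summaries
# ---------------------------------------------------------------------------

def classify_assembly(beta_nti_value: float, rc_bray_value: float) -> str:
    """Five-way assembly-process call from one (betaNTI, RC-bray) pair.

    betaNTI > 2: variable selection; betaNTI < -2: homogeneous selection;
    otherwise RC-bray > 0.95: dispersal limitation, < -0.95: homogenizing
    dispersal, else drift.
    """
    if np.isnan(beta_nti_value):
        raise ValidationError("betaNTI is undefined for this pair")
    if beta_nti_value > BNTI_THRESHOLD:
        return "variable_selection"
    if beta_nti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if np.isnan(rc_bray_value):
        raise ValidationError("RC-bray is undefined for this pair")
    if rc_bray_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def pairwise_assembly(counts: CountMatrix, tree: TreeNode,
                      groups: SampleGroups | None = None, n_null: int = 999,
                      seed: int = 0, abundance_weighted: bool = True,
                      ) -> pd.DataFrame:
    """Per sample-pair betaMNTD, betaNTI, RC-bray, and process label.

    ``group_context`` is the shared group label for within-group pairs and
    "between" otherwise.  Pairs with an undefined betaNTI get a null
    process label and are excluded from summaries.
    """
    bn = beta_nti(counts, tree, n_null=n_null, seed=seed,
                  abundance_weighted=abundance_weighted)
    rc = rc_bray(counts, n_null=n_null, seed=seed + 1)
    ids = counts.sample_ids
    rows = []
    for k in range(len(ids)):
        for m in range(k + 1, len(ids)):
            i, j = ids[k], ids[m]
            b = bn.bnti.loc[i, j]
            r = rc.loc[i, j]
            if np.isnan(b):
                proc = None
            else:
                proc = classify_assembly(b, r)
            ctx = "between"
            if groups is not None:
                gi, gj = groups.group_of(i), groups.group_of(j)
                ctx = gi if gi == gj else "between"
            rows.append({
                "sample_i": i, "sample_j": j,
                "beta_mntd_obs": bn.beta_mntd_obs.loc[i, j],
                "beta_nti": b, "rc_bray": r,
                "process": proc, "group_context": ctx,
            })
    return pd.DataFrame(rows)


def summarize_processes(pairs: pd.DataFrame,
                        scope: str = "overall") -> pd.DataFrame:
    """Process-label counts and fractions.

    scope="overall": one row over all classified pairs; scope="within_group":
    one row per within-group context plus an overall row.  Deterministic =
    variable + homogeneous selection; stochastic = the other three.
    """
    classified = pairs[pairs["process"].notna()]
    n_undefined = int(pairs["process"].isna().sum())

    def _row(sub: pd.DataFrame, label: str) -> dict:
        if len(sub) == 0:
            raise ValidationError(f"no classified pairs in scope {label!r}")
        rec: dict = {"scope": label, "n_pairs": len(sub),
                     "n_undefined": n_undefined if label == "overall" else
                     int(pairs.loc[pairs["group_context"] == label,
                                   "process"].isna().sum())}
        for proc in PROCESS_LABELS:
            k = int((sub["process"] == proc).sum())
            rec[f"n_{proc}"] = k
            rec[f"frac_{proc}"] = k / len(sub)
        rec["deterministic_fraction"] = sum(rec[f"frac_{p}"] for p in DETERMINISTIC)
        rec["stochastic_fraction"] = sum(rec[f"frac_{p}"] for p in STOCHASTIC)
        return rec

    if scope == "overall":
        return pd.DataFrame([_row(classified, "overall")])
    if scope != "within_group":
        raise ValidationError(f"unknown scope {scope!r}")
    rows = [_row(classified, "overall")]
    for g in dict.fromkeys(classified["group_context"]):
        if g == "between":
            continue
        rows.append(_row(classified[classified["group_context"] == g], g))
    return pd.DataFrame(rows)


def process_fractions_from_counts(counts_per_process: dict[str, int]) -> dict[str, float]:
    """Deterministic/stochastic split from raw per-process pair counts."""
    total = sum(counts_per_process.values())
    if total == 0:
        raise ValidationError("no pairs")
    det = sum(counts_per_process.get(p, 0) for p in DETERMINISTIC)
    return {
        "deterministic_fraction": det / total,
        "stochastic_fraction": (total - det) / total,
    }


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """One-sided Mantel test (Pearson r of the upper triangles; permutation
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm))."""
    if set(dm1.ids) != set(dm2.ids):
        raise ValidationError("distance matrices have mismatched ids")
    if dm1.shape[0] < 4:
        raise ValidationError("Mantel test needs >= 4 samples")
    dm2 = dm2.filter(dm1.ids)
    r, p, _ = _skbio_mantel(dm1, dm2, method="pearson",
                            permutations=n_perm, alternative="greater",
                            seed=seed)
    return float(r), float(p)


def zscore_euclidean(env: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between samples on z-scored environmental
    variables (columns standardized to mean 0, sd 1)."""
    z = (env - env.mean()) / env.std(ddof=0)
    from scipy.spatial.distance import pdist, squareform
    return DistanceMatrix(squareform(pdist(z.to_numpy())), ids=list(env.index))
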