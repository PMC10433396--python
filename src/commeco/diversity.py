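"""Alpha diversity estimators, beta-diversity distances, and PCoA.

Alpha estimators follow the mothur conventions for OTU tables: Good's
coverage 1 - F1/N, bias-corrected Chao1, ACE with rare cutoff 10, Shannon
in bits (base-2 logs), and Simpson reported as the Gini-Simpson index
1 - sum(p_i^2) so that larger means more diverse.  Beta diversity is
Bray-Curtis on raw counts or unweighted UniFrac on presence/absence
against a rooted tree; ordination is classical PCoA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha as _alpha
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from commeco.io import CountMatrix, ValidationError, align_counts_to_tree


def _as_counts(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.sum() <= 0:
        raise ValidationError("sample has zero total count")
    return arr


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: the chance the next read is a seen taxon."""
    arr = _as_counts(counts)
    return float(1.0 - (arr == 1).sum() / arr.sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness; bias-corrected form S + F1(F1-1)/(2(F2+1)) by default."""
    return float(_alpha.chao1(_as_counts(counts), bias_corrected=bias_corrected))


def ace(counts, rare_cutoff: int = 10) -> float:
    """ACE richness estimator with the standard rare/abundant split at 10.

    Falls back to Chao1 when the rare-class coverage C_ACE is zero (all
    rare taxa are singletons)."""
    arr = _as_counts(counts)
    rare = arr[(arr > 0) & (arr <= rare_cutoff)]
    if len(rare) and (rare == 1).all():
        return chao1(arr)
    return float(_alpha.ace(arr, rare_threshold=rare_cutoff))


def shannon(counts, log_base: float = 2) -> float:
    """Shannon entropy H = -sum p log_b p, in bits by default."""
    return float(_alpha.shannon(_as_counts(counts), base=log_base))


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (larger = more diverse)."""
    return float(_alpha.simpson(_as_counts(counts)))


def alpha_table(counts: CountMatrix) -> pd.DataFrame:
    """Per-sample alpha diversity summary (reads, observed OTUs, coverage,
    Chao1, ACE, Shannon, Simpson)."""
    rows = []
    for sid in counts.sample_ids:
        vec = counts.data.loc[sid].to_numpy()
        rows.append({
            "sample_id": sid,
            "reads": int(vec.sum()),
            "observed_otus": int((vec > 0).sum()),
            "coverage": goods_coverage(vec),
            "chao1": chao1(vec),
            "ace": ace(vec),
            "shannon": shannon(vec),
            "simpson": simpson(vec),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def alpha_group_summary(alpha: pd.DataFrame, groups) -> pd.DataFrame:
    """Group mean +/- sd layout for each alpha index."""
    g = alpha.copy()
    g["group"] = [groups.group_of(s) for s in alpha.index]
    agg = g.groupby("group", sort=False).agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(counts: CountMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples on raw counts."""
    if counts.shape[0] < 2:
        raise ValidationError("need >= 2 samples for beta diversity")
    return beta_diversity("braycurtis", counts.counts(), ids=counts.sample_ids)


def unweighted_unifrac(counts: CountMatrix, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: fraction of branch length unique to one of the two
    communities, on presence/absence."""
    if counts.shape[0] < 2:
        raise ValidationError("need >= 2 samples for beta diversity")
    aligned = align_counts_to_tree(counts, tree)  # hard error if tips missing
    return beta_diversity(
        "unweighted_unifrac", aligned.counts(), ids=aligned.sample_ids,
        taxa=aligned.taxon_ids, tree=tree,
    )


@dataclass
class Ordination:
    """PCoA result: sample coordinates, eigenvalues, and the proportion of
    variance per axis (negative eigenvalues are excluded from proportions
    and reported separately)."""

    coordinates: pd.DataFrame      # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray        # all eigenvalues, decreasing
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical (Gower) principal coordinates analysis of a distance matrix."""
    n = dm.shape[0]
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", dimensions=0,
                          warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 0]
    prop = np.where(eig > 0, eig / pos.sum(), 0.0)
    k = min(k, (eig > 0).sum())
    coords = res.samples.iloc[:, :k].copy()
    coords.index = list(dm.ids)
    coords.columns = [f"PCo{i + 1}" for i in range(k)]
    return Ordination(
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=prop[:k],
        negative_eigenvalues=eig[eig < 0],
    )


def rarefy(counts: CountMatrix, depth: int, seed: int = 0) -> CountMatrix:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (with the ids noted
    in the raised error if none remain)."""
    rng = np.random.default_rng(seed)
    keep_rows, ids = [], []
    for sid in counts.sample_ids:
        vec = counts.data.loc[sid].to_numpy()
        if vec.sum() < depth:
            continue
        reads = np.repeat(np.arange(len(vec)), vec)
        sub = rng.choice(reads, size=depth, replace=False)
        keep_rows.append(np.bincount(sub, minlength=len(vec)))
        ids.append(sid)
    if not keep_rows:
        raise ValidationError(f"no sample has >= {depth} reads")
    return CountMatrix(pd.DataFrame(keep_rows, index=ids,
                                    columns=counts.taxon_ids))
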