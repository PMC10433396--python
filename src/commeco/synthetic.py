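"""Synthetic communities with known assembly regimes.

The generator emulates a 4-treatment x 3-replicate soil survey: a
phylogeny over a few hundred OTUs, a Brownian habitat-preference trait on
that phylogeny, and per-sample multinomial read sampling at fixed depth
under one of three regimes:

``selection``
    Gaussian habitat filtering of the shared species pool around a
    per-group trait optimum, combined with a per-replicate recruitment
    lottery (each taxon establishes independently with probability
    ``establishment`` and a mild log-normal abundance jitter):
    ``w_i ∝ pool_i * exp(-(trait_i - optimum_g)^2 / (2 sigma_env^2))
    * Bernoulli(establishment) * LogNormal(0, jitter)``.
    Filtering confines every replicate to the same clades while the
    lottery turns membership over *within* those clades, so replicates
    show less phylogenetic turnover than a tip-shuffling null expects
    (betaNTI < -2, homogeneous selection).
``neutral``
    Every sample draws from the same log-normal pool after replicate-level
    demographic drift: a Dirichlet draw centred on the pool with
    concentration ``drift_concentration``.  Pure multinomial read sampling
    alone makes replicates far *more* similar than a richness/occupancy-
    preserving null expects (every pair would look homogenized);
    finite-community drift is what places neutral pairs in the RC-bray
    drift band.
``dispersal_limited``
    Each sample draws from its own log-normally perturbed copy of the
    pool, mixed back into the shared pool with migration rate ``m``; low
    ``m`` produces compositional divergence with no phylogenetic structure
    (dispersal limitation: |betaNTI| <= 2 but RC-bray -> 1).

The default phylogeny ("otu_clusters") is a Yule backbone over cherry
clades with very short within-clade branches, emulating the shape of a
real OTU tree (97%-identity clusters radiating on a deep backbone).  That
fine-scale structure is what gives the nearest-taxon statistics their
contrast at a few hundred taxa; a plain Yule tree is available as
``model="yule"``.

Seeds for the tree, the trait, and the community sampling are derived from
the scenario seed by fixed stage offsets, so each stage can be regenerated
independently.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from commeco.io import (
    CountMatrix,
    SampleGroups,
    ValidationError,
    write_count_table,
    write_metadata,
    write_newick,
)

# fixed stage offsets for sub-seed derivation
_STAGE_TREE = 1
_STAGE_TRAIT = 2
_STAGE_COMMUNITY = 3
_STAGE_GUILD = 4

# default treatment labels mirroring a 4-arm tillage/straw design
DEFAULT_GROUP_LABELS = ("CntWt", "CntWntS", "CntWtS", "CntWnt")

# pool heterogeneity (log-normal sigma of the shared species pool); the
# per-replicate pool perturbation of the dispersal_limited regime; and the
# abundance jitter of the selection regime's recruitment lottery.  Evenness
# is deliberately higher than in field data: at a few hundred taxa the
# averaging that real datasets get from thousands of rare OTUs has to come
# from evenness instead.
POOL_SIGMA = 0.8
PERTURBATION_SIGMA = 2.0
RECRUIT_JITTER = 0.3


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


@dataclass
class SyntheticScenario:
    """Parameters defining one simulated study.

    Defaults emulate the field design downstream analyses expect: 4
    treatment groups x 3 replicates = 12 samples, 200 taxa, 2,000 reads
    per sample.  ``selection_strength`` (sigma_env) is the width of the
    Gaussian habitat filter in units of the realized trait standard
    deviation, so scenarios transfer across trees.
    """

    n_taxa: int = 200
    n_groups: int = 4
    reps_per_group: int = 3
    depth: int = 2000
    regime: str = "selection"  # selection | neutral | dispersal_limited
    selection_strength: float = 0.3   # sigma_env / sd(trait)
    establishment: float = 0.55       # recruitment lottery, selection only
    trait_sigma: float = 1.0          # Brownian rate of the habitat trait
    group_optima: tuple[float, ...] | None = None  # one optimum per group
    migration: float = 0.3            # m, dispersal_limited only
    drift_concentration: float = 8000.0  # Dirichlet concentration, neutral
    tree_model: str = "otu_clusters"  # otu_clusters | yule
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("selection", "neutral", "dispersal_limited"):
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if self.reps_per_group < 2:
            raise ValidationError("reps_per_group must be >= 2")
        if not 0.0 <= self.migration <= 1.0:
            raise ValidationError("migration must lie in [0, 1]")
        if self.selection_strength < 0:
            raise ValidationError("selection_strength must be >= 0")
        if not 0.0 < self.establishment <= 1.0:
            raise ValidationError("establishment must lie in (0, 1]")
        if self.drift_concentration <= 0:
            raise ValidationError("drift_concentration must be > 0")
        if self.group_optima is not None and len(self.group_optima) != self.n_groups:
            raise ValidationError("group_optima must supply one optimum per group")

    def group_labels(self) -> list[str]:
        if self.n_groups == len(DEFAULT_GROUP_LABELS):
            return list(DEFAULT_GROUP_LABELS)
        return [f"Grp{i + 1:02d}" for i in range(self.n_groups)]


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    tree: TreeNode
    groups: SampleGroups
    traits: pd.Series
    scenario: SyntheticScenario
    group_optima: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tree and trait simulation
# ---------------------------------------------------------------------------

def _yule(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Pure-birth tree, rate 1, grown to ``n_tips``; ultrametric by
    construction, tips unnamed."""
    left, right = TreeNode(length=0.0), TreeNode(length=0.0)
    root = TreeNode(children=[left, right], length=0.0)
    active = [left, right]
    while True:
        dt = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += dt
        if len(active) == n_tips:
            break
        parent = active.pop(int(rng.integers(len(active))))
        kids = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(kids)
        active.extend(kids)
    return root


def simulate_tree(n_taxa: int, seed: int = 0, model: str = "otu_clusters",
                  clade_size: int = 2, radiation_depth: float = 0.03,
                  ) -> TreeNode:
    """Simulate an ultrametric phylogeny with tips OTU0001...OTUnnnn.

    ``model="yule"`` is a plain pure-birth (rate 1) tree.  The default
    ``"otu_clusters"`` grows a Yule backbone over ``n_taxa / clade_size``
    clades and replaces each backbone tip by a shallow radiation of depth
    ``radiation_depth`` — the two-scale shape of real OTU trees, where
    97%-identity clusters sit on deep stems.  Branch lengths are in
    expected-substitution units; deterministic for a fixed seed.
    """
    if n_taxa < 3:
        raise ValidationError("n_taxa must be >= 3")
    rng = _stage_rng(seed, _STAGE_TREE)
    if model == "yule":
        root = _yule(n_taxa, rng)
    elif model == "otu_clusters":
        if clade_size < 1:
            raise ValidationError("clade_size must be >= 1")
        n_clades = max(2, round(n_taxa / clade_size))
        sizes = [n_taxa // n_clades] * n_clades
        for i in range(n_taxa - sum(sizes)):
            sizes[i] += 1
        root = _yule(n_clades, rng)
        for tip, size in zip(list(root.tips()), sizes):
            if size <= 1:
                continue
            sub = _yule(size, rng)
            depth = max(t.accumulate_to_ancestor(sub) for t in sub.tips())
            scale = radiation_depth / depth
            for node in sub.traverse(include_self=False):
                node.length *= scale
            tip.length = max(tip.length - radiation_depth, 1e-6)
            tip.extend(list(sub.children))
    else:
        raise ValidationError(f"unknown tree model {model!r}")
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU{i + 1:04d}"
    return root


def evolve_trait(tree: TreeNode, trait_sigma: float = 1.0,
                 seed: int = 0) -> pd.Series:
    """Evolve a continuous habitat trait by Brownian motion along the tree.

    Per branch of length L the increment is N(0, trait_sigma^2 * L); the
    root value is 0.  ``trait_sigma = 0`` is the degenerate limit where all
    tips inherit the root value.
    """
    if trait_sigma < 0:
        raise ValidationError("trait_sigma must be >= 0")
    rng = _stage_rng(seed, _STAGE_TRAIT)
    values: dict[int, float] = {id(tree): 0.0}
    tips: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        L = node.length or 0.0
        val = values[id(node.parent)] + rng.normal(0.0, trait_sigma * np.sqrt(L))
        values[id(node)] = val
        if node.is_tip():
            tips[node.name] = val
    order = [t.name for t in tree.tips()]
    return pd.Series([tips[n] for n in order], index=order, name="trait")


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def _default_optima(traits: pd.Series, n_groups: int) -> np.ndarray:
    # evenly spaced interior quantiles of the realized trait distribution
    qs = (np.arange(n_groups) + 1) / (n_groups + 1)
    return np.quantile(traits.to_numpy(), qs)


def gaussian_filter(traits: np.ndarray, optimum: float,
                    sigma_env: float) -> np.ndarray:
    """Habitat filter exp(-(trait - optimum)^2 / (2 sigma_env^2));
    all-ones in the sigma_env -> infinity limit."""
    if np.isinf(sigma_env):
        return np.ones_like(traits)
    return np.exp(-((traits - optimum) ** 2) / (2.0 * sigma_env**2))


def assemble_communities(tree: TreeNode, traits: pd.Series,
                         scenario: SyntheticScenario) -> SyntheticDataset:
    """Draw multinomial communities under the scenario's assembly regime."""
    taxa = [t.name for t in tree.tips()]
    traits = traits.loc[taxa]
    rng = _stage_rng(scenario.seed, _STAGE_COMMUNITY)
    n = len(taxa)

    pool = np.exp(rng.normal(0.0, POOL_SIGMA, size=n))  # shared species pool
    pool /= pool.sum()

    labels = scenario.group_labels()
    tr = traits.to_numpy()
    trait_sd = tr.std() if tr.std() > 0 else 1.0
    if scenario.regime == "selection":
        if scenario.selection_strength == 0:
            raise ValidationError("selection regime needs selection_strength > 0")
        if scenario.group_optima is not None:
            optima = np.asarray(scenario.group_optima, float)
        else:
            optima = _default_optima(traits, scenario.n_groups)
        sigma_env = scenario.selection_strength * trait_sd
    else:
        optima = np.full(scenario.n_groups, np.nan)
        sigma_env = np.nan

    rows, sample_ids, group_col = [], [], []
    for g, label in enumerate(labels):
        for rep in range(scenario.reps_per_group):
            if scenario.regime == "selection":
                w = pool * gaussian_filter(tr, optima[g], sigma_env)
                # recruitment lottery: independent establishment + jitter
                w = w * (rng.random(n) < scenario.establishment)
                w = w * np.exp(rng.normal(0.0, RECRUIT_JITTER, size=n))
                if w.sum() == 0:  # pathological filter: fall back to pool
                    w = pool.copy()
            elif scenario.regime == "neutral":
                # demographic drift around the shared pool
                w = rng.dirichlet(scenario.drift_concentration * pool + 1e-12)
            else:  # dispersal_limited
                pert = pool * np.exp(rng.normal(0.0, PERTURBATION_SIGMA, size=n))
                pert /= pert.sum()
                w = scenario.migration * pool + (1.0 - scenario.migration) * pert
            w = w / w.sum()
            rows.append(rng.multinomial(scenario.depth, w))
            sample_ids.append(f"{label}_r{rep + 1}")
            group_col.append(label)

    counts = CountMatrix(pd.DataFrame(rows, index=sample_ids, columns=taxa))
    groups = SampleGroups(pd.Series(group_col, index=sample_ids))
    optima_map = (
        {lab: float(optima[g]) for g, lab in enumerate(labels)}
        if scenario.regime == "selection" else {}
    )
    return SyntheticDataset(counts, tree, groups, traits, scenario, optima_map)


def simulate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Tree + trait + communities in one call (in memory)."""
    tree = simulate_tree(scenario.n_taxa, seed=scenario.seed,
                         model=scenario.tree_model)
    traits = evolve_trait(tree, scenario.trait_sigma, seed=scenario.seed)
    return assemble_communities(tree, traits, scenario)


def generate_dataset(scenario: SyntheticScenario, outdir: str | os.PathLike,
                     force: bool = False) -> SyntheticDataset:
    """Simulate a dataset and write counts.tsv, tree.nwk, metadata.tsv, and a
    manifest.json recording every scenario parameter and the seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in
             ("counts.tsv", "tree.nwk", "metadata.tsv", "manifest.json")}
    existing = [str(p) for p in paths.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {existing}; pass force=True to replace"
        )
    ds = simulate_dataset(scenario)
    write_count_table(ds.counts, paths["counts.tsv"])
    write_newick(ds.tree, paths["tree.nwk"])
    write_metadata(ds.groups, paths["metadata.tsv"])
    manifest = dataclasses.asdict(scenario)
    manifest["group_optima_used"] = ds.group_optima
    with open(paths["manifest.json"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ds


# ---------------------------------------------------------------------------
# planted co-occurrence guilds (network ground truth)
# ---------------------------------------------------------------------------

def simulate_guild_counts(n_guilds: int = 2, taxa_per_guild: int = 10,
                          n_samples: int = 20, n_background: int = 20,
                          depth: int = 5000, association: float = 1.5,
                          noise: float = 0.3, seed: int = 0,
                          ) -> tuple[CountMatrix, pd.Series]:
    """Communities with planted guilds of positively co-varying taxa.

    Each guild g has a latent factor f_gs ~ N(0,1) per sample; a member
    taxon's abundance weight is exp(association * f_gs + eps) with
    eps ~ N(0, noise^2), so all members of a guild rise and fall together
    across samples.  Background taxa fluctuate independently.  Returns the
    count table and a Series mapping each guild taxon to its guild id
    (background taxa are absent from the Series).
    """
    rng = _stage_rng(seed, _STAGE_GUILD)
    factors = rng.normal(size=(n_guilds, n_samples))
    cols, weights, guild_of = [], [], {}
    for g in range(n_guilds):
        for t in range(taxa_per_guild):
            name = f"G{g + 1}T{t + 1:02d}"
            cols.append(name)
            guild_of[name] = g
            weights.append(np.exp(association * factors[g]
                                  + rng.normal(0, noise, size=n_samples)))
    for b in range(n_background):
        cols.append(f"BG{b + 1:02d}")
        weights.append(np.exp(rng.normal(0, 1.0, size=n_samples)))
    W = np.array(weights).T  # samples x taxa
    W /= W.sum(axis=1, keepdims=True)
    rows = [rng.multinomial(depth, W[s]) for s in range(n_samples)]
    ids = [f"S{s + 1:02d}" for s in range(n_samples)]
    counts = CountMatrix(pd.DataFrame(rows, index=ids, columns=cols))
    return counts, pd.Series(guild_of, name="guild")
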