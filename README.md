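# commeco

Community ecology inference for OTU count tables: alpha/beta diversity,
phylogenetic null-model community-assembly analysis (βMNTD / βNTI /
RC<sub>bray</sub> with five-way process classification), and ensemble
co-occurrence network construction — plus a synthetic-community generator
with *known* assembly regimes, so every stage of the pipeline can be
validated against ground truth without sequencing data.

The package is aimed at microbial ecologists who ask, for a set of
treatment groups with replicated 16S OTU tables: how diverse are the
communities, are they assembled by deterministic selection or by
stochastic processes (drift, dispersal), and which taxa co-occur?

## The statistics at the core

**Assembly inference.** For each sample pair, the abundance-weighted
between-community mean nearest taxon distance

βMNTD(k,m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} d(i,j) + Σ_{j∈m} f_jm · min_{i∈k} d(i,j) ]

is standardized against a null that shuffles taxon labels across all tree
tips (one shared permutation per draw):

βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null).

βNTI > +2 → variable selection; βNTI < −2 → homogeneous selection.
Pairs inside |βNTI| ≤ 2 are resolved by the Bray–Curtis Raup–Crick
metric RC<sub>bray</sub> ∈ [−1, 1], the rescaled rank of the observed
dissimilarity inside a null that preserves each sample's richness and
read total (taxa drawn by occupancy, reads by pool abundance):
RC<sub>bray</sub> > 0.95 → dispersal limitation, < −0.95 → homogenizing
dispersal, otherwise drift.

**Diversity.** Good's coverage 1 − F₁/N, bias-corrected Chao1, ACE,
Shannon (bits), Gini–Simpson 1 − Σp², Bray–Curtis, unweighted UniFrac,
and classical PCoA.

**Networks.** Dominant taxa (mean relative abundance > 0.5%) are scored
pairwise with Pearson, Spearman and Bray–Curtis similarity on relative
abundances; per-metric permutation p-values are merged with Brown's
method (Kost–McDermott covariances), BH-corrected, and edges kept when
|ρ| > 0.6 and q < 0.01. Topology reports link counts and signs, density
2E/(n(n−1)), average degree 2E/n, greedy-modularity modules, and
module-hub keystone taxa.

## Worked example

```bash
python analysis/01_simulate_datasets.py
python analysis/03_assembly_processes.py
```

prints (three simulated 4-group × 3-replicate studies, 199 null draws):

```
selection: deterministic 57.6%, stochastic 42.4% (n=66 pairs); modal process = variable_selection
neutral: deterministic 3.0%, stochastic 97.0% (n=66 pairs); modal process = drift
dispersal_limited: deterministic 9.1%, stochastic 90.9% (n=66 pairs); modal process = dispersal_limitation
Mantel |betaNTI| vs environmental optimum distance: r = 0.848, p = 0.001
```

Reading it: under the selection regime, within-group pairs (same habitat
optimum) are dominated by homogeneous selection (βNTI < −2) while pairs
that straddle different optima show variable selection (βNTI > +2) — so
the overall deterministic share is the mix of both. Neutral communities
land almost entirely in drift, and low-migration communities in
dispersal limitation, which is exactly the ground truth each generator
regime encodes. The Mantel test confirms that pairwise |βNTI| tracks the
distance between habitat optima.

The same stages are available as a CLI (`commeco simulate | alpha | beta
| pcoa | assembly | network | run`) and as a one-shot pipeline with a
reproducibility manifest:

```bash
commeco run --simulate selection --seed 7 --out run1
```

## Layout

```
src/commeco/        io, synthetic, diversity, assembly, network, pipeline, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit + property + acceptance)
scripts/acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
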