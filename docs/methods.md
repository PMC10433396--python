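# Methods

## Scope and data model

The pipeline operates on three inputs: a sample × taxon table of
non-negative integer read counts (TSV; BIOM-style `#OTU ID` orientation
accepted), a rooted Newick phylogeny with branch lengths covering the
taxa, and a sample → treatment-group metadata table. Counts are kept as
integers throughout; relative abundances are derived on the fly and
never stored, so repeated round-trips cannot accumulate rounding drift.
Validation is strict and total: duplicate ids, negative/non-integer
cells, empty samples, metadata gaps, and count-table taxa missing from
the tree all raise typed errors. Taxa absent from the tree are a hard
error by default with an explicit `prune=True` escape hatch, because
silently dropping taxa changes every phylogenetic statistic downstream.

## Diversity estimators

Alpha diversity follows the mothur conventions for OTU tables: Good's
coverage 1 − F₁/N; Chao1 in the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) (classic form behind a flag — the corrected
form is defined when F₂ = 0); ACE with the rare/abundant split at 10 and
a Chao1 fallback when the rare class is all singletons (C_ACE = 0);
Shannon entropy in **bits** (base-2 logs; at thousands of OTUs only a
base-2 Shannon reaches the 9–10 range that OTU-survey tables report,
which natural logs cannot); and Simpson reported as Gini–Simpson
1 − Σp² so that larger means more diverse. These wrap scikit-bio's
estimators and are pinned by hand-computed oracles in the tests.

Beta diversity is Bray–Curtis on raw counts and unweighted UniFrac
(presence/absence fraction of unique branch length) via scikit-bio, with
classical (Gower) PCoA for ordination. Negative eigenvalues are excluded
from variance proportions and reported separately. No rarefaction is
applied by default; `rarefy(depth, seed)` exists for parity experiments.

## Assembly inference

The core statistics are authored here (not wrapped):

* **MNTD / ses.MNTD** — abundance-weighted mean nearest taxon distance
  within a sample, standardized against a taxa-label null (see below);
  NTI = −ses.MNTD.
* **βMNTD** — ½[Σ_{i∈k} f_ik min_{j∈m} d(i,j) + Σ_{j∈m} f_jm min_{i∈k}
  d(i,j)]; a taxon shared by both samples is its own nearest neighbour
  at distance 0.
* **βNTI** — (observed − null mean)/null sd over `n_null` tip-label
  permutations (default 999, floor 99). One permutation per draw is
  applied to the whole tree and shared by both samples of every pair.
  This shared-shuffle convention means identical communities produce a
  degenerate null (sd = 0); such pairs are flagged `undefined` (NaN)
  with a warning rather than crashing or silently becoming 0. Degeneracy
  is detected with a relative tolerance of 1e-12 because identical
  multisets summed in different orders differ in the last float bit.
* **RC_bray** — null communities preserve each sample's observed
  richness and read total: richness taxa are drawn without replacement
  with probability ∝ occupancy (number of samples containing the taxon),
  each receives one read, and the remaining reads are allotted
  multinomially ∝ metacommunity relative abundance. The sequential
  weighted draw is implemented as Gumbel top-k (Efraimidis–Spirakis),
  which is both vectorizable and exactly enumerable — the test suite
  checks the Monte-Carlo estimate against an exhaustive enumeration of
  the null on a 4-taxon metacommunity. Ties with the observed
  Bray–Curtis (within 1e-12) carry half weight;
  RC = 2·(rank fraction − ½) ∈ [−1, 1]. Null draws are generated once
  per sample and shared across the pairs involving that sample; this is
  statistically equivalent to per-pair nulls and ~10× cheaper.
* **Classification** — βNTI > 2: variable selection; βNTI < −2:
  homogeneous selection; otherwise RC_bray > 0.95: dispersal limitation;
  < −0.95: homogenizing dispersal; else drift. Thresholds are strict
  inequalities; values exactly at a threshold fall to the stochastic /
  drift side. Pairs with undefined βNTI are excluded from summaries and
  counted in a diagnostics column.
* **Mantel** — Pearson correlation of upper triangles with one-sided
  permutation p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), via scikit-bio
  with an explicit seed; an `zscore_euclidean` helper builds
  environmental distance matrices from z-scored variables (variables
  with different units cannot be mixed unstandardized).

Process summaries report per-label counts and fractions overall and per
within-group context; deterministic = variable + homogeneous selection,
stochastic = the rest, and the two always sum to 1 over classified pairs.

## Ensemble co-occurrence networks

Dominant taxa are those whose **mean** relative abundance across samples
exceeds the threshold (default 0.5%); a per-sample-minimum reading is
available as `mode="min"`. Every unordered taxon pair is scored on
relative-abundance profiles with Pearson r, Spearman ρ, and Bray–Curtis
similarity (1 − dissimilarity, so all three orient "larger = more
associated"). Zero-variance taxa are excluded and reported. Permutation
p-values (default 1,000, floor 99) permute sample order; correlations
are two-sided on |stat| and the bounded similarity is two-sided on its
deviation from the null mean. The three p-values are merged with Brown's
method: T = −2Σln p, E[T] = 2k, Var[T] = 4k + 2Σcov with
cov ≈ 3.263ρ + 0.710ρ² + 0.027ρ³ (Kost–McDermott) evaluated at the
empirical correlation of the statistics across pairs; the merged p is
the upper tail of the scaled χ² with c = Var/2E, df = 2E²/Var. At zero
correlation this reduces exactly to Fisher's method (asserted to 1e-10).
The merge accepts any k ≥ 2 p-values. Benjamini–Hochberg correction is
applied to the merged p; edges are kept when |ρ| > 0.6 **and** q < 0.01,
signed by ρ. Modules come from deterministic greedy modularity
maximization (networkx); `n_modules` counts modules of ≥ 3 nodes;
keystone taxa are the top within-module-degree hubs with name-based tie
breaking. With only 3 replicates per group, pairwise correlations across
samples are undefined-to-meaningless, so `pairwise_metrics` requires
≥ 4 samples and the pipeline's default network scope pools all samples;
per-group networks are available when groups have ≥ 4 replicates, with a
warning below 5.

A `NetworkSummary.from_link_counts(n_nodes, positive, negative)`
constructor computes the topology quantities that follow from printed
node/link counts alone (positive percentage, density 2E/(n(n−1)),
average degree 2E/n). Note that published topology tables for such
networks are not always internally consistent with these standard
formulas (e.g. 173 links on 49 nodes gives density 0.147, not 0.141);
this package always reports the standard formulas.

## Synthetic communities (ground truth)

The generator emulates a 4-treatment × 3-replicate soil survey: 200 taxa
(100–500 supported), 2,000 reads/sample, one rooted phylogeny, and a
Brownian habitat-preference trait. Three regimes encode the processes
the classifier is supposed to recover.

**Phylogeny.** The default `otu_clusters` model is a Yule (pure-birth,
rate 1) backbone over n/2 clades whose tips are replaced by shallow
radiations (depth 0.03), emulating the two-scale shape of real OTU trees
— tight 97%-identity clusters on deep stems. This shape matters: the
nearest-taxon statistics draw their signal from the contrast between
tiny within-cluster and large between-cluster distances. On a plain Yule
tree (available as `model="yule"`) terminal branches average ~0.5 while
random nearest-neighbour distances are ~2.5, a contrast too weak for
|βNTI| > 2 at a few hundred taxa; a coalescent tree has fine-scale
structure but so skewed a null that βNTI is bounded above −2 (the
standardized score cannot exceed −μ_null/σ_null, and heavy-tailed
nearest-neighbour distributions push that ratio toward 1).

**Species pool.** Log-normal(0, 0.8) relative abundances shared by all
samples. Evenness is deliberately higher than field surveys: at a few
hundred taxa the central-limit averaging that real datasets get from
thousands of rare OTUs has to come from evenness instead, otherwise the
null distributions of the nearest-taxon statistics are dominated by a
handful of heavy taxa.

**Selection.** Sampling weight pool × exp(−(trait − optimum_g)²/2σ_env²)
with σ_env expressed in units of the realized trait sd (default 0.3) and
per-group optima at evenly spaced trait quantiles (override with
`group_optima`), times a per-replicate recruitment lottery: each taxon
establishes independently with probability 0.55 and receives a mild
log-normal(0, 0.3) abundance jitter. The filter confines every replicate
to the same clades; the lottery turns membership over *within* those
clades across the whole abundance range. Both ingredients are necessary:
without turnover, replicates share nearly all abundance mass and the
shared-shuffle null is blind (shared taxa contribute 0 to both observed
and null βMNTD); without the filter, turnover is phylogenetically
random. At the defaults, within-group pairs classify as homogeneous
selection in 75–92% of cases (seeds 7/11/23, 400 taxa), and pairs across
different optima show variable selection — ecologically correct, since
those pairs experience divergent selection.

**Neutral.** Each replicate's realized weights are a Dirichlet draw
centred on the pool with concentration 8,000 — demographic drift of a
finite local community. Pure multinomial read sampling alone would make
replicates far *more* similar than the richness/occupancy-preserving
Raup–Crick null expects, classifying every neutral pair as homogenizing
dispersal; finite-community drift is what places neutral pairs in the
drift band. The concentration was calibrated once so that RC_bray is
centred near 0 with the modal label drift and ≥ 90% of pairs inside
|βNTI| ≤ 2, robust across seeds.

**Dispersal limitation.** Each replicate mixes the shared pool with its
own log-normal(0, 2) perturbed copy at migration rate m (default 0.3;
m = 0.05 in the recovery tests). Divergence is phylogenetically random,
so |βNTI| stays ≤ 2 while RC_bray → 1. At m = 1 the regime collapses
onto the shared pool.

**Guild benchmark.** For network validation: 2 guilds × 10 taxa whose
abundance weights share a per-sample latent factor (association 1.5,
noise 0.3) plus 20 independent background taxa, 20 samples at depth
5,000. The planted guilds are recovered as modules with ARI 1.0 at the
tested seeds and all within-guild edges positive.

Stage seeds (tree, trait, communities, guilds) derive from the scenario
seed via fixed offsets, so any stage can be regenerated independently;
re-running a manifest reproduces every file byte-identically.

### What the generator does not emulate

Sequencing error, chimeras, PCR/primer bias, compositional artefacts of
relative-abundance correlation (no SparCC-style correction is applied),
soil-chemistry covariates, and realistic abundance skew (see above).
Passing the recovery tests therefore shows that the statistics respond
correctly to the *mechanisms* they target under clean conditions — not
that field data of this design would yield the same fractions.

## Problem sizes and numerical choices

Null-model defaults are 999 draws/permutations (floors at 99); the test
suite runs its calibration and recovery checks at 199 draws and the
acceptance script at 999. Calibration datasets are 200 taxa × 12
samples × depth 2,000; selection recovery uses 400 taxa, where the
scaled-down system has enough turnover taxa for the null to be
well-behaved. PCoA uses dense symmetric eigendecomposition. Tie bands:
1e-12 absolute on Bray–Curtis ranks, 1e-12 relative on null-sd
degeneracy. All randomness flows through explicit integer seeds and
`numpy.random.default_rng`.

## Known limitations

* βMPD / ses.comdist (basal phylogenetic turnover) is not implemented;
  the nearest-taxon family (βMNTD/βNTI) is the decision statistic.
* RC_bray's occupancy-weighted null is one of several published
  variants; alternative pool restrictions are out of scope.
* Correlation networks from ≤ 3 replicates are refused rather than
  approximated.
* The classifier treats each pair independently; no multiple-comparison
  control is applied to βNTI across pairs.
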