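"""Ensemble co-occurrence network inference for OTU tables.

The pipeline mirrors the CoNet ensemble recipe: keep dominant taxa
(mean relative abundance above a threshold), score every taxon pair with
Pearson, Spearman, and Bray-Curtis similarity on relative abundances,
attach permutation p-values per metric, merge them with Brown's method
(Fisher's chi-square generalized to dependent tests via the
Kost-McDermott covariance polynomial), correct with Benjamini-Hochberg,
and keep edges with |Spearman rho| above a magnitude gate and adjusted
p below a significance gate.  Topology reporting covers link counts and
signs, density, average degree, greedy-modularity modules, and
module-hub keystone taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from commeco.io import CountMatrix, ValidationError

METRICS = ("pearson_r", "spearman_rho", "bray_curtis_sim")


def filter_dominant(counts: CountMatrix, threshold: float = 0.005,
                    mode: str = "mean") -> CountMatrix:
    """Keep dominant taxa: mean relative abundance across samples above
    ``threshold`` (default 0.5%).  ``mode="min"`` instead requires the
    taxon to exceed the threshold in every sample."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    rel = counts.relative_abundance()
    if mode == "mean":
        keep = rel.mean(axis=0) > threshold
    elif mode == "min":
        keep = rel.min(axis=0) > threshold
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if not keep.any():
        raise ValidationError(
            f"no taxon exceeds relative abundance {threshold}; lower the threshold"
        )
    return counts.select_taxa(list(rel.columns[keep]))


# ---------------------------------------------------------------------------
# pairwise association metrics
# ---------------------------------------------------------------------------

def _rankdata_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _row_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between each row of A and the matching-index rows
    of B, all pairs: returns corr[i, j] = corr(A[i], B[j])."""
    n = A.shape[1]
    Az = (A - A.mean(axis=1, keepdims=True))
    Bz = (B - B.mean(axis=1, keepdims=True))
    Az /= np.sqrt((Az ** 2).sum(axis=1, keepdims=True))
    Bz /= np.sqrt((Bz ** 2).sum(axis=1, keepdims=True))
    return Az @ Bz.T


def _bray_curtis_sim_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """1 - Bray-Curtis between each row of A and each row of B."""
    num = np.abs(A[:, None, :] - B[None, :, :]).sum(axis=2)
    den = (A[:, None, :] + B[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(den > 0, num / den, 1.0)
    return 1.0 - bc


def _taxon_profiles(counts: CountMatrix) -> tuple[np.ndarray, list[str], list[str]]:
    """Relative-abundance profiles per taxon (taxa x samples); zero-variance
    taxa are excluded (their correlations are undefined)."""
    rel = counts.relative_abundance()
    X = rel.to_numpy().T
    variances = X.var(axis=1)
    keep = variances > 0
    excluded = [t for t, k in zip(rel.columns, keep) if not k]
    X = X[keep]
    taxa = [t for t, k in zip(rel.columns, keep) if k]
    return X, taxa, excluded


def pairwise_metrics(counts: CountMatrix) -> pd.DataFrame:
    """Pearson r, Spearman rho, and Bray-Curtis similarity for every
    unordered taxon pair, on relative-abundance profiles across samples.

    The returned frame carries the excluded (zero-variance) taxa in
    ``.attrs["excluded_taxa"]``.
    """
    if counts.shape[0] < 4:
        raise ValidationError("need >= 4 samples for pairwise correlations")
    X, taxa, excluded = _taxon_profiles(counts)
    if len(taxa) < 2:
        raise ValidationError("fewer than 2 taxa with nonzero variance")
    R = _row_correlations(X, X)
    Rho = _row_correlations(_rankdata_rows(X), _rankdata_rows(X))
    Sim = _bray_curtis_sim_cross(X, X)
    iu, ju = np.triu_indices(len(taxa), k=1)
    table = pd.DataFrame({
        "taxon_a": [taxa[i] for i in iu],
        "taxon_b": [taxa[j] for j in ju],
        "pearson_r": R[iu, ju],
        "spearman_rho": Rho[iu, ju],
        "bray_curtis_sim": Sim[iu, ju],
    })
    table.attrs["excluded_taxa"] = excluded
    return table


def permutation_pvalues(counts: CountMatrix, n_perm: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Permutation p-values per pair and metric.

    The null permutes one taxon's profile across samples; p = (1 +
    #{null at least as extreme as observed}) / (1 + n_perm).  Correlations
    are two-sided on |stat|; Bray-Curtis similarity is two-sided on the
    deviation from its null mean.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    X, taxa, _ = _taxon_profiles(counts)
    n_taxa, n_samples = X.shape
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_taxa, k=1)

    obs_r = _row_correlations(X, X)[iu, ju]
    Xr = _rankdata_rows(X)
    obs_rho = _row_correlations(Xr, Xr)[iu, ju]
    obs_sim = _bray_curtis_sim_cross(X, X)[iu, ju]

    exceed_r = np.zeros(len(iu))
    exceed_rho = np.zeros(len(iu))
    null_sim = np.empty((n_perm, len(iu)))
    for d in range(n_perm):
        perm = rng.permutation(n_samples)
        Xp = X[:, perm]
        exceed_r += np.abs(_row_correlations(X, Xp)[iu, ju]) >= np.abs(obs_r)
        exceed_rho += (np.abs(_row_correlations(Xr, Xr[:, perm])[iu, ju])
                       >= np.abs(obs_rho))
        null_sim[d] = _bray_curtis_sim_cross(X, Xp)[iu, ju]
    sim_center = null_sim.mean(axis=0)
    exceed_sim = (np.abs(null_sim - sim_center)
                  >= np.abs(obs_sim - sim_center)).sum(axis=0)

    return pd.DataFrame({
        "taxon_a": [taxa[i] for i in iu],
        "taxon_b": [taxa[j] for j in ju],
        "p_pearson": (1.0 + exceed_r) / (1.0 + n_perm),
        "p_spearman": (1.0 + exceed_rho) / (1.0 + n_perm),
        "p_bray_curtis": (1.0 + exceed_sim) / (1.0 + n_perm),
    })


# ---------------------------------------------------------------------------
# p-value merging and correction
# ---------------------------------------------------------------------------

def _kost_mcdermott_cov(rho: np.ndarray) -> np.ndarray:
    """Covariance of two -2 ln p statistics as a cubic in the correlation of
    the underlying test statistics (Kost & McDermott approximation)."""
    return 3.263 * rho + 0.710 * rho**2 + 0.027 * rho**3


def browns_merge(pvalues: np.ndarray,
                 metric_correlations: np.ndarray | None = None) -> np.ndarray:
    """Brown's method: combine dependent p-values via a scaled chi-square.

    ``pvalues`` is (n_tests, k); ``metric_correlations`` the k x k
    correlation matrix of the underlying statistics (identity -> Fisher's
    method exactly).  T = -2 sum ln p; E[T] = 2k; Var[T] = 4k +
    2 sum_{i<j} cov_ij; merged p is the upper tail of c * chi2_df with
    c = Var / (2E) and df = 2 E^2 / Var evaluated at T.
    """
    P = np.atleast_2d(np.asarray(pvalues, dtype=float))
    if P.shape[1] < 2:
        raise ValidationError("Brown's method needs >= 2 p-values per test")
    if np.any(P <= 0):
        raise ValidationError("p-values must be > 0")
    if np.any(P > 1):
        raise ValidationError("p-values must be <= 1")
    k = P.shape[1]
    if metric_correlations is None:
        C = np.eye(k)
    else:
        C = np.asarray(metric_correlations, dtype=float)
        if C.shape != (k, k):
            raise ValidationError("metric_correlations must be k x k")
    iu, ju = np.triu_indices(k, 1)
    expected = 2.0 * k
    variance = 4.0 * k + 2.0 * _kost_mcdermott_cov(C[iu, ju]).sum()
    c = variance / (2.0 * expected)
    df = 2.0 * expected**2 / variance
    T = -2.0 * np.log(P).sum(axis=1)
    return stats.chi2.sf(T / c, df)


def metric_correlation_matrix(edge_table: pd.DataFrame) -> np.ndarray:
    """Empirical correlation of the three association statistics across all
    scored pairs — the dependence estimate Brown's method needs."""
    M = edge_table.loc[:, list(METRICS)].to_numpy(dtype=float)
    M = M[np.isfinite(M).all(axis=1)]
    if M.shape[0] < 3:
        return np.eye(len(METRICS))
    return np.corrcoef(M.T)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def edge_table(counts: CountMatrix, n_perm: int = 1000,
               seed: int = 0) -> pd.DataFrame:
    """Full ensemble edge table: metrics, per-metric permutation p, Brown's
    merged p, BH q, and the edge sign (sign of Spearman rho)."""
    scores = pairwise_metrics(counts)
    pvals = permutation_pvalues(counts, n_perm=n_perm, seed=seed)
    table = scores.merge(pvals, on=["taxon_a", "taxon_b"], validate="1:1")
    C = metric_correlation_matrix(table)
    table["merged_p"] = browns_merge(
        table[["p_pearson", "p_spearman", "p_bray_curtis"]].to_numpy(), C
    )
    table["q"] = bh_adjust(table["merged_p"].to_numpy())
    table["sign"] = np.where(table["spearman_rho"] >= 0, "positive", "negative")
    table.attrs["excluded_taxa"] = scores.attrs["excluded_taxa"]
    return table


# ---------------------------------------------------------------------------
# graph construction and topology
# ---------------------------------------------------------------------------

def build_network(edges: pd.DataFrame, rho_threshold: float = 0.6,
                  q_threshold: float = 0.01) -> nx.Graph:
    """Keep an edge iff |Spearman rho| > rho_threshold and q < q_threshold;
    the sign comes from rho; taxa with no surviving edge are absent."""
    if not 0.0 <= rho_threshold < 1.0:
        raise ValidationError("rho_threshold must lie in [0, 1)")
    if not 0.0 < q_threshold <= 1.0:
        raise ValidationError("q_threshold must lie in (0, 1]")
    keep = (edges["spearman_rho"].abs() > rho_threshold) & \
           (edges["q"] < q_threshold)
    G = nx.Graph()
    for _, row in edges[keep].iterrows():
        G.add_edge(row["taxon_a"], row["taxon_b"],
                   sign=row["sign"], spearman_rho=float(row["spearman_rho"]),
                   q=float(row["q"]))
    return G


def detect_modules(graph: nx.Graph, seed: int = 0) -> tuple[dict[str, int], float]:
    """Greedy modularity maximization; returns node -> module id and Q.

    The algorithm is deterministic; ``seed`` is accepted for interface
    stability."""
    if graph.number_of_nodes() == 0:
        return {}, 0.0
    communities = nx.community.greedy_modularity_communities(graph)
    q = nx.community.modularity(graph, communities)
    partition = {}
    for i, comm in enumerate(communities):
        for node in comm:
            partition[node] = i
    return partition, float(q)


def keystone_taxa(graph: nx.Graph, partition: dict[str, int],
                  top_k: int = 2) -> list[str]:
    """Module hubs: the nodes with the highest within-module degree, top_k
    over the whole network (ties broken by name for determinism)."""
    scores = []
    for node in graph.nodes:
        within = sum(1 for nb in graph.neighbors(node)
                     if partition.get(nb) == partition.get(node))
        scores.append((-within, node))
    return [name for _, name in sorted(scores)[:top_k]]


@dataclass
class NetworkSummary:
    """Topology report: link counts/signs, density 2E/(n(n-1)), average
    degree 2E/n, modularity, large-module count, and keystone taxa."""

    n_nodes: int
    total_links: int
    positive_links: int
    negative_links: int
    pct_positive: float
    density: float
    average_degree: float
    modularity: float = float("nan")
    n_modules: int = 0
    keystones: list[str] = field(default_factory=list)

    @classmethod
    def from_link_counts(cls, n_nodes: int, positive_links: int,
                         negative_links: int) -> "NetworkSummary":
        """Summary derivable from printed node/link counts alone (the
        modularity fields stay unset)."""
        total = positive_links + negative_links
        if total <= 0 or n_nodes <= 1:
            raise ValidationError("need positive link and node counts")
        return cls(
            n_nodes=n_nodes,
            total_links=total,
            positive_links=positive_links,
            negative_links=negative_links,
            pct_positive=100.0 * positive_links / total,
            density=2.0 * total / (n_nodes * (n_nodes - 1)),
            average_degree=2.0 * total / n_nodes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_nodes": self.n_nodes, "total_links": self.total_links,
            "positive_links": self.positive_links,
            "negative_links": self.negative_links,
            "pct_positive": self.pct_positive, "density": self.density,
            "average_degree": self.average_degree,
            "modularity": self.modularity, "n_modules": self.n_modules,
            "keystones": ";".join(self.keystones),
        }])


def topology(graph: nx.Graph, seed: int = 0, top_k: int = 2,
             min_module_size: int = 3) -> NetworkSummary:
    """Table-style topology summary of a signed co-occurrence graph."""
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        return NetworkSummary(0, 0, 0, 0, float("nan"), 0.0, 0.0, 0.0, 0, [])
    pos = sum(1 for _, _, d in graph.edges(data=True)
              if d.get("sign") == "positive")
    neg = e - pos
    partition, q = detect_modules(graph, seed=seed)
    sizes = pd.Series(partition).value_counts()
    return NetworkSummary(
        n_nodes=n, total_links=e, positive_links=pos, negative_links=neg,
        pct_positive=100.0 * pos / e if e else float("nan"),
        density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        average_degree=2.0 * e / n,
        modularity=q,
        n_modules=int((sizes >= min_module_size).sum()),
        keystones=keystone_taxa(graph, partition, top_k=top_k),
    )


def infer_network(counts: CountMatrix, threshold: float = 0.005,
                  rho_threshold: float = 0.6, q_threshold: float = 0.01,
                  n_perm: int = 1000, seed: int = 0,
                  ) -> tuple[pd.DataFrame, nx.Graph, NetworkSummary]:
    """Dominant-taxon filter -> ensemble edge table -> thresholded graph ->
    topology summary, in one call."""
    dominant = filter_dominant(counts, threshold=threshold)
    edges = edge_table(dominant, n_perm=n_perm, seed=seed)
    graph = build_network(edges, rho_threshold=rho_threshold,
                          q_threshold=q_threshold)
    return edges, graph, topology(graph, seed=seed)
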