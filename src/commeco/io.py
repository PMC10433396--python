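"""Readers, writers, and validated containers for the pipeline's file formats.

Count tables, sample metadata, and all tabular results are plain TSV
(tab-separated, UTF-8, "." decimal, no quoting; first column is the id
column; a leading "#OTU ID" header cell is tolerated).  Trees are
single-tree Newick with branch lengths.  Networks are exported as SIF
edge lists and GraphML.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode


class ValidationError(ValueError):
    """A malformed input: every validation failure raises this, nothing is coerced."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sample x taxon table of non-negative integer read counts.

    Invariants enforced at construction: unique sample and taxon ids, no
    negative entries, every sample total > 0.  Relative abundances are
    always derived on the fly (`relative_abundance`), never stored.
    """

    data: pd.DataFrame  # rows = samples, columns = taxa, dtype int

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise ValidationError(f"non-numeric counts in columns: {list(bad)}")
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if np.any(arr != np.floor(arr)):
            r, c = np.argwhere(arr != np.floor(arr))[0]
            raise ValidationError(
                f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        totals = arr.sum(axis=1)
        if np.any(totals == 0):
            empty = df.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")
        self.data = df.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        return self.data.div(self.data.sum(axis=1), axis=0)

    def select_taxa(self, taxa: list[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(taxa)])

    def select_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(samples), :])


@dataclass
class SampleGroups:
    """Mapping of sample id to treatment-group label."""

    assignments: pd.Series  # index = sample ids, values = group labels

    def __post_init__(self) -> None:
        s = self.assignments
        if s.index.duplicated().any():
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        self.assignments = s.astype(str)
        self.assignments.index = self.assignments.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments:
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return list(self.assignments.index[self.assignments == group])

    def group_of(self, sample: str) -> str:
        return str(self.assignments.loc[sample])

    def check_counts(self, counts: CountMatrix, min_per_group: int = 2) -> None:
        """Every count-table sample must be assigned; groups need >=2 members
        for within-group pairwise statistics."""
        missing = [s for s in counts.sample_ids if s not in self.assignments.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        sub = self.assignments.loc[counts.sample_ids]
        small = sub.value_counts()
        small = small[small < min_per_group]
        if len(small):
            raise ValidationError(
                f"groups with fewer than {min_per_group} samples: {list(small.index)}"
            )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | os.PathLike,
                     orientation: str = "samples_as_rows") -> CountMatrix:
    """Read a TSV OTU table and return a validated samples x taxa CountMatrix.

    Parameters
    ----------
    orientation :
        "samples_as_rows" (default) or "taxa_as_rows" (BIOM-TSV convention,
        e.g. a "#OTU ID" first header cell); the result is always samples x
        taxa.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "taxa_as_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return CountMatrix(df)


def write_count_table(counts: CountMatrix, path: str | os.PathLike,
                      orientation: str = "samples_as_rows") -> None:
    df = counts.data if orientation == "samples_as_rows" else counts.data.T
    label = "sample_id" if orientation == "samples_as_rows" else "#OTU ID"
    df.to_csv(path, sep="\t", index_label=label)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen, dups = set(), set()
        for t in tips:
            (dups if t in seen else seen).add(t)
        raise ValidationError(f"duplicate tip labels: {sorted(dups)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"missing branch length on node {node.name or '<internal>'}; "
                "phylogenetic null models require branch lengths"
            )
        if node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} on node "
                f"{node.name or '<internal>'}"
            )
    if tree.length is None:
        tree.length = 0.0
    return tree


def read_newick(path: str | os.PathLike) -> TreeNode:
    """Read and validate a single rooted Newick tree with branch lengths."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ValidationError(f"cannot parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    tree.write(str(path), format="newick")


def align_counts_to_tree(counts: CountMatrix, tree: TreeNode,
                         prune: bool = False) -> CountMatrix:
    """Check that every count-table taxon is a tree tip.

    Missing taxa are a hard error by default because silently dropping them
    changes every phylogenetic statistic downstream; pass ``prune=True`` to
    drop them explicitly.
    """
    tips = {t.name for t in tree.tips()}
    missing = [t for t in counts.taxon_ids if t not in tips]
    if not missing:
        return counts
    if not prune:
        raise ValidationError(
            f"{len(missing)} taxa absent from the tree (e.g. {missing[:5]}); "
            "rerun with prune=True to drop them explicitly"
        )
    keep = [t for t in counts.taxon_ids if t in tips]
    return counts.select_taxa(keep)


# ---------------------------------------------------------------------------
# metadata, edge lists, generic tables
# ---------------------------------------------------------------------------

def read_metadata(path: str | os.PathLike) -> SampleGroups:
    """Read a sample metadata TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"metadata {path} lacks required column {col!r}")
    return SampleGroups(pd.Series(df["group"].values, index=df["sample_id"].values))


def write_metadata(groups: SampleGroups, path: str | os.PathLike) -> None:
    pd.DataFrame({
        "sample_id": groups.assignments.index,
        "group": groups.assignments.values,
    }).to_csv(path, sep="\t", index=False)


def write_edge_list(edges: list[tuple[str, str, str]], path: str | os.PathLike) -> None:
    """Write edges as SIF: one ``taxonA <sign> taxonB`` row per edge,
    sign in {pos, neg}.  An empty edge set yields a valid empty file."""
    sign_map = {"positive": "pos", "negative": "neg", "pos": "pos", "neg": "neg"}
    with open(path, "w", encoding="utf-8") as fh:
        for a, sign, b in edges:
            if sign not in sign_map:
                raise ValidationError(f"unknown edge sign {sign!r}")
            fh.write(f"{a}\t{sign_map[sign]}\t{b}\n")


def write_table(table: pd.DataFrame, path: str | os.PathLike,
                index_label: str | None = None) -> None:
    """Write any tabular result as TSV with a deterministic column order."""
    table.to_csv(path, sep="\t", index=index_label is not None,
                 index_label=index_label, float_format="%.10g")
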