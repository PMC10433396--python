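"""Shared fixtures: hand-built trees and the session-scoped synthetic
datasets used by the null-model calibration and recovery tests.

The heavy fixtures run the full pairwise assembly inference once per
session at 199 null draws (a deliberate scale-down from the 999-draw
analysis default; the statistics stabilize well before that)."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from commeco.assembly import pairwise_assembly
from commeco.io import CountMatrix, SampleGroups
from commeco.synthetic import SyntheticScenario, simulate_dataset

N_NULL_TEST = 199
ASSEMBLY_SEED = 5


@pytest.fixture
def hand_tree() -> TreeNode:
    """3-tip tree with patristic d(A,B)=2, d(A,C)=d(B,C)=4."""
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def five_tip_tree() -> TreeNode:
    return TreeNode.read(["((A:0.5,B:0.5):1.5,((C:0.3,D:0.3):0.7,E:1.0):1.0);"])


@pytest.fixture
def star_tree() -> TreeNode:
    # star-like: rooted binary shape, but all pairwise tip distances equal 2
    return TreeNode.read(["((A:1,B:1):0,(C:1,D:1):0);"])


@pytest.fixture
def toy_counts() -> CountMatrix:
    return CountMatrix(pd.DataFrame(
        [[5, 3, 0, 1, 0], [0, 2, 4, 1, 1], [1, 0, 0, 6, 3]],
        index=["s1", "s2", "s3"], columns=list("ABCDE"),
    ))


@pytest.fixture(scope="session")
def neutral_assembly():
    ds = simulate_dataset(SyntheticScenario(regime="neutral", seed=7))
    pairs = pairwise_assembly(ds.counts, ds.tree, ds.groups,
                              n_null=N_NULL_TEST, seed=ASSEMBLY_SEED)
    return ds, pairs


@pytest.fixture(scope="session")
def selection_assembly():
    ds = simulate_dataset(SyntheticScenario(regime="selection", n_taxa=400,
                                            seed=7))
    pairs = pairwise_assembly(ds.counts, ds.tree, ds.groups,
                              n_null=N_NULL_TEST, seed=ASSEMBLY_SEED)
    return ds, pairs


@pytest.fixture(scope="session")
def dispersal_assembly():
    ds = simulate_dataset(SyntheticScenario(regime="dispersal_limited",
                                            migration=0.05, seed=7))
    pairs = pairwise_assembly(ds.counts, ds.tree, ds.groups,
                              n_null=N_NULL_TEST, seed=ASSEMBLY_SEED)
    return ds, pairs
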