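"""Phylogenetic null models: brute-force oracles, degenerate cases,
classifier rules, and Monte-Carlo calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from commeco import assembly as asm
from commeco.io import CountMatrix, SampleGroups, ValidationError
from commeco.synthetic import simulate_tree


def brute_force_mntd(abund, dist, weighted):
    present = [i for i, a in enumerate(abund) if a > 0]
    total = sum(abund[i] for i in present)
    out = 0.0
    for i in present:
        nearest = min(dist[i][j] for j in present if j != i)
        w = abund[i] / total if weighted else 1.0 / len(present)
        out += w * nearest
    return out


def brute_force_beta_mntd(a, b, dist):
    pa = [i for i, v in enumerate(a) if v > 0]
    pb = [j for j, v in enumerate(b) if v > 0]
    ta, tb = sum(a[i] for i in pa), sum(b[j] for j in pb)
    left = sum(a[i] / ta * min(dist[i][j] for j in pb) for i in pa)
    right = sum(b[j] / tb * min(dist[i][j] for i in pa) for j in pb)
    return 0.5 * (left + right)


class TestMntd:
    def test_two_taxa_is_their_distance(self, hand_tree):
        D = asm.patristic_matrix(hand_tree, ["A", "B", "C"])
        assert asm.mntd([1, 0, 9], D) == pytest.approx(4.0)  # A vs C
        assert asm.mntd([5, 1, 0], D) == pytest.approx(2.0)  # A vs B

    def test_star_tree_symmetry(self, star_tree):
        D = asm.patristic_matrix(star_tree, list("ABCD"))
        for abund in ([1, 1, 1, 1], [7, 1, 2, 0], [1, 0, 5, 3]):
            assert asm.mntd(abund, D) == pytest.approx(2.0)

    def test_matches_brute_force(self, five_tip_tree):
        taxa = list("ABCDE")
        D = asm.patristic_matrix(five_tip_tree, taxa)
        rng = np.random.default_rng(0)
        for _ in range(20):
            abund = rng.integers(0, 5, size=5)
            if (abund > 0).sum() < 2:
                continue
            for weighted in (True, False):
                assert asm.mntd(abund, D, weighted) == pytest.approx(
                    brute_force_mntd(abund, D, weighted), abs=1e-12)

    def test_fewer_than_two_taxa_rejected(self, hand_tree):
        D = asm.patristic_matrix(hand_tree, ["A", "B", "C"])
        with pytest.raises(ValidationError):
            asm.mntd([3, 0, 0], D)


class TestSesMntd:
    def test_full_community_null_is_degenerate(self, five_tip_tree):
        cm = CountMatrix(pd.DataFrame([[1, 2, 3, 4, 5], [2, 2, 2, 2, 2]],
                                      index=["s1", "s2"],
                                      columns=list("ABCDE")))
        res = asm.ses_mntd(cm, five_tip_tree, n_null=99, seed=0,
                          abundance_weighted=False)
        assert res.table["undefined"].all()
        assert res.table["ses_mntd"].isna().all()

    def test_deterministic_for_seed(self, five_tip_tree):
        cm = CountMatrix(pd.DataFrame([[1, 2, 0, 4, 0], [0, 2, 2, 0, 2]],
                                      index=["s1", "s2"],
                                      columns=list("ABCDE")))
        a = asm.ses_mntd(cm, five_tip_tree, n_null=99, seed=42).table
        b = asm.ses_mntd(cm, five_tip_tree, n_null=99, seed=42).table
        pd.testing.assert_frame_equal(a, b)

    def test_ses_near_standard_normal_under_null(self):
        """Random communities on random trees: ses.MNTD should be roughly
        standard normal (Monte-Carlo over 20 trees x 10 communities)."""
        rng = np.random.default_rng(1)
        ses_values = []
        for t in range(20):
            tree = simulate_tree(12, seed=100 + t, model="yule")
            taxa = [tip.name for tip in tree.tips()]
            rows = []
            while len(rows) < 10:
                row = (rng.random(12) < 0.5).astype(int) * rng.integers(
                    1, 10, size=12)
                if 2 <= (row > 0).sum() < 12:
                    rows.append(row)
            cm = CountMatrix(pd.DataFrame(
                rows, index=[f"c{i}" for i in range(10)], columns=taxa))
            res = asm.ses_mntd(cm, tree, n_null=199, seed=t)
            ses_values.extend(res.table["ses_mntd"].dropna())
        ses_values = np.array(ses_values)
        assert abs(ses_values.mean()) < 0.15
        assert 0.75 < ses_values.std() < 1.25


class TestBetaMntd:
    def test_identical_communities_are_zero(self, five_tip_tree):
        cm = CountMatrix(pd.DataFrame([[1, 2, 0, 4, 0], [1, 2, 0, 4, 0]],
                                      index=["s1", "s2"],
                                      columns=list("ABCDE")))
        dm = asm.beta_mntd(cm, five_tip_tree)
        assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_singleton_communities(self, hand_tree):
        cm = CountMatrix(pd.DataFrame([[9, 0, 0], [0, 0, 4]],
                                      index=["s1", "s2"],
                                      columns=["A", "B", "C"]))
        assert asm.beta_mntd(cm, hand_tree)["s1", "s2"] == pytest.approx(4.0)

    def test_matches_brute_force(self, five_tip_tree):
        cm = CountMatrix(pd.DataFrame([[3, 0, 1, 0, 2], [1, 1, 0, 0, 0],
                                       [0, 2, 0, 4, 1]],
                                      index=["s1", "s2", "s3"],
                                      columns=list("ABCDE")))
        D = asm.patristic_matrix(five_tip_tree, list("ABCDE"))
        dm = asm.beta_mntd(cm, five_tip_tree)
        X = cm.counts()
        for i, j in itertools.combinations(range(3), 2):
            expected = brute_force_beta_mntd(X[i], X[j], D)
            assert dm[cm.sample_ids[i], cm.sample_ids[j]] == pytest.approx(
                expected, abs=1e-12)


class TestBetaNti:
    def test_observed_invariant_to_orderings(self, five_tip_tree):
        cm = CountMatrix(pd.DataFrame([[3, 0, 1, 0, 2], [1, 1, 0, 2, 0],
                                       [0, 2, 0, 4, 1]],
                                      index=["s1", "s2", "s3"],
                                      columns=list("ABCDE")))
        shuffled = CountMatrix(cm.data[list("DBACE")].loc[["s3", "s1", "s2"]])
        a = asm.beta_mntd(cm, five_tip_tree)
        b = asm.beta_mntd(shuffled, five_tip_tree)
        for i, j in itertools.combinations(cm.sample_ids, 2):
            assert a[i, j] == pytest.approx(b[i, j], abs=1e-12)
        # betaNTI itself is order-invariant in distribution; at finite
        # null size the estimates agree within Monte-Carlo error
        r1 = asm.beta_nti(cm, five_tip_tree, n_null=399, seed=0)
        r2 = asm.beta_nti(shuffled, five_tip_tree, n_null=399, seed=1)
        for i, j in itertools.combinations(cm.sample_ids, 2):
            assert r1.bnti.loc[i, j] == pytest.approx(r2.bnti.loc[i, j],
                                                      abs=0.75)

    def test_identical_communities_flagged(self, five_tip_tree):
        cm = CountMatrix(pd.DataFrame([[1, 2, 0, 4, 0], [1, 2, 0, 4, 0],
                                       [0, 1, 1, 0, 3]],
                                      index=["s1", "s2", "s3"],
                                      columns=list("ABCDE")))
        with pytest.warns(UserWarning, match="degenerate"):
            res = asm.beta_nti(cm, five_tip_tree, n_null=99, seed=0)
        assert np.isnan(res.bnti.loc["s1", "s2"])
        assert res.undefined.loc["s1", "s2"]
        assert not res.undefined.loc["s1", "s3"]

    def test_deterministic_for_seed(self, neutral_assembly):
        ds, _ = neutral_assembly
        sub = CountMatrix(ds.counts.data.iloc[:4])
        a = asm.beta_nti(sub, ds.tree, n_null=99, seed=3).bnti
        b = asm.beta_nti(sub, ds.tree, n_null=99, seed=3).bnti
        pd.testing.assert_frame_equal(a, b)


class TestRcBray:
    def _exact_rc(self, X, obs_bc, n_taxa):
        """Exhaustive enumeration of the Raup-Crick null for a 2-sample
        metacommunity: successive occupancy-weighted subset draws, then all
        multinomial allocations of the extra reads."""
        occupancy = (X > 0).sum(axis=0).astype(float)
        pool = X.sum(axis=0).astype(float)

        def subset_probs(richness):
            p = occupancy / occupancy.sum()
            probs = {}
            for order in itertools.permutations(range(n_taxa), richness):
                pr, rem = 1.0, 1.0
                for t in order:
                    if p[t] == 0:
                        pr = 0.0
                        break
                    pr *= p[t] / rem
                    rem -= p[t]
                if pr > 0:
                    key = tuple(sorted(order))
                    probs[key] = probs.get(key, 0.0) + pr
            return probs

        def allocations(subset, depth):
            extra = depth - len(subset)
            w = pool[list(subset)] / pool[list(subset)].sum()
            out = {}
            for combo in itertools.product(range(extra + 1),
                                           repeat=len(subset)):
                if sum(combo) != extra:
                    continue
                pr = (math.factorial(extra) /
                      np.prod([math.factorial(c) for c in combo]) *
                      np.prod([wi**c for wi, c in zip(w, combo)]))
                vec = np.zeros(n_taxa)
                for t, c in zip(subset, combo):
                    vec[t] = 1 + c
                out[tuple(vec)] = out.get(tuple(vec), 0.0) + pr
            return out

        states = []
        for s in range(2):
            richness, depth = int((X[s] > 0).sum()), int(X[s].sum())
            dist = {}
            for subset, p_sub in subset_probs(richness).items():
                for vec, p_all in allocations(subset, depth).items():
                    dist[vec] = dist.get(vec, 0.0) + p_sub * p_all
            states.append(dist)

        below = ties = 0.0
        for va, pa in states[0].items():
            for vb, pb in states[1].items():
                a, b = np.array(va), np.array(vb)
                bc = np.abs(a - b).sum() / (a + b).sum()
                if bc < obs_bc - 1e-12:
                    below += pa * pb
                elif abs(bc - obs_bc) <= 1e-12:
                    ties += pa * pb
        return 2.0 * (below + 0.5 * ties - 0.5)

    def test_matches_exhaustive_enumeration(self):
        X = np.array([[2, 1, 0, 1], [0, 1, 1, 2]])
        cm = CountMatrix(pd.DataFrame(X, index=["s1", "s2"],
                                      columns=list("ABCD")))
        obs_bc = np.abs(X[0] - X[1]).sum() / (X[0] + X[1]).sum()
        exact = self._exact_rc(X, obs_bc, 4)
        mc = asm.rc_bray(cm, n_null=999, seed=0).loc["s1", "s2"]
        assert mc == pytest.approx(exact, abs=0.05)

    def test_boundaries(self):
        # identical samples: observed BC = 0, below every null draw
        same = CountMatrix(pd.DataFrame([[5, 3, 2, 1], [5, 3, 2, 1]],
                                        index=["s1", "s2"],
                                        columns=list("ABCD")))
        # null draws occasionally coincide exactly (tie at BC = 0), so the
        # estimate sits at -1 up to the half-weighted tie mass
        rc_same = asm.rc_bray(same, n_null=199, seed=1).loc["s1", "s2"]
        assert -1.0 <= rc_same <= -0.98
        # disjoint samples: observed BC = 1, above (or tying) every null
        # disjoint samples: observed BC = 1 >= every null; null subsets are
        # themselves disjoint (tying at BC = 1, half weight) about 1/6 of
        # the time here, so the estimate sits near 2*(5/6 + 1/12 - 1/2)
        disjoint = CountMatrix(pd.DataFrame(
            [[50, 30, 0, 0], [0, 0, 40, 40]],
            index=["s1", "s2"], columns=list("ABCD")))
        assert asm.rc_bray(disjoint, n_null=199, seed=1).loc["s1", "s2"] > 0.75

    def test_single_taxon_metacommunity_rejected(self):
        cm = CountMatrix(pd.DataFrame([[3], [5]], index=["s1", "s2"],
                                      columns=["A"]))
        with pytest.raises(ValidationError):
            asm.rc_bray(cm, n_null=99)


class TestClassifier:
    @pytest.mark.parametrize("bnti, rc, expected", [
        (-3.1, 0.2, "homogeneous_selection"),
        (2.5, -0.3, "variable_selection"),
        (1.0, 0.99, "dispersal_limitation"),
        (-1.0, -0.99, "homogenizing_dispersal"),
        (0.0, 0.0, "drift"),
    ])
    def test_paper_rules(self, bnti, rc, expected):
        assert asm.classify_assembly(bnti, rc) == expected

    def test_undefined_bnti_rejected(self):
        with pytest.raises(ValidationError):
            asm.classify_assembly(float("nan"), 0.0)

    def test_thresholds_are_strict(self):
        # exactly-at-threshold values are not deterministic / not dispersal
        assert asm.classify_assembly(2.0, 0.0) == "drift"
        assert asm.classify_assembly(-2.0, 0.95) == "drift"
        assert asm.classify_assembly(0.0, -0.95) == "drift"


class TestSummaries:
    def _pairs(self, labels, contexts=None):
        n = len(labels)
        return pd.DataFrame({
            "sample_i": [f"a{i}" for i in range(n)],
            "sample_j": [f"b{i}" for i in range(n)],
            "beta_mntd_obs": 0.0, "beta_nti": 0.0, "rc_bray": 0.0,
            "process": labels,
            "group_context": contexts or ["overall"] * n,
        })

    def test_58_of_66_deterministic(self):
        labels = (["homogeneous_selection"] * 58 + ["drift"] * 5 +
                  ["dispersal_limitation"] * 2 + ["homogenizing_dispersal"])
        summary = asm.summarize_processes(self._pairs(labels))
        assert summary.loc[0, "deterministic_fraction"] == pytest.approx(
            0.8788, abs=5e-5)
        assert summary.loc[0, "stochastic_fraction"] == pytest.approx(
            0.1212, abs=5e-5)

    def test_single_label_saturates(self):
        summary = asm.summarize_processes(self._pairs(["drift"] * 10))
        assert summary.loc[0, "frac_drift"] == 1.0
        assert summary.loc[0, "deterministic_fraction"] == 0.0

    def test_fractions_sum_to_one(self, neutral_assembly):
        _, pairs = neutral_assembly
        summary = asm.summarize_processes(pairs, scope="within_group")
        fracs = summary[[f"frac_{p}" for p in asm.PROCESS_LABELS]].sum(axis=1)
        assert np.allclose(fracs, 1.0, atol=1e-12)
        assert np.allclose(summary["deterministic_fraction"]
                           + summary["stochastic_fraction"], 1.0)

    def test_empty_scope_rejected(self):
        with pytest.raises(ValidationError):
            asm.summarize_processes(self._pairs([None]))


class TestMantel:
    def _random_dm(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 3))
        from scipy.spatial.distance import pdist, squareform
        return DistanceMatrix(squareform(pdist(pts)),
                              ids=[f"s{i}" for i in range(n)])

    def test_perfect_correlation(self):
        dm1 = self._random_dm(12, 0)
        dm2 = DistanceMatrix(2.0 * dm1.data, ids=dm1.ids)
        r, p = asm.mantel(dm1, dm2, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 1000)

    def test_mismatched_ids_rejected(self):
        dm1 = self._random_dm(5, 0)
        dm2 = DistanceMatrix(dm1.data, ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            asm.mantel(dm1, dm2)

    def test_p_uniform_under_independence(self):
        """With unrelated matrices the permutation p-value is uniform on its
        achievable grid (KS over 100 simulations)."""
        pvals = []
        for rep in range(100):
            dm1 = self._random_dm(7, 2 * rep)
            dm2 = self._random_dm(7, 2 * rep + 1)
            _, p = asm.mantel(dm1, dm2, n_perm=99, seed=rep)
            pvals.append(p)
        stat = stats.kstest(pvals, "uniform").pvalue
        assert stat > 0.01
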