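"""Phylogenetic-signal statistics against independent oracles."""

import numpy as np
import pytest

from fpdemog._rng import substream
from fpdemog.distance import DistanceMatrix
from fpdemog.signal import (
    blombergs_K,
    fritz_purvis_D,
    mantel_test,
    phylo_vcv,
    simulate_bm,
)
from fpdemog.tree import PhyloTree, simulate_phylogeny

BALANCED_8 = (
    "((((T1_a:1,T2_a:1):1,(T3_a:1,T4_a:1):1):1,"
    "((T5_a:1,T6_a:1):1,(T7_a:1,T8_a:1):1):1):0.0);"
)


class TestBlombergsK:
    def test_four_tip_matrix_algebra_oracle(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1); C written out by hand
        t = PhyloTree.from_newick("((A_a:1,B_b:1):1,(C_c:1,D_d:1):1);")
        trait = {"A_a": 1.0, "B_b": 2.0, "C_c": 4.0, "D_d": 7.0}
        labels, C = phylo_vcv(t)
        C_hand = {
            ("A_a", "A_a"): 2, ("B_b", "B_b"): 2, ("C_c", "C_c"): 2,
            ("D_d", "D_d"): 2, ("A_a", "B_b"): 1, ("C_c", "D_d"): 1,
            ("A_a", "C_c"): 0, ("A_a", "D_d"): 0, ("B_b", "C_c"): 0,
            ("B_b", "D_d"): 0,
        }
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                want = C_hand.get((a, b), C_hand.get((b, a)))
                assert C[i, j] == pytest.approx(want)
        # brute-force K from the definition, independent matrix algebra
        x = np.array([trait[lab] for lab in labels])
        n = 4
        Ci = np.linalg.inv(C)
        one = np.ones(n)
        ahat = (one @ Ci @ x) / (one @ Ci @ one)
        mse0 = ((x - ahat) ** 2).sum() / (n - 1)
        mse = ((x - ahat) @ Ci @ (x - ahat)) / (n - 1)
        expected = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
        K_hand = (mse0 / mse) / expected
        res = blombergs_K(t, trait, n_perm=99, seed=0)
        assert res.value == pytest.approx(K_hand, rel=1e-12)

    def test_matches_external_reference_value(self):
        # frozen reference: phytools::phylosig on this exact tree + trait
        # gives K = 1.4058840324 (permutation p ~ 0.0075)
        t = simulate_phylogeny(10, seed=42)
        labels, x = simulate_bm(t, substream(123, "oracle"), 1)
        trait = dict(zip(labels, x[:, 0]))
        res = blombergs_K(t, trait, n_perm=999, seed=5)
        assert res.value == pytest.approx(1.4058840324, abs=1e-8)
        assert res.p_value < 0.05

    def test_constant_trait_rejected(self, yule_tree_50):
        trait = {lab: 1.0 for lab in yule_tree_50.tip_labels}
        with pytest.raises(ValueError, match="constant"):
            blombergs_K(yule_tree_50, trait)

    def test_deterministic_p_value(self, yule_tree_50):
        labels, x = simulate_bm(yule_tree_50, substream(7, "t"), 1)
        trait = dict(zip(labels, x[:, 0]))
        a = blombergs_K(yule_tree_50, trait, n_perm=199, seed=3)
        b = blombergs_K(yule_tree_50, trait, n_perm=199, seed=3)
        assert (a.value, a.p_value) == (b.value, b.p_value)

    def test_bm_mean_near_one_small_batch(self):
        # fuller calibration lives in the acceptance suite
        vals = []
        for rep in range(60):
            t = simulate_phylogeny(50, seed=1000 + rep)
            labels, x = simulate_bm(t, substream(rep, "bm"), 1)
            vals.append(blombergs_K(t, dict(zip(labels, x[:, 0])),
                                    n_perm=1, seed=0).value)
        assert 0.8 < float(np.mean(vals)) < 1.2


class TestFritzPurvisD:
    def test_clade_clustered_trait_negative_D(self):
        t = PhyloTree.from_newick(BALANCED_8)
        trait = {f"T{i}_a": int(i <= 4) for i in range(1, 9)}
        res = fritz_purvis_D(t, trait, n_sim=500, seed=1)
        assert res.value < 0

    def test_brute_force_sum_of_changes(self):
        # hand tally on the balanced tree: all cherries and both
        # 4-clades are monomorphic (no change); only the root edge pair
        # contributes |1-0.5| + |0-0.5| = 1
        from fpdemog.signal import _sum_state_changes, _tree_arrays

        t = PhyloTree.from_newick(BALANCED_8)
        labels, order, n_total = _tree_arrays(t)
        obs = np.array([float(int(lab[1] in "1234")) for lab in labels])
        total = _sum_state_changes(obs[:, None], order, n_total)[0]
        assert total == pytest.approx(1.0)

    def test_shuffled_trait_D_near_one_small_batch(self):
        rng = np.random.default_rng(0)
        vals = []
        for rep in range(40):
            t = simulate_phylogeny(50, seed=2000 + rep)
            states = np.zeros(50)
            states[rng.choice(50, 25, replace=False)] = 1
            trait = dict(zip(t.tip_labels, states.astype(int)))
            vals.append(fritz_purvis_D(t, trait, n_sim=150, seed=rep).value)
        assert 0.7 < float(np.mean(vals)) < 1.3

    def test_monomorphic_trait_rejected(self, yule_tree_50):
        trait = {lab: 1 for lab in yule_tree_50.tip_labels}
        with pytest.raises(ValueError, match="binary"):
            fritz_purvis_D(yule_tree_50, trait)

    def test_deterministic(self):
        t = simulate_phylogeny(20, seed=3)
        trait = {lab: int(k % 2) for k, lab in enumerate(t.tip_labels)}
        a = fritz_purvis_D(t, trait, n_sim=100, seed=9)
        b = fritz_purvis_D(t, trait, n_sim=100, seed=9)
        assert (a.value, a.p_value) == (b.value, b.p_value)


class TestMantel:
    @staticmethod
    def _random_dm(rng, n, labels=None):
        M = rng.uniform(0.1, 1.0, size=(n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        labels = labels or tuple(f"L{i}_x" for i in range(n))
        return DistanceMatrix(labels, M)

    def test_identity_gives_r_one(self):
        D = self._random_dm(np.random.default_rng(1), 8)
        res = mantel_test(D, D, n_perm=99, seed=0)
        assert res.value == pytest.approx(1.0)

    def test_scale_invariance(self):
        D = self._random_dm(np.random.default_rng(2), 8)
        D2 = DistanceMatrix(D.labels, 2.0 * D.values)
        assert mantel_test(D, D2, n_perm=99, seed=0).value == pytest.approx(1.0)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(3)
        A = self._random_dm(rng, 10)
        B = self._random_dm(rng, 10, labels=A.labels)
        mine = mantel_test(A, B, n_perm=999, seed=1)
        r_ref, p_ref, _ = skbio_mantel(SkbioDM(A.values), SkbioDM(B.values),
                                       method="pearson", permutations=999,
                                       alternative="greater")
        assert mine.value == pytest.approx(float(r_ref), abs=1e-12)
        assert abs(mine.p_value - float(p_ref)) < 0.05  # both permutation MCs

    def test_zero_variance_rejected(self):
        n = 5
        vals = np.ones((n, n)) - np.eye(n)
        D = DistanceMatrix(tuple(f"L{i}_x" for i in range(n)), vals)
        with pytest.raises(ValueError, match="zero-variance"):
            mantel_test(D, D, n_perm=9)
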