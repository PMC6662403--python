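import subprocess
import textwrap

import numpy as np
import pytest

from ecospec import (
    align_trait,
    blomberg_k,
    k_permutation_test,
    morans_i,
    patristic_distances,
    phylo_correlogram,
    simulate_bm_traits,
    simulate_yule_tree,
    vcv_matrix,
    write_tree,
)

from conftest import morans_i_bruteforce


class TestBlombergK:
    def test_identity_vcv_gives_k_exactly_one(self, rng):
        """With C = I every matrix correction vanishes and K = K* = 1."""
        for n in (4, 10, 50):
            x = rng.normal(size=n)
            res = blomberg_k(x, np.eye(n))
            assert res.K == pytest.approx(1.0, abs=1e-10)
            assert res.K_star == pytest.approx(1.0, abs=1e-10)

    def test_k_and_k_star_coincide_on_star_tree(self, rng):
        import dendropy

        star = dendropy.Tree.get(
            data="(" + ",".join(f"t{i}:2" for i in range(8)) + ");",
            schema="newick", rooting="default-rooted",
        )
        v = vcv_matrix(star)
        x = rng.normal(size=8)
        res = blomberg_k(x, v)
        assert res.K == pytest.approx(res.K_star, abs=1e-10)

    def test_affine_invariance(self, yule32, rng):
        _, v = yule32
        x = rng.normal(size=32)
        base = blomberg_k(x, v)
        shifted = blomberg_k(3.7 * x - 11.0, v)
        assert shifted.K == pytest.approx(base.K, rel=1e-10)
        assert shifted.K_star == pytest.approx(base.K_star, rel=1e-10)

    def test_branch_length_rescaling_invariance(self, yule32, rng):
        _, v = yule32
        x = rng.normal(size=32)
        assert blomberg_k(x, 5.0 * v.C).K == pytest.approx(blomberg_k(x, v.C).K, rel=1e-10)

    def test_constant_trait_degenerate(self, yule32):
        _, v = yule32
        res = blomberg_k(np.full(32, 2.0), v)
        assert res.K == 0.0 and res.degenerate

    def test_matches_phytools_oracle(self, tmp_path):
        """Independent route: R phytools::phylosig on the same tree and trait."""
        tree = simulate_yule_tree(16, seed=42)
        trait = simulate_bm_traits(tree, seed=7)
        v = vcv_matrix(tree)
        res = blomberg_k(align_trait(trait, v.tip_labels), v)
        write_tree(tree, tmp_path / "t.nwk")
        trait.to_csv(tmp_path / "x.csv", header=True)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(phytools))
            tr <- read.tree("{tmp_path}/t.nwk")
            d <- read.csv("{tmp_path}/x.csv", row.names=1)
            x <- setNames(d[[1]], rownames(d))
            cat(sprintf("%.10f", phylosig(tr, x, method="K")))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        assert res.K == pytest.approx(float(out.stdout.strip().split()[-1]), abs=1e-6)

    def test_bm_traits_recover_k_near_one(self):
        tree = simulate_yule_tree(64, seed=77)
        v = vcv_matrix(tree)
        ks = [
            blomberg_k(align_trait(simulate_bm_traits(tree, seed=s), v.tip_labels), v).K
            for s in range(100)
        ]
        assert 0.85 <= np.mean(ks) <= 1.15

    def test_tip_shuffled_traits_lose_signal(self, rng):
        tree = simulate_yule_tree(64, seed=78)
        v = vcv_matrix(tree)
        ks = []
        for s in range(100):
            x = align_trait(simulate_bm_traits(tree, seed=s), v.tip_labels)
            ks.append(blomberg_k(rng.permutation(x), v).K)
        assert np.mean(ks) < 0.5

    def test_shape_mismatch_and_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            blomberg_k(rng.normal(size=5), np.eye(4))
        with pytest.raises(ValueError, match="at least 4"):
            blomberg_k(rng.normal(size=3), np.eye(3))

    def test_singular_vcv_reported(self, rng):
        C = np.ones((6, 6))  # identical tips: rank one
        with pytest.raises(ValueError, match="singular"):
            blomberg_k(rng.normal(size=6), C)


class TestPermutationTest:
    def test_deterministic_given_seed(self, yule32, rng):
        _, v = yule32
        x = rng.normal(size=32)
        p1 = k_permutation_test(x, v, n_perm=99, seed=5)
        p2 = k_permutation_test(x, v, n_perm=99, seed=5)
        assert p1.p_K == p2.p_K and p1.p_K_star == p2.p_K_star
        assert 0.0 < p1.p_K <= 1.0

    def test_strong_signal_detected(self):
        tree = simulate_yule_tree(64, seed=9)
        v = vcv_matrix(tree)
        hits = 0
        for s in range(40):
            x = align_trait(simulate_bm_traits(tree, seed=s), v.tip_labels)
            hits += k_permutation_test(x, v, n_perm=199, seed=s).p_K <= 0.05
        assert hits / 40 >= 0.9

    def test_constant_trait_p_is_one(self, yule32):
        _, v = yule32
        with pytest.warns(UserWarning, match="constant"):
            res = k_permutation_test(np.ones(32), v, n_perm=99, seed=1)
        assert res.p_K == 1.0

    def test_minimum_permutations_enforced(self, yule32, rng):
        _, v = yule32
        with pytest.raises(ValueError, match="99"):
            k_permutation_test(rng.normal(size=32), v, n_perm=10, seed=0)


class TestMoransI:
    def test_paired_blocks_give_plus_one(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        assert morans_i(x, W) == pytest.approx(1.0)

    def test_cross_blocks_give_minus_one(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = W[1, 3] = W[3, 1] = 1.0
        assert morans_i(x, W) == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 20))
            x = rng.normal(size=n)
            W = rng.random((n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            assert morans_i(x, W) == pytest.approx(morans_i_bruteforce(x, W), abs=1e-12)

    def test_permutation_null_mean(self, rng):
        """E[I] over random relabelings is -1/(n-1)."""
        n = 12
        x = rng.normal(size=n)
        W = rng.random((n, n))
        np.fill_diagonal(W, 0.0)
        vals = [morans_i(rng.permutation(x), W) for _ in range(10_000)]
        assert np.mean(vals) == pytest.approx(-1.0 / (n - 1), abs=0.01)

    def test_invalid_inputs(self, rng):
        x = rng.normal(size=4)
        with pytest.raises(ValueError, match="diagonal"):
            morans_i(x, np.eye(4))
        with pytest.raises(ValueError, match="zero"):
            morans_i(x, np.zeros((4, 4)))
        W = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(4), W)


class TestCorrelogram:
    def test_deterministic_given_seed(self, rng):
        tree = simulate_yule_tree(24, seed=14)
        d = patristic_distances(tree)
        x = align_trait(simulate_bm_traits(tree, seed=3), d.tip_labels)
        c1 = phylo_correlogram(x, d, n_classes=4, n_boot=50, seed=9)
        c2 = phylo_correlogram(x, d, n_classes=4, n_boot=50, seed=9)
        assert np.array_equal(c1.I, c2.I, equal_nan=True)
        assert np.array_equal(c1.ci_low, c2.ci_low, equal_nan=True)
        assert c1.significance == c2.significance

    def test_bm_trait_positive_at_short_distances(self):
        tree = simulate_yule_tree(64, seed=21)
        d = patristic_distances(tree)
        x = align_trait(simulate_bm_traits(tree, seed=2), d.tip_labels)
        cg = phylo_correlogram(x, d, n_classes=5, n_boot=100, seed=0)
        assert cg.significance[0] == "positive"
        assert cg.I[0] > cg.expected_i

    def test_ci_bounds_ordered(self, rng):
        tree = simulate_yule_tree(32, seed=22)
        d = patristic_distances(tree)
        x = rng.normal(size=32)
        cg = phylo_correlogram(x, d, n_classes=4, n_boot=100, seed=1)
        ok = ~np.isnan(cg.ci_low)
        assert (cg.ci_low[ok] <= cg.ci_high[ok]).all()

    def test_empty_class_flagged_missing(self):
        # three tight pairs at distance ~0.2 and ~4: middle classes empty
        import dendropy

        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.1):1.9,(C:0.1,D:0.1):1.9);",
            schema="newick", rooting="default-rooted",
        )
        d = patristic_distances(tree)
        x = np.array([0.1, 0.2, 5.0, 5.5])
        with pytest.warns(UserWarning, match="empty"):
            cg = phylo_correlogram(x, d, n_classes=6, n_boot=10, seed=0)
        assert np.isnan(cg.I).any()
        assert len(cg.warnings_) >= 1

    def test_frame_export_shape(self, rng):
        tree = simulate_yule_tree(16, seed=23)
        d = patristic_distances(tree)
        x = rng.normal(size=16)
        cg = phylo_correlogram(x, d, n_classes=3, n_boot=20, seed=4)
        frame = cg.to_frame()
        assert list(frame.columns) == ["class_mid", "I", "ci_low", "ci_high", "significance"]
        assert len(frame) == 3


def test_align_trait_reorders_and_validates(yule32):
    import pandas as pd

    _, v = yule32
    s = pd.Series(np.arange(32, dtype=float), index=v.tip_labels[::-1])
    x = align_trait(s, v.tip_labels)
    assert x[0] == 31.0
    with pytest.raises(KeyError, match="missing"):
        align_trait(s.iloc[:10], v.tip_labels)
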