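"""Closed-form and permutation-oracle checks of the distance metrics and
nonparametric tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from idhgan.fidelity import (DistanceProfile, bonferroni_threshold,
                             js_divergence_hist, kl_divergence_hist,
                             kruskal_wallis_test, mann_whitney_u_test,
                             per_feature_distances, wasserstein_1d)


class TestWasserstein:
    def test_identical_samples_zero(self):
        a = [1.0, 2.0, 5.0]
        assert wasserstein_1d(a, a) == 0.0

    def test_unit_shift(self):
        assert wasserstein_1d([0.0, 1.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_three_atom_transport(self):
        # brute-force optimal transport on the empirical measures of
        # {0,0,4} and {1,1,1} (three atoms of mass 1/3): move the two
        # zeros by 1 and the four by 3, total cost (1 + 1 + 3) / 3
        assert wasserstein_1d([0, 0, 4], [1, 1, 1]) == pytest.approx(5 / 3)

    def test_translation_invariance_of_shifted_pair(self):
        # W1(a + c, b + c) = W1(a, b)
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=40), rng.normal(size=30)
        base = wasserstein_1d(a, b)
        assert wasserstein_1d(a + 5.0, b + 5.0) == pytest.approx(base,
                                                                 abs=1e-12)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c = (rng.normal(size=15) for _ in range(3))
            ab = wasserstein_1d(a, b)
            bc = wasserstein_1d(b, c)
            ac = wasserstein_1d(a, c)
            assert ac <= ab + bc + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestKlJs:
    def test_identical_samples_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        assert kl_divergence_hist(x, x) < 1e-8
        assert js_divergence_hist(x, x) < 1e-8

    def test_two_bin_closed_form_ln2(self):
        # real mass (1, 0) vs synthetic mass (0.5, 0.5) over two bins:
        # KL -> ln 2 as the smoothing vanishes
        real = np.zeros(100)
        synth = np.concatenate([np.zeros(50), np.ones(50)])
        kl = kl_divergence_hist(real, synth, bins=2)
        assert kl == pytest.approx(math.log(2), abs=1e-6)

    def test_kl_asymmetry_witness(self):
        real = np.zeros(100)
        synth = np.concatenate([np.zeros(50), np.ones(50)])
        assert kl_divergence_hist(real, synth, bins=2) != \
            kl_divergence_hist(synth, real, bins=2)

    def test_disjoint_support_jsd_is_ln2(self):
        a = np.zeros(60)
        b = np.ones(60) * 10
        assert js_divergence_hist(a, b, bins=2) == pytest.approx(
            math.log(2), abs=1e-6)

    def test_jsd_symmetric_exactly(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 200), rng.normal(1, 2, 150)
        assert js_divergence_hist(a, b) == js_divergence_hist(b, a)

    def test_bounds_hold_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 2), 80)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 2), 90)
            assert kl_divergence_hist(a, b) >= 0.0
            assert 0.0 <= js_divergence_hist(a, b) <= math.log(2) + 1e-12

    def test_degenerate_range_warns_zero(self):
        with pytest.warns(UserWarning):
            assert kl_divergence_hist(np.ones(5), np.ones(7)) == 0.0


class TestPerFeatureDistances:
    def test_identical_tables_all_near_zero(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(300, 4)),
                          columns=list("abcd"))
        prof = per_feature_distances(df, df.copy(), method="copy")
        assert np.allclose(prof.wd, 0.0)
        assert np.all(prof.kld < 1e-8)
        assert np.all(prof.jsd < 1e-8)

    def test_vector_lengths_match_features(self):
        rng = np.random.default_rng(6)
        real = pd.DataFrame(rng.normal(size=(100, 5)),
                            columns=[f"f{i}" for i in range(5)])
        synth = pd.DataFrame(rng.normal(size=(120, 5)),
                             columns=[f"f{i}" for i in range(5)])
        prof = per_feature_distances(real, synth)
        assert len(prof.wd) == len(prof.kld) == len(prof.jsd) == 5
        assert len(prof.to_frame()) == 15

    def test_shift_raises_only_that_features_wd(self):
        rng = np.random.default_rng(7)
        real = pd.DataFrame(rng.normal(size=(2000, 3)),
                            columns=["a", "b", "c"])
        synth = real.copy()
        synth["b"] = synth["b"] + 0.8
        prof = per_feature_distances(real, synth)
        assert prof.wd[1] == pytest.approx(0.8, abs=0.05)
        assert prof.wd[0] < 0.05 and prof.wd[2] < 0.05

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_feature_distances(pd.DataFrame({"a": [1.0]}),
                                  pd.DataFrame({"b": [1.0]}))


class TestKruskalWallis:
    def test_hand_rank_sum_oracle(self):
        h, p = kruskal_wallis_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert 0 < p < 0.05

    def test_exchangeable_groups_no_signal(self):
        h, p = kruskal_wallis_test([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_group_order_invariance(self):
        groups = [[1, 5, 3], [9, 2, 8], [4, 7, 6]]
        h1, _ = kruskal_wallis_test(groups)
        h2, _ = kruskal_wallis_test(groups[::-1])
        assert h1 == pytest.approx(h2)

    def test_all_identical_values_warn(self):
        with pytest.warns(UserWarning):
            h, p = kruskal_wallis_test([[5.0, 5.0], [5.0, 5.0]])
        assert (h, p) == (0.0, 1.0)


class TestMannWhitney:
    def test_exact_enumeration_oracle(self):
        # all C(4,2)=6 labelings of {1,2,3,4}: observed U=0 occurs in
        # 2 of 6 orderings two-sided -> p = 1/3
        u, p = mann_whitney_u_test([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_high_p(self):
        x = np.arange(10.0)
        _, p = mann_whitney_u_test(x, x)
        assert p >= 0.99

    def test_u_is_the_smaller_statistic(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(2, 1, 15)
        u, _ = mann_whitney_u_test(a, b)
        assert 0 <= u <= len(a) * len(b) / 2


def _exact_mwu_p(a, b):
    """Permutation oracle: exact two-sided p over all group labelings."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_stat(idx_a):
        r_a = ranks[list(idx_a)].sum()
        u_a = r_a - n_a * (n_a + 1) / 2
        return min(u_a, n_a * len(b) - u_a)

    observed = u_stat(range(n_a))
    stats = [u_stat(c) for c in
             itertools.combinations(range(len(pooled)), n_a)]
    return np.mean([s <= observed for s in stats])


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_mann_whitney_matches_permutation_oracle_small_n(seed):
    rng = np.random.default_rng(seed)
    n_a = rng.integers(2, 5)
    n_b = rng.integers(2, 6)
    # distinct values to stay in the exact (tie-free) regime
    pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
    a, b = pooled[:n_a], pooled[n_a:]
    _, p = mann_whitney_u_test(a, b)
    assert p == pytest.approx(_exact_mwu_p(a, b), abs=1e-12)


class TestBonferroni:
    def test_six_comparisons(self):
        assert bonferroni_threshold(0.05, 6) == pytest.approx(0.0083333,
                                                              abs=1e-6)

    def test_ten_comparisons(self):
        assert bonferroni_threshold(0.05, 10) == 0.005

    def test_single_comparison_identity(self):
        assert bonferroni_threshold(0.07, 1) == 0.07

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestDistanceProfileInvariants:
    def test_mismatched_vector_lengths_rejected(self):
        with pytest.raises(ValueError):
            DistanceProfile(method="m", feature_names=["a", "b"],
                            wd=np.zeros(2), kld=np.zeros(1),
                            jsd=np.zeros(2))
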