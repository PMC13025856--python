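"""Permutation test exactness/calibration, motif & ORA hypergeometrics,
BH adjustment, and random-forest permutation importance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rloopscape.enrichment_stats import (
    bh_adjust,
    motif_enrichment,
    ora,
    permutation_enrichment,
    permutation_importance,
)

from oracles import exact_hypergeom_upper


class TestPermutationEnrichment:
    def test_exhaustive_small_pool_examples(self):
        # pool {1,2,3}, draws of size 2 -> null means {1.5, 2.0, 2.5}
        res = permutation_enrichment([2.6, 2.6], [1, 2, 3], exhaustive=True)
        assert res.empirical_p == 0.0 and res.n_permutations == 3
        res2 = permutation_enrichment([2.0, 2.0], [1, 2, 3], exhaustive=True)
        assert res2.empirical_p == pytest.approx(2 / 3)

    def test_degenerate_constant_input(self):
        res = permutation_enrichment([5, 5, 5], [5, 5, 5], exhaustive=True)
        assert res.empirical_p == 1.0 and res.z == 0.0 and res.enrichment == 0.0
        assert res.degenerate_null

    def test_sampling_converges_to_exhaustive(self, rng):
        """Sampled p agrees with enumerated p on pools small enough to enumerate."""
        for _ in range(10):
            pool = rng.uniform(0, 1, size=int(rng.integers(6, 12)))
            k = int(rng.integers(2, 5))
            obs = rng.uniform(0, 1, size=k)
            exact = permutation_enrichment(obs, pool, exhaustive=True)
            approx = permutation_enrichment(obs, pool, n_perm=20_000, seed=rng)
            assert approx.empirical_p == pytest.approx(exact.empirical_p, abs=0.02)

    def test_pool_smaller_than_input_flags_replacement(self):
        with pytest.warns(UserWarning):
            res = permutation_enrichment([1, 2, 3, 4], [1, 2], n_perm=100, seed=0)
        assert res.sampled_with_replacement

    def test_seed_reproducibility(self):
        a = permutation_enrichment(range(5), range(100), n_perm=500, seed=42)
        b = permutation_enrichment(range(5), range(100), n_perm=500, seed=42)
        assert a.empirical_p == b.empirical_p and a.z == b.z

    def test_null_calibration_p_is_uniform(self):
        """iid rloop/background: empirical p deciles hold 10% +/- 3% each.

        The background pool (500) is large relative to the input (10), the
        regime the subsampling null is used in; a pool barely larger than
        the input underestimates the null variance by the finite-population
        correction and is deliberately not claimed calibrated.
        """
        rng = np.random.default_rng(123)
        ps = np.empty(1000)
        for i in range(1000):
            obs = rng.normal(size=10)
            bg = rng.normal(size=500)
            ps[i] = permutation_enrichment(obs, bg, n_perm=500, seed=rng).empirical_p
        counts, _ = np.histogram(ps, bins=np.linspace(0, 1, 11))
        assert np.all(np.abs(counts / 1000 - 0.10) <= 0.03)


class TestMotifEnrichment:
    def test_fold_and_hypergeometric_tail(self):
        res = motif_enrichment([True] * 5 + [False] * 5, [True] * 10 + [False] * 90)
        assert res.fold == pytest.approx(5.0)
        assert res.p == pytest.approx(exact_hypergeom_upper(5, 110, 15, 10), rel=1e-10)

    def test_equal_rates_give_unit_fold_and_large_p(self):
        res = motif_enrichment([True] * 3 + [False] * 7, [True] * 30 + [False] * 70)
        assert res.fold == pytest.approx(1.0)
        assert res.p >= 0.5

    def test_zero_target_hits(self):
        res = motif_enrichment([False] * 10, [True] * 5 + [False] * 95)
        assert res.fold == 0.0 and res.p == 1.0

    def test_zero_background_rate_flags_infinite_fold(self):
        res = motif_enrichment([True] * 3 + [False] * 2, [False] * 20)
        assert math.isinf(res.fold)

    def test_binomial_model(self):
        from scipy.stats import binom

        res = motif_enrichment(
            [True] * 4 + [False] * 6, [True] * 10 + [False] * 90, model="binomial"
        )
        assert res.p == pytest.approx(float(binom.sf(3, 10, 0.1)))


class TestOra:
    def test_exact_hypergeometric_example(self):
        df = ora(
            [f"g{i}" for i in range(20)],
            {"T": {f"g{i}" for i in range(15, 25)}},  # 10 genes, overlap 5
            [f"g{i}" for i in range(100)],
        )
        expected = exact_hypergeom_upper(5, 100, 10, 20)
        assert df["p"].iloc[0] == pytest.approx(expected, rel=1e-10)
        assert df["overlap"].iloc[0] == 5

    def test_matches_factorial_computation_over_grid(self, rng):
        """scipy tail equals exact rational arithmetic to 1e-12 for N <= 200."""
        for _ in range(50):
            n_uni = int(rng.integers(20, 200))
            term = int(rng.integers(1, n_uni // 2))
            sel = int(rng.integers(1, n_uni // 2))
            genes = [f"g{i}" for i in range(n_uni)]
            term_set = set(rng.choice(genes, size=term, replace=False))
            sel_set = list(rng.choice(genes, size=sel, replace=False))
            df = ora(sel_set, {"T": term_set}, genes)
            k = df["overlap"].iloc[0]
            assert df["p"].iloc[0] == pytest.approx(
                exact_hypergeom_upper(int(k), n_uni, term, sel), abs=1e-12
            )

    def test_zero_overlap_p_is_one(self):
        df = ora(["a"], {"T": {"b", "c"}}, ["a", "b", "c", "d"])
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_selected_equals_universe_saturates(self):
        genes = [f"g{i}" for i in range(30)]
        df = ora(genes, {"T": set(genes[:10])}, genes)
        assert df["overlap"].iloc[0] == 10 and df["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora(["a"], {"T": {"a"}}, [])

    def test_significance_rule_is_joint(self):
        genes = [f"g{i}" for i in range(1000)]
        term = set(genes[:50])
        df = ora(genes[:40], {"T": term}, genes)  # heavy overlap => tiny p, q
        assert bool(df["significant"].iloc[0]) == (
            df["p"].iloc[0] < 0.01 and df["q"].iloc[0] < 0.05
        )


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_three_value_step_up(self):
        # m=3: q_i = min over j>=i of p_(j) * m / j => all 0.03
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_order_invariant(self, rng):
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPermutationImportance:
    @staticmethod
    def _planted(seed, n=800):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(
            {
                "f1": rng.normal(size=n),
                "f2": rng.normal(size=n),
                "f3": rng.normal(size=n),
            }
        )
        y = x["f1"] > 0
        return x, y.to_numpy()

    def test_single_class_rejected(self):
        x, _ = self._planted(0)
        with pytest.raises(ValueError):
            permutation_importance(x, np.zeros(len(x), dtype=bool), seed=0)

    def test_planted_feature_ranks_first(self):
        """Label = threshold on f1: f1 wins in >= 95% of 20 seeded runs."""
        wins = 0
        for seed in range(20):
            x, y = self._planted(seed)
            df = permutation_importance(x, y, n_repeats=3, seed=seed)
            if df["feature"].iloc[0] == "f1":
                wins += 1
        assert wins >= 19

    def test_independent_labels_give_near_zero_decreases(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = rng.random(n) < 0.5
        df = permutation_importance(x, y, n_repeats=3, seed=7)
        assert (df["mean_decrease_auc"].abs() < 0.02).all()

    def test_duplicated_feature_importance_splits_but_stays_nonnegative(self):
        x, y = self._planted(3)
        x = x.copy()
        x["f1_dup"] = x["f1"]
        df = permutation_importance(x, y, n_repeats=3, seed=3).set_index("feature")
        assert df.loc["f1", "mean_decrease_auc"] >= -0.02
        assert df.loc["f1_dup", "mean_decrease_auc"] >= -0.02

    def test_seeded_reproducibility(self):
        x, y = self._planted(5, n=300)
        a = permutation_importance(x, y, n_repeats=2, seed=11)
        b = permutation_importance(x, y, n_repeats=2, seed=11)
        pd.testing.assert_frame_equal(a, b)
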