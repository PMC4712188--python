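"""Fluctuation analysis: readout noise, summaries, inversion, exact test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from g4flux import (
    AlleleConfig,
    CloneState,
    ExpressionState,
    FACSNoise,
    FluctuationDataset,
    SimConfig,
    SyntheticSpec,
    TransitionParams,
    compare_fluctuations,
    estimate_p,
    fisher_exact_2xk,
    make_fluctuation,
    measure_clone,
    measure_fractions,
    summarize,
)


def _clone_state(high, medium, low):
    return CloneState({ExpressionState.HIGH: high, ExpressionState.MEDIUM: medium,
                       ExpressionState.LOW: low})


class TestMeasureClone:
    def test_pure_high_reads_zero_loss(self):
        m = measure_clone(_clone_state(1000, 0, 0), FACSNoise(misclass=0.0), seed=1)
        assert m.pct_loss == 0.0

    def test_pure_low_reads_full_loss(self):
        m = measure_clone(_clone_state(0, 0, 1000), FACSNoise(misclass=0.0), seed=1)
        assert m.pct_loss == 100.0

    def test_balanced_mixture_unbiased(self):
        noise = FACSNoise(n_events=10_000, misclass=0.0)
        vals = [measure_clone(_clone_state(500, 250, 250), noise, seed=s).pct_loss
                for s in range(200)]
        # binomial sampling law: SE of the mean of 200 draws of n=10^4 at f=0.5
        se = 100 * np.sqrt(0.25 / 10_000 / 200)
        assert abs(np.mean(vals) - 50.0) < 4 * se

    def test_misclassification_shifts_mean_as_predicted(self):
        # p_obs = f(1-eps) + (1-f)eps for symmetric gate errors
        noise = FACSNoise(n_events=10_000, misclass=0.05)
        f = 0.2
        vals = [measure_clone(_clone_state(8000, 2000, 0), noise, seed=s).pct_loss
                for s in range(200)]
        expected = 100 * (f * 0.95 + 0.8 * 0.05)
        assert abs(np.mean(vals) - expected) < 0.3

    def test_empty_clone_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_clone(_clone_state(0, 0, 0), FACSNoise(), seed=0)

    def test_batch_path_matches_single_path_in_mean(self):
        noise = FACSNoise(n_events=10_000, misclass=0.01)
        rng = np.random.default_rng(3)
        batch = measure_fractions(np.full(500, 0.3), noise, rng)
        single = [measure_clone(_clone_state(700, 300, 0), noise, seed=s).pct_loss
                  for s in range(500)]
        assert abs(batch.mean() - np.mean(single)) < 0.2

    def test_noise_model_validation(self):
        with pytest.raises(ValueError):
            FACSNoise(misclass=0.5)
        with pytest.raises(ValueError):
            FACSNoise(n_events=0)


class TestSummarize:
    def test_small_odd_set_interpolated_quartiles(self):
        ds = FluctuationDataset.from_values("g", [10, 20, 30])
        med, (q25, q75) = summarize(ds)
        assert med == 20
        assert (q25, q75) == (15, 25)

    def test_constant_dataset(self):
        ds = FluctuationDataset.from_values("g", [42.0] * 7)
        med, iqr = summarize(ds)
        assert med == 42.0 and iqr == (42.0, 42.0)

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 100, 23)
        ds = FluctuationDataset.from_values("g", vals)
        med, (q25, q75) = summarize(ds)

        def percentile_oracle(v, q):
            s = sorted(v)
            pos = (len(s) - 1) * q / 100
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert med == pytest.approx(percentile_oracle(vals, 50))
        assert q25 == pytest.approx(percentile_oracle(vals, 25))
        assert q75 == pytest.approx(percentile_oracle(vals, 75))

    def test_dataset_needs_a_clone(self):
        with pytest.raises(ValueError):
            FluctuationDataset("g", ())


class TestEstimateP:
    def test_degenerate_all_zero_returns_boundary_unreliable(self):
        ds = FluctuationDataset.from_values("g", [0.0] * 10)
        with pytest.warns(UserWarning, match="degenerate"):
            res = estimate_p(ds, grid=[0.0, 0.01, 0.02], n_reps=100, seed=1)
        assert res.p_hat == 0.0
        assert not res.reliable

    def test_estimator_is_monotone_in_true_rate(self):
        low = make_fluctuation(SyntheticSpec(seed=21, n_clones=40, true_p=0.02))
        high = make_fluctuation(SyntheticSpec(seed=22, n_clones=40, true_p=0.08))
        r_low = estimate_p(low, n_reps=150, seed=5, refine=False, n_boot=50)
        r_high = estimate_p(high, n_reps=150, seed=5, refine=False, n_boot=50)
        assert r_low.p_hat < r_high.p_hat

    def test_deterministic_given_seed(self):
        ds = make_fluctuation(SyntheticSpec(seed=30, n_clones=30, true_p=0.05))
        a = estimate_p(ds, n_reps=150, seed=9, n_boot=50)
        b = estimate_p(ds, n_reps=150, seed=9, n_boot=50)
        assert a.p_hat == b.p_hat
        assert a.grid == b.grid
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_brackets_point_estimate(self):
        ds = make_fluctuation(SyntheticSpec(seed=31, n_clones=30, true_p=0.05))
        r = estimate_p(ds, n_reps=150, seed=2, n_boot=100)
        assert r.ci_low <= r.p_hat <= r.ci_high

    def test_low_loss_dataset_flagged_unreliable(self):
        # a median below the ~10% quantification floor cannot be resolved
        ds = FluctuationDataset.from_values("g", [1.0, 2.0, 3.0, 4.0, 5.0])
        r = estimate_p(ds, n_reps=100, seed=0, refine=False, n_boot=50)
        assert not r.reliable

    def test_ks_metric_also_recovers_ordering(self):
        low = make_fluctuation(SyntheticSpec(seed=41, n_clones=30, true_p=0.02))
        high = make_fluctuation(SyntheticSpec(seed=42, n_clones=30, true_p=0.1))
        kw = dict(n_reps=150, seed=3, refine=False, n_boot=50, distance_metric="ks")
        assert estimate_p(low, **kw).p_hat < estimate_p(high, **kw).p_hat

    def test_grid_validation(self):
        ds = FluctuationDataset.from_values("g", [50.0, 60.0])
        with pytest.raises(ValueError):
            estimate_p(ds, grid=[], n_reps=100)
        with pytest.raises(ValueError):
            estimate_p(ds, grid=[0.1, 0.05], n_reps=100)
        with pytest.raises(ValueError):
            estimate_p(ds, grid=[0.0, 0.1], n_reps=50)

    def test_parameter_recovery_on_synthetic_truth(self):
        """The inversion recovers the generating rate from one dataset of
        the experimental size (50 clones, 20 divisions, coupled alleles)."""
        ds = make_fluctuation(SyntheticSpec(seed=55, n_clones=50, true_p=0.067))
        r = estimate_p(ds, n_reps=300, seed=17)
        assert abs(r.p_hat - 0.067) < 0.015
        assert r.reliable


class TestFisherExact:
    def test_identical_datasets_give_p_one(self):
        ds = FluctuationDataset.from_values("g", [5, 25, 45, 65, 85])
        assert compare_fluctuations(ds, ds) == pytest.approx(1.0)

    def test_extreme_separation_direct_enumeration(self):
        # all of a in the bottom bin, all of b in the top: only 2 tables as
        # extreme as observed out of C(10,5) equiprobable ones
        a = FluctuationDataset.from_values("a", [1, 2, 3, 4, 5])
        b = FluctuationDataset.from_values("b", [95, 96, 97, 98, 99])
        assert compare_fluctuations(a, b) == pytest.approx(2 / 252)

    def test_matches_scipy_on_all_small_2x2_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if (a + b) * (c + d) == 0 or (a + c) + (b + d) == 0:
                continue
            ours = fisher_exact_2xk(np.array([[a, b], [c, d]]))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12), (a, b, c, d)

    def test_pvalue_in_unit_interval(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 5))
            if t.sum(axis=1).min() == 0:
                continue
            p = fisher_exact_2xk(t)
            assert 0.0 < p <= 1.0

    def test_hundred_percent_joins_top_bin(self):
        a = FluctuationDataset.from_values("a", [100.0, 100.0])
        b = FluctuationDataset.from_values("b", [100.0, 100.0])
        assert compare_fluctuations(a, b) == 1.0

    def test_bin_width_must_divide_100(self):
        ds = FluctuationDataset.from_values("g", [50.0])
        with pytest.raises(ValueError):
            compare_fluctuations(ds, ds, bin_width=30)

    def test_null_calibration_small(self):
        """Under the null the exact conditional test is (conservatively)
        level-alpha."""
        rej = 0
        n = 60
        for i in range(n):
            a = make_fluctuation(SyntheticSpec(seed=5000 + 2 * i, n_clones=20, true_p=0.067))
            b = make_fluctuation(SyntheticSpec(seed=5001 + 2 * i, n_clones=20, true_p=0.067))
            rej += compare_fluctuations(a, b) < 0.05
        assert rej / n <= 0.10


class TestDatasetIO:
    def test_tsv_round_trip(self, tmp_path):
        ds = make_fluctuation(SyntheticSpec(seed=60, n_clones=10, true_p=0.05), genotype="mut")
        path = tmp_path / "fluct.tsv"
        ds.to_tsv(path)
        back = FluctuationDataset.from_tsv(path, genotype="mut")
        assert np.allclose(back.pct_values, ds.pct_values)
        assert [c.clone_id for c in back.clones] == [c.clone_id for c in ds.clones]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("x\ty\n1\t2\n")
        with pytest.raises(ValueError, match="expected columns"):
            FluctuationDataset.from_tsv(path)
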