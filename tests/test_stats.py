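"""Cohort statistics: normality screening, transforms, F/t tests, B-H, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dyadspeech as ds
from dyadspeech.errors import ValidationError
from dyadspeech.stats import apply_transforms, permutation_corr_pvalue


def exact_moments(n, mean, sd, rng):
    """A sample with exactly the requested sample mean and SD (ddof=1)."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestKsNormality:
    def test_normal_sample_passes(self, rng):
        _, p = ds.ks_normality(rng.normal(size=200))
        assert p > 0.05

    def test_lognormal_sample_fails(self, rng):
        _, p = ds.ks_normality(np.exp(rng.normal(size=200)))
        assert p < 0.05

    def test_preconditions(self, rng):
        with pytest.raises(ValidationError, match="n >= 4"):
            ds.ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError, match="constant"):
            ds.ks_normality([1.0] * 10)

    def test_lilliefors_mode_runs(self, rng):
        d, p = ds.ks_normality(rng.normal(size=50), lilliefors_correction=True)
        assert 0 <= p <= 1


def feature_cohort(**overrides):
    cohort = ds.simulate_feature_cohort(10, 6, seed=1)
    for feature, values in overrides.items():
        cohort.data[feature] = values
    return cohort


class TestTransforms:
    def test_shift_makes_minimum_one_before_log(self):
        cohort = feature_cohort(mean_turn_gap_s=np.linspace(-0.5, 1.0, 16))
        spec = {s.feature: s for s in ds.fit_transforms(cohort)}["mean_turn_gap_s"]
        assert spec.kind == "shifted_log"
        assert spec.shift_c == pytest.approx(1.5)
        transformed = spec.apply(cohort.data["mean_turn_gap_s"].to_numpy())
        assert transformed.min() == pytest.approx(0.0)

    def test_no_shift_when_minimum_already_one(self):
        cohort = feature_cohort(mean_turn_gap_s=np.linspace(1.0, 2.0, 16))
        spec = {s.feature: s for s in ds.fit_transforms(cohort)}["mean_turn_gap_s"]
        assert spec.shift_c == pytest.approx(0.0)

    def test_zero_pause_ratio_errors_in_strict_mode(self):
        values = np.linspace(0.01, 0.2, 16)
        values[3] = 0.0
        cohort = feature_cohort(pause_to_turn_ratio=values)
        specs = ds.fit_transforms(cohort)
        with pytest.raises(ValidationError, match="non-positive"):
            apply_transforms(cohort, specs, on_nonpositive="error")
        # default pipeline behaviour: undefined, not imputed
        X = apply_transforms(cohort, specs)
        assert X["pause_to_turn_ratio"].isna().sum() == 1

    def test_round_trip_recovers_raw_values(self):
        cohort = feature_cohort()
        specs = ds.fit_transforms(cohort)
        X = apply_transforms(cohort, specs)
        raw = cohort.data.set_index("participant_id")
        for spec in specs:
            back = spec.invert(X[spec.feature].to_numpy())
            assert np.allclose(back, raw[spec.feature].to_numpy(), atol=1e-12)


class TestVarianceRatioTest:
    def test_identical_groups(self, rng):
        x = rng.normal(size=30)
        f, p = ds.variance_ratio_test(x, x)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_constructed_variance_ratio(self, rng):
        x = exact_moments(20, 0.0, 2.0, rng)
        y = exact_moments(20, 0.0, 1.0, rng)
        f, p = ds.variance_ratio_test(x, y)
        assert f == pytest.approx(4.0, abs=1e-12)
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.f(19, 19).sf(4.0), abs=1e-12)

    def test_against_permutation_oracle(self, rng):
        x = rng.normal(0, 1.35, size=24)
        y = rng.normal(0, 1.0, size=24)
        _, p_param = ds.variance_ratio_test(x, y)
        pooled = np.concatenate([x, y])
        obs = np.var(x, ddof=1) / np.var(y, ddof=1)
        obs = max(obs, 1 / obs)
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f = np.var(perm[:24], ddof=1) / np.var(perm[24:], ddof=1)
            if max(f, 1 / f) >= obs:
                hits += 1
        p_perm = (1 + hits) / (1 + n_perm)
        assert p_param == pytest.approx(p_perm, abs=0.06)

    def test_reciprocal_symmetry(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=22)
        f_xy, p_xy = ds.variance_ratio_test(x, y)
        f_yx, p_yx = ds.variance_ratio_test(y, x)
        assert f_xy == pytest.approx(1 / f_yx)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValidationError):
            ds.variance_ratio_test(rng.normal(size=5), np.ones(5))


class TestMeanDifferenceTest:
    def test_identical_groups(self, rng):
        x = rng.normal(size=30)
        t, p = ds.mean_difference_test(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_pooled_t(self, rng):
        x = exact_moments(62, 2.8, 1.2, rng)
        y = exact_moments(17, 1.2, 1.2, rng)
        t, _ = ds.mean_difference_test(x, y, variant="pooled")
        assert t == pytest.approx(4.87, abs=0.01)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0.5, 1, 20), rng.normal(0, 1, 25)
        t_xy, p_xy = ds.mean_difference_test(x, y)
        t_yx, p_yx = ds.mean_difference_test(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)


def bh_oracle(p):
    """Step-up definition: adj_(k) = min_{j>=k} min(m p_(j) / j, 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBhAdjust:
    def test_step_up_by_hand(self):
        assert np.allclose(
            ds.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_test(self):
        assert ds.bh_adjust([0.5]) == pytest.approx([0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ds.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        adjusted = ds.bh_adjust(p)
        assert np.allclose(adjusted, bh_oracle(p), atol=1e-12)
        assert np.all(adjusted >= np.asarray(p) - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)


class TestTdDistance:
    def test_symmetry_and_zero(self):
        assert ds.td_distance(3.0, 3.0) == 0.0
        assert ds.td_distance(3.0 + 0.7, 3.0) == pytest.approx(0.7)
        assert ds.td_distance(3.0 - 0.7, 3.0) == pytest.approx(0.7)

    def test_vectorized_equals_elementwise(self, rng):
        x = rng.normal(size=50)
        vec = ds.td_distance(x, 0.3)
        loop = np.array([ds.td_distance(v, 0.3) for v in x])
        assert np.allclose(vec, loop)


class TestCorrelateWithScores:
    def make_cohort(self, rng, n=20):
        cohort = ds.simulate_feature_cohort(n, 4, seed=3)
        asd = cohort.data["group"] == "ASD"
        cohort.data.loc[asd, "reciprocity"] = np.arange(asd.sum())
        cohort.data.loc[asd, "mean_turn_gap_s"] = 0.1 * np.arange(asd.sum()) + 0.2
        return cohort

    def test_perfect_linear_pair(self, rng):
        cohort = self.make_cohort(rng)
        row = ds.correlate_with_scores(
            cohort, "mean_turn_gap_s", "reciprocity", method="permutation",
            n_perm=500, seed=11,
        )
        assert row.r == pytest.approx(1.0)
        assert row.p == pytest.approx(1 / 501)

    def test_permutation_reproducible_for_fixed_seed(self, rng):
        cohort = ds.simulate_feature_cohort(24, 4, seed=9)
        kwargs = dict(method="permutation", n_perm=300, seed=5)
        a = ds.correlate_with_scores(cohort, "sd_intensity", "reciprocity", **kwargs)
        b = ds.correlate_with_scores(cohort, "sd_intensity", "reciprocity", **kwargs)
        assert a.p == b.p

    def test_too_few_pairs(self):
        cohort = ds.simulate_feature_cohort(3, 3, seed=2)
        with pytest.raises(ValidationError, match="pairs"):
            ds.correlate_with_scores(cohort, "sd_intensity", "reciprocity")


class TestPrepareCorrelationInputs:
    def test_spread_only_features_get_td_distance(self):
        # strong spread difference without a mean difference
        rng = np.random.default_rng(12)
        cohort = ds.simulate_feature_cohort(62, 17, seed=12)
        asd = cohort.data["group"] == "ASD"
        cohort.data.loc[asd, "sd_block_log_f0"] = rng.normal(0.09, 0.06, asd.sum())
        cohort.data.loc[~asd, "sd_block_log_f0"] = rng.normal(0.09, 0.01, (~asd).sum())
        comparison = ds.comparison_table(cohort)
        row = comparison.set_index("feature").loc["sd_block_log_f0"]
        assert row["significant_F"] and not row["significant_t"]
        features, values = ds.prepare_correlation_inputs(cohort, comparison)
        assert "sd_block_log_f0" in features
        m_td = cohort.group("TD")["sd_block_log_f0"].mean()
        raw = cohort.data.set_index("participant_id")["sd_block_log_f0"]
        assert np.allclose(values["sd_block_log_f0"], np.abs(raw - m_td))

    def test_mean_shifted_features_stay_raw(self):
        cohort = ds.simulate_feature_cohort(
            62, 17, shifts={"mean_turn_gap_s": 0.8}, seed=13
        )
        comparison = ds.comparison_table(cohort)
        features, values = ds.prepare_correlation_inputs(cohort, comparison)
        assert "mean_turn_gap_s" in features
        raw = cohort.data.set_index("participant_id")["mean_turn_gap_s"]
        assert np.allclose(values["mean_turn_gap_s"], raw)


class TestComparisonTable:
    def test_empty_group_rejected(self):
        cohort = ds.simulate_feature_cohort(8, 2, seed=0)
        cohort.data["group"] = "ASD"
        df = cohort.data
        with pytest.raises(ValidationError, match="non-empty"):
            ds.comparison_table(ds.CohortTable(df))

    def test_adjusted_not_below_raw_and_shapes(self):
        cohort = ds.simulate_feature_cohort(30, 12, seed=4)
        table = ds.comparison_table(cohort)
        assert len(table) == 13
        assert (table["adjusted_p_F"] >= table["p_F"] - 1e-12).all()
        assert (table["adjusted_p_t"] >= table["p_t"] - 1e-12).all()

    def test_injected_gap_effect_detected(self):
        cohort = ds.simulate_feature_cohort(
            62, 17, shifts={"mean_turn_gap_s": 0.5}, seed=8
        )
        table = ds.comparison_table(cohort).set_index("feature")
        assert table.loc["mean_turn_gap_s", "adjusted_p_t"] < 0.05
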