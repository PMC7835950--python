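"""Saturation fitting: NLS and linearized coordinate systems, model selection."""

import numpy as np
import pytest

from oxokinetics.fitting import (
    FitError,
    SaturationSeries,
    fit_linearized,
    fit_one_site_nls,
    fit_two_site_nls,
    r_squared,
    select_model,
    split_concentration_ranges,
)
from oxokinetics.models import CoordinateMethod, SiteParams, mm_rate
from oxokinetics.simulate import heart_liver_presets, simulate_saturation_series

DEFAULT_SPLIT_GRID = [0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1, 2.5, 5, 10]


class TestOneSiteNLS:
    def test_exact_recovery(self, exact_one_site_series):
        fit = fit_one_site_nls(exact_one_site_series())
        assert fit.km == pytest.approx(0.45, rel=1e-6)
        assert fit.amax == pytest.approx(0.73, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_order_invariance(self, exact_one_site_series):
        series = exact_one_site_series()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(series))
        shuffled = SaturationSeries(
            measurements=tuple(series.measurements[i] for i in perm)
        )
        f1, f2 = fit_one_site_nls(series), fit_one_site_nls(shuffled)
        assert f1.km == pytest.approx(f2.km, rel=1e-12)

    def test_noisy_recovery_rate(self):
        """Km within 15% of the cardiac OA truth in >= 90% of seeded runs."""
        config = heart_liver_presets()["heart_OA"]
        hits = 0
        n = 60
        for seed in range(n):
            fit = fit_one_site_nls(simulate_saturation_series(config, seed=seed))
            hits += abs(fit.km - 0.55) / 0.55 < 0.15
        assert hits / n >= 0.90

    def test_constant_rates_unidentifiable(self):
        s = np.array([0.1, 0.25, 0.5, 1.0, 2.5, 5.0])
        series = SaturationSeries.from_arrays(s, np.full_like(s, 0.5))
        try:
            fit = fit_one_site_nls(series)
        except FitError:
            return
        assert fit.se_km / fit.km > 1.0  # flagged enormous

    def test_decreasing_rates_fail(self):
        s = np.array([0.1, 0.25, 0.5, 1.0, 2.5, 5.0])
        series = SaturationSeries.from_arrays(s, 1.0 / (1.0 + s))
        with pytest.raises(FitError):
            fit_one_site_nls(series)

    def test_too_few_distinct_concentrations(self):
        series = SaturationSeries.from_arrays(
            [0.1, 0.5, 1.0], [0.2, 0.4, 0.5]
        )
        with pytest.raises(FitError, match="distinct"):
            fit_one_site_nls(series)

    def test_brute_force_grid_oracle(self):
        """Dense 2-D SSE grid search agrees with the optimizer on a small series."""
        rng = np.random.default_rng(42)
        s = np.array([0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0])
        a = mm_rate(s, SiteParams(km=0.45, amax=0.73))
        a = a * (1 + rng.normal(0, 0.03, a.shape))
        series = SaturationSeries.from_arrays(s, a)
        fit = fit_one_site_nls(series)
        kms = np.linspace(0.2, 0.9, 300)
        amaxs = np.linspace(0.5, 1.0, 300)
        K, A = np.meshgrid(kms, amaxs)
        sse = np.zeros_like(K)
        for si, ai in zip(s, a):
            sse += (ai - A * si / (K + si)) ** 2
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.km == pytest.approx(K[i, j], abs=kms[1] - kms[0])
        assert fit.amax == pytest.approx(A[i, j], abs=amaxs[1] - amaxs[0])


class TestTwoSiteNLS:
    def test_exact_recovery(self, exact_two_site_series):
        fit = fit_two_site_nls(exact_two_site_series())
        p = fit.params
        assert p.site1.km == pytest.approx(0.0077, rel=1e-6)
        assert p.site1.amax == pytest.approx(0.0018, rel=1e-6)
        assert p.site2.km == pytest.approx(0.45, rel=1e-6)
        assert p.site2.amax == pytest.approx(0.0075, rel=1e-6)
        assert not fit.degenerate

    def test_canonical_ordering(self, exact_two_site_series):
        fit = fit_two_site_nls(exact_two_site_series())
        assert fit.params.site1.km < fit.params.site2.km

    def test_noisy_recovery_rate(self):
        """Both Km values within 25% of truth in >= 80% of seeded runs."""
        config = heart_liver_presets()["liver_OA"]
        hits = 0
        n = 60
        for seed in range(n):
            fit = fit_two_site_nls(simulate_saturation_series(config, seed=seed))
            ok1 = abs(fit.params.site1.km - 0.0077) / 0.0077 < 0.25
            ok2 = abs(fit.params.site2.km - 0.45) / 0.45 < 0.25
            hits += ok1 and ok2
        assert hits / n >= 0.80

    def test_one_site_truth_flagged_degenerate(self, exact_one_site_series):
        fit = fit_two_site_nls(exact_one_site_series())
        assert fit.degenerate

    def test_too_few_concentrations(self):
        s = np.array([0.01, 0.05, 0.1, 0.5, 1.0, 5.0])
        series = SaturationSeries.from_arrays(s, s / (1 + s))
        with pytest.raises(FitError, match="distinct"):
            fit_two_site_nls(series)


class TestLinearized:
    @pytest.mark.parametrize("method", [CoordinateMethod.LB, CoordinateMethod.EH])
    def test_exact_identity(self, method, exact_one_site_series):
        fit = fit_linearized(exact_one_site_series(), method)
        assert fit.km == pytest.approx(0.45, rel=1e-10)
        assert fit.amax == pytest.approx(0.73, rel=1e-10)

    def test_coordinate_system_equivalence_on_exact_data(
        self, exact_one_site_series
    ):
        """The central oracle: NLS, LB and EH coincide on noise-free data."""
        series = exact_one_site_series(km=0.55, amax=0.102)
        fits = [
            fit_one_site_nls(series),
            fit_linearized(series, CoordinateMethod.LB),
            fit_linearized(series, CoordinateMethod.EH),
        ]
        kms = [f.km for f in fits]
        amaxs = [f.amax for f in fits]
        assert max(kms) - min(kms) < 1e-8 * 0.55
        assert max(amaxs) - min(amaxs) < 1e-8 * 0.102

    def test_two_point_input_rejected(self):
        series = SaturationSeries.from_arrays([0.5, 1.0], [0.3, 0.4])
        with pytest.raises(FitError):
            fit_linearized(series, CoordinateMethod.LB)

    def test_nls_method_tag_rejected(self, exact_one_site_series):
        with pytest.raises(ValueError):
            fit_linearized(exact_one_site_series(), CoordinateMethod.NLS)

    def test_below_floor_points_excluded(self, exact_one_site_series):
        series = exact_one_site_series()
        flagged = SaturationSeries.from_arrays(
            series.s, series.rate, below_floor=series.s < 0.01
        )
        fit = fit_linearized(flagged, CoordinateMethod.EH)
        assert fit.n_excluded == int((series.s < 0.01).sum())
        assert fit.km == pytest.approx(0.45, rel=1e-9)


class TestRangeSplit:
    def test_default_bounds_partition_counts(self):
        series = SaturationSeries.from_arrays(
            DEFAULT_SPLIT_GRID, np.linspace(0.1, 1.0, 12)
        )
        low, high = split_concentration_ranges(series)
        assert len(low) == 5 and len(high) == 7

    def test_boundary_point_belongs_to_low(self):
        assert 0.05 in [m.substrate_conc for m in split_concentration_ranges(
            SaturationSeries.from_arrays(
                DEFAULT_SPLIT_GRID, np.linspace(0.1, 1.0, 12)
            )
        )[0].measurements]

    def test_gap_points_assigned_to_neither(self):
        grid = [0.01, 0.02, 0.05, 0.07, 0.1, 0.5, 1.0]
        series = SaturationSeries.from_arrays(grid, np.linspace(0.1, 1, 7))
        low, high = split_concentration_ranges(series)
        assert len(low) + len(high) == 6  # 0.07 orphaned

    def test_empty_series_rejected(self):
        with pytest.raises(FitError):
            split_concentration_ranges(SaturationSeries(measurements=()))

    def test_sparse_partition_rejected(self):
        series = SaturationSeries.from_arrays(
            [0.01, 0.02, 0.1, 0.5, 1.0], np.linspace(0.1, 1, 5)
        )
        with pytest.raises(FitError, match="too few"):
            split_concentration_ranges(series)


class TestModelSelection:
    def test_zero_threshold_never_escalates(self, exact_two_site_series):
        choice = select_model(exact_two_site_series(), threshold=0.0)
        assert choice.selected == "one_site"

    def test_biphasic_truth_escalates(self, exact_two_site_series):
        choice = select_model(exact_two_site_series())
        assert choice.selected == "two_site"
        assert choice.r2_one_site < 0.98
        assert choice.r2_two_site == pytest.approx(1.0, abs=1e-9)

    def test_one_site_truth_stays(self, exact_one_site_series):
        choice = select_model(exact_one_site_series())
        assert choice.selected == "one_site"
        assert choice.r2_one_site > 0.98

    def test_selection_rates_under_noise(self):
        presets = heart_liver_presets()
        one = sum(
            select_model(
                simulate_saturation_series(presets["heart_OG"], seed=s)
            ).selected
            == "one_site"
            for s in range(40)
        )
        two = sum(
            select_model(
                simulate_saturation_series(presets["liver_OA"], seed=s)
            ).selected
            == "two_site"
            for s in range(40)
        )
        assert one / 40 >= 0.95
        assert two / 40 >= 0.90


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_zero(self):
        assert r_squared([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_hand_computation(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_negative_for_terrible_fit(self):
        assert r_squared([1, 2, 3], [10, -5, 0]) < 0
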