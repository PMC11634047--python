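"""Running average, model fitting/selection, Spearman, threshold inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fallrisk.curve import (
    EmptyCurveError,
    FittedModel,
    InsufficientDataError,
    ModelSelectionError,
    SmoothedCurve,
    fit_models,
    running_average,
    select_model,
    spearman_on_curve,
    threshold_frs,
)
from fallrisk.simulate import DEFAULT_RATE_COEFFS, weekly_rate


def brute_force_running_average(frs, rates, window, adaptive=False):
    """Independent oracle: explicit window membership per grid value."""
    frs = np.asarray(frs, float)
    rates = np.asarray(rates, float)
    grid = sorted(set(np.rint(frs)))
    out = []
    for v in grid:
        half = (window / 100.0) * v / 2.0 if adaptive else window / 2.0
        members = [r for f, r in zip(frs, rates) if v - half <= f <= v + half]
        if members:
            out.append((v, sum(members) / len(members), len(members)))
    return out


def rank_with_ties(values):
    """Average ranks, computed from first principles."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of average ranks."""
    rx, ry = np.array(rank_with_ties(x)), np.array(rank_with_ties(y))
    return float(np.corrcoef(rx, ry)[0, 1])


def reference_quadratic():
    return FittedModel("quadratic", DEFAULT_RATE_COEFFS)


class TestRunningAverage:
    def test_constant_rates_pass_through(self):
        curve = running_average([10, 20, 30, 31], [0.3] * 4, window=2)
        assert np.allclose(curve.rate, 0.3)

    def test_degenerate_window_is_identity(self):
        frs = [10, 20, 30, 40]
        rates = [0.1, 0.2, 0.3, 0.4]
        curve = running_average(frs, rates, window=1.0)
        assert curve.frs.tolist() == frs
        assert np.allclose(curve.rate, rates)
        assert curve.counts.tolist() == [1, 1, 1, 1]

    def test_neighbouring_points_average(self):
        curve = running_average([30, 31], [0.1, 0.3], window=2)
        assert curve.frs.tolist() == [30, 31]
        assert np.allclose(curve.rate, [0.2, 0.2])
        assert curve.counts.tolist() == [2, 2]

    def test_empty_input_raises(self):
        with pytest.raises(EmptyCurveError):
            running_average([], [], window=2)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=60).map(float),
                st.floats(min_value=0, max_value=1, allow_nan=False),
            ),
            min_size=1,
            max_size=60,
        ),
        st.sampled_from([1.0, 2.0, 4.0, 7.0]),
        st.booleans(),
    )
    def test_matches_brute_force_oracle(self, obs, window, adaptive):
        frs = [o[0] for o in obs]
        rates = [o[1] for o in obs]
        expected = brute_force_running_average(frs, rates, window, adaptive)
        curve = running_average(frs, rates, window, adaptive=adaptive)
        assert curve.frs.tolist() == [e[0] for e in expected]
        assert np.allclose(curve.rate, [e[1] for e in expected])
        assert curve.counts.tolist() == [e[2] for e in expected]

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=40).map(float),
                st.floats(min_value=0, max_value=1, allow_nan=False),
            ),
            min_size=2,
            max_size=40,
        )
    )
    def test_smoothed_value_bounded_by_window_extremes(self, obs):
        frs = np.array([o[0] for o in obs])
        rates = np.array([o[1] for o in obs])
        curve = running_average(frs, rates, window=2)
        for v, r in zip(curve.frs, curve.rate):
            members = rates[np.abs(frs - v) <= 1.0]
            assert members.min() - 1e-12 <= r <= members.max() + 1e-12


class TestFitAndSelect:
    def test_noiseless_quadratic_recovered(self):
        frs = np.arange(1.0, 72.0)
        rate = weekly_rate(frs, clamp=False)  # exact polynomial values
        # the raw polynomial dips below zero at low FRS; shift it up so the
        # points satisfy the curve's non-negativity invariant
        curve = SmoothedCurve(frs, rate - rate.min(), np.ones_like(frs), 2.0)
        models = {m.family: m for m in fit_models(curve)}
        q = models["quadratic"]
        a, b, c = DEFAULT_RATE_COEFFS
        assert q.coefficients[0] == pytest.approx(a, rel=1e-8)
        assert q.coefficients[1] == pytest.approx(b, rel=1e-8)
        assert q.coefficients[2] == pytest.approx(c - rate.min(), rel=1e-8)
        assert q.rmse == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_linear_degenerates_quadratic(self):
        frs = np.arange(0.0, 50.0)
        rate = 0.002 * frs + 0.01
        curve = SmoothedCurve(frs, rate, np.ones_like(frs), 2.0)
        models = {m.family: m for m in fit_models(curve, ("linear", "quadratic"))}
        assert abs(models["quadratic"].coefficients[0]) < 1e-12
        assert models["linear"].rmse == pytest.approx(0.0, abs=1e-12)
        assert models["quadratic"].rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_curve_fit_by_all_families(self):
        frs = np.arange(0.0, 12.0)
        curve = SmoothedCurve(frs, np.full_like(frs, 0.05), np.ones_like(frs), 2.0)
        for m in fit_models(curve):
            if m.converged:
                assert m.rmse == pytest.approx(0.0, abs=1e-8)
                assert np.allclose(m.predict(frs), 0.05, atol=1e-6)

    def test_too_few_points(self):
        curve = SmoothedCurve(
            np.array([1.0, 2.0, 3.0]), np.zeros(3), np.ones(3), 2.0
        )
        with pytest.raises(InsufficientDataError):
            fit_models(curve)

    def test_reported_rmse_pattern_selects_quadratic(self):
        models = [
            FittedModel("linear", (0.0, 0.0), rmse=0.017),
            FittedModel("quadratic", (1e-5, 0.0, 0.0), rmse=0.015),
            FittedModel("exponential", (1.0, 0.01, 0.0), rmse=0.016),
        ]
        assert select_model(models).family == "quadratic"

    def test_tie_breaks_toward_fewer_parameters(self):
        models = [
            FittedModel("quadratic", (1e-5, 0.0, 0.0), rmse=0.02),
            FittedModel("linear", (0.0, 0.0), rmse=0.02),
        ]
        assert select_model(models).family == "linear"

    def test_single_converged_model_selected(self):
        models = [
            FittedModel("exponential", (1, 0.01, 0), rmse=math.inf, converged=False),
            FittedModel("quadratic", (1e-5, 0, 0), rmse=0.5),
        ]
        assert select_model(models).family == "quadratic"

    def test_no_converged_model(self):
        with pytest.raises(ModelSelectionError):
            select_model(
                [FittedModel("exponential", (1, 1, 1), math.inf, converged=False)]
            )

    @given(
        st.lists(
            st.floats(min_value=0, max_value=0.5, allow_nan=False),
            min_size=5,
            max_size=40,
        )
    )
    def test_quadratic_rmse_never_exceeds_linear(self, rates):
        frs = np.arange(float(len(rates)))
        curve = SmoothedCurve(frs, np.array(rates), np.ones_like(frs), 2.0)
        models = {m.family: m for m in fit_models(curve, ("linear", "quadratic"))}
        assert models["quadratic"].rmse <= models["linear"].rmse + 1e-12


class TestSpearman:
    def test_perfect_monotone(self):
        frs = np.arange(5.0)
        up = SmoothedCurve(frs, np.array([0.1, 0.2, 0.3, 0.4, 0.5]), np.ones(5), 2.0)
        down = SmoothedCurve(frs, np.array([0.5, 0.4, 0.3, 0.2, 0.1]), np.ones(5), 2.0)
        assert spearman_on_curve(up).rho == pytest.approx(1.0)
        assert spearman_on_curve(down).rho == pytest.approx(-1.0)

    def test_one_swap_gives_point_nine(self):
        frs = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        rates = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assoc = spearman_on_curve(SmoothedCurve(frs, rates, np.ones(5), 2.0))
        assert assoc.rho == pytest.approx(0.9)
        assert 0 <= assoc.p_value <= 1

    def test_constant_rates_flagged_degenerate(self):
        curve = SmoothedCurve(np.arange(4.0), np.full(4, 0.2), np.ones(4), 2.0)
        assoc = spearman_on_curve(curve)
        assert assoc.degenerate
        assert assoc.rho is None and assoc.p_value is None

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=3,
            max_size=30,
        ).filter(lambda v: len(set(v)) > 1)
    )
    def test_matches_rank_formula_oracle(self, rates):
        frs = np.arange(float(len(rates)))
        curve = SmoothedCurve(frs, np.array(rates), np.ones_like(frs), 2.0)
        assert spearman_on_curve(curve).rho == pytest.approx(
            spearman_oracle(frs, rates), abs=1e-10
        )


class TestThresholds:
    @pytest.mark.parametrize("horizon,expected", [(26, 45), (52, 32), (104, 24)])
    def test_reference_model_thresholds(self, horizon, expected):
        assert threshold_frs(reference_quadratic(), horizon) == expected

    def test_matches_integer_scan_oracle(self):
        model = reference_quadratic()
        for h in (13, 26, 40, 52, 104, 208):
            scan = next(
                (v for v in range(0, 101) if model.predict(v) * h >= 1.0), None
            )
            assert threshold_frs(model, h) == scan

    def test_monotone_in_horizon(self):
        model = reference_quadratic()
        ts = [threshold_frs(model, h) for h in (13, 26, 52, 104, 208)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_no_threshold_signal(self):
        tiny = FittedModel("quadratic", (1e-9, 0.0, 0.0))
        assert threshold_frs(tiny, 26) is None

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            threshold_frs(reference_quadratic(), 0)

    def test_requires_convex_quadratic(self):
        with pytest.raises(ValueError, match="leading coefficient"):
            threshold_frs(FittedModel("quadratic", (-1e-5, 0.0, 0.0)), 26)

    def test_monotone_family_scan(self):
        lin = FittedModel("linear", (0.001, 0.0))
        # 0.001*FRS*26 >= 1  <=>  FRS >= 38.46 -> 39
        assert threshold_frs(lin, 26) == 39

    def test_round_trip_from_regenerated_curve(self):
        """Thresholds survive a refit on noiseless model-generated points."""
        frs = np.arange(10.0, 72.0)
        rate = weekly_rate(frs)
        curve = SmoothedCurve(frs, rate, np.ones_like(frs), 2.0)
        refit = {m.family: m for m in fit_models(curve, ("quadratic",))}["quadratic"]
        for h in (26, 52, 104):
            assert threshold_frs(refit, h) == threshold_frs(reference_quadratic(), h)
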