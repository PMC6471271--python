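"""Level-A IVIVC: fraction handling, model fit, reconvolution, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltivivc import (
    ConcentrationTimeProfile,
    FractionProfile,
    IvivcModel,
    align_timepoints,
    amounts_to_fractions,
    fit_ivivc,
    internal_validation,
    loo_riegelman,
    pk_metrics,
    prediction_error,
    reconvolve,
    simulate_iv_bolus,
    simulate_oral,
)
from saltivivc.pk import macro_constants

from .conftest import first_order_absorption_profile


def _amount_profile(times, amounts, label):
    return ConcentrationTimeProfile(
        times=np.asarray(times, float), concentrations=np.asarray(amounts, float),
        unit="ug", label=label, time_unit="min",
    )


def _fraction(times, fr, basis="dissolved", label="", unit="min"):
    return FractionProfile(
        times=np.asarray(times, float), fractions=np.asarray(fr, float),
        basis=basis, label=label, time_unit=unit,
    )


class TestAmountsToFractions:
    def test_global_maximum_normalization(self):
        t = [0, 30, 60, 120]
        profs = [
            _amount_profile(t, [0, 60, 90, 100], "fast"),
            _amount_profile(t, [0, 40, 70, 80], "mid"),
            _amount_profile(t, [0, 20, 45, 60], "slow"),
        ]
        fracs = {f.label: f for f in amounts_to_fractions(profs)}
        assert fracs["fast"].fractions[-1] == pytest.approx(1.0)
        assert fracs["mid"].fractions[-1] == pytest.approx(0.8)
        assert fracs["slow"].fractions[-1] == pytest.approx(0.6)

    def test_single_profile_normalized_by_own_max(self):
        (f,) = amounts_to_fractions([_amount_profile([0, 10, 20], [0, 5, 10], "a")])
        assert f.fractions[-1] == pytest.approx(1.0)

    def test_invariant_to_common_rescaling(self):
        t = [0, 30, 60]
        profs = [_amount_profile(t, [0, 50, 100], "a"), _amount_profile(t, [0, 30, 70], "b")]
        scaled = [
            p.with_concentrations(p.concentrations * 3.7) for p in profs
        ]
        f1 = amounts_to_fractions(profs)
        f2 = amounts_to_fractions(scaled)
        for a, b in zip(f1, f2):
            assert np.allclose(a.fractions, b.fractions)

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            amounts_to_fractions([_amount_profile([0, 10], [0, 0], "a")])


class TestAlignTimepoints:
    def test_identical_grids_identity(self):
        a = _fraction([0, 10, 20], [0, 0.5, 1.0])
        b = _fraction([0, 10, 20], [0, 0.3, 0.9])
        t, av, bv = align_timepoints(a, b)
        assert np.allclose(t, a.times)
        assert np.allclose(av, a.fractions)
        assert np.allclose(bv, b.fractions)

    def test_linear_interpolation_at_midpoint(self):
        a = _fraction([0, 10], [0, 1.0])
        b = _fraction([0, 5, 10], [0, 0.2, 0.6])
        t, av, bv = align_timepoints(a, b)
        assert 5.0 in t
        assert av[list(t).index(5.0)] == pytest.approx(0.5)

    def test_left_grid_uses_only_first_profiles_times(self):
        a = _fraction([0, 10, 20], [0, 0.5, 1.0])
        b = _fraction(np.arange(0, 21, 2.0), np.linspace(0, 1, 11))
        t, _, _ = align_timepoints(a, b, grid="left")
        assert np.allclose(t, a.times)

    def test_no_extrapolation_outside_overlap(self):
        a = _fraction([0, 10, 20], [0, 0.5, 1.0])
        b = _fraction([5, 15, 30], [0.1, 0.6, 0.9])
        t, _, _ = align_timepoints(a, b)
        assert t[0] >= 5 and t[-1] <= 20

    def test_empty_intersection_is_error(self):
        a = _fraction([0, 5], [0, 0.5])
        b = _fraction([10, 20], [0.1, 0.9])
        with pytest.raises(ValueError, match="overlap"):
            align_timepoints(a, b)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_interpolated_values_bracketed_by_neighbors(self, seed):
        rng = np.random.default_rng(seed)
        ta = np.cumsum(rng.uniform(1, 5, 6))
        fa = np.minimum(np.cumsum(rng.uniform(0, 0.2, 6)), 1.0)
        tb = np.cumsum(rng.uniform(1, 5, 6))
        fb = np.minimum(np.cumsum(rng.uniform(0, 0.2, 6)), 1.0)
        a = _fraction(ta, fa)
        b = _fraction(tb, fb)
        try:
            t, av, bv = align_timepoints(a, b)
        except ValueError:
            return
        for tt, vv in zip(t, av):
            lo = fa[ta <= tt + 1e-12].max(initial=0.0)
            hi = fa[ta >= tt - 1e-12].min(initial=1.0)
            left = fa[ta <= tt + 1e-12]
            right = fa[ta >= tt - 1e-12]
            assert left[-1] - 1e-9 <= vv <= right[0] + 1e-9


class TestFitIvivc:
    def test_recovers_known_hill_curve(self):
        truth = IvivcModel("hill", {"gamma": 1.6, "f50": 0.35})
        f = np.linspace(0.02, 1.0, 40)
        model = fit_ivivc(f, truth.predict(f))
        assert model.coefficients["gamma"] == pytest.approx(1.6, rel=0.01)
        assert model.coefficients["f50"] == pytest.approx(0.35, rel=0.01)
        assert model.r_squared > 0.9999

    def test_identity_pairs_fit_close_to_identity(self):
        f = np.linspace(0.0, 1.0, 21)
        model = fit_ivivc(f, f)
        grid = np.linspace(0, 1, 101)
        assert np.max(np.abs(model.predict(grid) - grid)) < 0.01

    def test_noisy_pairs_still_fit_well(self):
        rng = np.random.default_rng(77)
        truth = IvivcModel("hill", {"gamma": 1.4, "f50": 0.4})
        f = np.linspace(0.02, 1.0, 60)
        y = np.clip(truth.predict(f) + rng.normal(0, 0.03, f.size), 0, 1)
        model = fit_ivivc(f, y)
        assert model.r_squared > 0.95

    def test_prediction_stays_in_unit_interval(self):
        truth = IvivcModel("hill", {"gamma": 1.6, "f50": 0.35})
        f = np.linspace(0.02, 1.0, 30)
        model = fit_ivivc(f, truth.predict(f))
        grid = np.linspace(-0.5, 1.5, 201)
        pred = model.predict(grid)
        assert np.all((pred >= 0) & (pred <= 1))
        assert np.all(np.diff(model.predict(np.linspace(0, 1, 101))) >= -1e-9)

    def test_rejects_non_monotone_cubic(self):
        coeffs = {"c1": 3.0, "c2": -6.0, "c3": 3.5}  # dips on (0, 1)
        f = np.linspace(0.0, 1.0, 30)
        y = np.clip(coeffs["c1"] * f + coeffs["c2"] * f**2 + coeffs["c3"] * f**3, 0, 1)
        with pytest.raises(RuntimeError, match="monotone"):
            fit_ivivc(f, y, form="polynomial3")

    def test_requires_span_and_count(self):
        with pytest.raises(ValueError):
            fit_ivivc([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        f = np.linspace(0.4, 0.6, 10)
        with pytest.raises(ValueError, match="span"):
            fit_ivivc(f, f)


class TestReconvolve:
    def test_zero_absorption_gives_zero_profile(self, disposition):
        fa = _fraction([0, 30, 60], [0, 0, 0], basis="absorbed")
        prof = reconvolve(fa, disposition, 5.0)
        assert np.all(prof.concentrations == 0)

    def test_round_trip_with_deconvolution(self, disposition):
        times = np.arange(0.0, 12.0001, 1.0 / 6.0)  # 10-min sampling
        prof = first_order_absorption_profile(disposition, 22500.0, 2.0, times)
        fa = loo_riegelman(prof, disposition)
        rec = reconvolve(fa, disposition, fa.metadata["plateau_over_v1"])
        rc = np.interp(times, rec.times, rec.concentrations)
        mask = prof.concentrations > 0
        rel = np.abs(rc[mask] - prof.concentrations[mask]) / prof.concentrations[mask]
        assert np.max(rel) < 0.02

    def test_matches_forward_convolution_oracle(self, disposition):
        # reconvolution driven by the exact absorbed-amount series must agree
        # with the exact linear-system propagation of the same input
        # absorption half-time ~40 min, resolved by the 15-min sampling grid
        ka, amount = 1.0, 22500.0
        times = np.arange(0.0, 12.0001, 0.25)
        fa_vals = (1 - np.exp(-ka * times)) / (1 - np.exp(-ka * times[-1]))
        fa = _fraction(times, fa_vals, basis="absorbed", unit="h")
        scale = amount * (1 - np.exp(-ka * times[-1])) / disposition.v1
        rec = reconvolve(fa, disposition, scale)
        oracle = first_order_absorption_profile(disposition, amount, ka, times)
        rc = np.interp(times, rec.times / 1.0, rec.concentrations)
        mask = oracle.concentrations > 0.01 * oracle.concentrations.max()
        rel = np.abs(rc[mask] - oracle.concentrations[mask]) / oracle.concentrations[mask]
        assert np.max(rel) < 0.02

    def test_grid_refinement_reduces_oracle_deviation(self, disposition):
        ka, amount = 2.0, 22500.0
        times = np.arange(0.0, 12.0001, 0.5)
        fa_vals = (1 - np.exp(-ka * times)) / (1 - np.exp(-ka * times[-1]))
        fa = _fraction(times, fa_vals, basis="absorbed", unit="h")
        scale = amount * (1 - np.exp(-ka * times[-1])) / disposition.v1
        oracle = first_order_absorption_profile(disposition, amount, ka, times)
        devs = []
        for dt_max in (15.0, 7.5, 3.75):
            rec = reconvolve(fa, disposition, scale, dt_max_min=dt_max)
            rc = np.interp(times, rec.times, rec.concentrations)
            mask = oracle.concentrations > 0
            devs.append(np.max(np.abs(rc[mask] - oracle.concentrations[mask])))
        assert devs[2] < devs[1] < devs[0]


class TestMetricsAndErrors:
    def test_cmax_of_decreasing_profile_is_first_point(self, disposition):
        prof = simulate_iv_bolus(disposition, 25000.0, np.linspace(0, 12, 25))
        cmax, _ = pk_metrics(prof)
        assert cmax == prof.concentrations[0]

    def test_triangle_auc(self):
        prof = ConcentrationTimeProfile(
            times=[0.0, 1.0, 2.0], concentrations=[0.0, 10.0, 0.0],
            unit="ug/mL", time_unit="h",
        )
        assert pk_metrics(prof)[1] == pytest.approx(10.0)

    def test_biexponential_auc_matches_closed_form(self, disposition):
        t = np.arange(0.0, 12.0001, 0.02)
        prof = simulate_iv_bolus(disposition, 25000.0, t)
        a, alpha, b, beta = macro_constants(disposition, 25000.0)
        closed = a / alpha * (1 - np.exp(-alpha * t[-1])) + b / beta * (
            1 - np.exp(-beta * t[-1])
        )
        assert pk_metrics(prof)[1] == pytest.approx(closed, rel=5e-3)

    @pytest.mark.parametrize(
        "exp, pred, re",
        [(2430.6, 2576.3, -5.99), (3177.3, 3062.5, 3.61), (100.0, 100.0, 0.0)],
    )
    def test_signed_relative_prediction_error(self, exp, pred, re):
        assert prediction_error(exp, pred) == pytest.approx(re, abs=0.01)

    def test_zero_experimental_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(0.0, 1.0)


class TestInternalValidation:
    def _setup(self, disposition):
        times = np.arange(0.0, 121.0, 5.0)
        fd = {
            "a": _fraction(times, 1 - np.exp(-0.04 * times), label="a"),
            "b": _fraction(times, 1 - np.exp(-0.025 * times), label="b"),
        }
        model = IvivcModel("hill", {"gamma": 1.2, "f50": 0.5})
        scales = {"a": 6.0, "b": 5.5}
        return fd, model, scales

    def test_self_consistent_metrics_give_zero_error(self, disposition):
        fd, model, scales = self._setup(disposition)
        # experimental metrics computed from the model's own predictions
        exp = {}
        for name in fd:
            fa = _fraction(fd[name].times, model.predict(fd[name].fractions),
                           basis="absorbed", label=name)
            prof = reconvolve(fa, disposition, scales[name], extend_to=720.0)
            cmax, auc = pk_metrics(prof)
            exp[name] = {"cmax": cmax, "auc": auc}
        report = internal_validation(fd, model, disposition, exp, scales,
                                     extend_to=720.0)
        assert report.average_abs_re["cmax"] == pytest.approx(0.0, abs=1e-9)
        assert report.average_abs_re["auc"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_experimental_metrics_drops_row(self, disposition):
        fd, model, scales = self._setup(disposition)
        exp = {"a": {"cmax": 5.0, "auc": 500.0}}
        report = internal_validation(fd, model, disposition, exp, scales,
                                     extend_to=720.0)
        assert set(report.rows) == {"a"}

    def test_averages_are_means_of_absolute_errors(self, disposition):
        fd, model, scales = self._setup(disposition)
        exp = {"a": {"cmax": 5.0, "auc": 500.0}, "b": {"cmax": 4.0, "auc": 450.0}}
        report = internal_validation(fd, model, disposition, exp, scales,
                                     extend_to=720.0)
        assert report.average_abs_re["cmax"] == pytest.approx(
            np.mean([abs(r["cmax_re"]) for r in report.rows.values()])
        )
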