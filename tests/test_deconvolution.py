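"""Loo-Riegelman deconvolution: exactness, reductions and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltivivc import (
    ConcentrationTimeProfile,
    DispositionParams,
    TruncatedAbsorptionError,
    cumulative_auc,
    loo_riegelman,
    normalize_cross_study,
    peripheral_profile,
    simulate_iv_bolus,
    simulate_oral,
    wagner_nelson,
)
from saltivivc.pk import macro_constants

from .conftest import first_order_absorption_profile, ode_two_compartment


def _profile(times_h, conc, label="x"):
    return ConcentrationTimeProfile(
        times=np.asarray(times_h, float), concentrations=np.asarray(conc, float),
        unit="ug/mL", label=label, time_unit="h",
    )


class TestCumulativeAuc:
    def test_constant_concentration(self):
        prof = _profile([0, 1, 2, 5], [3.0, 3.0, 3.0, 3.0])
        assert np.allclose(cumulative_auc(prof), [0, 3, 6, 15])

    def test_single_point_is_zero(self):
        assert cumulative_auc(_profile([1.0], [4.0])) == pytest.approx([0.0])

    def test_biexponential_matches_closed_form(self, disposition):
        t = np.arange(0.0, 12.0001, 0.02)
        prof = simulate_iv_bolus(disposition, 25000.0, t)
        a, alpha, b, beta = macro_constants(disposition, 25000.0)
        closed = a / alpha * (1 - np.exp(-alpha * t)) + b / beta * (1 - np.exp(-beta * t))
        auc = cumulative_auc(prof)
        assert np.allclose(auc[1:], closed[1:], rtol=1e-3)


class TestPeripheralProfile:
    def test_zero_concentration_gives_zero(self, disposition):
        prof = _profile([0, 1, 2], [0, 0, 0])
        assert np.all(peripheral_profile(prof, disposition) == 0)

    def test_constant_concentration_steady_state(self, disposition):
        # driven at constant C the peripheral amount approaches (k12/k21)·C
        t = np.arange(0.0, 40.0, 0.5)
        c = np.full(t.size, 2.0)
        c[0] = 0.0  # oral start
        prof = _profile(t, c)
        p = peripheral_profile(prof, disposition)
        expected = disposition.k12 / disposition.k21 * 2.0
        assert p[-1] == pytest.approx(expected, rel=1e-3)

    def test_matches_ode_peripheral_amounts(self, disposition):
        # finely sampled oral profile: the piecewise-linear discretization
        # must track the continuous peripheral amount within 0.5%
        times = np.arange(0.0, 12.0001, 0.05)
        prof = first_order_absorption_profile(disposition, 22500.0, 1.0, times)

        def rate(t):
            return 22500.0 * 1.0 * np.exp(-1.0 * t)

        _, xp = ode_two_compartment(disposition, times, rate_fn=rate)
        p = peripheral_profile(prof, disposition)
        oracle = xp / disposition.v1
        assert np.max(np.abs(p - oracle)) / oracle.max() < 0.005
        mask = oracle > 0.25 * oracle.max()
        assert np.max(np.abs(p[mask] - oracle[mask]) / oracle[mask]) < 0.005


class TestLooRiegelman:
    def test_recovers_first_order_absorption(self, disposition):
        times = np.arange(0.0, 12.0001, 0.25)
        ka = 2.0
        prof = first_order_absorption_profile(disposition, 22500.0, ka, times)
        fa = loo_riegelman(prof, disposition)
        truth = (1 - np.exp(-ka * times)) / (1 - np.exp(-ka * times[-1]))
        assert np.max(np.abs(fa.fractions - truth)) < 0.02

    def test_reduces_to_wagner_nelson_without_peripheral_compartment(self):
        p = DispositionParams(v1=2000.0, k10=0.8, k12=1e-12, k21=1.0)
        times = np.arange(0.0, 12.0001, 0.25)
        prof = first_order_absorption_profile(p, 10000.0, 1.7, times)
        lr = loo_riegelman(prof, p)
        wn = wagner_nelson(prof, p.k10)
        assert np.max(np.abs(lr.fractions - wn.fractions)) < 1e-6

    def test_final_fraction_is_one(self, disposition):
        times = np.arange(0.0, 12.0001, 0.25)
        prof = first_order_absorption_profile(disposition, 22500.0, 2.0, times)
        fa = loo_riegelman(prof, disposition)
        assert fa.fractions[-1] == pytest.approx(1.0)

    def test_invariant_to_concentration_rescaling(self, disposition):
        times = np.arange(0.0, 12.0001, 0.25)
        prof = first_order_absorption_profile(disposition, 22500.0, 2.0, times)
        scaled = prof.with_concentrations(prof.concentrations * 7.3)
        fa = loo_riegelman(prof, disposition)
        fa_scaled = loo_riegelman(scaled, disposition)
        assert np.allclose(fa.fractions, fa_scaled.fractions, atol=1e-12)
        assert fa_scaled.metadata["plateau_over_v1"] == pytest.approx(
            7.3 * fa.metadata["plateau_over_v1"]
        )

    def test_signals_truncated_absorption(self, disposition):
        times = np.arange(0.0, 1.26, 0.25)  # cut off mid-absorption
        prof = first_order_absorption_profile(disposition, 22500.0, 2.0, times)
        with pytest.raises(TruncatedAbsorptionError):
            loo_riegelman(prof, disposition)

    def test_rejects_nonzero_initial_concentration(self, disposition):
        prof = _profile([0, 1, 2, 3, 8, 12], [0.5, 3, 2, 1.5, 0.4, 0.1])
        with pytest.raises(ValueError, match="C=0"):
            loo_riegelman(prof, disposition)
        loo_riegelman(prof, disposition, backextrapolate_c0=True, plateau_rtol=0.5)

    def test_grid_refinement_halves_oracle_deviation(self, disposition):
        # trapezoid + piecewise-linear scheme is second order: halving the
        # sampling interval should cut the amount error by at least 2x
        ka, amount = 2.0, 22500.0
        errs = []
        for dt in (0.5, 0.25):
            times = np.arange(0.0, 12.0001, dt)
            prof = first_order_absorption_profile(disposition, amount, ka, times)
            fa = loo_riegelman(prof, disposition)
            raw = fa.metadata["raw_amounts_over_v1"]
            truth = amount * (1 - np.exp(-ka * times)) / disposition.v1
            errs.append(np.max(np.abs(raw - truth)))
        assert errs[1] * 2 <= errs[0]


class TestRoundTripProperty:
    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        k10=st.floats(0.4, 3.0),
        k12=st.floats(0.1, 2.0),
        k21=st.floats(0.3, 2.0),
        ka=st.floats(0.5, 2.0),
    )
    def test_reconvolution_inverts_deconvolution(self, k10, k12, k21, ka):
        """Deconvolve→reconvolve reproduces any simulated oral profile within
        2% at every sampling time, for arbitrary disposition constants and
        first-order absorption inputs on a 10-min grid."""
        from saltivivc.ivivc import reconvolve

        params = DispositionParams(v1=2500.0, k10=k10, k12=k12, k21=k21)
        times = np.arange(0.0, 12.0001, 1.0 / 6.0)
        prof = first_order_absorption_profile(params, 15000.0, ka, times)
        fa = loo_riegelman(prof, params)
        rec = reconvolve(fa, params, fa.metadata["plateau_over_v1"])
        rc = np.interp(times, rec.times, rec.concentrations)
        cmax = prof.concentrations.max()
        err = np.abs(rc - prof.concentrations)
        assert np.max(err) / cmax < 0.02
        mask = prof.concentrations > 0.05 * cmax
        assert np.max(err[mask] / prof.concentrations[mask]) < 0.02


class TestCrossStudyNormalization:
    def _triplet(self, factor_anchor=1.0, factor_study=1.0):
        t = np.arange(0.0, 6.0, 0.5)
        base = np.exp(-0.5 * t) * (1 - np.exp(-3 * t)) * 10
        ref_study = _profile(t, base * factor_study, "ref")
        ref_anchor = _profile(t, base * factor_anchor, "ref")
        test = _profile(t, base * 1.3 * factor_study, "test")
        return test, ref_study, ref_anchor

    def test_identical_references_leave_test_unchanged(self):
        test, ref_s, ref_a = self._triplet()
        out = normalize_cross_study(test, ref_s, ref_s)
        assert np.allclose(out.concentrations, test.concentrations)

    def test_doubled_anchor_doubles_test(self):
        test, ref_s, _ = self._triplet()
        ref_a = ref_s.with_concentrations(ref_s.concentrations * 2)
        out = normalize_cross_study(test, ref_s, ref_a)
        assert np.allclose(out.concentrations, 2 * test.concentrations)

    def test_auc_variant_agrees_for_proportional_study_effect(self):
        test, ref_s, ref_a = self._triplet(factor_anchor=1.0, factor_study=1.1)
        pointwise = normalize_cross_study(test, ref_s, ref_a)
        auc_based = normalize_cross_study(test, ref_s, ref_a, mode="auc")
        rel = np.abs(pointwise.concentrations[1:] - auc_based.concentrations[1:])
        rel /= pointwise.concentrations[1:]
        assert np.max(rel) < 0.02

    def test_floors_zero_reference_where_test_nonzero(self):
        t = np.arange(0.0, 3.0, 0.5)
        ref = _profile(t, np.zeros(t.size), "ref")
        test = _profile(t, np.linspace(0, 5, t.size), "test")
        with pytest.raises(ValueError, match="floor"):
            normalize_cross_study(test, ref, ref)

    def test_requires_shared_sampling_times(self):
        test, ref_s, _ = self._triplet()
        shifted = _profile(ref_s.times + 0.25, ref_s.concentrations, "ref")
        with pytest.raises(ValueError, match="sampling times"):
            normalize_cross_study(test, shifted, ref_s)
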