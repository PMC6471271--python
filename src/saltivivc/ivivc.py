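"""Two-step level-A in vitro-in vivo correlation (IVIVC).

Level A correlates the in vitro fraction dissolved f_diss(t) point-to-point
with the in vivo fraction absorbed f_abs(t) obtained by deconvolution. The
workflow implemented here:

1. :func:`amounts_to_fractions` — turn cumulative dissolved amounts into
   fractions using the single global maximum across formulations, so the
   fastest formulation reaches 1.0 and slower ones plateau below it.
2. :func:`align_timepoints` — pair the two fraction curves on the union of
   their grids by linear interpolation, never extrapolating.
3. :func:`fit_ivivc` — fit a monotone relationship f_abs = g(f_diss), by
   default a two-parameter Hill curve constrained through (0,0) and (1,1):
   g(f) = f^γ·(1 + f50^γ)/(f50^γ + f^γ). A cubic polynomial through the
   origin is available as an alternative form.
4. :func:`reconvolve` — back-transform a fraction-absorbed curve into a
   plasma profile by stepwise inversion of the two-compartment mass balance
   (the exact algebraic inverse of the deconvolution discretization:
   trapezoidal elimination term, exact piecewise-linear peripheral term).
5. :func:`internal_validation` — predict f_abs from each formulation's
   experimental f_diss, reconvolve to plasma, and compare predicted Cmax/AUC
   to the experimental values via the signed relative prediction error
   RE% = 100·(experimental − predicted)/experimental.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .deconvolution import _peripheral_weights
from .pk import DispositionParams
from .profiles import ConcentrationTimeProfile, FractionProfile

__all__ = [
    "IvivcModel",
    "ValidationReport",
    "amounts_to_fractions",
    "align_timepoints",
    "fit_ivivc",
    "reconvolve",
    "pk_metrics",
    "prediction_error",
    "internal_validation",
]


# ---------------------------------------------------------------------------
# fractions and pairing

def amounts_to_fractions(profiles: Iterable[ConcentrationTimeProfile]) -> list[FractionProfile]:
    """Normalize cumulative dissolved-amount profiles by their global maximum.

    All profiles are divided by the single largest amount observed across the
    whole set, so exactly one formulation attains fraction 1.0 and relative
    extents of dissolution are preserved. Small non-monotone dips (sampling
    noise) are removed with a running-maximum pass; raw fractions are kept in
    metadata.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile is required")
    global_max = max(float(np.max(p.concentrations)) for p in profiles)
    if global_max <= 0:
        raise ValueError("all profiles are zero; cannot form fractions")
    out = []
    for p in profiles:
        raw = p.concentrations / global_max
        mono = np.minimum(np.maximum.accumulate(raw), 1.0)
        if p.times[0] == 0:
            mono[0] = 0.0 if raw[0] == 0 else mono[0]
        out.append(
            FractionProfile(
                times=p.times.copy(), fractions=mono, basis="dissolved",
                label=p.label, time_unit=p.time_unit,
                metadata={"raw_fractions": raw, "global_max": global_max,
                          "amount_unit": p.unit},
            )
        )
    return out


def align_timepoints(
    a: FractionProfile, b: FractionProfile, *, grid: str = "union"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair two fraction curves inside their common time range.

    Values are linearly interpolated within each profile; times outside the
    intersection of the two ranges are dropped (no extrapolation). Returns
    ``(times, a_values, b_values)`` in ``a``'s time unit. ``grid`` selects
    the pairing times: ``"union"`` uses every sampling time of either curve;
    ``"left"`` uses only ``a``'s sampling times, appropriate when ``a`` is
    the sparser (e.g. in vivo) curve — interpolating a sparse curve at a
    dense partner's times would distort its shape between samples.
    """
    b = b.in_time_unit(a.time_unit)
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if hi <= lo:
        raise ValueError("time ranges do not overlap; cannot pair the profiles")
    if grid == "union":
        pts = np.union1d(a.times, b.times)
    elif grid == "left":
        pts = a.times
    else:
        raise ValueError("grid must be 'union' or 'left'")
    pts = pts[(pts >= lo) & (pts <= hi)]
    return pts, a.interp(pts), b.interp(pts)


# ---------------------------------------------------------------------------
# the correlation model

@dataclass
class IvivcModel:
    """Monotone in vitro → in vivo relationship f_abs = g(f_diss).

    ``form`` is ``"hill"`` (default, passes through (0,0) and (1,1)) or
    ``"polynomial3"`` (cubic through the origin). ``fit_diagnostics`` holds
    R² and the fit residuals.
    """

    form: str
    coefficients: dict[str, float]
    fit_diagnostics: dict = field(default_factory=dict)

    def predict(self, f_diss) -> np.ndarray:
        f = np.clip(np.asarray(f_diss, dtype=float), 0.0, 1.0)
        if self.form == "hill":
            g = self.coefficients["gamma"]
            f50 = self.coefficients["f50"]
            num = np.power(f, g) * (1.0 + f50 ** g)
            return np.clip(num / (f50 ** g + np.power(f, g)), 0.0, 1.0)
        if self.form == "polynomial3":
            c1, c2, c3 = (self.coefficients[k] for k in ("c1", "c2", "c3"))
            return np.clip(c1 * f + c2 * f * f + c3 * f ** 3, 0.0, 1.0)
        raise ValueError(f"unknown model form {self.form!r}")

    @property
    def r_squared(self) -> float:
        return self.fit_diagnostics.get("r_squared", float("nan"))


def fit_ivivc(
    f_dissolved,
    f_absorbed,
    *,
    form: str = "hill",
) -> IvivcModel:
    """Least-squares fit of the dissolved→absorbed relationship.

    ``f_dissolved``/``f_absorbed`` are pooled paired fractions over all
    formulations. Requires at least 6 pairs spanning at least half of the
    unit interval. The fitted curve is checked for monotonicity on a 0.01
    grid and rejected if it is not non-decreasing.
    """
    fd = np.asarray(f_dissolved, dtype=float)
    fa = np.asarray(f_absorbed, dtype=float)
    if fd.shape != fa.shape or fd.ndim != 1:
        raise ValueError("f_dissolved and f_absorbed must be 1-D and paired")
    if fd.size < 6:
        raise ValueError("at least 6 pairs are required")
    if fd.max() - fd.min() < 0.5:
        raise ValueError("pairs must span at least 0.5 of the unit interval")

    p = Parameters()
    if form == "hill":
        p.add("gamma", value=1.0, min=0.05, max=20.0)
        p.add("f50", value=0.5, min=1e-3, max=1e3)

        def model(pars, f):
            return IvivcModel(
                "hill", {"gamma": pars["gamma"].value, "f50": pars["f50"].value}
            ).predict(f)
    elif form == "polynomial3":
        p.add("c1", value=1.0)
        p.add("c2", value=0.0)
        p.add("c3", value=0.0)

        def model(pars, f):
            return pars["c1"].value * f + pars["c2"].value * f ** 2 + pars["c3"].value * f ** 3
    else:
        raise ValueError("form must be 'hill' or 'polynomial3'")

    out = minimize(lambda pars: model(pars, fd) - fa, p, method="leastsq",
                   xtol=1e-12, ftol=1e-12)
    if not out.success:
        raise RuntimeError(f"IVIVC fit did not converge: {out.message}")
    coeffs = {k: out.params[k].value for k in out.params}
    resid = np.asarray(out.residual)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((fa - fa.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    model_obj = IvivcModel(
        form=form, coefficients=coeffs,
        fit_diagnostics={"r_squared": r2, "residuals": resid, "n_pairs": fd.size},
    )
    grid = model_obj.predict(np.linspace(0, 1, 101))
    if np.any(np.diff(grid) < -1e-9):
        raise RuntimeError("fitted IVIVC curve is not monotone on [0, 1]")
    return model_obj


# ---------------------------------------------------------------------------
# reconvolution and validation

def reconvolve(
    f_abs: FractionProfile,
    params: DispositionParams,
    total_absorbed_over_v1: float,
    *,
    dt_max_min: float = 5.0,
    extend_to: float | None = None,
    label: str | None = None,
    unit: str = "ug/mL",
) -> ConcentrationTimeProfile:
    """Back-transform a fraction-absorbed curve into a plasma profile.

    ``total_absorbed_over_v1`` is the plateau absorbed amount divided by the
    central volume (concentration units) — typically the plateau stored by
    the deconvolution. At each step the two-compartment mass balance

        X_A/Vc = C + k10·AUC + P

    is solved for the current concentration, with the trapezoid rule for the
    elimination integral and the exact piecewise-linear update for the
    peripheral amount; this is the algebraic inverse of the Loo-Riegelman
    discretization. The working grid subdivides every interval to at most
    ``dt_max_min`` minutes to bound discretization error. ``extend_to``
    (same unit as ``f_abs.times``) continues the curve past its last sample
    holding the plateau, letting the profile decay. Negative intermediate
    concentrations are floored at zero and counted in
    ``metadata["negatives_floored"]``.
    """
    if total_absorbed_over_v1 < 0:
        raise ValueError("total_absorbed_over_v1 must be non-negative")
    prof = f_abs.in_time_unit("h")
    t = prof.times
    frac = prof.fractions
    if extend_to is not None:
        ext = extend_to * (1.0 / 60.0 if f_abs.time_unit == "min" else 1.0)
        if ext > t[-1]:
            t = np.append(t, ext)
            frac = np.append(frac, frac[-1])
    dt_max_h = dt_max_min / 60.0
    fine = [t[0]]
    for i in range(t.size - 1):
        n_sub = max(1, int(math.ceil((t[i + 1] - t[i]) / dt_max_h)))
        fine.extend(np.linspace(t[i], t[i + 1], n_sub + 1)[1:])
    tf = np.asarray(fine)
    xa = total_absorbed_over_v1 * np.interp(tf, t, frac)

    k10, k12, k21 = params.k10, params.k12, params.k21
    dt = np.diff(tf)
    a_w, b_w = _peripheral_weights(k21, dt)
    e = np.exp(-k21 * dt)
    c = np.zeros_like(tf)
    c[0] = xa[0]  # X_A(0)/Vc with empty peripheral compartment and no AUC yet
    auc = 0.0
    p = 0.0
    floored = 0
    for i in range(1, tf.size):
        d = dt[i - 1]
        known = (
            k10 * (auc + c[i - 1] * d / 2.0)
            + p * e[i - 1]
            + k12 * a_w[i - 1] * c[i - 1]
        )
        denom = 1.0 + k10 * d / 2.0 + k12 * b_w[i - 1]
        ci = (xa[i] - known) / denom
        if ci < 0:
            ci = 0.0
            floored += 1
        c[i] = ci
        auc += 0.5 * (c[i - 1] + c[i]) * d
        p = p * e[i - 1] + k12 * (a_w[i - 1] * c[i - 1] + b_w[i - 1] * c[i])

    # return the full working grid: downstream metrics (trapezoid AUC of a
    # decaying profile) need the fine resolution, not just the input samples
    factor = 60.0 if f_abs.time_unit == "min" else 1.0
    return ConcentrationTimeProfile(
        times=tf * factor, concentrations=c, unit=unit,
        label=label if label is not None else (f_abs.label or "reconvolved"),
        time_unit=f_abs.time_unit,
        metadata={"negatives_floored": floored, "dt_max_min": dt_max_min},
    )


def pk_metrics(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """(Cmax, AUC to the last sample) of a plasma profile.

    Cmax is the maximum observed concentration; the AUC uses the linear
    trapezoid rule up to the last sampling time, with no extrapolation.
    """
    c = profile.concentrations
    auc = float(np.trapezoid(c, profile.times))
    return float(np.max(c)), auc


def prediction_error(experimental: float, predicted: float) -> float:
    """Signed relative prediction error RE% = 100·(exp − pred)/exp."""
    if experimental == 0:
        raise ValueError("experimental value must be nonzero")
    return 100.0 * (experimental - predicted) / experimental


@dataclass
class ValidationReport:
    """Per-formulation experimental vs predicted exposure metrics.

    ``rows`` maps formulation label → dict with ``cmax_exp``, ``cmax_pred``,
    ``cmax_re``, ``auc_exp``, ``auc_pred``, ``auc_re``;
    ``average_abs_re`` holds the mean absolute RE% per metric.
    """

    rows: dict[str, dict[str, float]]
    average_abs_re: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        avg = {k: float("nan") for k in df.columns}
        avg["cmax_re"] = self.average_abs_re["cmax"]
        avg["auc_re"] = self.average_abs_re["auc"]
        df.loc["average"] = avg
        return df


def report_from_metric_pairs(metrics: Mapping[str, Mapping[str, float]]) -> ValidationReport:
    """Build a :class:`ValidationReport` from precomputed metric pairs.

    ``metrics`` maps label → dict with ``cmax_exp``, ``cmax_pred``,
    ``auc_exp``, ``auc_pred`` (e.g. a published validation table); RE% and
    averages are recomputed from the pairs.
    """
    rows = {}
    for name, m in metrics.items():
        rows[name] = {
            "cmax_exp": m["cmax_exp"], "cmax_pred": m["cmax_pred"],
            "cmax_re": prediction_error(m["cmax_exp"], m["cmax_pred"]),
            "auc_exp": m["auc_exp"], "auc_pred": m["auc_pred"],
            "auc_re": prediction_error(m["auc_exp"], m["auc_pred"]),
        }
    if not rows:
        raise ValueError("no metric pairs supplied")
    return ValidationReport(
        rows=rows,
        average_abs_re={
            "cmax": float(np.mean([abs(r["cmax_re"]) for r in rows.values()])),
            "auc": float(np.mean([abs(r["auc_re"]) for r in rows.values()])),
        },
    )


def internal_validation(
    f_diss: Mapping[str, FractionProfile],
    model: IvivcModel,
    params: DispositionParams,
    experimental_metrics: Mapping[str, Mapping[str, float]],
    scales: Mapping[str, float],
    *,
    extend_to: float | None = None,
    dt_max_min: float = 5.0,
    metric_times: Mapping[str, np.ndarray] | None = None,
) -> ValidationReport:
    """Internally validate an IVIVC against the formulations that built it.

    For every formulation with experimental metrics available, the model maps
    the experimental fraction dissolved to a predicted fraction absorbed,
    which is reconvolved (scaled by ``scales[label]``, the deconvolved
    plateau per central volume) into a predicted plasma profile; predicted
    Cmax and AUC are then compared with ``experimental_metrics[label]``
    (keys ``cmax`` and ``auc``) via the signed RE%. Formulations lacking
    experimental metrics are skipped. ``extend_to`` continues the predicted
    profile beyond the dissolution window so late decay contributes to AUC.
    ``metric_times`` (per formulation, same time unit as the dissolution
    curves) samples the predicted profile at the experimental sampling times
    before computing metrics, so predicted and experimental Cmax/AUC share
    the same observation grid.
    """
    rows: dict[str, dict[str, float]] = {}
    for name, fd in f_diss.items():
        if name not in experimental_metrics:
            continue
        if name not in scales:
            raise KeyError(f"no reconvolution scale for formulation {name!r}")
        fa_pred = model.predict(fd.fractions)
        fa_prof = FractionProfile(
            times=fd.times.copy(), fractions=np.maximum.accumulate(fa_pred),
            basis="absorbed", label=name, time_unit=fd.time_unit,
        )
        try:
            pred = reconvolve(
                fa_prof, params, scales[name],
                extend_to=extend_to, dt_max_min=dt_max_min,
            )
            if metric_times is not None and name in metric_times:
                mt = np.asarray(metric_times[name], dtype=float)
                mt = mt[(mt >= pred.times[0]) & (mt <= pred.times[-1])]
                pred = ConcentrationTimeProfile(
                    times=mt, concentrations=pred.interp(mt), unit=pred.unit,
                    label=pred.label, time_unit=pred.time_unit,
                )
            cmax_pred, auc_pred = pk_metrics(pred)
            exp = experimental_metrics[name]
            rows[name] = {
                "cmax_exp": exp["cmax"], "cmax_pred": cmax_pred,
                "cmax_re": prediction_error(exp["cmax"], cmax_pred),
                "auc_exp": exp["auc"], "auc_pred": auc_pred,
                "auc_re": prediction_error(exp["auc"], auc_pred),
            }
        except Exception as err:
            raise RuntimeError(f"validation failed for formulation {name!r}: {err}") from err
    if not rows:
        raise ValueError("no formulation had both dissolution data and experimental metrics")
    return ValidationReport(
        rows=rows,
        average_abs_re={
            "cmax": float(np.mean([abs(r["cmax_re"]) for r in rows.values()])),
            "auc": float(np.mean([abs(r["auc_re"]) for r in rows.values()])),
        },
    )
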