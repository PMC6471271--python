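"""Time-series containers shared across the package.

Two container types cover every profile the pipeline touches:

* :class:`ConcentrationTimeProfile` — a sampled concentration (or amount)
  versus time curve, tagged with its concentration unit and a free-text label
  (formulation, compartment or subject).
* :class:`FractionProfile` — a dimensionless fraction-of-dose curve
  (dissolved or absorbed), constrained to [0, 1] and non-decreasing.

Times are stored in the unit they were supplied in (``"min"`` or ``"h"``) and
converted explicitly; mixing units silently is an error by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "ConcentrationTimeProfile",
    "FractionProfile",
    "MIN_PER_H",
]

MIN_PER_H = 60.0

_TIME_UNITS = ("min", "h")


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _check_times(times: np.ndarray) -> None:
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] < 0:
        raise ValueError(f"first time must be >= 0, got {times[0]}")
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise ValueError(f"times must be strictly increasing (violation at index {bad})")


@dataclass
class ConcentrationTimeProfile:
    """Ordered concentration-time series with unit tags.

    Parameters
    ----------
    times : array-like
        Strictly increasing sampling times, first time >= 0.
    concentrations : array-like
        Non-negative concentrations, same length as ``times``.
    unit : str
        Concentration unit tag (e.g. ``"ug/mL"``, ``"ug"`` for amounts).
        Treated as an opaque tag: arithmetic never converts it.
    label : str
        Identifier for the series (formulation, compartment, subject...).
    time_unit : str
        ``"min"`` or ``"h"``.
    """

    times: np.ndarray
    concentrations: np.ndarray
    unit: str
    label: str = ""
    time_unit: str = "min"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)
        self.concentrations = _as_float_array(self.concentrations)
        _check_times(self.times)
        if self.concentrations.shape != self.times.shape:
            raise ValueError("times and concentrations must have the same shape")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.time_unit not in _TIME_UNITS:
            raise ValueError(f"time_unit must be one of {_TIME_UNITS}, got {self.time_unit!r}")
        if not self.unit:
            raise ValueError("a concentration unit tag is required")

    def __len__(self) -> int:
        return self.times.size

    def in_time_unit(self, unit: str) -> "ConcentrationTimeProfile":
        """Return a copy with times expressed in ``unit`` (``"min"`` or ``"h"``)."""
        if unit not in _TIME_UNITS:
            raise ValueError(f"unknown time unit {unit!r}")
        if unit == self.time_unit:
            return replace(self)
        factor = MIN_PER_H if (self.time_unit, unit) == ("h", "min") else 1.0 / MIN_PER_H
        return replace(self, times=self.times * factor, time_unit=unit)

    def with_concentrations(self, conc) -> "ConcentrationTimeProfile":
        return replace(self, concentrations=_as_float_array(conc))

    def interp(self, t) -> np.ndarray:
        """Linear interpolation inside the sampled range (no extrapolation)."""
        t = _as_float_array(t)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("interpolation outside the sampled time range")
        return np.interp(t, self.times, self.concentrations)


@dataclass
class FractionProfile:
    """Monotone non-decreasing fraction-of-dose series in [0, 1].

    ``basis`` records what the fraction refers to: ``"dissolved"`` (in vitro)
    or ``"absorbed"`` (in vivo). ``metadata`` carries provenance such as the
    raw (un-normalized) deconvolved amounts and the plateau scale.
    """

    times: np.ndarray
    fractions: np.ndarray
    basis: str
    label: str = ""
    time_unit: str = "min"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)
        self.fractions = _as_float_array(self.fractions)
        _check_times(self.times)
        if self.fractions.shape != self.times.shape:
            raise ValueError("times and fractions must have the same shape")
        if self.basis not in ("dissolved", "absorbed"):
            raise ValueError(f"basis must be 'dissolved' or 'absorbed', got {self.basis!r}")
        if self.time_unit not in _TIME_UNITS:
            raise ValueError(f"time_unit must be one of {_TIME_UNITS}")
        tol = 1e-9
        if np.any(self.fractions < -tol) or np.any(self.fractions > 1 + tol):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(self.fractions) < -tol):
            raise ValueError("fractions must be non-decreasing")
        if self.times[0] == 0 and self.fractions[0] > tol:
            raise ValueError("fraction at time 0 must be 0")
        np.clip(self.fractions, 0.0, 1.0, out=self.fractions)

    def __len__(self) -> int:
        return self.times.size

    def in_time_unit(self, unit: str) -> "FractionProfile":
        if unit not in _TIME_UNITS:
            raise ValueError(f"unknown time unit {unit!r}")
        if unit == self.time_unit:
            return replace(self)
        factor = MIN_PER_H if (self.time_unit, unit) == ("h", "min") else 1.0 / MIN_PER_H
        return replace(self, times=self.times * factor, time_unit=unit)

    def interp(self, t) -> np.ndarray:
        t = _as_float_array(t)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("interpolation outside the sampled time range")
        return np.interp(t, self.times, self.fractions)
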