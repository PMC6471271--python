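"""Delimited-text profile I/O and configuration loading.

Profile files are UTF-8, comma-delimited with a decimal point and one of two
headers:

* ``time,concentration,unit,label`` — concentration-time profiles,
* ``time,fraction,basis,label`` — fraction-of-dose profiles.

Times are always written in minutes (the package's canonical file unit) and
must be strictly increasing per label; a file may hold several labelled
series. ``read_profiles`` ∘ ``write_profiles`` is the identity on valid
files. Malformed rows are reported with their line number.
"""

from __future__ import annotations

import csv
from collections import OrderedDict
from pathlib import Path

import numpy as np
import yaml

from .pk import DispositionParams
from .profiles import ConcentrationTimeProfile, FractionProfile
from .salt_chemistry import SaltSystem

__all__ = [
    "ProfileParseError",
    "read_profiles",
    "read_profile",
    "write_profiles",
    "load_config",
    "disposition_from_config",
    "salt_system_from_config",
]

_CONC_HEADER = ["time", "concentration", "unit", "label"]
_FRAC_HEADER = ["time", "fraction", "basis", "label"]


class ProfileParseError(ValueError):
    """A profile file violated the format contract (message names the line)."""


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_profiles(path, profiles) -> None:
    """Write one or more profiles (all of the same kind) to ``path``.

    Times are converted to minutes before writing.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("nothing to write")
    kinds = {type(p) for p in profiles}
    if len(kinds) > 1:
        raise ValueError("cannot mix concentration and fraction profiles in one file")
    is_frac = isinstance(profiles[0], FractionProfile)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FRAC_HEADER if is_frac else _CONC_HEADER)
        for p in profiles:
            pm = p.in_time_unit("min")
            values = pm.fractions if is_frac else pm.concentrations
            tag = pm.basis if is_frac else pm.unit
            for t, v in zip(pm.times, values):
                w.writerow([_fmt(t), _fmt(v), tag, pm.label])


def read_profiles(path):
    """Read all labelled series from a profile file.

    Returns a list of :class:`ConcentrationTimeProfile` or
    :class:`FractionProfile` (one per label, in order of first appearance),
    with times in minutes. Raises :class:`ProfileParseError` naming the
    offending line for missing columns, unparsable numbers, negative values
    or non-monotone times.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ProfileParseError(f"{path}: empty file")
    header = [h.strip().lower() for h in rows[0]]
    if header == _CONC_HEADER:
        is_frac = False
    elif header == _FRAC_HEADER:
        is_frac = True
    else:
        raise ProfileParseError(
            f"{path}:1: unrecognized header {rows[0]!r}; expected "
            f"{','.join(_CONC_HEADER)} or {','.join(_FRAC_HEADER)}"
        )
    series: "OrderedDict[str, dict]" = OrderedDict()
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 4:
            raise ProfileParseError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
        try:
            t = float(row[0])
            v = float(row[1])
        except ValueError as err:
            raise ProfileParseError(f"{path}:{lineno}: non-numeric value ({err})") from None
        if v < 0:
            raise ProfileParseError(f"{path}:{lineno}: negative value {v}")
        tag, label = row[2].strip(), row[3].strip()
        entry = series.setdefault(label, {"t": [], "v": [], "tag": tag})
        if entry["tag"] != tag:
            raise ProfileParseError(
                f"{path}:{lineno}: unit/basis tag changed within label {label!r}"
            )
        if entry["t"] and t <= entry["t"][-1]:
            raise ProfileParseError(
                f"{path}:{lineno}: non-monotone time {t} for label {label!r}"
            )
        entry["t"].append(t)
        entry["v"].append(v)
    out = []
    for label, entry in series.items():
        if is_frac:
            out.append(FractionProfile(
                times=np.array(entry["t"]), fractions=np.array(entry["v"]),
                basis=entry["tag"], label=label, time_unit="min",
            ))
        else:
            out.append(ConcentrationTimeProfile(
                times=np.array(entry["t"]), concentrations=np.array(entry["v"]),
                unit=entry["tag"], label=label, time_unit="min",
            ))
    return out


def read_profile(path):
    """Read a file expected to contain exactly one labelled series."""
    profiles = read_profiles(path)
    if len(profiles) != 1:
        raise ProfileParseError(
            f"{path}: expected a single series, found {len(profiles)} labels"
        )
    return profiles[0]


def load_config(path) -> dict:
    """Load a YAML (or flat key: value) configuration file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def disposition_from_config(cfg: dict) -> DispositionParams:
    """Build disposition parameters from config keys v1, k10, k12, k21."""
    try:
        return DispositionParams(
            v1=float(cfg["v1"]), k10=float(cfg["k10"]),
            k12=float(cfg["k12"]), k21=float(cfg["k21"]),
        )
    except KeyError as err:
        raise KeyError(f"missing disposition parameter {err.args[0]!r} in config") from None


def salt_system_from_config(cfg: dict) -> SaltSystem:
    """Build a salt system from config keys ksp, s0, pka_acid, pka_counterion."""
    try:
        return SaltSystem(
            ksp=float(cfg["ksp"]), s0=float(cfg["s0"]),
            pka_acid=float(cfg["pka_acid"]),
            pka_counterion=float(cfg["pka_counterion"]),
        )
    except KeyError as err:
        raise KeyError(f"missing salt-system parameter {err.args[0]!r} in config") from None
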