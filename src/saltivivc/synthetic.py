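"""Synthetic study generator with known ground truth.

Emulates the data situation of a salt-formulation bioequivalence programme in
which no raw data are deposited: an intravenous dataset for disposition
fitting, oral plasma profiles for three formulations measured in two separate
trials (the reference formulation dosed in both, so cross-study
normalization is exercised), and matching in vitro transfer-dissolution
profiles — all generated from a known dissolved→absorbed relationship so
every pipeline stage can be checked against truth.

The forward chain is the package's own machinery: the gastrointestinal
transfer simulator produces cumulative jejunal dissolved amounts (with a
per-formulation scaling of the dissolution z-factor playing the role of the
formulation effect), the true IVIVC maps fractions dissolved to fractions
absorbed, and the two-compartment model turns the absorption input into
plasma concentrations. Measurement error is multiplicative lognormal with a
given CV (standard bioanalytical error model); the second trial is scaled by
a bioanalytical ``study_shift``. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import DKT_DISPOSITION, DKT_SYSTEM, TABLET_DOSE_SALT_UG
from .gis import DissolutionKinetics, protocol_preset, simulate as gis_simulate
from .ivivc import IvivcModel, amounts_to_fractions, pk_metrics
from .pk import DispositionParams, simulate_iv_bolus, simulate_oral
from .profiles import ConcentrationTimeProfile, FractionProfile
from .salt_chemistry import SaltSystem

__all__ = ["StudySpec", "StudyBundle", "generate_iv_dataset", "generate_study"]


def _default_truth() -> IvivcModel:
    # gently curved monotone relation through (0,0) and (1,1): in vivo
    # absorption runs ahead of the slower in vitro dissolution clock
    return IvivcModel(form="hill", coefficients={"gamma": 1.4, "f50": 0.4})


def _default_plasma_times() -> np.ndarray:
    return np.concatenate([np.arange(0.0, 2.25, 0.25), np.arange(3.0, 13.0, 1.0)])


@dataclass
class StudySpec:
    """Ground-truth description of a synthetic study.

    ``formulation_effects`` scales the dissolution z-factor per formulation
    (the non-bioequivalent-like arm dissolves 1.5x faster than reference,
    the bioequivalent-like arm slightly slower); ``study_shift`` multiplies
    every concentration of the second trial; ``bioavailable_amount_ug`` is
    the absorbed mass corresponding to complete dissolution.
    """

    disposition: DispositionParams = DKT_DISPOSITION
    salt_system: SaltSystem = DKT_SYSTEM
    formulation_effects: dict[str, float] = field(
        default_factory=lambda: {"reference": 1.0, "non_be": 1.5, "be": 0.85}
    )
    ivivc_truth: IvivcModel = field(default_factory=_default_truth)
    noise_cv: float = 0.05
    study_shift: float = 1.1
    seed: int = 42
    dose_salt_ug: float = TABLET_DOSE_SALT_UG
    bioavailable_amount_ug: float = 22_500.0
    base_kinetics: DissolutionKinetics = field(default_factory=DissolutionKinetics)
    protocol: str = "protocol2"
    plasma_times_h: np.ndarray = field(default_factory=_default_plasma_times)
    invitro_duration_min: float = 120.0
    invitro_interval_min: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if any(v <= 0 for v in self.formulation_effects.values()):
            raise ValueError("formulation effects must be positive")
        if self.study_shift <= 0:
            raise ValueError("study_shift must be positive")


@dataclass
class StudyBundle:
    """Everything :func:`generate_study` produces, ground truth included."""

    spec: StudySpec
    invitro_amounts: dict[str, ConcentrationTimeProfile]
    f_diss: dict[str, FractionProfile]
    plasma: dict[str, dict[str, ConcentrationTimeProfile]]  # trial -> label -> profile
    true_fa: dict[str, FractionProfile]
    true_metrics: dict[str, dict[str, float]]
    true_scales: dict[str, float]  # plateau absorbed amount over v1 per formulation


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def generate_iv_dataset(
    spec: StudySpec,
    dose: float,
    times,
    *,
    time_unit: str = "h",
) -> ConcentrationTimeProfile:
    """IV bolus profile with multiplicative lognormal noise.

    The underlying disposition parameters are embedded in ``metadata`` as
    ground truth; noise factors are drawn from the spec's seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    clean = simulate_iv_bolus(spec.disposition, dose, times, time_unit=time_unit,
                              label="iv")
    noisy = clean.concentrations * _lognormal_factors(rng, spec.noise_cv, len(clean))
    out = clean.with_concentrations(noisy)
    out.metadata = {
        "true_params": spec.disposition, "dose": dose,
        "noise_cv": spec.noise_cv, "seed": spec.seed,
    }
    return out


def _oral_profile(
    spec: StudySpec,
    f_diss: FractionProfile,
    label: str,
) -> tuple[ConcentrationTimeProfile, FractionProfile, float]:
    """Noise-free plasma profile from a dissolved-fraction curve via the truth.

    Returns (plasma profile on the plasma grid, true normalized
    fraction-absorbed curve, plateau absorbed amount over v1).
    """
    fd = f_diss.in_time_unit("h")
    truth = spec.ivivc_truth
    xa_frac = truth.predict(fd.fractions)  # fraction of full-dissolution absorption
    xa_frac = np.maximum.accumulate(xa_frac)
    # union grid: dissolution window plus plasma sampling times
    grid = np.union1d(fd.times, spec.plasma_times_h)
    grid = grid[grid >= 0]
    xa_on_grid = np.where(
        grid <= fd.times[-1],
        np.interp(grid, fd.times, xa_frac),
        xa_frac[-1],
    ) * spec.bioavailable_amount_ug
    rates = np.diff(xa_on_grid) / np.diff(grid)
    profile = simulate_oral(
        spec.disposition, grid, rates, time_unit="h", label=label
    )
    conc = np.interp(spec.plasma_times_h, grid, profile.concentrations)
    plasma = ConcentrationTimeProfile(
        times=spec.plasma_times_h.copy(), concentrations=conc, unit="ug/mL",
        label=label, time_unit="h",
    )
    plateau = xa_frac[-1]
    fa_true = FractionProfile(
        times=fd.times * 60.0, fractions=xa_frac / plateau if plateau > 0 else xa_frac,
        basis="absorbed", label=label, time_unit="min",
        metadata={"plateau_fraction_of_full": float(plateau)},
    )
    scale = spec.bioavailable_amount_ug * plateau / spec.disposition.v1
    return plasma, fa_true, scale


def generate_study(spec: StudySpec) -> StudyBundle:
    """Generate the full synthetic study bundle.

    Trial 1 doses the reference and the fast ("non_be") formulation; trial 2
    doses the reference again and the slower ("be") formulation, with every
    trial-2 concentration multiplied by ``study_shift`` so cross-study
    normalization is required before pooling.
    """
    rng = np.random.default_rng(spec.seed)
    config = protocol_preset(spec.protocol)

    invitro: dict[str, ConcentrationTimeProfile] = {}
    for label, effect in spec.formulation_effects.items():
        kin = replace(spec.base_kinetics, z_salt=spec.base_kinetics.z_salt * effect,
                      z_acid=spec.base_kinetics.z_acid * effect)
        result = gis_simulate(
            config, spec.salt_system, spec.dose_salt_ug, kin,
            duration=spec.invitro_duration_min,
            record_interval=spec.invitro_interval_min,
        )
        amt = result.jejunal_amount
        amt.label = label
        invitro[label] = amt

    f_diss = {f.label: f for f in amounts_to_fractions(invitro.values())}

    clean_plasma: dict[str, ConcentrationTimeProfile] = {}
    true_fa: dict[str, FractionProfile] = {}
    true_scales: dict[str, float] = {}
    true_metrics: dict[str, dict[str, float]] = {}
    for label in spec.formulation_effects:
        plasma, fa, scale = _oral_profile(spec, f_diss[label], label)
        clean_plasma[label] = plasma
        true_fa[label] = fa
        true_scales[label] = scale
        cmax, auc = pk_metrics(plasma)
        true_metrics[label] = {"cmax": cmax, "auc": auc}

    def noisy(profile: ConcentrationTimeProfile, shift: float) -> ConcentrationTimeProfile:
        factors = _lognormal_factors(rng, spec.noise_cv, len(profile))
        out = profile.with_concentrations(profile.concentrations * factors * shift)
        out.metadata = dict(profile.metadata, study_shift=shift,
                            noise_cv=spec.noise_cv, seed=spec.seed)
        return out

    plasma = {
        "trial1": {
            "reference": noisy(clean_plasma["reference"], 1.0),
            "non_be": noisy(clean_plasma["non_be"], 1.0),
        },
        "trial2": {
            "reference": noisy(clean_plasma["reference"], spec.study_shift),
            "be": noisy(clean_plasma["be"], spec.study_shift),
        },
    }
    return StudyBundle(
        spec=spec, invitro_amounts=invitro, f_diss=f_diss, plasma=plasma,
        true_fa=true_fa, true_metrics=true_metrics, true_scales=true_scales,
    )
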