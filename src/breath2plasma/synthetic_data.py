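"""Synthetic cohorts with the study's 3-group x 6-rat design.

Plasma time courses come from per-subject two-compartment parameters sampled
lognormally around group means; breath is derived from plasma through the
empirical power-law link (so the agreement stage has a known ground truth),
noised, converted to ppbv and LOD-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .calibration import CalibrationCurve, DEFAULT_LOD_PPBV
from .pk_core import DoseEvent, MicroParams, micro_to_macro, predict_concentration
from .preprocessing import (
    BELOW_LOD_ZEROED,
    ConcentrationSeries,
    censor_series,
)
from .units import convert_units

#: drug formulation strength used to convert infusion volume to duration
FORMULATION_MG_PER_ML = 10.0
#: pump rate: 0.4 mL per 30 s
PUMP_ML_PER_MIN = 0.8

DEFAULT_PLASMA_TIMES = (1.0, 3.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    dose_per_kg: float  # mg/kg
    n_subjects: int
    pk_mean: MicroParams  # group-mean plasma micro parameters


def _default_groups() -> Tuple[GroupSpec, ...]:
    return (
        GroupSpec("BL", 6.0, 6, MicroParams(2, V1=0.25, K10=0.23, K12=0.16, K21=0.05)),
        GroupSpec("BM", 12.0, 6, MicroParams(2, V1=0.21, K10=0.25, K12=0.13, K21=0.03)),
        GroupSpec("BH", 24.0, 6, MicroParams(2, V1=0.19, K10=0.19, K12=0.12, K21=0.08)),
    )


@dataclass
class CohortConfig:
    groups: Tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    body_mass_mean: float = 330.0  # g
    body_mass_sd: float = 25.0  # g
    iiv_cv: float = 0.25  # lognormal inter-individual CV on each micro parameter
    link_slope: float = 1.42
    link_intercept: float = -1.70
    noise_cv: float = 0.05  # multiplicative measurement noise
    lod_ppbv: float = DEFAULT_LOD_PPBV
    breath_interval: float = 1.0 / 3.0  # min (20 s)
    plasma_times: Tuple[float, ...] = DEFAULT_PLASMA_TIMES
    duration: float = 120.0  # min
    seed: int = 0

    def __post_init__(self):
        if self.iiv_cv < 0 or self.noise_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.breath_interval <= 0 or self.duration <= 0:
            raise ValueError("breath_interval and duration must be positive")
        if any(g.n_subjects < 1 for g in self.groups):
            raise ValueError("each group needs at least one subject")


@dataclass
class SubjectRecord:
    """One subject's data; ground-truth fields are None for loaded cohorts."""

    subject_id: str
    group: str
    breath: Optional[ConcentrationSeries] = None
    plasma: Optional[ConcentrationSeries] = None
    dose: Optional[DoseEvent] = None
    body_mass: Optional[float] = None
    true_params: Optional[MicroParams] = None


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-preserving lognormal draw with the given coefficient of variation."""
    if cv == 0:
        return mean
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(mean * np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _mult_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return values.copy()
    sigma = np.sqrt(np.log1p(cv * cv))
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape))


def generate_cohort(config: CohortConfig) -> Tuple[List[SubjectRecord], Dict]:
    """Generate subject records plus a ground-truth table.

    Deterministic for a given (config, seed): the same configuration always
    produces identical series.
    """
    rng = np.random.default_rng(config.seed)
    records: List[SubjectRecord] = []
    truth: Dict = {
        "link_slope": config.link_slope,
        "link_intercept": config.link_intercept,
        "lod_ppbv": config.lod_ppbv,
        "seed": config.seed,
        "subjects": {},
        "group_means": {
            g.name: {"V1": g.pk_mean.V1, "K10": g.pk_mean.K10,
                     "K12": g.pk_mean.K12, "K21": g.pk_mean.K21}
            for g in config.groups
        },
    }
    n_breath = int(round(config.duration / config.breath_interval))
    breath_times = np.concatenate(
        [[0.0], config.breath_interval * np.arange(1, n_breath + 1)]
    )
    plasma_times = np.concatenate([[0.0], np.asarray(config.plasma_times, dtype=float)])

    for group in config.groups:
        for i in range(group.n_subjects):
            sid = f"{group.name}{i + 1:02d}"
            mass = -1.0
            while mass <= 0:
                mass = rng.normal(config.body_mass_mean, config.body_mass_sd)
            amount = group.dose_per_kg * mass / 1000.0
            infusion_min = amount / FORMULATION_MG_PER_ML / PUMP_ML_PER_MIN
            dose = DoseEvent(amount=amount, start_time=0.0, duration=0.0)
            mp = group.pk_mean
            micro = MicroParams(
                2,
                V1=_lognormal_around(rng, mp.V1, config.iiv_cv),
                K10=_lognormal_around(rng, mp.K10, config.iiv_cv),
                K12=_lognormal_around(rng, mp.K12, config.iiv_cv),
                K21=_lognormal_around(rng, mp.K21, config.iiv_cv),
            )
            macro = micro_to_macro(micro, dose)

            # plasma (ug/mL): closed form at the draw schedule, noised
            cp_clean = predict_concentration(macro, dose, plasma_times[1:])
            cp_obs = _mult_noise(rng, cp_clean, config.noise_cv)
            plasma = ConcentrationSeries(
                subject_id=sid,
                matrix="plasma",
                times=plasma_times,
                values=np.concatenate([[0.0], cp_obs]),
                unit="μg/mL",
                flags=np.array(
                    [BELOW_LOD_ZEROED] + ["observed"] * cp_obs.size, dtype=object
                ),
            )

            # breath (ppbv): invert the log-log link from noiseless plasma
            cp_dense = predict_concentration(macro, dose, breath_times[1:])
            cp_ngml = convert_units(1.0, "μg/mL", "ng/mL") * cp_dense
            ln_ce = (np.log(cp_ngml) - config.link_intercept) / config.link_slope
            ce_pptv = _mult_noise(rng, np.exp(ln_ce), config.noise_cv)
            ce_ppbv = convert_units(1.0, "pptv", "ppbv") * ce_pptv
            breath = ConcentrationSeries(
                subject_id=sid,
                matrix="breath",
                times=breath_times,
                values=np.concatenate([[0.0], ce_ppbv]),
                unit="ppbv",
                flags=np.array(
                    [BELOW_LOD_ZEROED] + ["observed"] * ce_ppbv.size, dtype=object
                ),
            )
            breath = censor_series(breath, config.lod_ppbv)

            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group.name,
                    breath=breath,
                    plasma=plasma,
                    dose=dose,
                    body_mass=float(mass),
                    true_params=micro,
                )
            )
            truth["subjects"][sid] = {
                "group": group.name,
                "body_mass_g": float(mass),
                "dose_mg": amount,
                "infusion_duration_min": infusion_min,
                "V1": micro.V1,
                "K10": micro.K10,
                "K12": micro.K12,
                "K21": micro.K21,
            }
    return records, truth


def generate_calibration_standards(
    curve: CalibrationCurve,
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    seed: Optional[int] = None,
) -> List[Tuple[float, float]]:
    """Forward-evaluate the curve at given ppbv levels with optional noise."""
    rng = np.random.default_rng(seed)
    xs = np.asarray(list(concentrations), dtype=float)
    if xs.size == 0:
        return []
    lo, hi = curve.valid_range
    if np.any(xs < lo) or np.any(xs > hi):
        raise ValueError("standard concentrations must lie within the curve's range")
    ys = np.asarray(curve.signal(xs), dtype=float)
    ys = _mult_noise(rng, ys, noise_cv)
    return [(float(x), float(y)) for x, y in zip(xs, ys)]
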