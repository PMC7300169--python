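"""Measurement noise for simulated planar and SPECT/CT activity values.

Simulated activities are the ground truth multiplied by median-preserving
log-normal factors.  Planar noise (total coefficient of variation 20 % by
default) is a superposition of a systematic component — one factor drawn per
(patient, region, replicate) and shared across all planar time points,
representing region-specific overlap/attenuation errors of 2-D quantification
— and a stochastic component drawn independently per time point.  The
parameter ``f_syst`` sets the systematic share of the total planar error.
SPECT/CT noise is a single stochastic log-normal factor (5 % by default).

A log-normal factor with median 1 and coefficient of variation ``cv`` has
log-standard-deviation sigma_ln = sqrt(ln(1 + cv^2)).

The module also provides the counting-statistics utility used to argue that
Poisson noise stays negligible at late time points for whole-body planar
sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import VirtualPatient, true_activity
from .grid import HybridSchedule, PlanarSchedule, SingleTPSchedule

__all__ = [
    "NoiseConfig",
    "MeasurementSet",
    "lognormal_sigma",
    "lognormal_multiplier",
    "draw_noise_factors",
    "simulate_measurements",
    "planar_poisson_uncertainty",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise magnitudes for simulated measurements.

    ``syst_split`` chooses how ``f_syst`` partitions the total planar CV:
    ``"linear"`` sets CV_syst = f_syst * cv_planar_total (the default),
    ``"variance"`` sets CV_syst^2 = f_syst * cv_planar_total^2.
    """

    cv_planar_total: float = 0.20
    cv_spect: float = 0.05
    f_syst: float = 0.50
    syst_split: str = "linear"

    def __post_init__(self) -> None:
        if self.cv_planar_total < 0 or self.cv_spect < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if not 0.0 <= self.f_syst <= 1.0:
            raise ValueError("f_syst must lie in [0, 1]")
        if self.syst_split not in ("linear", "variance"):
            raise ValueError("syst_split must be 'linear' or 'variance'")

    @property
    def cv_syst(self) -> float:
        if self.syst_split == "linear":
            return self.f_syst * self.cv_planar_total
        return math.sqrt(self.f_syst) * self.cv_planar_total

    @property
    def cv_stoch(self) -> float:
        if self.syst_split == "linear":
            return (1.0 - self.f_syst) * self.cv_planar_total
        return math.sqrt(1.0 - self.f_syst) * self.cv_planar_total


@dataclass(frozen=True)
class MeasurementSet:
    """One replicate's simulated activity values for one region."""

    planar: tuple[tuple[float, float], ...]  # (time h, activity MBq)
    spect: Optional[tuple[float, float]]  # (time h, activity MBq)
    replicate_id: int
    region_id: str


def lognormal_sigma(cv: float) -> float:
    """Log-space standard deviation giving a multiplier CV of ``cv``."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    return math.sqrt(math.log1p(cv * cv))


def lognormal_multiplier(cv: float, rng: np.random.Generator, size=None):
    """Median-1 log-normal factor(s) with coefficient of variation ``cv``.

    ``cv = 0`` returns exactly 1 without consuming randomness, so a noiseless
    configuration reproduces ground truth bit-for-bit.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = lognormal_sigma(cv)
    return np.exp(sigma * rng.standard_normal(size))


def draw_noise_factors(cfg: NoiseConfig, rng: np.random.Generator,
                       n_reps: int, n_planar: int):
    """Draw all noise factors for ``n_reps`` replicates of one region.

    Returns ``(syst, stoch, spect)`` with shapes (n_reps,), (n_reps, n_planar)
    and (n_reps,).  The draw order is fixed (systematic, stochastic, SPECT) so
    that a stream seeded per (seed, schedule, patient, region) yields the same
    replicate rows regardless of when other streams are consumed.
    """
    syst = lognormal_multiplier(cfg.cv_syst, rng, size=n_reps)
    stoch = lognormal_multiplier(cfg.cv_stoch, rng, size=(n_reps, n_planar))
    spect = lognormal_multiplier(cfg.cv_spect, rng, size=n_reps)
    return syst, stoch, spect


def simulate_measurements(patient: VirtualPatient, region_id: str,
                          schedule, cfg: NoiseConfig,
                          rng: np.random.Generator,
                          replicate_id: int = 0) -> MeasurementSet:
    """Simulate one replicate's planar and SPECT/CT activity values.

    ``schedule`` is a :class:`HybridSchedule` (planar series + one SPECT/CT),
    a :class:`PlanarSchedule` (no SPECT/CT) or a :class:`SingleTPSchedule`
    (SPECT/CT only).
    """
    kinetics = dict((rid, k) for rid, _, k in patient.regions()).get(region_id)
    if kinetics is None:
        raise ValueError(f"patient has no region {region_id!r}")

    if isinstance(schedule, SingleTPSchedule):
        planar_times: tuple[float, ...] = ()
        t_spect: Optional[float] = schedule.t_ref
    elif isinstance(schedule, HybridSchedule):
        planar_times = schedule.planar.times
        t_spect = schedule.t_spect
    elif isinstance(schedule, PlanarSchedule):
        planar_times = schedule.times
        t_spect = None
    else:
        raise TypeError(f"unsupported schedule type {type(schedule).__name__}")

    syst, stoch, spect = draw_noise_factors(cfg, rng, 1, len(planar_times))
    planar = tuple(
        (t, float(true_activity(kinetics, t)) * syst[0] * stoch[0, i])
        for i, t in enumerate(planar_times)
    )
    spect_value = None
    if t_spect is not None:
        spect_value = (t_spect, float(true_activity(kinetics, t_spect)) * spect[0])
    return MeasurementSet(planar=planar, spect=spect_value,
                          replicate_id=replicate_id, region_id=region_id)


def planar_poisson_uncertainty(activity: float, sensitivity: float,
                               fov_z: float, bed_speed: float) -> float:
    """Relative Poisson uncertainty (%) of a planar whole-body sweep.

    Parameters
    ----------
    activity
        Region activity in MBq.
    sensitivity
        Camera sensitivity in counts/s per MBq.
    fov_z
        Axial field of view in cm (sets the dwell time of the sweep).
    bed_speed
        Bed speed in cm/min.

    The region stays in the field of view for ``fov_z / bed_speed`` minutes,
    so the expected counts are ``activity * sensitivity * (fov_z/bed_speed) * 60``
    and the relative standard deviation is ``100 / sqrt(counts)`` percent.
    """
    if min(activity, sensitivity, fov_z, bed_speed) <= 0:
        raise ValueError("all inputs must be positive")
    counts = activity * sensitivity * (fov_z / bed_speed) * 60.0
    return 100.0 / math.sqrt(counts)
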