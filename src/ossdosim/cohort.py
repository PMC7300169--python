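"""Virtual patients with parametric kidney and tumour time-activity curves.

Each region's ground-truth time-activity curve (TAC) is a two-exponential
uptake/washout (Bateman-type) curve modulated by physical decay:

    A(t) = C * (exp(-(lambda_bio + lambda_phys) t)
                - exp(-(lambda_up + lambda_phys) t))

with biological clearance rate ``lambda_bio``, uptake rate ``lambda_up`` and
the fixed physical decay constant of 177Lu.  The curve starts at zero, peaks
at a finite t_max and washes out mono-exponentially with effective half-life
ln 2 / (lambda_bio + lambda_phys).  ``lambda_up = inf`` degenerates to a pure
mono-exponential (instantaneous uptake), which several estimator identities
rely on.

The true time-integrated activity coefficient (TIAC) of a region is the
closed-form integral of A(t)/A0 over [0, inf):

    TIAC = (C / A0) * (1/(lambda_bio + lambda_phys)
                       - 1/(lambda_up + lambda_phys))     [hours]

Cohorts are sampled so that effective half-lives, times of maximum uptake and
injected activities match the population statistics observed in 177Lu-PSMA
therapy of mCRPC patients (13 patients, two analysed tumour lesions each).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LAMBDA_PHYS",
    "PHYSICAL_HALF_LIFE_H",
    "RegionKinetics",
    "VirtualPatient",
    "CohortConfig",
    "true_activity",
    "true_tiac",
    "effective_half_life",
    "solve_lambda_up",
    "sample_cohort",
    "monoexp_kinetics",
    "save_cohort",
    "load_cohort",
    "cohort_to_dict",
    "cohort_from_dict",
]

#: Physical half-life of 177Lu in hours (6.647 days).
PHYSICAL_HALF_LIFE_H: float = 6.647 * 24.0

#: Physical decay constant of 177Lu, 1/h.
LAMBDA_PHYS: float = math.log(2.0) / PHYSICAL_HALF_LIFE_H


@dataclass(frozen=True)
class RegionKinetics:
    """Ground-truth kinetic parameters of one region (kidney or lesion).

    Parameters
    ----------
    amplitude
        Curve prefactor C in MBq.
    lambda_bio
        Biological clearance rate in 1/h (>= 0).
    lambda_up
        Uptake rate in 1/h; must exceed ``lambda_bio``.  ``math.inf`` gives a
        pure mono-exponential washout curve.
    lambda_phys
        Physical decay constant in 1/h (fixed for 177Lu).
    """

    amplitude: float
    lambda_bio: float
    lambda_up: float
    lambda_phys: float = LAMBDA_PHYS

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.lambda_bio < 0:
            raise ValueError("lambda_bio must be non-negative")
        if self.lambda_up <= self.lambda_bio:
            raise ValueError("lambda_up must exceed lambda_bio")
        if self.lambda_phys <= 0:
            raise ValueError("lambda_phys must be positive")

    @property
    def lambda_bio_eff(self) -> float:
        return self.lambda_bio + self.lambda_phys

    @property
    def lambda_up_eff(self) -> float:
        return self.lambda_up + self.lambda_phys

    @property
    def t_max(self) -> float:
        """Time of the curve maximum in hours (0 for instantaneous uptake)."""
        if math.isinf(self.lambda_up):
            return 0.0
        lu, lb = self.lambda_up_eff, self.lambda_bio_eff
        return math.log(lu / lb) / (lu - lb)


@dataclass(frozen=True)
class VirtualPatient:
    """One virtual patient: injected activity plus three region TACs."""

    patient_id: str
    a0: float  # injected activity, MBq
    kidney: RegionKinetics
    lesions: tuple[RegionKinetics, RegionKinetics]

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("injected activity must be positive")
        if len(self.lesions) != 2:
            raise ValueError("exactly two tumour lesions are modelled")

    def regions(self) -> Iterator[tuple[str, str, RegionKinetics]]:
        """Yield (region_id, region_class, kinetics) for kidney and lesions."""
        yield "kidney", "kidney", self.kidney
        for i, lesion in enumerate(self.lesions):
            yield f"lesion{i + 1}", "tumour", lesion


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters for cohort sampling.

    Effective half-lives are drawn from triangular distributions
    (min, mode, max), times of maximum uptake from uniform ranges, and the
    injected activity from a normal distribution.  Peak-uptake fractions set
    the region amplitude relative to A0; relative TIAC deviations are
    invariant to this scale.
    """

    n_patients: int = 13
    kidney_t_eff: tuple[float, float, float] = (30.0, 40.0, 62.0)  # h
    tumour_t_eff: tuple[float, float, float] = (34.0, 50.0, 94.0)  # h
    kidney_t_max: tuple[float, float] = (0.6, 3.0)  # h
    tumour_t_max: tuple[float, float] = (0.5, 9.0)  # h
    a0_mean: float = 7300.0  # MBq
    a0_sd: float = 300.0  # MBq
    kidney_peak_frac: tuple[float, float] = (0.01, 0.03)
    lesion_peak_frac: tuple[float, float] = (0.0005, 0.02)
    kidney_uptake_frac_1h: float = 0.968  # min fraction of max reached at 1 h

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for lo, mode, hi in (self.kidney_t_eff, self.tumour_t_eff):
            if not (0 < lo <= mode <= hi):
                raise ValueError("T_eff (min, mode, max) must be positive and ordered")
            if hi > PHYSICAL_HALF_LIFE_H:
                # effective half-life cannot exceed the physical one
                raise ValueError(
                    f"T_eff max {hi} h exceeds the physical half-life "
                    f"{PHYSICAL_HALF_LIFE_H:.1f} h (implies lambda_bio < 0)")
        for rng_ in (self.kidney_t_max, self.tumour_t_max,
                     self.kidney_peak_frac, self.lesion_peak_frac):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError("range must be positive and ordered")
        if self.a0_mean <= 0 or self.a0_sd < 0:
            raise ValueError("invalid injected-activity parameters")


def true_activity(k: RegionKinetics, t):
    """Ground-truth activity of a region at time(s) ``t`` hours p.i. (MBq)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    washout = np.exp(-k.lambda_bio_eff * t)
    if math.isinf(k.lambda_up):
        uptake = np.zeros_like(washout)
    else:
        uptake = np.exp(-k.lambda_up_eff * t)
    out = k.amplitude * (washout - uptake)
    return float(out) if out.ndim == 0 else out


def true_tiac(k: RegionKinetics, a0: float) -> float:
    """Closed-form true TIAC in hours: integral of A(t)/A0 over [0, inf)."""
    if a0 <= 0:
        raise ValueError("injected activity must be positive")
    if k.lambda_bio_eff <= 0:
        raise ValueError("curve is not integrable")
    tail = 0.0 if math.isinf(k.lambda_up) else 1.0 / k.lambda_up_eff
    return (k.amplitude / a0) * (1.0 / k.lambda_bio_eff - tail)


def effective_half_life(k: RegionKinetics) -> float:
    """Effective washout half-life ln 2 / (lambda_bio + lambda_phys), hours."""
    return math.log(2.0) / k.lambda_bio_eff


def solve_lambda_up(lambda_bio_eff: float, t_max: float,
                    lambda_phys: float = LAMBDA_PHYS) -> float:
    """Biological uptake rate placing the curve maximum at ``t_max`` hours.

    Solves ln(r) = a (r - 1) with r = lambda_up_eff / lambda_bio_eff and
    a = t_max * lambda_bio_eff, which requires a < 1 (the peak must come
    before the washout timescale 1/lambda_bio_eff).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    a = t_max * lambda_bio_eff
    if a >= 1.0:
        raise ValueError("t_max too late for the requested washout rate")

    def f(r: float) -> float:
        return math.log(r) - a * (r - 1.0)

    r_hi = 2.0
    while f(r_hi) > 0:
        r_hi *= 2.0
    r = brentq(f, 1.0 + 1e-9, r_hi, xtol=1e-12, rtol=1e-14)
    return r * lambda_bio_eff - lambda_phys


def monoexp_kinetics(amplitude: float, t_eff: float) -> RegionKinetics:
    """Pure mono-exponential kinetics with effective half-life ``t_eff`` h."""
    lambda_bio = math.log(2.0) / t_eff - LAMBDA_PHYS
    if lambda_bio < 0:
        raise ValueError("t_eff exceeds the physical half-life")
    return RegionKinetics(amplitude=amplitude, lambda_bio=lambda_bio,
                          lambda_up=math.inf)


def _sample_region(rng: np.random.Generator, t_eff_tri: tuple[float, float, float],
                   t_max_range: tuple[float, float], peak: float,
                   min_frac_1h: float | None) -> RegionKinetics:
    """Draw one region's kinetics; optionally enforce the early-plateau rule."""
    t_eff = rng.triangular(*t_eff_tri)
    lambda_bio = math.log(2.0) / t_eff - LAMBDA_PHYS
    if lambda_bio < 0:
        raise ValueError("configured T_eff exceeds the physical half-life")
    lb_eff = lambda_bio + LAMBDA_PHYS
    for _ in range(10_000):
        t_max = rng.uniform(*t_max_range)
        lambda_up = solve_lambda_up(lb_eff, t_max)
        k = RegionKinetics(amplitude=1.0, lambda_bio=lambda_bio,
                           lambda_up=lambda_up)
        if min_frac_1h is None:
            break
        if true_activity(k, 1.0) >= min_frac_1h * true_activity(k, k.t_max):
            break
    else:
        raise RuntimeError("could not satisfy the early-plateau constraint")
    # rescale so the curve maximum equals the requested peak activity
    peak_unit = true_activity(k, k.t_max)
    return RegionKinetics(amplitude=peak / peak_unit, lambda_bio=lambda_bio,
                          lambda_up=lambda_up)


def sample_cohort(config: CohortConfig | None = None, *,
                  seed: int | np.random.SeedSequence = 0) -> list[VirtualPatient]:
    """Sample a reproducible virtual cohort.

    Each patient receives an injected activity A0, one kidney and two tumour
    lesions.  Kidney curves are rejection-sampled until at least
    ``kidney_uptake_frac_1h`` of the maximum is reached by 1 h p.i.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(config.n_patients):
        a0 = float(rng.normal(config.a0_mean, config.a0_sd))
        if a0 <= 0:
            raise RuntimeError("sampled non-positive injected activity")
        kidney = _sample_region(
            rng, config.kidney_t_eff, config.kidney_t_max,
            peak=a0 * rng.uniform(*config.kidney_peak_frac),
            min_frac_1h=config.kidney_uptake_frac_1h,
        )
        lesions = tuple(
            _sample_region(
                rng, config.tumour_t_eff, config.tumour_t_max,
                peak=a0 * rng.uniform(*config.lesion_peak_frac),
                min_frac_1h=None,
            )
            for _ in range(2)
        )
        patients.append(VirtualPatient(
            patient_id=f"vp{i + 1:02d}", a0=a0, kidney=kidney, lesions=lesions,
        ))
    return patients


# -- JSON serialisation -------------------------------------------------------

def _kinetics_to_dict(k: RegionKinetics) -> dict:
    d = asdict(k)
    if math.isinf(k.lambda_up):
        d["lambda_up"] = "inf"
    return d


def _kinetics_from_dict(d: dict) -> RegionKinetics:
    lam_up = math.inf if d["lambda_up"] == "inf" else float(d["lambda_up"])
    return RegionKinetics(amplitude=float(d["amplitude"]),
                          lambda_bio=float(d["lambda_bio"]),
                          lambda_up=lam_up,
                          lambda_phys=float(d["lambda_phys"]))


def cohort_to_dict(patients: Sequence[VirtualPatient], *, meta: dict | None = None) -> dict:
    return {
        "meta": meta or {},
        "patients": [
            {
                "patient_id": p.patient_id,
                "a0": p.a0,
                "kidney": _kinetics_to_dict(p.kidney),
                "lesions": [_kinetics_to_dict(l) for l in p.lesions],
            }
            for p in patients
        ],
    }


def cohort_from_dict(doc: dict) -> list[VirtualPatient]:
    return [
        VirtualPatient(
            patient_id=entry["patient_id"],
            a0=float(entry["a0"]),
            kidney=_kinetics_from_dict(entry["kidney"]),
            lesions=tuple(_kinetics_from_dict(l) for l in entry["lesions"]),
        )
        for entry in doc["patients"]
    ]


def save_cohort(patients: Sequence[VirtualPatient], path: str | Path, *,
                meta: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(cohort_to_dict(patients, meta=meta), indent=1, sort_keys=True)
    )


def load_cohort(path: str | Path) -> list[VirtualPatient]:
    return cohort_from_dict(json.loads(Path(path).read_text()))
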