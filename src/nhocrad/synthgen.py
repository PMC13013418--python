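"""Synthetic phantoms and simulated cohorts with known ground truth.

Two generators make every pipeline stage testable without patient data:

* :func:`make_phantom` builds a lung-like PET/CT pair — an ellipsoidal
  lesion of plateau SUV carrying a Gaussian metabolic hotspot whose centre
  sits at a programmable fraction ``f`` of the lesion radius from the
  centroid, over a noisy lung background — so the measured NHOC of the
  segmented lesion can be compared against the programmed offset.

* :func:`simulate_cohort` draws survival times from an exponential
  proportional-hazards model over NHOC, simplified stage and a latent
  radiomic risk, with independent uniform censoring calibrated to a target
  rate, radiomic feature columns that mix the latent risk with pure noise,
  and optional per-site batch shifts for harmonisation tests.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .imgvol import BinaryMask, ScalarVolume, VolumeGeometry

LUNG_HU = -700.0
LESION_HU = 30.0


@dataclass(frozen=True)
class PhantomParams:
    shape: tuple[int, int, int] = (120, 120, 120)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radii_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    background_suv: float = 0.5
    plateau_suv: float = 5.0
    peak_suv: float = 10.0
    hotspot_offset_fraction: float = 0.0
    hotspot_sigma_mm: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.peak_suv > self.plateau_suv > self.background_suv > 0):
            raise ValueError("need peak > plateau > background > 0")
        if not 0 <= self.hotspot_offset_fraction < 1:
            raise ValueError("hotspot offset fraction must be in [0, 1)")


def make_phantom(p: PhantomParams = PhantomParams()):
    """Ellipsoidal hot lesion with an off-centre hotspot in a lung background.

    Returns (pet, ct, lung_mask, seed_point).  The hotspot Gaussian is
    confined to the lesion, so an MTV40 segmentation recovers the full
    ellipsoid whenever 0.4 × peak < plateau, and the measured NHOC of that
    mask approximates the programmed offset fraction.  The hotspot is
    displaced along +x by ``f × r_x``.
    """
    geom = VolumeGeometry(shape=p.shape, spacing=p.spacing)
    extent = np.asarray(geom.extent_mm)
    radii = np.asarray(p.lesion_radii_mm)
    centre = extent / 2.0
    margin = radii + np.asarray([10.0, 10.0, 10.0])
    if np.any(centre - margin < 0):
        raise ValueError(
            f"lesion radii {tuple(radii)} mm do not fit grid extent {tuple(extent)} mm "
            "with room for the annulus"
        )

    idx = np.indices(p.shape)
    coords = [idx[ax] * p.spacing[ax] for ax in range(3)]
    ell = sum(((coords[ax] - centre[ax]) / radii[ax]) ** 2 for ax in range(3))
    lesion = ell <= 1.0

    hotspot_centre = centre.copy()
    hotspot_centre[0] += p.hotspot_offset_fraction * radii[0]
    d2 = sum((coords[ax] - hotspot_centre[ax]) ** 2 for ax in range(3))
    hotspot = (p.peak_suv - p.plateau_suv) * np.exp(-d2 / (2 * p.hotspot_sigma_mm**2))

    pet = np.full(p.shape, p.background_suv, float)
    pet[lesion] = p.plateau_suv + hotspot[lesion]

    rng = np.random.default_rng(p.seed)
    if p.noise_sd > 0:
        pet = np.clip(pet + rng.normal(0, p.noise_sd, p.shape), 0, None)

    ct = np.full(p.shape, LUNG_HU, float)
    ct[lesion] = LESION_HU
    if p.noise_sd > 0:
        ct = ct + rng.normal(0, 5.0, p.shape)

    lung = np.ones(p.shape, bool)

    seed_point = tuple(int(round(c / s)) for c, s in zip(hotspot_centre, p.spacing))
    return (
        ScalarVolume(geometry=geom, values=pet, modality="PET"),
        ScalarVolume(geometry=geom, values=ct, modality="CT"),
        BinaryMask(geometry=geom, values=lung, label="lung"),
        seed_point,
    )


@dataclass(frozen=True)
class CohortParams:
    n: int = 200
    betas: dict = field(default_factory=lambda: {"nhoc": 0.8, "latent": 1.0, "stage": 0.5})
    baseline_rate: float = 1.0 / 600.0  # events per day at the covariate mean
    censor_rate: float = 0.3
    n_informative: int = 5  # feature columns mixing in the latent risk
    n_noise: int = 15
    sites: tuple[str, ...] = ("siteA",)
    batch_shift: dict = field(default_factory=dict)  # site → additive feature shift
    batch_scale: dict = field(default_factory=dict)  # site → multiplicative factor
    seed: int = 0

    def __post_init__(self):
        if self.n < 20:
            raise ValueError("cohort size must be at least 20")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor rate must be in [0, 1)")


@dataclass
class CohortTruth:
    nhoc: np.ndarray
    latent: np.ndarray
    stage: np.ndarray
    linear_predictor: np.ndarray
    betas: dict
    censor_horizon_days: float
    observed_censor_rate: float


def _calibrate_uniform_censoring(rates: np.ndarray, target: float) -> float:
    """Upper bound u of U(0, u) censoring achieving the target censored fraction.

    For exponential event time with rate λ and uniform censoring on (0, u),
    P(censored) = (1 − e^{−λu}) / (λu); the mean over patients is solved
    for u by bisection.
    """
    if target == 0:
        return float("inf")

    def mean_censored(u):
        lu = rates * u
        return float(np.mean((1 - np.exp(-lu)) / lu))

    lo, hi = 1e-6, 1e8
    if mean_censored(hi) > target:
        raise ValueError(f"censor rate {target} not achievable (too low for these hazards)")
    return float(optimize.brentq(lambda u: mean_censored(u) - target, lo, hi))


def simulate_cohort(params: CohortParams = CohortParams()):
    """Simulated survival cohort with radiomic-like features and known truth.

    Returns (features, clinical, truth): a patients × features table, a
    clinical table (time_days, event, stage_simple, nhoc, site, age), and
    the generating ground truth.  Survival times are exponential with
    hazard ``baseline_rate × exp(β·x)`` over centred covariates.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    ids = [f"pt{i:04d}" for i in range(p.n)]

    nhoc = np.clip(rng.beta(2, 3, p.n), 0, 1)  # mass around 0.2-0.6, like tumours
    latent = rng.normal(0, 1, p.n)
    stage = rng.integers(1, 5, p.n)
    age = rng.normal(68, 10, p.n)
    sites = np.asarray(p.sites)[rng.integers(0, len(p.sites), p.n)]

    x = {
        "nhoc": nhoc - nhoc.mean(),
        "latent": latent - latent.mean(),
        "stage": stage - stage.mean(),
    }
    lp = sum(p.betas.get(k, 0.0) * v for k, v in x.items())
    rates = p.baseline_rate * np.exp(lp)
    event_time = rng.exponential(1.0 / rates)

    horizon = _calibrate_uniform_censoring(rates, p.censor_rate)
    if np.isfinite(horizon):
        censor_time = rng.uniform(0, horizon, p.n)
    else:
        censor_time = np.full(p.n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1.0)  # survival times strictly positive (days)

    cols = {}
    for j in range(p.n_informative):
        w = 0.7 + 0.3 * rng.random()
        cols[f"feat_info_{j:02d}"] = w * latent + rng.normal(0, 0.5, p.n)
    for j in range(p.n_noise):
        cols[f"feat_noise_{j:02d}"] = rng.normal(0, 1, p.n)
    features = pd.DataFrame(cols, index=ids)

    for site, shift in p.batch_shift.items():
        features.loc[sites == site] += shift
    for site, scale in p.batch_scale.items():
        features.loc[sites == site] *= scale

    clinical = pd.DataFrame({
        "time_days": time,
        "event": event,
        "stage_simple": stage,
        "age_years": age,
        "nhoc": nhoc,
        "site": sites,
    }, index=ids)
    clinical.index.name = "patient_id"
    features.index.name = "patient_id"

    truth = CohortTruth(
        nhoc=nhoc, latent=latent, stage=stage, linear_predictor=lp,
        betas=dict(p.betas), censor_horizon_days=horizon,
        observed_censor_rate=float(1 - event.mean()),
    )
    return features, clinical, truth
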