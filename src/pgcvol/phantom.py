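"""Synthetic CT phantoms and synthetic cohorts with known ground truth.

The phantom generator builds an anisotropic CT grid (default 0.49 x 0.49 x
1.5 mm, the acquisition geometry the pipeline targets) holding a uniform
soft-tissue background with optional Gaussian noise, an ellipsoidal
"third ventricle" written into a label mask, and spherical calcified
inclusions of known analytic and voxelized volume.  Membership of a voxel
in the ventricle or in a blob is decided by its center point, so an
exhaustive voxel-center scan reproduces the truth exactly and the
volumetry stage can be validated to the voxel.

The cohort generator plants an age-confounded association between
calcification volume and PSQI total: calcification volume rises with age
(gamma-distributed around an age-dependent mean, right-skewed as real
calcification volumes are), and the PSQI total is a rounded, clamped
Gaussian linear predictor in calcification volume, age, sex and —
optionally — tertile indicators.  Defaults are calibrated to a
middle-aged-and-older rural cohort: age 56.5 +/- 12.6 years truncated to
40+, 57% female, calcification 51 +/- 53.5 uL, PSQI 5.3 +/- 2.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .imaging_io import CTVolume, LabelMask
from .volumetry import voxel_centers

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "AgeDistribution",
    "PGCModel",
    "PSQIModel",
    "CohortSpec",
    "make_cohort",
    "write_cohort",
    "read_cohort",
]


# ---------------------------------------------------------------------------
# imaging phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Recipe for one synthetic CT volume plus its ventricle mask.

    World coordinates are RAS+ with the voxel (0, 0, 0) center at the
    origin.  ``calc_blobs`` is a list of ``(center_mm, radius_mm,
    intensity_HU)`` spheres; blob intensities must exceed 50 HU and the
    background plus four noise SDs must stay below 50 HU so that the
    calcified/non-calcified truth is unambiguous.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing_mm: tuple[float, float, float] = (0.49, 0.49, 1.5)
    ventricle_center_mm: tuple[float, float, float] = (23.3, 32.0, 35.0)
    ventricle_semiaxes_mm: tuple[float, float, float] = (4.0, 6.0, 5.0)
    calc_blobs: list = field(
        default_factory=lambda: [((23.3, 12.0, 35.0), 2.5, 150.0)]
    )
    background_HU: float = 20.0
    noise_sd_HU: float = 5.0
    target_label: int = 1
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
        return aff

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("shape must be strictly positive")
        if self.background_HU + 4.0 * self.noise_sd_HU >= 50.0:
            raise ValueError(
                "background + 4*noise_sd must stay below 50 HU so ground "
                "truth is unambiguous"
            )
        hi = (np.array(self.shape) - 1) * np.array(self.spacing_mm)
        for center, radius, intensity in self.calc_blobs:
            if intensity <= 50.0:
                raise ValueError(
                    f"blob intensity {intensity} HU must exceed 50 HU"
                )
            if radius <= 0:
                raise ValueError("blob radius must be > 0")
            c = np.asarray(center, dtype=float)
            if np.any(c < 0) or np.any(c > hi):
                raise ValueError(
                    f"blob center {tuple(c)} lies outside the volume's "
                    f"world bounding box (0..{tuple(hi)})"
                )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom.

    ``true_calc_volume_uL`` is the analytic sphere volume summed over
    blobs; ``true_voxelized_volume_uL`` counts voxel centers inside any
    blob times the voxel volume and is the value an exact voxel-center
    volumetry must recover.
    """

    blob_volumes_uL: list[float]
    true_calc_volume_uL: float
    true_voxelized_volume_uL: float
    n_calc_voxels: int
    ventricle_centroid_mm: np.ndarray


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelMask, PhantomTruth]:
    """Generate a phantom volume, its ventricle label mask and the truth.

    Voxel values are background + Gaussian noise, overridden by the blob
    intensity wherever the voxel center falls inside a blob.  Deterministic
    given ``spec.seed``.  A blob overlapping the ventricle mask is an
    error, since the centroid truth would then be ambiguous.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine
    world = voxel_centers(spec.shape, affine)  # (3, nx, ny, nz)

    voxels = np.full(spec.shape, float(spec.background_HU))
    if spec.noise_sd_HU > 0:
        voxels += rng.normal(0.0, spec.noise_sd_HU, size=spec.shape)

    vc = np.asarray(spec.ventricle_center_mm, dtype=float)
    va = np.asarray(spec.ventricle_semiaxes_mm, dtype=float)
    ventricle = (
        ((world - vc[:, None, None, None]) / va[:, None, None, None]) ** 2
    ).sum(axis=0) <= 1.0

    calc = np.zeros(spec.shape, dtype=bool)
    blob_volumes = []
    for center, radius, intensity in spec.calc_blobs:
        c = np.asarray(center, dtype=float)
        inside = (
            ((world - c[:, None, None, None]) ** 2).sum(axis=0) <= radius ** 2
        )
        if (inside & ventricle).any():
            raise ValueError(
                "calcified blob overlaps the ventricle mask; ground truth "
                "would be ambiguous"
            )
        voxels[inside] = float(intensity)
        calc |= inside
        blob_volumes.append(4.0 / 3.0 * math.pi * radius ** 3)

    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[ventricle] = spec.target_label

    vol = CTVolume(voxels=voxels, affine=affine)
    mask = LabelMask(labels=labels, affine=affine, target_label=spec.target_label)

    vent_idx = np.argwhere(ventricle)
    if vent_idx.size:
        centroid = (vent_idx @ affine[:3, :3].T + affine[:3, 3]).mean(axis=0)
    else:
        centroid = np.full(3, np.nan)
    n_calc = int(calc.sum())
    truth = PhantomTruth(
        blob_volumes_uL=blob_volumes,
        true_calc_volume_uL=float(sum(blob_volumes)),
        true_voxelized_volume_uL=n_calc * vol.voxel_volume_uL,
        n_calc_voxels=n_calc,
        ventricle_centroid_mm=centroid,
    )
    return vol, mask, truth


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeDistribution:
    """Truncated-normal age model; mean/sd refer to the truncated law."""

    mean: float = 56.5
    sd: float = 12.6
    min: float = 40.0
    max: float = 95.0


@dataclass(frozen=True)
class PGCModel:
    """Age-dependent calcification volume in microlitres.

    Expected volume is ``mean_uL + slope_uL_per_year * (age - age_mean)``,
    floored at 1 uL; draws are gamma with that mean and constant SD
    ``noise_sd_uL``, giving the right-skewed marginal real calcification
    volumes show.
    """

    mean_uL: float = 51.0
    slope_uL_per_year: float = 0.55
    noise_sd_uL: float = 53.0


@dataclass(frozen=True)
class PSQIModel:
    """Gaussian linear predictor for the PSQI total, rounded and clamped.

    ``total = clip(round(intercept + beta_pgc*pgc + beta_age*age +
    beta_female*female + beta_tertile2*I(t=2) + beta_tertile3*I(t=3) +
    N(0, noise_sd)), 0, 21)``.  Tertile indicators are computed from the
    generated volumes with the same rounding/tie rules the analysis uses,
    so printed tertile effects can be planted directly.
    """

    intercept: float = 2.7
    beta_pgc: float = 0.004
    beta_age: float = 0.04
    beta_female: float = 0.25
    beta_tertile2: float = 0.0
    beta_tertile3: float = 0.0
    noise_sd: float = 2.7


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort table."""

    n: int = 1009
    age: AgeDistribution = AgeDistribution()
    female_frac: float = 0.57
    pgc: PGCModel = PGCModel()
    psqi: PSQIModel = PSQIModel()
    seed: int = 0


def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float):
    """Solve for parent (mu, sigma) whose [lo, hi]-truncation has the
    requested mean and SD; returns a frozen scipy distribution."""
    def residual(p):
        mu, log_sig = p
        sig = math.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.fsolve(residual, [mean, math.log(sd)], full_output=False)
    mu, sig = float(sol[0]), math.exp(float(sol[1]))
    a, b = (lo - mu) / sig, (hi - mu) / sig
    return stats.truncnorm(a, b, loc=mu, scale=sig)


_TRUNCNORM_CACHE: dict[tuple, object] = {}


def _age_sampler(age: AgeDistribution):
    key = (age.mean, age.sd, age.min, age.max)
    if key not in _TRUNCNORM_CACHE:
        _TRUNCNORM_CACHE[key] = _truncnorm_parent(*key)
    return _TRUNCNORM_CACHE[key]


def make_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Generate a cohort table: id, age, sex, pgc_uL, psqi_total, psqi_poor.

    ``sex`` is a female indicator (1 = female).  Deterministic given
    ``spec.seed``; volumes are non-negative and PSQI totals are integers in
    [0, 21] by construction.
    """
    if spec.n <= 0:
        raise ValueError("cohort size n must be positive")
    rng = np.random.default_rng(spec.seed)

    age = _age_sampler(spec.age).rvs(size=spec.n, random_state=rng)
    female = (rng.random(spec.n) < spec.female_frac).astype(int)

    mu = spec.pgc.mean_uL + spec.pgc.slope_uL_per_year * (age - spec.age.mean)
    mu = np.maximum(mu, 1.0)
    sd = spec.pgc.noise_sd_uL
    if sd > 0:
        shape_k = (mu / sd) ** 2
        scale = sd ** 2 / mu
        pgc = rng.gamma(shape_k, scale)
    else:
        pgc = mu.copy()

    m = spec.psqi
    lp = (m.intercept + m.beta_pgc * pgc + m.beta_age * age
          + m.beta_female * female)
    if m.beta_tertile2 != 0.0 or m.beta_tertile3 != 0.0:
        from .cohort_stats import assign_tertiles

        labels = assign_tertiles(pgc).labels
        lp = lp + m.beta_tertile2 * (labels == 2) + m.beta_tertile3 * (labels == 3)
    total = lp + rng.normal(0.0, m.noise_sd, size=spec.n)
    total = np.clip(np.rint(total), 0, 21).astype(int)

    return pd.DataFrame({
        "id": np.arange(1, spec.n + 1),
        "age": age,
        "sex": female,
        "pgc_uL": pgc,
        "psqi_total": total,
        "psqi_poor": total >= 6,
    })


COHORT_COLUMNS = ("id", "age", "sex", "pgc_uL", "psqi_total", "psqi_poor")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {', '.join(missing)}")
    df["psqi_poor"] = df["psqi_poor"].astype(bool)
    return df
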