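"""Synthetic brain phantoms and cohorts with known ground truth.

The phantom is a set of nested similar ellipsoids sharing one centre:
ventricles innermost, then a white-matter shell, a cortical shell, and an
intracranial envelope.  Lobar regions are angular wedges in the
anterior-posterior / superior-inferior plane (frontal, parietal, occipital,
temporal quadrants) split into hemispheres along the first axis; the basal
ganglia are a bilateral pair of elongated para-ventricular ellipsoids that
span the full ventricle-to-cortex depth so that every one of the 36
region x layer parcels is populated.

The cohort generator draws per-subject parcel volumes from a correlated
log-normal model with a block latent structure (default: three correlated
factors), plus covariates and cognitive scores with configurable linear
effects — the ground truth needed to validate the component-recovery and
association stages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .parcellation import (
    N_LAYERS,
    PARCEL_CODES,
    BullseyeMap,
    parcel_code,
    parcel_decode,
)
from .volumes import LabelVolume

__all__ = [
    "PhantomGeometry",
    "PhantomBrain",
    "LesionGroundTruth",
    "SimulatedCohort",
    "InvalidGeometryError",
    "CapacityError",
    "make_phantom_brain",
    "seed_wmh_lesions",
    "default_block_assignment",
    "default_loading_pattern",
    "default_factor_corr",
    "simulate_cohort",
]


class InvalidGeometryError(ValueError):
    """Phantom geometry with non-nested or degenerate radii."""


class CapacityError(ValueError):
    """Requested lesion volume exceeds a parcel's available volume."""


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG stream derived from one global integer seed.

    Uses a stable digest of the name (``hash()`` is salted per process).
    """
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class PhantomGeometry:
    """Radii as fractions of the half field-of-view along each axis.

    Nesting ``ventricle < wm < cortex_outer <= skull`` is required.
    """

    ventricle_radius: float = 0.22
    wm_radius: float = 0.80           # outer white-matter boundary = inner cortex
    cortex_radius: float = 0.90       # outer cortical boundary
    skull_radius: float = 0.97        # intracranial envelope
    bg_center: float = 0.50           # basal-ganglia ellipsoid centre offset (axis 0)
    bg_semiaxes: tuple[float, float, float] = (0.27, 0.13, 0.13)
    jitter: float = 0.01              # relative radius jitter drawn from the seed

    def validate(self) -> None:
        radii = (self.ventricle_radius, self.wm_radius, self.cortex_radius, self.skull_radius)
        if any(r <= 0 for r in radii):
            raise InvalidGeometryError(f"all radii must be positive, got {radii}")
        if not (self.ventricle_radius < self.wm_radius < self.cortex_radius <= self.skull_radius):
            raise InvalidGeometryError(
                "radii must nest: ventricle < wm < cortex <= skull, got "
                f"{radii}"
            )
        if any(a <= 0 for a in self.bg_semiaxes):
            raise InvalidGeometryError("basal-ganglia semiaxes must be positive")


@dataclass
class PhantomBrain:
    ventricle_mask: LabelVolume
    cortex_mask: LabelVolume
    wm_mask: LabelVolume
    lobar_labels: LabelVolume
    intracranial_mask: LabelVolume
    spacing: tuple[float, float, float]
    seed: int

    @property
    def etiv_mm3(self) -> float:
        return self.intracranial_mask.volume_mm3()

    @property
    def basal_ganglia_mask(self) -> np.ndarray:
        return self.lobar_labels.data == 9

    @property
    def domain_mask(self) -> np.ndarray:
        """White matter plus basal ganglia — the parcellation domain."""
        return self.wm_mask.as_bool() | self.basal_ganglia_mask


def make_phantom_brain(
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    geometry: PhantomGeometry | None = None,
    seed: int = 0,
) -> PhantomBrain:
    """Build a deterministic synthetic brain from nested ellipsoids.

    ``seed`` perturbs the ventricle/white-matter radii by at most
    ``geometry.jitter`` (relative), keeping the nesting and all 36 parcels
    populated for the default geometry.
    """
    geometry = geometry or PhantomGeometry()
    geometry.validate()
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 32 for s in shape):
        raise ValueError(f"shape must be 3 ints >= 32, got {shape}")
    spacing = tuple(float(s) for s in spacing)

    rng = _stream(seed, "phantom-geometry")
    if geometry.jitter > 0:
        scale = 1.0 + geometry.jitter * rng.uniform(-1, 1, size=2)
        geometry = replace(
            geometry,
            ventricle_radius=geometry.ventricle_radius * scale[0],
            wm_radius=geometry.wm_radius * scale[1],
        )
        geometry.validate()

    half = np.array([(n * s) / 2.0 for n, s in zip(shape, spacing)])  # mm
    axes = [(np.arange(n) + 0.5) * s - h for n, s, h in zip(shape, spacing, half)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    # normalized elliptic radius: 1.0 on the field-of-view boundary ellipsoid
    rho = np.sqrt((x / half[0]) ** 2 + (y / half[1]) ** 2 + (z / half[2]) ** 2)

    vent = rho <= geometry.ventricle_radius
    wm_shell = (rho > geometry.ventricle_radius) & (rho <= geometry.wm_radius)
    cortex = (rho > geometry.wm_radius) & (rho <= geometry.cortex_radius)
    intracranial = rho <= geometry.skull_radius
    if not vent.any():
        raise InvalidGeometryError("ventricle region is empty on this grid")

    # bilateral basal ganglia: elongated ellipsoids along axis 0, clipped to the shell
    bg = np.zeros(shape, dtype=bool)
    a = np.array(geometry.bg_semiaxes) * half
    for sign in (-1.0, 1.0):
        cx = sign * geometry.bg_center * half[0]
        bg |= ((x - cx) / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2 <= 1.0
    bg &= wm_shell
    wm = wm_shell & ~bg

    # lobar wedges in the (y, z) plane: frontal +y, parietal +z, occipital -y,
    # temporal -z; hemisphere from the sign of x (left = negative)
    phi = np.degrees(np.arctan2(z, y))
    lobe = np.zeros(shape, dtype=np.int32)  # 0 frontal, 1 parietal, 2 temporal, 3 occipital
    lobe[(phi > 45) & (phi <= 135)] = 1
    lobe[(phi <= -45) & (phi > -135)] = 2
    lobe[(phi > 135) | (phi <= -135)] = 3
    base = np.array([1, 3, 5, 7], dtype=np.int32)  # frontal/parietal/temporal/occipital L codes
    labels = np.zeros(shape, dtype=np.int32)
    labels[wm] = base[lobe[wm]] + (x[wm] >= 0).astype(np.int32)
    labels[bg] = 9

    mk = lambda arr: LabelVolume(arr.astype(np.int32), spacing)
    return PhantomBrain(
        ventricle_mask=mk(vent),
        cortex_mask=mk(cortex),
        wm_mask=mk(wm),
        lobar_labels=mk(labels),
        intracranial_mask=mk(intracranial),
        spacing=spacing,
        seed=seed,
    )


@dataclass
class LesionGroundTruth:
    target_volumes: dict[int, float]  # parcel code -> mm^3
    lesion_mask: LabelVolume

    def total_mm3(self) -> float:
        return float(sum(self.target_volumes.values()))


def seed_wmh_lesions(
    parcels: BullseyeMap,
    targets: dict[int, float],
    spacing: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> LesionGroundTruth:
    """Place lesions with exact per-parcel volumes.

    Each parcel's lesion is grown outward from one randomly chosen seed voxel
    (closest-first in mm), guaranteeing the target voxel count exactly.
    Targets must be non-negative multiples of the voxel volume and fit within
    the parcel.
    """
    spacing = spacing or parcels.spacing
    vox = float(np.prod(spacing))
    codes = parcels.values.data
    lesion = np.zeros(codes.shape, dtype=bool)
    kept: dict[int, float] = {}
    rng = _stream(seed, "lesion-seeding")
    for code in sorted(targets):
        mm3 = float(targets[code])
        if mm3 < 0:
            raise ValueError(f"negative target volume for parcel {code}")
        n_f = mm3 / vox
        n = int(round(n_f))
        if abs(n_f - n) > 1e-6:
            raise ValueError(
                f"target {mm3} mm^3 for parcel {code} is not a multiple of the "
                f"voxel volume {vox} mm^3"
            )
        kept[code] = mm3
        if n == 0:
            continue
        idx = np.argwhere(codes == code)
        if n > len(idx):
            raise CapacityError(
                f"parcel {code}: target {mm3} mm^3 ({n} voxels) exceeds capacity "
                f"of {len(idx)} voxels"
            )
        start = idx[rng.integers(len(idx))]
        d2 = np.sum(((idx - start) * np.asarray(spacing)) ** 2, axis=1)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
        chosen = idx[order[:n]]
        lesion[tuple(chosen.T)] = True
    mask = LabelVolume(lesion.astype(np.int32), spacing, affine=parcels.values.affine)
    return LesionGroundTruth(target_volumes=kept, lesion_mask=mask)


# --------------------------------------------------------------------------
# cohort simulation


def default_block_assignment() -> dict[int, int]:
    """Map each of the 36 parcel codes to one of 3 latent blocks.

    Block 1: frontal/parietal + basal ganglia, periventricular emphasis;
    block 2: occipital; block 3: temporal plus juxtacortical frontal/parietal.
    """
    assign: dict[int, int] = {}
    for code in PARCEL_CODES:
        region, layer = parcel_decode(code)
        if region in (7, 8):
            assign[code] = 2
        elif region in (5, 6):
            assign[code] = 3
        elif region in (1, 2, 3, 4):
            assign[code] = 1 if layer <= 2 else 3
        else:  # basal ganglia
            assign[code] = 1
    return assign


#: Parcels given a weaker dominant loading: boundary regions that the latent
#: blocks represent poorly (mirrors low-communality behaviour at the edges).
_WEAK_PARCELS = frozenset({parcel_code(5, 1), parcel_code(6, 1),
                           parcel_code(7, 4), parcel_code(8, 4),
                           parcel_code(9, 3), parcel_code(9, 4)})


def default_loading_pattern(
    dominant: float = 0.75, weak: float = 0.65
) -> np.ndarray:
    """36 x 3 block loading matrix used by the default cohort model."""
    assign = default_block_assignment()
    pattern = np.zeros((len(PARCEL_CODES), 3))
    for j, code in enumerate(PARCEL_CODES):
        lam = weak if code in _WEAK_PARCELS else dominant
        pattern[j, assign[code] - 1] = lam
    return pattern


def default_factor_corr() -> np.ndarray:
    """Latent factor correlations; the block-1/block-3 pair is strongest."""
    return np.array([
        [1.0, 0.45, 0.55],
        [0.45, 1.0, 0.40],
        [0.55, 0.40, 1.0],
    ])


_DEFAULT_COVARIATE_MODEL: dict = {
    "age_range": (58.0, 84.0),
    "female_rate": 0.546,
    "education_mean": 15.0,
    "education_sd": 2.5,
    "hypertension_rate": 0.35,
    "etiv_mean": 1.5e6,
    "etiv_sd": 1.5e5,
    "bpf_intercept": 80.0,
    "bpf_age_slope": -0.25,   # percent per year beyond age 70
    "bpf_sd": 2.0,
    # correlation of standardized age with each latent factor
    "age_factor_corr": (0.45, 0.22, 0.40),
    # cognitive effects: domain -> {"factor": index 1..3 or None, "beta": float}
    "cognitive_effects": {
        "memory": {"factor": 3, "beta": -0.34},
        "speed": {"factor": 1, "beta": -0.23},
        "reasoning": {"factor": None, "beta": 0.0},
        "vocabulary": {"factor": None, "beta": 0.0},
    },
    "education_beta": 0.10,
    "cognitive_noise_sd": 0.85,
    "missing_rate": 0.0,
    # log-scale volume location by layer (periventricular-heavy), mm^3 medians
    "layer_median_mm3": (600.0, 300.0, 150.0, 80.0),
    "occipital_layer_median_mm3": (150.0, 200.0, 250.0, 400.0),
    "log_scale_sd": 0.9,
}

DOMAINS = ("memory", "speed", "reasoning", "vocabulary")


@dataclass
class SimulatedCohort:
    """Simulated cohort table plus the generative ground truth."""

    table: pd.DataFrame
    factors: np.ndarray               # n x k latent factor scores
    loading_pattern: np.ndarray       # 36 x k
    block_assignment: dict[int, int]  # parcel code -> dominant block (1-based)
    seed: int


def simulate_cohort(
    n: int = 108,
    loading_pattern: np.ndarray | None = None,
    factor_corr: np.ndarray | None = None,
    unique_sd: np.ndarray | None = None,
    covariate_model: dict | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a cohort of parcel volumes, covariates and cognition.

    Log-scale parcel values are ``loading_pattern @ factors + unique noise``,
    exponentiated and scaled to mm^3, giving right-skewed marginals with the
    block correlation structure.  Standardized age feeds positively into the
    factors; cognition is linear in the designated factor and covariates.
    """
    cfg = dict(_DEFAULT_COVARIATE_MODEL)
    if covariate_model:
        cfg.update(covariate_model)
    pattern = default_loading_pattern() if loading_pattern is None else np.asarray(loading_pattern, float)
    corr = default_factor_corr() if factor_corr is None else np.asarray(factor_corr, float)
    p, k = pattern.shape
    if p != len(PARCEL_CODES):
        raise ValueError(f"loading_pattern must have {len(PARCEL_CODES)} rows")
    if corr.shape != (k, k):
        raise ValueError(f"factor_corr must be {k}x{k}")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("factor_corr is not positive definite") from exc
    if unique_sd is None:
        unique_sd = np.sqrt(np.clip(1.0 - np.sum(pattern**2, axis=1), 1e-6, None))
    else:
        unique_sd = np.broadcast_to(np.asarray(unique_sd, float), (p,)).copy()

    rng_cov = _stream(seed, "cohort-covariates")
    rng_fac = _stream(seed, "cohort-factors")
    rng_vol = _stream(seed, "cohort-volumes")
    rng_cog = _stream(seed, "cohort-cognition")
    rng_mis = _stream(seed, "cohort-missingness")

    age = rng_cov.uniform(*cfg["age_range"], size=n)
    z_age = (age - age.mean()) / age.std(ddof=1)
    sex = np.where(rng_cov.random(n) < cfg["female_rate"], "female", "male")
    education = np.clip(
        np.round(rng_cov.normal(cfg["education_mean"], cfg["education_sd"], size=n)), 8, 22
    )
    hypertension = (rng_cov.random(n) < cfg["hypertension_rate"]).astype(int)
    etiv = np.clip(rng_cov.normal(cfg["etiv_mean"], cfg["etiv_sd"], size=n), 8e5, None)
    bpf = np.clip(
        cfg["bpf_intercept"]
        + cfg["bpf_age_slope"] * (age - 70.0)
        + rng_cov.normal(0, cfg["bpf_sd"], size=n),
        1.0,
        100.0,
    )

    # latent factors: correlated noise plus an age-driven component
    age_load = np.asarray(cfg["age_factor_corr"], float)[:k]
    eps = rng_fac.standard_normal((n, k)) @ chol.T
    factors = age_load * z_age[:, None] + np.sqrt(1.0 - age_load**2) * eps

    # parcel volumes on the log scale
    zvol = factors @ pattern.T + unique_sd * rng_vol.standard_normal((n, p))
    mu = np.empty(p)
    for j, code in enumerate(PARCEL_CODES):
        region, layer = parcel_decode(code)
        medians = (
            cfg["occipital_layer_median_mm3"] if region in (7, 8) else cfg["layer_median_mm3"]
        )
        mu[j] = np.log(medians[layer - 1])
    volumes = np.exp(mu + cfg["log_scale_sd"] * zvol)

    # cognition: standardized base noise, then linear effects
    fz = (factors - factors.mean(axis=0)) / factors.std(axis=0, ddof=1)
    z_edu = (education - education.mean()) / education.std(ddof=1)
    cog: dict[str, np.ndarray] = {}
    for domain in DOMAINS:
        base = rng_cog.standard_normal(n)
        base = (base - base.mean()) / base.std(ddof=1)  # mean 0, SD 1 pre-injection
        spec_d = cfg["cognitive_effects"][domain]
        effect = np.zeros(n)
        if spec_d["factor"] is not None and spec_d["factor"] <= k:
            effect = spec_d["beta"] * fz[:, spec_d["factor"] - 1]
        cog[domain] = effect + cfg["education_beta"] * z_edu + cfg["cognitive_noise_sd"] * base

    data: dict[str, object] = {
        "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
        "age": age,
        "sex": sex,
        "education": education,
        "hypertension": hypertension,
        "bpf": bpf,
        "etiv": etiv,
    }
    for j, code in enumerate(PARCEL_CODES):
        data[f"p{code}"] = volumes[:, j]
    for domain in DOMAINS:
        data[domain] = cog[domain]
        miss = rng_mis.random(n) < cfg["missing_rate"]
        data[f"{domain}_missing"] = miss.astype(int)
        data[domain] = np.where(miss, np.nan, data[domain])
    table = pd.DataFrame(data)
    return SimulatedCohort(
        table=table,
        factors=factors,
        loading_pattern=pattern,
        block_assignment=default_block_assignment() if loading_pattern is None else {},
        seed=seed,
    )
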