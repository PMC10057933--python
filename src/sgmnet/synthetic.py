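"""Synthetic cohorts of preprocessed-looking gray matter volumes.

Real inputs to the analysis are segmented, DARTEL-normalized, smoothed gray
matter maps from a cohort of 812 healthy adults (407 women, 405 men, ages
25.8-85.1, two 3-T scanners).  No such data ship with this package, so this
module synthesizes volumes with the statistical structure the analysis
assumes:

* gray-matter-like intensity fields inside an ellipsoidal "brain" mask,
  built from independent voxel noise plus a *pattern-mixture* component:
  a small bank of high-frequency cube-sized template patterns blended by
  spatially smooth weight fields, so that nearby cubes share morphology,
  distant cubes are diverse, and occasional weight coincidences create
  long-range similarity (the ingredients of small-world similarity
  networks);
* a per-subject *covariance strength* in [0, 1] weighting the structured
  component against the voxel noise — the knob through which age and sex
  effects reach the similarity networks;
* covariance strength declining linearly with age, offset upward in women,
  with an extra female decline above a changepoint age (default 70 y),
  emulating the faster late-life network decline reported for women;
* a mild global intensity decline with age (gray matter atrophy), which is
  what gives a brain-age model something to learn at cohort scale.

The generator emits *unsmoothed* fields; callers apply the stage-appropriate
smoothing (8 mm FWHM for networks, 4 mm for brain age).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import FWHM_TO_SIGMA, GrayMatterVolume, gaussian_smooth

__all__ = [
    "EffectParams",
    "CohortSpec",
    "SubjectRecord",
    "generate_smooth_gm_volume",
    "generate_cohort",
    "write_cohort",
    "load_cohort_table",
]


@dataclass
class EffectParams:
    """How covariance strength depends on age and sex.

    covariance_strength = baseline - age_slope*age + sex_offset*[F]
                          - female_post_slope*max(0, age - changepoint_age)*[F]
                          + Normal(0, noise_scale)

    clipped to [0, 1].  Defaults are chosen so that strengths stay inside
    [0, 1] over ages 25-86 and span a range over which the downstream
    small-world metrics respond measurably.
    """

    baseline: float = 0.535
    age_slope: float = 0.0029  # per year
    sex_offset: float = 0.08  # added for women
    changepoint_age: float | None = 70.0
    female_post_slope: float = 0.011  # extra per-year decline for women past the changepoint
    noise_scale: float = 0.02
    atrophy_per_year: float = 0.006  # fractional mean-intensity decline per year
    male_size_offset: float = 0.02  # relative brain-mask enlargement for men
    shrink_per_year: float = 0.0006  # relative brain-mask shrinkage per year (atrophy)

    def covariance_strength(self, age: float, is_female: bool, noise: float = 0.0) -> float:
        c = self.baseline - self.age_slope * age
        if is_female:
            c += self.sex_offset
            if self.changepoint_age is not None and age > self.changepoint_age:
                c -= self.female_post_slope * (age - self.changepoint_age)
        return c + noise


@dataclass
class CohortSpec:
    """Cohort layout and effect structure for :func:`generate_cohort`."""

    n_subjects: int = 812
    age_range: tuple[float, float] = (25.8, 85.1)
    sex_ratio: float = 407 / 812  # fraction female
    scanner_labels: tuple[str, str] = ("philips", "siemens")
    effect: EffectParams = field(default_factory=EffectParams)
    shape: tuple[int, int, int] = (30, 30, 30)
    voxel_size: float = 6.0  # mm (coarse desk-scale grid; one cube = 18 mm)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        cp = self.effect.changepoint_age
        if cp is not None and not (lo <= cp <= hi):
            raise ValueError("changepoint_age must lie within age_range (or be None)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["effect"] = EffectParams(**d["effect"])
        for key in ("age_range", "scanner_labels", "shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SubjectRecord:
    """One cohort member; network properties and brain age fill in downstream."""

    id: str
    age: float
    sex: str  # "F" or "M"
    scanner: str
    covariance_strength: float = np.nan
    n_nodes: int | None = None
    properties: object | None = None  # NetworkProperties, filled downstream
    predicted_age: float | None = None

    @property
    def brain_pad(self) -> float | None:
        if self.predicted_age is None:
            return None
        return self.predicted_age - self.age


def _ellipsoid_mask(shape: tuple[int, int, int], scale: float = 1.0) -> np.ndarray:
    """Boolean ellipsoid inscribed in the grid, semi-axes scaled by ``scale``."""
    grids = np.indices(shape).astype(float)
    sq = np.zeros(shape)
    for ax, n in enumerate(shape):
        center = (n - 1) / 2.0
        radius = scale * n / 2.0
        sq += ((grids[ax] - center) / radius) ** 2
    return sq <= 1.0


def _pattern_mixture_field(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    coherence: float,
    n_templates: int,
    template_scale_cubes: float,
) -> np.ndarray:
    """Structured component: template patterns blended by weight fields.

    A bank of ``n_templates`` high-frequency 3x3x3 template patterns is
    blended, cube by cube, by per-template weight fields over the cube
    grid.  Each cube's weight vector mixes a *specific* part — spatially
    smooth fields (Gaussian scale ``template_scale_cubes``), so that
    neighboring cubes share morphology and chance weight alignments create
    sporadic long-range similarity — with a subject-wide *common* morphology
    vector, in proportion ``coherence`` : ``1 - coherence``.  At coherence 1
    morphology is fully differentiated (sparse, locally clustered
    similarity); as coherence falls, the common mode raises a similarity
    floor between all cubes, the thresholded graph densifies
    non-specifically, and its topology drifts toward a random graph — which
    is how age-related network degradation (de-differentiation) is
    emulated.
    """
    from scipy import ndimage

    edge = 3
    grid = tuple(int(np.ceil(s / edge)) for s in shape)
    templates = rng.standard_normal((n_templates, edge, edge, edge))
    templates -= templates.mean(axis=(1, 2, 3), keepdims=True)
    templates /= templates.std(axis=(1, 2, 3), keepdims=True)
    smooth = ndimage.gaussian_filter(
        rng.standard_normal((n_templates, *grid)),
        sigma=(0, *(template_scale_cubes,) * 3),
        mode="reflect",
    )
    smooth /= smooth.std() or 1.0
    common = rng.standard_normal(n_templates)
    common /= np.linalg.norm(common)
    # per-cube de-differentiation degree: a smooth field jittered around the
    # subject-level coherence, so the common-mode similarity floor rises
    # gradually (cube by cube) instead of switching on at a sharp threshold
    jitter = ndimage.gaussian_filter(
        rng.standard_normal(grid), sigma=template_scale_cubes, mode="reflect"
    )
    jitter /= jitter.std() or 1.0
    ci = np.clip(coherence + 0.15 * jitter, 0.0, 1.0)
    weights = ci * smooth + (1.0 - ci) * common[:, None, None, None]
    # unit weight vector per cube position => unit-variance structured field
    norm = np.sqrt((weights**2).sum(axis=0, keepdims=True))
    norm[norm == 0] = 1.0
    weights = weights / norm
    # voxel value at cube g, local offset l:  sum_k w_k(g) * T_k(l)
    field = np.einsum("kabc,kxyz->xaybzc", templates, weights)
    field = field.reshape(grid[0] * edge, grid[1] * edge, grid[2] * edge)
    return field[: shape[0], : shape[1], : shape[2]]


def generate_smooth_gm_volume(
    shape: tuple[int, int, int],
    voxel_size: float = 2.0,
    fwhm_mm: float = 0.0,
    covariance_strength: float = 0.8,
    seed: int = 0,
    mean_intensity: float = 0.6,
    amplitude: float = 0.25,
    n_templates: int = 32,
    template_scale_cubes: float = 1.5,
    detail_fraction: float = 0.25,
    mask_scale: float = 1.0,
) -> GrayMatterVolume:
    """Generate one gray-matter-like random volume.

    ``covariance_strength`` sets the spatial coherence of the cube-level
    morphology (see :func:`_pattern_mixture_field`): at 0 the field has no
    spatial covariance structure beyond chance, at 1 neighboring cubes are
    maximally similar.  A fixed ``detail_fraction`` of i.i.d. voxel noise
    is always present.  The mixture is smoothed at ``fwhm_mm``, shifted to
    ``mean_intensity``, clipped at zero, and masked to an ellipsoid
    inscribed in the grid.  Deterministic given ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 9 for s in shape):
        raise ValueError("shape must be 3D with every axis >= 9 voxels")
    if not (0.0 <= covariance_strength <= 1.0):
        raise ValueError("covariance_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    struct = _pattern_mixture_field(
        shape, rng, covariance_strength, n_templates, template_scale_cubes
    )
    field_ = (1.0 - detail_fraction) * struct + detail_fraction * white
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    intensities = np.clip(mean_intensity + amplitude * field_, 0.0, None)
    mask = _ellipsoid_mask(shape, scale=mask_scale)
    intensities = intensities * mask
    vol = GrayMatterVolume(intensities, (voxel_size,) * 3, mask=mask)
    if fwhm_mm > 0:
        vol = gaussian_smooth(vol, fwhm_mm)
        vol = dataclasses.replace(vol, intensities=vol.intensities * mask)
    return vol


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], list[GrayMatterVolume]]:
    """Generate subject records and their (unsmoothed) volumes.

    Ages are uniform over ``spec.age_range`` (the source cohort's age
    distribution was even across decades); sex counts are exact per
    ``sex_ratio``; scanner labels alternate.  Each subject's volume is
    generated with the covariance strength implied by
    ``spec.effect`` for that subject's age and sex.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    n = spec.n_subjects
    n_female = int(round(spec.sex_ratio * n))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    noise = rng.normal(0.0, spec.effect.noise_scale, size=n)
    size_noise = rng.normal(0.0, 0.015, size=n)  # individual head-size variation
    vol_seeds = np.random.SeedSequence([spec.seed, 202]).generate_state(n) % (2**31)

    records: list[SubjectRecord] = []
    volumes: list[GrayMatterVolume] = []
    clipped = 0
    for i in range(n):
        c = spec.effect.covariance_strength(ages[i], sexes[i] == "F", noise[i])
        if not (0.0 <= c <= 1.0):
            clipped += 1
            c = float(np.clip(c, 0.0, 1.0))
        mean_intensity = 0.6 * (1.0 - spec.effect.atrophy_per_year * (ages[i] - spec.age_range[0]))
        mask_scale = (
            0.97
            + spec.effect.male_size_offset * (sexes[i] == "M")
            - spec.effect.shrink_per_year * (ages[i] - spec.age_range[0])
            + size_noise[i]
        )
        vol = generate_smooth_gm_volume(
            spec.shape,
            voxel_size=spec.voxel_size,
            fwhm_mm=0.0,
            covariance_strength=c,
            seed=int(vol_seeds[i]),
            mean_intensity=mean_intensity,
            mask_scale=mask_scale,
        )
        records.append(
            SubjectRecord(
                id=f"sub-{i + 1:04d}",
                age=float(ages[i]),
                sex=str(sexes[i]),
                scanner=spec.scanner_labels[i % len(spec.scanner_labels)],
                covariance_strength=c,
            )
        )
        volumes.append(vol)
    if clipped:
        warnings.warn(
            f"covariance_strength clipped to [0, 1] for {clipped} subjects; "
            "effect parameters may be too strong for the age range",
            stacklevel=2,
        )
    return records, volumes


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "scanner": [r.scanner for r in records],
        }
    )


def write_cohort(
    records: list[SubjectRecord],
    volumes: list[GrayMatterVolume],
    out_dir,
    spec: CohortSpec | None = None,
) -> list[Path]:
    """Write volumes (NIfTI-1 .nii.gz), the cohort CSV, and the CohortSpec JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rec, vol in zip(records, volumes):
        p = out_dir / f"{rec.id}.nii.gz"
        vol.save(p)
        written.append(p)
    table_path = out_dir / "cohort.csv"
    cohort_table(records).to_csv(table_path, index=False)
    written.append(table_path)
    if spec is not None:
        spec_path = out_dir / "cohort_spec.json"
        spec_path.write_text(spec.to_json())
        written.append(spec_path)
    return written


def load_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "age", "sex", "scanner"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df
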