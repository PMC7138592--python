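"""Synthetic phantom cohorts with the statistical structure the analysis assumes.

The generator emulates, at desk scale, an elderly imaging cohort in which
periventricular white matter lesions drive cognitive scores and degrade
diffusion metrics:

* a common 2 mm grid (default 48x56x48) with an ellipsoidal "brain", two
  ventricle slabs, a cerebellum exclusion region, and ~12 white matter
  regions laid out as boxes — a desk-scale stand-in for the 2 mm standard
  space and a 48-region white matter label atlas;
* lesion masks sampled as connected blobs from a spatial probability field
  that decays exponentially with distance to the ventricles, scaled so the
  per-subject lesion volume follows a log-normal distribution (range
  roughly 1-40 ml) that increases with age;
* a FLAIR-like channel where lesions are hyperintense and a T1-like channel
  where they are hypointense, plus Gaussian noise;
* cognitive scores generated as noisy linear functions of the lesion load
  (mm^3) in designated atlas regions, so ground-truth "top regions" exist;
* optional FA/MD/AD/RD maps whose values shift inside lesions (FA down,
  diffusivities up).

Everything is deterministic given ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import AtlasLabelMap, SubjectRecord, Volume, check_same_grid

__all__ = [
    "RegionBox",
    "AtlasSpec",
    "LesionModel",
    "IntensityModel",
    "ScoreTestModel",
    "DTIMetricModel",
    "CovariateModel",
    "PhantomSpec",
    "Cohort",
    "default_phantom_spec",
    "build_atlas",
    "generate_cohort",
    "regional_lesion_loads",
    "lesion_volumes_ml",
    "cohort_summary",
]


# ---------------------------------------------------------------------------
# Spec dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned box (or inscribed ellipsoid) in voxel coordinates."""

    name: str
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # inclusive
    hemisphere: str = "none"
    shape: str = "box"  # "box" | "ellipsoid"

    def paint(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(grid_shape, dtype=bool)
        sl = tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))
        if self.shape == "box":
            out[sl] = True
        else:
            c = [(l + h) / 2.0 for l, h in zip(self.lo, self.hi)]
            r = [max((h - l) / 2.0, 0.5) for l, h in zip(self.lo, self.hi)]
            idx = np.indices(grid_shape, dtype=float)
            d2 = sum(((idx[i] - c[i]) / r[i]) ** 2 for i in range(3))
            out = d2 <= 1.0
        if not out.any():
            raise ValueError(f"region {self.name!r} paints zero voxels")
        return out


@dataclass(frozen=True)
class AtlasSpec:
    regions: tuple[RegionBox, ...]
    ventricle: RegionBox
    cerebellum: RegionBox
    brain_center: tuple[float, float, float]
    brain_semiaxes: tuple[float, float, float]  # in voxels


@dataclass(frozen=True)
class LesionModel:
    """Periventricular lesion sampling parameters.

    ``volume_ml_median`` acts as the base rate: per-subject lesion volume is
    log-normal around it (sd ``volume_ml_log_sd`` in log space), shifted by
    ``age_log_slope`` per year of age, then clipped to
    [volume_ml_min, volume_ml_max].
    """

    decay_length_mm: float = 8.0
    volume_ml_median: float = 6.0
    volume_ml_log_sd: float = 0.65
    volume_ml_min: float = 1.0
    volume_ml_max: float = 42.0
    age_log_slope: float = 0.045  # per year, on log volume
    blob_mean_voxels: int = 60
    blob_log_sd: float = 0.6


@dataclass(frozen=True)
class IntensityModel:
    """Per-channel tissue means / noise and lesion contrast.

    Contrast must be positive on the FLAIR-like channel (hyperintense
    lesions) and negative on the T1-like channel (hypointense).
    """

    tissue_mean: Mapping[str, float] = field(
        default_factory=lambda: {"t1": 100.0, "flair": 100.0}
    )
    csf_mean: Mapping[str, float] = field(
        default_factory=lambda: {"t1": 40.0, "flair": 30.0}
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"t1": 3.0, "flair": 3.0}
    )
    lesion_contrast: Mapping[str, float] = field(
        default_factory=lambda: {"t1": -25.0, "flair": 35.0}
    )

    def __post_init__(self) -> None:
        if self.lesion_contrast.get("flair", 1.0) <= 0:
            raise ValueError("lesion contrast must be positive on flair")
        if self.lesion_contrast.get("t1", -1.0) >= 0:
            raise ValueError("lesion contrast must be negative on t1")


@dataclass(frozen=True)
class ScoreTestModel:
    """One neuropsychological test: score = intercept + beta . load + noise.

    ``beta`` maps region name -> weight per mm^3 of lesion load in that
    region; regions not listed have weight 0.
    """

    intercept: float
    beta: Mapping[str, float]
    noise_sd: float


@dataclass(frozen=True)
class DTIMetricModel:
    healthy_mean: float
    lesion_delta: float
    noise_sd: float


@dataclass(frozen=True)
class CovariateModel:
    age_range: tuple[float, float] = (62.0, 80.0)
    female_fraction: float = 0.464
    education_mean: float = 14.89
    education_sd: float = 1.20


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    n_subjects: int
    atlas_spec: AtlasSpec
    lesion_model: LesionModel
    intensity_model: IntensityModel
    score_model: Mapping[str, ScoreTestModel]
    dti_model: Mapping[str, DTIMetricModel]
    covariate_model: CovariateModel
    seed: int = 0
    include_dti: bool = True

    def __post_init__(self) -> None:
        if not self.score_model:
            raise ValueError("score_model must define at least one test")
        region_names = {r.name for r in self.atlas_spec.regions}
        for test, m in self.score_model.items():
            unknown = set(m.beta) - region_names
            if unknown:
                raise ValueError(
                    f"score model for {test!r} references unknown regions "
                    f"{sorted(unknown)}"
                )

    def replace(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


@dataclass
class Cohort:
    """A generated phantom cohort on one common grid."""

    subjects: list[SubjectRecord]
    atlas: AtlasLabelMap
    brain_mask: Volume
    ventricle_mask: Volume
    exclusion_mask: Volume  # cerebellum
    spec: PhantomSpec

    def __post_init__(self) -> None:
        for s in self.subjects:
            if s.true_lesion_mask is None or not s.true_lesion_mask.is_binary():
                raise ValueError(
                    f"subject {s.subject_id}: true_lesion_mask must be binary"
                )
            check_same_grid(self.atlas.labels, s.true_lesion_mask)

    @property
    def analysis_mask(self) -> np.ndarray:
        """Brain minus cerebellum — the feature support for prediction."""
        return (self.brain_mask.data > 0) & (self.exclusion_mask.data == 0)


# ---------------------------------------------------------------------------
# Default spec
# ---------------------------------------------------------------------------

def _default_regions() -> tuple[RegionBox, ...]:
    # 12 white matter regions in 6 left/right pairs, arranged around the
    # ventricles on a 48x56x48 grid (x: L->R, y: posterior->anterior,
    # z: inferior->superior).
    pairs = [
        ("tapetum", (13, 20, 21), (17, 28, 28)),
        ("posterior_corona_radiata", (12, 11, 25), (17, 19, 33)),
        ("posterior_thalamic_radiation", (14, 11, 16), (18, 19, 23)),
        ("anterior_corona_radiata", (13, 38, 24), (17, 46, 32)),
        ("superior_longitudinal_fasciculus", (9, 22, 30), (13, 36, 36)),
        ("anterior_limb_internal_capsule", (16, 30, 19), (19, 37, 26)),
    ]
    regions: list[RegionBox] = []
    nx = 48
    for name, lo, hi in pairs:
        regions.append(RegionBox(f"{name}_L", lo, hi, hemisphere="L"))
        mlo = (nx - 1 - hi[0], lo[1], lo[2])
        mhi = (nx - 1 - lo[0], hi[1], hi[2])
        regions.append(RegionBox(f"{name}_R", mlo, mhi, hemisphere="R"))
    return tuple(regions)


def _default_score_model() -> dict[str, ScoreTestModel]:
    # The tapetum pair is the designated ground-truth signal pair: it drives
    # a global-cognition test (declining with lesion load) and a timed test
    # (rising with lesion load — the low-noise recovery target, since the
    # positive-weight contribution convention needs a positive-beta test);
    # a memory test is driven by the posterior thalamic radiation.
    return {
        "GLOBALCOG": ScoreTestModel(
            intercept=28.0,
            beta={"tapetum_L": -0.004, "tapetum_R": -0.004},
            noise_sd=0.6,
        ),
        "MEMORY": ScoreTestModel(
            intercept=14.0,
            beta={
                "posterior_thalamic_radiation_L": -0.003,
                "posterior_thalamic_radiation_R": -0.003,
            },
            noise_sd=1.0,
        ),
        "TRAILSPEED": ScoreTestModel(
            intercept=35.0,
            beta={"tapetum_L": 0.008, "tapetum_R": 0.008},
            noise_sd=0.5,
        ),
    }


def _default_dti_model() -> dict[str, DTIMetricModel]:
    # Diffusivities in 1e-3 mm^2/s; lesions lower FA and raise MD/AD/RD,
    # with AD perturbed most and FA least (relative to noise).
    return {
        "fa": DTIMetricModel(0.45, -0.06, 0.040),
        "md": DTIMetricModel(0.75, +0.15, 0.050),
        "ad": DTIMetricModel(1.20, +0.25, 0.050),
        "rd": DTIMetricModel(0.55, +0.20, 0.050),
    }


def default_phantom_spec(
    n_subjects: int = 40, seed: int = 0, include_dti: bool = True
) -> PhantomSpec:
    """The package's default desk-scale phantom cohort specification."""
    atlas = AtlasSpec(
        regions=_default_regions(),
        ventricle=RegionBox("ventricles", (18, 18, 21), (29, 34, 28)),
        cerebellum=RegionBox(
            "cerebellum", (14, 4, 4), (33, 17, 13), shape="ellipsoid"
        ),
        brain_center=(23.5, 27.5, 25.0),
        brain_semiaxes=(21.0, 26.0, 21.0),
    )
    return PhantomSpec(
        grid_shape=(48, 56, 48),
        voxel_size=(2.0, 2.0, 2.0),
        n_subjects=n_subjects,
        atlas_spec=atlas,
        lesion_model=LesionModel(),
        intensity_model=IntensityModel(),
        score_model=_default_score_model(),
        dti_model=_default_dti_model(),
        covariate_model=CovariateModel(),
        seed=seed,
        include_dti=include_dti,
    )


# ---------------------------------------------------------------------------
# Atlas / masks
# ---------------------------------------------------------------------------

def build_atlas(spec: PhantomSpec) -> tuple[AtlasLabelMap, Volume, Volume, Volume]:
    """Rasterize the atlas spec.

    Returns (atlas, brain_mask, ventricle_mask, cerebellum_mask); regions are
    painted sequentially and claim only voxels inside the brain that are not
    ventricle, cerebellum, or an earlier region.
    """
    shape = spec.grid_shape
    idx = np.indices(shape, dtype=float)
    c = spec.atlas_spec.brain_center
    a = spec.atlas_spec.brain_semiaxes
    brain = sum(((idx[i] - c[i]) / a[i]) ** 2 for i in range(3)) <= 1.0
    ventricle = spec.atlas_spec.ventricle.paint(shape) & brain
    cerebellum = spec.atlas_spec.cerebellum.paint(shape) & brain
    if not ventricle.any():
        raise ValueError("ventricle structure paints zero in-brain voxels")

    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    hemis: dict[int, str] = {}
    free = brain & ~ventricle & ~cerebellum
    for i, region in enumerate(spec.atlas_spec.regions, start=1):
        mask = region.paint(shape) & free & (labels == 0)
        if not mask.any():
            raise ValueError(
                f"region {region.name!r} has zero in-brain voxels"
            )
        labels[mask] = i
        names[i] = region.name
        hemis[i] = region.hemisphere

    def vol(data, dtype=np.uint8):
        return Volume(
            data=data.astype(dtype),
            voxel_size=spec.voxel_size,
            space_tag="phantom",
        )

    atlas = AtlasLabelMap(
        labels=vol(labels, np.int32),
        region_names=names,
        region_hemisphere=hemis,
    )
    return atlas, vol(brain), vol(ventricle), vol(cerebellum)


def periventricular_field(
    spec: PhantomSpec, ventricle: np.ndarray, eligible: np.ndarray
) -> np.ndarray:
    """Lesion seeding probability field exp(-d/lambda), d = mm to ventricle."""
    dist = ndimage.distance_transform_edt(
        ~ventricle, sampling=spec.voxel_size
    )
    fieldv = np.exp(-dist / spec.lesion_model.decay_length_mm)
    fieldv[~eligible] = 0.0
    return fieldv


# ---------------------------------------------------------------------------
# Lesion sampling
# ---------------------------------------------------------------------------

_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _sample_lesion_mask(
    rng: np.random.Generator,
    target_voxels: int,
    fieldv: np.ndarray,
    eligible: np.ndarray,
    blob_mean_voxels: int = 60,
    blob_log_sd: float = 0.6,
) -> np.ndarray:
    """Connected-blob lesion mask with exactly ``target_voxels`` voxels
    (fewer only if eligible voxels run out)."""
    shape = fieldv.shape
    lesion = np.zeros(shape, dtype=bool)
    flat_field = fieldv.ravel()
    n_placed = 0
    while n_placed < target_voxels:
        avail = eligible & ~lesion
        weights = np.where(avail, fieldv, 0.0).ravel()
        total = weights.sum()
        if total <= 0:
            break
        seed_flat = rng.choice(weights.size, p=weights / total)
        blob_target = int(np.round(np.exp(rng.normal(
            np.log(blob_mean_voxels), blob_log_sd
        ))))
        blob_target = max(4, min(blob_target, target_voxels - n_placed))
        blob = np.zeros(shape, dtype=bool)
        blob.ravel()[seed_flat] = True
        size = 1
        while size < blob_target:
            frontier = (
                ndimage.binary_dilation(blob, structure=_STRUCT)
                & ~blob & eligible & ~lesion
            )
            cand = np.flatnonzero(frontier.ravel())
            if cand.size == 0:
                break
            w = flat_field[cand]
            w = w / w.sum()
            take = min(blob_target - size, max(1, cand.size // 2))
            chosen = rng.choice(cand, size=take, replace=False, p=w)
            blob.ravel()[chosen] = True
            size += take
        lesion |= blob
        n_placed = int(lesion.sum())
    return lesion


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Generate a full phantom cohort; deterministic given ``spec.seed``."""
    atlas, brain, ventricle, cerebellum = build_atlas(spec)
    brain_b = brain.data.astype(bool)
    vent_b = ventricle.data.astype(bool)
    cer_b = cerebellum.data.astype(bool)
    eligible = brain_b & ~vent_b & ~cer_b
    fieldv = periventricular_field(spec, vent_b, eligible)
    vox_mm3 = float(np.prod(spec.voxel_size))

    cm = spec.covariate_model
    lm = spec.lesion_model
    age_mid = 0.5 * (cm.age_range[0] + cm.age_range[1])

    region_names = atlas.region_names
    label_of = {v: k for k, v in region_names.items()}
    atlas_lab = atlas.labels.data

    subjects: list[SubjectRecord] = []
    for i in range(spec.n_subjects):
        # independent per-subject substream: the draws that define a subject
        # (age, covariates, target volume) stay aligned across spec variants
        rng = np.random.default_rng([spec.seed, i])
        age = rng.uniform(*cm.age_range)
        sex = float(rng.random() < cm.female_fraction)  # 1 = female
        edu = float(np.clip(rng.normal(cm.education_mean, cm.education_sd),
                            8.0, 20.0))

        log_v = (
            np.log(lm.volume_ml_median)
            + lm.age_log_slope * (age - age_mid)
            + rng.normal(0.0, lm.volume_ml_log_sd)
        )
        vol_ml = float(np.clip(np.exp(log_v), lm.volume_ml_min,
                               lm.volume_ml_max))
        target_voxels = max(1, int(np.round(vol_ml * 1000.0 / vox_mm3)))
        lesion = _sample_lesion_mask(
            rng, target_voxels, fieldv, eligible,
            blob_mean_voxels=lm.blob_mean_voxels,
            blob_log_sd=lm.blob_log_sd,
        )

        channels: dict[str, Volume] = {}
        im = spec.intensity_model
        for ch in ("t1", "flair"):
            data = np.zeros(spec.grid_shape, dtype=np.float32)
            data[brain_b] = im.tissue_mean[ch]
            data[vent_b] = im.csf_mean[ch]
            data[lesion] += im.lesion_contrast[ch]
            noise = rng.normal(0.0, im.noise_sd[ch],
                               size=spec.grid_shape).astype(np.float32)
            data[brain_b] += noise[brain_b]
            channels[ch] = Volume(data, spec.voxel_size, "phantom")
        if spec.include_dti:
            for metric, dm in spec.dti_model.items():
                data = np.zeros(spec.grid_shape, dtype=np.float32)
                data[brain_b] = dm.healthy_mean
                data[lesion] += dm.lesion_delta
                noise = rng.normal(0.0, dm.noise_sd,
                                   size=spec.grid_shape).astype(np.float32)
                data[brain_b] += noise[brain_b]
                channels[metric] = Volume(data, spec.voxel_size, "phantom")

        loads = {
            name: float((lesion & (atlas_lab == lab)).sum()) * vox_mm3
            for name, lab in label_of.items()
        }
        scores: dict[str, float] = {}
        for test, model in spec.score_model.items():
            signal = sum(model.beta.get(r, 0.0) * loads[r] for r in loads)
            noise_s = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 \
                else 0.0
            scores[test] = float(model.intercept + signal + noise_s)

        subjects.append(SubjectRecord(
            subject_id=f"sub-{i:04d}",
            channels=channels,
            scores=scores,
            covariates={"age": age, "sex": sex, "education": edu},
            true_lesion_mask=Volume(
                lesion.astype(np.uint8), spec.voxel_size, "phantom"
            ),
        ))

    return Cohort(
        subjects=subjects,
        atlas=atlas,
        brain_mask=brain,
        ventricle_mask=ventricle,
        exclusion_mask=cerebellum,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Spec serialization (for manifests)
# ---------------------------------------------------------------------------

def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-ready dict of a PhantomSpec (inverse of :func:`spec_from_dict`)."""
    import dataclasses

    d = dataclasses.asdict(spec)
    d["score_model"] = {k: dataclasses.asdict(v)
                        for k, v in spec.score_model.items()}
    d["dti_model"] = {k: dataclasses.asdict(v)
                      for k, v in spec.dti_model.items()}
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    def box(b):
        return RegionBox(
            name=b["name"], lo=tuple(b["lo"]), hi=tuple(b["hi"]),
            hemisphere=b.get("hemisphere", "none"),
            shape=b.get("shape", "box"),
        )

    a = d["atlas_spec"]
    atlas = AtlasSpec(
        regions=tuple(box(r) for r in a["regions"]),
        ventricle=box(a["ventricle"]),
        cerebellum=box(a["cerebellum"]),
        brain_center=tuple(a["brain_center"]),
        brain_semiaxes=tuple(a["brain_semiaxes"]),
    )
    return PhantomSpec(
        grid_shape=tuple(d["grid_shape"]),
        voxel_size=tuple(d["voxel_size"]),
        n_subjects=int(d["n_subjects"]),
        atlas_spec=atlas,
        lesion_model=LesionModel(**d["lesion_model"]),
        intensity_model=IntensityModel(**d["intensity_model"]),
        score_model={k: ScoreTestModel(**v)
                     for k, v in d["score_model"].items()},
        dti_model={k: DTIMetricModel(**v)
                   for k, v in d["dti_model"].items()},
        covariate_model=CovariateModel(
            **{**d["covariate_model"],
               "age_range": tuple(d["covariate_model"]["age_range"])}
        ),
        seed=int(d["seed"]),
        include_dti=bool(d.get("include_dti", True)),
    )


# ---------------------------------------------------------------------------
# Derived tables
# ---------------------------------------------------------------------------

def lesion_volumes_ml(cohort: Cohort) -> pd.Series:
    """Per-subject true lesion volume in ml (voxel count x voxel volume)."""
    vox = cohort.atlas.labels.voxel_volume_mm3
    return pd.Series(
        {
            s.subject_id: float(s.true_lesion_mask.data.sum()) * vox / 1000.0
            for s in cohort.subjects
        },
        name="lesion_volume_ml",
    )


def regional_lesion_loads(cohort: Cohort) -> pd.DataFrame:
    """Subjects x regions matrix of true lesion load in mm^3."""
    atlas_lab = cohort.atlas.labels.data
    vox = cohort.atlas.labels.voxel_volume_mm3
    names = cohort.atlas.region_names
    n_labels = int(atlas_lab.max())
    rows = {}
    for s in cohort.subjects:
        lesion = s.true_lesion_mask.data.astype(bool)
        counts = np.bincount(atlas_lab[lesion], minlength=n_labels + 1)
        rows[s.subject_id] = {
            names[lab]: counts[lab] * vox for lab in names
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Demographics / score summary in the shape of a cohort table.

    One row per variable with mean, SD (NaN for a single subject), min, max;
    score rows additionally carry the partial correlation (controlling for
    sex and education) of the score with age and with lesion volume.
    """
    from .stats import partial_pearson  # local import avoids cycle

    if not cohort.subjects:
        raise ValueError("empty cohort")
    vols = lesion_volumes_ml(cohort)
    cov = pd.DataFrame(
        {s.subject_id: s.covariates for s in cohort.subjects}
    ).T
    scores = pd.DataFrame(
        {s.subject_id: s.scores for s in cohort.subjects}
    ).T

    rows = []

    def basic(name, series):
        x = pd.Series(series, dtype=float)
        return {
            "variable": name,
            "mean": x.mean(),
            "sd": x.std(ddof=1),
            "min": x.min(),
            "max": x.max(),
            "r_age": np.nan,
            "p_age": np.nan,
            "r_wml": np.nan,
            "p_wml": np.nan,
        }

    rows.append(basic("age", cov["age"]))
    rows.append(basic("education", cov["education"]))
    rows.append(basic("sex_female", cov["sex"]))
    rows.append(basic("lesion_volume_ml", vols))

    n = len(cohort.subjects)
    covmat = cov[["sex", "education"]].to_numpy(float)
    for test in scores.columns:
        row = basic(test, scores[test])
        y = scores[test].to_numpy(float)
        if n >= 5 and np.std(y) > 0:
            for tag, x in (("age", cov["age"].to_numpy(float)),
                           ("wml", vols.to_numpy(float))):
                try:
                    res = partial_pearson(x, y, covmat)
                    row[f"r_{tag}"] = res.r
                    row[f"p_{tag}"] = res.p
                except ValueError:
                    pass
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
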