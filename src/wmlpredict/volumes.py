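"""Shared image data model and NIfTI / score-table I/O.

Every pipeline stage exchanges :class:`Volume` objects — plain 3-D scalar
grids with millimetre voxel sizes — that are required to live on one common,
pre-aligned grid.  Registration is deliberately out of scope: world-coordinate
affines read from NIfTI headers are carried through I/O untouched and never
used for resampling.  Voxel indexing is 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "AtlasLabelMap",
    "SubjectRecord",
    "GridMismatchError",
    "check_same_grid",
    "read_volume",
    "write_volume",
    "read_score_table",
    "write_score_table",
]


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


@dataclass
class Volume:
    """A 3-D scalar image on a common grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values: intensities, probabilities, labels, weights or
        diffusion indices — the carrier is the same for all of them.
    voxel_size : tuple of 3 floats
        Edge lengths of a voxel in mm, strictly positive.
    space_tag : str
        Free-text identifier of the common space the grid lives in.
    affine : ndarray (4, 4), optional
        World-coordinate affine carried through I/O; never used to resample.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    space_tag: str = "common"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume data must be 3-D, got {self.data.ndim}-D array"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3:
            raise ValueError("voxel_size must have exactly 3 components")
        if any(not np.isfinite(v) or v <= 0 for v in vs):
            raise ValueError(f"voxel_size components must be > 0, got {vs}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume with the same grid metadata but different values."""
        return Volume(
            data=data,
            voxel_size=self.voxel_size,
            space_tag=self.space_tag,
            affine=self.affine,
        )

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())


def check_same_grid(*volumes: Volume) -> None:
    """Validate that all volumes share shape and voxel size.

    Raises
    ------
    GridMismatchError
        If any pair differs in grid shape or voxel size.
    """
    if len(volumes) < 2:
        return
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_grid(v):
            raise GridMismatchError(
                f"grid mismatch: {ref.shape}@{ref.voxel_size} vs "
                f"{v.shape}@{v.voxel_size}"
            )


@dataclass
class AtlasLabelMap:
    """Integer-labelled parcellation of white matter regions.

    ``labels.data`` holds nonnegative integers; 0 is background.  Every
    nonzero label occurring in the grid must be named in ``region_names``.
    ``region_hemisphere`` maps each label to "L", "R" or "none".
    """

    labels: Volume
    region_names: dict[int, str]
    region_hemisphere: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = self.labels.data
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValueError("atlas labels must be integers")
            self.labels = self.labels.with_data(lab.astype(np.int32))
            lab = self.labels.data
        if lab.min() < 0:
            raise ValueError("atlas labels must be nonnegative")
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"labels without region names: {sorted(missing)}")
        for k in self.region_names:
            self.region_hemisphere.setdefault(k, "none")

    @property
    def region_labels(self) -> list[int]:
        return sorted(self.region_names)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels.data == label


@dataclass
class SubjectRecord:
    """One subject: image channels, scores, covariates, optional ground truth.

    ``channels`` must at least contain "t1" and "flair"; diffusion maps
    ("fa", "md", "ad", "rd") are optional.  ``true_lesion_mask`` is the
    synthetic ground-truth lesion mask (binary) when the subject comes from
    the phantom generator, otherwise None.
    """

    subject_id: str
    channels: dict[str, Volume]
    scores: dict[str, float]
    covariates: dict[str, float]
    true_lesion_mask: Volume | None = None

    def __post_init__(self) -> None:
        vols = list(self.channels.values())
        if self.true_lesion_mask is not None:
            vols.append(self.true_lesion_mask)
        check_same_grid(*vols)

    def score(self, test_name: str) -> float:
        return float(self.scores[test_name])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, space_tag: str = "common") -> Volume:
    """Read a 3-D NIfTI-1 image (optionally gzipped) into a Volume.

    Voxel sizes come from the header zooms; data order follows the header
    orientation with no resampling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got {data.ndim}-D: {path}")
    zooms = img.header.get_zooms()[:3]
    return Volume(
        data=data,
        voxel_size=tuple(float(z) for z in zooms),
        space_tag=space_tag,
        affine=np.asarray(img.affine),
    )


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1; round-trips data and voxel_size."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory missing: {path.parent}")
    affine = v.affine if v.affine is not None else np.diag(
        list(v.voxel_size) + [1.0]
    )
    data = v.data
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.voxel_size)
    nib.save(img, str(path))


_COVARIATE_COLUMNS = ("age", "sex", "education")


def read_score_table(
    path: str | Path,
) -> list[tuple[str, dict[str, float], dict[str, float]]]:
    """Parse a delimited score table into (subject_id, scores, covariates).

    The file must have a header row and a ``subject_id`` column; ``age``,
    ``sex`` and ``education`` columns become covariates and every other
    column a score.  Empty cells become NaN markers, never zeros, and the
    subject is retained.  Duplicate subject ids are a validation error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "subject_id" not in df.columns:
        raise ValueError("score table must have a 'subject_id' column")
    ids = df["subject_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate subject_id values: {dup}")
    cov_cols = [c for c in _COVARIATE_COLUMNS if c in df.columns]
    score_cols = [
        c for c in df.columns if c != "subject_id" and c not in cov_cols
    ]
    records = []
    for _, row in df.iterrows():
        scores = {c: float(row[c]) if pd.notna(row[c]) else float("nan")
                  for c in score_cols}
        covs = {c: float(row[c]) if pd.notna(row[c]) else float("nan")
                for c in cov_cols}
        records.append((str(row["subject_id"]), scores, covs))
    return records


def write_score_table(
    records: Sequence[tuple[str, Mapping[str, float], Mapping[str, float]]],
    path: str | Path,
) -> None:
    """Inverse of :func:`read_score_table` (TSV for .tsv/.txt, else CSV)."""
    path = Path(path)
    rows = []
    for sid, scores, covs in records:
        row: dict[str, object] = {"subject_id": sid}
        row.update(covs)
        row.update(scores)
        rows.append(row)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
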