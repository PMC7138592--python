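"""Supervised KNN voxel classification of white matter lesions.

This follows the BIANCA recipe: per-voxel features are the z-scored image
intensities (T1-like and FLAIR-like channels by default) plus the voxel
coordinates in mm scaled by a spatial-weighting factor; a training set of
2000 lesion / 10000 non-lesion points ("fixed + unbalanced") is pooled from
a handful of manually-labelled subjects; each voxel's lesion probability is
the fraction of lesion-labelled points among its k nearest training points;
the probability map is thresholded at 0.9 (strict inequality) to obtain the
lesion mask and volume.

Conventions the published recipe leaves open, fixed here and documented:
intensities are z-scored within the brain mask per subject with the
population-SD (divide-by-n) convention; spatial features are voxel-centre
coordinates in mm in the common space; distance ties are broken by lower
training-point index so probabilities are fully deterministic; k defaults
to 40.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .config import KNNParams
from .volumes import SubjectRecord, Volume, check_same_grid

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingPointSet",
    "LesionSegmentation",
    "KNNLesionSegmenter",
    "extract_features",
    "build_training_set",
    "knn_probability",
    "segment_subject",
    "dice",
]


@dataclass
class TrainingPointSet:
    """Labelled feature points sampled from manually-masked subjects."""

    features: np.ndarray  # (n_points, n_features)
    labels: np.ndarray    # binary, 1 = lesion
    provenance: list[tuple[str, tuple[int, int, int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (points x feature dim)")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must align with feature rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_points(self) -> int:
        return self.features.shape[0]


@dataclass
class LesionSegmentation:
    """Probability map, thresholded mask and lesion volume for one subject."""

    probability_map: Volume
    binary_mask: Volume
    volume_ml: float
    threshold: float

    def __post_init__(self) -> None:
        p = self.probability_map.data
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probability map values must lie in [0, 1]")
        expected = p > self.threshold
        if not np.array_equal(self.binary_mask.data.astype(bool), expected):
            raise ValueError(
                "binary_mask must equal probability_map > threshold"
            )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _zscore_population(x: np.ndarray) -> np.ndarray:
    """Z-score with population SD (divide by n); all-zero if constant."""
    mu = x.mean()
    sd = x.std()  # ddof=0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - mu) / sd


def extract_features(
    subject: SubjectRecord, cfg: KNNParams, brain_mask: Volume
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel KNN features for all in-mask voxels.

    Returns ``(voxel_indices, features)`` where ``voxel_indices`` is an
    (n, 3) integer array and each feature row is the z-scored channel
    intensities (z within the brain mask, population SD) followed by the
    three voxel-centre coordinates, z-scored within the brain mask the same
    way and multiplied by ``cfg.spatial_weighting``.  Putting coordinates on
    the same (unit-variance) footing as the intensities makes a spatial
    weighting of 1 mean "space counts as much as intensity"; raw millimetre
    coordinates would otherwise dominate every distance.
    """
    if not brain_mask.is_binary():
        raise ValueError("brain_mask must be binary")
    missing = [c for c in cfg.feature_channels if c not in subject.channels]
    if missing:
        raise ValueError(
            f"subject {subject.subject_id} missing channels {missing}"
        )
    vols = [subject.channels[c] for c in cfg.feature_channels]
    check_same_grid(brain_mask, *vols)

    mask = brain_mask.data.astype(bool)
    idx = np.argwhere(mask)
    cols = [
        _zscore_population(v.data[mask].astype(float)) for v in vols
    ]
    coords_mm = idx.astype(float) * np.asarray(brain_mask.voxel_size)
    coords_z = np.column_stack(
        [_zscore_population(coords_mm[:, i]) for i in range(3)]
    )
    cols.append(cfg.spatial_weighting * coords_z)
    features = np.column_stack(cols)
    return idx, features


# ---------------------------------------------------------------------------
# Training set
# ---------------------------------------------------------------------------

def build_training_set(
    labeled_subjects: list[SubjectRecord],
    cfg: KNNParams,
    brain_mask: Volume,
    seed: int = 0,
) -> TrainingPointSet:
    """Sample the fixed + unbalanced training point set.

    Lesion points are drawn uniformly without replacement from manual-mask
    voxels pooled across the labelled subjects; non-lesion points from any
    in-brain non-lesion voxel.  If a class has fewer eligible voxels than
    configured, all are used and a warning is logged.
    """
    if not labeled_subjects:
        raise ValueError("need at least one labelled subject")
    rng = np.random.default_rng(seed)

    feat_rows: list[np.ndarray] = []
    lab_rows: list[np.ndarray] = []
    prov: list[tuple[str, tuple[int, int, int]]] = []
    pooled_feats = []
    pooled_labels = []
    pooled_prov = []
    for s in labeled_subjects:
        if s.true_lesion_mask is None:
            raise ValueError(f"subject {s.subject_id} has no manual mask")
        idx, feats = extract_features(s, cfg, brain_mask)
        lesion = s.true_lesion_mask.data.astype(bool)[
            idx[:, 0], idx[:, 1], idx[:, 2]
        ]
        pooled_feats.append(feats)
        pooled_labels.append(lesion.astype(np.int8))
        pooled_prov.extend(
            (s.subject_id, tuple(v)) for v in idx
        )
    features = np.vstack(pooled_feats)
    labels = np.concatenate(pooled_labels)

    lesion_pool = np.flatnonzero(labels == 1)
    nonlesion_pool = np.flatnonzero(labels == 0)
    if lesion_pool.size == 0:
        raise ValueError("no lesion voxels available for training")

    def sample(pool: np.ndarray, n_wanted: int, what: str) -> np.ndarray:
        if pool.size < n_wanted:
            logger.warning(
                "only %d %s voxels available (wanted %d); using all",
                pool.size, what, n_wanted,
            )
            return pool.copy()
        return rng.choice(pool, size=n_wanted, replace=False)

    sel = np.concatenate([
        sample(lesion_pool, cfg.n_lesion_points, "lesion"),
        sample(nonlesion_pool, cfg.n_nonlesion_points, "non-lesion"),
    ])
    feat_rows = features[sel]
    lab_rows = labels[sel]
    prov = [pooled_prov[i] for i in sel]
    return TrainingPointSet(features=feat_rows, labels=lab_rows,
                            provenance=prov)


# ---------------------------------------------------------------------------
# KNN probability
# ---------------------------------------------------------------------------

class KNNLesionSegmenter(BaseEstimator):
    """K-nearest-neighbour lesion-probability classifier.

    The probability assigned to a query is the fraction of lesion-labelled
    points among its ``k`` nearest training points (Euclidean distance);
    distance ties are broken deterministically by lower training-point
    index.  Probabilities are therefore exact multiples of 1/k.

    Neighbours are found with a k-d tree; rows whose k-th and (k+1)-th
    neighbour distances coincide exactly are re-resolved by exhaustive
    distance computation with the index tie-break, so the result is
    identical to a full sort regardless of tree traversal order.

    Parameters
    ----------
    k : int, default=40
        Neighbour count; must not exceed the training-set size at fit time.
    """

    def __init__(self, k: int = 40):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNLesionSegmenter":
        from scipy.spatial import cKDTree

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y.shape != (X.shape[0],):
            raise ValueError("y must align with X rows")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.k > X.shape[0]:
            raise ValueError(
                f"k={self.k} exceeds training size {X.shape[0]}"
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.X_ = X
        self.y_ = y.astype(np.int8)
        self.tree_ = cKDTree(X)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Lesion probability per query row (vector of multiples of 1/k)."""
        if not hasattr(self, "X_"):
            raise RuntimeError("fit before predict_proba")
        Q = np.asarray(X, dtype=float)
        if Q.ndim != 2 or Q.shape[1] != self.n_features_in_:
            raise ValueError("query feature dimension mismatch")
        k = self.k
        n_train = self.X_.shape[0]
        labels = self.y_.astype(float)
        if k == n_train:
            return np.full(Q.shape[0], labels.mean())
        dist, idx = self.tree_.query(Q, k=k + 1)
        counts = labels[idx[:, :k]].sum(axis=1)
        # exact boundary tie: the k-th and (k+1)-th neighbours are
        # equidistant, so membership depends on the tie-break rule
        tie_rows = np.flatnonzero(dist[:, k - 1] == dist[:, k])
        for r in tie_rows:
            d2 = ((self.X_ - Q[r]) ** 2).sum(axis=1)
            kth = np.partition(d2, k - 1)[k - 1]
            less = d2 < kth
            n_less = int(less.sum())
            eq_idx = np.flatnonzero(d2 == kth)
            take = eq_idx[: k - n_less]  # lowest indices win ties
            counts[r] = labels[less].sum() + labels[take].sum()
        return counts / k


def knn_probability(
    query_features: np.ndarray, train: TrainingPointSet, k: int
) -> np.ndarray:
    """Lesion probability for each query row (see KNNLesionSegmenter)."""
    est = KNNLesionSegmenter(k=k)
    est.fit(train.features, train.labels)
    return est.predict_proba(query_features)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_subject(
    subject: SubjectRecord,
    train: TrainingPointSet,
    cfg: KNNParams,
    brain_mask: Volume,
    threshold: float | None = None,
) -> LesionSegmentation:
    """Segment one subject: probability map, strict-threshold mask, volume.

    The probability map is 0 outside the brain mask; the binary mask keeps
    voxels with probability strictly greater than the threshold (default
    ``cfg.probability_threshold``), so threshold 1.0 always yields an empty
    mask; lesion volume is mask count x voxel volume / 1000 (ml).
    """
    thr = cfg.probability_threshold if threshold is None else float(threshold)
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    idx, feats = extract_features(subject, cfg, brain_mask)
    proba = knn_probability(feats, train, cfg.k)
    pmap = np.zeros(brain_mask.shape, dtype=float)
    pmap[idx[:, 0], idx[:, 1], idx[:, 2]] = proba
    mask = pmap > thr
    vol_ml = float(mask.sum()) * brain_mask.voxel_volume_mm3 / 1000.0
    return LesionSegmentation(
        probability_map=brain_mask.with_data(pmap),
        binary_mask=brain_mask.with_data(mask.astype(np.uint8)),
        volume_ml=vol_ml,
        threshold=thr,
    )


def dice(a: Volume, b: Volume) -> float:
    """Dice overlap 2|a n b| / (|a| + |b|); 1.0 when both masks are empty."""
    check_same_grid(a, b)
    if not (a.is_binary() and b.is_binary()):
        raise ValueError("dice requires binary volumes")
    am = a.data.astype(bool)
    bm = b.data.astype(bool)
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((am & bm).sum()) / float(denom)
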