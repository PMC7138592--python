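"""Cross-validated prediction of cognitive scores with permutation testing.

Each neuropsychological test is analysed separately: the per-subject lesion
probability maps (flattened over the analysis mask, cerebellum excluded)
are the features, the test scores the targets.  Subjects are split into
seven near-equal folds by a seeded shuffle; an RVR model is fitted on each
fold's complement and predicts the held-out subjects, so every subject is
predicted exactly once.  The pooled out-of-fold predictions are scored by

    CORR      Pearson correlation between observed and predicted scores
    MSE       (1/N) sum (y_n - f(x_n))^2
    norm MSE  MSE / (y_max - y_min)

and their significance by a permutation scheme in which the target vector
is shuffled and the *entire* cross-validated pipeline is retrained for each
of (by default) 1000 permutations, with add-one p-values
p = (1 + #extreme) / (1 + n_permutations).  High CORR and low (norm) MSE
count as extreme in their respective one-sided tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .phantom import Cohort
from .rvr import RelevanceVectorRegression, RVRState, _state_from_estimator

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedMetricError",
    "PredictionResult",
    "PermutationResult",
    "compute_corr",
    "compute_mse",
    "compute_norm_mse",
    "lesion_feature_matrix",
    "crossval_predict",
    "permutation_test",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. constant vector)."""


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _paired(y_obs, y_pred):
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors differ in length")
    return y_obs, y_pred


def compute_corr(y_obs, y_pred) -> float:
    """Pearson correlation between observed and predicted scores."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    if y_obs.size < 2:
        raise ValueError("need at least 2 samples")
    dy = y_obs - y_obs.mean()
    df = y_pred - y_pred.mean()
    denom = np.sqrt((dy @ dy) * (df @ df))
    if denom == 0:
        raise UndefinedMetricError("constant vector: correlation undefined")
    return float(dy @ df / denom)


def compute_mse(y_obs, y_pred) -> float:
    """Mean squared error (1/N) sum (y_n - f(x_n))^2."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    return float(np.mean((y_obs - y_pred) ** 2))


def compute_norm_mse(y_obs, y_pred) -> float:
    """Range-normalized MSE: MSE / (y_max - y_min) of the observed scores."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    y_range = y_obs.max() - y_obs.min()
    if y_range == 0:
        raise UndefinedMetricError("y_max equals y_min: norm MSE undefined")
    return compute_mse(y_obs, y_pred) / float(y_range)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def lesion_feature_matrix(
    cohort: Cohort,
    use_true_masks: bool = True,
    probability_maps: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Subjects x voxels matrix of lesion features over the analysis mask.

    By default the phantom ground-truth masks serve as the (thresholded)
    lesion probability maps; alternatively pass per-subject probability maps
    keyed by subject id (e.g. KNN segmentations).  The analysis mask is the
    brain minus the cerebellum exclusion region.
    """
    mask = cohort.analysis_mask
    rows = []
    for s in cohort.subjects:
        if probability_maps is not None:
            vol = probability_maps[s.subject_id]
        elif use_true_masks:
            vol = s.true_lesion_mask.data
        else:
            raise ValueError("no lesion maps supplied")
        rows.append(np.asarray(vol, dtype=float)[mask])
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Pooled out-of-fold predictions and the three evaluation metrics."""

    test_name: str
    y_obs: np.ndarray
    y_pred: np.ndarray
    fold_assignment: np.ndarray
    corr: float
    mse: float
    norm_mse: float
    per_fold_states: list[RVRState] = field(default_factory=list)
    fold_train_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.y_obs.size

    @property
    def mean_obs(self) -> float:
        return float(self.y_obs.mean())

    @property
    def mean_pred(self) -> float:
        return float(self.y_pred.mean())

    @property
    def y_max(self) -> float:
        return float(self.y_obs.max())

    @property
    def y_min(self) -> float:
        return float(self.y_obs.min())


@dataclass
class PermutationResult:
    """Observed metrics, their permutation nulls and add-one p-values."""

    test_name: str
    n_permutations: int
    observed: dict[str, float]
    null_distributions: dict[str, np.ndarray]
    p_values: dict[str, float]


def _make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Per-subject fold ids from a seeded shuffle; sizes differ by <= 1."""
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {n}")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(kf.split(np.zeros((n, 1)))):
        fold[test_idx] = f
    return fold


def crossval_predict(
    features: np.ndarray,
    y: np.ndarray,
    n_folds: int = 7,
    seed: int = 0,
    test_name: str = "",
    rvr_params: dict | None = None,
    keep_states: bool = True,
    _gram: np.ndarray | None = None,
) -> PredictionResult:
    """Out-of-fold RVR predictions of one test score, with pooled metrics.

    The full Gram matrix ``features @ features.T`` is computed once and each
    fold's model is fitted on its sub-block, which is exactly equivalent to
    fitting a linear-kernel RVR on the fold's feature rows.  ``_gram``
    allows reuse across permutations.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("features and y differ in length")
    params = dict(rvr_params or {})
    params.pop("kernel", None)
    fold = _make_folds(n, n_folds, seed)
    G = _gram if _gram is not None else X @ X.T

    y_pred = np.empty(n, dtype=float)
    states: list[RVRState] = []
    train_indices: list[np.ndarray] = []
    for f in range(n_folds):
        test_m = fold == f
        train_idx = np.flatnonzero(~test_m)
        est = RelevanceVectorRegression(kernel="precomputed", **params)
        est.fit(G[np.ix_(train_idx, train_idx)], y[train_idx])
        y_pred[test_m] = est.predict(G[np.ix_(np.flatnonzero(test_m),
                                              train_idx)])
        if keep_states:
            st = _state_from_estimator(est)
            # map relevance indices back to cohort subject indices and
            # attach the relevance vectors' features for back-projection
            st.relevance_indices = train_idx[st.relevance_indices]
            st.training_feature_refs = X[st.relevance_indices]
            st.kernel = "linear"
            states.append(st)
            train_indices.append(train_idx)

    try:
        corr = compute_corr(y, y_pred)
    except UndefinedMetricError:
        # fully-pruned models predict a constant; no linear dependence
        corr = 0.0
    mse = compute_mse(y, y_pred)
    norm_mse = compute_norm_mse(y, y_pred)
    return PredictionResult(
        test_name=test_name,
        y_obs=y,
        y_pred=y_pred,
        fold_assignment=fold,
        corr=corr,
        mse=mse,
        norm_mse=norm_mse,
        per_fold_states=states,
        fold_train_indices=train_indices,
    )


def permutation_test(
    features: np.ndarray,
    y: np.ndarray,
    n_folds: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
    test_name: str = "",
    rvr_params: dict | None = None,
    observed: PredictionResult | None = None,
) -> PermutationResult:
    """Permutation significance of the cross-validated prediction.

    For each permutation the target vector is shuffled and the entire
    cross-validated pipeline (fold models included) is retrained.  P-values
    use the add-one formula, so the smallest attainable p is
    1/(n_permutations + 1); high CORR counts as extreme for CORR, low MSE /
    norm MSE for the error metrics.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    G = X @ X.T
    if observed is None:
        observed = crossval_predict(
            X, y, n_folds=n_folds, seed=seed, test_name=test_name,
            rvr_params=rvr_params, keep_states=False, _gram=G,
        )
    rng = np.random.default_rng(seed)
    nulls = {"corr": np.empty(n_permutations),
             "mse": np.empty(n_permutations),
             "norm_mse": np.empty(n_permutations)}
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        res = crossval_predict(
            X, y_perm, n_folds=n_folds, seed=seed,
            rvr_params=rvr_params, keep_states=False, _gram=G,
        )
        nulls["corr"][b] = res.corr
        nulls["mse"][b] = res.mse
        nulls["norm_mse"][b] = res.norm_mse

    obs = {"corr": observed.corr, "mse": observed.mse,
           "norm_mse": observed.norm_mse}
    p_values = {
        "corr": (1 + int((nulls["corr"] >= obs["corr"]).sum()))
                / (1 + n_permutations),
        "mse": (1 + int((nulls["mse"] <= obs["mse"]).sum()))
               / (1 + n_permutations),
        "norm_mse": (1 + int((nulls["norm_mse"] <= obs["norm_mse"]).sum()))
                    / (1 + n_permutations),
    }
    return PermutationResult(
        test_name=test_name,
        n_permutations=n_permutations,
        observed=obs,
        null_distributions=nulls,
        p_values=p_values,
    )
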