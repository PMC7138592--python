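"""Relevance vector regression: sparse Bayesian linear-kernel regression.

The model places zero-mean Gaussian priors with per-weight precision
hyperparameters ``alpha_i`` on the weights of a kernel expansion
``f(x) = sum_n w_n K(x, x_n) + b`` and estimates the hyperparameters by
type-II maximum likelihood (evidence maximisation) with iterative
re-estimation:

    Sigma = (sigma^-2 Phi^T Phi + A)^-1          posterior covariance
    mu    = sigma^-2 Sigma Phi^T y               posterior mean
    gamma_i = 1 - alpha_i Sigma_ii               well-determinedness
    alpha_i <- gamma_i / mu_i^2
    sigma^2 <- ||y - Phi mu||^2 / (N - sum gamma)

Basis functions whose precision grows beyond ``prune_threshold`` are
removed; the training samples whose kernel columns survive are the
*relevance vectors*.  With a linear kernel the fitted function is itself
linear in the input features, so it back-projects exactly onto a voxel-space
weight map ``w_vox = sum_n mu_n x_n`` with ``f(x) = x . w_vox + b`` — the
property that makes voxel-level weight maps well-defined.

The bias is carried as an extra basis column with a large, fixed prior
variance (tiny fixed ``alpha``), so it is effectively unpenalized and never
pruned.  The fit is fully deterministic: no random initialisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator, RegressorMixin

from .volumes import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "RelevanceVectorRegression",
    "RVRState",
    "VoxelWeightMap",
    "fit_rvr",
    "predict_rvr",
    "backproject_weights",
]


class RelevanceVectorRegression(RegressorMixin, BaseEstimator):
    """Sparse Bayesian regression with a linear (or precomputed) kernel.

    Parameters
    ----------
    kernel : {"linear", "precomputed"}, default="linear"
        "linear": ``K_ij = x_i . x_j`` computed from the input features.
        "precomputed": ``fit`` expects the square training Gram matrix and
        ``predict`` expects Gram rows of new samples against the *original*
        training samples.
    alpha_init : float or None
        Initial weight precision for kernel columns; None means ``1/N^2``.
    sigma2_init : float or None
        Initial noise variance; None means ``0.1 * var(y)``.
    bias_alpha : float, default=1e-6
        Fixed precision of the bias basis (large prior variance); the bias
        is never pruned and its precision never re-estimated.
    prune_threshold : float, default=1e9
        Kernel columns with ``alpha > prune_threshold`` are removed.
    tol : float, default=1e-3
        Convergence on ``max |delta log alpha|`` over surviving columns.
    max_iter : int, default=500
    update_hyperparams : bool, default=True
        False freezes ``alpha`` and ``sigma^2`` at their initial values, in
        which case the posterior mean is exactly the ridge-regression
        closed form ``(Phi^T Phi + alpha sigma^2 I)^-1 Phi^T y``.
    normalize_basis : bool, default=True
        Rescale each basis column to unit Euclidean norm inside the
        hyperparameter loop.  This is a pure reparameterization of the model
        (weights and precisions map back exactly) that makes ``alpha_init``
        and ``prune_threshold`` scale-free: without it, a kernel whose
        entries are large (e.g. dot products of thousands of voxels) leaves
        the prior negligible at any fixed ``alpha_init`` and the noise
        variance collapses onto an interpolating, non-sparse solution.
        Disable to interpret ``alpha_init`` on the raw basis columns (as in
        the frozen-hyperparameter ridge identity).
    jitter : float, default=1e-10
        Relative diagonal jitter added on Cholesky failure (escalated, logged).

    Attributes
    ----------
    relevance_ : int array — indices of training samples kept as relevance
        vectors.
    mu_ : float array — posterior mean weights, bias first then one entry
        per relevance vector.
    alpha_ : float array aligned with ``mu_``.
    sigma2_ : float — estimated noise variance.
    lml_path_ : float array — log marginal likelihood per iteration.
    converged_ : bool;  n_iter_ : int.
    X_rv_ : feature rows of the relevance vectors (linear kernel only).
    """

    def __init__(
        self,
        kernel: str = "linear",
        alpha_init: float | None = None,
        sigma2_init: float | None = None,
        bias_alpha: float = 1e-6,
        prune_threshold: float = 1e9,
        tol: float = 1e-3,
        max_iter: int = 500,
        update_hyperparams: bool = True,
        normalize_basis: bool = True,
        jitter: float = 1e-10,
    ):
        self.kernel = kernel
        self.alpha_init = alpha_init
        self.sigma2_init = sigma2_init
        self.bias_alpha = bias_alpha
        self.prune_threshold = prune_threshold
        self.tol = tol
        self.max_iter = max_iter
        self.update_hyperparams = update_hyperparams
        self.normalize_basis = normalize_basis
        self.jitter = jitter

    # -- internals ---------------------------------------------------------

    def _posterior(self, Phi_a, alpha_a, sigma2, y):
        """Posterior (Sigma, mu) and the Cholesky logdet of Sigma^-1."""
        m = Phi_a.shape[1]
        B = Phi_a.T @ Phi_a / sigma2 + np.diag(alpha_a)
        B = 0.5 * (B + B.T)
        jit = 0.0
        jit_step = self.jitter * max(np.trace(B) / m, 1.0)
        cf = None
        for _ in range(10):
            try:
                cf = cho_factor(B + jit * np.eye(m), lower=True)
                break
            except LinAlgError:
                jit = jit_step if jit == 0.0 else jit * 10.0
                logger.debug("cholesky jitter escalated to %g", jit)
        if cf is None:  # pragma: no cover - pathological
            raise LinAlgError("posterior precision not factorizable")
        Sigma = cho_solve(cf, np.eye(m))
        mu = cho_solve(cf, Phi_a.T @ y) / sigma2
        logdet_B = 2.0 * np.log(np.diag(cf[0])).sum()
        return Sigma, mu, logdet_B

    @staticmethod
    def _lml(y, Phi_a, mu, alpha_a, sigma2, logdet_B):
        """Type-II log marginal likelihood at the current hyperparameters."""
        N = y.shape[0]
        logdet_C = N * np.log(sigma2) - np.log(alpha_a).sum() + logdet_B
        quad = (y @ y - y @ (Phi_a @ mu)) / sigma2
        return -0.5 * (N * np.log(2.0 * np.pi) + logdet_C + quad)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RelevanceVectorRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        N = X.shape[0]
        if y.shape[0] != N:
            raise ValueError("X and y lengths differ")
        if N < 3:
            raise ValueError("need at least 3 training samples")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        y_var = float(np.var(y))
        if y_var == 0.0:
            raise ValueError("y is constant: noise scale undefined")

        if self.kernel == "linear":
            K = X @ X.T
            self._X_train = X
        elif self.kernel == "precomputed":
            if X.shape[1] != N:
                raise ValueError("precomputed kernel must be square")
            K = X
            self._X_train = None
        else:
            raise ValueError(f"unsupported kernel: {self.kernel!r}")

        Phi = np.column_stack([np.ones(N), K])  # column 0 = bias
        if self.normalize_basis:
            col_scale = np.linalg.norm(Phi, axis=0)
            col_scale[col_scale == 0] = 1.0
            Phi = Phi / col_scale
        else:
            col_scale = np.ones(N + 1)
        alpha0 = self.alpha_init if self.alpha_init is not None else 1.0 / N**2
        sigma2 = (self.sigma2_init if self.sigma2_init is not None
                  else 0.1 * y_var)
        sigma2_floor = 1e-12 * max(y_var, 1.0)

        active = np.arange(N + 1)          # indices into Phi columns
        alpha = np.full(N + 1, alpha0, dtype=float)
        alpha[0] = self.bias_alpha

        lml_path: list[float] = []
        converged = False
        n_iter = 0

        def evaluate(act, sig2):
            """Posterior and evidence at (alpha[act], sig2)."""
            Phi_a = Phi[:, act]
            alpha_a = alpha[act]
            Sigma, mu, logdet_B = self._posterior(Phi_a, alpha_a, sig2, y)
            lml = self._lml(y, Phi_a, mu, alpha_a, sig2, logdet_B)
            return Sigma, mu, lml

        Sigma, mu, lml = evaluate(active, sigma2)
        for n_iter in range(1, self.max_iter + 1):
            lml_path.append(lml)
            if not self.update_hyperparams:
                converged = True
                break

            alpha_a = alpha[active]
            diag_S = np.diag(Sigma)
            gamma = np.clip(1.0 - alpha_a * diag_S, 1e-12, None)
            resid = y - Phi[:, active] @ mu
            rss = float(resid @ resid)

            # MacKay re-estimation (fast), with an EM fallback when it would
            # decrease the evidence — the two updates share the same fixed
            # points and the EM step is guaranteed non-decreasing
            with np.errstate(divide="ignore"):
                alpha_mk = np.where(mu**2 > 0, gamma / mu**2, np.inf)
            sigma2_mk = max(rss / max(N - gamma.sum(), 1e-12), sigma2_floor)
            alpha_em = 1.0 / (mu**2 + diag_S)
            sigma2_em = max((rss + sigma2 * gamma.sum()) / N, sigma2_floor)

            accepted = None
            for alpha_try, sigma2_try in ((alpha_mk, sigma2_mk),
                                          (alpha_em, sigma2_em)):
                alpha_try = alpha_try.copy()
                alpha_try[0] = alpha_a[0]  # bias precision fixed
                keep = alpha_try <= self.prune_threshold
                keep[0] = True
                saved = alpha[active].copy()
                alpha[active] = np.where(np.isfinite(alpha_try), alpha_try,
                                         np.inf)
                act_c = active[keep]
                S_c, mu_c, lml_c = evaluate(act_c, sigma2_try)
                if lml_c >= lml - 1e-9:
                    accepted = (act_c, alpha_try, keep, sigma2_try,
                                S_c, mu_c, lml_c)
                    break
                alpha[active] = saved  # roll back, try the EM step
            if accepted is None:
                converged = True  # numerically at a maximum: stop here
                break
            act_c, alpha_new, keep, sigma2, Sigma, mu, lml = accepted
            finite = np.isfinite(alpha_new) & keep
            delta = np.abs(
                np.log(alpha_new[finite][1:]) - np.log(alpha_a[finite][1:])
            ) if finite[1:].any() else np.array([0.0])
            pruned_any = not keep.all()
            active = act_c
            if not pruned_any and (delta.size == 0 or delta.max() < self.tol):
                converged = True
                break

        if self.update_hyperparams and (not lml_path or lml_path[-1] != lml):
            lml_path.append(lml)
        alpha_a = alpha[active]
        scale_a = col_scale[active]

        self.relevance_ = active[1:] - 1  # kernel column -> sample index
        # map posterior back to raw-basis units (w_raw = w_norm / scale)
        self.mu_ = mu / scale_a
        self.alpha_ = alpha_a * scale_a**2
        self.sigma2_ = float(sigma2)
        self.Sigma_ = Sigma / np.outer(scale_a, scale_a)
        self.lml_path_ = np.asarray(lml_path)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        self.n_train_ = N
        if self._X_train is not None:
            self.X_rv_ = self._X_train[self.relevance_]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "mu_"):
            raise RuntimeError("fit before predict")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        mu_bias = self.mu_[0]
        mu_k = self.mu_[1:]
        if self.kernel == "linear":
            if X.shape[1] != self.n_features_in_:
                raise ValueError("feature dimension mismatch")
            if mu_k.size == 0:
                return np.full(X.shape[0], mu_bias)
            return X @ (self.X_rv_.T @ mu_k) + mu_bias
        # precomputed: rows are Gram values against original training samples
        if X.shape[1] != self.n_train_:
            raise ValueError(
                "precomputed prediction needs Gram rows against all "
                f"{self.n_train_} training samples"
            )
        if mu_k.size == 0:
            return np.full(X.shape[0], mu_bias)
        return X[:, self.relevance_] @ mu_k + mu_bias

    def voxel_weights(self) -> np.ndarray:
        """Exact voxel-space weight vector (linear kernel only).

        ``predict(X) == X @ voxel_weights() + mu_[0]`` to machine precision.
        """
        if self.kernel != "linear":
            raise ValueError(
                "voxel weight back-projection requires the linear kernel"
            )
        if not hasattr(self, "mu_"):
            raise RuntimeError("fit before voxel_weights")
        mu_k = self.mu_[1:]
        if mu_k.size == 0:
            return np.zeros(self.n_features_in_)
        return self.X_rv_.T @ mu_k


# ---------------------------------------------------------------------------
# Functional facade + state container
# ---------------------------------------------------------------------------

@dataclass
class RVRState:
    """Serializable snapshot of a fitted relevance vector regression."""

    relevance_indices: np.ndarray
    posterior_mean_weights: np.ndarray  # bias first, then per RV
    alpha: np.ndarray
    sigma2: float
    kernel: str
    training_feature_refs: np.ndarray | None
    converged: bool
    n_iterations: int
    lml_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if np.any(np.asarray(self.alpha) <= 0):
            raise ValueError("alpha entries must be > 0")

    @property
    def n_relevance(self) -> int:
        return int(np.size(self.relevance_indices))

    def to_json(self, path: str | Path) -> None:
        d = {
            "relevance_indices": np.asarray(self.relevance_indices).tolist(),
            "posterior_mean_weights":
                np.asarray(self.posterior_mean_weights).tolist(),
            "alpha": np.asarray(self.alpha).tolist(),
            "sigma2": self.sigma2,
            "kernel": self.kernel,
            "training_feature_refs":
                None if self.training_feature_refs is None
                else np.asarray(self.training_feature_refs).tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "RVRState":
        d = json.loads(Path(path).read_text())
        return cls(
            relevance_indices=np.asarray(d["relevance_indices"], dtype=int),
            posterior_mean_weights=np.asarray(d["posterior_mean_weights"]),
            alpha=np.asarray(d["alpha"]),
            sigma2=float(d["sigma2"]),
            kernel=d["kernel"],
            training_feature_refs=(
                None if d["training_feature_refs"] is None
                else np.asarray(d["training_feature_refs"])
            ),
            converged=bool(d["converged"]),
            n_iterations=int(d["n_iterations"]),
        )


@dataclass
class VoxelWeightMap:
    """Voxel-space weight map of a fitted linear-kernel model."""

    weights: Volume
    test_name: str = ""
    fold_id: int | str = "all"


def _state_from_estimator(est: RelevanceVectorRegression) -> RVRState:
    return RVRState(
        relevance_indices=np.asarray(est.relevance_, dtype=int),
        posterior_mean_weights=np.asarray(est.mu_),
        alpha=np.asarray(est.alpha_),
        sigma2=est.sigma2_,
        kernel=est.kernel,
        training_feature_refs=getattr(est, "X_rv_", None),
        converged=est.converged_,
        n_iterations=est.n_iter_,
        lml_path=est.lml_path_,
    )


def fit_rvr(X: np.ndarray, y: np.ndarray, **params) -> RVRState:
    """Fit an RVR model and return its serializable state."""
    est = RelevanceVectorRegression(**params)
    est.fit(X, y)
    return _state_from_estimator(est)


def predict_rvr(state: RVRState, X_new: np.ndarray) -> np.ndarray:
    """Predict scores from a fitted state: f(x) = sum mu_n (x.x_n) + bias."""
    if state.kernel != "linear":
        raise ValueError("predict_rvr requires a linear-kernel state")
    X_new = np.asarray(X_new, dtype=float)
    mu_bias = state.posterior_mean_weights[0]
    mu_k = state.posterior_mean_weights[1:]
    if mu_k.size == 0:
        return np.full(X_new.shape[0], mu_bias)
    refs = np.asarray(state.training_feature_refs, dtype=float)
    if X_new.shape[1] != refs.shape[1]:
        raise ValueError("feature dimension mismatch")
    return X_new @ (refs.T @ mu_k) + mu_bias


def backproject_weights(
    state: RVRState, analysis_mask: Volume,
    test_name: str = "", fold_id: int | str = "all",
) -> VoxelWeightMap:
    """Embed the exact voxel-space weight vector into the analysis mask.

    ``f(x) = x . w_vox + bias`` holds exactly for the returned weights; the
    map is zero outside the analysis mask (brain minus cerebellum).
    """
    if state.kernel != "linear":
        raise ValueError("back-projection requires the linear kernel")
    mask = analysis_mask.data.astype(bool)
    n_vox = int(mask.sum())
    mu_k = state.posterior_mean_weights[1:]
    if mu_k.size == 0:
        w_vox = np.zeros(n_vox)
    else:
        refs = np.asarray(state.training_feature_refs, dtype=float)
        if refs.shape[1] != n_vox:
            raise ValueError(
                f"mask has {n_vox} voxels but features have {refs.shape[1]}"
            )
        w_vox = refs.T @ mu_k
    out = np.zeros(analysis_mask.shape, dtype=float)
    out[mask] = w_vox
    return VoxelWeightMap(
        weights=analysis_mask.with_data(out),
        test_name=test_name,
        fold_id=fold_id,
    )
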