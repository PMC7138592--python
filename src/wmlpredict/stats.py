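"""Classical association statistics.

Partial Pearson correlations (cognitive score vs. age or lesion volume,
controlling for sex and education) and per-(test, metric) multiple linear
regression of cognitive scores on the mean diffusion metric (FA/MD/AD/RD)
in the top-weighted atlas regions, reported as an overall F test.

"Multivariate linear regression" here is a single-response multiple
regression per (test, metric) pair — one F statistic per pair, the shape
in which such results are tabulated; a multi-response model would not
produce that table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .volumes import AtlasLabelMap, Volume, check_same_grid

__all__ = [
    "PartialCorrResult",
    "MultiRegResult",
    "partial_pearson",
    "extract_region_means",
    "multivariate_regression",
]


@dataclass
class PartialCorrResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    n_covariates: int


@dataclass
class MultiRegResult:
    test_name: str
    metric: str
    F: float
    p: float
    df_model: int
    df_resid: int
    coefficients: np.ndarray
    perfect_fit: bool = False  # SSE ~ 0: F reported as inf


def partial_pearson(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    pair: tuple[str, str] = ("x", "y"),
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualized on ``[1, covariates]`` by least squares;
    r is the plain Pearson correlation of the residuals and the two-sided
    p-value comes from ``t = r sqrt((n - 2 - q) / (1 - r^2))`` with q
    covariates.  With no covariates this reduces exactly to the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y differ in length")
    if covariates is None or np.size(covariates) == 0:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariates misaligned with x/y")
    q = Z.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, q={q})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    # residualize on [1, covariates]
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    # residuals at rounding level mean the variable is fully explained by
    # the covariates; their "correlation" would be numerical noise
    tiny_x = sx <= 1e-10 * max(np.linalg.norm(x - x.mean()), 1e-300)
    tiny_y = sy <= 1e-10 * max(np.linalg.norm(y - y.mean()), 1e-300)
    if sx == 0 or sy == 0 or tiny_x or tiny_y:
        # a variable fully explained by the covariates carries no residual
        # association: report r = 0 rather than failing
        return PartialCorrResult(pair=pair, r=0.0, p=1.0, n=n,
                                 n_covariates=q)
    r = float((rx @ ry) / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - 2 - q
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(pair=pair, r=r, p=max(p, np.finfo(float).tiny),
                             n=n, n_covariates=q)


def extract_region_means(
    metric_volume: Volume,
    atlas: AtlasLabelMap,
    labels: list[int],
) -> np.ndarray:
    """Mean metric value over each of the given atlas regions, in order."""
    check_same_grid(metric_volume, atlas.labels)
    lab = atlas.labels.data
    out = np.empty(len(labels), dtype=float)
    for i, label in enumerate(labels):
        sel = lab == label
        if not sel.any():
            raise ValueError(f"atlas region {label} is empty")
        out[i] = float(metric_volume.data[sel].mean())
    return out


def multivariate_regression(
    scores: np.ndarray,
    profiles: np.ndarray,
    test_name: str = "",
    metric: str = "",
    covariates: np.ndarray | None = None,
) -> MultiRegResult:
    """OLS of score on the k region means; overall F for the region block.

    F = (SSR/k) / (SSE/(n - k - 1)) with p from the F distribution.  An
    exactly linear relation (SSE ~ 0) is reported as ``F = inf`` with the
    ``perfect_fit`` flag set.  Optional covariates enter the design but the
    reported F remains the overall model F from the OLS fit.
    """
    y = np.asarray(scores, dtype=float).ravel()
    X = np.asarray(profiles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.size != n:
        raise ValueError("scores misaligned with profiles")
    if covariates is not None and np.size(covariates):
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        X = np.column_stack([X, Z])
    p_pred = X.shape[1]
    if n <= p_pred + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={p_pred})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    sse = float(fit.ssr)  # statsmodels: ssr = sum of squared residuals
    scale = float(np.sum((y - y.mean()) ** 2))
    if scale > 0 and sse / scale < 1e-12:
        return MultiRegResult(
            test_name=test_name, metric=metric, F=np.inf, p=0.0,
            df_model=p_pred, df_resid=n - p_pred - 1,
            coefficients=np.asarray(fit.params), perfect_fit=True,
        )
    return MultiRegResult(
        test_name=test_name,
        metric=metric,
        F=float(fit.fvalue),
        p=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        coefficients=np.asarray(fit.params),
    )
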