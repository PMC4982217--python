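"""Between-sample normalization methods.

All methods require a fully imputed matrix (no missing cells) and preserve
shape and labels. The vsn method expects raw-scale input because it carries
its own arsinh transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import AssayMatrix, SCALE_NORMALIZED, SCALE_TRANSFORMED

__all__ = [
    "NormResult", "VSNConvergenceError", "normalize", "quantile_normalize",
    "improved_quantile_normalize", "loess_normalize", "global_median_normalize",
    "rsn_normalize", "zscore_normalize", "vsn_normalize",
]

NORMALIZE_METHODS = ("loess", "global", "quantile", "quanimpr", "rsn",
                     "zscore", "vsn")


@dataclass
class NormResult:
    matrix: AssayMatrix
    method: str
    params: dict = field(default_factory=dict)


class VSNConvergenceError(RuntimeError):
    def __init__(self, trace: list[float]):
        self.trace = trace
        super().__init__(
            f"vsn calibration did not converge in {len(trace)} iterations; "
            f"objective trace: {trace}")


def _require_imputed(matrix: AssayMatrix, method: str) -> np.ndarray:
    if matrix.missing_mask.any():
        raise ValueError(f"{method} normalization requires an imputed matrix "
                         "(no missing cells)")
    return matrix.values.copy()


def _quantile_reference(X: np.ndarray) -> np.ndarray:
    """Mean across columns of the per-column order statistics."""
    return np.sort(X, axis=0).mean(axis=1)


def _map_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Assign reference order statistics by rank; tied values receive the mean
    of the reference values their positions span."""
    order = np.argsort(col, kind="mergesort")
    out = np.empty_like(ref)
    out[order] = ref
    s = col[order]
    # group boundaries of equal values in sorted order
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    ends = np.r_[starts[1:], s.size]
    for a, b in zip(starts, ends):
        if b - a > 1:
            out[order[a:b]] = ref[a:b].mean()
    return out


def quantile_normalize(matrix: AssayMatrix) -> NormResult:
    """Classic quantile normalization: every column is mapped onto the mean
    reference distribution of order statistics."""
    X = _require_imputed(matrix, "quantile")
    ref = _quantile_reference(X)
    out = np.column_stack([_map_to_reference(X[:, j], ref)
                           for j in range(X.shape[1])])
    return NormResult(matrix.with_values(out, scale_tag=SCALE_NORMALIZED),
                      "quantile", {"reference": ref})


def _default_dither(col: np.ndarray) -> float:
    u = np.unique(col)
    if u.size < 2:
        return 0.0
    gaps = np.diff(u)
    gaps = gaps[gaps > 0]
    return float(gaps.min()) if gaps.size else 0.0


def improved_quantile_normalize(matrix: AssayMatrix, seed: int,
                                dither_scale: Optional[float] = None,
                                ) -> NormResult:
    """Dithered quantile normalization: uniform noise U(-d/2, d/2) is added
    before quantile normalization to soften the pull of few strong signals.

    ``d`` defaults per column to the smallest nonzero gap between distinct
    values (the 1-LSB dithering analogue). A seed is mandatory.
    """
    if seed is None:
        raise ValueError("improved_quantile_normalize requires a seed")
    X = _require_imputed(matrix, "quanimpr")
    rng = np.random.default_rng(seed)
    ds = []
    noisy = X.copy()
    for j in range(X.shape[1]):
        d = _default_dither(X[:, j]) if dither_scale is None else float(dither_scale)
        ds.append(d)
        if d > 0:
            noisy[:, j] = X[:, j] + rng.uniform(-d / 2.0, d / 2.0, size=X.shape[0])
    res = quantile_normalize(matrix.with_values(noisy))
    res.method = "quanimpr"
    res.params.update({"dither": ds, "seed": seed})
    return res


def loess_normalize(matrix: AssayMatrix, span: float = 0.4) -> NormResult:
    """MA-style loess against the per-analyte mean pseudo-reference: for each
    sample the locally weighted trend of M = x - r over A = (x + r)/2 is
    subtracted."""
    X = _require_imputed(matrix, "loess")
    r = X.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        x = X[:, j]
        M = x - r
        A = (x + r) / 2.0
        if np.ptp(A) == 0:
            out[:, j] = x - M.mean()
            continue
        fit = lowess(M, A, frac=span, return_sorted=True)
        mhat = np.interp(A, fit[:, 0], fit[:, 1])
        out[:, j] = x - mhat
    return NormResult(matrix.with_values(out, scale_tag=SCALE_NORMALIZED),
                      "loess", {"span": span})


def global_median_normalize(matrix: AssayMatrix) -> NormResult:
    """Equalize sample medians additively: subtract each column's median and
    add back the grand median of the pre-normalization column medians."""
    X = _require_imputed(matrix, "global")
    med = np.median(X, axis=0)
    grand = float(np.median(med))
    out = X - med[None, :] + grand
    return NormResult(matrix.with_values(out, scale_tag=SCALE_NORMALIZED),
                      "global", {"sample_medians": med, "grand_median": grand})


def rsn_normalize(matrix: AssayMatrix, n_knots: int = 8,
                  winsor: tuple[float, float] = (0.01, 0.99)) -> NormResult:
    """Robust spline normalization: each sample is mapped onto the
    quantile-normalization reference via a monotone cubic (PCHIP) spline fit
    through evenly spaced quantile anchors, winsorized at the 1st/99th
    percentiles."""
    X = _require_imputed(matrix, "rsn")
    ref_sorted = np.sort(_quantile_reference(X))
    lo, hi = winsor
    qs = np.linspace(lo, hi, n_knots)
    ref_q = np.quantile(ref_sorted, qs)
    out = np.empty_like(X)
    knots = []
    for j in range(X.shape[1]):
        x = X[:, j]
        smp_q = np.quantile(x, qs)
        xs, keep = np.unique(smp_q, return_index=True)
        ys = ref_q[keep]
        if xs.size < 2:
            # (nearly) constant column: plain median shift
            out[:, j] = x - np.median(x) + np.median(ref_sorted)
            knots.append((xs, ys))
            continue
        spline = PchipInterpolator(xs, ys, extrapolate=True)
        out[:, j] = spline(x)
        knots.append((xs, ys))
    return NormResult(matrix.with_values(out, scale_tag=SCALE_NORMALIZED),
                      "rsn", {"n_knots": n_knots, "knots": knots})


def zscore_normalize(matrix: AssayMatrix) -> NormResult:
    """Per-column standardization to mean 0, SD 1 (ddof = 1)."""
    X = _require_imputed(matrix, "zscore")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zscore undefined for constant sample columns: {bad}")
    out = (X - mu[None, :]) / sd[None, :]
    return NormResult(matrix.with_values(out, scale_tag=SCALE_NORMALIZED),
                      "zscore", {"mean": mu, "sd": sd})


def _vsn_value_grad(theta: np.ndarray, X: np.ndarray, K: np.ndarray,
                    ) -> tuple[float, np.ndarray]:
    """Trimmed negative profile log-likelihood of h(x) = asinh(a_s + b_s*x)
    against the per-row means, with analytic gradient in (a_s, log b_s).

    The log-Jacobian term log h'(x) is essential: without it the fit
    collapses to b -> 0 (constant columns). ``K`` flags the untrimmed cells.
    """
    n, S = X.shape
    a = theta[:S]
    beta = theta[S:]
    b = np.exp(beta)
    U = a[None, :] + b[None, :] * X
    W = 1.0 / np.sqrt(1.0 + U ** 2)      # dh/du
    H = np.arcsinh(U)
    mu = H.mean(axis=1)
    R = H - mu[:, None]
    RK = np.where(K, R, 0.0)
    k = int(K.sum())
    rss = float((RK * R).sum())
    log_jac = float((K * (beta[None, :] - 0.5 * np.log1p(U ** 2))).sum())
    f = 0.5 * k * np.log(max(rss / k, 1e-300)) - log_jac

    row_kr = RK.sum(axis=1)
    V = b[None, :] * X * W               # dh/dbeta
    g_rss_a = 2.0 * ((RK * W).sum(axis=0) - (W * row_kr[:, None]).sum(axis=0) / S)
    g_rss_b = 2.0 * ((RK * V).sum(axis=0) - (V * row_kr[:, None]).sum(axis=0) / S)
    UW2 = U * W ** 2                     # d(0.5 log(1+u^2))/du
    g_jac_a = -(K * UW2).sum(axis=0)
    g_jac_b = K.sum(axis=0) - (K * UW2 * b[None, :] * X).sum(axis=0)
    scale = 0.5 * k / max(rss, 1e-300)
    grad = np.concatenate([scale * g_rss_a - g_jac_a,
                           scale * g_rss_b - g_jac_b])
    return f, grad


def vsn_normalize(matrix: AssayMatrix, trim: float = 0.1, tol: float = 1e-6,
                  max_iter: int = 50) -> NormResult:
    """Variance-stabilizing calibration: per-sample arsinh model
    h(x) = asinh(a_s + b_s * x), b_s > 0, fitted by minimizing a trimmed
    (10 % by default) negative profile log-likelihood of deviations from the
    per-analyte row means, alternating parameter fits with re-selection of
    the trimmed cells until the objective is stable.

    Input must be the raw-scale, QC'd and imputed matrix (the method carries
    its own transformation). Raises :class:`VSNConvergenceError` with the
    objective trace when the fit does not converge.
    """
    if matrix.scale_tag == SCALE_TRANSFORMED:
        raise ValueError("vsn carries a built-in transformation and must be "
                         "applied to the raw-scale imputed matrix")
    X = _require_imputed(matrix, "vsn")
    n, S = X.shape
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    b0 = 1.0 / sd
    a0 = -X.mean(axis=0) * b0
    theta = np.concatenate([a0, np.log(b0)])
    n_keep = max(1, int(np.floor((1.0 - trim) * n)))

    trace: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        # re-select per-column trimmed cells at the current parameters
        a, beta = theta[:S], theta[S:]
        H = np.arcsinh(a[None, :] + np.exp(beta)[None, :] * X)
        R2 = (H - H.mean(axis=1)[:, None]) ** 2
        K = np.zeros_like(R2, dtype=bool)
        order = np.argsort(R2, axis=0)
        for j in range(S):
            K[order[:n_keep, j], j] = True
        res = minimize(_vsn_value_grad, theta, args=(X, K), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        theta = res.x
        total = float(res.fun)
        trace.append(total)
        if np.isfinite(prev) and abs(prev - total) <= tol * max(abs(total), 1.0):
            converged = True
            break
        prev = total
    if not converged:
        raise VSNConvergenceError(trace)
    a_fit = theta[:S]
    b_fit = np.exp(theta[S:])
    out = np.arcsinh(a_fit[None, :] + b_fit[None, :] * X)
    return NormResult(matrix.with_values(out, scale_tag=SCALE_NORMALIZED),
                      "vsn", {"a": a_fit, "b": b_fit, "trace": trace})


def normalize(matrix: AssayMatrix, method: str, seed: Optional[int] = None,
              **kwargs) -> NormResult:
    """Dispatch to one of the seven normalization methods."""
    if method not in NORMALIZE_METHODS:
        raise ValueError(f"unknown normalization {method!r}")
    if method == "vsn":
        if matrix.scale_tag == SCALE_TRANSFORMED:
            raise ValueError("vsn must be applied to raw-scale imputed data, "
                             "not to transformed data")
        return vsn_normalize(matrix, **kwargs)
    if method == "quanimpr":
        if seed is None:
            raise ValueError("quanimpr requires a seed")
        return improved_quantile_normalize(matrix, seed=seed, **kwargs)
    dispatch = {
        "loess": loess_normalize,
        "global": global_median_normalize,
        "quantile": quantile_normalize,
        "rsn": rsn_normalize,
        "zscore": zscore_normalize,
    }
    return dispatch[method](matrix, **kwargs)
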