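"""Element-wise transformations: identity, log2, asinh, Box-Cox (plain and
geometric-mean weighted) and a variance-stabilizing transform fitted from
reference-pool replicates.

The Box-Cox exponent is chosen by maximizing the profile log-likelihood
  -(n/2) * log(var(y_t)) + (lambda - 1) * sum(log y)
over a grid, ties broken toward the lambda nearest zero, then the smallest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import AssayMatrix, SCALE_RAW, SCALE_TRANSFORMED

__all__ = [
    "BoxCoxParams", "VSTParams", "transform", "boxcox_transform",
    "boxcox_weighted_transform", "estimate_lambda", "vst_transform",
    "default_lambda_grid",
]

TRANSFORM_METHODS = ("no", "log2", "asinh", "boxcox", "boxcoxweights", "vst")


def default_lambda_grid() -> np.ndarray:
    """Candidate exponents: -2 .. 2 in steps of 0.01."""
    return np.round(np.arange(-200, 201) / 100.0, 2)


@dataclass
class BoxCoxParams:
    lam: float
    geometric_mean: Optional[float] = None  # weighted variant only
    grid: np.ndarray = field(default_factory=default_lambda_grid)
    scope: str = "global"  # or "per_analyte"
    per_analyte_lam: Optional[np.ndarray] = None


@dataclass
class VSTParams:
    c0: float  # additive SD component (intercept of SD ~ mean fit)
    c1: float  # multiplicative SD component (slope)

    @property
    def b(self) -> float:
        return self.c1 / self.c0


def boxcox_transform(y, lam: float):
    """(y**lam - 1)/lam, with the natural-log limit at lam == 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y[~np.isnan(y)] <= 0):
        raise ValueError("boxcox_transform requires strictly positive values")
    # expm1 keeps the map accurate for small lambda; below ~1e-300 the
    # product lam*log(y) underflows, so fall back to the exact lam->0 limit
    if abs(lam) < 1e-300:
        return np.log(y)
    return np.expm1(lam * np.log(y)) / lam


def boxcox_weighted_transform(y, lam: float, gmean: float):
    """Geometric-mean-weighted Box-Cox:
    (y**lam - 1)/(lam * gmean**(lam-1)); at lam == 0, log(y) * gmean."""
    y = np.asarray(y, dtype=float)
    if np.any(y[~np.isnan(y)] <= 0):
        raise ValueError("boxcox_weighted_transform requires positive values")
    if gmean <= 0:
        raise ValueError("geometric mean must be positive")
    if abs(lam) < 1e-300:
        return np.log(y) * gmean
    return np.expm1(lam * np.log(y)) / (lam * np.exp((lam - 1.0) * np.log(gmean)))


def estimate_lambda(values: Sequence[float] | np.ndarray,
                    grid: Optional[np.ndarray] = None) -> float:
    """Grid maximizer of the Box-Cox profile log-likelihood.

    Degenerate (constant) input returns 1.0 with a warning. Ties are broken
    toward the candidate nearest 0, then the smallest.
    """
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 3:
        raise ValueError("need at least 3 positive observed values")
    if (y <= 0).any():
        raise ValueError("lambda estimation requires strictly positive values")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.ptp(y) == 0:
        warnings.warn("constant input; returning lambda = 1", stacklevel=2)
        return 1.0
    n = y.size
    sum_log = float(np.log(y).sum())
    ll = np.empty(grid.size)
    for k, lam in enumerate(grid):
        yt = boxcox_transform(y, float(lam))
        v = float(np.var(yt))  # ML variance (ddof = 0)
        ll[k] = -0.5 * n * np.log(v) + (lam - 1.0) * sum_log if v > 0 else -np.inf
    best = ll.max()
    cands = grid[ll >= best - 1e-10]
    return float(min(cands, key=lambda l: (abs(l), l)))


def _geometric_mean(values: np.ndarray) -> float:
    v = values[np.isfinite(values)]
    if (v <= 0).any():
        raise ValueError("geometric mean needs strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def _fit_vst(matrix: AssayMatrix, reference_samples: Sequence[str]) -> VSTParams:
    idx = matrix.sample_index(list(reference_samples))
    if idx.size < 2:
        qualifying = list(reference_samples)
        raise ValueError(
            "vst needs at least 2 reference-pool replicate columns to estimate "
            f"the mean-variance trend; got {qualifying!r}"
        )
    sub = matrix.values[:, idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(sub, axis=1)
        s = np.nanstd(sub, axis=1, ddof=1)
    ok = np.isfinite(m) & np.isfinite(s)
    m, s = m[ok], s[ok]
    if m.size < 3 or np.ptp(m) == 0:
        return VSTParams(c0=max(float(np.median(s)) if s.size else 1.0, 1e-8), c1=0.0)
    # robust SD ~ c0 + c1 * mean trend across analytes
    slope, intercept, _, _ = stats.theilslopes(s, m)
    c1 = max(float(slope), 0.0)
    c0 = float(intercept)
    if c0 <= 0:
        floor = np.median(s[s > 0]) if (s > 0).any() else 1.0
        c0 = max(1e-3 * float(floor), 1e-8)
    return VSTParams(c0=c0, c1=c1)


def vst_transform(matrix: AssayMatrix, reference_samples: Sequence[str],
                  params: Optional[VSTParams] = None,
                  ) -> tuple[AssayMatrix, VSTParams]:
    """Generalized-log transform h(y) = asinh(1 + (c1/c0) * y) with the SD
    trend SD ~ c0 + c1 * mean fitted robustly from reference replicates."""
    if params is None:
        params = _fit_vst(matrix, reference_samples)
    vals = matrix.values.copy()
    obs = ~matrix.missing_mask
    vals[obs] = np.arcsinh(1.0 + params.b * vals[obs])
    return matrix.with_values(vals, scale_tag=SCALE_TRANSFORMED), params


def transform(matrix: AssayMatrix, method: str,
              params: Optional[object] = None,
              reference_samples: Optional[Sequence[str]] = None,
              lambda_grid: Optional[np.ndarray] = None,
              lambda_scope: str = "global",
              ) -> tuple[AssayMatrix, Optional[object]]:
    """Apply one of the six transformations to the observed cells.

    Missing cells stay missing; the returned matrix is tagged
    ``transformed``. Fitted parameters (Box-Cox lambda / geometric mean, VST
    coefficients) are returned for reuse on new data.
    """
    if method not in TRANSFORM_METHODS:
        raise ValueError(f"unknown transformation {method!r}")
    if matrix.scale_tag != SCALE_RAW:
        raise ValueError("transform expects a raw-scale (QC'd) matrix")

    obs = ~matrix.missing_mask
    vals = matrix.values.copy()

    if method == "no":
        return matrix.with_values(vals, scale_tag=SCALE_TRANSFORMED), None

    if method == "asinh":
        vals[obs] = np.arcsinh(vals[obs])
        return matrix.with_values(vals, scale_tag=SCALE_TRANSFORMED), None

    if method == "vst":
        if params is not None:
            return vst_transform(matrix, reference_samples or [], params)
        if reference_samples is None:
            raise ValueError("vst requires reference_samples")
        return vst_transform(matrix, reference_samples)

    # log/power maps require positives; QC should have masked <= 0
    if (vals[obs] <= 0).any():
        raise ValueError(
            "non-positive value reached a log/power transform; run QC first")

    if method == "log2":
        vals[obs] = np.log2(vals[obs])
        return matrix.with_values(vals, scale_tag=SCALE_TRANSFORMED), None

    # Box-Cox variants
    weighted = method == "boxcoxweights"
    if params is None:
        grid = default_lambda_grid() if lambda_grid is None else lambda_grid
        if lambda_scope == "per_analyte":
            lams = np.empty(matrix.n_analytes)
            for i in range(matrix.n_analytes):
                row = vals[i][obs[i]]
                lams[i] = estimate_lambda(row, grid) if row.size >= 3 else 1.0
            params = BoxCoxParams(lam=float(np.median(lams)), grid=grid,
                                  scope="per_analyte", per_analyte_lam=lams)
        else:
            lam = estimate_lambda(vals[obs], grid)
            params = BoxCoxParams(lam=lam, grid=grid, scope="global")
        if weighted:
            params.geometric_mean = _geometric_mean(vals[obs])
    assert isinstance(params, BoxCoxParams)

    def _apply(block: np.ndarray, lam: float) -> np.ndarray:
        if weighted:
            return boxcox_weighted_transform(block, lam, params.geometric_mean)
        return boxcox_transform(block, lam)

    if params.scope == "per_analyte" and params.per_analyte_lam is not None:
        for i in range(matrix.n_analytes):
            row_obs = obs[i]
            vals[i, row_obs] = _apply(vals[i, row_obs],
                                      float(params.per_analyte_lam[i]))
    else:
        vals[obs] = _apply(vals[obs], params.lam)
    return matrix.with_values(vals, scale_tag=SCALE_TRANSFORMED), params
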