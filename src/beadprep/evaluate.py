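"""Evaluation criteria and scoring.

Six criteria grade each pre-processed dataset 0 (poor), 1 (fair) or 2 (good):
three plot-based criteria (mean-SD, Bland-Altman, nonparametric volcano)
normally graded by a panel of 15 readers (an automated surrogate is provided),
quantile-based skewness (log S) and tail length (T) with fixed threshold
bands, and a rank-sum repeatability criterion built on per-analyte
coefficients of variation across the reference-pool replicates. Totals range
0-12.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .core import AssayMatrix, ComboSpec, CriterionScores

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionStats", "CVSummary", "VolcanoStats", "MeanSDStats",
    "BlandAltmanStats", "quantile_est", "skewness_logS", "tail_length_T",
    "score_skewness", "score_tail", "score_cv_percent", "cv_rank_score",
    "mean_sd_stats", "bland_altman_pairs", "volcano_stats", "qq_mannwhitney",
    "aggregate_reader_scores", "intra_rater_reliability", "auto_rate_plot",
    "total_score",
]

_QS = (0.025, 0.125, 0.5, 0.875, 0.975)


# ---------------------------------------------------------------------------
# distribution shape: quantile skewness and tail length
# ---------------------------------------------------------------------------

@dataclass
class DistributionStats:
    quantiles: dict[float, float]
    log_S: float
    T: float


def quantile_est(values, q) -> float | np.ndarray:
    """Linear-interpolation order-statistic quantile (numpy default, R type 7)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values for a quantile estimate")
    return np.quantile(v, q, method="linear")


def skewness_logS(values) -> float:
    """log of (x~0.975 - x~0.5)/(x~0.5 - x~0.025); 0 for symmetric data,
    positive when right-skewed."""
    q025, q5, q975 = quantile_est(values, [0.025, 0.5, 0.975])
    denom = q5 - q025
    num = q975 - q5
    if denom <= 0 or num <= 0:
        raise ValueError(
            f"log S undefined: quantile spread non-positive (num={num}, denom={denom})")
    return float(np.log(num / denom))


def tail_length_T(values) -> float:
    """(x~0.975 - x~0.025)/(x~0.875 - x~0.125); 1 at minimum, larger for
    longer-tailed distributions (1.704 for the normal)."""
    q025, q125, q875, q975 = quantile_est(values, [0.025, 0.125, 0.875, 0.975])
    denom = q875 - q125
    if denom <= 0:
        raise ValueError("tail length undefined: interquantile range is zero")
    return float((q975 - q025) / denom)


def distribution_stats(values) -> DistributionStats:
    qs = quantile_est(values, list(_QS))
    return DistributionStats(quantiles=dict(zip(_QS, map(float, qs))),
                             log_S=skewness_logS(values),
                             T=tail_length_T(values))


def score_skewness(log_S: float) -> int:
    """2 if -0.5 < log S < 0.5; 0 if |log S| > 0.75; else 1."""
    a = abs(log_S)
    if a < 0.5:
        return 2
    if a > 0.75:
        return 0
    return 1


def score_tail(T: float) -> int:
    """2 if 1.625 < T < 2; 0 if T <= 1.525 or T >= 2.1; else 1."""
    if 1.625 < T < 2.0:
        return 2
    if T <= 1.525 or T >= 2.1:
        return 0
    return 1


# ---------------------------------------------------------------------------
# repeatability: CV rank sums across combos
# ---------------------------------------------------------------------------

@dataclass
class CVSummary:
    combo: str
    cv_rank_sum: float
    cv_percent: float
    score: int
    per_analyte_cv: Optional[np.ndarray] = None


def score_cv_percent(cv_percent: float) -> int:
    """2 if CV_s,p <= 50 %, 1 if <= 80 %, else 0."""
    if cv_percent <= 50.0:
        return 2
    if cv_percent <= 80.0:
        return 1
    return 0


def cv_rank_score(matrices: dict[str, AssayMatrix],
                  reference_samples: Sequence[str],
                  eps: float = 1e-12) -> list[CVSummary]:
    """Rank per-analyte CVs (SD/|mean| over the reference replicates) across
    combos, sum ranks per combo (CV_s) and convert to the percentage
    CV_s,p = 100 * CV_s / (A * M) for scoring.

    Analytes whose mean is ~0 in any combo are dropped from the ranking for
    all combos symmetrically.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    names = list(matrices)
    M = len(names)
    analyte_sets = {tuple(m.analyte_ids) for m in matrices.values()}
    if len(analyte_sets) != 1:
        raise ValueError("all combos must share the same analyte set")
    cvs = []
    for name in names:
        m = matrices[name]
        idx = m.sample_index(list(reference_samples))
        if idx.size < 2:
            raise ValueError(
                f"combo {name}: need >= 2 reference replicates for CVs")
        sub = m.values[:, idx]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(np.abs(mean) < eps, np.nan, sd / np.abs(mean))
        cvs.append(cv)
    C = np.column_stack(cvs)  # analytes x combos
    usable = ~np.isnan(C).any(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("cv_rank_score: dropped %d near-zero-mean analytes", n_dropped)
    A = int(usable.sum())
    if A == 0:
        raise ValueError("no analytes with well-defined CVs in every combo")
    ranks = np.apply_along_axis(stats.rankdata, 1, C[usable])  # ties -> average
    sums = ranks.sum(axis=0)
    out = []
    for k, name in enumerate(names):
        pct = 100.0 * sums[k] / (A * M)
        out.append(CVSummary(combo=name, cv_rank_sum=float(sums[k]),
                             cv_percent=float(pct), score=score_cv_percent(pct),
                             per_analyte_cv=C[usable, k]))
    return out


# ---------------------------------------------------------------------------
# plot statistics: mean-SD, Bland-Altman, volcano, QQ
# ---------------------------------------------------------------------------

@dataclass
class MeanSDStats:
    mean: np.ndarray
    sd: np.ndarray
    rank_of_mean: np.ndarray
    trend: np.ndarray  # lowess-fitted SD at each rank, ordered by rank
    spearman: float


def mean_sd_stats(matrix: AssayMatrix, reference_samples: Sequence[str],
                  span: float = 0.4) -> MeanSDStats:
    """Per-analyte mean and SD over the reference replicates with the
    ranked-mean ordering and a lowess trend of SD on rank(mean)."""
    idx = matrix.sample_index(list(reference_samples))
    if idx.size < 2:
        raise ValueError("mean-SD needs >= 2 reference replicates")
    sub = matrix.values[:, idx]
    if np.isnan(sub).any():
        raise ValueError("mean-SD expects imputed (complete) data")
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    rank = stats.rankdata(mean)
    if np.ptp(sd) == 0 or np.ptp(rank) == 0:
        rho = 0.0
        trend = np.full(mean.size, sd.mean())
    else:
        rho = float(stats.spearmanr(rank, sd).statistic)
        fit = _lowess(sd, rank, frac=span, return_sorted=True)
        trend = np.interp(np.sort(rank), fit[:, 0], fit[:, 1])
    return MeanSDStats(mean=mean, sd=sd, rank_of_mean=rank, trend=trend,
                       spearman=rho)


@dataclass
class BlandAltmanStats:
    pair_mean: np.ndarray      # (analytes * pairs,)
    pair_diff: np.ndarray
    mean_diff: float
    loa_low: float
    loa_high: float
    trend_spearman: float      # diff vs mean
    funnel_spearman: float     # |diff| vs mean


def bland_altman_pairs(matrix: AssayMatrix,
                       reference_samples: Sequence[str]) -> BlandAltmanStats:
    """All replicate pairs (earlier minus later) pooled over analytes:
    66 pairs per analyte for 12 replicates; limits = mean +/- 1.96 SD."""
    idx = matrix.sample_index(list(reference_samples))
    n = idx.size
    if n < 2:
        raise ValueError("Bland-Altman needs >= 2 reference replicates")
    sub = matrix.values[:, idx]
    if np.isnan(sub).any():
        raise ValueError("Bland-Altman expects imputed (complete) data")
    pairs = list(itertools.combinations(range(n), 2))
    means, diffs = [], []
    for i, j in pairs:
        means.append((sub[:, i] + sub[:, j]) / 2.0)
        diffs.append(sub[:, i] - sub[:, j])
    pair_mean = np.concatenate(means)
    pair_diff = np.concatenate(diffs)
    md = float(pair_diff.mean())
    sd = float(pair_diff.std(ddof=1)) if pair_diff.size > 1 else 0.0
    if np.ptp(pair_diff) == 0 or np.ptp(pair_mean) == 0:
        trend = funnel = 0.0
    else:
        trend = float(stats.spearmanr(pair_mean, pair_diff).statistic)
        ad = np.abs(pair_diff)
        funnel = (0.0 if np.ptp(ad) == 0
                  else float(stats.spearmanr(pair_mean, ad).statistic))
    return BlandAltmanStats(pair_mean=pair_mean, pair_diff=pair_diff,
                            mean_diff=md, loa_low=md - 1.96 * sd,
                            loa_high=md + 1.96 * sd, trend_spearman=trend,
                            funnel_spearman=funnel)


@dataclass
class VolcanoStats:
    analyte_id: str
    relative_effect: float
    p_value: float

    @property
    def minus_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


def _relative_effects(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rank-based relative effect of B over A per row:
    p-hat = (mean combined rank of B - (n_b + 1)/2) / n_a, midranks for ties.
    Equals P(a < b) + 0.5 P(a = b)."""
    n_a, n_b = A.shape[1], B.shape[1]
    comb = np.concatenate([A, B], axis=1)
    R = np.apply_along_axis(stats.rankdata, 1, comb)
    rb = R[:, n_a:].mean(axis=1)
    return (rb - (n_b + 1) / 2.0) / n_a


def volcano_stats(matrix: AssayMatrix, group_a_samples: Sequence[str],
                  group_b_samples: Sequence[str]) -> list[VolcanoStats]:
    """Two-sided Wilcoxon rank-sum p-value and rank-based relative effect per
    analyte for group B (cases) versus group A (controls).

    p-values come from ``scipy.stats.mannwhitneyu(method="auto")``: exact for
    small tie-free samples, tie- and continuity-corrected normal
    approximation otherwise.
    """
    ia = matrix.sample_index(list(group_a_samples))
    ib = matrix.sample_index(list(group_b_samples))
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need >= 2 samples")
    A = matrix.values[:, ia]
    B = matrix.values[:, ib]
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("volcano expects imputed (complete) data")
    res = stats.mannwhitneyu(B, A, axis=1, alternative="two-sided",
                             method="auto")
    pvals = np.clip(np.atleast_1d(res.pvalue), 1e-300, 1.0)
    rel = _relative_effects(A, B)
    return [VolcanoStats(aid, float(rel[i]), float(pvals[i]))
            for i, aid in enumerate(matrix.analyte_ids)]


def qq_mannwhitney(matrix: AssayMatrix, case_group_samples: Sequence[str],
                   n_reps: int = 25, seed: Optional[int] = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Null diagnostic: split one case group into random equal halves
    ``n_reps`` times, compute per-analyte Mann-Whitney U, standardize with the
    tie-corrected null moments, pool all z over analytes x replications, and
    pair the sorted z with standard-normal quantiles."""
    if seed is None:
        raise ValueError("qq_mannwhitney requires a seed")
    ids = list(case_group_samples)
    if len(ids) % 2 == 1:
        ids = ids[:-1]  # trim to an even split
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 case samples to split")
    idx = matrix.sample_index(ids)
    X = matrix.values[:, idx]
    if np.isnan(X).any():
        raise ValueError("QQ diagnostic expects imputed (complete) data")
    rng = np.random.default_rng(seed)
    half = n // 2
    zs = []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        g1, g2 = perm[:half], perm[half:]
        comb = np.concatenate([X[:, g1], X[:, g2]], axis=1)
        R = np.apply_along_axis(stats.rankdata, 1, comb)
        u1 = R[:, :half].sum(axis=1) - half * (half + 1) / 2.0
        mean_u = half * half / 2.0
        nn = 2 * half
        tie_term = np.zeros(X.shape[0])
        for i in range(X.shape[0]):
            _, counts = np.unique(comb[i], return_counts=True)
            tie_term[i] = float((counts ** 3 - counts).sum())
        var_u = (half * half / 12.0) * ((nn + 1)
                                        - tie_term / (nn * (nn - 1.0)))
        sd_u = np.sqrt(np.maximum(var_u, 1e-300))
        zs.append((u1 - mean_u) / sd_u)
    z = np.sort(np.concatenate(zs))
    probs = (np.arange(1, z.size + 1) - 0.5) / z.size
    theo = stats.norm.ppf(probs)
    return z, theo


# ---------------------------------------------------------------------------
# reader ratings and the automated surrogate
# ---------------------------------------------------------------------------

def aggregate_reader_scores(ratings: Sequence[int]) -> tuple[int, int]:
    """Sum 15 readers' 0/1/2 ratings (range 0-30) and classify:
    good (2) for 21-30, fair (1) for 11-20, poor (0) otherwise."""
    ratings = list(ratings)
    if len(ratings) != 15:
        raise ValueError(f"expected exactly 15 ratings, got {len(ratings)}")
    if any(r not in (0, 1, 2) for r in ratings):
        raise ValueError("ratings must be in {0, 1, 2}")
    s = int(sum(ratings))
    if 21 <= s <= 30:
        return s, 2
    if 11 <= s <= 20:
        return s, 1
    return s, 0


def intra_rater_reliability(round1_totals: Sequence[float],
                            round2_totals: Sequence[float]) -> float:
    """Pearson correlation of per-combo totals between the two rating rounds."""
    a = np.asarray(round1_totals, dtype=float)
    b = np.asarray(round2_totals, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equally sized total vectors (n >= 2)")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class AutoRateThresholds:
    mean_sd_good: float = 0.1
    mean_sd_fair: float = 0.3
    ba_bias_frac: float = 0.05
    ba_trend_good: float = 0.1
    ba_funnel_poor: float = 0.3
    volcano_good: float = 0.5
    volcano_fair: float = 0.2


def auto_rate_plot(criterion: str, statistics,
                   thresholds: Optional[AutoRateThresholds] = None) -> int:
    """Automated, non-canonical surrogate for the human reader panel.

    mean_sd: graded on |Spearman(rank(mean), SD)|. bland_altman: graded on
    relative bias, trend and funnel correlations. volcano: graded on the
    length ratio of the two funnel sides (max -log10 p on either side of
    relative effect 0.5).
    """
    t = thresholds or AutoRateThresholds()
    if criterion == "mean_sd":
        rho = abs(statistics.spearman)
        if rho < t.mean_sd_good:
            return 2
        if rho < t.mean_sd_fair:
            return 1
        return 0
    if criterion == "bland_altman":
        width = statistics.loa_high - statistics.loa_low
        bias = abs(statistics.mean_diff) / width if width > 0 else 0.0
        trend = abs(statistics.trend_spearman)
        funnel = abs(statistics.funnel_spearman)
        if funnel >= t.ba_funnel_poor or trend >= t.ba_funnel_poor:
            return 0
        if bias < t.ba_bias_frac and trend < t.ba_trend_good:
            return 2
        return 1
    if criterion == "volcano":
        left = [v.minus_log10_p for v in statistics if v.relative_effect < 0.5]
        right = [v.minus_log10_p for v in statistics if v.relative_effect > 0.5]
        if not left or not right:
            return 0
        lo, hi = sorted([max(left), max(right)])
        ratio = lo / hi if hi > 0 else 0.0
        if ratio >= t.volcano_good:
            return 2
        if ratio >= t.volcano_fair:
            return 1
        return 0
    raise ValueError(f"unknown plot criterion {criterion!r}")


def total_score(scores: CriterionScores) -> int:
    """Sum of the six 0/1/2 criterion scores (0-12)."""
    return scores.total
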