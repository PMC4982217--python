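"""Quality control: bead-count masking, null-fraction exclusion rules and
median imputation.

Order matters and mirrors the processing contract: values <= 0 are masked
first, analytes whose null fraction exceeds the analyte threshold are dropped,
then samples are screened using null fractions computed on the surviving
analytes (a ``sample_frac_mode="pre"`` switch is exposed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AssayMatrix, SCALE_RAW

logger = logging.getLogger(__name__)

__all__ = ["QCReport", "filter_bead_counts", "qc_filter", "impute_median"]


@dataclass
class QCReport:
    """Bookkeeping of what QC removed, masked and imputed."""

    excluded_analytes: list[tuple[str, float]] = field(default_factory=list)
    excluded_samples: list[tuple[str, float]] = field(default_factory=list)
    n_cells_masked_nonpositive: int = 0
    n_cells_masked_beadcount: int = 0
    n_cells_imputed: int = 0

    def null_percent(self, n_null: int, n_total: int) -> float:
        """Null percentage as reported in QC logs, rounded to two decimals."""
        return round(100.0 * n_null / n_total, 2)

    def log_lines(self) -> list[str]:
        lines = [
            f"masked {self.n_cells_masked_nonpositive} non-positive cells",
            f"masked {self.n_cells_masked_beadcount} low-bead-count cells",
        ]
        lines += [f"excluded analyte {a} (null fraction {100 * f:.2f} %)"
                  for a, f in self.excluded_analytes]
        lines += [f"excluded sample {s} (null fraction {100 * f:.2f} %)"
                  for s, f in self.excluded_samples]
        if self.n_cells_imputed:
            lines.append(f"imputed {self.n_cells_imputed} cells")
        return lines


def filter_bead_counts(matrix: AssayMatrix, min_beads: int = 35) -> AssayMatrix:
    """Mask cells whose bead count is not strictly greater than ``min_beads``.

    A cell with exactly ``min_beads`` beads is masked ("> 35 beads" is a
    strict criterion). A matrix without bead counts is returned unchanged
    with a warning.
    """
    if matrix.bead_counts is None:
        warnings.warn("no bead counts present; bead-count filter is a no-op",
                      stacklevel=2)
        return matrix.copy()
    if (matrix.bead_counts < 0).any():
        raise ValueError("negative bead counts encountered")
    out = matrix.copy()
    low = out.bead_counts <= min_beads
    out.missing_mask = out.missing_mask | low
    out.values = np.where(out.missing_mask, np.nan, out.values)
    return out


def qc_filter(matrix: AssayMatrix, analyte_null_max: float = 0.19,
              sample_null_max: float = 0.20, sample_frac_mode: str = "post",
              ) -> tuple[AssayMatrix, QCReport]:
    """Mask non-positive intensities, then drop analytes and samples whose
    null fraction exceeds (strictly) the respective threshold.

    "Null" means missing-or-nonpositive; after the masking step the two
    notions coincide. Sample fractions are computed after analyte exclusion
    by default (``sample_frac_mode="post"``).
    """
    if matrix.scale_tag != SCALE_RAW:
        raise ValueError("qc_filter expects a raw-scale matrix")
    if sample_frac_mode not in ("post", "pre"):
        raise ValueError("sample_frac_mode must be 'post' or 'pre'")
    report = QCReport()
    work = matrix.copy()
    with np.errstate(invalid="ignore"):
        nonpos = ~work.missing_mask & (work.values <= 0)
    report.n_cells_masked_nonpositive = int(nonpos.sum())
    work.missing_mask = work.missing_mask | nonpos
    work.values = np.where(work.missing_mask, np.nan, work.values)

    # Excluding samples can push surviving analytes back over the threshold,
    # so the two rules are applied (analytes first, then samples) until a
    # fixed point: qc_filter(qc_filter(m)) == qc_filter(m).
    while work.n_analytes and work.n_samples:
        null = work.missing_mask
        analyte_frac = null.mean(axis=1)
        keep_analytes = analyte_frac <= analyte_null_max
        report.excluded_analytes += [
            (work.analyte_ids[i], float(analyte_frac[i]))
            for i in np.flatnonzero(~keep_analytes)
        ]
        if not keep_analytes.any():
            raise ValueError("all analytes excluded by QC")

        if sample_frac_mode == "post":
            sample_frac = null[keep_analytes].mean(axis=0)
        else:
            sample_frac = null.mean(axis=0)
        keep_samples = sample_frac <= sample_null_max
        report.excluded_samples += [
            (work.sample_ids[j], float(sample_frac[j]))
            for j in np.flatnonzero(~keep_samples)
        ]
        changed = (~keep_analytes).any() or (~keep_samples).any()
        work = work.subset(np.flatnonzero(keep_analytes),
                           np.flatnonzero(keep_samples))
        if not changed:
            break

    for line in report.log_lines():
        logger.info("qc: %s", line)
    return work, report


def impute_median(matrix: AssayMatrix, report: QCReport | None = None) -> AssayMatrix:
    """Replace each missing cell by the median of its analyte's observed
    values. Intended to run on transformed data (transform -> impute ->
    normalize); observed values are never changed."""
    out = matrix.copy()
    if not out.missing_mask.any():
        return out
    n_obs = (~out.missing_mask).sum(axis=1)
    if (n_obs == 0).any():
        bad = [out.analyte_ids[i] for i in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"analytes with no observed values (QC should have "
                         f"removed them): {bad}")
    med = np.nanmedian(out.values, axis=1)
    n_imputed = int(out.missing_mask.sum())
    out.values = np.where(out.missing_mask, med[:, None], out.values)
    out.missing_mask = np.zeros_like(out.missing_mask)
    if report is not None:
        report.n_cells_imputed += n_imputed
    return out
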