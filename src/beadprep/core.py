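"""Core data containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

SCALE_RAW = "raw"
SCALE_TRANSFORMED = "transformed"
SCALE_NORMALIZED = "normalized"
_SCALES = (SCALE_RAW, SCALE_TRANSFORMED, SCALE_NORMALIZED)


class Group(str, Enum):
    """Sample group labels."""

    reference_pool = "reference_pool"
    control = "control"
    case_MS = "case_MS"
    case_NMO = "case_NMO"


@dataclass
class SampleMeta:
    """Annotation record for one sample column."""

    sample_id: str
    group: Group
    plate: str
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)


@dataclass
class AssayMatrix:
    """Analytes x samples matrix of MFI-scale values with a missing mask.

    ``values`` holds NaN wherever ``missing_mask`` is True; the mask is the
    source of truth for missingness. ``bead_counts``, when present, is an
    integer matrix aligned cell-for-cell with ``values``.
    """

    analyte_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    bead_counts: Optional[np.ndarray] = None
    scale_tag: str = SCALE_RAW

    def __post_init__(self) -> None:
        self.analyte_ids = [str(a) for a in self.analyte_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.analyte_ids)) != len(self.analyte_ids):
            raise ValueError("duplicate analyte IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.analyte_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.analyte_ids)} analytes x {len(self.sample_ids)} samples"
            )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        # NaN <=> masked
        self.values = np.where(self.missing_mask, np.nan, self.values)
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValueError("NaN value at an unmasked cell")
        if self.bead_counts is not None:
            self.bead_counts = np.asarray(self.bead_counts)
            if self.bead_counts.shape != self.values.shape:
                raise ValueError("bead_counts shape mismatch")
        if self.scale_tag not in _SCALES:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")

    # -- shape helpers -------------------------------------------------
    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def copy(self) -> "AssayMatrix":
        return AssayMatrix(
            analyte_ids=list(self.analyte_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            bead_counts=None if self.bead_counts is None else self.bead_counts.copy(),
            scale_tag=self.scale_tag,
        )

    def with_values(self, values: np.ndarray, scale_tag: Optional[str] = None,
                    missing_mask: Optional[np.ndarray] = None) -> "AssayMatrix":
        """New matrix with the same labels but different values."""
        return AssayMatrix(
            analyte_ids=list(self.analyte_ids),
            sample_ids=list(self.sample_ids),
            values=np.asarray(values, dtype=float),
            missing_mask=self.missing_mask.copy() if missing_mask is None else missing_mask,
            bead_counts=None if self.bead_counts is None else self.bead_counts.copy(),
            scale_tag=self.scale_tag if scale_tag is None else scale_tag,
        )

    def subset(self, analyte_idx: Optional[np.ndarray] = None,
               sample_idx: Optional[np.ndarray] = None) -> "AssayMatrix":
        ai = np.arange(self.n_analytes) if analyte_idx is None else np.asarray(analyte_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return AssayMatrix(
            analyte_ids=[self.analyte_ids[i] for i in ai],
            sample_ids=[self.sample_ids[j] for j in si],
            values=self.values[np.ix_(ai, si)],
            missing_mask=self.missing_mask[np.ix_(ai, si)],
            bead_counts=None if self.bead_counts is None else self.bead_counts[np.ix_(ai, si)],
            scale_tag=self.scale_tag,
        )


TRANSFORMATIONS = ("no", "log2", "asinh", "boxcox", "boxcoxweights", "vst")
NORMALIZATIONS = ("loess", "global", "quantile", "quanimpr", "rsn", "zscore", "vsn")
CRITERIA = ("mean_sd", "bland_altman", "volcano", "skewness", "tail", "cv")


@dataclass(frozen=True)
class ComboSpec:
    """One transformation/normalization pairing.

    The vsn normalization carries its own transformation, so the single vsn
    pathway has ``transformation=None`` and is named plain ``"vsn"``.
    """

    transformation: Optional[str]
    normalization: str

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "vsn":
            if self.transformation is not None:
                raise ValueError("the vsn pathway does not take a transformation")
        elif self.transformation not in TRANSFORMATIONS:
            raise ValueError(f"unknown transformation {self.transformation!r}")

    @property
    def name(self) -> str:
        if self.normalization == "vsn":
            return "vsn"
        return f"{self.transformation}_{self.normalization}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class CriterionScores:
    """The six 0/1/2 criterion scores and their 0-12 total for one combo."""

    combo: ComboSpec
    mean_sd: int
    bland_altman: int
    volcano: int
    skewness: int
    tail: int
    cv: int

    def __post_init__(self) -> None:
        for crit in CRITERIA:
            v = getattr(self, crit)
            if v not in (0, 1, 2):
                raise ValueError(f"criterion {crit} score {v!r} not in {{0,1,2}}")

    @property
    def total(self) -> int:
        return sum(getattr(self, crit) for crit in CRITERIA)

    def as_dict(self) -> dict:
        d = {"combo": self.combo.name}
        d.update({crit: getattr(self, crit) for crit in CRITERIA})
        d["total"] = self.total
        return d


def group_samples(meta: Sequence[SampleMeta], group: Group | str,
                  within: Optional[Sequence[str]] = None) -> list[str]:
    """Sample IDs belonging to ``group``, optionally restricted to ``within``."""
    group = Group(group)
    keep = None if within is None else set(within)
    return [m.sample_id for m in meta
            if m.group == group and (keep is None or m.sample_id in keep)]
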