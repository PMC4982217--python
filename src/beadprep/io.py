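"""Text-format I/O: assay matrices, sample annotations, bead counts, scores,
reader ratings.

Canonical dialect: comma-separated UTF-8, analytes as rows, sample IDs in the
header, first column analyte IDs. Missing cells are written empty and parsed
from blank / "NA" / "NaN". Floats are written with shortest round-trip repr so
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AssayMatrix, CriterionScores, Group, SampleMeta, CRITERIA

_NA_TOKENS = ("", "NA", "NaN", "nan")


def _fmt(x: float) -> str:
    return "" if np.isnan(x) else repr(float(x))


def write_assay(matrix: AssayMatrix, path: str | Path,
                beadcount_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally its bead counts) as CSV."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["analyte_id", *matrix.sample_ids])
        for i, aid in enumerate(matrix.analyte_ids):
            w.writerow([aid, *(_fmt(v) for v in matrix.values[i])])
    if beadcount_path is not None:
        if matrix.bead_counts is None:
            raise ValueError("matrix has no bead_counts to write")
        write_bead_counts(matrix, beadcount_path)


def write_bead_counts(matrix: AssayMatrix, path: str | Path) -> None:
    if matrix.bead_counts is None:
        raise ValueError("matrix has no bead_counts")
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["analyte_id", *matrix.sample_ids])
        for i, aid in enumerate(matrix.analyte_ids):
            w.writerow([aid, *(int(c) for c in matrix.bead_counts[i])])


def write_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group", "plate", "replicate"])
        for m in meta:
            w.writerow([m.sample_id, m.group.value, m.plate,
                        "" if m.replicate is None else m.replicate])


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, na_values=list(_NA_TOKENS),
                     keep_default_na=False, dtype_backend="numpy_nullable")
    df.index = df.index.astype(str)
    return df


def read_assay(matrix_path: str | Path, meta_path: str | Path | None = None,
               beadcount_path: str | Path | None = None,
               ) -> tuple[AssayMatrix, Optional[list[SampleMeta]]]:
    """Read a matrix CSV plus optional annotation and bead-count CSVs.

    Returns the matrix with ``scale_tag="raw"``. The matrix and annotation
    must describe exactly the same sample set, otherwise a ``ValueError``
    names the offending sample IDs.
    """
    df = _read_table(matrix_path)
    analyte_ids = [str(a) for a in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(analyte_ids)) != len(analyte_ids):
        dupes = sorted({a for a in analyte_ids if analyte_ids.count(a) > 1})
        raise ValueError(f"duplicate analyte IDs in {matrix_path}: {dupes}")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample IDs in {matrix_path}: {dupes}")
    values = df.to_numpy(dtype=float, na_value=np.nan)

    bead_counts = None
    if beadcount_path is not None:
        bc = _read_table(beadcount_path)
        if list(bc.index) != analyte_ids or list(bc.columns) != sample_ids:
            raise ValueError("bead-count file labels do not match the matrix")
        bead_counts = bc.to_numpy(dtype=float, na_value=np.nan)
        bead_counts = np.where(np.isnan(bead_counts), 0, bead_counts).astype(int)

    meta = None
    if meta_path is not None:
        meta = read_meta(meta_path)
        meta_ids = [m.sample_id for m in meta]
        only_matrix = sorted(set(sample_ids) - set(meta_ids))
        only_meta = sorted(set(meta_ids) - set(sample_ids))
        if only_matrix or only_meta:
            raise ValueError(
                "sample sets differ between matrix and annotation; "
                f"matrix-only: {only_matrix}; annotation-only: {only_meta}"
            )
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample IDs in annotation file")

    matrix = AssayMatrix(analyte_ids=analyte_ids, sample_ids=sample_ids,
                         values=values, bead_counts=bead_counts, scale_tag="raw")
    return matrix, meta


def read_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, na_values=list(_NA_TOKENS), keep_default_na=False)
    required = {"sample_id", "group", "plate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    meta = []
    for _, row in df.iterrows():
        rep = row.get("replicate")
        rep = None if rep is None or (isinstance(rep, float) and np.isnan(rep)) else int(rep)
        meta.append(SampleMeta(str(row["sample_id"]), Group(row["group"]),
                               str(row["plate"]), rep))
    return meta


def write_scores(scores: Iterable[CriterionScores], path: str | Path) -> None:
    """One row per combination, six criterion columns plus the total,
    ordered by combination name."""
    rows = sorted((s.as_dict() for s in scores), key=lambda d: d["combo"])
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["combo", *CRITERIA, "total"])
        for d in rows:
            w.writerow([d["combo"], *(d[c] for c in CRITERIA), d["total"]])


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Reader-rating table: combo, criterion, round, reader_id, rating."""
    df = pd.read_csv(path)
    required = {"combo", "criterion", "round", "reader_id", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings file missing columns: {sorted(missing)}")
    if not df["rating"].isin([0, 1, 2]).all():
        bad = sorted(df.loc[~df["rating"].isin([0, 1, 2]), "rating"].unique())
        raise ValueError(f"ratings must be 0/1/2, found {bad}")
    return df
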