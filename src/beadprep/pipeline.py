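"""End-to-end orchestration: enumerate the 37 combinations, run
QC -> transform -> impute -> normalize -> evaluate, and emit score tables.

The stage order is fixed: quality control on raw data, transformation,
median imputation, then normalization. The vsn pathway skips the
transformation stage (it has a built-in one) and consumes the raw-scale
QC'd, imputed matrix directly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import io as bio
from . import qc as qcmod
from . import transforms as tr
from .normalize import normalize as _normalize
from .core import (AssayMatrix, ComboSpec, CriterionScores, Group, SampleMeta,
                   group_samples, NORMALIZATIONS, TRANSFORMATIONS)
from .synthetic import SimConfig, simulate_assay

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComboResult", "RunResult", "enumerate_combos",
           "run_pipeline"]


def enumerate_combos() -> list[ComboSpec]:
    """All 37 valid pairings: 6 transformations x 6 plain normalizations plus
    the single vsn pathway, in deterministic order."""
    combos = [ComboSpec(t, n) for t in TRANSFORMATIONS
              for n in NORMALIZATIONS if n != "vsn"]
    combos.append(ComboSpec(None, "vsn"))
    return combos


@dataclass
class RunConfig:
    """Everything one pipeline run needs; every stochastic stage is seeded."""

    sim: Optional[SimConfig] = None
    matrix_path: Optional[str] = None
    meta_path: Optional[str] = None
    beadcount_path: Optional[str] = None
    analyte_null_max: float = 0.19
    sample_null_max: float = 0.20
    min_beads: int = 35
    lambda_scope: str = "global"
    loess_span: float = 0.4
    rsn_knots: int = 8
    seed: int = 0
    auto_rate: bool = True
    ratings_path: Optional[str] = None
    out_dir: Optional[str] = None
    write_matrices: bool = False
    make_plots: bool = False
    qq_reps: int = 25

    def validate(self) -> None:
        if self.sim is None and self.matrix_path is None:
            raise ValueError("provide either a SimConfig or a matrix path")
        if not self.auto_rate and self.ratings_path is None:
            raise ValueError("either enable auto_rate or provide a ratings file")


@dataclass
class ComboResult:
    combo: ComboSpec
    status: str = "ok"  # "ok" | "failed"
    error: Optional[str] = None
    matrix: Optional[AssayMatrix] = None
    log_S: Optional[float] = None
    T: Optional[float] = None
    mean_sd: Optional[ev.MeanSDStats] = None
    bland_altman: Optional[ev.BlandAltmanStats] = None
    volcano: Optional[list[ev.VolcanoStats]] = None
    criterion_scores: dict[str, int] = field(default_factory=dict)
    seconds: float = 0.0


@dataclass
class RunResult:
    scores: list[CriterionScores]
    qc_report: qcmod.QCReport
    combo_results: dict[str, ComboResult]
    cv_summaries: list[ev.CVSummary]
    failures: dict[str, str]

    def ranked(self) -> list[CriterionScores]:
        return sorted(self.scores, key=lambda s: (-s.total, s.combo.name))


def _reader_class(ratings: pd.DataFrame, combo: str, criterion: str) -> int:
    sel = ratings[(ratings["combo"] == combo)
                  & (ratings["criterion"] == criterion)
                  & (ratings["round"] == 1)]
    if len(sel) != 15:
        raise ValueError(
            f"ratings file must contain exactly 15 round-1 ratings for "
            f"({combo}, {criterion}); found {len(sel)}")
    _, cls = ev.aggregate_reader_scores(sel["rating"].tolist())
    return cls


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every combination end-to-end and score it.

    A stage error aborts only that combination; it is logged and reported as
    "not evaluable" (distinct from a score of 0)."""
    config.validate()

    if config.sim is not None:
        sim = simulate_assay(config.sim)
        matrix, meta = sim.matrix, sim.meta
    else:
        matrix, meta = bio.read_assay(config.matrix_path, config.meta_path,
                                      config.beadcount_path)
        if meta is None:
            raise ValueError("a sample annotation file is required")

    if matrix.bead_counts is not None:
        matrix = qcmod.filter_bead_counts(matrix, config.min_beads)
    matrix, qc_report = qcmod.qc_filter(matrix, config.analyte_null_max,
                                        config.sample_null_max)

    surviving = set(matrix.sample_ids)
    ref = group_samples(meta, Group.reference_pool, within=surviving)
    controls = group_samples(meta, Group.control, within=surviving)
    cases = (group_samples(meta, Group.case_MS, within=surviving)
             + group_samples(meta, Group.case_NMO, within=surviving))
    if len(ref) < 2:
        raise ValueError(
            "fewer than 2 reference-pool replicates survive QC; the mean-SD, "
            "Bland-Altman and CV criteria cannot be computed "
            f"(surviving reference samples: {ref})")

    # transform + impute once per transformation; vsn consumes raw imputed
    prepared: dict[Optional[str], AssayMatrix | Exception] = {}
    for t in TRANSFORMATIONS:
        t0 = time.perf_counter()
        try:
            tm, _ = tr.transform(matrix, t, reference_samples=ref,
                                 lambda_scope=config.lambda_scope)
            prepared[t] = qcmod.impute_median(tm, qc_report)
        except Exception as exc:  # noqa: BLE001 - isolate per stage
            prepared[t] = exc
        logger.info("prepare %s: %.2fs", t, time.perf_counter() - t0)
    try:
        prepared[None] = qcmod.impute_median(matrix, qc_report)
    except Exception as exc:  # noqa: BLE001
        prepared[None] = exc

    ratings = (bio.read_ratings(config.ratings_path)
               if config.ratings_path else None)

    combos = enumerate_combos()
    results: dict[str, ComboResult] = {}
    for k, combo in enumerate(combos):
        t0 = time.perf_counter()
        res = ComboResult(combo=combo)
        results[combo.name] = res
        try:
            base = prepared[combo.transformation]
            if isinstance(base, Exception):
                raise base
            seed_k = config.seed * 1000 + k  # deterministic per-combo seed
            nres = _normalize(
                base, combo.normalization, seed=seed_k,
                **({"span": config.loess_span} if combo.normalization == "loess"
                   else {"n_knots": config.rsn_knots} if combo.normalization == "rsn"
                   else {}))
            res.matrix = nres.matrix
            vals = nres.matrix.values
            res.log_S = ev.skewness_logS(vals.ravel())
            res.T = ev.tail_length_T(vals.ravel())
            res.criterion_scores["skewness"] = ev.score_skewness(res.log_S)
            res.criterion_scores["tail"] = ev.score_tail(res.T)
            res.mean_sd = ev.mean_sd_stats(nres.matrix, ref)
            res.bland_altman = ev.bland_altman_pairs(nres.matrix, ref)
            res.volcano = ev.volcano_stats(nres.matrix, controls, cases)
            if ratings is not None:
                for crit in ("mean_sd", "bland_altman", "volcano"):
                    res.criterion_scores[crit] = _reader_class(
                        ratings, combo.name, crit)
            else:
                res.criterion_scores["mean_sd"] = ev.auto_rate_plot(
                    "mean_sd", res.mean_sd)
                res.criterion_scores["bland_altman"] = ev.auto_rate_plot(
                    "bland_altman", res.bland_altman)
                res.criterion_scores["volcano"] = ev.auto_rate_plot(
                    "volcano", res.volcano)
        except Exception as exc:  # noqa: BLE001 - report, don't abort the run
            res.status = "failed"
            res.error = f"{type(exc).__name__}: {exc}"
            logger.warning("combo %s failed: %s", combo.name, res.error)
        res.seconds = time.perf_counter() - t0
        logger.info("combo %s: %s (%.2fs)", combo.name, res.status, res.seconds)

    ok = {name: r.matrix for name, r in results.items() if r.status == "ok"}
    cv_summaries: list[ev.CVSummary] = []
    if ok:
        cv_summaries = ev.cv_rank_score(ok, ref)
        for summ in cv_summaries:
            results[summ.combo].criterion_scores["cv"] = summ.score

    scores: list[CriterionScores] = []
    for name, r in results.items():
        if r.status != "ok":
            continue
        scores.append(CriterionScores(combo=r.combo, **{
            c: r.criterion_scores[c]
            for c in ("mean_sd", "bland_altman", "volcano",
                      "skewness", "tail", "cv")}))

    failures = {n: r.error for n, r in results.items() if r.status == "failed"}
    run = RunResult(scores=scores, qc_report=qc_report, combo_results=results,
                    cv_summaries=cv_summaries, failures=failures)

    if config.out_dir is not None:
        _write_outputs(run, config, matrix, meta, ref, controls, cases)
    return run


def _write_outputs(run: RunResult, config: RunConfig, qc_matrix: AssayMatrix,
                   meta: Sequence[SampleMeta], ref: list[str],
                   controls: list[str], cases: list[str]) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bio.write_scores(run.scores, out / "scores.csv")
    bio.write_meta(meta, out / "sample_meta.csv")

    with open(out / "qc_report.csv", "w", encoding="utf-8") as fh:
        fh.write("kind,id,null_fraction\n")
        for a, f in run.qc_report.excluded_analytes:
            fh.write(f"analyte,{a},{f!r}\n")
        for s, f in run.qc_report.excluded_samples:
            fh.write(f"sample,{s},{f!r}\n")

    ranked = run.ranked()
    with open(out / "summary.csv", "w", encoding="utf-8") as fh:
        fh.write("rank,combo,total,status\n")
        for i, s in enumerate(ranked, start=1):
            fh.write(f"{i},{s.combo.name},{s.total},ok\n")
        for name in sorted(run.failures):
            fh.write(f",{name},,not evaluable\n")

    stats_rows = []
    for name in sorted(run.combo_results):
        r = run.combo_results[name]
        if r.status != "ok":
            continue
        stats_rows.append({"combo": name, "log_S": r.log_S, "T": r.T,
                           "mean_sd_spearman": r.mean_sd.spearman,
                           "ba_mean_diff": r.bland_altman.mean_diff})
    pd.DataFrame(stats_rows).to_csv(out / "criteria_stats.csv", index=False)
    cv_rows = [{"combo": c.combo, "cv_rank_sum": c.cv_rank_sum,
                "cv_percent": c.cv_percent, "score": c.score}
               for c in sorted(run.cv_summaries, key=lambda c: c.combo)]
    pd.DataFrame(cv_rows).to_csv(out / "cv_summary.csv", index=False)

    if config.write_matrices:
        mdir = out / "matrices"
        mdir.mkdir(exist_ok=True)
        for name, r in run.combo_results.items():
            if r.status == "ok" and r.matrix is not None:
                bio.write_assay(r.matrix, mdir / f"{name}.csv")

    if config.make_plots:
        from . import plots
        pdir = out / "plots"
        pdir.mkdir(exist_ok=True)
        for name, r in run.combo_results.items():
            if r.status != "ok":
                continue
            plots.plot_mean_sd(r.mean_sd, pdir / f"{name}_mean_sd.png", name)
            plots.plot_bland_altman(r.bland_altman,
                                    pdir / f"{name}_bland_altman.png", name)
            plots.plot_volcano(r.volcano, pdir / f"{name}_volcano.png", name)

    manifest = {
        "seed": config.seed,
        "n_combos": len(run.combo_results),
        "n_ok": len(run.scores),
        "failures": run.failures,
        "reference_samples": ref,
        "controls": controls,
        "cases": cases,
        "files": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
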