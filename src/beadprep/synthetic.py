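"""Synthetic assay generator emulating a reference-pool / case-control design.

Produces right-skewed raw intensities whose SD grows with the mean
(multiplicative log-scale noise plus a small additive floor), plate shifts,
repeated reference-pool measurements distributed across plates, a subset of
case-affected analytes, and injected non-positive / missing readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import AssayMatrix, Group, SampleMeta

__all__ = ["SimConfig", "SimOutput", "simulate_assay", "toy_fixture"]


@dataclass
class SimConfig:
    """Parameters of the synthetic assay. Counts follow the study design:
    12 controls, 18 + 12 cases on 4 plates, 12 reference-pool replicates."""

    n_analytes: int = 384
    n_controls: int = 12
    n_case1: int = 18
    n_case2: int = 12
    n_ref_replicates: int = 12
    n_plates: int = 4
    baseline_log_mean_range: tuple[float, float] = (4.0, 9.0)
    noise_cv: float = 0.2
    plate_shift_sd: float = 0.05
    sample_effect_sd: float = 0.15
    additive_sd: float = 3.0
    frac_affected_analytes: float = 0.1
    effect_size_log2: float = 1.0
    frac_missing: float = 0.005
    frac_nonpositive: float = 0.005
    bead_count_mean: float = 0.0  # 0 disables the bead-count matrix
    frac_low_beads: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_analytes=self.n_analytes, n_controls=self.n_controls,
                      n_case1=self.n_case1, n_case2=self.n_case2,
                      n_ref_replicates=self.n_ref_replicates, n_plates=self.n_plates)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in ("frac_affected_analytes", "frac_missing",
                     "frac_nonpositive", "frac_low_beads"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ValueError("baseline_log_mean_range must be (lo, hi) with lo <= hi")
        if self.frac_affected_analytes > 0 and self.effect_size_log2 != 0:
            if self.n_case1 < 1 or self.n_case2 < 1 or self.n_controls < 1:
                raise ValueError("case effects requested but a group size is zero")

    @property
    def n_samples(self) -> int:
        return self.n_controls + self.n_case1 + self.n_case2 + self.n_ref_replicates


@dataclass
class SimOutput:
    matrix: AssayMatrix
    meta: list[SampleMeta]
    truth: pd.DataFrame  # analyte_id, baseline_log_mean, affected, effect_log2
    config: Optional[SimConfig] = None


def _sigma_mult(cv: float) -> float:
    # log-normal sigma giving raw-scale CV == cv
    return float(np.sqrt(np.log1p(cv ** 2)))


def simulate_assay(config: SimConfig) -> SimOutput:
    """Generate one synthetic assay dataset; fully reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    A = config.n_analytes

    # sample layout: controls, case1, case2, reference pool (last)
    sample_ids: list[str] = []
    meta: list[SampleMeta] = []
    study_groups = ([Group.control] * config.n_controls
                    + [Group.case_MS] * config.n_case1
                    + [Group.case_NMO] * config.n_case2)
    for i, g in enumerate(study_groups):
        sid = f"S{i + 1:02d}_{g.value}"
        plate = f"P{i % config.n_plates + 1}"  # round-robin across plates
        sample_ids.append(sid)
        meta.append(SampleMeta(sid, g, plate))
    per_plate = int(np.ceil(config.n_ref_replicates / config.n_plates))
    for r in range(config.n_ref_replicates):
        sid = f"REF{r + 1:02d}"
        plate = f"P{r // per_plate + 1}"  # e.g. 12 reps -> 3 per plate on 4 plates
        sample_ids.append(sid)
        meta.append(SampleMeta(sid, Group.reference_pool, plate, replicate=r + 1))
    n = len(sample_ids)

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=A)
    plate_ids = sorted({m.plate for m in meta})
    plate_shift = dict(zip(plate_ids, rng.normal(0.0, config.plate_shift_sd,
                                                 size=len(plate_ids))))
    # one latent subject effect per study sample; a single shared one for the pool
    subject_effect = rng.normal(0.0, config.sample_effect_sd, size=n)
    ref_start = len(study_groups)
    subject_effect[ref_start:] = rng.normal(0.0, config.sample_effect_sd)

    n_affected = int(round(config.frac_affected_analytes * A))
    affected = np.zeros(A, dtype=bool)
    affected[rng.choice(A, size=n_affected, replace=False)] = True
    effect_nat = config.effect_size_log2 * np.log(2.0)

    sig = _sigma_mult(config.noise_cv)
    log_mu = baseline[:, None] + np.array(
        [plate_shift[m.plate] + subject_effect[j] for j, m in enumerate(meta)]
    )[None, :]
    is_case = np.array([m.group in (Group.case_MS, Group.case_NMO) for m in meta])
    log_mu = log_mu + np.where(is_case[None, :] & affected[:, None], effect_nat, 0.0)

    values = np.exp(log_mu + rng.normal(0.0, sig, size=(A, n)))
    if config.additive_sd > 0:
        values = values + rng.normal(0.0, config.additive_sd, size=(A, n))

    # injected instrument artifacts: non-positive readouts, then dropouts
    total = A * n
    n_nonpos = int(round(config.frac_nonpositive * total))
    if n_nonpos:
        cells = rng.choice(total, size=n_nonpos, replace=False)
        flat = values.ravel()
        flat[cells] = rng.choice([0.0, -1.0, -0.5, -2.0], size=n_nonpos)
        values = flat.reshape(A, n)
    mask = np.zeros((A, n), dtype=bool)
    n_miss = int(round(config.frac_missing * total))
    if n_miss:
        cells = rng.choice(total, size=n_miss, replace=False)
        mask.ravel()[cells] = True

    bead_counts = None
    if config.bead_count_mean > 0:
        bead_counts = rng.poisson(config.bead_count_mean, size=(A, n))
        if config.frac_low_beads > 0:
            n_low = int(round(config.frac_low_beads * total))
            cells = rng.choice(total, size=n_low, replace=False)
            bead_counts.ravel()[cells] = rng.integers(0, 36, size=n_low)

    matrix = AssayMatrix(
        analyte_ids=[f"BEAD{i + 1:04d}" for i in range(A)],
        sample_ids=sample_ids,
        values=np.where(mask, np.nan, values),
        missing_mask=mask,
        bead_counts=bead_counts,
        scale_tag="raw",
    )
    truth = pd.DataFrame({
        "analyte_id": matrix.analyte_ids,
        "baseline_log_mean": baseline,
        "affected": affected,
        "effect_log2": np.where(affected, config.effect_size_log2, 0.0),
    })
    return SimOutput(matrix=matrix, meta=meta, truth=truth, config=config)


def toy_fixture() -> SimOutput:
    """Tiny deterministic dataset with hand-checkable values.

    8 analytes x 8 samples (2 controls, 2 MS, 2 NMO, 2 reference replicates).
    Contains one value <= 0 (T05/S3) and one analyte (T06) missing in 2 of 8
    samples (25 % > 19 %), so QC has something to catch.
    """
    nan = np.nan
    values = np.array([
        # S1    S2    S3    S4    S5    S6    R1    R2
        [100., 110., 105., 120., 115., 108., 102., 104.],
        [ 50.,  55.,  52.,  60.,  58.,  54.,  51.,  53.],
        [800., 820., 790., 900., 880., 810., 805., 815.],
        [ 10.,  12.,  11.,  14.,  13.,  12.,  10.,  11.],
        [200., 210.,  -1., 240., 230., 205., 202., 208.],
        [300.,  nan, 310.,  nan, 330., 305., 302., 308.],
        [ 40.,  42.,  41.,  48.,  46.,  43.,  40.,  41.],
        [600., 610., 605., 700., 680., 615., 602., 608.],
    ])
    meta = [
        SampleMeta("S1", Group.control, "P1"),
        SampleMeta("S2", Group.control, "P2"),
        SampleMeta("S3", Group.case_MS, "P1"),
        SampleMeta("S4", Group.case_MS, "P2"),
        SampleMeta("S5", Group.case_NMO, "P1"),
        SampleMeta("S6", Group.case_NMO, "P2"),
        SampleMeta("R1", Group.reference_pool, "P1", replicate=1),
        SampleMeta("R2", Group.reference_pool, "P2", replicate=2),
    ]
    matrix = AssayMatrix(
        analyte_ids=[f"T{i + 1:02d}" for i in range(8)],
        sample_ids=[m.sample_id for m in meta],
        values=values,
        scale_tag="raw",
    )
    truth = pd.DataFrame({
        "analyte_id": matrix.analyte_ids,
        "baseline_log_mean": np.log(np.nanmedian(np.where(values > 0, values, np.nan),
                                                 axis=1)),
        "affected": [False] * 8,
        "effect_log2": [0.0] * 8,
    })
    return SimOutput(matrix=matrix, meta=meta, truth=truth, config=None)
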