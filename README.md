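# beadprep

Benchmarking toolkit for pre-processing multiplex bead-array (Luminex
xMAP-style) median-fluorescence-intensity (MFI) matrices. It implements the
full pipeline

```
quality control  ->  transformation  ->  median imputation  ->  normalization
```

for all **37 valid combinations** of 6 transformations (`no`, `log2`,
`asinh`, `boxcox`, `boxcoxweights`, `vst`) and 7 normalizations (`loess`,
`global`, `quantile`, `quanimpr`, `rsn`, `zscore`, `vsn` — the vsn pathway
carries its own transformation and is applied to raw, QC'd, imputed data),
and scores each combination on **six criteria** (0/1/2 each, total 0–12):

| criterion | basis |
|---|---|
| mean-SD | SD vs rank(mean) over reference-pool replicates |
| Bland-Altman | all replicate pairs pooled, bias/trend/funnel |
| volcano | Wilcoxon rank-sum p vs rank-based relative effects |
| skewness | quantile statistic log S with ±0.5 / ±0.75 bands |
| tail length | quantile statistic T with 1.525/1.625/2.0/2.1 bands |
| CV | rank-sum of per-analyte CVs across combos, % thresholds 50/80 |

The three plot criteria are normally graded by a 15-reader panel (ratings
CSV, 0–30 aggregate → 0/1/2 classes); an automated surrogate
(`--auto-rate`) is provided for unattended runs. A QQ diagnostic
(Mann–Whitney U on 25 random splits of one case group) is also included.

A synthetic-data module (`beadprep.synthetic`) generates datasets with the
benchmark's study design — 384 analytes; 12 controls, 18 + 12 cases and 12
reference-pool replicates (3 per plate on 4 plates); right-skewed,
heteroscedastic intensities; plate shifts; injected non-positive and missing
readouts — so everything is testable without external data.

## CLI

```bash
# generate a synthetic dataset (matrix.csv, sample_meta.csv, truth.csv)
beadprep simulate --seed 1 --out-dir data/

# run all 37 combinations end-to-end with the automated plot ratings
beadprep run --matrix data/matrix.csv --meta data/sample_meta.csv \
             --auto-rate --seed 1 --out-dir out/

# or in one step on a fresh simulation
beadprep run --simulate --seed 1 --out-dir out/
```

Outputs under `--out-dir`: `scores.csv` (six criteria + total per combo),
`summary.csv` (ranked, failures reported as "not evaluable" rather than 0),
`cv_summary.csv`, `criteria_stats.csv`, `qc_report.csv`, `manifest.json`,
and optionally per-combo matrices (`--config` with `write_matrices: true`)
and plots (`--make-plots`). Single stages are available as
`beadprep qc|transform|normalize|evaluate`.

File formats are plain CSV: matrix with analytes as rows and a sample-ID
header; sample annotations (`sample_id,group,plate,replicate` with groups
`reference_pool|control|case_MS|case_NMO`); optional bead-count matrix
(cells with ≤ 35 beads are masked); reader ratings
(`combo,criterion,round,reader_id,rating`).

## API sketch

```python
from beadprep import (SimConfig, simulate_assay, qc_filter, impute_median,
                      transform, normalize, RunConfig, run_pipeline)

sim = simulate_assay(SimConfig(seed=1))
result = run_pipeline(RunConfig(sim=SimConfig(seed=1), seed=1, auto_rate=True))
for s in result.ranked()[:5]:
    print(s.combo.name, s.total)
```
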