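# ergscreen

A pipeline for large-scale electroretinography (ERG) screening of mouse
cohorts: waveform quality control, component amplitude extraction,
soft-window temporal weighting of wildtype controls, weighted genotype
ANOVA with percentage effect sizes, and between-eye concordance hit
calling — plus a synthetic cohort generator so the entire screen runs
at desk scale with no external data.

## What the pipeline does

1. **Validation** — referential integrity, duplicate keys, missing
   trials, sampling/epoch violations (`waveform_io.validate_cohort`).
2. **Offset correction** — the mean of the pre-stimulus baseline
   (40 samples scotopic / 20 photopic) is subtracted from every trace.
3. **Inter-trial MAD QC** — per (mouse, eye, condition), the mean
   absolute deviation across repeated trials is summed over the trace;
   units above the upper-1% quantile of the pooled per-condition score
   distribution are excluded.
4. **Trial averaging and component extraction** — a-wave (baseline to
   trough), b-wave (a-trough to peak), and for scotopic recordings the
   c-wave (baseline to peak) and FO-like wave (c-peak to trough), each
   inside configurable closed search windows.
5. **Extreme-value QC** — wildtype mean ± 3·SD limits per parameter ×
   eye, applied to every mouse.
6. **Sample-size gate** — strains need ≥ 5 QC-passing mice per
   condition.
7. **Soft-window weighting** — wildtype controls receive weights in
   [0, 1] from a flat-top logistic-product kernel centred on the mutant
   strain's test dates; window size/shape is grid-searched to minimise
   weighted control variance subject to a minimum effective sample size.
8. **Weighted genotype fits** — `Y = B0 + B1·genotype` per eye and
   pooled across eyes; effect size = 100·B1/B0 (% change from
   wildtype). A strain × parameter is a **concordant hit** iff
   p ≤ 0.01 in each eye and p ≤ 0.0001 combined.
9. **Sex analyses** — Welch t-tests for wildtype sexual dimorphism
   (Bonferroni 0.004) and sex×genotype interaction models for strains
   with ≥ 4 mutants per sex.

The synthetic generator (`ergscreen.synthetic_data`) produces cohorts
with weekly wildtype batches (5 M + 5 F), mutant strains tested in 1–6
batches, per-mouse and per-trial variation, multi-year baseline/gain
drift, injected artifact trials, gross outlier mice, and multiplicative
strain effects — with a ground-truth record for scoring every stage.

## CLI

```sh
# generate a documented synthetic preset and its ground truth
ergscreen simulate --preset one-hit --out-dir scratch/cohort

# run the full screen on a cohort (traces.tsv + sessions.tsv)
ergscreen screen --cohort scratch/cohort --out-dir scratch/out

# QC or extraction stages individually
ergscreen qc --cohort scratch/cohort --out-dir scratch/qc
ergscreen extract --cohort scratch/cohort --out-dir scratch/amp

# volcano / waterfall tables (and optional SVG figures)
ergscreen report --results scratch/out/results.tsv --out-dir scratch/rep

# everything end-to-end from a preset
ergscreen all --preset one-hit --out-dir scratch/all
```

Presets: `tiny-clean`, `one-hit`, `drifted`, `dimorphic`. Screen
thresholds and component windows can be overridden with a YAML config
passed via `--config` (keys mirror `ergscreen.pipeline.ScreenConfig`).

Outputs: `results.tsv` (per strain × parameter fits, effects, p-values,
hit labels), `qc_report.tsv`, `weights.tsv` (soft-window audit),
`gate.tsv`, `dimorphism.tsv`, `interactions.tsv`, and `manifest.json`
(thresholds, window grid, config hash) for reproducibility.

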