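# hdsemg-seating

Analysis pipeline for high-density surface EMG (HDsEMG) of the lumbar
erector spinae in seated musicians, built around a two-chair crossover
design: does a chair with lumbar support lower back-muscle activity — and
perceived discomfort — compared with a standard stool?

The package is written for researchers in neuromuscular physiology and
ergonomics who record grid EMG (two 16×8 monopolar grids, 10 mm pitch,
2048 Hz, one grid per side of the spine) during long seated tasks. It
covers the full chain:

- **synthetic_data** — a cohort generator with known ground truth: spatially
  shaped band-limited activity, common-mode ECG, 50 Hz interference with
  harmonics, sensor noise, per-subject heterogeneity and an injected
  multiplicative chair effect. Every downstream stage is testable without
  human recordings.
- **preprocess** — single-differential derivation along the fiber
  direction, zero-phase 4th-order Butterworth band-pass (20–400 Hz), and
  power-line removal by spectral interpolation in ten harmonic windows
  (48–52, 96–104, …).
- **mapping** — RMS topographical maps (one value per channel over the
  20 s epoch), bicubic ×15 interpolation, Chan–Vese active-contour
  segmentation of the Region of Activity (ROA), RMS_ROA and the
  intensity-weighted centroid

  X_CM = Σᵢⱼ xᵢⱼ·I(i,j) / Σᵢⱼ I(i,j),  Y_CM = Σᵢⱼ yᵢⱼ·I(i,j) / Σᵢⱼ I(i,j)

  over ROA pixels only, plus the chair-related centroid displacement
  Δ(X,Y) = (CM_A − CM_SS)|end − (CM_A − CM_SS)|start.
- **stats** — per-trial percent change 100·(RMS_SS − RMS_A)/RMS_SS,
  per-subject exact Wilcoxon signed-rank tests with Dunn adjustment, the
  exact binomial sign argument P(X ≥ k | n, ½), a linear mixed model
  (fixed: chair, side; random: subject, trial time), centroid ANOVA,
  Spearman/Pearson correlations and Lilliefors normality checks.
- **questionnaires** — General Comfort Rating (1–10), Helander–Zhang
  comfort/discomfort statements (7 + 9 items, 1–10) with paired t-tests
  and min–max percentage scores, and Body Part Discomfort (10 parts,
  0–10) with a body-part random-factor mixed model.
- **workflow** — configuration (YAML), the simulate → preprocess → map →
  analyze chain with provenance, and a `hdsemg-seating` command line with
  per-stage subcommands.

## Worked example

A miniature cohort (4 subjects, 6 trials per chair and side, injected mean
chair effects of 30% left / 35% right):

```python
from hdsemg_seating import CohortConfig, StudyConfig, run_pipeline

cfg = StudyConfig(cohort=CohortConfig(n_subjects=4, n_trials=6, seed=42))
bundle = run_pipeline(cfg, out_dir="results/demo")

cols = ["subject", "side", "mean_pct_change", "sd_pct_change", "p_value", "significant"]
print(bundle["table2"][cols].round(2).to_string(index=False))
```

prints

```
subject side  mean_pct_change  sd_pct_change  p_value significant
      1    L            13.13           6.33     0.03        True
      1    R            45.39           4.49     0.03        True
      2    L            -2.04           9.49     0.44       False
      2    R            12.02           6.51     0.03        True
      3    L            25.19           7.60     0.03        True
      3    R            34.42           3.50     0.03        True
      4    L            59.53           4.48     0.03        True
      4    R            61.10           3.96     0.03        True
  Total    L            23.95          24.14      NaN        <NA>
  Total    R            38.23          18.78      NaN        <NA>
```

Each row is one subject and side: the mean ± SD over the six paired trials
of the percent RMS_ROA reduction on the lumbar-support chair relative to
the stool, the exact Wilcoxon p-value of the paired comparison, and
whether that subject shows an individually significant reduction (p < 0.05
exact; with six pairs the smallest attainable p is 0.03). The pooled
"Total" rows average all subjects' trials — here 23.95% (left) and 38.23%
(right), scattered around the injected 30/35% because four subjects carry
substantial between-subject heterogeneity. The same bundle carries the
mixed model (`chair: F = 151.7, p = 7.4e-35; side: F = 2.4, p = 0.12` for
this small cohort), the centroid analysis, and the questionnaire summaries
(`GCR modes: A = 3 "quite comfortable", SS = 4 "not very comfortable",
ANOVA p = 0.0073`).

The same chain is available from the shell:

```sh
hdsemg-seating run --seed 42 --out results/full   # full 16-subject study
hdsemg-seating simulate --out data/sim            # or stage by stage
hdsemg-seating preprocess --in data/sim/epochs --out data/clean
hdsemg-seating map --in data/clean --out data/maps
hdsemg-seating analyze --roa data/maps/roa.csv --out results
```

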