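# Methods

This note documents the models, algorithms and numerical choices behind
`hdsemg_seating`, and what its synthetic experiments do and do not show.

## The measurement model

The package analyses high-density surface EMG (HDsEMG) of the lumbar
erector spinae recorded with two 16×8 monopolar electrode grids (10 mm
inter-electrode distance, 2048 Hz) in a two-chair crossover design: each
subject plays for 55 min on a standard stool (SS) in one session and on a
chair with lumbar support (A) in the other, with twelve 20 s epochs
acquired 5 min apart per session and side.

The analysis chain per epoch:

1. **Single-differential derivation** along the columns (≈ fiber
   direction): `out[r] = mono[r+1] − mono[r]`, 15×8 = 120 channels per
   grid. Components common to all electrodes (ECG) cancel exactly.
2. **Band-pass 20–400 Hz**, 4th-order Butterworth applied bidirectionally
   (zero phase). Implementation: the squared magnitude response is applied
   in the frequency domain after 1 s reflection padding — this is the same
   linear operator as forward–backward IIR filtering (verified against
   `sosfiltfilt` to <1% interior error) at a fraction of the cost, which
   matters when a cohort of 768 epochs is processed.
3. **Power-line removal by spectral interpolation**: for harmonics
   k = 1..10 of 50 Hz, magnitude-spectrum bins strictly inside
   (48k, 52k) Hz are replaced by a line between the spectrum levels just
   outside the window; phases are retained, so the operation is real,
   leaves everything outside the windows untouched, and is idempotent.
   *Numerical choice*: each edge level is the RMS magnitude of the 5
   nearest outside bins. Periodogram magnitudes of stochastic signals
   fluctuate (Rayleigh); interpolating between two single noisy bins
   under-replaces in-window power by ≈ 2w(1−w)(1−π/4) per bin (−2% total
   epoch RMS over ten windows), while the block-RMS level is unbiased in
   power.
4. **RMS map**: per-channel RMS over the full 20 s epoch, arranged by grid
   position (15×8). Channels that are non-finite or exceed 10× the grid
   median RMS are excluded and imputed from their valid 4-neighbours;
   a trial aborts if more than 25% of channels are excluded.
5. **Interpolation ×15**: bicubic spline sampled at a pitch of exactly
   ied/15 = 0.667 mm (some reports round this to 0.6 mm), output 211×106.
6. **Region of activity (ROA)**: if the map's spatial mean exceeds the
   noise level (default 5.0 µV_RMS), a two-phase Chan–Vese active contour
   (µ = 0.25, λ₁ = λ₂ = 1, tol 10⁻³, ≤200 iterations) segments the map;
   otherwise the whole map is the ROA ("full-map fallback") and its mean
   is reported. RMS_ROA is the spatial mean inside the mask; the centroid
   (X_CM, Y_CM) is the intensity-weighted mean of the mask pixels'
   coordinates (origin at the map's top-left pixel centre, mm).

### Why the active contour is initialized from the Otsu threshold

The segmentation runs on the map normalized by its maximum, so the energy
depends only on relative contrast. Initializing from an *absolute*
threshold (pixels above the noise level) leaves the contour far from
equilibrium when the iteration cap is reached, and the resulting mask then
depends on the map's overall amplitude: two maps that differ only by a
multiplicative factor — e.g. the same muscle on the two chairs — get
systematically different masks, which biases the between-chair amplitude
ratio (in synthetic recovery, an injected 30% reduction was read back as
19%). Initializing from the Otsu threshold of the normalized map makes the
initialization itself contrast-based; the solver converges within the cap
and the whole operator commutes with amplitude scaling (asserted in the
tests). The noise level keeps its two other roles: the full-map fallback
gate and the degenerate-segmentation fallback mask.

### Noise level

The default 5.0 µV_RMS mirrors the conservative working rule for resting
baseline maps whose spatial means averaged ≈2.6 µV_RMS: take about twice
the mean and 1.5 times the maximum (`estimate_noise_level` implements
max(2·mean, 1.5·max)).

## Statistics

- **Per-trial percent change**: 100·(RMS_SS,i − RMS_A,i)/RMS_SS,i, positive
  when the lumbar-support chair lowers activity; per (subject, side) the
  mean ± SD over the 12 trial pairs is reported (a Table-2-style summary),
  with a pooled mean over all subjects' trials per side.
- **Per-subject Wilcoxon signed-rank** on the 12 paired trials, exact null
  distribution (DP over all 2ⁿ sign assignments using doubled midranks, so
  ties are handled exactly) for n ≤ 25, normal approximation with tie and
  continuity correction beyond. Zero differences are dropped; an all-zero
  comparison returns p = 1 with a warning. Dunn's multiple-comparison
  adjustment is the Bonferroni-type p_adj = min(1, m·p) over the family of
  all (subject × side) tests.
- **Binomial sign argument**: P(X ≥ k | n, p = ½) computed exactly from
  binomial coefficients (14 of 16 concordant subjects gives 137/65536 ≈
  0.00209).
- **Mixed model**: RMS_ROA ~ chair + side with a random intercept per
  subject and a variance component over trial times (statsmodels MixedLM,
  REML). Single-df fixed effects are reported as Wald F = z²; the subject
  random effect is tested by a likelihood-ratio against the
  fixed-effects-only model with the ½χ²₁ boundary correction; marginal and
  conditional R² follow the variance-partition definition.
- **Centroid ANOVA**: per coordinate, OLS with chair and side as factors
  of interest and subject and trial index as blocking factors, type-II
  F tests.
- **Correlations**: Spearman with Fisher-z CI; Pearson with its exact CI;
  KS normality uses the Lilliefors correction since mean and SD are
  estimated.
- **Questionnaires**: GCR modal score with label plus one-way ANOVA across
  chairs; Helander–Zhang statements compared with paired t-tests
  per statement ("mean decrease" = mean(A) − mean(SS)); subscale
  percentages are the min–max-normalized sums, 100·(Σ − n)/(9n) — the
  percentage definition is an interpretation, the source scale does not
  define one; BPD compared with a mixed model, chair fixed and body part
  as the random grouping factor. Likert responses are treated as
  continuous, as is conventional for ≥5-category scales. The 10 BPD body
  parts shipped in `questionnaires.BPD_BODY_PARTS` are a package choice
  and configurable.

## The synthetic cohort

`synthetic_data` generates monopolar epochs whose ground truth is known:

- **Activity**: per differential channel, stationary Gaussian noise with
  the power spectrum of white noise through the 20–400 Hz Butterworth
  band-pass (synthesized spectrally, normalized to exact per-channel RMS),
  spatially shaped by an elliptical amplitude bump and cumulatively summed
  along the rows so the differential montage recovers exactly the intended
  channels. Optional on/off burst modulation (durations 100–390 ms, rates
  1.5–2.5 s⁻¹; off by default) renormalizes to preserve the RMS target.
- **Artifacts**: a Ricker-pulse ECG at ≈1.2 Hz added identically to all
  electrodes (it must cancel in the differentials); 50 Hz interference
  with 10 harmonics decaying as 1/k, whose per-electrode coupling gain
  varies (CV 0.3) so a realistic residual survives differentiation; white
  sensor noise per electrode, default 2.6/√2 µV so a differential channel
  carries the observed ≈2.6 µV_RMS baseline floor.
- **Geometry**: bump peak 16 µV on a 4.5 µV background, σ = (20, 45) mm,
  centred 15 mm from the medial grid edge. These values were chosen so
  that (a) typical maps — including A-chair maps reduced by ~30–35% —
  stay above the 5 µV reliability threshold, as the clean per-subject
  results of the motivating study imply, and (b) measured RMS_ROA values
  span ≈ the observed 3.4–20.4 µV_RMS window. The **true region** is the
  elevated phase of the two-means (ISODATA) partition of the amplitude
  map: a smooth bump has no unique boundary, and the two-means partition
  is both invariant under amplitude scaling and consistent with what a
  converged two-phase segmentation estimates.
- **Effects**: the chair effect multiplies the A-chair activity amplitude
  by (1 − e/100) with e drawn per subject and side from N(30, 15²) on the
  left and N(35, 15²) on the right (clipped to (−60, 90)); subjects carry
  a lognormal overall amplitude scale (σ = 0.12) and a right-side gain of
  1.15; epochs carry lognormal trial-to-trial jitter (σ = 0.08, giving
  per-trial percent-change SDs of ≈8, matching the observed per-subject
  SDs). The *observed* between-subject spread of mean percent changes is
  larger than the injected 15 pp because the measurement process itself —
  in particular the full-map fallback on weak A-chair maps — amplifies
  extreme subjects; this mirrors the spread reported for the real cohort.
- **Fast path**: `simulate_rms_table` skips signal synthesis and draws
  RMS_ROA directly from the same random-factor hierarchy through a
  noiseless measurement model (activity ⊕ noise floor in quadrature,
  the contrast-based segmentation mask computed once per side, the
  full-map fallback rule). It reproduces the full pipeline's biases and is
  used where many replicate cohorts are needed (type-I calibration,
  Monte-Carlo intervals, flag-count medians).

### What the generator does not emulate

Volume conduction and electrode–tissue coupling, motor-unit firing
structure (the activity is Gaussian), innervation zones, electrode lift-off
or motion artifacts, postural drift of the activity centroid, and any
relation between questionnaire responses and the EMG of the same synthetic
subject (the quantitative–qualitative correlation operation is therefore
exercised for its contract, not for effect recovery). Passing recovery
tests show the *pipeline* is unbiased and calibrated under this model;
they do not validate the physiological assumptions themselves.

## Known limitations and expected numbers

- The measured RMS_ROA underestimates the injected activity amplitude by
  a few percent (noise floor adds in quadrature; the second band-pass
  application attenuates the activity's own Butterworth-shaped band
  edges); percent changes are ratios and largely immune.
- The full-map fallback inflates the percent change of subjects whose
  A-chair maps drop below the reliability threshold; pooled recovered
  changes therefore sit a few points above the injected means in some
  cohorts. The reproduction script's Monte-Carlo interval quantifies this.
- Problem sizes: the reproduction script runs the full 16-subject ×
  12-trial signal cohort (768 epochs), 50 maps per SNR level for
  segmentation recovery, and 20 replicate cohorts (amplitude level) for
  the flag-count median; the test suite runs the same experiments at
  reduced sizes (6×6 signal cohort, 12 maps per level) with the full-size
  checks delegated to the amplitude-level path.
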