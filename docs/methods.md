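# Methods

## Generative model of the fMRI sessions

A session follows the block design: per run, 5 dummy volumes then six
22.4 s condition blocks (7 volumes at TR 3.2 s), each followed by 16 s
fixation (5 volumes) — 77 volumes per run; 10 runs; 8 participants; six
conditions = {static, slow, fast} × {45°, 135°}, each occurring exactly once
per run in randomized order.

Per ROI, each voxel *i* draws a preferred orientation θᵢ ~ U[0°, 180°) and
responds to a static stimulus at orientation θ with a von-Mises tuning curve
on the doubled angle (period 180°):

    fᵢ(θ) = g · exp(κ (cos 2(θ − θᵢ) − 1)),   κ = 1 / (4 σ²_rad)

so the small-angle limit is a Gaussian of width σ (`tuning_width_deg`,
default 30°; `tuning_gain` g, default 1). Motion-direction maps dᵢ (fast)
and d′ᵢ (slow) use the same functional form with independent preferences and
a reduced amplitude (`direction_gain_ratio`, default 0.05·g): block-design
voxel patterns in practice carry much weaker direction than orientation
information, and the analysis outcome of interest is transfer, not
within-motion decoding.

Condition amplitudes per voxel:

    static: r · fᵢ(θ)
    fast:   r · [ w_f·fᵢ(θ) + (1 − w_f)·dᵢ(θ) + m_fast ]
    slow:   r · [ w_s·fᵢ(θ) + (1 − w_s)·d′ᵢ(θ) + m_slow ]

where r is the per-ROI gain (default V1 1.0, V2 1.0, V3 0.15, hMT 0.1,
control 0 — the control ROI therefore carries no stimulus-specific signal),
w_f = `shared_weight_fast` is the motion-streak signal (default per-ROI
profile 0.05 / 0.75 / 0.2 / 0.2 / 0, putting the strongest
orientation↔fast-motion transfer in "V2"), w_s = `shared_weight_slow`
defaults to 0, and m (`motion_generic_gain`, default fast 0.6 / slow 0.1) is
a direction-nonspecific motion response, larger for fast, which drives the
univariate fast > slow effect without adding decodable signal.

Each block's amplitude profile is a boxcar convolved with a peak-normalized
gamma-variate HRF, gamma(shape 7, scale 0.8 s): peak at 4.8 s — so the
method's 1-TR (3.2 s) shift lands block windows on the plateau of the
response — and decayed to ~0.1% of peak 16 s after offset, i.e. by the end
of a fixation interval, as for the canonical haemodynamic response. A
fatter-tailed HRF would bleed each block's (strong) orientation pattern into
the next block's analysis window and measurably over-disperses null
transfer accuracies. I.i.d. Gaussian noise (`noise_sd`, default 3 response
units against a tuning gain of 1) is added per voxel and volume, plus a
run-specific baseline offset (SD 0.5) on a baseline of 100; dummy volumes
carry an elevated baseline (+3) and no task signal, so the discard step is
consequential. Default ROI size is 100 voxels.

The defaults were calibrated once so that the full pipeline reproduces the
intended qualitative pattern — orientation decodable in V1/V2 but not
V3/hMT/control, orientation↔fast transfer only in V2, slow transfer at
chance — with signal-to-noise generous compared to real group data (e.g.
within-static accuracies near ceiling in V1/V2, where real studies report
~0.6). They are package defaults, not empirical estimates.

## Preprocessing conventions

Order: discard dummies → z-score per run → shift → block-average. Volume
indexing is 0-based; block windows are half-open [onset+shift,
onset+shift+duration). Z-scoring uses the (n−1) SD denominator; voxels
whose within-run SD is ≤ 1e−12·(|mean|+1) — constant up to float rounding —
are flagged, logged and set to zero rather than amplifying cancellation
noise. The default design yields 60 patterns (blocks) per participant per
ROI; 20 per stimulus type.

## Decoding

Three interchangeable binary classifiers over the 45°/135° labels:

- **svm** — scikit-learn `SVC(kernel="linear")`, C = 1.0 (a conventional
  default; exposed in config).
- **correlation** — nearest class-mean template by Pearson correlation.
- **lda** — pooled-covariance discriminant with identity shrinkage
  S = (1−λ)·S_pooled + λ·(tr S/p)·I, λ = 0.1, which keeps the direction
  defined when blocks ≪ voxels. Correlation and LDA are implemented in-repo
  and verified against brute-force evaluations of their stated decision
  rules.

Ties (zero decision value) break deterministically toward 45°. Within-type
decoding uses leave-one-run-out CV (10 folds × 2 test patterns).
Cross-type generalization offers two fold schemes: `all-blocks` (default —
train on every block of the training type; no leakage is possible because
train and test types never share a block) and `run-matched` (mirrors the
LORO folds for comparability). Both directions of each train/test pair are
computed and reported separately.

## Group inference

- **Chance distribution.** Per iteration, each participant's correct count
  is Binomial(n_runs·trials_per_run, 0.5); the group mean accuracy is
  recorded; the CI bounds are nearest-rank empirical 2.5th/97.5th
  percentiles. With the study's sizes the group-mean support is k/160 and
  the bounds equal the Binomial(160, 0.5) quantiles 0.425 and 0.575 exactly,
  for any seed — the discrete support absorbs the percentile-convention
  choice.
- **t-tests** are classical and two-tailed; zero-variance inputs yield a
  flagged 0 (at chance) or signed infinity (off chance) rather than an
  exception. Significance against chance uses p < 0.05/n_ROIs (default 5,
  i.e. p < 0.01, strict inequality).
- **Repeated-measures ANOVA** (1–2 within factors, balanced complete
  designs) is computed by statsmodels' AnovaRM; each effect is tested
  against its subject-by-effect interaction error term; no sphericity
  correction is applied. An in-repo sums-of-squares decomposition detects
  the 0/0 case (zero effect and zero error, e.g. noise-free constant data),
  flags the effect as degenerate and reports F = NaN; the test suite checks
  the F values against an independent hand-coded decomposition.
- **Percent signal change** is computed on un-z-scored data after dummy
  discard: 100 × (mean over the lag-shifted block window − mean over
  fixation volumes) / global run mean. The paired-t table corrects by
  Bonferroni across its cells (divisor configurable, default = number of
  ROI × contrast cells).

## QUEST psychophysics

The 2AFC observer responds correctly with probability

    Ψ(x) = γ + (1 − γ − δ)(1 − exp(−10^{β (x − T)}))

on log10 contrast x — the Watson–Pelli Weibull parameterization — with
γ = 0.5 (left/right guessing), δ = 0.01 lapse, β = 3.5. At x = T this gives
Ψ(T) = 0.5 + 0.49·(1 − e⁻¹) ≈ 0.8097, the criterion level that defines
"threshold" here. Adapted thresholds are T = t₀ + log10(elevation factor);
default factors {fast: parallel 2.0, orthogonal 1.2; slow: parallel 1.1,
orthogonal 1.6} encode the crossover hypothesis and are repo defaults, not
fitted values.

QUEST keeps a posterior over T on a uniform grid (−4…0 in 0.005 steps)
starting from a Gaussian prior (SD 1 log unit) centred on the observer's
unadapted ballpark; each trial is placed at the posterior mean (mode
available via config), clipped to the grid; the update multiplies the
posterior pointwise by the response likelihood under Ψ. Two staircases per
condition are interleaved trial-by-trial (40 trials each by default); the
estimate is the mean of the per-staircase posterior means. Elevation is
20·log10(threshold ratio) — the amplitude dB convention, so a factor-10
elevation is 20 dB; a `db_factor=10` switch gives the power convention.
Adaptation timing (initial and top-up adaptation durations) does not enter
the observer model; it is schedule metadata only.

## Validation suite: problem sizes and what passing shows

The end-to-end checks run at these sizes, chosen to keep the default test
run fast while leaving comfortable statistical margins: parameter recovery,
100 cohorts × 8 participants (V2 ROI, 100 voxels, LDA); null calibration,
200 zero-signal cohorts against a 3σ binomial band around the 5% rate;
shared-weight monotonicity, 5 weights × 10 common-seed cohorts; QUEST
recovery, 100 cohorts × 8 observers × 5 conditions at 40 trials/staircase.

A note on the recovery check: the group-mean transfer accuracy of a *null*
(unshared) condition is compared against the simulated 95% chance CI, whose
own coverage is ~95.5% under ideal independence — the criterion necessarily
sits near that knife-edge, and per-participant idiosyncrasies can only
lower coverage. Under the correlation classifier the two same-run test
blocks' outcomes are positively correlated (an interaction of within-run
z-scoring with per-pattern correlation normalization), over-dispersing the
null group means by ~8%; LDA and SVM are slightly under-dispersed and are
used for these checks.

What the synthetic data does **not** emulate: cortical geometry and
retinotopy (voxels are unordered features), spatial noise correlations,
physiological drift and motion artefacts, haemodynamic nonlinearity,
attention/adaptation dynamics within a session, and realistic
accuracy magnitudes (see calibration note above). Passing tests therefore
validate the *analysis machinery* — preprocessing arithmetic, fold
hygiene, classifier correctness, statistical calibration, recovery of
planted shared structure — not claims about real cortical data.

## Known limitations

- The generator's shared/distinct representation model is linear-additive;
  real streak signals may interact nonlinearly with direction signals.
- The chance simulation assumes trial-level independence; empirically,
  decoder outputs violate this mildly (see the dispersion note above),
  which is itself a caution when comparing real decoding accuracies against
  binomial chance bands.
- `run-matched` generalization reuses LORO folds but still trains on the
  full training type of the remaining runs; other schemes (e.g. split-half)
  are not implemented.
- Only balanced, complete within-subject designs are supported by
  `rm_anova`.
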