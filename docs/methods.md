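# Methods

## Scope and model

The package quantifies within-person concordance between continuous
subjective valence (1–9, neutral at 5, sampled at 1 Hz) and facial-EMG
envelope activity from the corrugator supercilii (CS) and zygomatic major
(ZM). The statistical core is a two-level linear mixed model with the
standardized EMG envelope as response, valence as predictor, and random
by-participant slopes and intercepts, fitted by maximum likelihood (not
REML). Fixed-slope inference uses one-tailed t-tests with m − l − 1 degrees
of freedom (m participants, l participant-level predictors), a deliberately
conservative level-2 rule: with 15 participants and no level-2 predictors
the df is 14, with 23 it is 22, regardless of the (thousands of) 1-s
observations. Directions are fixed a priori — CS negative, ZM positive —
and configurable for reuse.

## Envelope extraction

Raw surface EMG is broadband (20–400 Hz) activity whose amplitude envelope
tracks muscle activation. The pipeline, in fixed order:

1. **20 Hz low-cut filter.** 4th-order Butterworth high-pass applied
   forward–backward (zero phase). The realization is a design choice (only
   the cutoff is inherent to the procedure); zero-phase application is
   chosen so the envelope is not delayed against the rating clock.
2. **51-point moving-average subtraction (wearable only).** Centered window,
   shrunken (truncated) at the edges so length is preserved without padding
   artifacts. Applied before rectification, i.e. directly after filtering.
3. **Full-wave rectification** (absolute value).
4. **Epoching and 1000-ms binning**, aligned to stimulus onset; a trailing
   partial bin is dropped (the 1 Hz series should contain whole-second bins
   only). Samples inside annotated artifact intervals are excluded from bin
   averages; a bin with more than 50% of its samples excluded is marked
   missing. Machine-readable artifact intervals replace manual video review,
   making artifact excision reproducible.
5. **Baseline correction** subtracts each trial's mean rectified envelope
   over the full 10-s pre-stimulus window. The exergame mode has no baseline
   windows and skips this step entirely.
6. **Within-individual standardization** z-scores the concatenation of a
   participant's trials (per device × muscle), excluding missing bins, which
   stay missing. The SD convention is the sample SD (n − 1), declared in the
   processing log; downstream t statistics are invariant to the convention.
   Session-level concatenation is used in both modes (frames are not
   standardized individually).

Two properties pin the pipeline down: multiplying a raw recording by any
positive constant leaves the standardized output unchanged to 1e−9 (so the
generator's arbitrary µV scale cannot matter downstream), and trial
processing order cannot leak (per-trial outputs are independent of
processing order).

## Mixed-model estimation

For participant j, `y_j = X_j β + Z_j b_j + ε_j` with `Z_j = (1, x_j)`,
`b_j ~ N(0, Ψ)`, `ε ~ N(0, σ² I)`. β and σ² are profiled out analytically;
the profiled ML deviance is minimized over the relative covariance factor Λ
(Ψ = σ² Λ Λᵀ) in log-Cholesky coordinates, which guarantees a positive
semidefinite Ψ including boundary (singular) fits. Each deviance evaluation
reduces by the Woodbury identity to 2×2 algebra on per-group cross-products,
so cost is independent of observations per participant. Optimization is
deterministic: a fixed two-point L-BFGS-B multi-start (relative SDs 0.5 and
0.05, zero correlation; gradient tolerance 1e−8) followed by a Nelder–Mead
polish; the best value is kept and a fit is flagged non-converged unless the
chosen optimum came from (or ties with) a successful optimizer run. The
random-slope variable is centered internally for conditioning — the model
family is translation-equivariant and estimates are mapped back exactly, so
results are invariant to shifting the rating scale. Fits with σ̂² at its
floor are reported as boundary fits (e.g. exactly linear data). Standard
errors come from the observed information of the profiled GLS problem at
the optimum, `σ̂² (Σ Xᵀ V̂⁻¹ X)⁻¹`.

The tests require the fit to match statsmodels' `MixedLM` (ML) to 1e−3 in
slope and 1e−2 in log-likelihood across 20 film-preset datasets, and the
log-likelihood was additionally verified against a dense brute-force
evaluation of the marginal Gaussian likelihood. (statsmodels is given a
Powell-first optimizer sequence in that test; its default gradient
optimizers frequently stall on these surfaces at likelihoods tens of nats
below the optimum, which the dense evaluation confirms are inferior, not
alternative, optima.)

**Residuals and outliers.** Standardized residuals are conditional —
`(y − Xβ̂ − Z b̂_j)/σ̂` with BLUP `b̂_j` — by default; marginal residuals are
also available. Observations with |z| > 3 are removed and the model refit
with df unchanged (the participant count does not change). Removal that
would leave a participant with fewer than 3 observations retains that
participant's data with a warning. The "> 3 SD" reading of residual
screening is interpreted as |standardized residual| > 3.

**Covariate sensitivity.** A participant-level binary covariate (sex) can be
added to the fixed part; df becomes m − 1 − 1 and the report states whether
the slope's significance changes and the covariate's two-tailed p. Under a
null covariate its p-values are uniform to a KS check at α = 0.01 over 200
replicate fits.

**Lag choice.** Analysis is at zero lag; `cross_correlation` computes
Pearson r over integer-second lags on the overlapping support for checking
that zero lag is where concordance peaks.

## Synthetic-data generator

The generator is first-class, tested code that defines the study conditions
for every downstream check.

* **Latent valence** per trial is a discretized Ornstein–Uhlenbeck process
  at 1 Hz around a condition-specific mean, clipped to [1, 9]; lag-1
  autocorrelation is exp(−1/smoothness) with smoothness 10 s by default
  (slow, film-like affect drifts) and stationary SD 1.0. The film preset
  uses condition means 2.5/3.5/5/6.5/7.5 (very negative → very positive)
  and durations 138–205 s (mean ≈ 173 s); the exergame preset draws frames
  of 26.7 ± 8.9 s (minimum 8 s) filling a 600-s session around a mildly
  positive mean of 6.
* **Coupling** is linear on the standardized-envelope scale:
  `z(t) = (γ00 + u0j) + (γ10 + u1j)(v(t) − 5) + ε(t)`, matching the
  linearity the analysis assumes. Fixed slopes default to −0.20 (CS) and
  +0.15 (ZM) in the film preset and ∓0.03 in the exergame preset — the
  magnitude regimes of strong film-induced and subtle game-induced affect.
  Random-slope SDs default to 0.10 (film) and 0.06 (game), the scale implied
  by slope-to-SE ratios typical of such designs at m = 15 and 23; random-
  intercept SD 0.15, correlation 0. Residual envelope noise SD is 0.92 so
  the standardized-scale envelope has variance near 1 given the film
  preset's valence spread, making within-individual z-scoring nearly the
  identity on the latent scale.
* **Raw EMG** is amplitude-modulated band-limited Gaussian noise: carrier
  band 20–min(400, 0.45·fs) Hz (truncated below Nyquist at 500 Hz), with
  >95% of carrier power inside the band. The µV envelope is
  `amp · max(1 + 0.25·z, 0.05)` with amp = 30 µV — affine in z except at a
  rarely-hit positivity floor, so rectified-mean binning inverts it. Slow
  drift (low-passed random walk, 20 µV RMS, 1 Hz corner) is added and
  removed again by the 20 Hz low cut; baseline and inter-trial seconds use
  the same model with the valence term set to zero. Artifact bursts are
  broadband transients at 15× the resting amplitude inside Poisson-placed
  annotated intervals (exergame default 1.3/min × 3 s ≈ 6.5% of play time,
  the excision fraction typical of free-movement recording).
* **Ratings.** Overall ratings are truncated normals (SD 1, rounded,
  clipped to 1–9) around condition valence/arousal means; only their
  direction against the neutral midpoint matters downstream. Cued-recall
  traces are a 5-s smoothed, noise-perturbed (SD 0.5) copy of the on-line
  trace, giving the strong positive on-line/recall correlations the
  procedure presumes.
* **Determinism.** All randomness flows from one seed through spawned
  `SeedSequence` streams per participant/component; identical config + seed
  gives byte-identical datasets.

What the generator does not emulate: electrode placement and impedance,
muscle cross-talk, the device's quantitative noise floor, nonstationary
long-recording variance, or any nonlinear valence–EMG relationship. Passing
tests therefore demonstrate that the pipeline recovers what it assumes —
linear coupling under realistic noise, drift, and artifact structure — not
that real facial EMG obeys that model.

## Rating analyses

Overall ratings are tested against the neutral midpoint 5 with two-tailed
one-sample t-tests, Bonferroni-corrected by the number of tests (10 in the
film design: 5 conditions × 2 scales), corrected p clipped at 1. Zero-
variance ratings centered at 5 report t = 0; zero variance elsewhere is
rejected as degenerate. Recall validation computes per-participant Pearson r
between on-line and recalled traces (constant traces excluded and counted)
and tests the untransformed r values against zero per condition (a Fisher-z
variant was considered and omitted: the two-step procedure tests raw
coefficients). Sample-size planning finds the smallest n whose one-sample
t-test reaches the target power under a noncentral t with noncentrality
d·√n, by exhaustive integer scan to n = 1000 — exactness over closed-form
approximation at this scale.

## Problem sizes and numerical choices

The test suite runs the film preset at full scale (15 participants, 5 films,
two devices; ≈13k paired observations per muscle) and the exergame preset at
full scale (23 participants × 600 s), each in seconds on one CPU thanks to
the cross-product sufficient-statistics formulation. Oracle-equivalence uses
20 film-preset datasets; recovery studies use 100 replicates per muscle;
rating-test calibration uses 5000 null replicates. Tolerances: standardized
series must hit mean 0 / SD 1 to 1e−9; scale invariance to 1e−9; df values
are exact; the σ̂² floor is 1e−12 relative to response variance. The
group time-course for variable-length frames is truncated at the shortest
duration covering 90% of frames.

## Known limitations

* The mixed model supports exactly one random-slope variable (valence);
  crossed or nested extra random effects, REML, and Satterthwaite/
  Kenward–Roger df are out of scope.
* Bins are aligned to stimulus onset at integer-sample precision; event
  times are assumed accurate to one sample.
* The sex-covariate report treats the covariate as binary.
* Arousal is generated and tested against neutral but not modelled against
  EMG.
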