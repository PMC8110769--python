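# Methods

## Setting and conventions

Orientation lives on a 180°-periodic circle: a grating rotated by 180° is
the same stimulus. All differences between orientations are signed acute
angles in (−90°, 90°], computed as `d = (a − b) mod 180`, then `d − 180` if
`d > 90`; an exact 90° difference maps to +90° (the tie has measure zero in
data but needs a deterministic rule). The history variable Δ is always
*previous minus present*. An adjustment error with the same sign as Δ is a
bias toward the history orientation (attraction, positive amplitudes); the
opposite sign is repulsion. Representational momentum — displacement of the
report forward along an implied rotation — has the same signature as
repulsion in this convention, because the future state lies opposite the
previous one.

## Experimental designs emulated

- **E1/E2**: 4 blocks × 72 trials, conditions blocked and alternating with
  the starting condition drawn from the seed. Each trial shows six
  orientations; the first is drawn from {0°, 20°, …, 160°}; Rotational
  trials step by a fixed Δ ∈ ±{20°, 40°, 60°}; Random trials are shuffles
  of Rotational sequences that keep the final two stimuli (hence the
  per-Δ trial counts) and are redrawn until the shuffled sequence is not
  itself a constant rotation. E2 additionally samples per-stimulus
  positions uniformly in a disc of radius 3° around fixation; positions are
  metadata only and never enter the analysis.
- **E3**: 4 blocks × 80 trials, sequences of 4–12 stimuli, Δ ∈ ±{20°, 40°}.
  Random sequences replace every non-final stimulus farther than 40° from
  the target by one at 20° or 40° on the side of the trial's rotation
  direction, so the Random condition carries *more* same-side adaptors than
  the Rotational one — the design that dissociates momentum from
  adaptation.
- **Control trials**: 20% of E1/E2 trials terminate early (after 1–5
  stimuli); 16% of Rotational trials replace the final orientation with a
  random grid orientation that breaks the expected step. Quotas are
  realized per block by largest-remainder rounding: 0.20 × 288 = 57.6 is
  not an integer, so a default E1 session contains 58 early controls
  (79.86% full-length trials) and 23 rotation-break controls among 144
  Rotational trials (15.97%) — the closest achievable integer realizations.
  E3 keeps the rotation-break controls but has no early terminations
  (sequence length already varies by design).

Each Random block shuffles the source sequences generated for its paired
Rotational block. Consequently every Random trial's final-pair Δ equals its
Rotational source's Δ exactly; with control proportions set to zero the two
conditions' final-Δ multisets coincide exactly. With controls enabled the
analyzed (non-control) sets cannot match exactly, since rotation-break
controls randomize the final orientation in the Rotational condition only.

## Synthetic observer

The report is the target plus three additive bias terms, wrapped Gaussian
noise, and an optional lapse (uniform report, default rate 0):

- adaptation: `dog(Δ_stim; a_adapt, w_adapt)` of the immediately preceding
  stimulus (an option extends it to a decay-weighted sum over the whole
  sequence, for studying E3-style adaptor stacking);
- serial dependence: `dog(Δ_report; a_sd, w_sd)` of the *previous trial's
  report* — serial dependence follows decisions, not raw stimulation — with
  the chain resetting at block boundaries;
- momentum: a constant shift `−sign(Δ)·rm_shift` on non-control Rotational
  trials (constant rather than velocity-scaled: the designs use one
  rotation step per trial).

Defaults are the regime estimated from human data with this paradigm:
`a_adapt = −2.16°` peaking at 24°, `a_sd = +1.24°` peaking at 28°,
`rm_shift = 3°` (the approximate excess of the rotational over the random
repulsion), `noise_sd = 9°` (mean absolute error ≈ 7.4°, matching the
reported ≈ 9–11° range once biases and lapses are included), reaction times
lognormal with median 1.6 s. Noise is wrapped Gaussian rather than von
Mises; at σ ≤ 15° the two are indistinguishable and degrees stay the native
unit. `noise_sd = 0` is allowed as the exactly-noiseless limit used by
convergence tests.

What the simulator deliberately lacks: between-participant parameter
variability (all simulated observers share one parameter set, so group
t-statistics on synthetic data are much larger than human ones), attention
fluctuations, spatial-position effects on precision, and any interaction
between adaptation and serial dependence (the terms are additive). Passing
recovery tests therefore shows the *pipeline* is unbiased and calibrated,
not that the generative model captures human data.

## Preprocessing

Raw error = acute(reported − target). Outliers (one pass, raw errors): trials
whose error deviates from the participant's mean by strictly more than
3 SD, reaction times strictly below 0.5 s or above 10 s, and missing
reports. The trial immediately following an outlier is also removed, within
block only. Participants with an error SD above 30° are excluded (a uniform
guesser has SD 180/√12 ≈ 52°). Control trials, outliers and post-outlier
trials are then dropped, and errors are mean-corrected per participant ×
condition, computed on the retained trials. The previous-report predictor
is recomputed after filtering: a trial whose predecessor was removed has no
serial-dependence predictor by default (`chain_prev_report=True` instead
chains to the nearest earlier retained trial). Filtering is one-pass by
design: re-applying it to the clean table removes nothing (the 3-SD rule is
not iterated).

## DoG fit

`error = Δ·α·w·c·exp(−(wΔ)²)` with `c = √2/e^(−1/2)`, which makes the curve's
extremum, at Δ = 1/(√2 w), equal α exactly — so amplitude, peak bias and
"peak percentage" (100·|α| divided by the peak Δ) are all closed-form. The
fit minimizes trial-level SSE under box constraints α ∈ [−30, 30]°,
w ∈ [0.005, 0.20]/° (peak locations ≈ 3.5–141°, comfortably bracketing
empirically reported peaks of 23–28°; both bounds are arguments). Because
the model is linear in α at fixed w, α is profiled out in closed form
(clipped to its bounds) and the optimization reduces to a deterministic 1-D
search over w: a 25-point geometric grid, then bounded Brent refinement
around every local minimum of the grid profile. A dense exhaustive
(α, w) grid search is kept as an independent oracle and the fit is verified
never to end above it. Trials at Δ = 0 are excluded (the model is
identically zero there). Ill-posed inputs degrade gracefully
(`converged=False`) rather than raising mid-bootstrap.

## Inference

- **Stratified bootstrap** (default 5000 iterations): ⌊0.8·n_p⌋ trials per
  participant, *without* replacement (the scheme is a grand-subject
  subsampling rather than a classical bootstrap), pooled, refit. p = the
  proportion of resampled amplitudes on the side of zero opposite to the
  full-data amplitude's sign (one-sided by construction; a two-sided
  variant is exposed). Both the full-data fit and bootstrap mean/median are
  reported.
- **Permutation test** (default 10,000): condition labels shuffled
  trial-wise within participant; each permutation refits per label and
  records the amplitude difference; two-sided p. Since only labels move,
  all refits share one regressor matrix: the amplitude is profiled on a
  dense 64-point w-grid and whole permutation batches are evaluated as
  single matrix products, with the observed statistic going through the
  identical path — this is what makes 200-replicate calibration runs cheap.
  Measured type-I error at nominal 5% is ≈ 5–7%.
- **Model-free index**: mean error at Δ ∈ [+20°, +40°] minus mean error at
  Δ ∈ [−40°, −20°] per participant (|Δ| = 60° excluded), oriented so that
  positive = attraction. The literal subtraction order
  (negative-minus-positive, i.e. repulsion-positive) is available via
  `literal_sign=True`; the default orientation is the one under which
  attractive effects carry positive t-statistics. One-sample and paired
  t-tests with Cohen's d = mean/SD of the (difference) scores (= t/√n).
- **Dominance analysis**: on trials where both history Δs lie in the
  ±[20°, 40°] band (where the DoG is near-linear), errors are regressed on
  the *signs* of the two Δs (±1 coding, intercept included) inside the same
  stratified resampling scheme; the distribution of b(stimulus) −
  b(report) is kept per condition, along with both coefficient
  distributions. Note the raw difference is negative whenever either a
  repulsive stimulus effect or an attractive report effect dominates; the
  coefficient distributions themselves disambiguate which predictor carries
  the weight, and the directionality checks assert on those.
- **Control checks**: paired t-tests of per-participant mean |error| for
  early-control trials ending at the fifth stimulus vs full sequences, and
  for rotation-break controls vs complete Rotational trials, run on the
  unfiltered table.

## Numerical and reproducibility choices

Every stochastic operation takes an explicit seed or NumPy `Generator`; the
pipeline's master seed spawns fixed per-stage `SeedSequence` children so
stages rerun in isolation bit-identically. Boundary thresholds are strict
inequalities (exactly 3 SD, exactly 0.5 s/10 s are retained), matching the
filter definitions' wording ("larger than", "smaller than"). Degenerate
cases: zero-variance group tests report an infinite t with a warning;
resamples with collinear dominance predictors or fewer than 20 trials are
redrawn and logged; a session's block count must be even because conditions
alternate in pairs.

Problem sizes used by the test suite and the acceptance script — 100
recovery replicates at 14 × 288 trials, 200 calibration replicates at
6 × 288 with 500 permutations, 28-participant cohorts for the dominance
directionality checks (the double-band restriction keeps only ~13 trials
per participant, so the silent coefficient needs the larger cohort for a
usefully small sampling SE), 500–1000 bootstrap iterations — were chosen so
the whole battery runs in a few minutes on one CPU while keeping
Monte-Carlo error well below the margins being asserted.

## Known limitations

- The percentage rule (100·|α| / peak Δ) is reported as computed; published
  roundings of similar quantities do not always match it exactly.
- The dominance statistic mixes sign and magnitude; with opposite-sign
  effects the raw coefficient difference alone cannot say which history
  source "wins", which is why both coefficient distributions are retained.
- The generator preserves each Random trial's orientation multiset from its
  Rotational source; designs that only match Δ counts without reusing
  multisets would need a different shuffling rule.
- Lapses default to 0 in simulations; nonzero lapse rates inflate the noise
  floor and are screened (imperfectly) by the outlier rules, as in real
  data.
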