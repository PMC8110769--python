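# serialbias

Analysis pipeline for history biases in orientation-adjustment experiments:
**serial dependence** (attraction of the current report toward recently
*reported* orientations), **adaptation** (repulsion away from recently
*seen* orientations) and **representational momentum** (forward displacement
of reports along an implied rotational trajectory).

The package is aimed at visual psychophysicists running adjustment tasks in
which an observer reproduces the orientation of the last Gabor in a sequence
that unfolds either randomly or as a constant rotation. It provides, as
tested library code plus a thin CLI:

- generators for the three experimental designs (six-stimulus foveal
  sequences; the same sequences at random retinal locations; 4–12-stimulus
  noisy sequences with adaptor-stacked random controls);
- a synthetic observer with configurable adaptation, serial-dependence and
  momentum components, used to validate every stage by parameter recovery;
- circular error preprocessing (acute-angle errors, 3-SD outlier and
  reaction-time screening, participant exclusion, mean correction);
- the derivative-of-Gaussian (DoG) bias model with a constrained
  least-squares fit;
- stratified "grand-subject" bootstrap and label-permutation inference, a
  model-free ±Δ index with t-tests and effect sizes, a stimulus-vs-report
  dominance regression, and control-trial sanity checks.

## The model

Adjustment errors (reported − actual orientation, signed acute angle) are
modelled as a function of Δ, the acute difference between a history
orientation (previous stimulus, or previous trial's report) and the current
target, with the convention Δ = previous − present:

```
error(Δ) = Δ · α · w · c · exp(−(wΔ)²),   c = √2 / e^(−1/2)
```

The amplitude α (degrees) equals the curve's peak value, reached at
Δ = 1/(√2·w); w is the inverse curve width. Errors sharing the sign of Δ
indicate attraction toward the history orientation (α > 0), opposite signs
indicate repulsion (α < 0); in this convention representational momentum
appears as an extra repulsive displacement on rotational sequences. The fit
minimizes the trial-level sum of squared residuals under box constraints
(α ∈ [−30, 30]°, w ∈ [0.005, 0.20]/°). Group-level uncertainty comes from a
stratified bootstrap: 80% of each participant's trials, drawn without
replacement, pooled and refit, 5000 times; condition differences are tested
by shuffling condition labels within participant.

## Worked example

Simulate 14 participants of the foveal experiment with the default observer
(repulsive adaptation −2.16° peaking at Δ = 24°, serial dependence +1.24°
peaking at 28°, 3° momentum shift, 9° motor noise), preprocess, and fit:

```python
import serialbias as sb

spec = sb.DesignSpec.for_experiment(1)
table = sb.simulate_dataset(spec, 14, sb.ObserverParams(), seed=11)
clean, log = sb.preprocess(table)

for label, subset, predictor in [
        ("Random / previous stimulus",
         clean[clean.condition == "Random"], "delta_prev_stim"),
        ("Rotational / previous stimulus",
         clean[clean.condition == "Rotational"], "delta_prev_stim"),
        ("all / previous report", clean, "delta_prev_report")]:
    fit = sb.fit_dog(subset[predictor], subset["error"])
    print(f"{label}: alpha = {fit.alpha:+.2f} deg, "
          f"peak at {fit.peak_delta:.1f} deg ({fit.peak_percent:.1f}%)")

boot = sb.stratified_bootstrap_alpha(
    clean[clean.condition == "Rotational"], "prev_stim", n_iter=1000, seed=1)
print(f"Rotational bootstrap: alpha = {boot.alpha_point:+.2f} deg, "
      f"p = {boot.p_value:.4f}")
```

prints

```
Random / previous stimulus: alpha = -2.58 deg, peak at 22.1 deg (11.7%)
Rotational / previous stimulus: alpha = -5.31 deg, peak at 28.7 deg (18.5%)
all / previous report: alpha = +1.88 deg, peak at 23.2 deg (8.1%)
Rotational bootstrap: alpha = -5.31 deg, p = 0.0000
```

Random sequences show pure repulsive adaptation; adding rotational structure
roughly doubles the repulsion (momentum pushes reports forward, away from
the previous orientation); the previous trial's *report* attracts. The
bootstrap p-value is the fraction of resampled amplitudes crossing zero.

The same pipeline runs from the shell:

```
serialbias simulate --participants 14 --seed 11 --out trials.csv
serialbias preprocess --in trials.csv --out clean.csv
serialbias fit --in clean.csv --predictor prev_report
serialbias all --quick --outdir run/      # full report.json in one step
```

External datasets in the trial-table CSV schema (one row per trial, a
semicolon-joined orientation sequence, reported orientation, reaction time
and control flags) are read with `sb.read_trials(path, column_map=...)`,
where the column map adapts foreign header names.

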