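"""Synthetic adjustment-response observer for end-to-end pipeline validation.

The observer reports the target orientation corrupted by three configurable
history biases plus wrapped Gaussian motor noise and occasional lapses:

* **adaptation** — a DoG-shaped bias as a function of the acute difference
  between the preceding stimulus in the sequence and the target (negative
  amplitude = repulsion away from the recent stimulus, the usual aftereffect
  direction);
* **serial dependence** — a DoG-shaped bias toward the orientation
  *reported* on the previous trial (positive amplitude = attraction), since
  serial dependence follows perceptual decisions rather than raw stimulation;
* **representational momentum** — a constant forward displacement along the
  implied trajectory on non-control Rotational trials, i.e. away from the
  previous orientation (entering the error-vs-delta curve with negative
  sign, like repulsion).

Default parameter values put the simulated observer in the regime estimated
from human data with this paradigm: repulsion of about 2.2 degrees peaking
near delta 24, serial dependence of about 1.2 degrees peaking near 28, a
3-degree momentum shift, 9-degree response noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (DesignSpec, TrialSequence, ROTATIONAL, make_session)
from .dog import dog
from .preprocessing import acute_diff, join_orientations, wrap_orientation

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


def w_for_peak(peak_delta: float) -> float:
    """Inverse width placing the DoG peak at the given delta (degrees)."""
    return 1.0 / (SQRT2 * peak_delta)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic observer (degrees unless noted)."""

    a_adapt: float = -2.16          # adaptation amplitude; < 0 repels
    w_adapt: float = w_for_peak(24.0)   # 1/deg
    a_sd: float = 1.24              # serial-dependence amplitude; > 0 attracts
    w_sd: float = w_for_peak(28.0)      # 1/deg
    rm_shift: float = 3.0           # forward displacement on Rotational trials
    noise_sd: float = 9.0           # wrapped Gaussian response noise SD (0 = noiseless)
    lapse_rate: float = 0.0         # probability of a uniform random report
    adapt_all_stimuli: bool = False  # extend adaptation over the whole sequence
    adapt_decay: float = 0.5        # per-lag weight when adapt_all_stimuli

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0 (0 is the noiseless limit)")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.w_adapt <= 0 or self.w_sd <= 0:
            raise ValueError("w parameters must be > 0")

    @classmethod
    def null(cls, noise_sd: float = 9.0) -> "ObserverParams":
        """Bias-free observer: noise only."""
        return cls(a_adapt=0.0, a_sd=0.0, rm_shift=0.0, noise_sd=noise_sd)


def simulate_response(trial: TrialSequence, prev_report: float | None,
                      params: ObserverParams, rng: np.random.Generator
                      ) -> float:
    """One adjustment report for a trial, wrapped to [0, 180).

    ``prev_report`` is the orientation reported on the previous trial (None
    on a session's or block's first trial, in which case the serial-
    dependence term is omitted).
    """
    if trial.n_stimuli < 1:
        raise ValueError("trial must contain at least one stimulus")
    if params.lapse_rate > 0 and rng.uniform() < params.lapse_rate:
        return float(rng.uniform(0.0, 180.0))
    target = trial.orientations[-1]
    report = target

    if trial.n_stimuli >= 2 and params.a_adapt != 0:
        if params.adapt_all_stimuli:
            for lag, prev in enumerate(reversed(trial.orientations[:-1]), start=1):
                weight = params.adapt_decay ** (lag - 1)
                report += weight * dog(acute_diff(prev, target),
                                       params.a_adapt, params.w_adapt)
        else:
            d_stim = acute_diff(trial.orientations[-2], target)
            report += dog(d_stim, params.a_adapt, params.w_adapt)

    if prev_report is not None and params.a_sd != 0:
        d_rep = acute_diff(prev_report, target)
        report += dog(d_rep, params.a_sd, params.w_sd)

    if (trial.condition == ROTATIONAL and not trial.is_early_control
            and not trial.is_rotation_break_control and trial.n_stimuli >= 2
            and params.rm_shift != 0):
        # forward along the trajectory = away from the previous orientation
        report -= math.copysign(params.rm_shift, trial.rotation_delta)

    report += rng.normal(0.0, params.noise_sd)
    return wrap_orientation(report)


def simulate_session(trials: list[TrialSequence], params: ObserverParams,
                     rng: np.random.Generator, block_size: int,
                     rt_median: float = 1.6, rt_sigma: float = 0.3
                     ) -> list[tuple[float, float]]:
    """Responses and lognormal reaction times for an ordered trial list.

    The serial-dependence term chains across consecutive trials within a
    block; the chain resets at block boundaries.
    """
    out = []
    prev_report: float | None = None
    for i, trial in enumerate(trials):
        if block_size and i % block_size == 0:
            prev_report = None
        report = simulate_response(trial, prev_report, params, rng)
        rt = float(rng.lognormal(math.log(rt_median), rt_sigma))
        out.append((report, rt))
        prev_report = report
    return out


def simulate_dataset(spec: DesignSpec, n_participants: int,
                     params: ObserverParams | None = None,
                     seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Simulate full sessions for several participants as a trial table.

    One independent session per participant (independent sub-streams of the
    seed), responses generated sequentially so the serial-dependence term
    chains across trials.  Returns the trial-table schema used by the
    preprocessing stage.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    params = params or ObserverParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rows = []
    for p, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        trials = make_session(spec, rng)
        responses = simulate_session(trials, params, rng,
                                     block_size=spec.trials_per_block)
        pid = f"p{p + 1:02d}"
        for i, (trial, (report, rt)) in enumerate(zip(trials, responses)):
            block = i // spec.trials_per_block
            rows.append({
                "participant": pid,
                "experiment": trial.experiment,
                "condition": trial.condition,
                "block": block,
                "trial": i - block * spec.trials_per_block,
                "n_stimuli": trial.n_stimuli,
                "orientations": join_orientations(trial.orientations),
                "target": trial.target,
                "reported": report,
                "rt": rt,
                "rotation_delta": trial.rotation_delta,
                "is_early_control": trial.is_early_control,
                "is_rotation_break_control": trial.is_rotation_break_control,
            })
    return pd.DataFrame(rows)
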