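"""Stimulus-sequence generators for the three adjustment experiments.

Each trial presents a sequence of oriented Gabor patches and the observer
reproduces the orientation of the last one (the *target*).  Sequences come
in two conditions:

``Rotational``
    consecutive orientations differ by a fixed signed step (the rotation
    delta), mimicking constant rotational motion;
``Random``
    a shuffle of a Rotational sequence that keeps the final pair (and hence
    the per-delta trial counts) but destroys the temporal structure.

Experiments 1 and 2 use six-stimulus sequences with rotation steps of
+/-{20, 40, 60} degrees; Experiment 2 additionally places each stimulus at a
random location within 3 degrees of fixation (metadata only, the analysis is
location-blind).  Experiment 3 uses 4-12 stimulus sequences with steps of
+/-{20, 40} and Random sequences whose off-range stimuli are replaced by
extra same-side adaptors near the target, deliberately stacking adaptation
against the rotation effect.

All angles are degrees on the 180-degree orientation circle, and the delta
convention is ``previous - present``: a Rotational trial with stored delta d
steps each orientation by ``-d``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import (acute_diff, join_orientations, wrap_orientation)

logger = logging.getLogger(__name__)

FIRST_ORIENTATIONS = tuple(float(x) for x in range(0, 161, 20))
ROTATIONAL = "Rotational"
RANDOM = "Random"

_MAX_SHUFFLE_TRIES = 100


@dataclass(frozen=True)
class TrialSequence:
    """One trial's ordered stimulus orientations plus condition metadata."""

    orientations: tuple[float, ...]
    condition: str                      # Rotational | Random
    experiment: str = "E1"              # E1 | E2 | E3
    rotation_delta: float | None = None  # fixed within-trial step (prev - present);
                                         # for Random trials, the preserved final-pair delta
    is_early_control: bool = False
    is_rotation_break_control: bool = False
    locations: tuple[tuple[float, float], ...] | None = None  # E2 metadata

    @property
    def n_stimuli(self) -> int:
        return len(self.orientations)

    @property
    def target(self) -> float:
        return self.orientations[-1]

    @property
    def delta_prev_stim(self) -> float:
        """Acute difference between the penultimate stimulus and the target."""
        if self.n_stimuli < 2:
            return math.nan
        return acute_diff(self.orientations[-2], self.orientations[-1])

    def consecutive_deltas(self) -> np.ndarray:
        """Signed acute differences previous - present along the sequence."""
        o = np.asarray(self.orientations)
        return acute_diff(o[:-1], o[1:])


@dataclass(frozen=True)
class DesignSpec:
    """Session layout of one experiment."""

    experiment: str = "E1"
    n_blocks: int = 4
    trials_per_block: int = 72
    p_early_control: float = 0.20
    p_rotation_break_control: float = 0.16
    delta_set: tuple[float, ...] = (-60.0, -40.0, -20.0, 20.0, 40.0, 60.0)
    sequence_length_range: tuple[int, int] = (6, 6)

    def __post_init__(self):
        if not 0.0 <= self.p_early_control <= 1.0:
            raise ValueError("p_early_control must lie in [0, 1]")
        if not 0.0 <= self.p_rotation_break_control <= 1.0:
            raise ValueError("p_rotation_break_control must lie in [0, 1]")
        if any(d == 0 for d in self.delta_set):
            raise ValueError("delta 0 is excluded: no rotation, incompatible "
                             "with constant rotational motion")
        if self.n_blocks % 2:
            raise ValueError("n_blocks must be even (conditions are blocked "
                             "and counterbalanced in pairs)")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @classmethod
    def for_experiment(cls, experiment: int | str, **overrides) -> "DesignSpec":
        """Default session layout of experiment 1, 2 or 3."""
        key = str(experiment).upper().lstrip("E")
        if key in ("1", "2"):
            base = dict(experiment=f"E{key}")
        elif key == "3":
            base = dict(experiment="E3", trials_per_block=80,
                        p_early_control=0.0,
                        delta_set=(-40.0, -20.0, 20.0, 40.0),
                        sequence_length_range=(4, 12))
        else:
            raise ValueError(f"unknown experiment {experiment!r}")
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# single-trial constructors
# ---------------------------------------------------------------------------

def make_rotational_trial(first_orientation: float, delta: float,
                          n_stimuli: int, experiment: str = "E1",
                          ) -> TrialSequence:
    """Constant-rotation sequence: orientation k is ``first - k*delta`` (mod 180).

    ``delta`` is the fixed previous-minus-present step, so a positive delta
    rotates the sequence in the negative orientation direction.
    """
    if n_stimuli < 2:
        raise ValueError("a rotational trial needs at least 2 stimuli")
    if delta == 0:
        raise ValueError("delta = 0 is not a rotation")
    ks = np.arange(n_stimuli)
    oris = wrap_orientation(first_orientation - ks * delta)
    return TrialSequence(tuple(float(o) for o in oris), ROTATIONAL,
                         experiment=experiment, rotation_delta=float(delta))


def make_random_trial(rotational: TrialSequence, rng: np.random.Generator
                      ) -> TrialSequence:
    """Shuffle a Rotational sequence, preserving the final two stimuli.

    The orientation multiset and the last-pair delta are unchanged (so the
    per-delta trial counts match across conditions), while permutations whose
    consecutive deltas are all equal are rejected and redrawn, removing the
    temporal structure.
    """
    if rotational.condition != ROTATIONAL or rotational.is_early_control \
            or rotational.is_rotation_break_control:
        raise ValueError("make_random_trial needs a non-control Rotational trial")
    n = rotational.n_stimuli
    if n < 4:
        raise ValueError("sequences shorter than 4 stimuli cannot be shuffled "
                         "while preserving the final pair")
    oris = np.asarray(rotational.orientations)
    for _ in range(_MAX_SHUFFLE_TRIES):
        head = rng.permutation(oris[:-2])
        seq = np.concatenate([head, oris[-2:]])
        deltas = acute_diff(seq[:-1], seq[1:])
        if not np.allclose(deltas, deltas[0]):
            return dataclasses.replace(
                rotational, orientations=tuple(float(o) for o in seq),
                condition=RANDOM)
    raise RuntimeError("could not find a non-rotational permutation in "
                       f"{_MAX_SHUFFLE_TRIES} tries")


def make_exp3_random_trial(rotational: TrialSequence, rng: np.random.Generator
                           ) -> TrialSequence:
    """Experiment-3 Random sequence with stacked same-side adaptors.

    Starting from a shuffle (final pair preserved), every earlier stimulus
    lying more than 40 degrees from the target is replaced by one at 20 or
    40 degrees on the same side as the trial's rotation delta, so Random
    sequences carry at least as many near-target adaptors as their
    Rotational source, all tilted in the rotation direction.
    """
    shuffled = make_random_trial(rotational, rng)
    seq = list(shuffled.orientations)
    target = seq[-1]
    side = math.copysign(1.0, shuffled.rotation_delta)
    changed = False
    for i in range(len(seq) - 2):
        if abs(acute_diff(seq[i], target)) > 40.0:
            seq[i] = wrap_orientation(target + side * rng.choice([20.0, 40.0]))
            changed = True
    if not changed:
        return shuffled
    return dataclasses.replace(shuffled, orientations=tuple(seq))


def count_adaptors(trial: TrialSequence, max_delta: float = 40.0) -> int:
    """Number of non-target stimuli within ``max_delta`` degrees of the target."""
    target = trial.orientations[-1]
    return int(sum(abs(acute_diff(o, target)) <= max_delta
                   for o in trial.orientations[:-1]))


# ---------------------------------------------------------------------------
# session construction
# ---------------------------------------------------------------------------

def _largest_remainder_counts(quota: float, n_cells: int) -> list[int]:
    """Integer counts per cell whose total is the rounded total quota."""
    base = math.floor(quota)
    counts = [base] * n_cells
    extra = round(quota * n_cells) - base * n_cells
    for i in range(extra):
        counts[i % n_cells] += 1
    return counts


def _random_location(rng: np.random.Generator, radius: float = 3.0
                     ) -> tuple[float, float]:
    # uniform over a disc of the given radius (degrees of visual angle)
    r = radius * math.sqrt(rng.uniform())
    th = rng.uniform(0.0, 2.0 * math.pi)
    return (r * math.cos(th), r * math.sin(th))


def make_session(spec: DesignSpec, rng: np.random.Generator
                 ) -> list[TrialSequence]:
    """Generate a full session of ``spec.n_trials`` trials.

    Conditions alternate block-wise (starting condition counterbalanced by
    the random stream).  Each Random block shuffles the stimulus sequences
    generated for its paired Rotational block, so every Random trial has a
    Rotational source with the same orientation multiset and final-pair
    delta.  Early-termination controls (sequence cut after 1-5 stimuli) and
    rotation-break controls (random final orientation, Rotational condition
    only) are realized per block by deterministic largest-remainder rounding
    of the nominal proportions, then placed at shuffled positions.
    """
    n_pairs = spec.n_blocks // 2
    first_cond = rng.choice([ROTATIONAL, RANDOM])
    block_conditions = [first_cond if b % 2 == 0 else
                        (RANDOM if first_cond == ROTATIONAL else ROTATIONAL)
                        for b in range(spec.n_blocks)]

    early_counts = _largest_remainder_counts(
        spec.p_early_control * spec.trials_per_block, n_pairs)
    break_counts = _largest_remainder_counts(
        spec.p_rotation_break_control * spec.trials_per_block, n_pairs)

    lo, hi = spec.sequence_length_range
    sources: list[list[TrialSequence]] = []
    for _ in range(n_pairs):
        pair_sources = []
        for _ in range(spec.trials_per_block):
            first = rng.choice(FIRST_ORIENTATIONS)
            delta = rng.choice(spec.delta_set)
            n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            pair_sources.append(make_rotational_trial(
                first, delta, n, experiment=spec.experiment))
        sources.append(pair_sources)

    trials: list[TrialSequence] = []
    pair_index = {ROTATIONAL: 0, RANDOM: 0}
    for cond in block_conditions:
        k = pair_index[cond]
        pair_index[cond] += 1
        block = _make_block(spec, cond, sources[k], early_counts[k],
                            break_counts[k], rng)
        trials.extend(block)
    return trials


def _make_block(spec: DesignSpec, condition: str,
                sources: list[TrialSequence], n_early: int, n_break: int,
                rng: np.random.Generator) -> list[TrialSequence]:
    tpb = spec.trials_per_block
    slots = rng.permutation(tpb)
    early_slots = set(slots[:n_early].tolist())
    break_slots = set(slots[n_early:n_early + n_break].tolist()) \
        if condition == ROTATIONAL else set()

    block = []
    for i, source in enumerate(sources):
        if condition == ROTATIONAL:
            trial = source
            if i in break_slots:
                trial = _break_rotation(trial, rng)
        else:
            if spec.experiment == "E3":
                trial = make_exp3_random_trial(source, rng)
            else:
                trial = make_random_trial(source, rng)
        if i in early_slots:
            cut = int(rng.integers(1, min(6, trial.n_stimuli)))
            trial = dataclasses.replace(
                trial, orientations=trial.orientations[:cut],
                is_early_control=True)
        if spec.experiment == "E2":
            trial = dataclasses.replace(
                trial, locations=tuple(_random_location(rng)
                                       for _ in range(trial.n_stimuli)))
        block.append(trial)
    return block


def _break_rotation(trial: TrialSequence, rng: np.random.Generator
                    ) -> TrialSequence:
    """Replace the last orientation with a random one off the expected step."""
    expected = trial.orientations[-1]
    while True:
        last = float(rng.choice(FIRST_ORIENTATIONS))
        if not math.isclose(acute_diff(last, expected), 0.0):
            break
    return dataclasses.replace(
        trial, orientations=trial.orientations[:-1] + (last,),
        is_rotation_break_control=True)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def session_to_frame(trials: list[TrialSequence], participant="p01",
                     block_size: int | None = None) -> pd.DataFrame:
    """Serialize trials into the trial-table schema (without responses)."""
    rows = []
    for i, t in enumerate(trials):
        block = i // block_size if block_size else 0
        rows.append({
            "participant": participant,
            "experiment": t.experiment,
            "condition": t.condition,
            "block": block,
            "trial": i - block * block_size if block_size else i,
            "n_stimuli": t.n_stimuli,
            "orientations": join_orientations(t.orientations),
            "target": t.target,
            "reported": np.nan,   # filled by an observer (human or simulated)
            "rt": np.nan,
            "rotation_delta": t.rotation_delta,
            "is_early_control": t.is_early_control,
            "is_rotation_break_control": t.is_rotation_break_control,
        })
    return pd.DataFrame(rows)
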