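"""Circular orientation arithmetic, error computation, trial filtering and table I/O.

The interchange format of the whole pipeline is the *trial table*: a tidy
:class:`pandas.DataFrame` with one row per trial, ordered by participant,
block and trial index.  Orientations live on the 180-degree-periodic circle
(a Gabor patch rotated by 180 degrees is the same stimulus), so every
difference between two orientations is taken as the signed acute angle in
``(-90, 90]``.

Sign convention used throughout: ``delta = previous - present``.  An error
with the same sign as delta is a bias *toward* the previous orientation
(attractive, positive); opposite signs mean repulsion.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ORIENTATION_PERIOD = 180.0

#: Mandatory columns of the trial-table CSV schema.
REQUIRED_COLUMNS = (
    "participant",
    "condition",
    "block",
    "trial",
    "orientations",
    "reported",
    "rt",
    "is_early_control",
    "is_rotation_break_control",
)

#: Default filtering thresholds (overridable in every entry point).
OUTLIER_SD_CRITERION = 3.0      # |error - participant mean| > 3 SD
RT_MIN_S = 0.5                  # reaction times strictly below are outliers
RT_MAX_S = 10.0                 # reaction times strictly above are outliers
PARTICIPANT_SD_EXCLUSION = 30.0  # error SD above this excludes the participant


class SchemaError(ValueError):
    """Raised when a trial-table file does not conform to the CSV schema."""


# ---------------------------------------------------------------------------
# circular arithmetic
# ---------------------------------------------------------------------------

def acute_diff(a, b):
    """Signed acute difference ``a - b`` on the 180-degree orientation circle.

    Returns values in ``(-90, 90]``; an exact 90-degree difference maps to
    ``+90``.  Accepts scalars or array-likes (broadcast like numpy).

    >>> acute_diff(10, 170)
    20.0
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float),
               ORIENTATION_PERIOD)
    out = np.where(d > 90.0, d - ORIENTATION_PERIOD, d)
    if out.ndim == 0:
        return float(out)
    return out


def wrap_orientation(x):
    """Wrap angles to the canonical orientation range ``[0, 180)``."""
    out = np.mod(np.asarray(x, dtype=float), ORIENTATION_PERIOD)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# sequence-string helpers
# ---------------------------------------------------------------------------

def join_orientations(orientations: Iterable[float]) -> str:
    return ";".join(f"{float(o):.10g}" for o in orientations)


def split_orientations(s: str) -> np.ndarray:
    return np.asarray([float(tok) for tok in str(s).split(";")], dtype=float)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trials(path, column_map: Mapping[str, str] | str | Path | None = None
                ) -> pd.DataFrame:
    """Read a trial-table CSV, optionally remapping external column names.

    Parameters
    ----------
    path:
        CSV file (UTF-8, header row, ``.`` decimal, ``;`` inside the
        orientation-sequence field).
    column_map:
        Either a mapping ``{external_name: schema_name}`` or the path of a
        YAML file containing one.  Used to adapt externally deposited data
        to the native schema.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message path
        raise SchemaError(f"could not parse {path!r} as a CSV trial table: {exc}")
    if column_map is not None:
        if isinstance(column_map, (str, Path)):
            with open(column_map) as fh:
                column_map = yaml.safe_load(fh)
        table = table.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(
            "trial table is missing mandatory columns: " + ", ".join(missing))
    for col in ("is_early_control", "is_rotation_break_control"):
        table[col] = table[col].astype(bool)
    table = table.sort_values(["participant", "block", "trial"],
                              kind="stable").reset_index(drop=True)
    if "target" not in table.columns:
        table["target"] = [split_orientations(s)[-1] for s in table["orientations"]]
    return table


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (inverse of :func:`read_trials`)."""
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# error computation
# ---------------------------------------------------------------------------

def compute_errors(table: pd.DataFrame) -> pd.DataFrame:
    """Add raw adjustment errors and history predictors to a trial table.

    Adds columns:

    ``error``
        acute difference ``reported - target`` (raw; mean correction is
        applied later, on the retained trials only).
    ``delta_prev_stim``
        acute difference between the second-to-last stimulus of the
        sequence and the target (``NaN`` for one-stimulus sequences).
    ``delta_prev_report``
        acute difference between the previous trial's reported orientation
        and the current target, taken over immediately adjacent trials of
        the same participant and block.  Recomputed on the filtered table
        by :func:`clean_trials`, where removed trials break the chain.
    ``missing_report``
        flag for rows whose report is absent; they are kept (and later
        marked as outliers) rather than silently dropped.
    """
    table = table.copy()
    seqs = [split_orientations(s) for s in table["orientations"]]
    target = np.asarray([s[-1] for s in seqs])
    table["target"] = target
    table["n_stimuli"] = [len(s) for s in seqs]
    reported = pd.to_numeric(table["reported"], errors="coerce").to_numpy()
    table["missing_report"] = ~np.isfinite(reported)
    if table["missing_report"].any():
        logger.warning("%d trials have missing reports; flagged, not dropped",
                       int(table["missing_report"].sum()))
    table["error"] = acute_diff(reported, target)
    table["delta_prev_stim"] = [
        acute_diff(s[-2], s[-1]) if len(s) >= 2 else np.nan for s in seqs]
    table["delta_prev_report"] = _delta_prev_report(table, require_adjacent=True)
    return table


def _delta_prev_report(table: pd.DataFrame, require_adjacent: bool) -> np.ndarray:
    """Previous-report predictor within participant and block.

    With ``require_adjacent`` the previous row must hold the immediately
    preceding trial index; otherwise the nearest earlier row of the block is
    used (chaining across gaps left by removed trials).
    """
    grouped = table.groupby(["participant", "block"], sort=False)
    prev_report = pd.to_numeric(grouped["reported"].shift(1),
                                errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(prev_report)
    if require_adjacent:
        prev_trial = grouped["trial"].shift(1).to_numpy(dtype=float)
        ok &= table["trial"].to_numpy(dtype=float) == prev_trial + 1
    target = table["target"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(ok, acute_diff(prev_report, target), np.nan)
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def flag_outliers(table: pd.DataFrame,
                  sd_criterion: float = OUTLIER_SD_CRITERION,
                  rt_min: float = RT_MIN_S,
                  rt_max: float = RT_MAX_S) -> pd.DataFrame:
    """Mark outlier trials and the trials immediately following them.

    A trial is an outlier when its error deviates from the participant's
    mean by strictly more than ``sd_criterion`` standard deviations (one
    pass, raw errors), when its reaction time is strictly below ``rt_min``
    or strictly above ``rt_max`` seconds, or when the report is missing.
    ``post_outlier`` is set on the next trial of the same block; the first
    trial of a block never inherits an outlier from the previous block.
    """
    table = table.copy()
    err = pd.to_numeric(table["error"], errors="coerce")
    counts = err.notna().groupby(table["participant"]).transform("sum")
    low = counts < 10
    if low.any():
        for pid in table.loc[low, "participant"].unique():
            logger.warning("participant %r has fewer than 10 usable trials", pid)
    by_part = err.groupby(table["participant"])
    mu = by_part.transform("mean")
    sd = by_part.transform(lambda e: e.std(ddof=1))
    dev = (err - mu).abs()
    is_out = ((sd > 0) & (dev > sd_criterion * sd)).to_numpy(dtype=bool)
    rt = pd.to_numeric(table["rt"], errors="coerce").to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        is_out |= (rt < rt_min) | (rt > rt_max)
    is_out |= ~np.isfinite(err.to_numpy(dtype=float))
    table["is_outlier"] = is_out

    grouped = table.groupby(["participant", "block"], sort=False)
    prev_out = grouped["is_outlier"].shift(1, fill_value=False)
    prev_trial = grouped["trial"].shift(1).to_numpy(dtype=float)
    adjacent = table["trial"].to_numpy(dtype=float) == prev_trial + 1
    table["post_outlier"] = prev_out.to_numpy(dtype=bool) & adjacent
    return table


def exclude_participants(table: pd.DataFrame,
                         sd_threshold: float = PARTICIPANT_SD_EXCLUSION
                         ) -> tuple[pd.DataFrame, list]:
    """Drop participants whose raw error SD exceeds ``sd_threshold`` degrees.

    Returns the reduced table and the list of excluded participant ids.
    """
    excluded = []
    for pid, grp in table.groupby("participant", sort=False):
        e = grp["error"].to_numpy(dtype=float)
        e = e[np.isfinite(e)]
        if len(e) > 1 and np.std(e, ddof=1) > sd_threshold:
            excluded.append(pid)
    if excluded:
        logger.info("excluding participants with error SD > %g deg: %r",
                    sd_threshold, excluded)
        table = table[~table["participant"].isin(excluded)].copy()
    return table, excluded


def clean_trials(table: pd.DataFrame, chain_prev_report: bool = False
                 ) -> pd.DataFrame:
    """Remove control trials, outliers and post-outlier trials.

    ``delta_prev_report`` is recomputed on the retained trials: by default a
    trial whose predecessor was removed has no previous-report predictor;
    with ``chain_prev_report`` the nearest earlier retained trial of the
    same block is used instead.
    """
    keep = (~table["is_early_control"]
            & ~table["is_rotation_break_control"]
            & ~table["is_outlier"]
            & ~table["post_outlier"])
    clean = table[keep].copy()
    clean["delta_prev_report"] = _delta_prev_report(
        clean, require_adjacent=not chain_prev_report)
    return clean


def mean_correct(table: pd.DataFrame,
                 by: tuple[str, ...] = ("participant", "condition")
                 ) -> pd.DataFrame:
    """Subtract the per-group mean error (default: participant x condition)."""
    table = table.copy()
    table["error"] = table["error"] - table.groupby(list(by))["error"].transform("mean")
    return table


def preprocess(table: pd.DataFrame,
               sd_criterion: float = OUTLIER_SD_CRITERION,
               rt_min: float = RT_MIN_S,
               rt_max: float = RT_MAX_S,
               participant_sd_threshold: float = PARTICIPANT_SD_EXCLUSION,
               chain_prev_report: bool = False
               ) -> tuple[pd.DataFrame, dict]:
    """Full preprocessing chain: errors -> outliers -> exclusion -> clean -> mean-correct.

    Returns the clean table and a run-log dictionary (excluded participants,
    outlier counts and rates).
    """
    table = compute_errors(table)
    table = flag_outliers(table, sd_criterion, rt_min, rt_max)
    table, excluded = exclude_participants(table, participant_sd_threshold)
    n_outliers = int(table["is_outlier"].sum())
    clean = clean_trials(table, chain_prev_report=chain_prev_report)
    clean = mean_correct(clean)
    log = {
        "excluded_participants": list(excluded),
        "n_trials": int(len(table)),
        "n_outliers": n_outliers,
        "outlier_rate": n_outliers / len(table) if len(table) else 0.0,
        "n_clean": int(len(clean)),
    }
    return clean, log
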