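"""Group-level inference on adjustment-error biases.

Implements the statistics applied to the clean trial table: stratified
bootstrap of the DoG amplitude (the "grand subject" scheme: a fixed fraction
of trials per participant, sampled without replacement, pooled and refit),
condition-label permutation tests on the amplitude difference, the
model-free +/-delta bias index with one-sample / paired t-tests, the
regression-based dominance analysis of stimulus history versus report
history, and the control-trial sanity checks.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dog import (DEFAULT_ALPHA_BOUNDS, DEFAULT_W_BOUNDS, DoGFitResult,
                  fit_dog)

logger = logging.getLogger(__name__)

PREDICTOR_COLUMNS = {
    "prev_stim": "delta_prev_stim",
    "prev_report": "delta_prev_report",
}

MODEL_FREE_DELTA_RANGE = (20.0, 40.0)  # |delta| band of the model-free index
MIN_FIT_TRIALS = 20


def _predictor_column(predictor: str) -> str:
    try:
        return PREDICTOR_COLUMNS[predictor]
    except KeyError:
        raise ValueError(f"unknown predictor {predictor!r}; expected one of "
                         f"{sorted(PREDICTOR_COLUMNS)}")


def _usable(table: pd.DataFrame, predictor: str) -> pd.DataFrame:
    col = _predictor_column(predictor)
    d = pd.to_numeric(table[col], errors="coerce")
    e = pd.to_numeric(table["error"], errors="coerce")
    ok = np.isfinite(d) & np.isfinite(e) & (d != 0)
    return table.loc[ok]


# ---------------------------------------------------------------------------
# stratified bootstrap of the DoG amplitude
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    """Distribution of the DoG amplitude over stratified resamples."""

    alphas: np.ndarray          # one amplitude per resample
    n_iter: int
    frac: float                 # fraction of trials resampled per participant
    p_value: float              # one-sided sign test against zero (see below)
    alpha_point: float          # amplitude of the full-data fit
    w_point: float
    point_fit: DoGFitResult

    @property
    def alpha_mean(self) -> float:
        return float(np.mean(self.alphas))

    @property
    def alpha_median(self) -> float:
        return float(np.median(self.alphas))

    def p_two_sided(self) -> float:
        """Two-sided variant: twice the smaller tail proportion, capped at 1."""
        below = float(np.mean(self.alphas < 0))
        above = float(np.mean(self.alphas > 0))
        return min(1.0, 2.0 * min(below, above))


def stratified_bootstrap_alpha(table: pd.DataFrame, predictor: str = "prev_stim",
                               n_iter: int = 5000, frac: float = 0.80,
                               seed=None,
                               alpha_bounds=DEFAULT_ALPHA_BOUNDS,
                               w_bounds=DEFAULT_W_BOUNDS) -> BootstrapResult:
    """Grand-subject bootstrap of the DoG amplitude.

    Each iteration draws ``floor(frac * n_p)`` trials without replacement
    from every participant ``p``, pools them, and refits the DoG.  The
    p-value is the proportion of bootstrap amplitudes on the side of zero
    opposite to the full-data amplitude's sign (one-sided by construction;
    use :meth:`BootstrapResult.p_two_sided` for the symmetric variant).
    """
    rng = np.random.default_rng(seed)
    data = _usable(table, predictor)
    col = _predictor_column(predictor)
    if data["participant"].nunique() < 2:
        logger.warning("stratified bootstrap over %d participant(s)",
                       data["participant"].nunique())
    deltas = data[col].to_numpy(dtype=float)
    errors = data["error"].to_numpy(dtype=float)
    groups = [np.flatnonzero((data["participant"] == pid).to_numpy())
              for pid in data["participant"].unique()]
    take = [max(int(math.floor(frac * len(g))), 1) for g in groups]

    point_fit = fit_dog(deltas, errors, alpha_bounds, w_bounds)
    alphas = np.empty(n_iter)
    it = 0
    while it < n_iter:
        idx = np.concatenate([rng.choice(g, size=k, replace=False)
                              for g, k in zip(groups, take)])
        if len(idx) < MIN_FIT_TRIALS:
            logger.warning("resample of %d trials < %d; redrawing",
                           len(idx), MIN_FIT_TRIALS)
            continue
        fit = fit_dog(deltas[idx], errors[idx], alpha_bounds, w_bounds)
        alphas[it] = fit.alpha
        it += 1

    if point_fit.alpha > 0:
        p = float(np.mean(alphas < 0))
    elif point_fit.alpha < 0:
        p = float(np.mean(alphas > 0))
    else:
        p = 0.5
    return BootstrapResult(alphas=alphas, n_iter=n_iter, frac=frac,
                           p_value=p, alpha_point=point_fit.alpha,
                           w_point=point_fit.w, point_fit=point_fit)


# ---------------------------------------------------------------------------
# permutation test on the amplitude difference between conditions
# ---------------------------------------------------------------------------

def _grid_alphas(M, D, e2col, alpha_bounds):
    """Best grid-profile amplitude per column of a masked design.

    ``M = G * errors`` and ``D = G * G`` are (n_w x n) matrices of the
    unit-amplitude DoG regressor; a column of the inputs holds the per-trial
    membership weights of one permutation.  Returns the amplitude at the
    sse-minimizing w per column.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(D > 0, M / np.maximum(D, 1e-300), 0.0)
    alpha = np.clip(alpha, *alpha_bounds)
    sse = e2col[None, :] - 2.0 * alpha * M + np.square(alpha) * D
    best = np.argmin(sse, axis=0)
    return alpha[best, np.arange(alpha.shape[1])]


def permutation_test_alpha(table: pd.DataFrame, predictor: str = "prev_stim",
                           n_perm: int = 10_000, seed=None,
                           condition_col: str = "condition",
                           alpha_bounds=DEFAULT_ALPHA_BOUNDS,
                           w_bounds=DEFAULT_W_BOUNDS,
                           n_w_grid: int = 64,
                           chunk: int = 250) -> dict:
    """Two-sided permutation test of the between-condition amplitude difference.

    Condition labels are shuffled trial-wise *within participant* (keeping
    the stratification intact); each permutation refits the DoG per label on
    the pooled data and records the amplitude difference.  Returns the
    observed difference, per-label observed amplitudes, the surrogate
    distribution and ``p`` = proportion of |surrogate| >= |observed|.

    Because the trials are fixed and only their labels move, every refit
    shares the same regressor matrix: the amplitude is profiled on a dense
    ``n_w_grid`` w-grid and all permutations are evaluated as one matrix
    product per chunk.  The observed statistic goes through the identical
    path, so the p-value is exact up to grid resolution of the statistic.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation p-values")
    rng = np.random.default_rng(seed)
    data = _usable(table, predictor)
    col = _predictor_column(predictor)
    labels = np.sort(data[condition_col].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two condition labels, got {list(labels)}")
    for pid, grp in data.groupby("participant", sort=False):
        if grp[condition_col].nunique() < 2:
            raise ValueError(
                f"participant {pid!r} has only one condition; labels are "
                "confounded with participant, within-participant shuffling "
                "is impossible")

    deltas = data[col].to_numpy(dtype=float)
    errors = data["error"].to_numpy(dtype=float)
    cond = (data[condition_col] == labels[1]).to_numpy()
    part_groups = [np.flatnonzero((data["participant"] == pid).to_numpy())
                   for pid in data["participant"].unique()]

    ws = np.geomspace(w_bounds[0], w_bounds[1], n_w_grid)
    G = deltas[None, :] * ws[:, None] * \
        np.exp(-np.square(ws[:, None] * deltas[None, :]))
    G *= math.sqrt(2.0) * math.exp(0.5)
    M = G * errors[None, :]
    D = G * G
    e2 = np.square(errors)

    def alpha_diff_batch(mask_matrix):
        """mask_matrix: (n x k) 0/1 membership of label[1] per permutation."""
        out = []
        for B in (1.0 - mask_matrix, mask_matrix):   # label[0] then label[1]
            out.append(_grid_alphas(M @ B, D @ B, e2 @ B, alpha_bounds))
        return out[0] - out[1], out[0], out[1]

    obs_mask = cond.astype(float)[:, None]
    observed, a0, a1 = (float(v[0]) for v in alpha_diff_batch(obs_mask))

    surrogate = np.empty(n_perm)
    done = 0
    mask = cond.copy()
    while done < n_perm:
        k = min(chunk, n_perm - done)
        B = np.empty((len(cond), k))
        for j in range(k):
            for g in part_groups:
                mask[g] = mask[g][rng.permutation(len(g))]
            B[:, j] = mask
        surrogate[done:done + k] = alpha_diff_batch(B)[0]
        done += k

    p = float(np.mean(np.abs(surrogate) >= abs(observed)))
    alpha0, alpha1 = a0, a1
    return {
        "labels": [str(labels[0]), str(labels[1])],
        "alpha_by_label": {str(labels[0]): alpha0, str(labels[1]): alpha1},
        "observed_diff": float(observed),
        "surrogate": surrogate,
        "p_value": p,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# model-free +/-delta index and group tests
# ---------------------------------------------------------------------------

def model_free_index(table: pd.DataFrame, predictor: str = "prev_stim",
                     delta_range: tuple[float, float] = MODEL_FREE_DELTA_RANGE,
                     literal_sign: bool = False) -> pd.Series:
    """Per-participant bias index from errors at small positive vs negative delta.

    ``index = mean(error | delta in [+20, +40]) - mean(error | delta in
    [-40, -20])`` so that a positive index means attraction toward the
    history item and a negative index repulsion (trials at |delta| outside
    the band, e.g. 60, are excluded).  ``literal_sign`` flips the sign to
    the subtraction order "negative minus positive" (repulsion-positive).
    """
    data = _usable(table, predictor)
    col = _predictor_column(predictor)
    lo, hi = delta_range
    out = {}
    for pid, grp in data.groupby("participant", sort=False):
        d = grp[col].to_numpy(dtype=float)
        e = grp["error"].to_numpy(dtype=float)
        band = (np.abs(d) >= lo - 1e-9) & (np.abs(d) <= hi + 1e-9)
        pos = band & (d > 0)
        neg = band & (d < 0)
        if not pos.any() or not neg.any():
            logger.warning("participant %r lacks trials on one side of the "
                           "delta band; index undefined", pid)
            out[pid] = np.nan
            continue
        idx = float(np.mean(e[pos]) - np.mean(e[neg]))
        out[pid] = -idx if literal_sign else idx
    return pd.Series(out, name=f"model_free_{predictor}")


@dataclass(frozen=True)
class ModelFreeResult:
    """One-sample or paired t-test summary of per-participant indices."""

    t: float
    df: int
    p_value: float
    cohen_d: float          # mean / SD of the (difference) scores
    n: int
    mean: float
    paired: bool


def group_tests(indices, paired_indices=None) -> ModelFreeResult:
    """Two-tailed t-test of per-participant values against zero (or paired).

    Cohen's d is the mean divided by the standard deviation of the scores
    (of the differences for a paired design), which for these designs equals
    ``t / sqrt(n)``.  Zero variance yields an infinite t with a warning.
    """
    x = np.asarray(pd.Series(indices).dropna(), dtype=float)
    if paired_indices is not None:
        y = np.asarray(pd.Series(paired_indices).dropna(), dtype=float)
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        scores = x - y
        paired = True
    else:
        scores = x
        paired = False
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 values for a group test")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    if sd == 0:
        warnings.warn("zero variance in group test; t is infinite")
        t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
        p = 0.0 if mean != 0 else 1.0
        d = math.copysign(math.inf, mean) if mean != 0 else 0.0
        return ModelFreeResult(t=t, df=n - 1, p_value=p, cohen_d=d, n=n,
                               mean=mean, paired=paired)
    if paired:
        res = stats.ttest_rel(x, y)
    else:
        res = stats.ttest_1samp(scores, 0.0)
    return ModelFreeResult(t=float(res.statistic), df=n - 1,
                           p_value=float(res.pvalue), cohen_d=mean / sd,
                           n=n, mean=mean, paired=paired)


# ---------------------------------------------------------------------------
# dominance analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominanceResult:
    """Bootstrap distributions of b(last stimulus) - b(last report) per condition."""

    diffs: dict                 # condition -> np.ndarray of coefficient differences
    coef_stim: dict             # condition -> np.ndarray of b(last stimulus)
    coef_report: dict           # condition -> np.ndarray of b(last report)
    n_iter: int
    frac: float

    def summary(self) -> dict:
        out = {}
        for cond, d in self.diffs.items():
            out[cond] = {
                "median": float(np.median(d)),
                "mean": float(np.mean(d)),
                "ci95": [float(np.percentile(d, 2.5)),
                         float(np.percentile(d, 97.5))],
                "frac_below_zero": float(np.mean(d < 0)),
                "coef_stim_mean": float(np.mean(self.coef_stim[cond])),
                "coef_report_mean": float(np.mean(self.coef_report[cond])),
            }
        return out


def _ols_sign_regression(errors, x1, x2):
    """OLS of error on [1, sign(d_stim), sign(d_report)]; returns (b1, b2)."""
    X = np.column_stack([np.ones_like(x1), x1, x2])
    coef, _, rank, _ = np.linalg.lstsq(X, errors, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("collinear predictors")
    return float(coef[1]), float(coef[2])


def dominance_analysis(table: pd.DataFrame, n_iter: int = 5000,
                       frac: float = 0.80, seed=None,
                       delta_range: tuple[float, float] = MODEL_FREE_DELTA_RANGE
                       ) -> DominanceResult:
    """Relative predictive dominance of stimulus history vs report history.

    Restricted to trials where both history deltas lie in the +/-[20, 40]
    band (where the DoG is approximately linear), the error is regressed on
    the signs of the two deltas (+/-1 coding, intercept included) within
    each stratified-bootstrap resample, separately per condition; the
    distribution of ``b(last stimulus) - b(last report)`` is returned.
    Resamples with collinear sign predictors are redrawn.
    """
    rng = np.random.default_rng(seed)
    lo, hi = delta_range
    d1 = pd.to_numeric(table["delta_prev_stim"], errors="coerce")
    d2 = pd.to_numeric(table["delta_prev_report"], errors="coerce")
    band = (np.abs(d1).between(lo, hi) & np.abs(d2).between(lo, hi)
            & np.isfinite(table["error"]))
    data = table.loc[band.to_numpy(dtype=bool)]
    diffs, coef_stim, coef_report = {}, {}, {}
    for cond, grp in data.groupby("condition", sort=True):
        errors = grp["error"].to_numpy(dtype=float)
        x1 = np.sign(grp["delta_prev_stim"].to_numpy(dtype=float))
        x2 = np.sign(grp["delta_prev_report"].to_numpy(dtype=float))
        groups = [np.flatnonzero((grp["participant"] == pid).to_numpy())
                  for pid in grp["participant"].unique()]
        take = [max(int(math.floor(frac * len(g))), 1) for g in groups]
        b1s = np.empty(n_iter)
        b2s = np.empty(n_iter)
        it = 0
        attempts = 0
        while it < n_iter:
            idx = np.concatenate([rng.choice(g, size=k, replace=False)
                                  for g, k in zip(groups, take)])
            attempts += 1
            try:
                b1, b2 = _ols_sign_regression(errors[idx], x1[idx], x2[idx])
            except np.linalg.LinAlgError:
                if attempts > 10 * n_iter:
                    raise RuntimeError("persistent collinearity in dominance "
                                       "resamples")
                logger.warning("collinear sign predictors in resample; redrawing")
                continue
            b1s[it], b2s[it] = b1, b2
            it += 1
        diffs[str(cond)] = b1s - b2s
        coef_stim[str(cond)] = b1s
        coef_report[str(cond)] = b2s
    return DominanceResult(diffs=diffs, coef_stim=coef_stim,
                           coef_report=coef_report, n_iter=n_iter, frac=frac)


# ---------------------------------------------------------------------------
# control-trial checks
# ---------------------------------------------------------------------------

def control_checks(table: pd.DataFrame) -> dict:
    """Sanity checks on control trials (run on the unfiltered table).

    Compares per-participant mean absolute error (i) on early-termination
    trials ending at the fifth stimulus versus full-length non-control
    trials, and (ii) on rotation-break controls versus complete Rotational
    trials; paired two-tailed t-tests.  Marked not applicable when the
    relevant control trials are absent.
    """
    if "error" not in table.columns:
        raise ValueError("compute errors before running control checks")
    report: dict = {}

    def paired_mean_abs(mask_a, mask_b, name):
        a = table[mask_a].groupby("participant")["error"].apply(
            lambda e: np.nanmean(np.abs(e)))
        b = table[mask_b].groupby("participant")["error"].apply(
            lambda e: np.nanmean(np.abs(e)))
        common = a.index.intersection(b.index)
        if len(common) < 3:
            report[name] = {"applicable": False}
            return
        res = group_tests(a.loc[common], b.loc[common])
        report[name] = {
            "applicable": True,
            "t": res.t, "df": res.df, "p_value": res.p_value,
            "cohen_d": res.cohen_d, "n": res.n, "mean_diff": res.mean,
        }

    early5 = table["is_early_control"] & (table["n_stimuli"] == 5)
    full = ~table["is_early_control"] & ~table["is_rotation_break_control"]
    if early5.any():
        paired_mean_abs(early5, full, "fifth_vs_sixth")
    else:
        report["fifth_vs_sixth"] = {"applicable": False}

    brk = table["is_rotation_break_control"]
    rot_full = full & (table["condition"] == "Rotational")
    if brk.any():
        paired_mean_abs(brk, rot_full, "rotation_break_vs_complete")
    else:
        report["rotation_break_vs_complete"] = {"applicable": False}
    return report
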