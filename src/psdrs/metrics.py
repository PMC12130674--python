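"""Treatment-effect and covariate-balance metrics, per replicate and summarized.

The matched-cohort effect is the treatment coefficient of a logistic
regression of outcome on treatment alone, which equals the log odds
ratio of the matched 2x2 table.  Balance is the average absolute
standardized mean difference (ASMD) over the 56 baseline covariates,
using the continuous-variable SMD for normal columns and the
proportion-based SMD for binary columns.  Relative bias compares the
estimated log odds ratio with the simulated truth ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import BINARY_COLUMNS, Cohort, NonEstimableError, TRUE_LOG_OR
from .matching import MatchedSet

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(NonEstimableError):
    """The matched 2x2 table has a zero cell; the log odds ratio is infinite."""


def smd_continuous(x_treated, x_control) -> float:
    """(mean_T - mean_C) / sqrt((var_T + var_C) / 2), sample variances.

    Returns NaN (non-estimable) when both variances are zero but the
    means differ; 0.0 when the two groups are identical constants.
    """
    x_t = np.asarray(x_treated, dtype=float)
    x_c = np.asarray(x_control, dtype=float)
    if x_t.size == 0 or x_c.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = x_t.mean() - x_c.mean()
    v_t = x_t.var(ddof=1) if x_t.size > 1 else 0.0
    v_c = x_c.var(ddof=1) if x_c.size > 1 else 0.0
    denom = math.sqrt((v_t + v_c) / 2.0)
    if denom == 0.0:
        return 0.0 if diff == 0.0 else float("nan")
    return float(diff / denom)


def smd_binary(p_treated: float, p_control: float) -> float:
    """Proportion-based SMD: (p_T - p_C) / sqrt((p_T(1-p_T) + p_C(1-p_C)) / 2)."""
    if not (0.0 <= p_treated <= 1.0 and 0.0 <= p_control <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    denom = math.sqrt((p_treated * (1 - p_treated) + p_control * (1 - p_control)) / 2.0)
    if denom == 0.0:
        return 0.0 if p_treated == p_control else float("nan")
    return float((p_treated - p_control) / denom)


def average_asmd(cohort: Cohort, membership=None, *, covariates: str = "all") -> float:
    """Mean |SMD| over the baseline covariates for a (sub)cohort.

    ``membership`` selects the rows: ``None`` uses the full cohort
    (pre-matching balance), a :class:`~psdrs.matching.MatchedSet` uses the
    matched rows, and any integer index array is taken as-is.  Binary
    columns use the proportion formula, normal columns the continuous one.
    Columns whose SMD is non-estimable (degenerate denominator with
    unequal means) are dropped from the average; if every column is
    non-estimable the result is NaN.

    ``covariates="confounders"`` restricts the average to the 50
    confounders (default is all 56 baseline covariates).
    """
    if isinstance(membership, MatchedSet):
        rows = membership.matched_rows()
    elif membership is None:
        rows = np.arange(cohort.n)
    else:
        rows = np.asarray(membership, dtype=int)

    T = cohort.T[rows]
    if T.sum() == 0 or T.sum() == T.size:
        raise NonEstimableError("ASMD requires both treated and control rows")

    cols = [
        c
        for c in cohort.X.columns
        if covariates == "all" or cohort.roles[c] == "confounder"
    ]
    X = cohort.X.iloc[rows]
    treated = T == 1
    smds = []
    for c in cols:
        col = X[c].to_numpy()
        if c in BINARY_COLUMNS:
            s = smd_binary(col[treated].mean(), col[~treated].mean())
        else:
            s = smd_continuous(col[treated], col[~treated])
        if not math.isnan(s):
            smds.append(abs(s))
    return float(np.mean(smds)) if smds else float("nan")


def _two_by_two(Y: np.ndarray, T: np.ndarray) -> tuple[int, int, int, int]:
    a = int(np.sum((T == 1) & (Y == 1)))  # treated events
    b = int(np.sum((T == 1) & (Y == 0)))
    c = int(np.sum((T == 0) & (Y == 1)))
    d = int(np.sum((T == 0) & (Y == 0)))
    return a, b, c, d


def estimate_effect(cohort: Cohort, matched: MatchedSet, *, zero_cell: str = "error") -> float:
    """Log odds ratio of Y on T over the matched rows (pairing ignored).

    Fitted as a logistic regression with treatment as the sole predictor;
    its coefficient coincides with ln[(a d)/(b c)] of the matched 2x2
    table.  A zero cell raises :class:`SeparationError` by default;
    ``zero_cell="haldane"`` applies the Haldane-Anscombe +0.5 correction
    to the table instead (sensitivity analyses only).
    """
    if matched.n_pairs == 0:
        raise NonEstimableError("no matched pairs; effect not estimable")
    rows = matched.matched_rows()
    Y, T = cohort.Y[rows], cohort.T[rows]
    a, b, c, d = _two_by_two(Y, T)
    if min(a, b, c, d) == 0:
        if zero_cell == "haldane":
            return math.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
        raise SeparationError("zero cell in matched 2x2 table")
    design = sm.add_constant(T.astype(float))
    fit = sm.GLM(Y.astype(float), design, family=sm.families.Binomial()).fit()
    return float(fit.params[1])


def relative_bias(estimated_log_or: float, true_effect: float = TRUE_LOG_OR) -> float:
    """|estimated - true| / true."""
    if true_effect == 0:
        raise ValueError("true_effect must be nonzero")
    return abs(estimated_log_or - true_effect) / true_effect


@dataclass
class RepResult:
    """Metrics of one (scenario, replicate, learner, score-kind) cell."""

    scenario_id: int
    rep_index: int
    score_kind: str
    learner: str
    estimated_log_or: float = float("nan")
    relative_bias: float = float("nan")
    asmd_pre: float = float("nan")
    asmd_post: float = float("nan")
    brier: float = float("nan")
    n_pairs: int = 0
    clipped_count: int = 0
    failure_reason: str | None = None
    tuning_record: dict | None = None

    @property
    def estimable(self) -> bool:
        return self.failure_reason is None


def _mean_ci(values: np.ndarray, *, ci_mode: str = "se") -> tuple[float, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    half = Z95 * (sd / math.sqrt(values.size) if ci_mode == "se" else sd)
    return mean, mean - half, mean + half


@dataclass
class ScenarioSummary:
    """Across-replicate aggregation of one (scenario, learner, score-kind) cell."""

    scenario_id: int
    score_kind: str
    learner: str
    n_estimable: int
    n_failed: int
    mean_relative_bias: float = float("nan")
    relative_bias_ci: tuple[float, float] = (float("nan"), float("nan"))
    mean_asmd_pre: float = float("nan")
    mean_asmd_post: float = float("nan")
    asmd_post_ci: tuple[float, float] = (float("nan"), float("nan"))
    mean_brier: float = float("nan")
    brier_ci: tuple[float, float] = (float("nan"), float("nan"))
    unreliable: bool = False


def _finite(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def summarize(results: list[RepResult], *, ci_mode: str = "se") -> ScenarioSummary:
    """Aggregate per-replicate metrics into means with 95% CIs.

    Each metric is averaged over the replicates where it is defined: a
    replicate excluded for separation contributes no effect estimate but
    still has a valid matched-cohort ASMD and Brier loss.  CIs are
    mean +/- 1.96 SD/sqrt(R) by default; ``ci_mode="sd"`` uses the raw-SD
    form.  Fewer than two effect-estimable replicates flag the summary as
    unreliable.
    """
    if not results:
        raise ValueError("summarize requires at least one RepResult")
    first = results[0]
    ok = [r for r in results if r.estimable]
    summary = ScenarioSummary(
        scenario_id=first.scenario_id,
        score_kind=first.score_kind,
        learner=first.learner,
        n_estimable=len(ok),
        n_failed=len(results) - len(ok),
    )
    summary.unreliable = len(ok) < 2

    def agg(values):
        vals = _finite(values)
        if vals.size == 0:
            return float("nan"), (float("nan"), float("nan"))
        if vals.size == 1:
            return float(vals[0]), (float("nan"), float("nan"))
        mean, lo, hi = _mean_ci(vals, ci_mode=ci_mode)
        return mean, (lo, hi)

    summary.mean_relative_bias, summary.relative_bias_ci = agg(
        [r.relative_bias for r in results]
    )
    summary.mean_asmd_pre, _ = agg([r.asmd_pre for r in results])
    summary.mean_asmd_post, summary.asmd_post_ci = agg([r.asmd_post for r in results])
    summary.mean_brier, summary.brier_ci = agg([r.brier for r in results])
    return summary
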