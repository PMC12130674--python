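"""Orchestration of the scenario x learner x score-kind Monte Carlo grid.

One replicate is: simulate a cohort, fit the score, match on its logit
with a 0.2-SD caliper, estimate the matched log odds ratio, and record
bias and balance metrics.  Any degenerate condition (single-class
target, zero matched pairs, a zero cell in the matched table) becomes a
flagged, non-estimable :class:`~psdrs.metrics.RepResult` rather than an
exception, so failure rates are part of the results.

Replicate seeds are derived deterministically from
(base_seed, scenario_id, rep_index) — and a learner/score tag for the
model-fitting randomness — so runs are reproducible and parallel-safe,
and results never depend on execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import metrics
from .cohort import (
    Cohort,
    NonEstimableError,
    ScenarioSpec,
    canonical_scenarios,
    replicate_seed_sequence,
    simulate_cohort,
)
from .matching import greedy_match
from .metrics import RepResult, ScenarioSummary, relative_bias, summarize
from .scores import LEARNER_NAMES, SCORE_KINDS, LearnerSpec, brier_loss, fit_score

logger = logging.getLogger(__name__)

_KEY = ["scenario_id", "rep_index", "score_kind", "learner"]


@dataclass
class RunConfig:
    """Everything needed to execute (part of) the Monte Carlo grid."""

    scenarios: list[ScenarioSpec] = field(default_factory=canonical_scenarios)
    learners: tuple[str, ...] = ("reference", "lasso", "gbdt", "mlp")
    score_kinds: tuple[str, ...] = ("PS", "DRS_full_cohort")
    n_reps: int = 100
    base_seed: int = 0
    output_dir: str | Path | None = None
    parallel_workers: int = 1
    freeze_coefficients: bool = False
    learner_grids: dict[str, dict] = field(default_factory=dict)
    cv_folds: int = 10

    def __post_init__(self) -> None:
        ids = [s.scenario_id for s in self.scenarios]
        if len(ids) != len(set(ids)):
            raise ValueError("scenario_id values must be unique")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for k in self.score_kinds:
            if k not in SCORE_KINDS:
                raise ValueError(f"unknown score kind {k!r}")

    def learner_spec(self, name: str) -> LearnerSpec:
        return LearnerSpec(
            name=name, hyperparameter_grid=self.learner_grids.get(name), cv_folds=self.cv_folds
        )


def _model_seed(spec: ScenarioSpec, rep_index: int, learner: str, score_kind: str) -> int:
    # hash() is salted per process for strings; derive a stable tag instead
    tag = sum(ord(ch) * (i + 1) for i, ch in enumerate(f"{learner}|{score_kind}"))
    ss = np.random.SeedSequence(
        entropy=int(spec.base_seed),
        spawn_key=(int(spec.scenario_id), int(rep_index), int(tag)),
    )
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def run_replicate(
    spec: ScenarioSpec,
    rep_index: int,
    learner: LearnerSpec | str,
    score_kind: str,
    *,
    cohort: Cohort | None = None,
    freeze_coefficients: bool = False,
    caliper_multiplier: float = 0.2,
) -> RepResult:
    """Simulate, score, match and evaluate one replicate.

    A pre-simulated ``cohort`` may be passed to share one dataset across
    learners and score kinds (the default grid runner does this).
    """
    if isinstance(learner, str):
        learner = LearnerSpec(name=learner)
    result = RepResult(
        scenario_id=spec.scenario_id,
        rep_index=rep_index,
        score_kind=score_kind,
        learner=learner.name,
    )
    if cohort is None:
        cohort = simulate_cohort(spec, rep_index, freeze_coefficients=freeze_coefficients)

    try:
        if cohort.degenerate:
            raise NonEstimableError("single-class treatment draw")
        result.asmd_pre = metrics.average_asmd(cohort)
        seed = _model_seed(spec, rep_index, learner.name, score_kind)
        score = fit_score(cohort, score_kind, learner, seed)
        result.clipped_count = score.clipped_count
        result.tuning_record = score.tuning_record
        target = cohort.T if score_kind == "PS" else cohort.Y
        result.brier = brier_loss(score.values, target)
        matched = greedy_match(score, cohort.T, caliper_multiplier)
        result.n_pairs = matched.n_pairs
        if matched.n_pairs == 0:
            result.failure_reason = "zero_pairs"
            return result
        result.asmd_post = metrics.average_asmd(cohort, matched)
        est = metrics.estimate_effect(cohort, matched)
        result.estimated_log_or = est
        result.relative_bias = relative_bias(est, cohort.coefficients.true_effect)
    except metrics.SeparationError:
        result.failure_reason = "separation"
    except NonEstimableError:
        result.failure_reason = "single_class"
    return result


def _replicate_block(
    spec: ScenarioSpec,
    rep_index: int,
    learner_specs: list[LearnerSpec],
    score_kinds: tuple[str, ...],
    freeze_coefficients: bool,
) -> list[RepResult]:
    cohort = simulate_cohort(spec, rep_index, freeze_coefficients=freeze_coefficients)
    return [
        run_replicate(spec, rep_index, ls, kind, cohort=cohort)
        for ls in learner_specs
        for kind in score_kinds
    ]


def results_to_frame(results: list[RepResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dataclasses.asdict(r)
        row["tuning_record"] = json.dumps(r.tuning_record) if r.tuning_record else ""
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dataclasses.asdict(s)
        for name in ("relative_bias_ci", "asmd_post_ci", "brier_ci"):
            lo, hi = row.pop(name)
            row[f"{name}_lo"], row[f"{name}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def run_grid(config: RunConfig, *, resume: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full grid; returns (per-replicate results, per-cell summaries).

    When ``output_dir`` is set, writes ``results.csv``, ``summary.csv`` and
    ``summary.json`` there; with ``resume=True`` rows already present in an
    existing ``results.csv`` are kept and not recomputed.
    """
    out = Path(config.output_dir) if config.output_dir else None
    existing = pd.DataFrame()
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")  # fail fast on unwritable output
        probe.unlink()
        results_path = out / "results.csv"
        if resume and results_path.exists():
            # round_trip parsing keeps resumed runs bit-identical
            existing = pd.read_csv(results_path, float_precision="round_trip")

    done = set()
    if len(existing):
        done = set(map(tuple, existing[_KEY].itertuples(index=False, name=None)))

    learner_specs = [config.learner_spec(name) for name in config.learners]
    jobs = []
    for spec in config.scenarios:
        spec = dataclasses.replace(spec, n_reps=config.n_reps, base_seed=config.base_seed)
        for rep in range(config.n_reps):
            pending = [
                (ls, kind)
                for ls in learner_specs
                for kind in config.score_kinds
                if (spec.scenario_id, rep, kind, ls.name) not in done
            ]
            if pending:
                jobs.append((spec, rep, pending))

    def _run(job):
        spec, rep, pending = job
        cohort = simulate_cohort(spec, rep, freeze_coefficients=config.freeze_coefficients)
        return [run_replicate(spec, rep, ls, kind, cohort=cohort) for ls, kind in pending]

    if config.parallel_workers > 1:
        blocks = Parallel(n_jobs=config.parallel_workers)(delayed(_run)(j) for j in jobs)
    else:
        blocks = [_run(j) for j in jobs]
    fresh = [r for block in blocks for r in block]

    results = pd.concat([existing, results_to_frame(fresh)], ignore_index=True)
    if len(results):
        results = results.sort_values(_KEY).reset_index(drop=True)

    summaries = summarize_frame(results)
    if out is not None:
        results.to_csv(out / "results.csv", index=False)
        summaries.to_csv(out / "summary.csv", index=False)
        (out / "summary.json").write_text(summaries.to_json(orient="records", indent=2))
        failures = (
            results[results.failure_reason.notna()].failure_reason.value_counts().to_dict()
            if len(results)
            else {}
        )
        with open(out / "run.log", "a") as fh:
            fh.write(
                f"base_seed={config.base_seed} n_reps={config.n_reps} "
                f"scenarios={[s.scenario_id for s in config.scenarios]} "
                f"learners={list(config.learners)} score_kinds={list(config.score_kinds)} "
                f"grids={ {n: config.learner_spec(n).hyperparameter_grid for n in config.learners} } "
                f"fresh_rows={len(fresh)} resumed_rows={len(existing)} failures={failures}\n"
            )
    return results, summaries


def _results_to_represults(df: pd.DataFrame) -> list[RepResult]:
    fields = {f.name for f in dataclasses.fields(RepResult)} - {"tuning_record"}
    out = []
    for row in df.to_dict("records"):
        kw = {k: row[k] for k in fields if k in row}
        if isinstance(kw.get("failure_reason"), float):  # NaN from CSV round-trip
            kw["failure_reason"] = None
        out.append(RepResult(**kw))
    return out


def summarize_frame(results: pd.DataFrame, *, ci_mode: str = "se") -> pd.DataFrame:
    """Aggregate a per-replicate results table into per-cell summaries."""
    summaries = []
    if not len(results):
        return pd.DataFrame()
    for _, group in results.groupby(["scenario_id", "score_kind", "learner"], sort=True):
        summaries.append(summarize(_results_to_represults(group), ci_mode=ci_mode))
    return summaries_to_frame(summaries)


def compare_report(
    summaries: pd.DataFrame, kind_a: str = "PS", kind_b: str = "DRS_full_cohort"
) -> pd.DataFrame:
    """Per scenario x learner differences between two score kinds.

    Positive ``bias_diff`` means ``kind_a`` (PS by default) has the larger
    mean relative bias, i.e. ``kind_b`` (DRS) did better.  ``ci_overlap``
    flags whether the two 95% CIs on relative bias overlap.
    """
    a = summaries[summaries.score_kind == kind_a].set_index(["scenario_id", "learner"])
    b = summaries[summaries.score_kind == kind_b].set_index(["scenario_id", "learner"])
    idx = sorted(set(a.index) | set(b.index))
    rows = []
    for key in idx:
        row = {"scenario_id": key[0], "learner": key[1]}
        if key in a.index and key in b.index:
            ra, rb = a.loc[key], b.loc[key]
            row["bias_diff"] = ra.mean_relative_bias - rb.mean_relative_bias
            row["asmd_post_diff"] = ra.mean_asmd_post - rb.mean_asmd_post
            row["ci_overlap"] = bool(
                ra.relative_bias_ci_lo <= rb.relative_bias_ci_hi
                and rb.relative_bias_ci_lo <= ra.relative_bias_ci_hi
            )
        else:
            logger.warning("missing summary cell for %s", key)
        rows.append(row)
    return pd.DataFrame(rows)
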