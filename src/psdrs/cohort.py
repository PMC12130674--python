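"""Synthetic confounded-cohort generator.

Simulates binary-treatment / binary-outcome cohorts with 50 confounders
(25 standard normal, 25 Bernoulli), 5 standard-normal instrumental
variables affecting only treatment, and 1 Bernoulli risk factor affecting
only the outcome.  Treatment and outcome are drawn from logistic models
whose slope coefficients are sampled uniform[0, 1) and whose intercepts
are calibrated by root-finding so that the cohort hits a target marginal
treatment prevalence and untreated outcome risk.  A "nonlinear" variant
adds 15 two-way interactions and 5 cubic terms (plus their products with
binary covariates) to both linear predictors.

Column names follow the convention X1..X25 (normal confounders),
X26..X50 (binary confounders), X66..X70 (instruments), X71 (risk
factor); the gap X51..X65 is intentional and carries no variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

TRUE_LOG_OR = math.log(2.0)

NORMAL_CONFOUNDERS = tuple(f"X{i}" for i in range(1, 26))
BINOMIAL_CONFOUNDERS = tuple(f"X{i}" for i in range(26, 51))
INSTRUMENTS = tuple(f"X{i}" for i in range(66, 71))
RISK_FACTOR = "X71"
CONFOUNDERS = NORMAL_CONFOUNDERS + BINOMIAL_CONFOUNDERS
COLUMNS = CONFOUNDERS + INSTRUMENTS + (RISK_FACTOR,)

#: role of every baseline covariate column
ROLES = {
    **{c: "confounder" for c in CONFOUNDERS},
    **{c: "instrument" for c in INSTRUMENTS},
    RISK_FACTOR: "risk_factor",
}

#: columns that are Bernoulli draws (the rest are standard normal)
BINARY_COLUMNS = frozenset(BINOMIAL_CONFOUNDERS) | {RISK_FACTOR}

# nonlinear / nonadditive design: 5 normal-by-binary interactions,
# 5 normal-by-normal interactions, 5 cubic terms, 5 cubic-by-binary products
INTERACTIONS_NORMAL_BINARY = tuple((f"X{i}", f"X{i + 20}") for i in range(6, 11))
INTERACTIONS_NORMAL_NORMAL = tuple((f"X{i}", f"X{i + 1}") for i in range(11, 21, 2))
CUBIC_BASES = tuple(f"X{i}" for i in range(1, 6))
CUBIC_BINARY_PARTNERS = tuple(f"X{i}" for i in range(31, 36))

NONLINEAR_TERMS = (
    tuple(f"{a}*{b}" for a, b in INTERACTIONS_NORMAL_BINARY)
    + tuple(f"{a}*{b}" for a, b in INTERACTIONS_NORMAL_NORMAL)
    + tuple(f"{c}^3" for c in CUBIC_BASES)
    + tuple(f"{c}^3*{b}" for c, b in zip(CUBIC_BASES, CUBIC_BINARY_PARTNERS))
)

STRUCTURES = ("linear", "nonlinear")


class NonEstimableError(RuntimeError):
    """A replicate cannot be analysed (degenerate class structure)."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: a cell of the prevalence x risk x size x structure grid."""

    scenario_id: int
    treatment_prevalence: float
    outcome_risk: float
    sample_size: int
    structure: str
    n_reps: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.treatment_prevalence < 1.0:
            raise ValueError("treatment_prevalence must be in (0, 1)")
        if not 0.0 < self.outcome_risk < 1.0:
            raise ValueError("outcome_risk must be in (0, 1)")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


_PREVALENCES = (0.01, 0.05, 0.1, 0.25, 0.5)
_BLOCKS = (
    # (sample_size, structure, outcome_risk) for scenario blocks 1-5, 6-10, ...
    (500, "linear", 0.5),
    (10_000, "linear", 0.5),
    (500, "nonlinear", 0.5),
    (10_000, "nonlinear", 0.5),
    (10_000, "nonlinear", 0.02),
)


def canonical_scenarios(n_reps: int = 100, base_seed: int = 0) -> list[ScenarioSpec]:
    """The 25 canonical scenarios of the study grid."""
    specs = []
    sid = 1
    for n, structure, risk in _BLOCKS:
        for prev in _PREVALENCES:
            specs.append(
                ScenarioSpec(
                    scenario_id=sid,
                    treatment_prevalence=prev,
                    outcome_risk=risk,
                    sample_size=n,
                    structure=structure,
                    n_reps=n_reps,
                    base_seed=base_seed,
                )
            )
            sid += 1
    return specs


@dataclass
class CoefficientSet:
    """Sampled slopes and calibrated intercepts of the treatment and outcome models."""

    beta_treat: dict[str, float]
    beta_out: dict[str, float]
    structure: str
    alpha_treat: float = float("nan")
    alpha_out: float = float("nan")
    true_effect: float = TRUE_LOG_OR


@dataclass
class Cohort:
    """One simulated dataset: covariates with role labels, treatment and outcome."""

    X: pd.DataFrame
    roles: dict[str, str]
    T: np.ndarray
    Y: np.ndarray
    coefficients: CoefficientSet
    seed: int
    scenario_id: int = -1
    rep_index: int = -1

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def degenerate(self) -> bool:
        """True when the cohort has no treated or no untreated subjects."""
        s = int(self.T.sum())
        return s == 0 or s == len(self.T)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["T"] = self.T
        out["Y"] = self.Y
        return out


def sample_covariates(
    n: int, rng_seed, binomial_p: float = 0.5
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw the n x 56 baseline covariate block.

    Normal columns are i.i.d. N(0, 1); binary columns i.i.d. Bernoulli(binomial_p);
    all columns mutually independent.  ``rng_seed`` may be an int, SeedSequence or
    Generator.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(rng_seed)
    data = {}
    for col in COLUMNS:
        if col in BINARY_COLUMNS:
            data[col] = rng.binomial(1, binomial_p, size=n).astype(float)
        else:
            data[col] = rng.standard_normal(n)
    return pd.DataFrame(data, columns=list(COLUMNS)), dict(ROLES)


def build_design_terms(X: pd.DataFrame, structure: str) -> pd.DataFrame:
    """Expand the covariate block into model terms.

    ``linear`` returns the 56 main-effect columns; ``nonlinear`` appends the
    20 interaction/cubic columns, for 76 named columns total.
    """
    if list(X.columns) != list(COLUMNS):
        raise ValueError("X must have the canonical 56 columns in order")
    if structure == "linear":
        return X.copy()
    if structure != "nonlinear":
        raise ValueError(f"unknown structure {structure!r}")
    out = X.copy()
    for a, b in INTERACTIONS_NORMAL_BINARY + INTERACTIONS_NORMAL_NORMAL:
        out[f"{a}*{b}"] = X[a] * X[b]
    for c in CUBIC_BASES:
        out[f"{c}^3"] = X[c] ** 3
    for c, b in zip(CUBIC_BASES, CUBIC_BINARY_PARTNERS):
        out[f"{c}^3*{b}"] = X[c] ** 3 * X[b]
    return out


def treatment_terms(structure: str) -> tuple[str, ...]:
    """Term names entering the treatment model (confounders + instruments)."""
    base = CONFOUNDERS + INSTRUMENTS
    return base + NONLINEAR_TERMS if structure == "nonlinear" else base


def outcome_terms(structure: str) -> tuple[str, ...]:
    """Term names entering the outcome model (confounders + risk factor)."""
    base = CONFOUNDERS + (RISK_FACTOR,)
    return base + NONLINEAR_TERMS if structure == "nonlinear" else base


def draw_coefficients(structure: str, rng_seed) -> CoefficientSet:
    """Sample uniform[0, 1) slopes for the treatment and outcome models.

    Instruments enter only the treatment model, the risk factor only the
    outcome model; under the nonlinear structure the 20 derived terms enter
    both, with independently drawn coefficients.  Intercepts are left unset.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    rng = np.random.default_rng(rng_seed)
    t_terms = treatment_terms(structure)
    o_terms = outcome_terms(structure)
    beta_t = dict(zip(t_terms, rng.uniform(0.0, 1.0, size=len(t_terms))))
    beta_o = dict(zip(o_terms, rng.uniform(0.0, 1.0, size=len(o_terms))))
    return CoefficientSet(beta_treat=beta_t, beta_out=beta_o, structure=structure)


def calibrate_intercept(linear_predictor: np.ndarray, target_prob: float) -> float:
    """Find alpha with mean(expit(alpha + lp)) == target_prob to 1e-6.

    The objective is strictly increasing in alpha, so the root is unique;
    solved by Brent's method on an expanding bracket.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear_predictor must be finite")
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must be in (0, 1)")

    def objective(alpha: float) -> float:
        return float(expit(alpha + lp).mean()) - target_prob

    lo, hi = -40.0, 40.0
    while objective(lo) > 0:
        lo *= 2
    while objective(hi) < 0:
        hi *= 2
    return float(brentq(objective, lo, hi, xtol=1e-9))


def replicate_seed_sequence(
    base_seed: int, scenario_id: int, rep_index: int
) -> np.random.SeedSequence:
    """Deterministic per-replicate seed stream, safe under parallel execution."""
    return np.random.SeedSequence(
        entropy=int(base_seed), spawn_key=(int(scenario_id), int(rep_index))
    )


def _linear_predictor(terms: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    names = list(beta)
    return terms[names].to_numpy() @ np.fromiter(beta.values(), dtype=float, count=len(names))


def simulate_cohort(
    spec: ScenarioSpec,
    rep_index: int,
    *,
    freeze_coefficients: bool = False,
    binomial_p: float = 0.5,
    outcome_risk_population: str = "untreated",
    coefficient_scale: float = 1.0,
) -> Cohort:
    """Simulate one replicate of a scenario.

    Slope coefficients are re-drawn each replicate (``freeze_coefficients``
    fixes them per scenario instead).  The treatment intercept is calibrated
    so the mean treatment probability over this replicate's covariates equals
    the target prevalence; the outcome intercept is calibrated with treatment
    forced to 0, so ``outcome_risk`` is the untreated marginal risk
    (``outcome_risk_population="overall"`` calibrates against the realised
    treatment vector instead).

    A draw that happens to contain zero treated or zero untreated subjects is
    returned as-is with ``Cohort.degenerate`` set; it is not an exception.

    ``coefficient_scale`` multiplies every sampled slope; 0.0 yields the
    null-confounding data-generating process where only the true treatment
    effect links T to Y.
    """
    if not 0 <= rep_index < spec.n_reps:
        raise ValueError("rep_index out of range")
    if outcome_risk_population not in ("untreated", "overall"):
        raise ValueError("outcome_risk_population must be 'untreated' or 'overall'")

    ss = replicate_seed_sequence(spec.base_seed, spec.scenario_id, rep_index)
    ss_cov, ss_coef, ss_treat, ss_out = ss.spawn(4)
    if freeze_coefficients:
        ss_coef = np.random.SeedSequence(
            entropy=int(spec.base_seed), spawn_key=(int(spec.scenario_id),)
        )

    X, roles = sample_covariates(spec.sample_size, ss_cov, binomial_p=binomial_p)
    coefs = draw_coefficients(spec.structure, ss_coef)
    if coefficient_scale != 1.0:
        coefs.beta_treat = {k: v * coefficient_scale for k, v in coefs.beta_treat.items()}
        coefs.beta_out = {k: v * coefficient_scale for k, v in coefs.beta_out.items()}
    terms = build_design_terms(X, spec.structure)

    lp_treat = _linear_predictor(terms, coefs.beta_treat)
    coefs.alpha_treat = calibrate_intercept(lp_treat, spec.treatment_prevalence)
    p_treat = expit(coefs.alpha_treat + lp_treat)
    T = np.random.default_rng(ss_treat).binomial(1, p_treat)

    lp_out = _linear_predictor(terms, coefs.beta_out)
    if outcome_risk_population == "untreated" and 0 < T.sum() < T.size:
        # expected outcome risk among the realised untreated subjects hits the
        # target; the treated are a selected high-risk subset, so calibrating
        # over everyone at T=0 would undershoot the observed untreated risk
        calib_lp = lp_out[T == 0]
    else:
        calib_lp = lp_out + coefs.true_effect * T
    coefs.alpha_out = calibrate_intercept(calib_lp, spec.outcome_risk)
    p_out = expit(coefs.alpha_out + lp_out + coefs.true_effect * T)
    Y = np.random.default_rng(ss_out).binomial(1, p_out)

    return Cohort(
        X=X,
        roles=roles,
        T=T,
        Y=Y,
        coefficients=coefs,
        seed=int(ss.generate_state(1, np.uint32)[0]),
        scenario_id=spec.scenario_id,
        rep_index=rep_index,
    )
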