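import dataclasses

import numpy as np
import pytest

from psdrs import ScenarioSpec, canonical_scenarios, simulate_cohort


def make_spec(scenario_id=99, prevalence=0.25, risk=0.5, n=400, structure="linear",
              n_reps=100, base_seed=7) -> ScenarioSpec:
    return ScenarioSpec(
        scenario_id=scenario_id,
        treatment_prevalence=prevalence,
        outcome_risk=risk,
        sample_size=n,
        structure=structure,
        n_reps=n_reps,
        base_seed=base_seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A fixed 400-subject linear cohort with plenty of treated and controls."""
    return simulate_cohort(make_spec(), 0)


@pytest.fixture(scope="session")
def canonical():
    return canonical_scenarios()


def scenario_by_id(sid: int, *, base_seed: int = 7, n_reps: int = 100) -> ScenarioSpec:
    spec = next(s for s in canonical_scenarios() if s.scenario_id == sid)
    return dataclasses.replace(spec, base_seed=base_seed, n_reps=n_reps)
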