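"""Run-configuration and scenario-catalogue file handling (YAML/JSON)."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .cohort import ScenarioSpec, canonical_scenarios
from .experiment import RunConfig


def load_scenario_catalogue(path: str | Path | None = None) -> list[ScenarioSpec]:
    """Load scenario specs from a YAML/JSON catalogue (packaged one by default)."""
    if path is None:
        text = resources.files("psdrs.data").joinpath("scenarios.yaml").read_text()
    else:
        text = Path(path).read_text()
    payload = yaml.safe_load(text)
    rows = payload["scenarios"] if isinstance(payload, dict) else payload
    return [ScenarioSpec(**row) for row in rows]


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML (or JSON) file.

    Recognised keys mirror the RunConfig fields; ``scenarios`` may be a list
    of scenario mappings, a list of canonical scenario ids, or absent (all 25).
    """
    path = Path(path)
    payload = yaml.safe_load(path.read_text()) if path.suffix != ".json" else json.loads(path.read_text())
    payload = dict(payload or {})
    scenarios = payload.pop("scenarios", None)
    if scenarios is None:
        specs = canonical_scenarios()
    elif all(isinstance(s, int) for s in scenarios):
        catalogue = {s.scenario_id: s for s in canonical_scenarios()}
        specs = [catalogue[i] for i in scenarios]
    else:
        specs = [ScenarioSpec(**row) for row in scenarios]
    for key in ("learners", "score_kinds"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return RunConfig(scenarios=specs, **payload)
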