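"""Run configuration files and report writing.

A run configuration is a small YAML document naming either a registered
scenario or an explicit network file, plus optional overrides::

    scenario: fig4a            # or: network_file: my_net.json
    t_end: 500                 # minutes
    schedule:                  # timed parameter steps
      - {time: 50, parameter: b1, value: 4}
    parameter_overrides:       # patch rate constants before running
      k1: 0.25
    tolerances:
      drift_tol: 1.0e-6
      residual_tol: 1.0e-8
    output_dir: results
    flags: {rpa: false, degradation: false, scan: false}

Unknown keys are rejected (fail fast).  Reports are a tidy trajectories CSV
plus a JSON summary; re-running an identical configuration reproduces
byte-identical CSV numbers because the whole pipeline is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crn import ReactionNetwork, network_from_json
from .motifs import RegulatorSpec, close_loop
from .scenarios import SCENARIOS, get_scenario
from .simulate import (
    DisturbanceEvent,
    DisturbanceSchedule,
    SimOptions,
    SimulationResult,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "write_report"]


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


_TOP_KEYS = {
    "scenario", "network_file", "regulator", "t_end", "schedule",
    "parameter_overrides", "tolerances", "output_dir", "flags",
}
_TOL_KEYS = {"rtol", "atol", "drift_tol", "residual_tol"}
_FLAG_KEYS = {"rpa", "degradation", "scan"}
_REGULATOR_KEYS = {
    "family", "parameters", "extra_inhibition_on_Y1",
    "controller_degradation_rate",
}


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    scenario: str | None = None
    network_file: str | None = None
    regulator: dict | None = None
    t_end: float = 500.0
    schedule: DisturbanceSchedule | None = None   # None → scenario default
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    options: SimOptions = field(default_factory=SimOptions)
    output_dir: str = "results"
    rpa: bool = False
    degradation: bool = False
    scan: bool = False

    def resolve(self) -> tuple[ReactionNetwork, DisturbanceSchedule,
                               RegulatorSpec | None]:
        """Materialize the network, schedule and regulator spec to run."""
        if self.scenario is not None:
            scen = get_scenario(self.scenario)
            net = scen.network()
            schedule = self.schedule if self.schedule is not None else scen.schedule
            spec = scen.spec
        else:
            net = network_from_json(Path(self.network_file).read_text())
            spec = None
            if self.regulator is not None:
                spec = RegulatorSpec(
                    family=self.regulator["family"],
                    parameters=dict(self.regulator.get("parameters", {})),
                    extra_inhibition_on_Y1=self.regulator.get(
                        "extra_inhibition_on_Y1", False),
                    controller_degradation_rate=self.regulator.get(
                        "controller_degradation_rate", 0.0),
                )
                net = close_loop(net, spec)
            schedule = self.schedule or DisturbanceSchedule()
        for pname, value in self.parameter_overrides.items():
            if pname not in net.parameters:
                raise ConfigError(f"override names unknown parameter {pname!r}")
            net.parameters[pname] = float(value)
        if schedule.events and self.t_end <= schedule.events[-1].time:
            raise ConfigError(
                f"t_end={self.t_end} must exceed the last scheduled event at "
                f"t={schedule.events[-1].time}"
            )
        return net, schedule, spec


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")

    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    has_scenario = "scenario" in doc
    has_network = "network_file" in doc
    if has_scenario == has_network:
        raise ConfigError(
            f"{path}: exactly one of 'scenario' or 'network_file' is required"
        )
    if has_scenario and doc["scenario"] not in SCENARIOS:
        raise ConfigError(
            f"{path}: unknown scenario {doc['scenario']!r}; "
            f"available: {sorted(SCENARIOS)}"
        )

    schedule = None
    if "schedule" in doc:
        events = []
        for i, ev in enumerate(doc["schedule"] or []):
            missing = {"time", "parameter", "value"} - set(ev)
            if missing:
                raise ConfigError(
                    f"{path}: schedule entry {i} missing keys {sorted(missing)}"
                )
            events.append(DisturbanceEvent(
                float(ev["time"]), str(ev["parameter"]), float(ev["value"])))
        schedule = DisturbanceSchedule(tuple(events))

    tol_doc = doc.get("tolerances", {}) or {}
    unknown = set(tol_doc) - _TOL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown tolerance keys {sorted(unknown)}")
    for key, value in tol_doc.items():
        if not float(value) > 0:
            raise ConfigError(f"{path}: tolerance {key!r} must be positive")
    options = dataclasses.replace(
        SimOptions(), **{k: float(v) for k, v in tol_doc.items()}
    )

    flags_doc = doc.get("flags", {}) or {}
    unknown = set(flags_doc) - _FLAG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown flags {sorted(unknown)}")

    if "regulator" in doc and doc["regulator"] is not None:
        unknown = set(doc["regulator"]) - _REGULATOR_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown regulator keys {sorted(unknown)}")

    return RunConfig(
        scenario=doc.get("scenario"),
        network_file=doc.get("network_file"),
        regulator=doc.get("regulator"),
        t_end=float(doc.get("t_end", 500.0)),
        schedule=schedule,
        parameter_overrides={
            str(k): float(v)
            for k, v in (doc.get("parameter_overrides") or {}).items()
        },
        options=options,
        output_dir=str(doc.get("output_dir", "results")),
        rpa=bool(flags_doc.get("rpa", False)),
        degradation=bool(flags_doc.get("degradation", False)),
        scan=bool(flags_doc.get("scan", False)),
    )


# ---------------------------------------------------------------------------
# reports


def trajectories_frame(result: SimulationResult) -> pd.DataFrame:
    """Tidy (time, species, concentration_nM) table."""
    frames = [
        pd.DataFrame({
            "time": result.times,
            "species": name,
            "concentration_nM": series,
        })
        for name, series in result.trajectories.items()
    ]
    if not frames:
        return pd.DataFrame(columns=["time", "species", "concentration_nM"])
    return pd.concat(frames, ignore_index=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_report(
    result: SimulationResult | None,
    reports: dict | None,
    out_dir: str | Path,
    stem: str = "run",
) -> list[Path]:
    """Write trajectories CSV + JSON summary; returns the paths written.

    ``reports`` may hold any JSON-serializable extras (objective results,
    stability reports, resolved parameter tables); dataclasses and numpy
    scalars/arrays are converted.  Numbers are formatted with 12 significant
    digits so identical runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / f"{stem}_trajectories.csv"
    frame = (trajectories_frame(result) if result is not None
             else pd.DataFrame(columns=["time", "species", "concentration_nM"]))
    frame.to_csv(csv_path, index=False, float_format="%.12g")
    written.append(csv_path)

    summary: dict = {}
    if result is not None:
        summary["steady_state_nM"] = result.steady_state
        summary["converged"] = result.converged
        summary["residual_nM_per_min"] = result.residual
        summary["final_parameters"] = result.final_parameters
        summary["events_applied"] = [
            {"time": e.time, "parameter": e.parameter, "value": e.new_value}
            for e in result.events_applied
        ]
        summary["clip_incidents"] = result.clip_incidents
    if reports:
        summary.update(_jsonify(reports))
    json_path = out / f"{stem}_summary.json"
    json_path.write_text(json.dumps(_jsonify(summary), indent=2, sort_keys=True))
    written.append(json_path)
    return written
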