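"""Configuration loading, session (de)serialization and settings tables.

All artifacts are plain text with stable field ordering: run configuration
as YAML/JSON (schema-validated, unknown keys rejected), session logs as
versioned JSON, stimulation-setting tables as CSV in the configuration
dialect (``"E1: -70%, E2, E3, E4: -10%"``).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from dbsteer.lead import (
    ExplorationPoint,
    StimSetting,
    format_configuration,
    parse_configuration,
    setting_from_percents,
)
from dbsteer.optimizer import AlgorithmConfig, SessionRecord, SessionStep
from dbsteer.scoring import SymptomAssessment, WeightedScoreSpec

SESSION_SCHEMA_VERSION = 1

SETTINGS_COLUMNS = [
    "subject",
    "hemisphere",
    "arm",
    "amplitude_mA",
    "frequency_Hz",
    "pulse_width_us",
    "electrode_configuration",
    "stimulation_mode",
]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration: algorithm parameters plus patient source."""

    algorithm: AlgorithmConfig = dataclasses.field(default_factory=AlgorithmConfig)
    patient_seed: int = 0
    patient_preset: str = "clinical"
    patient_file: str | None = None
    verbosity: int = 1


_ALGO_FIELDS = {f.name for f in dataclasses.fields(AlgorithmConfig)}
_RUN_FIELDS = {"algorithm", "patient_seed", "patient_preset", "patient_file", "verbosity"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing keys fall back to documented defaults (130 Hz, 60 us pulse
    width, 30 s wash-in); unknown keys are rejected with a list of the
    offending names.
    """
    text = Path(path).read_text(encoding="utf-8")
    payload = yaml.safe_load(text) if text.strip() else {}
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = sorted(set(payload) - _RUN_FIELDS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {unknown}")
    algo_payload = payload.get("algorithm", {}) or {}
    if not isinstance(algo_payload, dict):
        raise ConfigError("'algorithm' must be a mapping")
    unknown = sorted(set(algo_payload) - _ALGO_FIELDS)
    if unknown:
        raise ConfigError(f"unknown algorithm keys: {unknown}")
    for key in ("predefined_ring_points", "predefined_directional_points"):
        if key in algo_payload:
            algo_payload[key] = tuple(tuple(p) for p in algo_payload[key])
    try:
        algorithm = AlgorithmConfig(**algo_payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid algorithm configuration: {exc}") from exc
    kwargs = {k: v for k, v in payload.items() if k != "algorithm"}
    if "patient_preset" in kwargs and kwargs["patient_preset"] not in (
        "easy",
        "clinical",
        "adversarial",
    ):
        raise ConfigError(f"unknown patient preset {kwargs['patient_preset']!r}")
    return RunConfig(algorithm=algorithm, **kwargs)


# ---------------------------------------------------------------------------
# Session JSON
# ---------------------------------------------------------------------------


def _point_to_dict(point: ExplorationPoint) -> dict:
    return {"stage": point.stage, "coord1": point.coord1, "amplitude": point.amplitude}


def _setting_to_dict(setting: StimSetting) -> dict:
    return {
        "amplitude": setting.amplitude,
        "fractions": list(setting.fractions),
        "frequency": setting.frequency,
        "pulse_width": setting.pulse_width,
        "mode": setting.mode,
    }


def _step_to_dict(step: SessionStep) -> dict:
    return {
        "index": step.index,
        "stage": step.stage,
        "point": _point_to_dict(step.point),
        "setting": _setting_to_dict(step.setting),
        "scores": dict(sorted(step.scores.items())),
        "total": step.total,
        "side_effect": step.side_effect,
        "timestamp_s": step.timestamp_s,
    }


def _step_from_dict(payload: dict) -> SessionStep:
    return SessionStep(
        index=payload["index"],
        stage=payload["stage"],
        point=ExplorationPoint(**payload["point"]),
        setting=StimSetting(
            amplitude=payload["setting"]["amplitude"],
            fractions=tuple(payload["setting"]["fractions"]),
            frequency=payload["setting"]["frequency"],
            pulse_width=payload["setting"]["pulse_width"],
            mode=payload["setting"]["mode"],
        ),
        scores=dict(payload["scores"]),
        total=payload["total"],
        side_effect=payload["side_effect"],
        timestamp_s=payload["timestamp_s"],
    )


def session_to_dict(record: SessionRecord) -> dict:
    return {
        "schema_version": SESSION_SCHEMA_VERSION,
        "spec": {
            "symptoms": [dataclasses.asdict(a) for a in record.spec.symptoms],
            "raw_weights": list(record.spec.raw_weights),
            "normalized_weights": list(record.spec.normalized_weights),
        },
        "config": {
            **dataclasses.asdict(record.config),
            "predefined_ring_points": [
                list(p) for p in record.config.predefined_ring_points
            ],
            "predefined_directional_points": [
                list(p) for p in record.config.predefined_directional_points
            ],
        },
        "steps": [_step_to_dict(s) for s in record.steps],
        "stage_transitions": [list(t) for t in record.stage_transitions],
        "converged": dict(record.converged),
        "best_per_stage": {
            stage: step.index for stage, step in record.best_per_stage.items()
        },
    }


def session_from_dict(payload: dict) -> SessionRecord:
    version = payload.get("schema_version")
    if version != SESSION_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported session schema version {version!r} "
            f"(expected {SESSION_SCHEMA_VERSION})"
        )
    spec = WeightedScoreSpec(
        symptoms=tuple(SymptomAssessment(**a) for a in payload["spec"]["symptoms"]),
        raw_weights=tuple(payload["spec"]["raw_weights"]),
        normalized_weights=tuple(payload["spec"]["normalized_weights"]),
    )
    config_payload = dict(payload["config"])
    for key in ("predefined_ring_points", "predefined_directional_points"):
        config_payload[key] = tuple(tuple(p) for p in config_payload[key])
    config = AlgorithmConfig(**config_payload)
    record = SessionRecord(spec=spec, config=config)
    record.steps = [_step_from_dict(s) for s in payload["steps"]]
    record.stage_transitions = [tuple(t) for t in payload["stage_transitions"]]
    record.converged = dict(payload["converged"])
    by_index = {s.index: s for s in record.steps}
    record.best_per_stage = {
        stage: by_index[idx] for stage, idx in payload["best_per_stage"].items()
    }
    return record


def write_session(record: SessionRecord, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(session_to_dict(record), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_session(path) -> SessionRecord:
    with open(path, encoding="utf-8") as fh:
        return session_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Settings tables (CSV dialect)
# ---------------------------------------------------------------------------


def read_settings_table(path) -> pd.DataFrame:
    """Read a stimulation-settings CSV and attach parsed settings.

    The returned frame carries a ``setting`` column of
    :class:`~dbsteer.lead.StimSetting` objects built from each row.
    """
    frame = pd.read_csv(path)
    missing = [c for c in SETTINGS_COLUMNS if c not in frame.columns and c != "arm"]
    if missing:
        raise ValueError(f"settings table missing columns: {missing}")
    frame = frame.copy()
    frame["setting"] = [
        setting_from_percents(
            parse_configuration(row.electrode_configuration),
            amplitude=row.amplitude_mA,
            frequency=row.frequency_Hz,
            pulse_width=row.pulse_width_us,
            mode=row.stimulation_mode,
        )
        for row in frame.itertuples()
    ]
    return frame


def write_settings_table(frame: pd.DataFrame, path) -> None:
    """Write a settings table, regenerating the configuration strings."""
    out = frame.copy()
    if "setting" in out.columns:
        out["electrode_configuration"] = [
            format_configuration(s) for s in out["setting"]
        ]
        out = out.drop(columns=["setting"])
    out.to_csv(path, index=False)


def load_reference_settings() -> pd.DataFrame:
    """Bundled example cohort of paired conventional vs algorithm settings."""
    with resources.files("dbsteer.data").joinpath("reference_settings.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return read_settings_table(fh)
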