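"""Configuration loading/serialization, result writers and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .outcomes import IncrementalResult, StrategyResult
from .parameters import ParameterSet

PathLike = Union[str, Path]

BASE_CASE_RESOURCE = "base_case.yaml"


class ConfigError(ValueError):
    """Raised for invalid configuration files, with field locations."""


def _format_validation_error(exc: ValidationError, source: str) -> str:
    lines = [f"invalid configuration {source}:"]
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "\n".join(lines)


def parameter_set_from_dict(data: dict, source: str = "<dict>") -> ParameterSet:
    try:
        return ParameterSet.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc, source)) from exc


def load_config(path: PathLike) -> ParameterSet:
    """Read and schema-validate a YAML (or JSON) parameter file.

    Validation failures raise :class:`ConfigError` naming the offending
    field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parameter_set_from_dict(data, str(path))


def parameter_set_to_dict(params: ParameterSet) -> dict:
    return params.model_dump(mode="json")


def save_config(params: ParameterSet, path: PathLike) -> None:
    """Serialize a parameter set to YAML; loading it back reproduces the
    same values exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameter_set_to_dict(params), fh, sort_keys=False)


def base_case_path() -> Path:
    return Path(str(resources.files("afcea").joinpath("data", BASE_CASE_RESOURCE)))


def load_base_case() -> ParameterSet:
    """The bundled base-case configuration."""
    text = resources.files("afcea").joinpath("data", BASE_CASE_RESOURCE).read_text()
    return parameter_set_from_dict(yaml.safe_load(text), BASE_CASE_RESOURCE)


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def results_frame(results: Sequence[StrategyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = r.as_dict()
        row.pop("expected_events", None)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    results: Sequence[StrategyResult],
    incremental: Optional[IncrementalResult],
    out_dir: PathLike,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(out / "strategy_results.csv", index=False)
    payload = {"strategies": [r.as_dict() for r in results]}
    if incremental is not None:
        payload["incremental"] = incremental.as_dict()
    with open(out / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly."""

    command: str
    config_path: str
    config_sha256: str
    scenario: Optional[str]
    seed: Optional[int]
    n_iterations: Optional[int]
    output_dir: str
    tool_version: str
    timestamp: str

    def write(self, out_dir: PathLike) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return path


def make_manifest(
    command: str,
    config_path: PathLike,
    out_dir: PathLike,
    scenario: Optional[str] = None,
    seed: Optional[int] = None,
    n_iterations: Optional[int] = None,
) -> RunManifest:
    from . import __version__

    digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    return RunManifest(
        command=command,
        config_path=str(config_path),
        config_sha256=digest,
        scenario=scenario,
        seed=seed,
        n_iterations=n_iterations,
        output_dir=str(out_dir),
        tool_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
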