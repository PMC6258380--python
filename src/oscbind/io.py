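"""Configuration parsing, result serialization, and run manifests.

A run is configured by one YAML file with ``model:``, ``protocol:`` and
``simulate:`` blocks.  Results are written as delimited text with a JSON
sidecar echoing the full configuration and carrying content hashes, so any
result file can be regenerated bit-identically from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import OscillationSummary, PhasePattern, frequencies
from .model import Trajectory, OUTPUT_STEP, RTOL, ATOL
from .params import (
    ModelParameters,
    ParameterError,
    StimulusProtocol,
    StimulusPulse,
    preset,
)

__all__ = [
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_pattern_report",
    "write_results",
    "RunManifest",
]

_MODEL_KEYS = set(ModelParameters().to_dict())
_PULSE_KEYS = {"target", "amplitude", "width", "onset"}
_SIM_KEYS = {"t_end", "output_step", "rtol", "atol", "solver", "initial"}
_SIM_DEFAULTS = {"t_end": 1000.0, "output_step": OUTPUT_STEP, "rtol": RTOL,
                 "atol": ATOL, "solver": "dopri", "initial": "baseline"}


def load_config(path) -> tuple[ModelParameters, StimulusProtocol, dict]:
    """Parse a YAML run configuration.

    ``model:`` takes either ``preset: <name>`` plus overrides, or explicit
    fields; ``protocol:`` is a list of pulse mappings (targets are 1-based
    in configs); ``simulate:`` holds solver options.  Unknown keys are
    rejected by name.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"model", "protocol", "simulate"}
    if unknown:
        raise ParameterError(f"unknown top-level config keys: {sorted(unknown)}")

    mraw = dict(raw.get("model") or {})
    name = mraw.pop("preset", None)
    bad = set(mraw) - _MODEL_KEYS
    if bad:
        raise ParameterError(f"unknown model keys: {sorted(bad)}")
    params = preset(name, **mraw) if name else ModelParameters(**mraw)

    pulses = []
    for i, praw in enumerate(raw.get("protocol") or []):
        bad = set(praw) - _PULSE_KEYS
        if bad:
            raise ParameterError(f"unknown pulse keys in entry {i}: {sorted(bad)}")
        missing = _PULSE_KEYS - set(praw)
        if missing:
            raise ParameterError(f"pulse entry {i} missing keys: {sorted(missing)}")
        pulses.append(StimulusPulse(int(praw["target"]) - 1,
                                    float(praw["amplitude"]),
                                    float(praw["width"]),
                                    float(praw["onset"])))
    protocol = StimulusProtocol(tuple(pulses))
    protocol.validate(params.N)

    sraw = dict(raw.get("simulate") or {})
    bad = set(sraw) - _SIM_KEYS
    if bad:
        raise ParameterError(f"unknown simulate keys: {sorted(bad)}")
    options = {**_SIM_DEFAULTS, **sraw}
    return params, protocol, options


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    N = traj.N
    cols = {"t": traj.times}
    for name, arr in (("u", traj.u), ("v", traj.v), ("n", traj.n)):
        for j in range(N):
            cols[f"{name}{j + 1}"] = arr[:, j]
    return pd.DataFrame(cols)


def write_trajectory(traj: Trajectory, path, float_format: str = "%.10g") -> Path:
    """CSV with header t,u1..uN,v1..vN,n1..nN plus a JSON metadata sidecar."""
    path = Path(path)
    trajectory_frame(traj).to_csv(path, index=False, float_format=float_format)
    meta = {
        "model": traj.params.to_dict(),
        "protocol": [asdict(p) for p in traj.protocol.pulses],
        "output_step": traj.dt,
        "sha256": _sha256(path),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    params = ModelParameters(**meta["model"])
    proto = StimulusProtocol(tuple(StimulusPulse(**p) for p in meta["protocol"]))
    N = params.N
    return Trajectory(
        times=df["t"].to_numpy(),
        u=df[[f"u{j + 1}" for j in range(N)]].to_numpy(),
        v=df[[f"v{j + 1}" for j in range(N)]].to_numpy(),
        n=df[[f"n{j + 1}" for j in range(N)]].to_numpy(),
        params=params, protocol=proto,
    )


def pattern_row(pattern: PhasePattern,
                summaries: list[OscillationSummary] | None = None) -> dict:
    row = {
        "label": pattern.label,
        "groups": pattern.partition,
        "T": pattern.period,
    }
    try:
        pop_f, inter_f = frequencies(pattern)
    except Exception:
        pop_f = inter_f = float("nan")
    if summaries is not None:
        for s in summaries:
            row[f"Ta{s.population + 1}"] = s.t_active
            row[f"Tq{s.population + 1}"] = s.t_quiet
    row["population_frequency_Hz"] = pop_f
    row["interpopulation_frequency_Hz"] = inter_f
    return row


def write_pattern_report(rows: list[dict], path) -> Path:
    """One line per trajectory: label, groups, periods, phase durations,
    frequencies."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
    return path


@dataclass
class RunManifest:
    """Config echo plus content hashes of everything a run wrote."""

    config: dict
    outputs: dict[str, str]           # filename -> sha256
    version: str = "0.1.0"

    def write(self, directory) -> Path:
        out = Path(directory) / "manifest.json"
        out.write_text(json.dumps(
            {"version": self.version, "config": self.config,
             "outputs": self.outputs}, indent=1, sort_keys=True))
        return out


def write_results(objects: dict, directory, config: dict | None = None) -> RunManifest:
    """Write a mapping name -> object (Trajectory, pattern-report rows,
    DataFrame, array, or JSON-serialisable) and a manifest alongside."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for name, obj in objects.items():
        if isinstance(obj, Trajectory):
            f = write_trajectory(obj, directory / f"{name}.csv")
        elif isinstance(obj, pd.DataFrame):
            f = directory / f"{name}.csv"
            obj.to_csv(f, index=False, float_format="%.10g")
        elif isinstance(obj, np.ndarray):
            f = directory / f"{name}.csv"
            np.savetxt(f, obj, delimiter=",", fmt="%.10g")
        elif isinstance(obj, list) and obj and isinstance(obj[0], dict):
            f = write_pattern_report(obj, directory / f"{name}.csv")
        else:
            f = directory / f"{name}.json"
            f.write_text(json.dumps(obj, indent=1, default=str))
        hashes[f.name] = _sha256(f)
    manifest = RunManifest(config=config or {}, outputs=hashes)
    manifest.write(directory)
    return manifest
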