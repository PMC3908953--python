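"""Result serialization: CSV time series and JSON reports.

Time series go to CSV with a ``#``-prefixed metadata header (resolved SI
parameters, solver settings, verdict) followed by one row per time point
carrying both SI and clinical-unit columns. Reports (steady states, maps,
sensitivity) go to JSON with provenance: a config hash, the solver
tolerances and a determinism note (the model has no random elements, so
identical configs give byte-identical output).
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .engine import ABS_TOLERANCES, REL_TOLERANCE, SteadyStateResult, TimeSeries
from .state import STATE_NAMES
from .units import DYN_PER_CM2_TO_PA, MMHG_TO_PA, UL_PER_S_TO_M3_PER_S, UM_TO_M

__all__ = ["write_timeseries", "read_timeseries", "write_report", "config_hash"]

#: clinical-unit companion columns added to time-series output
_CLINICAL = {
    "P": ("P_mmHg", 1.0 / MMHG_TO_PA),
    "Q": ("Q_uL_s", 1.0 / UL_PER_S_TO_M3_PER_S),
    "tau": ("tau_dyn_cm2", 1.0 / DYN_PER_CM2_TO_PA),
    "r_i": ("r_i_um", 1.0 / UM_TO_M),
    "r_islack": ("r_islack_um", 1.0 / UM_TO_M),
    "l": ("l_um", 1.0 / UM_TO_M),
    "h": ("h_um", 1.0 / UM_TO_M),
}


def config_hash(resolved: dict[str, Any]) -> str:
    """Stable short hash of a resolved configuration mapping."""
    blob = json.dumps(resolved, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _meta_lines(metadata: dict[str, Any]) -> list[str]:
    lines = ["# arterywall time series",
             "# units: SI columns unsuffixed; *_mmHg, *_uL_s, *_dyn_cm2, *_um are clinical",
             f"# rtol: {REL_TOLERANCE}  atol: {ABS_TOLERANCES.tolist()}"]
    for key, value in metadata.items():
        lines.append(f"# {key}: {json.dumps(value, sort_keys=True, default=float)}")
    return lines


def write_timeseries(
    ts: TimeSeries, path: str | Path, metadata: dict[str, Any] | None = None
) -> None:
    """Write a trajectory as CSV with a metadata header."""
    frame = ts.frame.copy()
    for col, (name, factor) in _CLINICAL.items():
        if col in frame:
            frame[name] = frame[col] * factor
    buf = _io.StringIO()
    meta = {"verdict": ts.verdict, "reason": ts.reason, **(metadata or {})}
    buf.write("\n".join(_meta_lines(meta)) + "\n")
    frame.to_csv(buf, index=False)
    try:
        Path(path).write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"failed to write time series to {path}: {exc}") from exc


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read back a CSV written by :func:`write_timeseries`."""
    text = Path(path).read_text()
    verdict, reason = "completed", ""
    for line in text.splitlines():
        if line.startswith("# verdict:"):
            verdict = json.loads(line.split(":", 1)[1])
        elif line.startswith("# reason:"):
            reason = json.loads(line.split(":", 1)[1])
    frame = pd.read_csv(_io.StringIO(text), comment="#")
    return TimeSeries(frame=frame, verdict=verdict, reason=reason)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, SteadyStateResult):
        return {
            "state": dict(zip(STATE_NAMES, obj.state.as_array().tolist())),
            "inputs": {"P": obj.inputs.P, "Q": obj.inputs.Q,
                       "CON": obj.inputs.CON, "DIL": obj.inputs.DIL},
            "verdict": obj.verdict,
            "residual_norm": obj.residual_norm,
            "derived": {k: float(v) for k, v in obj.derived.items()},
        }
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="table"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(
    results: Any, path: str | Path, resolved_config: dict[str, Any] | None = None
) -> None:
    """Write results as JSON with provenance.

    The report carries the resolved configuration and its hash, the solver
    tolerances and a determinism note. For a divergent steady-state result
    the serialized object still contains the verdict and last valid state.
    """
    resolved = resolved_config or {}
    doc = {
        "provenance": {
            "config": _jsonable(resolved),
            "config_hash": config_hash(resolved),
            "rtol": REL_TOLERANCE,
            "atol": ABS_TOLERANCES.tolist(),
            "determinism": "model is fully deterministic; no seeds involved",
        },
        "results": _jsonable(results),
    }
    try:
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write report to {path}: {exc}") from exc
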