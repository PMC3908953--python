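"""Run configuration, validation and built-in scenarios.

Config files are YAML with four optional sections::

    parameters: {l_ref: 85e-6, ecf: 0.8}     # SI overrides by name
    variant: GROWTH
    protocol:
      units: clinical          # or "si" (default)
      segments:
        - {t_start: 0, P: 80, Q: 0.25, CON: 0, DIL: 0}
    solver: {rtol: 1.0e-5, t_end: 1.0e8}
    guards: {collapse_frac: 0.01, runaway_factor: 20}

With ``units: clinical`` pressures are mmHg, flows µL/s and CON/DIL
dyn/cm²-equivalents; conversion to SI happens here and nowhere deeper.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import DEFAULT_HORIZON, Guards, REL_TOLERANCE
from .params import DEFAULT_PARAMETERS, ModelParameters, PARAMETER_NAMES
from .regulation import Inputs, StimulusProtocol, VARIANT_NAMES
from .units import DYN_PER_CM2_TO_PA, MMHG_TO_PA, UL_PER_S_TO_M3_PER_S

__all__ = ["DEFAULT_INPUTS", "RunConfig", "load_config", "builtin_scenarios"]

#: default input conditions: 80 mmHg, 0.25 µL/s, no vasoactive agents
DEFAULT_INPUTS = Inputs(P=80.0 * MMHG_TO_PA, Q=0.25 * UL_PER_S_TO_M3_PER_S)


@dataclass
class RunConfig:
    """Validated configuration for one run."""

    parameters: ModelParameters = DEFAULT_PARAMETERS
    variant: str = "GROWTH"
    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol([(0.0, DEFAULT_INPUTS)])
    )
    rtol: float = REL_TOLERANCE
    t_end: float = DEFAULT_HORIZON
    guards: Guards = Guards()
    scenario: str | None = None

    def resolved_parameters(self) -> dict[str, float]:
        """All parameters in SI, for the run log / report provenance."""
        return self.parameters.as_dict()


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _warn_units(inp: Inputs) -> None:
    # range heuristics: SI pressures are kPa-scale, clinical mmHg-scale
    if 0.0 < inp.P < 500.0:
        warnings.warn(
            f"pressure {inp.P} Pa is suspiciously low for SI units — "
            "did you mean mmHg (set protocol.units: clinical)?",
            stacklevel=3,
        )
    if inp.Q > 1e-3:
        warnings.warn(
            f"flow {inp.Q} m³/s is suspiciously high for SI units — "
            "did you mean µL/s (set protocol.units: clinical)?",
            stacklevel=3,
        )


def _parse_protocol(section: dict) -> StimulusProtocol:
    _check_keys(section, {"units", "segments", "allow_negative_agents"}, "protocol")
    units = section.get("units", "si")
    if units not in ("si", "clinical"):
        raise ValueError(f"protocol.units must be 'si' or 'clinical', got {units!r}")
    fp, fq, fs = (
        (MMHG_TO_PA, UL_PER_S_TO_M3_PER_S, DYN_PER_CM2_TO_PA)
        if units == "clinical"
        else (1.0, 1.0, 1.0)
    )
    segments = []
    for seg in section.get("segments", [{"t_start": 0.0}]):
        _check_keys(seg, {"t_start", "P", "Q", "CON", "DIL"}, "protocol.segments")
        inp = Inputs(
            P=seg.get("P", 80.0 if units == "clinical" else DEFAULT_INPUTS.P) * fp,
            Q=seg.get("Q", 0.25 if units == "clinical" else DEFAULT_INPUTS.Q) * fq,
            CON=seg.get("CON", 0.0) * fs,
            DIL=seg.get("DIL", 0.0) * fs,
        )
        if units == "si":
            _warn_units(inp)
        segments.append((float(seg.get("t_start", 0.0)), inp))
    return StimulusProtocol(
        segments, allow_negative_agents=section.get("allow_negative_agents", False)
    )


def parse_config(doc: dict | None) -> RunConfig:
    """Build a validated RunConfig from a parsed YAML document."""
    doc = doc or {}
    _check_keys(doc, {"parameters", "variant", "protocol", "solver", "guards"},
                "config")
    overrides = doc.get("parameters", {}) or {}
    _check_keys(overrides, set(PARAMETER_NAMES), "parameters")
    params = DEFAULT_PARAMETERS.replace(
        **{k: float(v) for k, v in overrides.items()}
    )

    variant = str(doc.get("variant", "GROWTH")).upper()
    if variant not in VARIANT_NAMES:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {', '.join(VARIANT_NAMES)}"
        )

    protocol = (
        _parse_protocol(doc["protocol"])
        if "protocol" in doc and doc["protocol"]
        else StimulusProtocol([(0.0, DEFAULT_INPUTS)])
    )

    solver = doc.get("solver", {}) or {}
    _check_keys(solver, {"rtol", "t_end"}, "solver")
    guards_doc = doc.get("guards", {}) or {}
    _check_keys(guards_doc, {"collapse_frac", "runaway_factor"}, "guards")

    return RunConfig(
        parameters=params,
        variant=variant,
        protocol=protocol,
        rtol=float(solver.get("rtol", REL_TOLERANCE)),
        t_end=float(solver.get("t_end", DEFAULT_HORIZON)),
        guards=Guards(**{k: float(v) for k, v in guards_doc.items()}),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; defaults fill the gaps."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is not None and not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    return parse_config(doc)


def builtin_scenarios() -> dict[str, RunConfig]:
    """Ready-to-run fixtures for the model's canonical experiments."""
    p100 = dataclasses.replace(DEFAULT_INPUTS, P=100.0 * MMHG_TO_PA)
    q2x = dataclasses.replace(DEFAULT_INPUTS, Q=0.5 * UL_PER_S_TO_M3_PER_S)
    return {
        "pressure_radius_curves": RunConfig(scenario="pressure_radius_curves"),
        "pressure_step": RunConfig(
            scenario="pressure_step",
            protocol=StimulusProtocol([(0.0, p100)]),
        ),
        "flow_step": RunConfig(
            scenario="flow_step",
            protocol=StimulusProtocol([(0.0, q2x)]),
        ),
        "response_map": RunConfig(scenario="response_map"),
        "sensitivity": RunConfig(scenario="sensitivity"),
        "dilator_scan": RunConfig(scenario="dilator_scan"),
    }
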