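"""Computational experiments: pressure-radius curves, step responses,
steady-state maps, parameter sensitivity and the dilator-instability scan.

These reproduce the standard in-silico protocols for a single resistance
segment: quasi-static pressure-radius relations around the working point,
step changes of pressure or flow for each model variant, steady-state
response maps over one-at-a-time input grids, a central-difference
sensitivity matrix of nine steady-state outputs to four key parameters,
and a dilator scan that locates the instability threshold where
shear-plus-dilator stimulation can no longer be balanced.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    SteadyStateResult,
    TimeSeries,
    find_steady_state,
    integrate,
    steady_state_outputs,
    default_steady_state,
)
from .mechanics import equilibrium_strain, derive_geometry
from .params import ModelParameters, DEFAULT_PARAMETERS
from .regulation import Inputs, StimulusProtocol, make_variant
from .state import DegenerateGeometryError, VesselState
from .units import MMHG_TO_PA, UL_PER_S_TO_M3_PER_S, to_dyn_cm2

__all__ = [
    "PressureRadiusCurve",
    "SensitivityMatrix",
    "pressure_radius_curves",
    "step_response",
    "steady_state_map",
    "radius_reserve",
    "tension_match",
    "sensitivity_matrix",
    "dilator_shear_sum_scan",
    "SENSITIVITY_OUTPUTS",
    "SENSITIVITY_PARAMETERS",
]

#: the nine reported steady-state outputs, in presentation order
SENSITIVITY_OUTPUTS = (
    "r_i", "tone", "l", "r_islack", "wcsa", "sigma", "tau",
    "tension_match", "radius_reserve",
)

#: the four parameters probed by the sensitivity analysis
SENSITIVITY_PARAMETERS = ("ecf", "l_ref", "beta_strain", "sigma_ref")


@dataclass
class PressureRadiusCurve:
    """Quasi-static pressure-radius relation at fixed structure.

    mode: 'frozen' pins tone at the baseline working-point value,
    'passive' at 0 and 'active' at 1. NaN entries mark pressures without
    a mechanical equilibrium at that tone/structure.
    """

    mode: str
    P: np.ndarray
    r_i: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"P_Pa": self.P, "P_mmHg": self.P / MMHG_TO_PA, "r_i_m": self.r_i}
        )


def pressure_radius_curves(
    baseline: SteadyStateResult,
    P_grid: np.ndarray,
    mode: str = "frozen",
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> PressureRadiusCurve:
    """Pressure-radius relation with adaptation frozen at the baseline.

    Structure (span, slack radius, wall area) is fixed at the baseline
    steady state; tone is pinned per `mode`. Each point is the strain of
    quasi-static mechanical equilibrium, continued from the previous
    pressure so the curve follows one branch through the myogenic regime.
    """
    st = baseline.state
    if mode == "frozen":
        tone = st.tone
    elif mode == "passive":
        tone = 0.0
    elif mode == "active":
        tone = 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    P_grid = np.asarray(P_grid, dtype=float)
    order = np.argsort(P_grid)
    r_i = np.full(P_grid.shape, np.nan)
    guess = st.eps
    for k in order:
        try:
            eps = equilibrium_strain(
                P_grid[k], tone, st.span, st.r_mslack, st.wcsa, params, guess=guess
            )
        except DegenerateGeometryError:
            continue
        guess = eps
        r_i[k] = derive_geometry(
            VesselState(eps, tone, st.span, st.r_mslack, st.wcsa)
        ).r_i
    return PressureRadiusCurve(mode=mode, P=P_grid, r_i=r_i)


def step_response(
    variant: str,
    step: dict[str, float],
    t_end: float = 1e8,
    params: ModelParameters = DEFAULT_PARAMETERS,
    state0: VesselState | None = None,
) -> TimeSeries:
    """Response of a named variant to a step in one or more inputs at t=0.

    The run starts from the default-conditions equilibrium (shared by all
    variants, since every rate law vanishes there) and applies the stepped
    inputs from t=0 on a log-spaced evaluation grid. `step` maps input
    names ('P', 'Q', 'CON', 'DIL', SI units) to their post-step values.
    """
    from .config import DEFAULT_INPUTS

    unknown = set(step) - {"P", "Q", "CON", "DIL"}
    if unknown:
        raise ValueError(f"unknown step input(s): {sorted(unknown)}")
    after = Inputs(
        P=step.get("P", DEFAULT_INPUTS.P),
        Q=step.get("Q", DEFAULT_INPUTS.Q),
        CON=step.get("CON", DEFAULT_INPUTS.CON),
        DIL=step.get("DIL", DEFAULT_INPUTS.DIL),
    )
    if state0 is None:
        state0 = default_steady_state(params)
    mask = make_variant(variant)
    protocol = StimulusProtocol([(0.0, after)])
    return integrate(state0, protocol, mask, t_end=t_end, params=params)


def radius_reserve(
    ss: SteadyStateResult, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Fully dilated over actual inner radius (>= 1) at a stable state."""
    if not ss.stable:
        raise ValueError("radius reserve requires a stable steady state")
    derived = ss.derived or steady_state_outputs(ss, params)
    return derived["radius_reserve"]


def tension_match(
    ss: SteadyStateResult, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Optimal-active over passive-at-100-mmHg inner radius at a stable state."""
    if not ss.stable:
        raise ValueError("tension match requires a stable steady state")
    derived = ss.derived or steady_state_outputs(ss, params)
    return derived["tension_match"]


#: default one-at-a-time input grids for the steady-state response map
DEFAULT_MAP_GRIDS: dict[str, np.ndarray] = {
    "P": np.array([40, 60, 80, 100, 120, 140, 160]) * MMHG_TO_PA,
    "Q": np.array([0.0625, 0.125, 0.25, 0.5, 1.0]) * UL_PER_S_TO_M3_PER_S,
    "CON": np.array([0.0, 5e3, 10e3, 20e3, 30e3]),
    "DIL": np.array([0.0, 0.5, 1.0, 2.0, 3.0]),
}


def steady_state_map(
    variants: tuple[str, ...] = ("MECH", "FUNCT", "PLAST", "REMOD", "GROWTH",
                                 "PLASTKO", "REMODKO"),
    input_grids: dict[str, np.ndarray] | None = None,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Steady states (or instability verdicts) per variant and input.

    Each input is varied one-at-a-time about the defaults. The tidy result
    has one row per (variant, input, value): the verdict, the nine outputs
    at stable states, and their relative deviation from that variant's
    default-conditions steady state.
    """
    from .config import DEFAULT_INPUTS

    grids = DEFAULT_MAP_GRIDS if input_grids is None else input_grids
    rows = []
    for variant in variants:
        mask = make_variant(variant)
        base = find_steady_state(DEFAULT_INPUTS, mask, params=params)
        base_out = base.derived if base.stable else {}
        for input_name, grid in grids.items():
            for value in grid:
                inp = Inputs(
                    P=value if input_name == "P" else DEFAULT_INPUTS.P,
                    Q=value if input_name == "Q" else DEFAULT_INPUTS.Q,
                    CON=value if input_name == "CON" else DEFAULT_INPUTS.CON,
                    DIL=value if input_name == "DIL" else DEFAULT_INPUTS.DIL,
                )
                ss = find_steady_state(inp, mask, params=params)
                row = {
                    "variant": variant,
                    "input": input_name,
                    "value": float(value),
                    "verdict": ss.verdict,
                }
                if ss.stable:
                    for name in SENSITIVITY_OUTPUTS:
                        row[name] = ss.derived[name]
                        if base_out.get(name):
                            row[f"{name}_rel_dev"] = (
                                ss.derived[name] / base_out[name] - 1.0
                            )
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SensitivityMatrix:
    """Relative-change sensitivities of outputs (rows) to parameters
    (columns), as produced by :func:`sensitivity_matrix`."""

    table: pd.DataFrame
    rel_step: float
    unstable: list[tuple[str, float]] = field(default_factory=list)

    def loc(self, output: str, parameter: str) -> float:
        return float(self.table.loc[output, parameter])


def sensitivity_matrix(
    param_names: tuple[str, ...] = SENSITIVITY_PARAMETERS,
    output_names: tuple[str, ...] = SENSITIVITY_OUTPUTS,
    rel_step: float = 0.05,
    params: ModelParameters = DEFAULT_PARAMETERS,
    use_fixed_point: bool = False,
) -> SensitivityMatrix:
    """Central-difference sensitivity of full-model steady-state outputs.

    Each parameter is perturbed by ±rel_step about its default; entries
    are (Δoutput/output) / (Δparameter/parameter). Perturbed runs that do
    not converge are recorded in `unstable` and yield NaN entries.
    `use_fixed_point=True` evaluates steady states by the semi-analytic
    reduction instead of integrate-then-polish (for cross-checks).
    """
    from .config import DEFAULT_INPUTS
    from .engine import solve_growth_fixed_point

    def outputs_for(p: ModelParameters) -> dict | None:
        if use_fixed_point:
            try:
                st = solve_growth_fixed_point(DEFAULT_INPUTS, p)
            except ValueError:
                return None
            ss = SteadyStateResult(
                state=st, inputs=DEFAULT_INPUTS, mask=make_variant("GROWTH"),
                verdict="stable", residual_norm=0.0,
            )
            return steady_state_outputs(ss, p)
        ss = find_steady_state(DEFAULT_INPUTS, make_variant("GROWTH"), params=p)
        return ss.derived if ss.stable else None

    base = outputs_for(params)
    if base is None:
        raise RuntimeError("default steady state did not converge")

    unstable: list[tuple[str, float]] = []
    data = {}
    for pname in param_names:
        v0 = getattr(params, pname)
        col = {}
        hi = outputs_for(params.replace(**{pname: v0 * (1 + rel_step)}))
        lo = outputs_for(params.replace(**{pname: v0 * (1 - rel_step)}))
        if hi is None:
            unstable.append((pname, v0 * (1 + rel_step)))
        if lo is None:
            unstable.append((pname, v0 * (1 - rel_step)))
        for out in output_names:
            if hi is None or lo is None:
                col[out] = float("nan")
            else:
                col[out] = (hi[out] - lo[out]) / base[out] / (2 * rel_step)
        data[pname] = col
    table = pd.DataFrame(data, index=list(output_names))
    return SensitivityMatrix(table=table, rel_step=rel_step, unstable=unstable)


def dilator_shear_sum_scan(
    DIL_grid: np.ndarray | None = None,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Full-model steady-state shear across dilator levels.

    For each dilator level (equipotent shear stress, Pa) the scan reports
    the steady-state wall shear stress, the sum tau + DIL in dyn/cm², and
    the stability verdict. Across the stable range the sum is conserved —
    the tone balance fixes the total shear stimulus — and dilator levels
    beyond that total drive unbounded dilation (runaway). The largest
    stable DIL is the estimated instability threshold (attrs['threshold']).
    """
    if DIL_grid is None:
        DIL_grid = np.arange(0.0, 5.25, 0.25)
    rows = []
    for dil in np.asarray(DIL_grid, dtype=float):
        from .config import DEFAULT_INPUTS

        inp = Inputs(P=DEFAULT_INPUTS.P, Q=DEFAULT_INPUTS.Q, DIL=dil)
        ss = find_steady_state(inp, make_variant("GROWTH"), params=params)
        row = {"DIL": dil, "DIL_dyn_cm2": to_dyn_cm2(dil), "verdict": ss.verdict}
        if ss.stable:
            tau = ss.derived["tau"]
            row["tau"] = tau
            row["tau_dyn_cm2"] = to_dyn_cm2(tau)
            row["sum_dyn_cm2"] = to_dyn_cm2(tau + dil)
        rows.append(row)
    frame = pd.DataFrame(rows)
    stable = frame[frame["verdict"] == "stable"]
    frame.attrs["threshold"] = (
        float(stable["DIL"].max()) if len(stable) else float("nan")
    )
    return frame
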