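"""Stiff time integration, steady-state solving and stability verdicts.

The five processes span time scales from seconds (mechanics) to months
(growth), so trajectories are integrated with an implicit variable-step
method for stiff systems (BDF) at the tolerances the model was designed
for: relative 1e-5 and absolute 1e-5 (strain), 1e-3 (tone, span),
0.01 µm (slack radius) and 1 µm² (wall cross-sectional area).

Steady states are found by integrate-then-polish: a long integration
approaches the attractor (the physiologically meaningful equilibrium even
when unstable manifolds exist elsewhere in state space), then damped
root-finding on the masked derivative brings the residual to solver
precision. Divergent runs are classified as collapse (lumen closing) or
runaway (unbounded dilation) by guard bounds on the internal radius
rather than raising, so parameter sweeps can tabulate instability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .mechanics import (
    derive_geometry,
    equilibrium_strain,
    mean_wall_stress,
)
from .params import ModelParameters, DEFAULT_PARAMETERS
from .regulation import (
    Inputs,
    StimulusProtocol,
    VariantMask,
    hill,
    state_derivative,
)
from .state import DegenerateGeometryError, STATE_NAMES, VesselState

__all__ = [
    "ABS_TOLERANCES",
    "Guards",
    "TimeSeries",
    "SteadyStateResult",
    "integrate",
    "find_steady_state",
    "classify_stability",
    "solve_growth_fixed_point",
    "default_steady_state",
    "lumen_open_at_strain_floor",
]

#: per-component absolute tolerances, also the scales for residual norms
ABS_TOLERANCES = np.array([1e-5, 1e-3, 1e-3, 0.01e-6, 1e-12])

#: default relative tolerance of the stiff integrator
REL_TOLERANCE = 1e-5

#: residual threshold (in scaled units) below which a state counts as stable
RESIDUAL_TOL = 1e-10

#: default integration horizon (s); ~3 years, beyond the slowest (growth)
#: time scale 1/(k_growth·sigma_ref) ≈ 3.3e5 s
DEFAULT_HORIZON = 1e8

#: cap on right-hand-side evaluations per integration; a healthy run needs
#: a few thousand, so hitting this means the trajectory never settles
#: (e.g. sustained vasomotion-like oscillation) and the run is truncated
DEFAULT_RHS_BUDGET = 300_000


class _RhsBudgetExceeded(RuntimeError):
    pass


def mask_horizon(mask: VariantMask) -> float:
    """Integration horizon suited to the slowest active process.

    Frozen processes need no settling time, so e.g. a mechanics+tone
    variant converges (or visibly fails to) within ~3e5 s while the full
    model needs ~1e8 s for structural convergence.
    """
    if mask.growth:
        return DEFAULT_HORIZON
    if mask.remodeling:
        return 3e7
    if mask.plasticity:
        return 3e6
    if mask.tone:
        return 3e5
    return 1e4


@dataclass(frozen=True)
class Guards:
    """Radius guard bounds, relative to the initial internal radius.

    The run terminates with verdict 'collapse' when r_i falls below
    `collapse_frac` times its initial value and 'runaway' when it exceeds
    `runaway_factor` times it. The defaults (1% and 20x) terminate
    divergence quickly without triggering on physiological transients.
    """

    collapse_frac: float = 0.01
    runaway_factor: float = 20.0


@dataclass
class TimeSeries:
    """A trajectory with derived quantities and the applied inputs.

    `frame` has one row per time point: the five state variables, derived
    geometry (r_m, h, r_i, l, r_islack), stresses (sigma, sigma_eq, tau)
    and the inputs (P, Q, CON, DIL). `verdict` records early termination.
    """

    frame: pd.DataFrame
    verdict: str = "completed"
    reason: str = ""

    @property
    def t(self) -> np.ndarray:
        return self.frame["t"].to_numpy()

    def state_at(self, i: int) -> VesselState:
        row = self.frame.iloc[i]
        return VesselState(*(float(row[k]) for k in STATE_NAMES))

    def final_state(self) -> VesselState:
        return self.state_at(-1)


@dataclass
class SteadyStateResult:
    """Converged state (or divergence diagnosis) under constant inputs."""

    state: VesselState
    inputs: Inputs
    mask: VariantMask
    verdict: str  # stable | collapse | runaway | nonconvergent
    residual_norm: float
    derived: dict = field(default_factory=dict)

    @property
    def stable(self) -> bool:
        return self.verdict == "stable"


def lumen_open_at_strain_floor(state: VesselState) -> bool:
    """Whether the lumen stays open over the whole admissible strain range.

    The midwall radius can constrict down to r_mslack (1 + EPS_FLOOR); if
    the wall area is large enough that r_i <= 0 there (r_m² <= wcsa / 4π),
    a constricting transient can close the lumen entirely before the
    slower processes react, and the state lies outside the geometrically
    representable basin of the model.
    """
    from .state import EPS_FLOOR

    r_m_floor = state.r_mslack * (1.0 + EPS_FLOOR)
    return r_m_floor * r_m_floor > state.wcsa / (4.0 * math.pi)


def slack_inner_radius(state: VesselState) -> float:
    """Inner radius of the unloaded (zero-strain) vessel."""
    h_slack = state.wcsa / (2.0 * math.pi * state.r_mslack)
    return state.r_mslack - h_slack / 2.0


def _derived_row(state: VesselState, inputs: Inputs, params: ModelParameters) -> dict:
    geom = derive_geometry(state)
    ws = mean_wall_stress(state, params, P=inputs.P, Q=inputs.Q)
    return {
        "r_m": geom.r_m,
        "h": geom.h,
        "r_i": geom.r_i,
        "l": geom.l,
        "r_islack": slack_inner_radius(state),
        "sigma": ws.sigma,
        "sigma_eq": ws.sigma_eq,
        "tau": ws.tau,
        "P": inputs.P,
        "Q": inputs.Q,
        "CON": inputs.CON,
        "DIL": inputs.DIL,
    }


def _radius_events(r_i0: float, guards: Guards):
    lo = guards.collapse_frac * r_i0
    hi = guards.runaway_factor * r_i0

    def _r_i(y: np.ndarray) -> float:
        eps, _, _, r_mslack, wcsa = y
        r_m = r_mslack * (1.0 + max(eps, -0.5))
        return r_m - wcsa / (2.0 * math.pi * r_m) / 2.0

    def collapse(t, y, *args):
        return _r_i(y) - lo

    def runaway(t, y, *args):
        return hi - _r_i(y)

    collapse.terminal = True
    collapse.direction = -1.0
    runaway.terminal = True
    runaway.direction = -1.0
    return collapse, runaway


def _segment_times(t0: float, t1: float, n: int) -> np.ndarray:
    """Geometric (log-spaced) evaluation grid within one protocol segment."""
    span = t1 - t0
    start = min(1e-2, span / n)
    pts = np.geomspace(start, span, n)
    return np.concatenate(([t0], t0 + pts))


def integrate(
    state0: VesselState,
    protocol: StimulusProtocol,
    mask: VariantMask = VariantMask(),
    t_end: float = DEFAULT_HORIZON,
    params: ModelParameters = DEFAULT_PARAMETERS,
    rtol: float = REL_TOLERANCE,
    atol: np.ndarray | None = None,
    guards: Guards = Guards(),
    n_eval: int = 200,
    max_rhs_evals: int = DEFAULT_RHS_BUDGET,
) -> TimeSeries:
    """Integrate the masked 5-D system under a piecewise-constant protocol.

    Integration restarts at every protocol breakpoint (the inputs are
    discontinuous there). Evaluation points are log-spaced within each
    segment, suiting the model's spread of time scales. Radius guard
    crossings terminate the run with a collapse/runaway verdict; solver
    failures are reported as verdict 'solver_failure'; exceeding the RHS
    evaluation budget (a trajectory that never settles, e.g. sustained
    oscillation) truncates the run with verdict 'truncated'.
    """
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    state0.validate()
    atol = ABS_TOLERANCES if atol is None else np.asarray(atol, dtype=float)

    n_evals = 0

    def rhs(t, y, *args):
        nonlocal n_evals
        n_evals += 1
        if n_evals > max_rhs_evals:
            raise _RhsBudgetExceeded(
                f"RHS evaluation budget {max_rhs_evals} exceeded at t={t:.4g} s"
            )
        return state_derivative(t, y, *args)

    r_i0 = derive_geometry(state0).r_i
    collapse, runaway = _radius_events(r_i0, guards)

    breakpoints = [t for t in protocol.breakpoints if t < t_end] + [t_end]
    y = state0.as_array()
    rows: list[dict] = []
    verdict, reason = "completed", ""

    inp0 = protocol.inputs_at(0.0)
    rows.append({"t": 0.0, **dict(zip(STATE_NAMES, y)), **_derived_row(state0, inp0, params)})

    for t0, t1 in zip(breakpoints, breakpoints[1:]):
        inputs = protocol.inputs_at(t0)
        try:
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method="BDF",
                t_eval=_segment_times(t0, t1, n_eval)[1:],
                args=(inputs, params, mask),
                rtol=rtol,
                atol=atol,
                events=[collapse, runaway],
                dense_output=False,
            )
        except _RhsBudgetExceeded as exc:
            verdict, reason = "truncated", str(exc)
            break
        ts_seg = sol.t
        ys_seg = sol.y.T
        for t, yv in zip(ts_seg, ys_seg):
            st = VesselState.from_array(yv)
            try:
                drow = _derived_row(st, inputs, params)
            except DegenerateGeometryError:
                verdict, reason = "collapse", "degenerate geometry"
                break
            rows.append({"t": float(t), **dict(zip(STATE_NAMES, yv)), **drow})
        if sol.status == 1:  # a terminal event fired
            which = 0 if len(sol.t_events[0]) else 1
            verdict = "collapse" if which == 0 else "runaway"
            reason = f"r_i guard crossed at t={sol.t_events[which][0]:.4g} s"
            # record the event state if geometry still evaluates
            ye = sol.y_events[which][0]
            try:
                st = VesselState.from_array(ye)
                rows.append(
                    {
                        "t": float(sol.t_events[which][0]),
                        **dict(zip(STATE_NAMES, ye)),
                        **_derived_row(st, inputs, params),
                    }
                )
            except (DegenerateGeometryError, ValueError):
                pass
            break
        if sol.status < 0:
            verdict, reason = "solver_failure", sol.message
            break
        if verdict != "completed":
            break
        y = ys_seg[-1]

    frame = pd.DataFrame(rows).drop_duplicates(subset="t").reset_index(drop=True)
    return TimeSeries(frame=frame, verdict=verdict, reason=reason)


def classify_stability(
    ts: TimeSeries,
    inputs: Inputs,
    mask: VariantMask,
    params: ModelParameters = DEFAULT_PARAMETERS,
    residual_tol: float = RESIDUAL_TOL,
) -> str:
    """Trajectory-based verdict: stable, collapse, runaway or nonconvergent.

    Collapse/runaway verdicts from the guard events are passed through;
    otherwise the scaled derivative norm at the final state decides
    between stable and nonconvergent.
    """
    if len(ts.frame) == 0:
        raise ValueError("empty trajectory")
    if ts.verdict in ("collapse", "runaway"):
        return ts.verdict
    y = ts.final_state().as_array()
    f = state_derivative(0.0, y, inputs, params, mask)
    if np.max(np.abs(f / ABS_TOLERANCES)) < residual_tol:
        return "stable"
    return "nonconvergent"


def _polish(
    y0: np.ndarray,
    inputs: Inputs,
    mask: VariantMask,
    params: ModelParameters,
) -> tuple[np.ndarray, float]:
    """Root-polish the masked derivative from y0; frozen components fixed."""
    active = mask.as_array() > 0.0
    idx = np.where(active)[0]
    scale = np.maximum(np.abs(y0), ABS_TOLERANCES)

    def fun(x: np.ndarray) -> np.ndarray:
        y = y0.copy()
        y[idx] = x * scale[idx]
        f = state_derivative(0.0, y, inputs, params, mask)
        return f[idx] / ABS_TOLERANCES[idx]

    sol = root(fun, y0[idx] / scale[idx], method="hybr", options={"xtol": 1e-14})
    y = y0.copy()
    if sol.success:
        y[idx] = sol.x * scale[idx]

    # hybr's step-size test can stall one step short when started very close;
    # a few damped Newton iterations push the residual to the noise floor
    x = y[idx] / scale[idx]
    f = np.asarray(fun(x))
    best_x, best = x.copy(), float(np.max(np.abs(f)))
    for _ in range(12):
        if best < 1e-12:
            break
        n = len(x)
        J = np.empty((n, n))
        hstep = 1e-7 * np.maximum(np.abs(x), 1e-3)
        for j in range(n):
            xp, xm = x.copy(), x.copy()
            xp[j] += hstep[j]
            xm[j] -= hstep[j]
            J[:, j] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2 * hstep[j])
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            break
        lam, improved = 1.0, False
        for _ in range(8):
            x_new = x + lam * dx
            try:
                f_new = np.asarray(fun(x_new))
            except (FloatingPointError, ValueError):
                lam *= 0.5
                continue
            r_new = float(np.max(np.abs(f_new)))
            if r_new < best:
                x, f, improved = x_new, f_new, True
                best_x, best = x_new.copy(), r_new
                break
            lam *= 0.5
        if not improved:
            break
    y[idx] = best_x * scale[idx]
    f_final = state_derivative(0.0, y, inputs, params, mask)
    return y, float(np.max(np.abs(f_final / ABS_TOLERANCES)))


def find_steady_state(
    inputs: Inputs,
    mask: VariantMask = VariantMask(),
    state0: VesselState | None = None,
    params: ModelParameters = DEFAULT_PARAMETERS,
    t_horizon: float | None = None,
    guards: Guards = Guards(),
    residual_tol: float = RESIDUAL_TOL,
    initial_kick: float = 1e-3,
) -> SteadyStateResult:
    """Steady state of the masked system under constant inputs.

    The default horizon adapts to the slowest active process (see
    :func:`mask_horizon`).

    A long stiff integration from `state0` (default: the canonical vessel,
    i.e. the full-model equilibrium at default parameters and inputs)
    approaches the attractor; damped root-finding on the masked derivative
    then polishes the state to residual precision. Divergence and
    non-convergence become verdicts, never exceptions.

    The integration starts from `state0` relatively displaced by
    `initial_kick`: stability is judged from the trajectory, and a start
    exactly on an unstable equilibrium (a measure-zero situation) would
    otherwise sit on the saddle forever and be misread as stable. For
    attracting states the kick is simply re-absorbed and the polish step
    removes any residual offset.
    """
    if state0 is None:
        state0 = default_steady_state(DEFAULT_PARAMETERS)
    protocol = StimulusProtocol(
        [(0.0, inputs)],
        allow_negative_agents=(inputs.CON < 0.0 or inputs.DIL < 0.0),
    )
    kick = 1.0 + initial_kick * mask.as_array()  # frozen components untouched
    kicked = VesselState.from_array(state0.as_array() * kick)
    horizon = mask_horizon(mask) if t_horizon is None else t_horizon
    ts = integrate(
        kicked, protocol, mask, t_end=horizon, params=params,
        guards=guards, n_eval=120,
    )
    y_end = ts.final_state().as_array()
    if ts.verdict in ("collapse", "runaway", "solver_failure", "truncated"):
        verdict = ts.verdict if ts.verdict in ("collapse", "runaway") else "nonconvergent"
        return SteadyStateResult(
            state=ts.final_state(), inputs=inputs, mask=mask,
            verdict=verdict, residual_norm=float("inf"),
        )

    try:
        y, resid = _polish(y_end, inputs, mask, params)
    except (DegenerateGeometryError, FloatingPointError):
        y, resid = y_end, float("inf")
    # reject a polish that jumped to a different (non-attracting) root
    rel_jump = np.max(np.abs(y - y_end) / np.maximum(np.abs(y_end), ABS_TOLERANCES))
    if rel_jump > 1e-2:
        y = y_end
        f = state_derivative(0.0, y, inputs, params, mask)
        resid = float(np.max(np.abs(f / ABS_TOLERANCES)))

    state = VesselState.from_array(y)
    verdict = "stable" if resid < residual_tol else "nonconvergent"
    result = SteadyStateResult(
        state=state, inputs=inputs, mask=mask,
        verdict=verdict, residual_norm=resid,
    )
    if verdict == "stable":
        result.derived = steady_state_outputs(result, params)
    return result


def steady_state_outputs(
    ss: SteadyStateResult, params: ModelParameters = DEFAULT_PARAMETERS
) -> dict:
    """The nine reported quantities at a converged state.

    r_i, tone, l, r_islack, wcsa, sigma, tau plus the two derived indices:
    radius reserve (fully dilated over actual inner radius, at the same
    structure and pressure) and tension match (inner radius of optimal
    active stress capacity over the passive inner radius at 100 mmHg).
    """
    from .units import MMHG_TO_PA  # boundary constant

    st, inputs = ss.state, ss.inputs
    geom = derive_geometry(st)
    ws = mean_wall_stress(st, params, P=inputs.P, Q=inputs.Q)

    # fully dilated radius: tone = 0 mechanical equilibrium, same structure
    eps_dil = equilibrium_strain(
        inputs.P, 0.0, st.span, st.r_mslack, st.wcsa, params, guess=st.eps
    )
    st_dil = VesselState(eps_dil, 0.0, st.span, st.r_mslack, st.wcsa)
    r_i_dil = derive_geometry(st_dil).r_i

    # passive radius at 100 mmHg, same structure
    eps_100 = equilibrium_strain(
        100.0 * MMHG_TO_PA, 0.0, st.span, st.r_mslack, st.wcsa, params,
        guess=max(st.eps, 0.5),
    )
    st_100 = VesselState(eps_100, 0.0, st.span, st.r_mslack, st.wcsa)
    r_i100 = derive_geometry(st_100).r_i

    # radius at which SMC length is optimal for the current span/structure
    r_m_opt = params.l_opt / (2.0 * math.pi * st.span)
    h_opt = st.wcsa / (2.0 * math.pi * r_m_opt)
    r_i_opt = r_m_opt - h_opt / 2.0

    return {
        "r_i": geom.r_i,
        "tone": st.tone,
        "l": geom.l,
        "r_islack": slack_inner_radius(st),
        "wcsa": st.wcsa,
        "sigma": ws.sigma,
        "tau": ws.tau,
        "radius_reserve": r_i_dil / geom.r_i,
        "tension_match": r_i_opt / r_i100,
    }


def solve_growth_fixed_point(
    inputs: Inputs | None = None,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> VesselState:
    """Semi-analytic fixed point of the full (all-processes) model.

    At a full-model equilibrium the rate laws force l = l_ref,
    sigma = sigma_ref and beta_strain·eps = alpha_tone·A, which reduces the
    system to a scalar root for tone in the wall-composition closure; the
    tone set-point equation then yields the required shear, the Poiseuille
    relation the radius, and the Laplace relation the wall thickness.
    Raises ValueError when no equilibrium exists (e.g. dilator beyond the
    shear the wall-side equations demand).
    """
    from .mechanics import (
        active_stress_capacity,
        cytoskeletal_stress,
        matrix_stress,
    )

    if inputs is None:
        from .config import DEFAULT_INPUTS

        inputs = DEFAULT_INPUTS

    p = params
    s_cap = active_stress_capacity(p.l_ref, p)
    s_cyt = cytoskeletal_stress(p.l_ref, p)

    def closure(A: float) -> float:
        eps = p.alpha_tone / p.beta_strain * A
        return (
            p.af_p * matrix_stress(eps, p)
            + p.af_a * A * s_cap
            + p.af_c * s_cyt
            - p.sigma_ref
        )

    if closure(0.0) > 0.0 or closure(1.0) < 0.0:
        raise ValueError("no equilibrium tone in (0, 1) for these parameters")
    A = brentq(closure, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16)
    eps = p.alpha_tone / p.beta_strain * A

    h_act = hill(p.sigma_ref + inputs.CON, p.sigma_50, p.hc)
    trf = A / h_act
    if not 0.0 < trf <= 1.0:
        raise ValueError("tone set-point unreachable: required TRF outside (0, 1]")
    h_dil = (1.0 - trf) / p.ecf if p.ecf > 0.0 else 0.0
    if h_dil >= 1.0:
        raise ValueError("required dilation exceeds Hill-curve range")
    if h_dil <= 0.0:
        total_shear_stim = 0.0
    else:
        total_shear_stim = p.tau_50 * (h_dil / (1.0 - h_dil)) ** (1.0 / p.hd)
    tau = total_shear_stim - inputs.DIL
    if tau <= 0.0:
        raise ValueError(
            "no positive-shear equilibrium: dilator stimulus exceeds the "
            "total shear the tone balance demands (runaway regime)"
        )

    r_i = (4.0 * p.eta * inputs.Q / (math.pi * tau)) ** (1.0 / 3.0)
    h = inputs.P * r_i / p.sigma_ref
    r_m = r_i + h / 2.0
    return VesselState(
        eps=eps,
        tone=A,
        span=p.l_ref / (2.0 * math.pi * r_m),
        r_mslack=r_m / (1.0 + eps),
        wcsa=2.0 * math.pi * r_m * h,
    )


def default_steady_state(
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> VesselState:
    """The canonical starting vessel: full-model equilibrium at default
    inputs (80 mmHg, 0.25 µL/s, no agents) for the given parameters."""
    from .config import DEFAULT_INPUTS

    return solve_growth_fixed_point(DEFAULT_INPUTS, params)
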