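"""Tone set-point, the five rate laws, and model variants.

The vessel state evolves by five simultaneous first-order processes:

* mechanics: strain relaxes toward the Laplace load,
  d(eps)/dt = k_mech (sigma_eq - sigma);
* tone: activation relaxes toward its equilibrium set-point,
  dA/dt = k_tone (A_eq - A), where A_eq is a Hill curve of wall stress
  (plus equipotent constrictor) multiplied by a shear/dilator
  tone-reducing factor;
* SMC plasticity: span adapts so cell length returns to its reference,
  d(span)/dt = k_span (l_ref - l) l / l_ref;
* eutrophic remodeling: the slack matrix radius drifts with the signed
  balance of strain (outward) and tone (inward),
  d(r_mslack)/dt = k_slack r_mslack (beta_strain eps - alpha_tone A);
* growth: wall cross-sectional area grows above the reference stress,
  d(wcsa)/dt = k_growth wcsa (sigma - sigma_ref).

A VariantMask switches individual processes off (rate identically zero,
the component frozen), which defines the model hierarchy MECH, FUNCT,
PLAST, REMOD, GROWTH and the software knockouts FUNCTKO, PLASTKO,
REMODKO.
"""
from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, DEFAULT_PARAMETERS
from .state import EPS_FLOOR, VesselState

__all__ = [
    "Inputs",
    "StimulusProtocol",
    "VariantMask",
    "VARIANT_NAMES",
    "make_variant",
    "hill",
    "tone_reducing_factor",
    "equilibrium_tone",
    "state_derivative",
    "characteristic_times",
]


def hill(stimulus: float, half: float, coeff: float) -> float:
    """Saturating Hill curve s^n / (half^n + s^n); 0 for s <= 0."""
    if stimulus <= 0.0:
        return 0.0
    ratio = stimulus / half
    if ratio > 1e12:  # saturated far beyond any physical stimulus
        return 1.0
    x = ratio**coeff
    return x / (1.0 + x)


def tone_reducing_factor(
    tau: float,
    DIL: float = 0.0,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> float:
    """Fractional tone reduction by shear stress and extrinsic dilators.

    TRF = 1 - ecf · Hill(tau + DIL; tau_50, hd), between 1 - ecf and 1.
    Extrinsic dilators act as equipotent shear stress; ecf scales the
    endothelium-dependent pathway (ecf = 0 abolishes all dilation).
    """
    return 1.0 - params.ecf * hill(tau + DIL, params.tau_50, params.hd)


def equilibrium_tone(
    sigma: float,
    CON: float = 0.0,
    trf: float = 1.0,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> float:
    """Equilibrium activation A_eq once tone adaptation is complete.

    A_eq = Hill(sigma + CON; sigma_50, hc) · TRF. Constrictors add as
    equipotent wall stress inside the myogenic Hill curve.
    """
    return hill(sigma + CON, params.sigma_50, params.hc) * trf


@dataclass(frozen=True)
class Inputs:
    """Constant stimulus levels: pressure (Pa), flow (m³/s), and extrinsic
    constrictor / dilator as equipotent wall stress / shear stress (Pa)."""

    P: float
    Q: float
    CON: float = 0.0
    DIL: float = 0.0

    def validate(self, allow_negative_agents: bool = False) -> None:
        if self.P < 0.0 or self.Q < 0.0:
            raise ValueError("P and Q must be non-negative")
        if not allow_negative_agents and (self.CON < 0.0 or self.DIL < 0.0):
            raise ValueError(
                "negative CON/DIL require allow_negative_agents=True"
            )


class StimulusProtocol:
    """Piecewise-constant stimulus protocol.

    Built from ordered (t_start, Inputs) segments; the first segment must
    start at t = 0. Negative constrictor/dilator values (the convention
    for endothelium-dependent constriction or endothelium-independent
    dilation) are only accepted behind the explicit flag.
    """

    def __init__(
        self,
        segments: list[tuple[float, Inputs]],
        allow_negative_agents: bool = False,
    ) -> None:
        if not segments:
            raise ValueError("protocol needs at least one segment")
        times = [t for t, _ in segments]
        if times[0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        for _, inp in segments:
            inp.validate(allow_negative_agents)
        self.segments = list(segments)
        self._times = times

    @classmethod
    def constant(
        cls, P: float, Q: float, CON: float = 0.0, DIL: float = 0.0, **kw
    ) -> "StimulusProtocol":
        return cls([(0.0, Inputs(P=P, Q=Q, CON=CON, DIL=DIL))], **kw)

    @classmethod
    def step(
        cls,
        before: Inputs,
        after: Inputs,
        t_step: float = 0.0,
        **kw,
    ) -> "StimulusProtocol":
        """Step protocol; for t_step = 0 the 'after' inputs apply from t=0
        and 'before' only documents the pre-step condition."""
        if t_step <= 0.0:
            return cls([(0.0, after)], **kw)
        return cls([(0.0, before), (t_step, after)], **kw)

    def inputs_at(self, t: float) -> Inputs:
        i = bisect.bisect_right(self._times, t) - 1
        return self.segments[max(i, 0)][1]

    @property
    def breakpoints(self) -> list[float]:
        return list(self._times)


@dataclass(frozen=True)
class VariantMask:
    """Which of the five rate processes are active.

    Mechanics is always on: even the pure-mechanics variant lets strain
    follow the load. A disabled process contributes exactly zero rate, so
    its state component stays frozen at its initial value.
    """

    mech: bool = True
    tone: bool = True
    plasticity: bool = True
    remodeling: bool = True
    growth: bool = True

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mech, self.tone, self.plasticity, self.remodeling, self.growth],
            dtype=float,
        )


_VARIANTS: dict[str, VariantMask] = {
    # hierarchy of increasing complexity
    "MECH": VariantMask(mech=True, tone=False, plasticity=False,
                        remodeling=False, growth=False),
    "FUNCT": VariantMask(mech=True, tone=True, plasticity=False,
                         remodeling=False, growth=False),
    "PLAST": VariantMask(mech=True, tone=True, plasticity=True,
                         remodeling=False, growth=False),
    "REMOD": VariantMask(mech=True, tone=True, plasticity=True,
                         remodeling=True, growth=False),
    "GROWTH": VariantMask(),
    # software knockouts: full model minus one biological process
    "FUNCTKO": VariantMask(tone=False),
    "PLASTKO": VariantMask(plasticity=False),
    "REMODKO": VariantMask(remodeling=False),
}

VARIANT_NAMES = tuple(_VARIANTS)


def make_variant(name: str) -> VariantMask:
    """Mask for a named model variant (MECH ... GROWTH, *KO)."""
    try:
        return _VARIANTS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; choose from {', '.join(_VARIANTS)}"
        ) from None


def state_derivative(
    t: float,
    y: np.ndarray,
    inputs: Inputs,
    params: ModelParameters = DEFAULT_PARAMETERS,
    mask: VariantMask = VariantMask(),
) -> np.ndarray:
    """Time derivative of the 5-vector (eps, A, span, r_mslack, wcsa).

    Evaluates geometry, constitutive stresses, Laplace load and shear at
    the (floored/clamped) state, forms the five rate laws and applies the
    variant mask. Raises on non-finite rates.
    """
    eps, A, span, r_mslack, wcsa = y
    # numerical guards: strain floor/cap, tone clamp — solvers may probe far
    # outside the physical region; stresses at eps = 10 are already ~1e9 Pa
    eps_c = min(max(eps, EPS_FLOOR), 10.0)
    A_c = min(max(A, 0.0), 1.0)

    r_m = r_mslack * (1.0 + eps_c)
    h = wcsa / (2.0 * math.pi * r_m)
    r_i = r_m - h / 2.0
    l = span * 2.0 * math.pi * r_m
    if r_i <= 0.0 or l <= 0.0:
        # inside the collapse guard; push strain outward, freeze the rest
        return mask.as_array() * np.array([params.k_mech * 1e5, 0, 0, 0, 0])

    # element stresses and composition
    if eps_c <= 0.0:
        s_p = 0.0
    else:
        s_p = params.c_p1 * math.expm1(params.c_p3 * eps_c) + params.c_p2 * math.expm1(
            params.c_p4 * eps_c
        )
    z = (l - params.l_opt) / params.l_w
    s_cap = params.sigma_amax * math.exp(-min(z * z, 400.0))
    s_c = params.c_c1 * math.exp(
        min(params.c_c2 * math.log(l / params.c_c3), 400.0)
    )
    sigma = params.af_p * s_p + params.af_a * A_c * s_cap + params.af_c * s_c

    sigma_eq = inputs.P * r_i / h
    tau = 4.0 * params.eta * inputs.Q / (math.pi * r_i**3)

    trf = tone_reducing_factor(tau, inputs.DIL, params)
    a_eq = equilibrium_tone(sigma, inputs.CON, trf, params)

    d_eps = params.k_mech * (sigma_eq - sigma)
    # the strain floor is a hard constraint on the state: project the rate
    # so eps cannot be driven (far) below it during stiff transients
    if eps <= EPS_FLOOR and d_eps < 0.0:
        d_eps = 0.0
    d_tone = params.k_tone * (a_eq - A_c)
    d_span = params.k_span * (params.l_ref - l) * (l / params.l_ref)
    d_rms = params.k_slack * r_mslack * (
        params.beta_strain * eps_c - params.alpha_tone * A_c
    )
    d_wcsa = params.k_growth * wcsa * (sigma - params.sigma_ref)

    rates = mask.as_array() * np.array([d_eps, d_tone, d_span, d_rms, d_wcsa])
    if not np.all(np.isfinite(rates)):
        raise FloatingPointError(f"non-finite derivative at state {y!r}")
    return rates


def characteristic_times(
    state: VesselState,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> dict[str, float]:
    """Order-of-magnitude relaxation times (s) of the five processes.

    Linearized around the given state: mechanics relaxes at roughly
    k_mech·dσ/dε, tone at k_tone, plasticity at k_span·2π r_m, remodeling
    at k_slack and growth at k_growth·σ_ref. Used as a sanity check on the
    time-scale separation that makes the system stiff.
    """
    from .mechanics import derive_geometry  # local to avoid cycle

    geom = derive_geometry(state)
    de = 1e-6
    e = max(state.eps, de)
    dsig_deps = (
        params.af_p
        * (
            params.c_p1 * params.c_p3 * math.exp(params.c_p3 * e)
            + params.c_p2 * params.c_p4 * math.exp(params.c_p4 * e)
        )
    )
    return {
        "mechanics": 1.0 / (params.k_mech * dsig_deps),
        "tone": 1.0 / params.k_tone,
        "plasticity": 1.0 / (params.k_span * 2.0 * math.pi * geom.r_m),
        "remodeling": 1.0 / params.k_slack,
        "growth": 1.0 / (params.k_growth * params.sigma_ref),
    }
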