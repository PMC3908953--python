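"""Wall composition, constitutive stress laws, geometry and hemodynamics.

Three stress-carrying elements are arranged in parallel across the wall:
passive matrix, active SMC contractile filaments, and the SMC
cytoskeleton. Mean wall stress is their area-fraction-weighted sum. The
load side is the Laplace relation sigma_eq = P r_i / h, and endothelial
shear follows Poiseuille flow, tau = 4 eta Q / (pi r_i^3).

Constitutive laws
-----------------
* matrix: bi-exponential stress-strain curve, slack (zero stress) for
  eps <= 0;
* active capacity: Gaussian bell of SMC length, peaking at sigma_amax for
  l = l_opt with width l_w; actual active stress is tone x capacity;
* cytoskeleton: steep power-law stretch brake, c_c1 at length c_c3 with
  exponent c_c2 — negligible at the reference length, dominant above c_c3.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters, DEFAULT_PARAMETERS
from .state import (
    EPS_FLOOR,
    DegenerateGeometryError,
    Geometry,
    VesselState,
    WallStresses,
)

__all__ = [
    "derive_geometry",
    "matrix_stress",
    "active_stress_capacity",
    "cytoskeletal_stress",
    "mean_wall_stress",
    "laplace_stress",
    "wall_shear_stress",
    "equilibrium_strain",
]


def derive_geometry(state: VesselState) -> Geometry:
    """Loaded dimensions of the annular wall for a given state.

    The midwall radius distends with matrix strain,
    r_m = r_mslack (1 + eps); the annulus identity wcsa = 2π r_m h gives
    the thickness; the internal radius sits half a thickness inside the
    midwall; and one SMC of span `span` covers l = span · 2π r_m of the
    circumference.

    Raises
    ------
    DegenerateGeometryError
        If the wall is too thick for the lumen (r_i <= 0).
    """
    r_m = state.r_mslack * (1.0 + max(state.eps, EPS_FLOOR))
    if r_m <= 0.0:
        raise DegenerateGeometryError(f"midwall radius {r_m} <= 0")
    h = state.wcsa / (2.0 * math.pi * r_m)
    r_i = r_m - h / 2.0
    if r_i <= 0.0:
        raise DegenerateGeometryError(
            f"internal radius {r_i} <= 0 (wall thicker than lumen permits)"
        )
    l = state.span * 2.0 * math.pi * r_m
    return Geometry(r_m=r_m, h=h, r_i=r_i, l=l)


def matrix_stress(eps: float, params: ModelParameters = DEFAULT_PARAMETERS) -> float:
    """Passive matrix stress (Pa) at strain eps.

    Bi-exponential curve c_p1 (e^{c_p3 eps} - 1) + c_p2 (e^{c_p4 eps} - 1);
    the slack matrix (eps <= 0) bears no load.
    """
    if eps <= 0.0:
        return 0.0
    return params.c_p1 * math.expm1(params.c_p3 * eps) + params.c_p2 * math.expm1(
        params.c_p4 * eps
    )


def active_stress_capacity(
    l: float, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Maximal (tone = 1) active stress (Pa) at SMC length l.

    Bell-shaped: sigma_amax · exp(-((l - l_opt)/l_w)^2), symmetric about
    the optimal length.
    """
    if l <= 0.0:
        raise ValueError(f"SMC length must be positive, got {l}")
    z = (l - params.l_opt) / params.l_w
    return params.sigma_amax * math.exp(-z * z)


def cytoskeletal_stress(
    l: float, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Cytoskeletal stretch-brake stress (Pa) at SMC length l.

    Steep power law c_c1 (l / c_c3)^{c_c2}: equals c_c1 at l = c_c3,
    negligible at the reference length, and rises as a brake above c_c3.
    """
    if l <= 0.0:
        raise ValueError(f"SMC length must be positive, got {l}")
    return params.c_c1 * (l / params.c_c3) ** params.c_c2


def mean_wall_stress(
    state: VesselState,
    params: ModelParameters = DEFAULT_PARAMETERS,
    P: float = float("nan"),
    Q: float = float("nan"),
) -> WallStresses:
    """Element stresses and their parallel composition for a state.

    sigma = af_p·sigma_p + af_a·tone·sigma_acap + af_c·sigma_c, with the
    SMC length taken from the derived geometry. If P (Pa) or Q (m³/s) are
    given, the Laplace equilibrium stress and wall shear stress are filled
    in as well.
    """
    geom = derive_geometry(state)
    s_p = matrix_stress(state.eps, params)
    s_cap = active_stress_capacity(geom.l, params)
    s_a = state.tone * s_cap
    s_c = cytoskeletal_stress(geom.l, params)
    sigma = params.af_p * s_p + params.af_a * s_a + params.af_c * s_c
    sigma_eq = laplace_stress(P, geom) if not math.isnan(P) else float("nan")
    tau = (
        wall_shear_stress(Q, geom.r_i, params) if not math.isnan(Q) else float("nan")
    )
    return WallStresses(
        sigma_p=s_p,
        sigma_acap=s_cap,
        sigma_a=s_a,
        sigma_c=s_c,
        sigma=sigma,
        sigma_eq=sigma_eq,
        tau=tau,
    )


def laplace_stress(P: float, geom: Geometry) -> float:
    """Laplace equilibrium wall stress sigma_eq = P r_i / h (Pa)."""
    if geom.h == 0.0:
        raise ZeroDivisionError("Laplace stress undefined for zero wall thickness")
    return P * geom.r_i / geom.h


def wall_shear_stress(
    Q: float, r_i: float, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Poiseuille wall shear stress tau = 4 eta Q / (pi r_i^3) (Pa)."""
    if r_i <= 0.0:
        raise DegenerateGeometryError(f"internal radius must be positive, got {r_i}")
    return 4.0 * params.eta * Q / (math.pi * r_i**3)


def _load_imbalance(
    eps: float,
    P: float,
    tone: float,
    span: float,
    r_mslack: float,
    wcsa: float,
    params: ModelParameters,
) -> float:
    # wall stress minus Laplace load at strain eps, structure and tone fixed
    state = VesselState(eps=eps, tone=tone, span=span, r_mslack=r_mslack, wcsa=wcsa)
    geom = derive_geometry(state)
    ws = mean_wall_stress(state, params)
    return ws.sigma - laplace_stress(P, geom)


def equilibrium_strain(
    P: float,
    tone: float,
    span: float,
    r_mslack: float,
    wcsa: float,
    params: ModelParameters = DEFAULT_PARAMETERS,
    guess: float | None = None,
    eps_max: float = 6.0,
    n_scan: int = 600,
) -> float:
    """Strain of quasi-static mechanical equilibrium at fixed structure/tone.

    Solves sigma(eps) = P r_i(eps) / h(eps) for eps with the structural
    state (span, r_mslack, wcsa) and tone pinned. When several equilibria
    exist (the myogenic regime of an activated vessel), the mechanically
    stable root nearest `guess` is returned — this mimics slow quasi-static
    loading from that point.

    Raises
    ------
    DegenerateGeometryError
        If no equilibrium exists in (EPS_FLOOR, eps_max].
    """
    lo = EPS_FLOOR + 1e-9
    # keep r_i > 0 at the lower end of the bracket
    h0 = wcsa / (2.0 * math.pi * r_mslack * (1.0 + lo))
    while r_mslack * (1.0 + lo) <= h0 / 2.0 and lo < eps_max:
        lo += 0.01
        h0 = wcsa / (2.0 * math.pi * r_mslack * (1.0 + lo))

    grid = np.linspace(lo, eps_max, n_scan)
    vals = np.array(
        [_load_imbalance(e, P, tone, span, r_mslack, wcsa, params) for e in grid]
    )
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            roots.append(
                brentq(
                    _load_imbalance,
                    grid[i],
                    grid[i + 1],
                    args=(P, tone, span, r_mslack, wcsa, params),
                    xtol=1e-14,
                    rtol=1e-14,
                )
            )
    # mechanically stable: wall stiffens faster than the load with strain
    stable = []
    de = 1e-7
    for r in roots:
        slope = (
            _load_imbalance(r + de, P, tone, span, r_mslack, wcsa, params)
            - _load_imbalance(r - de, P, tone, span, r_mslack, wcsa, params)
        ) / (2 * de)
        if slope > 0.0:
            stable.append(r)
    candidates = stable or roots
    if not candidates:
        raise DegenerateGeometryError(
            f"no mechanical equilibrium for P={P:.6g} Pa at this structure"
        )
    if guess is None:
        return candidates[0]
    return min(candidates, key=lambda r: abs(r - guess))
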