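"""State and derived-quantity containers."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: floor on matrix strain; below this the geometry degenerates numerically
EPS_FLOOR = -0.5


class DegenerateGeometryError(ValueError):
    """Raised when the wall geometry has no physical solution (r_i <= 0)."""


@dataclass
class VesselState:
    """The five state variables of the vessel wall.

    eps
        Matrix strain: relative extension of the midwall radius from its
        slack value (dimensionless, >= EPS_FLOOR).
    tone
        SMC activation A in [0, 1] (ratio of actual to maximal active
        stress at the same cell length).
    span
        Fraction of the circumference covered by one SMC (> 0).
    r_mslack
        Slack (unloaded) midwall radius of the matrix (m, > 0).
    wcsa
        Wall cross-sectional area (m², > 0).
    """

    eps: float
    tone: float
    span: float
    r_mslack: float
    wcsa: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.eps, self.tone, self.span, self.r_mslack, self.wcsa]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "VesselState":
        return cls(*(float(v) for v in y))

    def validate(self) -> None:
        if self.eps < EPS_FLOOR:
            raise ValueError(f"eps {self.eps} below floor {EPS_FLOOR}")
        if not 0.0 <= self.tone <= 1.0:
            raise ValueError(f"tone must lie in [0, 1], got {self.tone}")
        if self.span <= 0.0:
            raise ValueError("span must be strictly positive")
        if self.r_mslack <= 0.0:
            raise ValueError("r_mslack must be strictly positive")
        if self.wcsa <= 0.0:
            raise ValueError("wcsa must be strictly positive")


#: state-component names, in the canonical array order
STATE_NAMES = ("eps", "tone", "span", "r_mslack", "wcsa")


@dataclass(frozen=True)
class Geometry:
    """Loaded vessel dimensions derived from a state.

    r_m is the midwall radius, h the wall thickness (annulus identity
    wcsa = 2π r_m h), r_i = r_m - h/2 the internal radius and
    l = span · 2π r_m the SMC length.
    """

    r_m: float
    h: float
    r_i: float
    l: float


@dataclass(frozen=True)
class WallStresses:
    """Element stresses, their composition and the mechanical loads (Pa).

    sigma is the area-fraction-weighted mean of the parallel elements;
    sigma_eq is the Laplace equilibrium stress P·r_i/h; tau the Poiseuille
    wall shear stress. sigma_eq and tau are NaN when pressure or flow were
    not supplied.
    """

    sigma_p: float
    sigma_acap: float
    sigma_a: float
    sigma_c: float
    sigma: float
    sigma_eq: float = float("nan")
    tau: float = float("nan")
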