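"""Model parameters for the single-segment resistance-artery model.

All values are SI. The defaults describe a generic small artery of roughly
70 µm inner radius operating at 80 mmHg and 0.25 µL/s: one third each of
the wall cross-section is passive matrix, active contractile filament and
SMC cytoskeleton; tone follows a Hill curve of wall stress (half-activation
at 30 kPa) reduced by a Hill curve of shear (half-dilation at 5 Pa = 50
dyn/cm²); and five first-order rate constants set the widely separated
time scales of mechanics, tone, SMC plasticity, eutrophic remodeling and
growth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields


@dataclass(frozen=True)
class ModelParameters:
    """Every constant of the model, with physiological defaults.

    Attributes
    ----------
    af_p, af_a, af_c :
        Area fractions of passive matrix, active filaments and
        cytoskeleton. Must sum to 1.
    c_p1, c_p2, c_p3, c_p4 :
        Constants of the bi-exponential passive stress-strain law
        (Pa, Pa, -, -).
    l_opt, sigma_amax, l_w :
        Optimal SMC length (m), maximal active stress at that length (Pa)
        and the width of the bell-shaped length-stress curve (m).
    c_c1, c_c2, c_c3 :
        Cytoskeletal stretch brake: stress c_c1 (Pa) at length c_c3 (m),
        rising with steepness exponent c_c2.
    hc, sigma_50 :
        Hill coefficient and half-activation wall stress (Pa) of the
        myogenic activation curve.
    hd, tau_50 :
        Hill coefficient and half-dilation shear stress (Pa) of the
        shear/dilator relaxation curve.
    ecf :
        Endothelial cell function, 1 = fully intact, 0 = no
        shear/dilator-mediated relaxation at all.
    l_ref :
        Reference SMC length for plasticity (m).
    alpha_tone, beta_strain :
        Dimensionless weights of tone (inward) and matrix strain (outward)
        in the eutrophic remodeling balance.
    sigma_ref :
        Reference wall stress for the trophic (growth) response (Pa).
    eta :
        Blood viscosity (Pa s).
    k_mech, k_tone, k_span, k_slack, k_growth :
        First-order rate constants of the five processes
        (m² N⁻¹ s⁻¹, s⁻¹, m⁻¹ s⁻¹, s⁻¹, m² N⁻¹ s⁻¹).
    """

    # composition
    af_p: float = 1.0 / 3.0
    af_a: float = 1.0 / 3.0
    af_c: float = 1.0 / 3.0
    # passive matrix
    c_p1: float = 55_000.0
    c_p2: float = 0.0186
    c_p3: float = 1.5
    c_p4: float = 24.0
    # active SMC
    l_opt: float = 106.18e-6
    sigma_amax: float = 250_000.0
    l_w: float = 45.868e-6
    # cytoskeleton
    c_c1: float = 250_000.0
    c_c2: float = 30.0
    c_c3: float = 118.92e-6
    # tone
    hc: float = 3.0
    sigma_50: float = 30_000.0
    hd: float = 3.0
    tau_50: float = 5.0
    ecf: float = 1.0
    # SMC plasticity
    l_ref: float = 80e-6
    # eutrophic remodeling
    alpha_tone: float = 0.65
    beta_strain: float = 1.0
    # growth
    sigma_ref: float = 30_000.0
    # miscellaneous
    eta: float = 0.0035
    # rate constants
    k_mech: float = 1e-6
    k_tone: float = 0.005
    k_span: float = 3.75
    k_slack: float = 2e-5
    k_growth: float = 1e-10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ValueError on any violated parameter invariant."""
        for frac in ("af_p", "af_a", "af_c"):
            v = getattr(self, frac)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{frac} must lie in (0, 1), got {v}")
        if abs(self.af_p + self.af_a + self.af_c - 1.0) > 1e-12:
            raise ValueError(
                "area fractions af_p + af_a + af_c must sum to 1, got "
                f"{self.af_p + self.af_a + self.af_c!r}"
            )
        # ecf = 1 is intact endothelium; the sensitivity analysis perturbs
        # it above 1 (supra-normal function), so only non-negativity is hard
        if self.ecf < 0.0:
            raise ValueError(f"ecf must be non-negative, got {self.ecf}")
        positive = (
            "c_p1", "c_p3", "c_p4", "l_opt", "sigma_amax", "l_w",
            "c_c1", "c_c2", "c_c3", "hc", "sigma_50", "hd", "tau_50",
            "l_ref", "alpha_tone", "beta_strain", "sigma_ref", "eta",
            "k_mech", "k_tone", "k_span", "k_slack", "k_growth",
        )
        for name in positive:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c_p2 < 0.0:
            raise ValueError("c_p2 must be non-negative")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with some parameters overridden (revalidated)."""
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: names accepted by :meth:`ModelParameters.replace` / config overrides
PARAMETER_NAMES: tuple[str, ...] = tuple(
    f.name for f in fields(ModelParameters)
)

DEFAULT_PARAMETERS = ModelParameters()
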