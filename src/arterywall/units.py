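"""Unit conversion constants.

The model itself runs in strict SI; clinical units (mmHg, µL/s, dyn/cm²,
µm) are converted exactly at the I/O boundary and nowhere else.
"""

#: 1 mmHg in Pa (exact conversion used throughout)
MMHG_TO_PA = 133.322

#: 1 µL/s in m³/s
UL_PER_S_TO_M3_PER_S = 1e-9

#: 1 dyn/cm² in Pa
DYN_PER_CM2_TO_PA = 0.1

#: 1 µm in m
UM_TO_M = 1e-6


def mmhg(value: float) -> float:
    """Pressure in mmHg → Pa."""
    return value * MMHG_TO_PA


def ul_per_s(value: float) -> float:
    """Flow in µL/s → m³/s."""
    return value * UL_PER_S_TO_M3_PER_S


def dyn_cm2(value: float) -> float:
    """Stress in dyn/cm² → Pa."""
    return value * DYN_PER_CM2_TO_PA


def to_dyn_cm2(pa: float) -> float:
    """Stress in Pa → dyn/cm²."""
    return pa / DYN_PER_CM2_TO_PA


def to_um(m: float) -> float:
    """Length in m → µm."""
    return m / UM_TO_M
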