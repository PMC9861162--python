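"""Single-species allometric extrapolation from dog to human.

The general clearance form is CL_hum = b * CL_dog * (BW_hum/BW_dog)^a. The
simple single-species rule used here fixes a = 0, b = 1 — the same absolute
clearance per unit time — and keeps the weight-normalised steady-state volume
(L/kg) identical across species (Vss_hum = a * Vss_dog with a = 1). Clearance
output is converted from mL/min to L/h (factor 0.06, applied exactly once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["AllometryParams", "allometric_cl", "allometric_vss"]

ML_MIN_TO_L_H = 0.06


@dataclass(frozen=True)
class AllometryParams:
    """Inputs of the interspecies scaling step."""

    cl_dog: float  # mL/min
    vss_dog: float  # L/kg
    bw_dog: float = 10.0  # kg
    bw_hum: float = 73.0  # kg
    a: float = 0.0  # allometric exponent on the body-weight ratio (CL)
    b: float = 1.0  # allometric coefficient (CL)

    def __post_init__(self) -> None:
        if self.bw_dog <= 0 or self.bw_hum <= 0:
            raise ValueError("body weights must be positive")


def allometric_cl(params: AllometryParams) -> float:
    """Human clearance in L/h: b * CL_dog * (BW_hum/BW_dog)^a, mL/min -> L/h."""
    if params.cl_dog < 0:
        raise ValueError("cl_dog must be >= 0")
    cl_ml_min = params.b * params.cl_dog * (params.bw_hum / params.bw_dog) ** params.a
    return cl_ml_min * ML_MIN_TO_L_H


def allometric_vss(vss_dog: float, a: float = 1.0) -> float:
    """Human steady-state volume (L/kg): a * Vss_dog, default a = 1."""
    if vss_dog <= 0:
        raise ValueError("vss_dog must be positive")
    if a < 0:
        raise ValueError("a must be >= 0")
    if a == 0:
        warnings.warn("a = 0 yields a degenerate zero distribution volume", stacklevel=2)
    return a * vss_dog
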