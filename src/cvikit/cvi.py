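"""The cap vulnerability index (CVI).

CVI is the maximum over the fibrous-cap surface of the product of two
ratios: the mechanical utilization of the cap, sigma_c / sigma* (cap
membrane stress over the thin-walled critical stress p a / h), and the
local shear-to-pressure ratio ||WSS|| / p. High values flag caps that are
both close to their load-bearing limit and exposed to shear environments
associated with cap thinning.

Two unit conventions are supported for the second ratio:

``"consistent"``
    tau and p in the same pressure unit — the index is strictly
    dimensionless.
``"paper"`` (default)
    tau in dyn/cm² over p in mmHg, i.e. the consistent value scaled by
    1333.22. This convention puts typical coronary lesions in the
    0.1–1 range; it is a reverse-engineered reporting convention, recorded
    in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hemodynamics import HemodynamicState
from .mechanics import CapStressProfile

__all__ = ["CviResult", "compute_cvi", "PAPER_UNIT_FACTOR"]

# (dyn/cm^2 per Pa) / (mmHg per Pa) = 10 * 133.322
PAPER_UNIT_FACTOR = 1333.22


@dataclass(frozen=True)
class CviResult:
    """Pointwise index over the cap extent plus its maximum."""

    z: np.ndarray
    pointwise: np.ndarray
    cvi: float
    argmax_z: float
    unit_mode: str

    def __post_init__(self):
        if self.cvi < 0 or not np.isfinite(self.cvi):
            raise ValueError("CVI must be finite and non-negative")


def compute_cvi(
    stress: CapStressProfile,
    state: HemodynamicState,
    unit_mode: str = "paper",
) -> CviResult:
    """Evaluate the index pointwise over the cap and take the maximum.

    ``pointwise(z) = (sigma_c/sigma*)(z) * (tau/p)(z)`` with tau and p in
    the convention selected by ``unit_mode``; ties in the maximum resolve
    to the smallest z.
    """
    if unit_mode not in ("paper", "consistent"):
        raise ValueError("unit_mode must be 'paper' or 'consistent'")
    if stress.z.size == 0:
        raise ValueError("empty cap extent")
    idx = np.searchsorted(state.z, stress.z)
    if np.any(idx >= state.z.size) or not np.allclose(state.z[idx], stress.z):
        raise ValueError("stress profile stations are not on the hemodynamic grid")
    if unit_mode == "paper":
        tau, p = state.tau[idx], state.p[idx]
    else:
        tau, p = state.tau_pa()[idx], state.p_pa()[idx]
    if np.any(p <= 0):
        raise ValueError("pressure must be positive over the cap extent")
    pointwise = stress.ratio * (tau / p)
    i = int(np.argmax(pointwise))  # first maximum -> smallest z on ties
    return CviResult(
        z=stress.z,
        pointwise=pointwise,
        cvi=float(pointwise[i]),
        argmax_z=float(stress.z[i]),
        unit_mode=unit_mode,
    )
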