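"""End-to-end per-lesion analysis: geometry -> flow -> cap stress -> index.

``analyze_lesion`` runs the full chain and returns the 11 lesion features
used throughout the evaluation layer (DS, L, LAP, SC, PR, NRS, FFR, dFFR,
WSS, APS, CVI) together with the intermediate profile objects.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cvi import CviResult, compute_cvi
from .geometry import CapProperties, LesionGeometry, PlaqueComposition, diameter_stenosis, lesion_length
from .hemodynamics import FlowConditions, HemodynamicState, solve_flow
from .mechanics import CapStressProfile, stress_profile

__all__ = ["LesionAnalysis", "analyze_lesion", "FEATURE_NAMES"]

FEATURE_NAMES = ["ds", "length_mm", "lap", "sc", "pr", "nrs", "ffr", "dffr", "wss", "aps", "cvi"]


@dataclass(frozen=True)
class LesionAnalysis:
    geom: LesionGeometry
    plaque: PlaqueComposition
    cap: CapProperties
    state: HemodynamicState
    stress: CapStressProfile
    cvi: CviResult

    def features(self) -> dict:
        """The 11 lesion features as a flat dict (flags as 0/1 ints)."""
        return {
            "ds": diameter_stenosis(self.geom),
            "length_mm": lesion_length(self.geom),
            "lap": int(self.plaque.lap),
            "sc": int(self.plaque.sc),
            "pr": int(self.plaque.pr),
            "nrs": int(self.plaque.nrs),
            "ffr": self.state.FFR,
            "dffr": self.state.dFFR,
            "wss": self.state.wss_mean,
            "aps": self.state.aps_mean,
            "cvi": self.cvi.cvi,
        }


def analyze_lesion(
    geom: LesionGeometry,
    plaque: PlaqueComposition,
    cap: CapProperties | None = None,
    cond: FlowConditions | None = None,
    unit_mode: str = "paper",
    outer_bc: str = "free",
) -> LesionAnalysis:
    """Run flow, cap stress and the vulnerability index on one lesion."""
    cap = cap or CapProperties()
    cond = cond or FlowConditions()
    state = solve_flow(geom, cond)
    stress = stress_profile(geom, plaque, cap, state, outer_bc=outer_bc)
    result = compute_cvi(stress, state, unit_mode=unit_mode)
    return LesionAnalysis(geom=geom, plaque=plaque, cap=cap, state=state, stress=stress, cvi=result)
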