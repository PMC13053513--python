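"""Reduced-order steady coronary hemodynamics.

Pressure losses along the lesion combine a Poiseuille viscous term,
integrated along the lumen radius profile, and a Borda–Carnot/Young–Tsai
expansion loss downstream of the throat. Wall shear stress is the local
Poiseuille value. These profiles are the loads for the cap-stress model and
the source of the scalar lesion features FFR, ΔFFR, mean WSS and mean axial
plaque stress (APS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from . import units
from .geometry import LesionGeometry

__all__ = [
    "FlowConditions",
    "HemodynamicState",
    "solve_flow",
    "ffr",
    "delta_ffr",
    "axial_plaque_stress",
]

# Hyperemic flow giving WSS ~= 15 dyn/cm^2 in a straight 2 mm-radius vessel.
DEFAULT_Q_ML_S = 2.693


@dataclass(frozen=True)
class FlowConditions:
    """Steady hyperemic flow boundary conditions.

    Q in mL/s, viscosity mu in Pa·s, density rho in kg/m³, mean aortic
    pressure Pa in mmHg, Kt the dimensionless expansion-loss coefficient.
    """

    Q: float = DEFAULT_Q_ML_S
    mu: float = 0.0035
    rho: float = 1060.0
    Pa: float = 90.0
    Kt: float = 1.52
    autoregulate: bool = True

    def __post_init__(self):
        if self.Q < 0:
            raise ValueError("flow must be non-negative")
        if self.mu <= 0 or self.rho <= 0 or self.Pa <= 0:
            raise ValueError("mu, rho and Pa must be positive")
        if self.Kt < 0:
            raise ValueError("Kt must be non-negative")


@dataclass(frozen=True)
class HemodynamicState:
    """Pressure/WSS profiles plus the scalar hemodynamic lesion features.

    ``p`` in mmHg and ``tau`` in dyn/cm² on the geometry grid ``z`` (mm);
    SI accessors are provided. ``wss_mean`` and ``aps_mean`` are
    area-weighted lesion means (dyn/cm²).
    """

    z: np.ndarray
    p: np.ndarray
    tau: np.ndarray
    Q: float
    Pa: float
    FFR: float
    dFFR: float
    wss_mean: float
    aps_mean: float

    def __post_init__(self):
        if np.any(np.diff(self.p) > 1e-9):
            raise ValueError("pressure must be non-increasing downstream")
        if not 0 < self.FFR <= 1 + 1e-12:
            raise ValueError("FFR must lie in (0, 1]")
        if self.dFFR < -1e-12:
            raise ValueError("dFFR must be non-negative")

    def p_pa(self) -> np.ndarray:
        return units.mmhg_to_pa(self.p)

    def tau_pa(self) -> np.ndarray:
        return units.dyncm2_to_pa(self.tau)


def _area_weight(geom: LesionGeometry) -> np.ndarray:
    """Lateral surface area density dA/dz up to 2*pi: a*sqrt(1+a'^2)."""
    da = np.gradient(geom.a, geom.z)
    return geom.a * np.sqrt(1.0 + da**2)


def solve_flow(geom: LesionGeometry, cond: FlowConditions | None = None) -> HemodynamicState:
    """Solve the reduced-order steady flow problem on a lesion.

    The pressure profile is ``p(z) = Pa - dP_v(z) - dP_e(z)`` where the
    viscous term integrates the Poiseuille resistance
    ``dP_v(z) = int 8 mu Q / (pi a(s)^4) ds`` and the expansion loss
    ``dP_e = Kt (rho/2) Q^2 (1/A_s - 1/A_0)^2`` (A_s the minimal lumen area,
    A_0 the area at the lesion inlet) is deposited linearly between the
    throat and the lesion exit so p stays continuous. WSS is the Poiseuille
    wall value ``4 mu Q / (pi a^3)``.

    With ``cond.autoregulate`` (the default) ``cond.Q`` is the hyperemic
    flow of the *unobstructed* vessel; it fixes a distal microvascular
    resistance ``R_m = Pa/Q - R_ref`` (R_ref the straight reference-radius
    vessel's viscous resistance) and the actual flow solves
    ``Pa = (R_m + R_v) Q + c2 Q^2`` so distal pressure stays positive for
    arbitrarily tight stenoses. With ``autoregulate=False`` the flow is
    imposed as given and an over-severe lesion is rejected when the
    pressure would fall to zero.
    """
    if cond is None:
        cond = FlowConditions()
    z_m = geom.z * units.M_PER_MM
    a_m = geom.a * units.M_PER_MM
    if np.min(a_m) < 1e-6:
        raise ValueError("lumen is effectively occluded; flow solve rejected")
    pa_pa = units.mmhg_to_pa(cond.Pa)
    Q_nom = cond.Q * 1e-6  # m^3/s

    mask = geom.lesion_mask()
    idx_lesion = np.nonzero(mask)[0]
    i0, i1 = idx_lesion[0], idx_lesion[-1]
    i_throat = idx_lesion[np.argmin(a_m[idx_lesion])]
    A_s = np.pi * a_m[i_throat] ** 2
    A_0 = np.pi * a_m[i0] ** 2
    c2 = cond.Kt * 0.5 * cond.rho * (1.0 / A_s - 1.0 / A_0) ** 2

    # per-flow resistances: dP = R * Q (viscous), dP = c2 * Q^2 (expansion)
    rv_density = 8.0 * cond.mu / (np.pi * a_m**4)
    rv_cum = cumulative_trapezoid(rv_density, z_m, initial=0.0)
    R_v = rv_cum[-1]

    if Q_nom == 0.0:
        Q = 0.0
    elif cond.autoregulate:
        a_ref_m = geom.a_ref * units.M_PER_MM
        R_ref = 8.0 * cond.mu * (z_m[-1] - z_m[0]) / (np.pi * a_ref_m**4)
        R_m = pa_pa / Q_nom - R_ref
        if R_m <= 0:
            raise ValueError("nominal flow exceeds what the reference vessel can carry")
        b = R_m + R_v
        Q = 2.0 * pa_pa / (b + np.sqrt(b * b + 4.0 * c2 * pa_pa)) if c2 > 0 else pa_pa / b
    else:
        Q = Q_nom

    dpv = rv_cum * Q
    dpe_total = c2 * Q * Q
    dpe = np.zeros_like(z_m)
    if i_throat < i1:
        ramp = (z_m - z_m[i_throat]) / (z_m[i1] - z_m[i_throat])
        dpe = dpe_total * np.clip(ramp, 0.0, 1.0)
    else:
        dpe[i1:] = dpe_total

    p_pa = pa_pa - dpv - dpe
    if np.min(p_pa) <= 0:
        raise ValueError("pressure fell to zero: flow or stenosis out of model range")
    p = units.pa_to_mmhg(p_pa)
    tau = units.pa_to_dyncm2(4.0 * cond.mu * Q / (np.pi * a_m**3))

    w = _area_weight(geom)[mask]
    wss_mean = float(trapezoid(tau[mask] * w, geom.z[mask]) / trapezoid(w, geom.z[mask]))

    state = HemodynamicState(
        z=geom.z,
        p=p,
        tau=tau,
        Q=Q * 1e6,  # actual flow in mL/s (equals cond.Q unless autoregulated)
        Pa=cond.Pa,
        FFR=float(p[-1] / cond.Pa),
        dFFR=float((p[i0] - p[i1]) / cond.Pa),
        wss_mean=wss_mean,
        aps_mean=0.0,
    )
    aps_profile, aps_mean = axial_plaque_stress(geom, state)
    object.__setattr__(state, "aps_mean", aps_mean)
    return state


def ffr(state: HemodynamicState, distal_z: float | None = None) -> float:
    """FFR = downstream pressure / aortic pressure at ``distal_z``.

    Defaults to the most distal grid station.
    """
    if distal_z is None:
        return float(state.p[-1] / state.Pa)
    if not state.z[0] <= distal_z <= state.z[-1]:
        raise ValueError("distal_z outside the grid")
    return float(np.interp(distal_z, state.z, state.p) / state.Pa)


def delta_ffr(state: HemodynamicState, lesion_span: tuple[float, float]) -> float:
    """Drop of FFR across the lesion endpoints."""
    z0, z1 = lesion_span
    return ffr(state, z0) - ffr(state, z1)


def axial_plaque_stress(geom: LesionGeometry, state: HemodynamicState):
    """Axial hemodynamic traction on the wall and its lesion mean.

    Pointwise ``t_ax = p * n_z + tau * l_z`` with ``n_z = -a'/sqrt(1+a'^2)``
    the axial component of the outward wall normal and
    ``l_z = 1/sqrt(1+a'^2)`` that of the downstream tangent. The lesion
    summary is the area-weighted mean of |t_ax| in dyn/cm².

    Returns ``(t_ax profile in dyn/cm² on the full grid, lesion mean)``.
    """
    da = np.gradient(geom.a, geom.z)
    denom = np.sqrt(1.0 + da**2)
    n_z = -da / denom
    l_z = 1.0 / denom
    t_ax = units.pa_to_dyncm2(state.p_pa()) * n_z + state.tau * l_z
    mask = geom.lesion_mask()
    w = _area_weight(geom)[mask]
    mean = float(trapezoid(np.abs(t_ax[mask]) * w, geom.z[mask]) / trapezoid(w, geom.z[mask]))
    return t_ax, mean
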