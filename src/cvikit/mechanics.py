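"""Fibrous-cap stress from a per-station two-layer elasticity solution.

Each centerline station is treated as an axisymmetric plane-strain cylinder
with two concentric layers: the fibrous cap [a, a+h] (modulus Ec, Poisson
nu_c) and the plaque/wall annulus [a+h, b] (Ep, nu_p), loaded by the lumen
pressure p with either a traction-free or a clamped outer boundary. The
displacement in each layer is u(r) = A r + B / r (Lamé form); the four
coefficients follow from the inner pressure condition, displacement and
radial-traction continuity at the interface, and the outer condition.

The cap stress sigma_c is the thickness-averaged circumferential stress in
the cap layer — a membrane stress. The critical stress sigma* = p a / h is
the thin-walled-cylinder (Laplace) limit: a soft plaque offers little
support, pushing sigma_c toward sigma*.

Units: radii in mm, moduli and pressures in kPa, stresses in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .geometry import CapProperties, LesionGeometry, PlaqueComposition
from .hemodynamics import HemodynamicState

__all__ = ["CapStressProfile", "critical_stress", "cap_hoop_stress", "stress_profile"]


@dataclass(frozen=True)
class CapStressProfile:
    """Cap stress, critical stress and their ratio along the cap extent.

    ``z`` holds the grid stations inside the cap extent; ``sigma_c`` is the
    thickness-averaged cap hoop stress (kPa), ``sigma_c_inner`` the
    inner-surface peak value, ``sigma_star`` the Laplace limit p a / h (kPa)
    and ``ratio = max(sigma_c, 0) / sigma_star`` (dimensionless). A cap
    backed by very stiff plaque can be in hoop *compression* (the
    plane-strain Poisson coupling to radial compression dominates); such a
    cap carries no tensile rupture drive, so the ratio floors at zero while
    ``sigma_c`` keeps its sign.
    """

    z: np.ndarray
    sigma_c: np.ndarray
    sigma_star: np.ndarray
    ratio: np.ndarray
    sigma_c_inner: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(self.sigma_star > 0):
            raise ValueError("critical stress must be positive where pressure is positive")
        if not np.all(np.isfinite(self.ratio)) or np.any(self.ratio < 0):
            raise ValueError("stress ratio must be finite and non-negative")


def critical_stress(p, a, h):
    """Thin-walled-cylinder critical stress p*a/h (Laplace law).

    p in kPa, a and h in consistent length units; returns kPa.
    """
    if np.any(np.asarray(h) <= 0):
        raise ValueError("cap thickness must be positive")
    if np.any(np.asarray(a) <= 0):
        raise ValueError("lumen radius must be positive")
    if np.any(np.asarray(p) < 0):
        raise ValueError("pressure must be non-negative")
    return p * a / h


def _lame_constants(E, nu):
    G = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, G


def cap_hoop_stress(
    a,
    b,
    cap: CapProperties,
    Ep,
    nu_p: float = 0.45,
    p=10.0,
    outer_bc: str = "free",
    return_inner: bool = False,
):
    """Thickness-averaged circumferential cap stress (kPa), vectorized.

    Parameters
    ----------
    a, b : array_like
        Lumen and outer wall radii (mm), with ``a + h < b``.
    cap : CapProperties
        Cap modulus (kPa), Poisson ratio and thickness (µm).
    Ep : array_like
        Plaque/wall modulus (kPa), positive.
    nu_p : float
        Plaque Poisson ratio in [0, 0.5).
    p : array_like
        Lumen pressure (kPa), non-negative.
    outer_bc : {"free", "clamped"}
        Traction-free or zero-displacement condition at r = b.
    return_inner : bool
        Also return the inner-surface hoop stress.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.broadcast_to(np.asarray(b, dtype=float), a.shape).astype(float)
    Ep = np.broadcast_to(np.asarray(Ep, dtype=float), a.shape).astype(float)
    p = np.broadcast_to(np.asarray(p, dtype=float), a.shape).astype(float)
    h = cap.h_mm
    if np.any(a <= 0):
        raise ValueError("lumen radius must be positive")
    if np.any(a + h >= b):
        raise ValueError("layering impossible: need a + h < b")
    if np.any(Ep <= 0):
        raise ValueError("plaque modulus must be positive")
    if not 0 <= nu_p < 0.5:
        raise ValueError("plaque Poisson ratio must lie in [0, 0.5)")
    if outer_bc not in ("free", "clamped"):
        raise ValueError("outer_bc must be 'free' or 'clamped'")

    rm = a + h
    lam1, G1 = _lame_constants(cap.Ec, cap.nu_c)
    lam2, G2 = _lame_constants(Ep, nu_p)
    k1, g1 = 2.0 * (lam1 + G1), 2.0 * G1
    k2, g2 = 2.0 * (lam2 + G2), 2.0 * G2
    k2 = np.broadcast_to(k2, a.shape)
    g2 = np.broadcast_to(g2, a.shape)

    n = a.shape[0]
    M = np.zeros((n, 4, 4))
    rhs = np.zeros((n, 4))
    # sigma_rr^cap(a) = -p
    M[:, 0, 0] = k1
    M[:, 0, 1] = -g1 / a**2
    rhs[:, 0] = -p
    # displacement continuity at the interface
    M[:, 1, 0] = rm
    M[:, 1, 1] = 1.0 / rm
    M[:, 1, 2] = -rm
    M[:, 1, 3] = -1.0 / rm
    # radial traction continuity at the interface
    M[:, 2, 0] = k1
    M[:, 2, 1] = -g1 / rm**2
    M[:, 2, 2] = -k2
    M[:, 2, 3] = g2 / rm**2
    if outer_bc == "free":
        M[:, 3, 2] = k2
        M[:, 3, 3] = -g2 / b**2
    else:
        M[:, 3, 2] = b
        M[:, 3, 3] = 1.0 / b

    coef = np.linalg.solve(M, rhs[..., None])[..., 0]
    A1, B1 = coef[:, 0], coef[:, 1]
    # (1/h) int_a^rm sigma_thth dr with sigma_thth = k1 A1 + g1 B1 / r^2
    sigma_avg = k1 * A1 + g1 * B1 / (a * rm)
    if return_inner:
        sigma_inner = k1 * A1 + g1 * B1 / a**2
        return _unwrap(sigma_avg), _unwrap(sigma_inner)
    return _unwrap(sigma_avg)


def _unwrap(x):
    return float(x[0]) if x.shape == (1,) else x


def stress_profile(
    geom: LesionGeometry,
    plaque: PlaqueComposition,
    cap: CapProperties,
    state: HemodynamicState,
    outer_bc: str = "free",
) -> CapStressProfile:
    """Station-wise cap stress and critical stress over the cap extent.

    Applies the two-layer kernel independently at each grid station inside
    ``geom.cap_extent`` with the local radius, plaque modulus and pressure;
    there is no axial coupling between stations.
    """
    if geom.z.shape != state.z.shape or not np.allclose(geom.z, state.z):
        raise ValueError("geometry and hemodynamic state are on different grids")
    if plaque.plaque_modulus.shape != geom.z.shape:
        raise ValueError("plaque modulus profile is on a different grid")
    mask = geom.cap_mask()
    if not np.any(mask):
        raise ValueError("cap extent contains no grid stations")
    a = geom.a[mask]
    b = geom.b[mask]
    Ep = plaque.plaque_modulus[mask]
    p_kpa = state.p_pa()[mask] * units.KPA_PER_PA
    sig_c, sig_in = cap_hoop_stress(
        a, b, cap, Ep, nu_p=plaque.nu_p, p=p_kpa, outer_bc=outer_bc, return_inner=True
    )
    sig_star = critical_stress(p_kpa, a, cap.h_mm)
    sig_c = np.atleast_1d(sig_c)
    sig_star = np.atleast_1d(sig_star)
    return CapStressProfile(
        z=geom.z[mask],
        sigma_c=sig_c,
        sigma_star=sig_star,
        ratio=np.maximum(sig_c, 0.0) / sig_star,
        sigma_c_inner=np.atleast_1d(sig_in),
    )
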