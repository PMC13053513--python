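"""Idealized axisymmetric lesion geometry and plaque composition.

A lesion is represented by lumen and outer-wall radius profiles a(z), b(z)
on a uniform centerline grid. The stenosis is a smooth symmetric narrowing
(cosine bump by default, Gaussian optional) that reaches the minimum radius
``a_ref * (1 - severity)`` at the lesion midpoint. Plaque stiffness is a
surrogate of CT attenuation: a monotone piecewise-linear map from Hounsfield
units to an elastic modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LesionGeometry",
    "PlaqueComposition",
    "CapProperties",
    "DEFAULT_HU_ANCHORS",
    "build_lesion",
    "diameter_stenosis",
    "lesion_length",
    "hu_to_modulus",
]

# (HU, kPa) anchors: lipid-rich plaque is soft, calcium is orders of
# magnitude stiffer. The map is a config artifact, not a measured law.
DEFAULT_HU_ANCHORS = ((-30.0, 5.0), (30.0, 25.0), (150.0, 1000.0), (400.0, 10000.0))


@dataclass(frozen=True)
class LesionGeometry:
    """Axisymmetric lumen/wall radius profiles along the centerline.

    Attributes
    ----------
    z : ndarray
        Strictly increasing centerline coordinate (mm).
    a : ndarray
        Lumen radius profile (mm), positive everywhere.
    b : ndarray
        Outer wall radius profile (mm), ``b > a`` everywhere.
    a_ref : float
        Proximal reference lumen radius (mm).
    lesion_span : tuple of float
        ``(z0, z1)`` lesion endpoints (mm), ``z0 < z1``.
    cap_extent : tuple of float
        Sub-interval of ``lesion_span`` covered by the fibrous cap (mm).
    """

    z: np.ndarray
    a: np.ndarray
    b: np.ndarray
    a_ref: float
    lesion_span: tuple[float, float]
    cap_extent: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if z.ndim != 1 or len(z) < 2:
            raise ValueError("z grid must be 1-D with at least two samples")
        if not np.all(np.diff(z) > 0):
            raise ValueError("z grid must be strictly increasing")
        if a.shape != z.shape or b.shape != z.shape:
            raise ValueError("a and b must share the z grid shape")
        if not np.all(a > 0):
            raise ValueError("lumen radius must be positive everywhere")
        if not np.all(b > a):
            raise ValueError("outer wall radius must exceed lumen radius")
        if self.a_ref <= 0:
            raise ValueError("reference radius must be positive")
        z0, z1 = self.lesion_span
        if not (z0 < z1):
            raise ValueError("lesion_span must satisfy z0 < z1")
        if z0 < z[0] - 1e-12 or z1 > z[-1] + 1e-12:
            raise ValueError("lesion_span outside the grid range")
        if self.cap_extent is None:
            object.__setattr__(self, "cap_extent", (z0, z1))
        c0, c1 = self.cap_extent
        if not (z0 - 1e-12 <= c0 < c1 <= z1 + 1e-12):
            raise ValueError("cap_extent must be a sub-interval of lesion_span")

    def lesion_mask(self) -> np.ndarray:
        z0, z1 = self.lesion_span
        return (self.z >= z0 - 1e-12) & (self.z <= z1 + 1e-12)

    def cap_mask(self) -> np.ndarray:
        c0, c1 = self.cap_extent
        return (self.z >= c0 - 1e-12) & (self.z <= c1 + 1e-12)


@dataclass(frozen=True)
class PlaqueComposition:
    """Attenuation-derived plaque stiffness and adverse-plaque flags.

    ``hu`` is the attenuation profile along z (HU); ``plaque_modulus`` the
    derived stiffness profile Ep(z) in kPa. Flags: LAP (low-attenuation
    plaque, any pixel <= 30 HU), SC (spotty calcification), PR (positive
    remodeling, index >= 1.1), NRS (napkin-ring sign). SC and NRS cannot be
    derived from a 1-D attenuation profile; they are carried as labels.
    """

    hu: np.ndarray
    plaque_modulus: np.ndarray
    remodeling_index: float
    lap: bool
    sc: bool
    pr: bool
    nrs: bool
    nu_p: float = 0.45

    LAP_HU_THRESHOLD = 30.0
    PR_RI_THRESHOLD = 1.1

    def __post_init__(self):
        hu = np.asarray(self.hu, dtype=float)
        ep = np.asarray(self.plaque_modulus, dtype=float)
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "plaque_modulus", ep)
        if not np.all(ep > 0):
            raise ValueError("plaque modulus must be positive everywhere")
        if not 0 <= self.nu_p < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.lap != bool(np.min(hu) <= self.LAP_HU_THRESHOLD):
            raise ValueError("LAP flag inconsistent with attenuation profile")
        if self.pr != bool(self.remodeling_index >= self.PR_RI_THRESHOLD):
            raise ValueError("PR flag inconsistent with remodeling index")


@dataclass(frozen=True)
class CapProperties:
    """Fibrous-cap material and thickness: Ec (kPa), nu_c, h (µm)."""

    Ec: float = 200.0
    nu_c: float = 0.25
    h: float = 20.0

    def __post_init__(self):
        if self.Ec <= 0:
            raise ValueError("cap modulus must be positive")
        if not 0 <= self.nu_c < 0.5:
            raise ValueError("cap Poisson ratio must lie in [0, 0.5)")
        if self.h <= 0:
            raise ValueError("cap thickness must be positive")

    @property
    def h_mm(self) -> float:
        return self.h * 1e-3


def _bump(zeta: np.ndarray, family: str) -> np.ndarray:
    """Unit bump on zeta in [-1, 1], equal to 1 at 0 and ~0 at the edges."""
    if family == "cosine":
        out = 0.5 * (1.0 + np.cos(np.pi * np.clip(zeta, -1.0, 1.0)))
        return np.where(np.abs(zeta) <= 1.0, out, 0.0)
    if family == "gaussian":
        # sigma chosen so the bump decays to ~3e-4 at the lesion endpoints
        return np.exp(-0.5 * (zeta / 0.25) ** 2)
    raise ValueError(f"unknown stenosis profile family: {family!r}")


def build_lesion(
    *,
    a_ref: float = 1.5,
    severity: float = 0.5,
    length: float = 16.0,
    family: str = "cosine",
    dz: float = 0.1,
    inlet: float = 10.0,
    outlet: float = 10.0,
    wall_thickness: float = 1.0,
    hu_min: float = 60.0,
    hu_background: float = 120.0,
    remodeling_index: float = 1.0,
    sc: bool = False,
    nrs: bool = False,
    hu_anchors=DEFAULT_HU_ANCHORS,
    nu_p: float = 0.45,
) -> tuple[LesionGeometry, PlaqueComposition]:
    """Construct an idealized lesion: geometry plus plaque composition.

    The lumen narrows symmetrically from ``a_ref`` to
    ``a_ref * (1 - severity)`` at the lesion midpoint over ``length`` mm,
    with straight inlet/outlet segments on either side. The attenuation
    profile dips from ``hu_background`` to ``hu_min`` with the same bump
    shape, so the softest plaque sits at the throat. The outer wall follows
    the lumen at constant ``wall_thickness`` plus outward remodeling of the
    wall over the lesion (proportional to ``remodeling_index - 1``).

    Parameters use mm, HU and dimensionless severity in [0, 1).
    """
    if not 0 <= severity < 1:
        raise ValueError("severity must lie in [0, 1): total occlusion is not representable")
    if length <= 0:
        raise ValueError("lesion length must be positive")
    if dz <= 0:
        raise ValueError("grid step must be positive")

    z0, z1 = inlet, inlet + length
    total = inlet + length + outlet
    n = int(round(total / dz)) + 1
    z = np.linspace(0.0, total, n)
    mid = 0.5 * (z0 + z1)
    zeta = (z - mid) / (0.5 * length)
    bump = _bump(zeta, family)
    # outside the lesion the bump is forced to zero (cosine already is)
    bump = np.where((z >= z0) & (z <= z1), bump, 0.0)

    a = a_ref * (1.0 - severity * bump)
    # positive remodeling bulges the outer wall outward over the lesion
    outward = max(remodeling_index - 1.0, 0.0) * a_ref * bump
    b = a + wall_thickness + severity * a_ref * bump + outward

    hu = hu_background - (hu_background - hu_min) * bump
    ep = hu_to_modulus(hu, hu_anchors)

    geom = LesionGeometry(z=z, a=a, b=b, a_ref=a_ref, lesion_span=(z0, z1))
    plaque = PlaqueComposition(
        hu=hu,
        plaque_modulus=ep,
        remodeling_index=remodeling_index,
        lap=bool(np.min(hu) <= PlaqueComposition.LAP_HU_THRESHOLD),
        sc=sc,
        pr=bool(remodeling_index >= PlaqueComposition.PR_RI_THRESHOLD),
        nrs=nrs,
        nu_p=nu_p,
    )
    return geom, plaque


def diameter_stenosis(geom: LesionGeometry) -> float:
    """Diameter stenosis DS = 1 - min lumen diameter / reference diameter."""
    if geom.a_ref <= 0:
        raise ValueError("reference radius must be positive")
    a_min = float(np.min(geom.a[geom.lesion_mask()]))
    return 1.0 - a_min / geom.a_ref


def lesion_length(geom: LesionGeometry) -> float:
    """Centerline length between the lesion endpoints (mm)."""
    z0, z1 = geom.lesion_span
    return z1 - z0


def hu_to_modulus(hu, anchors=DEFAULT_HU_ANCHORS):
    """Map attenuation (HU) to an elastic modulus (kPa).

    Piecewise-linear and monotone between ``anchors`` ((hu, kPa) pairs,
    strictly increasing in both coordinates); clamped at the end anchors.
    """
    anchors = tuple(anchors)
    if len(anchors) < 2:
        raise ValueError("need at least two anchors")
    hu_pts = np.array([p[0] for p in anchors], dtype=float)
    e_pts = np.array([p[1] for p in anchors], dtype=float)
    if not (np.all(np.diff(hu_pts) > 0) and np.all(np.diff(e_pts) > 0)):
        raise ValueError("anchors must be strictly increasing in HU and in modulus")
    out = np.interp(np.asarray(hu, dtype=float), hu_pts, e_pts)
    return float(out) if np.isscalar(hu) else out
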