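"""Optical descriptions of the cornea and the pseudophakic eye.

Geometry lives in a single right-handed frame: z runs from the cornea
toward the retina, the origin sits at the anterior corneal vertex, and all
surface vertex positions are on that axis.  Curvatures are positive when
the centre of curvature lies toward the retina.  Lengths are in mm;
Zernike elevations are in um over their own normalization radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

import numpy as np

from .zernike import ZernikeExpansion, evaluate

if TYPE_CHECKING:  # pragma: no cover
    from .iol_select import ToricIOL

__all__ = [
    "ZernikeSagSurface",
    "BiconicSurface",
    "CornealModel",
    "EyeBiometry",
    "PseudophakicEye",
    "estimated_lens_position",
    "surface_sag",
    "surface_normal",
    "KERATOMETRIC_INDEX",
]

#: Clinical keratometric index used to express anterior curvature in D.
KERATOMETRIC_INDEX = 1.3375

#: Central-difference step (mm) used for surface gradients.
GRADIENT_STEP = 1e-5


@dataclass
class ZernikeSagSurface:
    """Conicoid base plus a Zernike elevation deviation.

    ``base_curvature`` is 1/mm (positive = centre of curvature toward the
    retina); ``zernike_elevation`` holds the sag deviation in um over its
    own normalization radius; ``vertex_z`` is the axial vertex position.
    """

    base_curvature: float
    conic_constant: float = 0.0
    zernike_elevation: Optional[ZernikeExpansion] = None
    aperture_radius: float = 3.25
    vertex_z: float = 0.0

    def __post_init__(self) -> None:
        if (self.zernike_elevation is not None
                and self.aperture_radius > self.zernike_elevation.pupil_radius + 1e-9):
            raise ValueError("aperture exceeds the Zernike normalization radius")

    def sag(self, x, y) -> np.ndarray:
        """Sag z - vertex_z (mm) at transverse position (x, y) in mm."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r2 = x * x + y * y
        c, k = self.base_curvature, self.conic_constant
        arg = 1.0 - (1.0 + k) * c * c * r2
        arg = np.maximum(arg, 0.0)  # aperture invariant keeps sag finite
        z = c * r2 / (1.0 + np.sqrt(arg))
        if self.zernike_elevation is not None:
            rn = self.zernike_elevation.pupil_radius
            z = z + 1e-3 * evaluate(self.zernike_elevation, x / rn, y / rn,
                                    mask_outside=False)
        return z


@dataclass
class BiconicSurface:
    """Biconic surface with independent principal curvatures.

    Used for toric IOL surfaces: ``cx``/``cy`` are the curvatures (1/mm)
    along the principal meridians after rotating by ``axis_deg`` (TABO).
    """

    cx: float
    cy: float
    axis_deg: float = 0.0
    kx: float = 0.0
    ky: float = 0.0
    aperture_radius: float = 3.0
    vertex_z: float = 0.0
    decenter_x: float = 0.0
    decenter_y: float = 0.0

    def sag(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float) - self.decenter_x
        y = np.asarray(y, dtype=float) - self.decenter_y
        a = math.radians(self.axis_deg)
        xr = x * math.cos(a) + y * math.sin(a)
        yr = -x * math.sin(a) + y * math.cos(a)
        num = self.cx * xr ** 2 + self.cy * yr ** 2
        arg = (1.0 - (1.0 + self.kx) * self.cx ** 2 * xr ** 2
               - (1.0 + self.ky) * self.cy ** 2 * yr ** 2)
        arg = np.maximum(arg, 0.0)
        return num / (1.0 + np.sqrt(arg))

    def rotated(self, offset_deg: float) -> "BiconicSurface":
        return BiconicSurface(self.cx, self.cy, self.axis_deg + offset_deg,
                              self.kx, self.ky, self.aperture_radius,
                              self.vertex_z, self.decenter_x, self.decenter_y)


def surface_sag(surface, x, y) -> np.ndarray:
    """Sag relative to the surface vertex; thin wrapper over ``surface.sag``."""
    return surface.sag(x, y)


def surface_normal(surface, x, y) -> np.ndarray:
    """Unit surface normal at (x, y), oriented toward -z (against incoming
    rays travelling in +z).

    Gradients are taken by central differences with step ``GRADIENT_STEP``
    (stated here rather than configurable per call; the surfaces are smooth
    at that scale).
    """
    h = GRADIENT_STEP
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dzdx = (surface.sag(x + h, y) - surface.sag(x - h, y)) / (2 * h)
    dzdy = (surface.sag(x, y + h) - surface.sag(x, y - h)) / (2 * h)
    n = np.stack([dzdx, dzdy, -np.ones_like(dzdx)], axis=-1)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("degenerate surface gradient")
    return n / norm


@dataclass
class CornealModel:
    """Two-surface cornea: anterior and posterior Zernike sag surfaces."""

    anterior: ZernikeSagSurface
    posterior: ZernikeSagSurface
    central_thickness: float = 0.55
    n_cornea: float = 1.376
    n_aqueous: float = 1.334
    n_object: float = 1.0  # index in front of the cornea (air)

    def __post_init__(self) -> None:
        if self.central_thickness <= 0:
            raise ValueError("central_thickness must be positive")
        self.posterior.vertex_z = self.central_thickness

    def keratometry_from_curvature(self) -> float:
        """Mean simulated K (D) from the anterior apical curvature with the
        clinical keratometric index 1.3375."""
        return (KERATOMETRIC_INDEX - 1.0) * self.anterior.base_curvature * 1000.0


@dataclass
class EyeBiometry:
    """Axial biometry: anterior chamber depth (epithelium to lens), lens
    thickness and axial length, all in mm."""

    acd: float
    lens_thickness: float
    axial_length: float

    def __post_init__(self) -> None:
        if min(self.acd, self.axial_length) <= 0 or self.lens_thickness < 0:
            raise ValueError("biometry must be positive")
        if self.axial_length <= self.acd + self.lens_thickness:
            raise ValueError("axial length must exceed ACD + lens thickness")


def estimated_lens_position(biometry: EyeBiometry) -> float:
    """Predicted IOL plane: ACD + 0.3 x lens thickness (mm)."""
    return biometry.acd + 0.3 * biometry.lens_thickness


@dataclass
class PseudophakicEye:
    """Four-surface pseudophakic eye: cornea + thick IOL + retina plane.

    ``rotation_offset`` rotates the toric axis of the implanted IOL away
    from its intended orientation; ``decentration`` shifts it transversally.
    Defaults encode perfect centration and no tilt.
    """

    cornea: CornealModel
    iol: "ToricIOL"
    elp: float
    axial_length: float
    n_vitreous: float = 1.334
    decentration: float = 0.0
    rotation_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.elp + self.iol.central_thickness >= self.axial_length:
            raise ValueError("IOL does not fit between ELP and retina")
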