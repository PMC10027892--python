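"""Exact sequential ray tracing through corneal and pseudophakic eye models.

A collimated bundle is propagated surface by surface (Newton iteration for
the ray/freeform intersection, vector Snell refraction), optical path
lengths are accumulated, and the optical path difference relative to the
chief ray — referenced to a sphere centred on the chosen focus — is fitted
with a 28-term (6th-order) Zernike expansion over the 4-mm entrance pupil.

Sign convention: OPD = OPL(chief) - OPL(ray).  With the reference sphere
centred beyond the actual focus of an over-powered (myopic) eye this gives
c(2,0) > 0, matching the refraction conventions of :mod:`rtiol.zernike`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .eye_model import CornealModel, PseudophakicEye, surface_normal
from .zernike import (ZernikeExpansion, fit, fit_residual_rms,
                      zernike_to_powervector)

__all__ = [
    "Ray",
    "RayBundle",
    "WavefrontMap",
    "RaytraceError",
    "refract",
    "intersect",
    "trace_corneal_wavefront",
    "trace_pseudophakic",
    "best_focus",
    "pupil_grid",
]

WAVELENGTH_UM = 0.555
MAX_DEAD_FRACTION = 0.02
_NEWTON_TOL = 1e-11  # mm
_NEWTON_MAXIT = 30


class RaytraceError(RuntimeError):
    pass


@dataclass
class Ray:
    """A single ray: origin (mm), unit direction, accumulated OPL (mm)."""

    origin: np.ndarray
    direction: np.ndarray
    opl: float = 0.0
    alive: bool = True


@dataclass
class RayBundle:
    """Vectorized ray state for a whole bundle."""

    pos: np.ndarray          # (N, 3) mm
    dirs: np.ndarray         # (N, 3) unit vectors
    opl: np.ndarray          # (N,) mm (geometric length x index)
    alive: np.ndarray        # (N,) bool
    pupil_xy: np.ndarray     # (N, 2) entrance-pupil coordinates, mm

    @property
    def n_dead(self) -> int:
        return int(np.sum(~self.alive))


@dataclass
class WavefrontMap:
    """Wave aberration at the 4-mm entrance pupil, 555 nm, as a 28-term
    Zernike expansion (piston and tilt removed)."""

    expansion: ZernikeExpansion
    wavelength: float = WAVELENGTH_UM
    reference: str = "best_focus"          # or "fixed_plane"
    residual_fit_rms: float = 0.0          # um
    best_focus_z: float | None = None      # mm (corneal traces)
    dead_ray_fraction: float = 0.0

    @property
    def pupil_radius(self) -> float:
        return self.expansion.pupil_radius


# ----------------------------------------------------------------------
# Elementary operations
# ----------------------------------------------------------------------

def refract(direction: np.ndarray, normal: np.ndarray, n1: float,
            n2: float) -> np.ndarray:
    """Vector Snell refraction of unit direction(s) at unit normal(s).

    Returns NaN rows for rays in total internal reflection; callers mark
    those rays dead and count them.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    nv = np.atleast_2d(np.asarray(normal, dtype=float))
    # orient normals against the incoming ray
    cosi = -np.sum(d * nv, axis=-1)
    flip = cosi < 0
    nv = np.where(flip[:, None], -nv, nv)
    cosi = np.abs(cosi)
    eta = n1 / n2
    k = 1.0 - eta * eta * (1.0 - cosi * cosi)
    tir = k < 0
    with np.errstate(invalid="ignore"):
        t = eta * d + (eta * cosi - np.sqrt(np.maximum(k, 0.0)))[:, None] * nv
    t[tir] = np.nan
    t = t / np.linalg.norm(t, axis=-1, keepdims=True)
    if np.ndim(direction) == 1:
        return t[0]
    return t


def intersect(pos: np.ndarray, dirs: np.ndarray, surface,
              alive: np.ndarray | None = None):
    """Ray/surface intersection by Newton iteration on
    ``f(t) = z(t) - vertex_z - sag(x(t), y(t))``, seeded at the vertex
    plane, with a bracketed (Brent) fallback for the rare non-monotone
    cases near steep keratoconic slopes.

    Returns ``(points, t, hit)`` where ``hit`` flags rays that converged
    inside the aperture.
    """
    pos = np.atleast_2d(pos)
    dirs = np.atleast_2d(dirs)
    n = pos.shape[0]
    if alive is None:
        alive = np.ones(n, dtype=bool)
    t = np.where(np.abs(dirs[:, 2]) > 1e-12,
                 (surface.vertex_z - pos[:, 2]) / dirs[:, 2], 0.0)

    def f_of(tv):
        p = pos + tv[:, None] * dirs
        return p[:, 2] - surface.vertex_z - surface.sag(p[:, 0], p[:, 1])

    converged = np.zeros(n, dtype=bool)
    for _ in range(_NEWTON_MAXIT):
        fv = f_of(t)
        converged = np.abs(fv) < _NEWTON_TOL
        if np.all(converged | ~alive):
            break
        h = 1e-6
        dfd = (f_of(t + h) - fv) / h
        step = np.where(np.abs(dfd) > 1e-14, fv / np.where(dfd == 0, 1, dfd), 0.0)
        step = np.clip(step, -2.0, 2.0)
        t = np.where(converged, t, t - step)
    if not np.all(converged | ~alive):
        # Brent fallback per remaining ray
        for i in np.flatnonzero(alive & ~converged):
            t[i] = _brent_intersection(pos[i], dirs[i], surface, t[i])
            converged[i] = np.isfinite(t[i])
    points = pos + t[:, None] * dirs
    r = np.hypot(points[:, 0], points[:, 1])
    hit = converged & (r <= surface.aperture_radius + 1e-9) & alive
    return points, t, hit


def _brent_intersection(p, d, surface, t0) -> float:
    def f(tv):
        q = p + tv * d
        return q[2] - surface.vertex_z - float(surface.sag(q[0], q[1]))

    lo, hi = t0 - 2.0, t0 + 2.0
    for _ in range(30):
        if f(lo) * f(hi) < 0:
            try:
                return brentq(f, lo, hi, xtol=1e-12)
            except ValueError:
                return np.nan
        lo -= 1.0
        hi += 1.0
    return np.nan


# ----------------------------------------------------------------------
# Bundle tracing
# ----------------------------------------------------------------------

def pupil_grid(pupil_radius: float, grid_density: int = 33) -> np.ndarray:
    """Square grid of ray heights covering the pupil (includes the chief
    ray at the centre when ``grid_density`` is odd)."""
    ax = np.linspace(-pupil_radius, pupil_radius, grid_density)
    xx, yy = np.meshgrid(ax, ax)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    keep = np.hypot(pts[:, 0], pts[:, 1]) <= pupil_radius + 1e-12
    return pts[keep]


def _trace_through(surfaces: Sequence, media: Sequence[float],
                   pupil_xy: np.ndarray, start_z: float = -5.0) -> RayBundle:
    """Propagate a collimated +z bundle through ``surfaces`` with
    refractive ``media`` (len = len(surfaces) + 1)."""
    n = pupil_xy.shape[0]
    pos = np.column_stack([pupil_xy, np.full(n, start_z)])
    dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    opl = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    for surf, n1, n2 in zip(surfaces, media[:-1], media[1:]):
        pts, t, hit = intersect(pos, dirs, surf, alive)
        dead_now = alive & ~hit
        alive &= hit
        opl = np.where(alive, opl + n1 * t, opl)
        pos = np.where(alive[:, None], pts, pos)
        if n1 != n2:
            newd = refract(dirs, surface_normal(surf, pts[:, 0], pts[:, 1]),
                           n1, n2)
            tirs = np.any(~np.isfinite(newd), axis=-1)
            alive &= ~tirs
            dirs = np.where(alive[:, None], newd, dirs)
        _ = dead_now
    return RayBundle(pos, dirs, opl, alive, pupil_xy)


def _opd_to_reference_sphere(bundle: RayBundle, center_z: float,
                             n_image: float) -> np.ndarray:
    """OPD (um) = OPL(chief) - OPL(ray), each ray virtually propagated
    (signed path) to the sphere centred at (0, 0, center_z) through the
    entrance-pupil vertex (radius = center_z)."""
    c = np.array([0.0, 0.0, center_z])
    radius = center_z
    oc = bundle.pos - c
    b = np.sum(bundle.dirs * oc, axis=-1)
    q = np.sum(oc * oc, axis=-1) - radius ** 2
    disc = b * b - q
    disc = np.maximum(disc, 0.0)
    root = np.sqrt(disc)
    # choose the branch of the sphere near the pupil (smaller z)
    t1, t2 = -b - root, -b + root
    z1 = bundle.pos[:, 2] + t1 * bundle.dirs[:, 2]
    z2 = bundle.pos[:, 2] + t2 * bundle.dirs[:, 2]
    t = np.where(np.abs(z1 - 0.0) <= np.abs(z2 - 0.0), t1, t2)
    opl_total = bundle.opl + n_image * t
    chief = np.argmin(np.hypot(bundle.pupil_xy[:, 0], bundle.pupil_xy[:, 1]))
    return (opl_total[chief] - opl_total) * 1e3  # mm -> um


def _fit_wavefront(bundle: RayBundle, opd_um: np.ndarray, pupil_radius: float,
                   max_order: int = 6) -> tuple[ZernikeExpansion, float]:
    ok = bundle.alive
    exp = fit(opd_um[ok], bundle.pupil_xy[ok, 0], bundle.pupil_xy[ok, 1],
              max_order, pupil_radius)
    res = fit_residual_rms(exp, opd_um[ok], bundle.pupil_xy[ok, 0],
                           bundle.pupil_xy[ok, 1])
    # remove piston and tilt: pointing, not blur
    for key in [(0, 0), (1, -1), (1, 1)]:
        exp.coefficients.pop(key, None)
    return exp, res


def _check_dead(bundle: RayBundle) -> float:
    frac = bundle.n_dead / bundle.pos.shape[0]
    if frac > MAX_DEAD_FRACTION:
        raise RaytraceError(
            f"{bundle.n_dead}/{bundle.pos.shape[0]} rays lost "
            "(surface miss or total internal reflection)")
    return frac


def best_focus(bundle: RayBundle, n_image: float, pupil_radius: float,
               bracket: tuple[float, float] = (10.0, 80.0)) -> float:
    """Axial reference position (mm) minimizing the RMS wavefront error
    (piston/tilt removed) — the 'best focus after iteration'.

    Bounded scalar minimization; tolerance corresponds to ~1e-4 D.
    """
    xn = bundle.pupil_xy[bundle.alive, 0] / pupil_radius
    yn = bundle.pupil_xy[bundle.alive, 1] / pupil_radius
    basis = np.column_stack([np.ones_like(xn), xn, yn])
    proj = basis @ np.linalg.pinv(basis)

    def rms_at(zf: float) -> float:
        opd = _opd_to_reference_sphere(bundle, zf, n_image)[bundle.alive]
        resid = opd - proj @ opd
        return float(np.sqrt(np.mean(resid ** 2)))

    res = minimize_scalar(rms_at, bounds=bracket, method="bounded",
                          options={"xatol": 2e-5})
    if not res.success:  # pragma: no cover
        raise RaytraceError("best-focus search did not converge; widen bracket")
    return float(res.x)


# ----------------------------------------------------------------------
# High-level traces
# ----------------------------------------------------------------------

def trace_corneal_wavefront(cornea: CornealModel, pupil_diameter: float = 4.0,
                            grid_density: int = 33) -> WavefrontMap:
    """Corneal wave aberration for a collimated 555-nm beam over the
    central ``pupil_diameter`` zone, referenced to the best-focus sphere.

    The defocus term is near zero by construction (best focus); residual
    second-order terms are the corneal astigmatism.
    """
    r_pupil = pupil_diameter / 2.0
    xy = pupil_grid(r_pupil, grid_density)
    media = [cornea.n_object, cornea.n_cornea, cornea.n_aqueous]
    bundle = _trace_through([cornea.anterior, cornea.posterior], media, xy)
    dead = _check_dead(bundle)
    if media[0] == media[1] == media[2]:
        # no refraction anywhere: the wavefront stays planar and there is
        # no focus to iterate; reference to a plane (infinite radius)
        zf = None
        opl_total = bundle.opl + media[-1] * (10.0 - bundle.pos[:, 2]) / bundle.dirs[:, 2]
        chief = np.argmin(np.hypot(xy[:, 0], xy[:, 1]))
        opd = (opl_total[chief] - opl_total) * 1e3
    else:
        zf = best_focus(bundle, media[-1], r_pupil)
        opd = _opd_to_reference_sphere(bundle, zf, media[-1])
    exp, res = _fit_wavefront(bundle, opd, r_pupil)
    return WavefrontMap(exp, reference="best_focus", residual_fit_rms=res,
                        best_focus_z=zf, dead_ray_fraction=dead)


def trace_pseudophakic(eye: PseudophakicEye, pupil_diameter: float = 4.0,
                       grid_density: int = 33) -> WavefrontMap:
    """Residual wave aberration of the four-surface pseudophakic eye,
    referenced to a sphere centred on the retina at the axial length.

    The second-order part of the result, via
    :func:`rtiol.zernike.zernike_to_powervector`, is the eye's residual
    refraction at the corneal plane.
    """
    r_pupil = pupil_diameter / 2.0
    xy = pupil_grid(r_pupil, grid_density)
    front, back = eye.iol.surfaces(elp=eye.elp,
                                   rotation_offset=eye.rotation_offset,
                                   decentration=eye.decentration)
    surfaces = [eye.cornea.anterior, eye.cornea.posterior, front, back]
    media = [eye.cornea.n_object, eye.cornea.n_cornea, eye.cornea.n_aqueous,
             eye.iol.n_iol, eye.n_vitreous]
    bundle = _trace_through(surfaces, media, xy)
    dead = _check_dead(bundle)
    opd = _opd_to_reference_sphere(bundle, eye.axial_length, eye.n_vitreous)
    exp, res = _fit_wavefront(bundle, opd, r_pupil)
    return WavefrontMap(exp, reference="fixed_plane", residual_fit_rms=res,
                        best_focus_z=None, dead_ray_fraction=dead)


def residual_refraction(eye: PseudophakicEye, pupil_diameter: float = 4.0,
                        grid_density: int = 33):
    """Convenience: (WavefrontMap, PowerVector) of the pseudophakic eye."""
    wf = trace_pseudophakic(eye, pupil_diameter, grid_density)
    return wf, zernike_to_powervector(wf.expansion)
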