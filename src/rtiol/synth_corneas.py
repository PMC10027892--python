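"""Seeded generator of synthetic corneas for seven keratoconus
progression groups (0 to 120 months after simulated onset).

Each group is specified by the marginal statistics of five descriptive
corneal parameters at the 4-mm pupil — steep/flat keratometry K1/K2,
corneal astigmatism, RMS of higher-order aberrations, and spherical
aberration c(4,0) — as mean +/- SD with [min, max] bounds.  Values are
drawn from truncated normals with rejection against the bounds.

A generated eye is a two-surface corneal model: a conicoid base (radius
from the sampled mean K with the 1.3375 keratometric index, Q = -0.26,
posterior radius 0.82x anterior) plus an anterior Zernike elevation that
realizes the sampled astigmatism and higher-order content.  The elevation
is computed as (W_target - W_base) / (n_cornea - 1), where W_base is the
ray-traced wavefront of the bare conicoid — a one-trace-per-eye
calibration that pins the realized (traced) aberrations to the sampled
targets to first order.  Keratoconic groups shape the higher-order budget
with a decentred inferior cone (Gaussian elevation bump fitted to the
Zernike basis, vertical-coma dominant) mixed with a broadband random
component; normal groups use the random component alone.  Progressive
central thinning accompanies the cone.

Biometry distributions (ACD 3.1 +/- 0.3 mm, LT 4.5 +/- 0.3 mm, AL 23.5
+/- 1.0 mm) are plausible adult values invented for this generator — the
group statistics above say nothing about axial biometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .eye_model import CornealModel, EyeBiometry, ZernikeSagSurface
from .raytrace import WavefrontMap, trace_corneal_wavefront
from .zernike import (ZernikeExpansion, fit, nm_modes, rms_hoa,
                      zernike_to_powervector)

__all__ = ["GroupStats", "SynthEye", "TABLE1", "GROUP_MONTHS",
           "generate_group", "generate_population", "validate_against_table1"]

CONIC_Q = -0.26
POSTERIOR_RATIO = 0.82
KERAT_INDEX = 1.3375
ELEVATION_NORM_RADIUS = 3.25   # mm; corneal diameter 6.5 mm
PUPIL_RADIUS = 2.0             # mm; statistics defined at the 4-mm pupil


@dataclass(frozen=True)
class Stat:
    mean: float
    sd: float
    lo: float
    hi: float


@dataclass(frozen=True)
class GroupStats:
    """Marginal statistics of one progression group (n = 30 eyes)."""

    months: int
    k1: Stat
    k2: Stat
    astigmatism: Stat      # D, negative-cylinder magnitude as negative values
    rms_hoa: Stat          # um, 4-mm pupil
    spherical_aberration: Stat  # um c(4,0), 4-mm pupil


TABLE1: Dict[int, GroupStats] = {
    0: GroupStats(0,
                  Stat(44.35, 1.49, 41.44, 48.56), Stat(43.72, 1.57, 41.08, 48.12),
                  Stat(-0.64, 0.35, -1.24, -0.05), Stat(0.10, 0.04, 0.04, 0.26),
                  Stat(0.04, 0.01, -0.01, 0.07)),
    12: GroupStats(12,
                   Stat(44.46, 1.31, 42.30, 48.43), Stat(43.86, 1.43, 41.17, 48.14),
                   Stat(-0.61, 0.30, -1.45, -0.09), Stat(0.16, 0.08, 0.03, 0.38),
                   Stat(0.03, 0.02, -0.01, 0.07)),
    24: GroupStats(24,
                   Stat(45.42, 2.48, 41.66, 54.86), Stat(43.86, 2.44, 40.60, 53.68),
                   Stat(-1.56, 0.93, -3.62, -0.22), Stat(0.48, 0.27, 0.16, 1.11),
                   Stat(-0.01, 0.09, -0.33, 0.17)),
    36: GroupStats(36,
                   Stat(45.98, 3.25, 40.67, 55.61), Stat(43.62, 3.50, 37.52, 52.31),
                   Stat(-2.36, 1.40, -5.96, -0.22), Stat(0.71, 0.36, 0.10, 1.51),
                   Stat(-0.05, 0.18, -0.68, 0.19)),
    48: GroupStats(48,
                   Stat(46.92, 3.24, 41.85, 52.90), Stat(44.04, 3.05, 37.18, 49.77),
                   Stat(-2.88, 1.28, -6.42, -0.83), Stat(0.80, 0.39, 0.22, 1.75),
                   Stat(-0.05, 0.15, -0.49, 0.22)),
    60: GroupStats(60,
                   Stat(46.51, 3.14, 41.95, 54.25), Stat(43.17, 3.40, 37.16, 51.36),
                   Stat(-3.33, 1.48, -6.12, -0.68), Stat(0.86, 0.56, 0.24, 2.56),
                   Stat(0.01, 0.16, -0.50, 0.21)),
    120: GroupStats(120,
                    Stat(47.22, 3.95, 40.81, 58.74), Stat(44.06, 3.63, 38.52, 51.14),
                    Stat(-3.15, 1.38, -7.61, -0.63), Stat(0.82, 0.47, 0.22, 2.35),
                    Stat(-0.03, 0.19, -0.66, 0.26)),
}

GROUP_MONTHS: Sequence[int] = tuple(TABLE1)

#: Default (invented) biometry distributions, mm.  Axial length is coupled
#: to mean keratometry (about -0.37 mm per D around 44 D, the emmetropic
#: trade-off) with residual scatter, so the population is realistically
#: near-emmetropic rather than uniformly ametropic.
BIOMETRY_DEFAULTS = {
    "acd": Stat(3.1, 0.3, 2.2, 4.0),
    "lens_thickness": Stat(4.5, 0.3, 3.5, 5.5),
    "axial_length_resid": Stat(0.0, 0.8, -2.0, 3.0),
}
AL_BASE = 23.3
AL_K_SLOPE = -0.37
AL_BOUNDS = (20.5, 28.0)


@dataclass
class SynthEye:
    """One synthetic eye: corneal model, biometry and realized statistics
    (K1/K2 as sampled; astigmatism, RMS HOA and spherical aberration as
    traced from the generated surfaces)."""

    eye_id: str
    months: int
    cornea: CornealModel
    biometry: EyeBiometry
    k1: float
    k2: float
    astigmatism: float
    rms_hoa: float
    spherical_aberration: float
    axis_deg: float
    wavefront: Optional[WavefrontMap] = None   # cached corneal trace
    rms_hoa_target: float = 0.0                # the sampled design value


from functools import lru_cache


@lru_cache(maxsize=None)
def _matched_params(s: Stat) -> tuple:
    """Truncated-normal parameters whose REALIZED mean and SD equal the
    group's printed mean and SD (the printed values describe the observed,
    i.e. bounded, sample — not a latent unbounded normal)."""
    from scipy.optimize import least_squares
    lo, hi = sorted((s.lo, s.hi))

    def resid(p):
        loc, scale = p
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        # the mean is the primary moment; some groups' printed SD is not
        # attainable under the printed bounds (skewed source samples)
        return [3.0 * (m - s.mean) / s.sd,
                (math.sqrt(max(v, 1e-12)) - s.sd) / s.sd]

    try:
        sol = least_squares(resid, [s.mean, s.sd],
                            bounds=([lo - 5 * s.sd, 1e-3 * s.sd],
                                    [hi + 5 * s.sd, 10 * s.sd]),
                            xtol=1e-12, ftol=1e-12)
        loc, scale = float(sol.x[0]), float(sol.x[1])
        if not (np.isfinite(loc) and scale > 0):
            raise ValueError
    except Exception:
        loc, scale = s.mean, s.sd
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return float(a), float(b), float(loc), float(scale)


def _draw(rng: np.random.Generator, s: Stat) -> float:
    a, b, loc, scale = _matched_params(s)
    return float(truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))


def _draw_stratified(rng: np.random.Generator, s: Stat, n: int) -> np.ndarray:
    """n truncated-normal draws with randomized quantile stratification.

    One draw per equiprobable stratum, in shuffled order: the sample
    marginals track the group statistics far more tightly than iid draws
    at n = 30, which is the point of a population emulator.
    """
    a, b, loc, scale = _matched_params(s)
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    return truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _cone_template(rng: np.random.Generator, max_order: int = 6) -> np.ndarray:
    """Higher-order mode mix of a decentred inferior cone: a Gaussian
    elevation bump fitted to the Zernike basis over the 4-mm pupil."""
    r_c = rng.uniform(0.4, 1.1)
    ang = math.radians(rng.normal(270.0, 20.0))
    cx, cy = r_c * math.cos(ang), r_c * math.sin(ang)
    sigma = rng.uniform(0.5, 0.9)
    ax = np.linspace(-PUPIL_RADIUS, PUPIL_RADIUS, 41)
    xx, yy = np.meshgrid(ax, ax)
    inside = np.hypot(xx, yy) <= PUPIL_RADIUS
    bump = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    exp = fit(bump[inside], xx[inside], yy[inside], max_order, PUPIL_RADIUS)
    vec = exp.to_vector()
    for j, (n, m) in enumerate(nm_modes(max_order)):
        if n < 3 or (n, m) == (4, 0):
            vec[j] = 0.0
    nrm = np.linalg.norm(vec)
    return vec / nrm if nrm > 0 else vec


def _random_hoa(rng: np.random.Generator, max_order: int = 6) -> np.ndarray:
    """Broadband random higher-order mix with a 1/n^2 magnitude decay."""
    modes = nm_modes(max_order)
    vec = np.array([rng.normal(0.0, 1.0 / n ** 2)
                    if (n >= 3 and (n, m) != (4, 0)) else 0.0
                    for n, m in modes])
    nrm = np.linalg.norm(vec)
    return vec / nrm if nrm > 0 else vec


def _sample_eye(rng: np.random.Generator, stats: GroupStats, eye_id: str,
                grid_density: int, km: float, astig: float, rms_t: float,
                sa_t: float, cyl_axis: float,
                biometry: EyeBiometry) -> SynthEye:
    a_mag = abs(astig)
    k1, k2 = km + a_mag / 2.0, km - a_mag / 2.0

    # base conicoid and its traced wavefront
    r_ant = (KERAT_INDEX - 1.0) * 1000.0 / km
    thinning = min(0.10, 0.012 * (stats.months / 12.0))
    thickness = 0.55 - thinning
    def bare(elev=None):
        return CornealModel(
            anterior=ZernikeSagSurface(1.0 / r_ant, CONIC_Q, elev,
                                       aperture_radius=ELEVATION_NORM_RADIUS),
            posterior=ZernikeSagSurface(1.0 / (POSTERIOR_RATIO * r_ant),
                                        CONIC_Q,
                                        aperture_radius=ELEVATION_NORM_RADIUS),
            central_thickness=thickness)
    cornea0 = bare()
    wf_base = trace_corneal_wavefront(cornea0, grid_density=grid_density)

    # target wavefront over the 4-mm pupil: astigmatism + shaped HOAs
    modes = nm_modes(6)
    target = np.zeros(len(modes))
    # low order: c(2,0)=0 at best focus; astigmatism from (C, axis)
    j0 = (a_mag / 2.0) * math.cos(2 * math.radians(cyl_axis))
    j45 = (a_mag / 2.0) * math.sin(2 * math.radians(cyl_axis))
    r2 = PUPIL_RADIUS ** 2
    target[modes.index((2, 2))] = -j0 * r2 / (2 * math.sqrt(6.0))
    target[modes.index((2, -2))] = -j45 * r2 / (2 * math.sqrt(6.0))
    # higher order: cone template (keratoconic groups) + random component
    if stats.months >= 24:
        mix = 0.85 * _cone_template(rng) + 0.15 * _random_hoa(rng)
    else:
        mix = _random_hoa(rng)
    mix /= np.linalg.norm(mix)
    # vertical coma of the cone points inferiorly (negative c(3,-1))
    i_coma = modes.index((3, -1))
    if stats.months >= 24 and mix[i_coma] > 0:
        mix = -mix
    budget = math.sqrt(max(rms_t ** 2 - sa_t ** 2, 0.0))
    target += budget * mix
    target[modes.index((4, 0))] = sa_t
    w_target = ZernikeExpansion.from_vector(target, PUPIL_RADIUS)

    # elevation that realizes (target - base) through the anterior surface;
    # iterate the first-order calibration until the traced wavefront matches
    # the target (strong keratoconic surfaces need 2-3 corrections)
    ax = np.linspace(-ELEVATION_NORM_RADIUS, ELEVATION_NORM_RADIUS, 49)
    xx, yy = np.meshgrid(ax, ax)
    inside = np.hypot(xx, yy) <= ELEVATION_NORM_RADIUS
    xs, ys = xx[inside], yy[inside]

    def rescale_to_cornea(exp2: ZernikeExpansion) -> np.ndarray:
        return exp2(xs / PUPIL_RADIUS, ys / PUPIL_RADIUS, mask_outside=False)

    elev_vals = np.zeros(xs.shape)
    wf = wf_base
    cornea = cornea0
    for _ in range(4):
        delta = w_target - wf.expansion.select(lambda n, m: n >= 2)
        err = math.sqrt(sum(c * c for c in delta.to_vector()))
        if err < 5e-3:
            break
        dcoef = delta.to_vector() / (cornea0.n_cornea - 1.0)
        elev_vals = elev_vals + rescale_to_cornea(
            ZernikeExpansion.from_vector(dcoef, PUPIL_RADIUS))
        elevation = fit(elev_vals, xs, ys, 6, ELEVATION_NORM_RADIUS)
        cornea = bare(elevation)
        wf = trace_corneal_wavefront(cornea, grid_density=grid_density)
    pv = zernike_to_powervector(wf.expansion)
    realized_astig = -2.0 * math.hypot(pv.J0, pv.J45)
    return SynthEye(
        eye_id=eye_id, months=stats.months, cornea=cornea, biometry=biometry,
        k1=k1, k2=k2, astigmatism=realized_astig,
        rms_hoa=rms_hoa(wf.expansion),
        spherical_aberration=wf.expansion.get(4, 0),
        axis_deg=cyl_axis, wavefront=wf, rms_hoa_target=rms_t)


def generate_group(months: int, n: int = 30, seed: int = 0,
                   grid_density: int = 33) -> List[SynthEye]:
    """Generate ``n`` synthetic eyes of one progression group.

    Deterministic for a fixed seed: the RNG stream is derived from
    ``(seed, months)`` so groups are independent of each other and of n.
    """
    if months not in TABLE1:
        raise ValueError(f"unknown group {months}; choose from {list(TABLE1)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    g = TABLE1[months]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(months,)))
    k_mean_stat = Stat((g.k1.mean + g.k2.mean) / 2.0,
                       (g.k1.sd + g.k2.sd) / 2.0,
                       (g.k1.lo + g.k2.lo) / 2.0,
                       (g.k1.hi + g.k2.hi) / 2.0)
    km = _draw_stratified(rng, k_mean_stat, n)
    astig = _draw_stratified(rng, g.astigmatism, n)
    rms_t = _draw_stratified(rng, g.rms_hoa, n)
    sa_t = _draw_stratified(rng, g.spherical_aberration, n)
    # pinned c(4,0) must fit inside the HOA budget: redraw offending SAs
    for i in range(n):
        tries = 0
        while abs(sa_t[i]) > 0.9 * rms_t[i]:
            sa_t[i] = _draw(rng, g.spherical_aberration)
            tries += 1
            if tries > 200:
                raise RuntimeError(
                    f"group {months}: could not reconcile RMS HOA and "
                    "spherical-aberration bounds")
    steep_axis = rng.normal(90.0, 15.0, size=n) % 180.0  # with-the-rule
    cyl_axis = (steep_axis - 90.0) % 180.0
    acd = _draw_stratified(rng, BIOMETRY_DEFAULTS["acd"], n)
    lt = _draw_stratified(rng, BIOMETRY_DEFAULTS["lens_thickness"], n)
    al = np.clip(AL_BASE + AL_K_SLOPE * (km - 44.0)
                 + _draw_stratified(rng, BIOMETRY_DEFAULTS["axial_length_resid"], n),
                 *AL_BOUNDS)

    eyes = []
    for i in range(n):
        eye_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(months, i)))
        eyes.append(_sample_eye(
            eye_rng, g, f"{months:03d}m-{i:03d}", grid_density,
            km=float(km[i]), astig=float(astig[i]), rms_t=float(rms_t[i]),
            sa_t=float(sa_t[i]), cyl_axis=float(cyl_axis[i]),
            biometry=EyeBiometry(float(acd[i]), float(lt[i]), float(al[i]))))
    return eyes


def generate_population(n_per_group: int = 30, seed: int = 0,
                        months: Sequence[int] | None = None,
                        grid_density: int = 33) -> List[SynthEye]:
    """All progression groups; ``n_per_group`` eyes each, one seed."""
    out: List[SynthEye] = []
    for mo in (months or GROUP_MONTHS):
        out.extend(generate_group(mo, n_per_group, seed, grid_density))
    return out


def validate_against_table1(eyes: Sequence[SynthEye],
                            mean_tol_se: float = 2.0,
                            range_slack: float = 0.10) -> pd.DataFrame:
    """Per-group comparison of realized statistics with the reference
    group statistics.

    Means must fall within ``mean_tol_se`` standard errors (SD/sqrt(n) of
    the realized sample size) of the reference mean; every value must lie
    within the reference [min, max] widened by ``range_slack`` of the
    span.  Groups with fewer than 10 eyes are skipped with a warning.
    """
    rows = []
    df = pd.DataFrame([{
        "months": e.months, "k1": e.k1, "k2": e.k2,
        "astigmatism": e.astigmatism, "rms_hoa": e.rms_hoa,
        "spherical_aberration": e.spherical_aberration,
    } for e in eyes])
    for months, sub in df.groupby("months"):
        g = TABLE1[int(months)]
        if len(sub) < 10:
            import warnings
            warnings.warn(f"group {months}: only {len(sub)} eyes; skipped")
            continue
        for name, stat in [("k1", g.k1), ("k2", g.k2),
                           ("astigmatism", g.astigmatism),
                           ("rms_hoa", g.rms_hoa),
                           ("spherical_aberration", g.spherical_aberration)]:
            vals = sub[name].to_numpy()
            se = stat.sd / math.sqrt(len(vals))
            lo, hi = sorted((stat.lo, stat.hi))
            span = hi - lo
            rows.append({
                "months": int(months), "parameter": name,
                "mean": vals.mean(), "sd": vals.std(ddof=1),
                "min": vals.min(), "max": vals.max(),
                "ref_mean": stat.mean, "ref_sd": stat.sd,
                "mean_ok": abs(vals.mean() - stat.mean) <= mean_tol_se * se,
                "range_ok": bool((vals >= lo - range_slack * span).all()
                                 and (vals <= hi + range_slack * span).all()),
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["ok"] = out.mean_ok & out.range_ok
    return out
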