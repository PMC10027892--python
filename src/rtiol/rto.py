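"""Through-focus / through-astigmatism Visual Strehl optimization.

The core of the method: every sphero-cylindrical correction on a dense
grid is combined with the cornea's natural higher-order aberrations and
scored with the VSOTF; the argmax is the optimal correction.  The grid
follows the aberration level of the eye:

* RMS HOA < 0.5 um  — defocus -5..+5 D, cylinder -0.5..-5 D;
* RMS HOA >= 0.5 um — defocus -10..+10 D, cylinder -0.5..-10 D;

both in 0.25 D steps with cylinder axes 0..175 deg in 5 deg steps, plus
the zero-cylinder column.  The reference "zero target" (full cancellation
of defocus and second-order astigmatism, HOAs untouched) is always scored
as an explicit member of the candidate set, so the visual benefit
VSOTF_opt / VSOTF_zero is >= 1 by construction.

The reported ``optimal`` refraction is the *residual target* — the
difference between the eye's full low-order refraction and the optimal
correction, i.e. the refraction a surgeon would aim the pseudophakic eye
at.  For an eye with no HOA interaction it is plano.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .image_quality import VsotfEngine, acceptable_vision
from .raytrace import WavefrontMap
from .zernike import (PowerVector, SpheroCylinder, powervector_to_sphcyl,
                      powervector_to_zernike, rms_hoa,
                      sphcyl_to_powervector, zernike_to_powervector)

__all__ = [
    "SearchGrid",
    "OptimizationResult",
    "search_ranges",
    "apply_correction",
    "optimize_target",
    "through_focus_curve",
    "search_surface",
    "optimize_population",
]

RMS_HOA_THRESHOLD_UM = 0.5

#: Floor applied to both terms of the visual-benefit ratio.  Severe phase
#: reversals can drive the zero-target VSOTF to zero or slightly negative;
#: flooring at 0.001 (far below the 0.12 acceptable-vision threshold, far
#: above numerical noise) keeps the ratio defined and preserves
#: visual_benefit >= 1.
BENEFIT_FLOOR = 1e-3


@dataclass(frozen=True)
class SearchGrid:
    """Candidate correction grid (dioptres / degrees)."""

    defocus_range: float          # +/- bound, D
    cylinder_range: float         # most negative cylinder searched, D (< 0)
    defocus_step: float = 0.25
    cylinder_step: float = 0.25
    axis_step: float = 5.0

    def defocus_values(self) -> np.ndarray:
        n = int(round(self.defocus_range / self.defocus_step))
        return np.arange(-n, n + 1) * self.defocus_step

    def cylinder_values(self) -> np.ndarray:
        """Searched cylinders: zero plus -0.5 .. cylinder_range."""
        n_lo = int(round(0.5 / self.cylinder_step))
        n_hi = int(round(-self.cylinder_range / self.cylinder_step))
        return np.concatenate([[0.0], -np.arange(n_lo, n_hi + 1) * self.cylinder_step])

    def axis_values(self) -> np.ndarray:
        return np.arange(0.0, 180.0, self.axis_step)


def search_ranges(rms_hoa_um: float) -> SearchGrid:
    """Grid bounds as a function of the eye's higher-order RMS (4-mm pupil):
    +/-5 D and cylinders to -5 D below 0.5 um, +/-10 D and -10 D at or
    above it."""
    if rms_hoa_um < 0:
        raise ValueError("rms_hoa must be non-negative")
    if rms_hoa_um < RMS_HOA_THRESHOLD_UM:
        return SearchGrid(defocus_range=5.0, cylinder_range=-5.0)
    return SearchGrid(defocus_range=10.0, cylinder_range=-10.0)


def apply_correction(corneal_wf: WavefrontMap, rx: SpheroCylinder) -> WavefrontMap:
    """Residual wavefront after a sphero-cylindrical correction.

    The correction's second-order Zernike equivalent is subtracted, so a
    correction whose power vector equals the eye's refraction zeroes the
    low-order terms; higher orders are untouched.
    """
    corr = powervector_to_zernike(sphcyl_to_powervector(rx),
                                  corneal_wf.pupil_radius)
    if not math.isclose(corr.pupil_radius, corneal_wf.pupil_radius,
                        abs_tol=1e-9):  # pragma: no cover
        raise ValueError("pupil mismatch")
    return WavefrontMap(corneal_wf.expansion - corr,
                        wavelength=corneal_wf.wavelength,
                        reference=corneal_wf.reference,
                        residual_fit_rms=corneal_wf.residual_fit_rms)


@dataclass
class OptimizationResult:
    """Outcome of the exhaustive VSOTF search for one cornea."""

    optimal: SpheroCylinder            # residual refraction target
    optimal_pv: PowerVector
    correction: SpheroCylinder         # the full optimal correction
    correction_pv: PowerVector
    vsotf_opt: float
    vsotf_zero: float
    visual_benefit: float
    through_focus_curve: List[Tuple[float, float]]
    acceptable_zero: bool
    acceptable_opt: bool
    rms_hoa: float


def _candidate_pairs(grid: SearchGrid) -> list[tuple[float, float, float, float]]:
    """(cyl, axis, J0, J45) for every astigmatism candidate (incl. plano)."""
    pairs = []
    for c in grid.cylinder_values():
        if c == 0.0:
            pairs.append((0.0, 0.0, 0.0, 0.0))
            continue
        for ax in grid.axis_values():
            a = math.radians(ax)
            pairs.append((c, ax, -(c / 2) * math.cos(2 * a),
                          -(c / 2) * math.sin(2 * a)))
    return pairs


def optimize_target(corneal_wf: WavefrontMap,
                    engine: VsotfEngine | None = None) -> OptimizationResult:
    """Exhaustive VSOTF maximization over the correction grid.

    Ties (exactly equal VSOTF) break deterministically toward the smaller
    |M|, then smaller |C|, then smaller axis, so the result is independent
    of evaluation order.
    """
    engine = engine or VsotfEngine()
    hoa = rms_hoa(corneal_wf.expansion)
    grid = search_ranges(hoa)
    pv_eye = zernike_to_powervector(corneal_wf.expansion)

    base_phase = engine.phase_from_wavefront(corneal_wf)
    m_values = grid.defocus_values()
    pairs = _candidate_pairs(grid)
    astig = [(j0, j45) for (_, _, j0, j45) in pairs]
    values = engine.sweep(base_phase, m_values, astig)

    # zero target: exact cancellation of the low-order terms
    vsotf_zero = float(engine.vsotf_batch(base_phase, np.array([pv_eye.M]),
                                          pv_eye.J0, pv_eye.J45)[0])

    # deterministic argmax with tie-breaking
    best = None
    for i, (c, ax, j0, j45) in enumerate(pairs):
        row = values[i]
        j = int(np.argmax(row))
        # scan ties within the row toward smallest |M|
        vmax = row[j]
        for jj in np.flatnonzero(row == vmax):
            key = (-vmax, abs(m_values[jj]), abs(c), ax)
            if best is None or key < best[0]:
                best = (key, i, jj)
    _, i_best, j_best = best
    c, ax, j0, j45 = pairs[i_best]
    corr_pv = PowerVector(float(m_values[j_best]), j0, j45)
    vsotf_opt = float(values[i_best, j_best])

    if vsotf_zero > vsotf_opt:   # zero target is part of the searched set
        corr_pv = pv_eye
        vsotf_opt = vsotf_zero
        i_best = None

    target_pv = pv_eye - corr_pv
    curve = list(zip(m_values.tolist(),
                     values[i_best].tolist() if i_best is not None
                     else engine.sweep(base_phase, m_values,
                                       [(corr_pv.J0, corr_pv.J45)])[0].tolist()))
    return OptimizationResult(
        optimal=powervector_to_sphcyl(target_pv),
        optimal_pv=target_pv,
        correction=powervector_to_sphcyl(corr_pv),
        correction_pv=corr_pv,
        vsotf_opt=vsotf_opt,
        vsotf_zero=vsotf_zero,
        visual_benefit=(max(vsotf_opt, BENEFIT_FLOOR)
                        / max(vsotf_zero, BENEFIT_FLOOR)),
        through_focus_curve=curve,
        acceptable_zero=acceptable_vision(vsotf_zero),
        acceptable_opt=acceptable_vision(vsotf_opt),
        rms_hoa=hoa,
    )


def through_focus_curve(corneal_wf: WavefrontMap, astig: SpheroCylinder,
                        engine: VsotfEngine | None = None
                        ) -> List[Tuple[float, float]]:
    """VSOTF versus defocus for a fixed cylinder correction (the curve of
    the through-focus plots)."""
    engine = engine or VsotfEngine()
    grid = search_ranges(rms_hoa(corneal_wf.expansion))
    pv = sphcyl_to_powervector(SpheroCylinder(0.0, astig.cylinder, astig.axis))
    m = grid.defocus_values()
    vals = engine.vsotf_batch(engine.phase_from_wavefront(corneal_wf), m,
                              pv.J0, pv.J45)
    return list(zip(m.tolist(), vals.tolist()))


def search_surface(corneal_wf: WavefrontMap,
                   engine: VsotfEngine | None = None) -> pd.DataFrame:
    """Full audit table of the exhaustive sweep: one row per candidate
    correction with columns (M, C, axis, J0, J45, vsotf).  The argmax of
    the ``vsotf`` column reproduces :func:`optimize_target`'s optimum."""
    engine = engine or VsotfEngine()
    grid = search_ranges(rms_hoa(corneal_wf.expansion))
    m_values = grid.defocus_values()
    pairs = _candidate_pairs(grid)
    values = engine.sweep(engine.phase_from_wavefront(corneal_wf), m_values,
                          [(j0, j45) for (_, _, j0, j45) in pairs])
    rows = []
    for (c, ax, j0, j45), row in zip(pairs, values):
        for m, v in zip(m_values, row):
            rows.append((m, c, ax, j0, j45, v))
    return pd.DataFrame(rows, columns=["M", "C", "axis", "J0", "J45",
                                       "vsotf"])


def optimize_population(wavefronts: Sequence[WavefrontMap],
                        engine: VsotfEngine | None = None,
                        ids: Sequence | None = None) -> pd.DataFrame:
    """Run the optimizer over a population; one row per eye with the
    summary columns (residual target M/J0/J45, peak and zero-target VSOTF,
    visual benefit, acceptability flags)."""
    engine = engine or VsotfEngine()
    rows = []
    for k, wf in enumerate(wavefronts):
        r = optimize_target(wf, engine)
        rows.append({
            "eye": ids[k] if ids is not None else k,
            "rms_hoa": r.rms_hoa,
            "target_M": r.optimal_pv.M,
            "target_J0": r.optimal_pv.J0,
            "target_J45": r.optimal_pv.J45,
            "correction_M": r.correction_pv.M,
            "correction_J0": r.correction_pv.J0,
            "correction_J45": r.correction_pv.J45,
            "vsotf_opt": r.vsotf_opt,
            "vsotf_zero": r.vsotf_zero,
            "visual_benefit": r.visual_benefit,
            "acceptable_zero": r.acceptable_zero,
            "acceptable_opt": r.acceptable_opt,
        })
    return pd.DataFrame(rows)
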