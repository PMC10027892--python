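"""Zernike polynomial machinery for corneal surfaces and ocular wavefronts.

Conventions used throughout the package
---------------------------------------
* **Indexing** — coefficients are stored under OSA/ANSI double indices
  ``(n, m)``; the single-index OSA (``j >= 0``) and Noll (``j >= 1``)
  orderings appear only at import/export boundaries.
* **Normalization** — orthonormal ("Zernike standard") polynomials: every
  mode has unit RMS over the unit disk, so a coefficient in micrometres is
  directly that mode's RMS contribution.
* **Signs** — wavefront error is positive where the phase is advanced
  relative to the reference sphere.  A myopic eye carries ``c(2,0) > 0``
  and needs a negative (diverging) correction, which fixes the conversion
  ``M = -4*sqrt(3)*c(2,0)/r**2`` (r = pupil radius in mm, c in um, M in D).
* **Axes** — ophthalmic TABO convention: degrees counter-clockwise from the
  positive x-axis viewed from in front of the eye, in ``[0, 180)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "ZernikeExpansion",
    "SpheroCylinder",
    "PowerVector",
    "osa_index",
    "osa_nm",
    "noll_index",
    "noll_nm",
    "osa_noll_convert",
    "nm_modes",
    "n_terms",
    "evaluate",
    "design_matrix",
    "fit",
    "rms",
    "rms_hoa",
    "sphcyl_to_zernike",
    "powervector_to_zernike",
    "zernike_to_powervector",
    "sphcyl_to_powervector",
    "powervector_to_sphcyl",
    "rescale_pupil",
]


# ----------------------------------------------------------------------
# Index conventions
# ----------------------------------------------------------------------

def nm_modes(max_order: int) -> list[Tuple[int, int]]:
    """All (n, m) modes up to radial order ``max_order`` in OSA order."""
    return [(n, m) for n in range(max_order + 1) for m in range(-n, n + 1, 2)]


def n_terms(max_order: int) -> int:
    """Number of modes up to ``max_order`` (28 for the 6th-order set)."""
    return (max_order + 1) * (max_order + 2) // 2


def osa_index(n: int, m: int) -> int:
    _check_nm(n, m)
    return (n * (n + 2) + m) // 2


def osa_nm(j: int) -> Tuple[int, int]:
    if j < 0:
        raise ValueError(f"OSA index must be >= 0, got {j}")
    n = math.ceil((-3 + math.sqrt(9 + 8 * j)) / 2)
    m = 2 * j - n * (n + 2)
    return n, m


@lru_cache(maxsize=None)
def _noll_table(max_order: int) -> Tuple[Tuple[int, int], ...]:
    """Noll ordering: n ascending; within n, |m| ascending; even j <-> m >= 0."""
    table: list[Tuple[int, int]] = []
    j = 1
    for n in range(max_order + 1):
        ms = sorted(range(-n, n + 1, 2), key=abs)
        k = 0
        while k < len(ms):
            m = ms[k]
            if m == 0:
                table.append((n, 0))
                j += 1
                k += 1
            else:
                # pair (+|m|, -|m|): even index gets m >= 0
                pos, neg = abs(m), -abs(m)
                first, second = (pos, neg) if j % 2 == 0 else (neg, pos)
                table.append((n, first))
                table.append((n, second))
                j += 2
                k += 2
    return tuple(table)


def noll_index(n: int, m: int) -> int:
    _check_nm(n, m)
    return _noll_table(n).index((n, m)) + 1


def noll_nm(j: int) -> Tuple[int, int]:
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    # grow table until it covers j
    order = 6
    while n_terms(order) < j:
        order += 2
    return _noll_table(order)[j - 1]


def osa_noll_convert(index: int, from_convention: str) -> int:
    """Convert a single-mode index between the OSA and Noll orderings.

    Applying the conversion twice (with the conventions swapped) is the
    identity.
    """
    conv = from_convention.lower()
    if conv == "osa":
        return noll_index(*osa_nm(index))
    if conv == "noll":
        return osa_index(*noll_nm(index))
    raise ValueError(f"unknown convention {from_convention!r}; use 'OSA' or 'Noll'")


def _check_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid Zernike mode (n={n}, m={m})")


# ----------------------------------------------------------------------
# Polynomial evaluation
# ----------------------------------------------------------------------

@lru_cache(maxsize=None)
def _radial_terms(n: int, am: int) -> Tuple[Tuple[float, int], ...]:
    """(coefficient, power) pairs of the radial polynomial R_n^|m|."""
    terms = []
    for k in range((n - am) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)))
        terms.append((float(c), n - 2 * k))
    return tuple(terms)


def zernike_mode(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike polynomial Z_n^m at polar pupil coordinates."""
    _check_nm(n, m)
    am = abs(m)
    r = np.zeros_like(rho, dtype=float)
    for c, p in _radial_terms(n, am):
        r += c * rho ** p
    norm = math.sqrt(2.0 * (n + 1)) if m != 0 else math.sqrt(n + 1.0)
    if m > 0:
        return norm * r * np.cos(am * theta)
    if m < 0:
        return norm * r * np.sin(am * theta)
    return norm * r


@dataclass
class ZernikeExpansion:
    """A Zernike coefficient set over a circular pupil.

    Parameters
    ----------
    coefficients
        Mapping ``(n, m) -> value`` in micrometres (OSA double indices,
        orthonormal normalization).
    pupil_radius
        Normalization radius in millimetres.
    max_order
        Highest radial order carried (6 gives the 28-term set).
    """

    coefficients: Dict[Tuple[int, int], float] = field(default_factory=dict)
    pupil_radius: float = 2.0
    max_order: int = 6

    def __post_init__(self) -> None:
        if self.pupil_radius <= 0:
            raise ValueError("pupil_radius must be positive")
        for (n, m) in self.coefficients:
            _check_nm(n, m)
            if n > self.max_order:
                raise ValueError(f"mode (n={n}) exceeds max_order={self.max_order}")
        self.coefficients = {k: float(v) for k, v in self.coefficients.items()}

    # -- containers ----------------------------------------------------
    def get(self, n: int, m: int) -> float:
        return self.coefficients.get((n, m), 0.0)

    def set(self, n: int, m: int, value: float) -> None:
        _check_nm(n, m)
        self.coefficients[(n, m)] = float(value)

    def to_vector(self) -> np.ndarray:
        """Dense OSA-ordered coefficient vector of length n_terms(max_order)."""
        v = np.zeros(n_terms(self.max_order))
        for (n, m), c in self.coefficients.items():
            v[osa_index(n, m)] = c
        return v

    @classmethod
    def from_vector(cls, vec: Iterable[float], pupil_radius: float,
                    max_order: int = 6) -> "ZernikeExpansion":
        vec = np.asarray(list(vec), dtype=float)
        coeffs = {osa_nm(j): float(c) for j, c in enumerate(vec) if c != 0.0}
        return cls(coeffs, pupil_radius, max_order)

    def copy(self) -> "ZernikeExpansion":
        return ZernikeExpansion(dict(self.coefficients), self.pupil_radius,
                                self.max_order)

    # -- algebra -------------------------------------------------------
    def __add__(self, other: "ZernikeExpansion") -> "ZernikeExpansion":
        self._check_compatible(other)
        out = dict(self.coefficients)
        for k, v in other.coefficients.items():
            out[k] = out.get(k, 0.0) + v
        return ZernikeExpansion(out, self.pupil_radius,
                                max(self.max_order, other.max_order))

    def __sub__(self, other: "ZernikeExpansion") -> "ZernikeExpansion":
        return self + other.scaled(-1.0)

    def scaled(self, factor: float) -> "ZernikeExpansion":
        return ZernikeExpansion({k: v * factor for k, v in self.coefficients.items()},
                                self.pupil_radius, self.max_order)

    def _check_compatible(self, other: "ZernikeExpansion") -> None:
        if not math.isclose(self.pupil_radius, other.pupil_radius,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("pupil radii differ; rescale before combining")

    # -- derived subsets ----------------------------------------------
    def select(self, predicate) -> "ZernikeExpansion":
        return ZernikeExpansion({k: v for k, v in self.coefficients.items()
                                 if predicate(*k)},
                                self.pupil_radius, self.max_order)

    def low_order(self) -> "ZernikeExpansion":
        """Second-order (defocus + astigmatism) part."""
        return self.select(lambda n, m: n == 2)

    def high_order(self) -> "ZernikeExpansion":
        """Radial order >= 3 part."""
        return self.select(lambda n, m: n >= 3)

    def rotated(self, angle_deg: float) -> "ZernikeExpansion":
        """Expansion of the same surface rotated by ``angle_deg`` CCW."""
        a = math.radians(angle_deg)
        out: Dict[Tuple[int, int], float] = {}
        for (n, m), c in self.coefficients.items():
            if c == 0.0:
                continue
            if m == 0:
                out[(n, 0)] = out.get((n, 0), 0.0) + c
                continue
            am = abs(m)
            ccos = self.get(n, am)
            # handle each |m| pair once (when we meet the cosine partner or
            # a pure-sine mode without partner)
            if m > 0 or (n, am) not in self.coefficients:
                csin = self.get(n, -am)
                cos_a, sin_a = math.cos(am * a), math.sin(am * a)
                out[(n, am)] = ccos * cos_a - csin * sin_a
                out[(n, -am)] = ccos * sin_a + csin * cos_a
        return ZernikeExpansion(out, self.pupil_radius, self.max_order)

    # -- evaluation ----------------------------------------------------
    def __call__(self, x: np.ndarray, y: np.ndarray,
                 mask_outside: bool = True) -> np.ndarray:
        return evaluate(self, x, y, mask_outside=mask_outside)


def evaluate(expansion: ZernikeExpansion, x, y, *,
             mask_outside: bool = True) -> np.ndarray:
    """Evaluate an expansion at normalized pupil coordinates ``(x, y)``.

    Points outside the unit disk evaluate to NaN when ``mask_outside`` is
    true (they are never silently extrapolated); with ``mask_outside=False``
    the polynomials are extended beyond the disk, which is what sag-surface
    evaluation beyond the normalization radius requires.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    out = np.zeros(np.broadcast(x, y).shape, dtype=float)
    for (n, m), c in expansion.coefficients.items():
        if c != 0.0:
            out = out + c * zernike_mode(n, m, rho, theta)
    if mask_outside:
        out = np.where(rho <= 1.0 + 1e-12, out, np.nan)
    return out


def design_matrix(x: np.ndarray, y: np.ndarray, max_order: int) -> np.ndarray:
    """Matrix whose columns are the OSA-ordered modes at (x, y) (normalized)."""
    x = np.ravel(np.asarray(x, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    cols = [zernike_mode(n, m, rho, theta) for n, m in nm_modes(max_order)]
    return np.column_stack(cols)


def fit(values, x, y, max_order: int, pupil_radius: float) -> ZernikeExpansion:
    """Least-squares Zernike fit of sampled heights.

    ``x, y`` are physical coordinates in mm; they are normalized by
    ``pupil_radius``.  Raises if the sampling cannot determine all modes.
    """
    values = np.ravel(np.asarray(values, dtype=float))
    xn = np.ravel(np.asarray(x, dtype=float)) / pupil_radius
    yn = np.ravel(np.asarray(y, dtype=float)) / pupil_radius
    nt = n_terms(max_order)
    if values.size < nt:
        raise ValueError(f"need at least {nt} samples, got {values.size}")
    a = design_matrix(xn, yn, max_order)
    coef, _, rank, _ = np.linalg.lstsq(a, values, rcond=None)
    if rank < nt:
        raise ValueError(
            f"rank-deficient sampling (rank {rank} < {nt} modes); "
            "spread sample points over the pupil")
    return ZernikeExpansion.from_vector(coef, pupil_radius, max_order)


def fit_residual_rms(expansion: ZernikeExpansion, values, x, y) -> float:
    """RMS of the fit residual on the sample points (um)."""
    values = np.ravel(np.asarray(values, dtype=float))
    pred = evaluate(expansion,
                    np.ravel(np.asarray(x)) / expansion.pupil_radius,
                    np.ravel(np.asarray(y)) / expansion.pupil_radius,
                    mask_outside=False)
    return float(np.sqrt(np.mean((values - pred) ** 2)))


def rms(expansion: ZernikeExpansion, *, include_piston: bool = False) -> float:
    tot = 0.0
    for (n, m), c in expansion.coefficients.items():
        if n == 0 and not include_piston:
            continue
        tot += c * c
    return math.sqrt(tot)


def rms_hoa(expansion: ZernikeExpansion) -> float:
    """RMS of the higher-order (n >= 3) coefficients, in um."""
    return math.sqrt(sum(c * c for (n, m), c in expansion.coefficients.items()
                         if n >= 3))


def rescale_pupil(expansion: ZernikeExpansion, new_radius: float,
                  grid: int = 64) -> ZernikeExpansion:
    """Re-express an expansion over a different normalization radius.

    The same polynomial surface is sampled (extrapolating radially where the
    new radius exceeds the old) and refitted at the same max order; since
    the polynomial space is closed under radial scaling this is exact up to
    least-squares round-off.
    """
    ax = np.linspace(-new_radius, new_radius, grid)
    xx, yy = np.meshgrid(ax, ax)
    inside = np.hypot(xx, yy) <= new_radius
    xs, ys = xx[inside], yy[inside]
    vals = evaluate(expansion, xs / expansion.pupil_radius,
                    ys / expansion.pupil_radius, mask_outside=False)
    return fit(vals, xs, ys, expansion.max_order, new_radius)


# ----------------------------------------------------------------------
# Refraction representations
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SpheroCylinder:
    """Refraction in negative-cylinder notation (sphere D, cylinder D <= 0,
    TABO axis in degrees [0, 180))."""

    sphere: float
    cylinder: float = 0.0
    axis: float = 0.0

    def __post_init__(self) -> None:
        if self.cylinder > 1e-12:
            raise ValueError("cylinder must be <= 0 (negative-cylinder notation)")
        object.__setattr__(self, "axis", float(self.axis) % 180.0)


@dataclass(frozen=True)
class PowerVector:
    """Refraction as (M, J0, J45) in dioptres."""

    M: float
    J0: float = 0.0
    J45: float = 0.0

    def norm(self) -> float:
        return math.sqrt(self.M ** 2 + self.J0 ** 2 + self.J45 ** 2)

    def __add__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.M + other.M, self.J0 + other.J0,
                           self.J45 + other.J45)

    def __sub__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.M - other.M, self.J0 - other.J0,
                           self.J45 - other.J45)


def sphcyl_to_powervector(rx: SpheroCylinder) -> PowerVector:
    a = math.radians(rx.axis)
    return PowerVector(
        M=rx.sphere + rx.cylinder / 2.0,
        J0=-(rx.cylinder / 2.0) * math.cos(2 * a),
        J45=-(rx.cylinder / 2.0) * math.sin(2 * a),
    )


def powervector_to_sphcyl(pv: PowerVector) -> SpheroCylinder:
    c = -2.0 * math.hypot(pv.J0, pv.J45)
    if c == 0.0:
        return SpheroCylinder(pv.M, 0.0, 0.0)
    axis = 0.5 * math.degrees(math.atan2(pv.J45, pv.J0)) % 180.0
    return SpheroCylinder(pv.M - c / 2.0, c, axis)


def powervector_to_zernike(pv: PowerVector, pupil_radius: float) -> ZernikeExpansion:
    """Second-order expansion whose refraction equals ``pv``.

    Inverse of :func:`zernike_to_powervector`; the sign convention makes a
    myopic eye's wavefront (M < 0 refraction) carry positive defocus.
    """
    r2 = pupil_radius ** 2
    return ZernikeExpansion({
        (2, 0): -pv.M * r2 / (4.0 * math.sqrt(3.0)),
        (2, 2): -pv.J0 * r2 / (2.0 * math.sqrt(6.0)),
        (2, -2): -pv.J45 * r2 / (2.0 * math.sqrt(6.0)),
    }, pupil_radius, max_order=max(2, 2))


def sphcyl_to_zernike(rx: SpheroCylinder, pupil_radius: float) -> ZernikeExpansion:
    return powervector_to_zernike(sphcyl_to_powervector(rx), pupil_radius)


def zernike_to_powervector(expansion: ZernikeExpansion) -> PowerVector:
    """Refraction (M, J0, J45 in D) of the second-order terms."""
    r2 = expansion.pupil_radius ** 2
    return PowerVector(
        M=-4.0 * math.sqrt(3.0) * expansion.get(2, 0) / r2,
        J0=-2.0 * math.sqrt(6.0) * expansion.get(2, 2) / r2,
        J45=-2.0 * math.sqrt(6.0) * expansion.get(2, -2) / r2,
    )
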