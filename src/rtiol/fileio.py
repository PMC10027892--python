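"""Plain-text file formats: Zernike coefficient files and eye-model files.

Zernike files are JSON with a header declaring the indexing convention
(OSA or Noll single indices are both accepted on read; storage is always
OSA (n, m) triples), the normalization radius and the units.  Eye-model
files are YAML bundles of the two corneal surfaces, the central
thickness, refractive indices and axial biometry, with a schema version.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .eye_model import CornealModel, EyeBiometry, ZernikeSagSurface
from .synth_corneas import SynthEye
from .zernike import ZernikeExpansion, noll_nm, osa_nm

__all__ = ["write_zernike", "read_zernike", "write_eye", "read_eye"]

ZERNIKE_SCHEMA = 1
EYE_SCHEMA = 1


def write_zernike(expansion: ZernikeExpansion, path: str | Path,
                  units: str = "um") -> None:
    doc = {
        "schema_version": ZERNIKE_SCHEMA,
        "convention": "OSA",
        "normalization": "orthonormal (unit RMS per mode)",
        "max_order": expansion.max_order,
        "pupil_radius_mm": expansion.pupil_radius,
        "units": units,
        "terms": [[n, m, v] for (n, m), v in
                  sorted(expansion.coefficients.items())],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_zernike(path: str | Path) -> ZernikeExpansion:
    doc = json.loads(Path(path).read_text())
    conv = doc.get("convention", "OSA").lower()
    coeffs = {}
    for term in doc["terms"]:
        if len(term) == 3:
            n, m, v = term
        else:  # single-index form [j, value]
            j, v = term
            n, m = noll_nm(j) if conv == "noll" else osa_nm(j)
        coeffs[(int(n), int(m))] = float(v)
    return ZernikeExpansion(coeffs, float(doc["pupil_radius_mm"]),
                            int(doc.get("max_order", 6)))


def _surface_doc(s: ZernikeSagSurface) -> dict:
    doc = {
        "base_curvature_per_mm": s.base_curvature,
        "conic_constant": s.conic_constant,
        "aperture_radius_mm": s.aperture_radius,
        "vertex_z_mm": s.vertex_z,
    }
    if s.zernike_elevation is not None:
        doc["zernike_elevation"] = {
            "pupil_radius_mm": s.zernike_elevation.pupil_radius,
            "max_order": s.zernike_elevation.max_order,
            "terms": [[n, m, v] for (n, m), v in
                      sorted(s.zernike_elevation.coefficients.items())],
        }
    return doc


def _surface_from(doc: dict) -> ZernikeSagSurface:
    elev = None
    if "zernike_elevation" in doc:
        z = doc["zernike_elevation"]
        elev = ZernikeExpansion(
            {(int(n), int(m)): float(v) for n, m, v in z["terms"]},
            float(z["pupil_radius_mm"]), int(z.get("max_order", 6)))
    return ZernikeSagSurface(
        base_curvature=float(doc["base_curvature_per_mm"]),
        conic_constant=float(doc.get("conic_constant", 0.0)),
        zernike_elevation=elev,
        aperture_radius=float(doc.get("aperture_radius_mm", 3.25)),
        vertex_z=float(doc.get("vertex_z_mm", 0.0)))


def write_eye(eye: SynthEye, path: str | Path) -> None:
    c = eye.cornea
    doc = {
        "schema_version": EYE_SCHEMA,
        "eye_id": eye.eye_id,
        "months": eye.months,
        "cornea": {
            "anterior": _surface_doc(c.anterior),
            "posterior": _surface_doc(c.posterior),
            "central_thickness_mm": c.central_thickness,
            "n_cornea": c.n_cornea,
            "n_aqueous": c.n_aqueous,
        },
        "biometry": {
            "acd_mm": eye.biometry.acd,
            "lens_thickness_mm": eye.biometry.lens_thickness,
            "axial_length_mm": eye.biometry.axial_length,
        },
        "stats": {
            "k1": eye.k1, "k2": eye.k2, "astigmatism": eye.astigmatism,
            "rms_hoa": eye.rms_hoa,
            "spherical_aberration": eye.spherical_aberration,
            "axis_deg": eye.axis_deg,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_eye(path: str | Path) -> SynthEye:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema_version", 1) > EYE_SCHEMA:
        raise ValueError("eye file schema newer than this reader")
    c = doc["cornea"]
    cornea = CornealModel(
        anterior=_surface_from(c["anterior"]),
        posterior=_surface_from(c["posterior"]),
        central_thickness=float(c["central_thickness_mm"]),
        n_cornea=float(c.get("n_cornea", 1.376)),
        n_aqueous=float(c.get("n_aqueous", 1.334)))
    b = doc["biometry"]
    biometry = EyeBiometry(float(b["acd_mm"]), float(b["lens_thickness_mm"]),
                           float(b["axial_length_mm"]))
    s = doc.get("stats", {})
    return SynthEye(
        eye_id=doc.get("eye_id", Path(path).stem),
        months=int(doc.get("months", 0)),
        cornea=cornea, biometry=biometry,
        k1=float(s.get("k1", 0.0)), k2=float(s.get("k2", 0.0)),
        astigmatism=float(s.get("astigmatism", 0.0)),
        rms_hoa=float(s.get("rms_hoa", 0.0)),
        spherical_aberration=float(s.get("spherical_aberration", 0.0)),
        axis_deg=float(s.get("axis_deg", 0.0)),
        wavefront=None)
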