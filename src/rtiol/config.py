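"""Run configuration: the constants of the optical model and the knobs of
the numerical machinery, with YAML round-tripping.

Defaults reproduce the study conditions: 4-mm pupil, 555 nm, corneal
indices 1.376/1.334, IOL index 1.46, A-constant 118.6.  Every pipeline
run writes its resolved configuration (including the seed) next to its
outputs so the run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    pupil_diameter: float = 4.0        # mm
    wavelength: float = 0.555          # um
    grid_n: int = 128                  # padded VSOTF grid
    grid_padding: int = 2
    pupil_px: int | None = None        # pupil samples across (None: n/padding)
    ray_grid_density: int = 33         # rays across the pupil diameter
    csf: dict = field(default_factory=lambda:
                      {"a": 2.6, "b": 0.0192, "c": 0.114, "d": 1.1})
    a_constant: float = 118.6
    catalogue: dict = field(default_factory=lambda:
                            {"sphere_min": 1.0, "sphere_max": 35.0,
                             "cylinder_min": 1.0, "cylinder_max": 10.0,
                             "step": 0.5})
    seed: int = 0
    schema_version: int = 1

    def engine(self):
        from .image_quality import NeuralCSF, VsotfEngine
        return VsotfEngine(self.grid_n, self.grid_padding,
                           pupil_radius=self.pupil_diameter / 2.0,
                           wavelength=self.wavelength,
                           csf=NeuralCSF(**self.csf),
                           pupil_px=self.pupil_px)

    def catalogue_obj(self):
        from .iol_select import IOLCatalogue
        return IOLCatalogue(**self.catalogue)

    # -- persistence ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write_resolved(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_yaml(outdir / "config.resolved.yaml")
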