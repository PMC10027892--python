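"""Shared fixtures: one VSOTF engine and cached optimized populations.

Population fixtures are session-scoped because generating + optimizing a
group is the expensive step shared by several statistical tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rtiol.image_quality import VsotfEngine
from rtiol.rto import optimize_population
from rtiol.synth_corneas import GROUP_MONTHS, generate_group

SEED = 1

#: engine geometry used for population statistics (48 pupil samples in an
#: 80-pixel padded grid; the autocorrelation identity keeps the weighted
#: OTF band exact at this padding)
POP_ENGINE_ARGS = dict(n=80, padding=2, pupil_px=48)


@pytest.fixture(scope="session")
def engine() -> VsotfEngine:
    return VsotfEngine(**POP_ENGINE_ARGS)


@pytest.fixture(scope="session")
def pop0(engine):
    """30 synthetic 0-month eyes with their optimization results."""
    eyes = generate_group(0, 30, seed=SEED)
    df = optimize_population([e.wavefront for e in eyes], engine,
                             ids=[e.eye_id for e in eyes])
    return eyes, df


@pytest.fixture(scope="session")
def pop12(engine):
    """30 synthetic 12-month eyes with their optimization results."""
    eyes = generate_group(12, 30, seed=SEED)
    df = optimize_population([e.wavefront for e in eyes], engine,
                             ids=[e.eye_id for e in eyes])
    return eyes, df


@pytest.fixture(scope="session")
def pooled10(engine):
    """10 eyes per progression group (70 total), optimized."""
    eyes, frames = [], []
    for mo in GROUP_MONTHS:
        grp = generate_group(mo, 10, seed=SEED)
        df = optimize_population([e.wavefront for e in grp], engine,
                                 ids=[e.eye_id for e in grp])
        df["months"] = mo
        eyes.extend(grp)
        frames.append(df)
    return eyes, pd.concat(frames, ignore_index=True)
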