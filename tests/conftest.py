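"""Shared fixtures: small synthetic trials generated at test time."""

import numpy as np
import pytest

from rowemg.pipeline import analyze_recording
from rowemg.synth import BurstSpec, SessionSpec, gen_session


@pytest.fixture(scope="session")
def default_session():
    """Full 16-channel trial at the default study conditions."""
    spec = SessionSpec(seed=42)
    rec, rest, truth = gen_session(spec)
    return spec, rec, rest, truth


@pytest.fixture(scope="session")
def clean_pair_session():
    """One bilateral muscle pair, jitter-free, for parameter recovery."""
    spec = SessionSpec(
        spm=24,
        n_cycles=30,
        jitter_pct=0.0,
        timing_jitter_pct=0.0,
        bursts={("soleus", s): BurstSpec(5.0, 45.0, peak_uv=60.0) for s in ("left", "right")},
        seed=7,
    )
    rec, rest, truth = gen_session(spec)
    return spec, rec, rest, truth


@pytest.fixture(scope="session")
def clean_pair_analysis(clean_pair_session):
    spec, rec, rest, truth = clean_pair_session
    return spec, truth, analyze_recording(rec, rest)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
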