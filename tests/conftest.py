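"""Shared fixtures: small synthetic speakers and default configurations."""

from __future__ import annotations

import numpy as np
import pytest

from prosodyml import (
    F0Config,
    RhythmConfig,
    generate_speaker,
)
from prosodyml.corpus_io import Utterance


@pytest.fixture(scope="session")
def rhythm_cfg() -> RhythmConfig:
    return RhythmConfig()


@pytest.fixture(scope="session")
def f0_cfg() -> F0Config:
    return F0Config()


@pytest.fixture(scope="session")
def en_speaker():
    """One deterministic synthetic English TD speaker (20 utterances)."""
    return generate_speaker("EN_TD_fixture", "TD", "EN", seed=7, gender="M")


def harmonic_utterance(f0_start: float, f0_end: float | None = None,
                       duration: float = 1.0, sr: int = 16000,
                       n_harm: int = 8, utterance_id: str = "tone") -> Utterance:
    """Constant-amplitude harmonic complex with a (possibly glided) f0."""
    f0_end = f0_start if f0_end is None else f0_end
    n = int(duration * sr)
    t = np.arange(n) / sr
    inst = f0_start * (f0_end / f0_start) ** (t / duration)
    phase = 2 * np.pi * np.cumsum(inst) / sr
    x = sum(np.sin(k * phase) / k for k in range(1, n_harm + 1))
    x = 0.8 * x / np.max(np.abs(x))
    return Utterance(utterance_id=utterance_id, samples=x, sample_rate=sr)
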