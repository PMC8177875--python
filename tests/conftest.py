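"""Shared fixtures: small deterministic recordings and spectra."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from alpharatio.cohortsim import Recording, make_channel_meta
from alpharatio.spectral import SpectralDensity


def make_recording(data: np.ndarray, fs: float = 600.0, **kwargs) -> Recording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(
        data=data, sampling_rate=fs, channel_meta=make_channel_meta(data.shape[0]), **kwargs
    )


def tone(freq: float, duration: float, fs: float = 600.0, amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def flat_psd(value: float = 1.0, n_signals: int = 1, fmax: float = 100.0, df: float = 0.25) -> SpectralDensity:
    freqs = np.arange(0.0, fmax + df / 2, df)
    return SpectralDensity(
        freqs=freqs,
        power=np.full((n_signals, len(freqs)), float(value)),
        n_windows=1,
        signal_meta=pd.DataFrame({"name": [f"s{i}" for i in range(n_signals)]}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
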