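"""Band decomposition: broadband plus the five conventional EEG bands.

All filters are third-order band-pass Butterworth, applied causally
(single pass).  Causality is deliberate: the amplitude features downstream
are defined on past samples only, so a zero-phase forward-backward pass
would leak future signal into them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from capscore.recording import EegRecording

#: band tag -> (low Hz, high Hz); BB is the clinical broadband
BAND_EDGES: dict[str, tuple[float, float]] = {
    "BB": (0.3, 35.0),
    "delta": (0.3, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (13.0, 16.0),
    "beta": (16.0, 35.0),
}

SUB_BANDS = ("delta", "theta", "alpha", "sigma", "beta")


@dataclass
class BandSet:
    """The six band-filtered versions of one recording, same length as input."""

    signals: dict[str, np.ndarray]
    fs: float
    band_edges: dict[str, tuple[float, float]]

    def __getitem__(self, tag: str) -> np.ndarray:
        return self.signals[tag]


def _design(fs: float, low: float, high: float) -> np.ndarray:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got ({low}, {high}) at fs={fs}"
        )
    # second-order-sections cascade: a 0.3 Hz edge at 512 Hz is
    # ill-conditioned in transfer-function form
    return sps.butter(3, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(x, fs: float, low: float, high: float) -> np.ndarray:
    """Causal third-order Butterworth band-pass; output length equals input."""
    x = np.asarray(x, dtype=float)
    return sps.sosfilt(_design(fs, low, high), x)


def decompose(recording: EegRecording) -> BandSet:
    """Filter a recording into BB, delta, theta, alpha, sigma and beta components."""
    out = {
        tag: bandpass(recording.samples, recording.fs, lo, hi)
        for tag, (lo, hi) in BAND_EDGES.items()
    }
    return BandSet(signals=out, fs=recording.fs, band_edges=dict(BAND_EDGES))
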