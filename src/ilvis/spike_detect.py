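"""Conventional threshold-crossing spike detection.

The classical baseline against which the embedding-based analysis is
compared: band-pass the extracellular signal to the spike band, set a
per-channel threshold at ``k_mult`` times the Median Sigma (the median of
the signal's absolute values — a robust amplitude scale), and count
negative-going threshold crossings, collapsing crossings inside a
refractory window into one event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .mea_preprocess import RecordingSet

__all__ = ["SpikeTrain", "detect_spikes", "median_sigma", "spike_counts_frame"]


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike sample indices for one channel."""

    channel: int
    spike_sample_indices: np.ndarray  # sorted, within [0, S)
    threshold: float  # microvolts (negative for negative-going detection)

    def __post_init__(self) -> None:
        idx = np.asarray(self.spike_sample_indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("spike indices must be strictly increasing")
        object.__setattr__(self, "spike_sample_indices", idx)

    @property
    def n_spikes(self) -> int:
        return self.spike_sample_indices.size

    def rate_hz(self, duration_s: float) -> float:
        return self.n_spikes / duration_s


def median_sigma(x: np.ndarray, mad_estimator: bool = False) -> float:
    """Robust amplitude scale: the median of the absolute signal values.

    ``mad_estimator=True`` instead returns the MAD-based Gaussian noise
    SD estimate median(|x|)/0.6745.
    """
    ms = float(np.median(np.abs(x)))
    return ms / 0.6745 if mad_estimator else ms


def detect_spikes(
    rec: RecordingSet,
    band: Tuple[float, float] = (300.0, 1000.0),
    k_mult: float = -4.0,
    refractory_ms: float = 1.0,
    order: int = 3,
    mad_estimator: bool = False,
    positive_going: bool = False,
) -> List[SpikeTrain]:
    """Detect spikes on every channel of a recording.

    The reference channel (if set) is subtracted from all others, a
    Butterworth band-pass (default 300-1000 Hz) isolates the spike band,
    and each channel is thresholded at ``k_mult * median_sigma`` — with
    the default negative multiplier a spike is a negative-going crossing,
    matching the polarity of extracellular action potentials.  Crossings
    within the refractory window collapse to one event.
    """
    lo, hi = band
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < Nyquist")
    sig = rec.signals
    if rec.reference_channel is not None:
        ref = sig[rec.reference_channel]
        sig = sig - ref[None, :]
    sos = sps.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    filt = sps.sosfiltfilt(sos, sig, axis=1)
    dead = max(1, int(round(refractory_ms * 1e-3 * rec.fs)))

    trains = []
    for ch in range(filt.shape[0]):
        x = -filt[ch] if positive_going else filt[ch]
        thr = k_mult * median_sigma(x, mad_estimator=mad_estimator)
        crossings = np.nonzero((x[1:] < thr) & (x[:-1] >= thr))[0] + 1
        kept = []
        last = -dead - 1
        for c in crossings:
            if c - last > dead:
                kept.append(int(c))
                last = c
        trains.append(
            SpikeTrain(
                channel=ch,
                spike_sample_indices=np.asarray(kept, dtype=int),
                threshold=float(thr),
            )
        )
    return trains


def spike_counts_frame(rec: RecordingSet, trains: List[SpikeTrain]) -> pd.DataFrame:
    """Per-channel spike counts and firing rates as a tidy table."""
    return pd.DataFrame(
        {
            "label": rec.label,
            "timepoint": rec.timepoint,
            "channel": [t.channel for t in trains],
            "n_spikes": [t.n_spikes for t in trains],
            "rate_hz": [t.rate_hz(rec.duration_s) for t in trains],
            "threshold_uv": [t.threshold for t in trains],
        }
    )
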