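"""Multi-electrode-array signal preprocessing into FFT feature increments.

Raw extracellular recordings (m electrodes x S samples, typically a 3x3
grid sampled at 25 kHz) are high-pass filtered to remove low-frequency
artifacts, cut into 4-s non-overlapping segments, and each segment is
summarized by a fixed-length amplitude-spectrum feature vector.  The
feature vectors of all segments recorded at one sampling timepoint form
that timepoint's data increment, the unit the incremental embedding is
trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .trajectory_sim import Increment, IncrementSet

__all__ = [
    "RecordingSet",
    "SegmentFeatures",
    "highpass",
    "segment",
    "fft_features",
    "build_increments",
]

DEFAULT_FS = 25_000.0
DEFAULT_WINDOW_S = 4.0
DEFAULT_K = 1000


@dataclass(frozen=True)
class RecordingSet:
    """One multichannel recording: m electrodes x S samples (microvolts)."""

    signals: np.ndarray  # (m, S)
    fs: float  # Hz
    timepoint: int
    label: str = "organoid"
    reference_channel: Optional[int] = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signals must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "signals", sig)

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("signals", data=self.signals.astype(np.float32))
            ds.attrs["fs"] = self.fs
            ds.attrs["timepoint"] = self.timepoint
            ds.attrs["label"] = self.label
            if self.reference_channel is not None:
                ds.attrs["reference_channel"] = self.reference_channel

    @classmethod
    def from_hdf5(cls, path) -> "RecordingSet":
        with h5py.File(path, "r") as fh:
            ds = fh["signals"]
            ref = ds.attrs.get("reference_channel")
            return cls(
                signals=np.asarray(ds, dtype=float),
                fs=float(ds.attrs["fs"]),
                timepoint=int(ds.attrs["timepoint"]),
                label=str(ds.attrs["label"]),
                reference_channel=None if ref is None else int(ref),
            )


@dataclass(frozen=True)
class SegmentFeatures:
    """Fixed-length amplitude-spectrum features of one signal segment."""

    features: np.ndarray  # (k,), non-negative
    timepoint: int
    segment_index: int
    label: str

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError("features must be finite and non-negative")
        object.__setattr__(self, "features", f)


def highpass(
    rec: RecordingSet,
    cutoff_hz: float = 300.0,
    order: int = 3,
    zero_phase: bool = True,
) -> RecordingSet:
    """Butterworth high-pass filter, applied per channel.

    Third order at 300 Hz by default, removing LFP-band and movement
    artifacts while leaving spike-band content intact.  Zero-phase
    (forward-backward) application avoids phase-distorting spike
    waveforms; set ``zero_phase=False`` for a causal single pass.
    """
    if cutoff_hz >= rec.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist ({rec.fs / 2} Hz)")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, rec.signals, axis=1)
    else:
        filtered = sps.sosfilt(sos, rec.signals, axis=1)
    return replace(rec, signals=filtered)


def segment(rec: RecordingSet, window_s: float = DEFAULT_WINDOW_S) -> List[np.ndarray]:
    """Cut a recording into non-overlapping windows of ``window_s`` seconds.

    Returns floor(S / (fs * window_s)) blocks of shape (m, fs * window_s);
    a trailing partial window is discarded.
    """
    w = rec.fs * window_s
    if abs(w - round(w)) > 1e-9:
        raise ValueError("fs * window_s must be an integer number of samples")
    w = int(round(w))
    n = rec.n_samples // w
    if n == 0:
        warnings.warn(
            f"recording of {rec.duration_s:.2f}s shorter than one "
            f"{window_s}s window; no segments"
        )
        return []
    return [rec.signals[:, i * w : (i + 1) * w] for i in range(n)]


def fft_features(
    block: np.ndarray,
    k: int = DEFAULT_K,
    method: str = "mean",
    timepoint: int = 0,
    segment_index: int = 0,
    label: str = "organoid",
) -> SegmentFeatures:
    """Reduce one m-channel segment to a k-vector of spectral amplitudes.

    Per channel the FFT amplitude spectrum is computed and, the signal
    being real-valued (conjugate-symmetric spectrum), only its first half
    (DC included) is kept.  The per-channel half-spectra are concatenated
    — preserving per-electrode information — and reduced to exactly k
    features.  Reduction methods:

    * ``"mean"`` (default): adjacent-bin averaging over contiguous blocks,
      deterministic and data-independent, preserving spectral ordering;
    * ``"truncate"``: the first k concatenated bins;
    * ``"max"``: adjacent-bin max-pooling.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError("block must be (channels, samples)")
    if not np.all(np.isfinite(block)):
        raise ValueError("block contains non-finite samples")
    m, w = block.shape
    half = w // 2
    amp = np.abs(np.fft.rfft(block, axis=1))[:, :half]  # DC bin included
    concat = amp.ravel()
    if k > concat.size:
        raise ValueError(
            f"k={k} exceeds the {concat.size} available spectrum bins"
        )
    if method == "truncate":
        feats = concat[:k]
    elif method in ("mean", "max"):
        chunks = np.array_split(concat, k)
        agg = np.mean if method == "mean" else np.max
        feats = np.array([agg(c) for c in chunks])
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return SegmentFeatures(
        features=feats, timepoint=timepoint, segment_index=segment_index, label=label
    )


def preprocess_recording(
    rec: RecordingSet,
    cutoff_hz: float = 300.0,
    order: int = 3,
    window_s: float = DEFAULT_WINDOW_S,
    k: int = DEFAULT_K,
    method: str = "mean",
) -> List[SegmentFeatures]:
    """High-pass filter, segment and featurize one recording."""
    filtered = highpass(rec, cutoff_hz=cutoff_hz, order=order)
    return [
        fft_features(
            blk, k=k, method=method,
            timepoint=rec.timepoint, segment_index=j, label=rec.label,
        )
        for j, blk in enumerate(segment(filtered, window_s=window_s))
    ]


def build_increments(
    features: Sequence[SegmentFeatures],
) -> Dict[str, IncrementSet]:
    """Group segment features into per-timepoint increments, per label.

    Within each label, the distinct timepoints are sorted and renumbered
    to consecutive increment indices 1..n (a label with a missing
    timepoint simply has fewer increments — the convention used when
    recording sessions are missed for some cell lines).
    """
    by_label: Dict[str, Dict[int, List[SegmentFeatures]]] = {}
    seen = set()
    for sf in features:
        key = (sf.label, sf.timepoint, sf.segment_index)
        if key in seen:
            raise ValueError(f"duplicate (label, timepoint, segment) key {key}")
        seen.add(key)
        by_label.setdefault(sf.label, {}).setdefault(sf.timepoint, []).append(sf)

    out: Dict[str, IncrementSet] = {}
    for label, by_tp in by_label.items():
        incs = []
        for new_idx, tp in enumerate(sorted(by_tp), start=1):
            sfs = sorted(by_tp[tp], key=lambda s: s.segment_index)
            pts = np.stack([s.features for s in sfs])
            incs.append(
                Increment(
                    index=new_idx,
                    t_values=np.full(len(sfs), tp, dtype=int),
                    points=pts,
                )
            )
        out[label] = IncrementSet(increments=tuple(incs), delta=None, label=label)
    return out


def features_to_frame(features: Sequence[SegmentFeatures]) -> pd.DataFrame:
    """Long-format feature matrix: label, timepoint, segment, f_1..f_k."""
    if not features:
        return pd.DataFrame()
    k = features[0].features.size
    rows = np.stack([sf.features for sf in features])
    df = pd.DataFrame(rows, columns=[f"f_{i + 1}" for i in range(k)])
    df.insert(0, "segment", [sf.segment_index for sf in features])
    df.insert(0, "timepoint", [sf.timepoint for sf in features])
    df.insert(0, "label", [sf.label for sf in features])
    return df
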