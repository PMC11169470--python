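"""Surrogate multichannel MEA recordings for end-to-end pipeline testing.

Real cortical-organoid recordings are not redistributable, so this
module synthesizes recordings with a controllable longitudinal drift:
each channel is Gaussian noise plus Poisson-timed biphasic spike
waveforms, and later timepoints follow a prescribed firing-rate schedule
(the hallmark of electrophysiological maturation is a gradual, nonlinear
increase in activity).  The output is a list of
:class:`~ilvis.mea_preprocess.RecordingSet`, one per timepoint, written
and read through the same interfaces as experimental data.

The surrogates are deliberately minimal: no bursting dynamics, no
synchrony across electrodes, no electrode cross-talk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .mea_preprocess import RecordingSet

__all__ = ["SurrogateSpec", "generate", "spike_template"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of a surrogate longitudinal MEA experiment.

    The default sampling rate is 5 kHz rather than the experimental
    25 kHz to keep end-to-end runs light; pass ``fs=25000`` to mirror
    the acquisition system exactly.
    """

    n_channels: int = 9
    fs: float = 5000.0
    duration_s: float = 60.0
    spike_rates_hz: Sequence[float] = (1.0, 2.5, 4.5, 7.0, 10.0)
    spike_amplitude_uv: float = 50.0
    noise_sd_uv: float = 5.0
    drift_hz_per_timepoint: float = 0.0  # spectral centroid shift of noise
    label: str = "organoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.spike_rates_hz) < 2:
            raise ValueError("need at least 2 timepoints")
        if any(r < 0 for r in self.spike_rates_hz):
            raise ValueError("spike rates must be >= 0")
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("invalid channel count, rate or duration")

    @property
    def n_timepoints(self) -> int:
        return len(self.spike_rates_hz)


def spike_template(fs: float, amplitude_uv: float) -> np.ndarray:
    """Biphasic extracellular spike waveform (~1 ms), negative-leading.

    Difference of two Gaussians: a sharp negative trough followed by a
    shallower positive overshoot, the canonical extracellular action
    potential shape, scaled so the trough reaches -amplitude_uv.
    """
    t = np.arange(int(round(2e-3 * fs))) / fs  # 2 ms support
    trough = np.exp(-((t - 0.5e-3) ** 2) / (2 * (0.15e-3) ** 2))
    overshoot = 0.4 * np.exp(-((t - 1.0e-3) ** 2) / (2 * (0.35e-3) ** 2))
    w = -trough + overshoot
    return amplitude_uv * w / np.abs(w).max()


def generate(spec: SurrogateSpec, return_truth: bool = False):
    """Synthesize one recording per timepoint, deterministically seeded.

    With ``return_truth=True`` also returns, per timepoint, a dict
    mapping channel -> sorted sample indices of the injected spike
    troughs (the ground truth for detector-recovery checks).
    """
    rng = np.random.default_rng(spec.seed)
    S = int(round(spec.fs * spec.duration_s))
    template = spike_template(spec.fs, spec.spike_amplitude_uv)
    trough_offset = int(np.argmin(template))
    recs, truths = [], []
    for i, rate in enumerate(spec.spike_rates_hz):
        sig = rng.normal(0.0, spec.noise_sd_uv, size=(spec.n_channels, S))
        if spec.drift_hz_per_timepoint > 0:
            # slow oscillation whose frequency climbs with maturation,
            # shifting the spectral centroid across timepoints
            f = 5.0 + spec.drift_hz_per_timepoint * i
            t = np.arange(S) / spec.fs
            sig += spec.noise_sd_uv * np.sin(2 * np.pi * f * t)[None, :]
        truth = {}
        for ch in range(spec.n_channels):
            n_spikes = rng.poisson(rate * spec.duration_s)
            starts = rng.integers(0, S - template.size, size=n_spikes)
            for s0 in starts:
                sig[ch, s0 : s0 + template.size] += template
            truth[ch] = np.sort(starts + trough_offset)
        truths.append(truth)
        recs.append(
            RecordingSet(
                signals=sig,
                fs=spec.fs,
                timepoint=i + 1,
                label=spec.label,
            )
        )
    return (recs, truths) if return_truth else recs
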