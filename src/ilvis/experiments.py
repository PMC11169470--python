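"""Canonical simulation-study experiments at their default conditions.

These runners wire the trajectory simulator to the incremental pipeline
under the study conditions used throughout validation: 100-dimensional
trajectories, five increments of (100 - delta) points, noise percentage
lambda in {0, 0.2}, sampling gaps delta in {0, 25, 50, 99} and
similarity factors alpha in {0.6, 0.7, 0.8, 0.9}.  Each returns plain
measurements so tests and reproduction scripts evaluate the same code
path.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.metrics import silhouette_score

from . import trajectory_sim as ts
from .metrics import trajectory_distance
from .pipeline import joint_model, orientation_qc
from .song import SongConfig

__all__ = [
    "trend_experiment",
    "trend_score",
    "cluster_experiment",
    "alpha_experiment",
    "ablation_experiment",
]

D_DEFAULT = 100
N_INCREMENTS = 5


def _study_trajectory(seed: int) -> ts.TrajectorySpec:
    line = ts.make_line(D_DEFAULT, seed=seed)
    return ts.make_trajectory(line, seed=seed + 1000, label="T1")


def _noisy_increments(
    traj: ts.TrajectorySpec, delta: int, noise_lambda: float, seed: int
) -> ts.IncrementSet:
    incs = ts.form_increments(traj, n=N_INCREMENTS, delta=delta)
    sd = ts.trajectory_sd(traj, N_INCREMENTS)
    return ts.add_noise(
        incs,
        ts.NoiseConfig(lambda_pct=noise_lambda, seed=seed + 5000, per_dim_sd=sd),
    )


def trend_score(medians: np.ndarray) -> int:
    """How many increments lie farther from the first median than their
    predecessor: the count of i with ||m_{i+1}-m_1|| > ||m_i-m_1||."""
    d = np.linalg.norm(medians - medians[0], axis=1)
    return int(sum(d[i + 1] > d[i] for i in range(len(d) - 1)))


def trend_experiment(
    seed: int,
    delta: int = 0,
    noise_lambda: float = 0.0,
    config: Optional[SongConfig] = None,
) -> int:
    """Model one gradually increasing trajectory and score the traced 2D
    trend (0..n-1; n-1 means strictly increasing distance from m_1)."""
    traj = _study_trajectory(seed)
    incs = _noisy_increments(traj, delta, noise_lambda, seed)
    _, projs = joint_model({"T1": incs}, config=config, seed=seed)
    return trend_score(projs[0].medians)


def cluster_experiment(
    seed: int,
    noise_lambda: float = 0.2,
    config: Optional[SongConfig] = None,
) -> float:
    """The largest-gap condition (delta=99): each increment collapses to
    one pseudo-time point, replicate-expanded to 100 points; returns the
    silhouette of the increment labels in the final 2D visualization."""
    traj = _study_trajectory(seed)
    incs = _noisy_increments(traj, 99, noise_lambda, seed)
    state, _ = joint_model({"T1": incs}, config=config, seed=seed)
    V = state.latest
    return float(
        silhouette_score(V[["x", "y"]].to_numpy(), V["increment"].to_numpy())
    )


def alpha_experiment(
    alpha: float,
    seed: int,
    config: Optional[SongConfig] = None,
) -> Dict[str, float]:
    """Jointly model the shared-origin principal pair and its two
    alpha-compositions (noiseless, delta=0) and measure the four traced
    trajectory distances that define the similarity ordering."""
    T1, T2 = ts.make_diverging_pair(D_DEFAULT, seed=seed)
    T3, T4 = ts.compose_secondary(T1, T2, alpha)
    streams = {
        T.label: ts.form_increments(T, n=N_INCREMENTS, delta=0, label=T.label)
        for T in (T1, T2, T3, T4)
    }
    _, projs = joint_model(streams, config=config, seed=seed)
    P = {p.label: p for p in projs}
    return {
        "d31": trajectory_distance(P["T3"], P["T1"]),
        "d32": trajectory_distance(P["T3"], P["T2"]),
        "d41": trajectory_distance(P["T4"], P["T1"]),
        "d42": trajectory_distance(P["T4"], P["T2"]),
    }


def ablation_experiment(
    seed: int, config: Optional[SongConfig] = None
) -> Tuple[float, float]:
    """Orientation QC with parameter carry-over vs per-session
    re-initialization on identical data; returns (carry, reset) mean
    normalized displacement across consecutive sessions."""
    traj = _study_trajectory(seed)
    incs = ts.form_increments(traj, n=N_INCREMENTS, delta=0)

    def mean_disp(reset: bool) -> float:
        state, _ = joint_model(
            {"T1": incs}, config=config, seed=seed, reset_params=reset
        )
        return float(np.mean([
            orientation_qc(state.history[i], state.history[i + 1])[
                "normalized_displacement"
            ]
            for i in range(len(state.history) - 1)
        ]))

    return mean_disp(False), mean_disp(True)
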