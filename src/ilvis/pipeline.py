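"""Incremental training sessions, median tracing and joint trajectory modeling.

One *session* corresponds to the arrival of one data increment per
modeled trajectory (a sampling timepoint).  At session i the embedding
model is fine-tuned on the union of all increments observed so far,
D_i = I_1 u ... u I_i — full replay of the accumulated data is the
mechanism that prevents catastrophic forgetting — and a partial
visualization V_i of D_i is produced.  Tracing the per-increment 2D
medians chronologically yields the low-dimensional progression
trajectory T^L of each modeled unit.

Multiple units (trajectories, organoids) can be modeled *jointly* in a
single shared embedding so that the directions and proximities of their
traced trajectories are mutually comparable; independently trained
embeddings have no common frame and cannot be compared this way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import procrustes

from .song import SongConfig, SongModel, init_model
from .trajectory_sim import Increment, IncrementSet

__all__ = [
    "SessionState",
    "TrajectoryProjection",
    "run_session",
    "trace_medians",
    "joint_model",
    "orientation_qc",
]


@dataclass
class TrajectoryProjection:
    """The traced 2D trajectory T^L of one modeled unit: chronologically
    ordered increment medians plus the per-increment point clouds."""

    label: str
    medians: np.ndarray  # (n, 2), chronological
    increment_ids: Tuple[int, ...]
    clouds: Dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.increment_ids)


@dataclass
class SessionState:
    """Model plus accumulated data D_i and the visualization history."""

    model: SongModel
    data: Dict[str, List[Tuple[int, np.ndarray]]] = field(default_factory=dict)
    i: int = 0
    history: List[pd.DataFrame] = field(default_factory=list)

    @property
    def latest(self) -> Optional[pd.DataFrame]:
        return self.history[-1] if self.history else None


def _accumulated_matrix(
    data: Dict[str, List[Tuple[int, np.ndarray]]],
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Stack all stored increments in (label, arrival) order and return
    the matrix plus row tags (label, increment, row)."""
    blocks, tags = [], []
    for label in sorted(data):
        for inc_idx, pts in data[label]:
            blocks.append(pts)
            tags.append(
                pd.DataFrame(
                    {
                        "label": label,
                        "increment": inc_idx,
                        "row": np.arange(pts.shape[0]),
                    }
                )
            )
    X = np.concatenate(blocks, axis=0)
    tag_df = pd.concat(tags, ignore_index=True)
    return X, tag_df


def run_session(
    state: SessionState,
    new_increments: Mapping[str, Union[Increment, Tuple[int, np.ndarray]]],
    epochs: Optional[int] = None,
) -> SessionState:
    """Advance one session: ingest one new increment per label, fine-tune
    the model on the full accumulated dataset D_i and produce V_i.

    ``new_increments`` maps each arriving label to its increment (labels
    with a missing timepoint may simply be absent; their increments keep
    their own consecutive numbering).
    """
    if not new_increments:
        raise ValueError("session requires at least one new increment")
    for label, inc in new_increments.items():
        if isinstance(inc, Increment):
            idx, pts = inc.index, inc.points
        else:
            idx, pts = inc
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != state.model.D:
            raise ValueError(
                f"increment for {label!r} has dimension {pts.shape}, "
                f"model expects (*, {state.model.D})"
            )
        seen = state.data.setdefault(label, [])
        if any(idx == k for k, _ in seen):
            raise ValueError(f"duplicate increment index {idx} for {label!r}")
        seen.append((int(idx), pts))

    X, tags = _accumulated_matrix(state.data)
    state.model.partial_fit(X, epochs=epochs)
    coords = state.model.transform(X)
    V = tags.copy()
    V.insert(0, "y", coords[:, 1])
    V.insert(0, "x", coords[:, 0])
    state.i += 1
    state.history.append(V)
    return state


def trace_medians(
    V: pd.DataFrame, method: str = "marginal"
) -> Dict[str, TrajectoryProjection]:
    """Trace the per-(label, increment) medians of a visualization.

    The coordinate-wise (marginal) median is the default because medians
    are robust to outlying segments; ``method="geometric"`` switches to
    the geometric median (Weiszfeld iteration).
    """
    if method not in ("marginal", "geometric"):
        raise ValueError("method must be 'marginal' or 'geometric'")
    out: Dict[str, TrajectoryProjection] = {}
    for label, g in V.groupby("label", sort=True):
        med, ids, clouds = [], [], {}
        for inc, gi in g.groupby("increment", sort=True):
            pts = gi[["x", "y"]].to_numpy(dtype=float)
            if pts.shape[0] == 0:  # pragma: no cover - defensive
                warnings.warn(f"empty increment {inc} for {label!r}; skipped")
                continue
            if method == "marginal":
                med.append(np.median(pts, axis=0))
            else:
                med.append(_geometric_median(pts))
            ids.append(int(inc))
            clouds[int(inc)] = pts
        out[str(label)] = TrajectoryProjection(
            label=str(label),
            medians=np.asarray(med),
            increment_ids=tuple(ids),
            clouds=clouds,
        )
    return out


def _geometric_median(pts: np.ndarray, iters: int = 100, tol: float = 1e-9) -> np.ndarray:
    y = pts.mean(axis=0)
    for _ in range(iters):
        d = np.linalg.norm(pts - y, axis=1)
        if np.any(d < tol):
            return pts[np.argmin(d)]
        w = 1.0 / d
        y_new = (w[:, None] * pts).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def joint_model(
    streams: Mapping[str, IncrementSet],
    config: Optional[SongConfig] = None,
    seed: int = 0,
    epochs: Optional[Union[int, Sequence[int]]] = None,
    reset_params: bool = False,
) -> Tuple[SessionState, List[TrajectoryProjection]]:
    """Model several increment streams together in one shared embedding.

    At session i the i-th available increment of every stream is
    introduced (streams shorter than the longest simply stop arriving).
    ``reset_params=True`` is the forgetting ablation: the model is
    re-initialized from scratch every session instead of fine-tuning the
    carried-over parameters, which destroys session-to-session
    orientation.
    """
    if not streams:
        raise ValueError("no streams to model")
    dims = {incs.increments[0].points.shape[1] for incs in streams.values()}
    if len(dims) != 1:
        raise ValueError(f"streams disagree on feature dimensionality: {dims}")
    D = dims.pop()
    n_sessions = max(incs.n for incs in streams.values())

    state = SessionState(model=init_model(D, config, seed=seed))
    for s in range(n_sessions):
        arriving = {
            label: incs.increments[s]
            for label, incs in streams.items()
            if s < incs.n
        }
        if reset_params and s > 0:
            fresh = init_model(D, config, seed=seed + 7919 * s)
            state = SessionState(
                model=fresh, data=state.data, i=state.i, history=state.history
            )
        ep = epochs[s] if isinstance(epochs, (list, tuple)) else epochs
        run_session(state, arriving, epochs=ep)
    projections = list(trace_medians(state.latest).values())
    return state, projections


def orientation_qc(V_prev: pd.DataFrame, V_curr: pd.DataFrame) -> Dict[str, float]:
    """Quantify how well a new visualization preserves the previous one.

    Matches the points shared by the two visualizations on their
    (label, increment, row) tags and reports the mean 2D displacement
    normalized by the bounding-box diagonal of the current visualization
    (0 = perfectly carried over), together with the Procrustes disparity
    after optimal similarity alignment as a shape-change diagnostic.
    """
    keys = ["label", "increment", "row"]
    merged = V_prev.merge(V_curr, on=keys, suffixes=("_prev", "_curr"))
    if merged.empty:
        raise ValueError("visualizations share no points")
    prev = merged[["x_prev", "y_prev"]].to_numpy(dtype=float)
    curr = merged[["x_curr", "y_curr"]].to_numpy(dtype=float)
    disp = float(np.mean(np.linalg.norm(curr - prev, axis=1)))
    bbox = V_curr[["x", "y"]].to_numpy(dtype=float)
    diag = float(np.linalg.norm(np.ptp(bbox, axis=0)))
    if disp == 0.0:
        disparity = 0.0
    else:
        try:
            _, _, disparity = procrustes(prev, curr)
        except ValueError:  # degenerate (e.g. all points identical)
            disparity = float("nan")
    return {
        "normalized_displacement": disp / diag if diag > 0 else 0.0,
        "procrustes_disparity": float(disparity),
        "n_shared": int(len(merged)),
    }
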