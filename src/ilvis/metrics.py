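"""Trajectory (dis)similarity metrics and manifold-preservation diagnostics.

The distance between two traced 2D trajectories A and B with matched
increment counts n is the mean Euclidean distance between corresponding
increment medians:

    D(A, B) = (1/n) * sum_i sqrt((a_i^x - b_i^x)^2 + (a_i^y - b_i^y)^2)

Distances are reported in raw embedding units; a reference-ranked table
(closest first) summarises how similar each trajectory's progression is
to a chosen reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .pipeline import TrajectoryProjection

__all__ = [
    "trajectory_distance",
    "rank_distances",
    "DistanceTable",
    "preservation_diagnostics",
]


def trajectory_distance(
    A: TrajectoryProjection,
    B: TrajectoryProjection,
    allow_truncation: bool = False,
) -> float:
    """Mean Euclidean distance between corresponding increment medians.

    Defined only for equal increment counts; ``allow_truncation=True``
    opts in to comparing the first min(n_A, n_B) increments instead of
    raising.
    """
    ma, mb = np.asarray(A.medians, float), np.asarray(B.medians, float)
    if len(ma) != len(mb):
        if not allow_truncation:
            raise ValueError(
                f"increment counts differ ({len(ma)} vs {len(mb)}); "
                "pass allow_truncation=True to compare the shared prefix"
            )
        n = min(len(ma), len(mb))
        ma, mb = ma[:n], mb[:n]
    if len(ma) == 0:
        raise ValueError("trajectories have no increments")
    return float(np.mean(np.linalg.norm(ma - mb, axis=1)))


@dataclass(frozen=True)
class DistanceTable:
    """Distances from a reference trajectory, ranked closest-first."""

    reference: str
    table: pd.DataFrame  # columns: label, distance, rank

    def to_markdown(self) -> str:
        lines = ["| label | distance | rank |", "| --- | --- | --- |"]
        lines.append(f"| {self.reference} | 0 | - |")
        for row in self.table.itertuples(index=False):
            lines.append(f"| {row.label} | {row.distance:.4g} | {row.rank} |")
        return "\n".join(lines)


def rank_distances(
    reference: TrajectoryProjection,
    others: Sequence[TrajectoryProjection],
) -> DistanceTable:
    """Rank trajectories by distance to the reference (rank 1 = closest).

    Ties are broken by label order (stable sort on (distance, label)).
    """
    if len(others) == 0:
        raise ValueError("no trajectories to rank")
    rows = [
        {"label": o.label, "distance": trajectory_distance(reference, o)}
        for o in others
    ]
    df = pd.DataFrame(rows).sort_values(
        ["distance", "label"], kind="stable", ignore_index=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return DistanceTable(reference=reference.label, table=df)


def preservation_diagnostics(
    medians_highdim: np.ndarray, medians_2d: np.ndarray
) -> Dict[str, object]:
    """Compare inter-increment median geometry before and after embedding.

    Builds the n x n pairwise Euclidean distance matrices between
    increment medians in the input space and in the 2D embedding and
    reports their Spearman rank correlation over upper-triangle entries
    (undefined, reported as NaN, for n < 3).
    """
    mh = np.asarray(medians_highdim, float)
    ml = np.asarray(medians_2d, float)
    if mh.shape[0] != ml.shape[0]:
        raise ValueError("increment counts differ between spaces")
    n = mh.shape[0]
    dh = np.linalg.norm(mh[:, None, :] - mh[None, :, :], axis=-1)
    dl = np.linalg.norm(ml[:, None, :] - ml[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    if n >= 3:
        rho = float(spearmanr(dh[iu], dl[iu]).statistic)
    else:
        rho = float("nan")
    return {
        "n": n,
        "highdim_distances": dh,
        "lowdim_distances": dl,
        "spearman_rho": rho,
    }
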