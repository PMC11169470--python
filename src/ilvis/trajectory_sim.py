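"""Simulated nonlinear high-dimensional progression trajectories.

A trajectory is built in three steps: a random line in D dimensions
(intercepts ``p``, gradients ``d``, pseudo-time ``t``), a nonlinear
transform that squares the components of a random subset of dimensions,
and — optionally — a convex combination of two such trajectories
controlled by a similarity factor ``alpha``.  Points are sampled along
integer pseudo-time into ordered, disjoint *increments* that play the
role of sampling timepoints in a longitudinal experiment, and Gaussian
noise scaled by a noise percentage ``lambda`` can be injected per
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LineSpec",
    "TrajectorySpec",
    "Increment",
    "IncrementSet",
    "NoiseConfig",
    "make_line",
    "make_trajectory",
    "make_diverging_pair",
    "evaluate",
    "compose_secondary",
    "form_increments",
    "add_noise",
    "trajectory_sd",
]

#: pseudo-time values spanned by one increment window (increment i covers
#: integer t in [WINDOW*(i-1), WINDOW*i - delta)).
WINDOW = 100

#: standard deviation of the replicate-expansion noise used when delta == 99
#: leaves a single point per increment.
EXPANSION_SD = 0.001
EXPANSION_COUNT = 100


@dataclass(frozen=True)
class LineSpec:
    """A line ``L(t) = d*t + p`` in D-dimensional space."""

    intercepts: np.ndarray  # p, shape (D,)
    gradients: np.ndarray  # d, shape (D,)

    def __post_init__(self) -> None:
        p = np.asarray(self.intercepts, dtype=float)
        d = np.asarray(self.gradients, dtype=float)
        if p.ndim != 1 or d.ndim != 1 or p.shape != d.shape:
            raise ValueError("intercepts and gradients must be 1-D and equal length")
        if p.size < 1:
            raise ValueError("dimensionality must be >= 1")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(d))):
            raise ValueError("line coefficients must be finite")
        object.__setattr__(self, "intercepts", p)
        object.__setattr__(self, "gradients", d)

    @property
    def ndim(self) -> int:
        return self.intercepts.size

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.multiply.outer(t, self.gradients) + self.intercepts


@dataclass(frozen=True)
class TrajectorySpec:
    """A nonlinear trajectory: a line with per-dimension exponents in {1, 2},
    or a convex combination of two parent trajectories.

    Exactly one of (``line``, ``exponents``) or (``parents``, ``alpha``)
    is set.  Composition acts on the already-exponentiated parents:
    ``T3(t) = alpha*T1(t) + (1-alpha)*T2(t)`` component-wise.
    """

    line: Optional[LineSpec] = None
    exponents: Optional[np.ndarray] = None
    parents: Optional[Tuple["TrajectorySpec", "TrajectorySpec"]] = None
    alpha: Optional[float] = None
    label: str = "T"

    def __post_init__(self) -> None:
        if self.parents is not None:
            if self.line is not None or self.exponents is not None:
                raise ValueError("composed trajectory cannot also carry a line")
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("alpha must lie in [0, 1]")
            t1, t2 = self.parents
            if t1.ndim != t2.ndim:
                raise ValueError("parent trajectories must share dimensionality")
        else:
            if self.line is None or self.exponents is None:
                raise ValueError("base trajectory needs a line and exponents")
            a = np.asarray(self.exponents, dtype=int)
            if a.shape != (self.line.ndim,):
                raise ValueError("exponents must match line dimensionality")
            if not np.all(np.isin(a, (1, 2))):
                raise ValueError("exponents must be 1 or 2")
            object.__setattr__(self, "exponents", a)

    @property
    def ndim(self) -> int:
        if self.parents is not None:
            return self.parents[0].ndim
        return self.line.ndim

    def __call__(self, t) -> np.ndarray:
        return evaluate(self, t)


def make_line(
    D: int,
    seed: int,
    intercept_range: Tuple[float, float] = (-1.0, 1.0),
    gradient_range: Tuple[float, float] = (0.0, 0.01),
) -> LineSpec:
    """Draw a random line: p ~ U(intercept_range), d ~ U(gradient_range).

    The default coefficient ranges keep component magnitudes of order
    1-100 over t in [0, 500) even after squaring, which is the scale the
    downstream embedding is exercised at.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*intercept_range, size=D)
    d = rng.uniform(*gradient_range, size=D)
    return LineSpec(intercepts=p, gradients=d)


def make_trajectory(
    line: LineSpec,
    seed: int,
    square_fraction: float = 0.5,
    label: str = "T",
) -> TrajectorySpec:
    """Square the components of a seeded random subset of dimensions.

    Each dimension independently receives exponent 2 with probability
    ``square_fraction`` (0 leaves the line unchanged, 1 squares every
    component).
    """
    if not 0.0 <= square_fraction <= 1.0:
        raise ValueError("square_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a = np.where(rng.random(line.ndim) < square_fraction, 2, 1)
    return TrajectorySpec(line=line, exponents=a, label=label)


def make_diverging_pair(
    D: int,
    seed: int,
    intercept_range: Tuple[float, float] = (-1.0, 1.0),
    gradient_range: Tuple[float, float] = (0.0, 0.01),
    square_fraction: float = 0.5,
) -> Tuple[TrajectorySpec, TrajectorySpec]:
    """Two principal trajectories sharing their origin but diverging.

    The trajectories share intercepts and the squared-dimension pattern
    (so they coincide exactly at t = 0) while their gradients are drawn
    independently, making them separate progressively as pseudo-time
    advances.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*intercept_range, size=D)
    d1 = rng.uniform(*gradient_range, size=D)
    d2 = rng.uniform(*gradient_range, size=D)
    a = np.where(rng.random(D) < square_fraction, 2, 1)
    T1 = TrajectorySpec(line=LineSpec(p, d1), exponents=a, label="T1")
    T2 = TrajectorySpec(line=LineSpec(p, d2), exponents=a, label="T2")
    return T1, T2


def evaluate(traj: TrajectorySpec, t) -> np.ndarray:
    """Evaluate a trajectory at pseudo-time t (scalar or array).

    Returns shape (D,) for scalar t, (len(t), D) otherwise.
    """
    if traj.parents is not None:
        t1, t2 = traj.parents
        a = traj.alpha
        return a * evaluate(t1, t) + (1.0 - a) * evaluate(t2, t)
    base = traj.line(t)
    return np.power(base, traj.exponents)


def compose_secondary(
    T1: TrajectorySpec, T2: TrajectorySpec, alpha: float
) -> Tuple[TrajectorySpec, TrajectorySpec]:
    """Build the two secondary trajectories tied to principals T1, T2.

    ``T3 = alpha*T1 + (1-alpha)*T2`` resembles T1 for alpha > 0.5, and
    ``T4 = (1-alpha)*T1 + alpha*T2`` resembles T2 symmetrically.
    """
    if T1.ndim != T2.ndim:
        raise ValueError("T1 and T2 must share dimensionality")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    T3 = TrajectorySpec(parents=(T1, T2), alpha=alpha, label="T3")
    T4 = TrajectorySpec(parents=(T1, T2), alpha=1.0 - alpha, label="T4")
    return T3, T4


@dataclass(frozen=True)
class Increment:
    """Points sampled along a trajectory for one sampling timepoint."""

    index: int  # 1-based
    t_values: np.ndarray  # integer pseudo-times, shape (M,)
    points: np.ndarray  # shape (M, D)

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_values", np.asarray(self.t_values))
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        if self.points.shape[0] != self.t_values.shape[0]:
            raise ValueError("t_values and points disagree on point count")


@dataclass(frozen=True)
class IncrementSet:
    """Ordered data increments I_1..I_n of one trajectory."""

    increments: Tuple[Increment, ...]
    delta: Optional[int]  # sampling gap; None for experimental increments
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "increments", tuple(self.increments))

    @property
    def n(self) -> int:
        return len(self.increments)

    def stacked(self) -> np.ndarray:
        """All points, increments concatenated in order, shape (sum M_i, D)."""
        return np.concatenate([inc.points for inc in self.increments], axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long format: trajectory_label, increment, t, x_1..x_D."""
        frames = []
        for inc in self.increments:
            D = inc.points.shape[1]
            df = pd.DataFrame(inc.points, columns=[f"x_{k + 1}" for k in range(D)])
            df.insert(0, "t", inc.t_values)
            df.insert(0, "increment", inc.index)
            df.insert(0, "trajectory_label", self.label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, delta: Optional[int] = None) -> "IncrementSet":
        labels = df["trajectory_label"].unique()
        if len(labels) != 1:
            raise ValueError("frame holds more than one trajectory label")
        xcols = [c for c in df.columns if c.startswith("x_")]
        incs = []
        for idx, g in df.groupby("increment", sort=True):
            incs.append(
                Increment(
                    index=int(idx),
                    t_values=g["t"].to_numpy(),
                    points=g[xcols].to_numpy(dtype=float),
                )
            )
        return cls(increments=tuple(incs), delta=delta, label=str(labels[0]))

    @classmethod
    def from_csv(cls, path, delta: Optional[int] = None) -> "IncrementSet":
        return cls.from_frame(pd.read_csv(path), delta=delta)


def form_increments(
    traj: TrajectorySpec, n: int, delta: int, label: Optional[str] = None
) -> IncrementSet:
    """Sample n increments: increment i holds one point per integer t in
    [100*(i-1), 100*i - delta), i.e. 100 - delta points.

    delta is the sampling gap — the number of trailing pseudo-time values
    omitted from each increment window, emulating gaps between sampling
    timepoints.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= delta <= 99:
        raise ValueError("delta must lie in [0, 99]")
    incs = []
    for i in range(1, n + 1):
        t = np.arange(WINDOW * (i - 1), WINDOW * i - delta)
        incs.append(Increment(index=i, t_values=t, points=evaluate(traj, t)))
    return IncrementSet(
        increments=tuple(incs), delta=delta, label=label or traj.label
    )


@dataclass(frozen=True)
class NoiseConfig:
    """Per-dimension Gaussian noise scaled by the noise percentage lambda.

    ``per_dim_sd`` defaults (None) to the sample SD of the noiseless
    trajectory values in each dimension over the full pseudo-time range,
    so ``lambda_pct = 0.2`` reads as "20% noise" regardless of the scale
    of a dimension.
    """

    lambda_pct: float
    seed: int
    per_dim_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.lambda_pct < 0:
            raise ValueError("lambda_pct must be >= 0")
        if self.per_dim_sd is not None:
            sd = np.asarray(self.per_dim_sd, dtype=float)
            if np.any(sd < 0):
                raise ValueError("per_dim_sd entries must be >= 0")
            object.__setattr__(self, "per_dim_sd", sd)


def add_noise(incs: IncrementSet, cfg: NoiseConfig) -> IncrementSet:
    """Inject lambda-scaled Gaussian noise; expand delta=99 singletons.

    When the sampling gap leaves one point per increment (delta == 99),
    each point is first replicated into 100 points perturbed by
    N(0, 0.001^2) — replication, not interpolation, so no artificial
    continuity is created between timepoints.  lambda_pct == 0 returns
    the input unchanged apart from that expansion.
    """
    if incs.n == 0:
        raise ValueError("increment set is empty")
    rng = np.random.default_rng(cfg.seed)

    increments = incs.increments
    if incs.delta == 99:
        expanded = []
        for inc in increments:
            pts = np.repeat(inc.points, EXPANSION_COUNT, axis=0)
            pts = pts + rng.normal(0.0, EXPANSION_SD, size=pts.shape)
            tv = np.repeat(inc.t_values, EXPANSION_COUNT)
            expanded.append(Increment(index=inc.index, t_values=tv, points=pts))
        increments = tuple(expanded)

    if cfg.lambda_pct == 0:
        if incs.delta == 99:
            return IncrementSet(increments=increments, delta=incs.delta, label=incs.label)
        return incs

    sd = cfg.per_dim_sd
    if sd is None:
        sd = _trajectory_sd(incs)
    noisy = []
    for inc in increments:
        phi = rng.normal(0.0, 1.0, size=inc.points.shape) * sd
        noisy.append(
            Increment(
                index=inc.index,
                t_values=inc.t_values,
                points=inc.points + cfg.lambda_pct * phi,
            )
        )
    return IncrementSet(increments=tuple(noisy), delta=incs.delta, label=incs.label)


def _trajectory_sd(incs: IncrementSet) -> np.ndarray:
    """Sample SD per dimension of the (noiseless) points across all increments."""
    return np.std(incs.stacked(), axis=0, ddof=1)


def trajectory_sd(traj: TrajectorySpec, n: int) -> np.ndarray:
    """Per-dimension sample SD of the noiseless trajectory over the full
    pseudo-time range [0, 100*n), including any sampling-gap region.

    This is the reference scale for the noise percentage lambda: passing
    it as ``NoiseConfig.per_dim_sd`` makes "20% noise" mean 20% of each
    dimension's spread along the whole trajectory, independent of delta.
    """
    vals = evaluate(traj, np.arange(0, WINDOW * n))
    return np.std(vals, axis=0, ddof=1)
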