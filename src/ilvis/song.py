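"""SONG-style incremental parametric dimensionality reduction.

The model maintains three coupled parameter sets, theta = {C, E, Y}:

* ``C`` — high-dimensional *coding vectors*, prototypes obtained by
  vector quantization of the input distribution; new coding vectors are
  spawned where quantization error is high, so the codebook grows into
  newly observed regions of the input space.
* ``E`` — a symmetric non-negative edge-weight matrix over the coding
  vectors.  Edges are reinforced (Hebbian-style, with decay) whenever a
  dense region of inputs lies between two coding vectors' neighborhoods,
  so ``G = (C, E)`` self-organizes into a topology graph of the data.
* ``Y`` — one 2D layout vector per coding vector (bijective with ``C``),
  optimized by stochastic gradient descent on a cross-entropy objective
  between the graph neighborhood distribution and the 2D similarities
  (attraction along high-weight edges, repulsion via negative sampling).

Because all three are retained, a later call to :meth:`SongModel.partial_fit`
fine-tunes the existing parameters instead of re-learning from scratch:
previously embedded structure keeps its position and orientation while
the codebook and layout expand to accommodate new data.  That carry-over
is what makes session-to-session visualizations of a growing longitudinal
dataset comparable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional

import numpy as np

__all__ = ["SongConfig", "SongModel", "init_model"]


@dataclass
class SongConfig:
    """Hyperparameters of the embedding.

    All defaults are desk-scale choices for inputs of a few hundred to a
    few thousand points in up to a few hundred dimensions.
    """

    n_init: int = 4  # initial codebook size
    points_per_code: int = 4  # codebook capacity ~ N / points_per_code
    max_codes: int = 600  # hard cap on codebook size
    growth_coeff: float = 1.5  # spawn where error > coeff * mean error
    grow_cap: int = 8  # new coding vectors per epoch at most
    epochs: int = 150  # epochs for the first training session
    epochs_incremental: int = 60  # epochs for fine-tuning sessions
    vq_lr: float = 0.4  # winner pull toward its cell mean
    graph_smooth: float = 0.02  # pull of codes toward graph neighbors
    edge_decay: float = 0.97  # per-epoch multiplicative edge decay
    prune_frac: float = 1e-3  # drop edges below this fraction of max
    layout_lr: float = 0.25  # initial 2D SGD learning rate
    layout_steps: int = 1  # layout SGD passes per epoch
    negative_samples: int = 10  # repulsion samples per code per epoch
    repulsion: float = 2.0  # weight of the repulsive force
    consolidation: float = 0.05  # layout learning-rate multiplier for
    # coding vectors created in earlier sessions; < 1 keeps the already
    # inferred layout stable while new codes remain fully plastic
    knn_edges: int = 10  # codebook nearest neighbors added to the layout
    # neighborhood with an adaptive exponential kernel; gives spatially
    # close but Hebbian-disconnected regions a distance-sensitive pull
    knn_weight: float = 0.3  # their weight relative to the strongest edge
    global_weight: float = 1.0  # strength of the global distance-matching
    # (stress) force that calibrates relative distances between regions
    # the neighborhood graph leaves unconstrained; 0 disables it
    pca_init_frac: float = 0.5  # first-session epoch fraction at which Y
    # is seeded from the first two principal components of the codebook
    transform_k: int = 3  # neighbors blended in transform()


def init_model(D: int, config: Optional[SongConfig] = None, seed: int = 0) -> "SongModel":
    """Create an empty model for D-dimensional inputs."""
    if D < 1:
        raise ValueError("D must be >= 1")
    return SongModel(D=D, config=config or SongConfig(), seed=seed)


class SongModel:
    """Growing vector-quantization codebook with a self-organized topology
    graph and a cross-entropy-optimized 2D layout.

    Attributes
    ----------
    C : (K, D) ndarray
        Coding vectors.
    E : (K, K) ndarray
        Symmetric edge weights, zero diagonal.
    Y : (K, 2) ndarray
        2D layout vectors, bijective with C.
    objective_history_ : list of float
        Mean per-pair cross-entropy of the layout, one entry per epoch,
        accumulated across sessions.
    """

    def __init__(self, D: int, config: SongConfig, seed: int):
        self.D = int(D)
        self.config = config
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        self.C = np.empty((0, D), dtype=float)
        self.Y = np.empty((0, 2), dtype=float)
        self.E = np.empty((0, 0), dtype=float)
        self.birth_session = np.empty((0,), dtype=int)
        self.fitted = False
        self.n_sessions = 0
        self.objective_history_: List[float] = []

    # ------------------------------------------------------------------ #
    # training
    # ------------------------------------------------------------------ #

    def partial_fit(self, X: np.ndarray, epochs: Optional[int] = None) -> "SongModel":
        """Fit / fine-tune theta = {C, E, Y} on a data matrix.

        The first call initializes a small codebook inside the data range;
        subsequent calls fine-tune the retained parameters (codebook
        positions, edge weights and layout), growing new coding vectors
        only where the new data is poorly quantized.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.D:
            raise ValueError(f"X must be (N, {self.D})")
        if X.shape[0] == 0:
            return self
        cfg = self.config
        if epochs is None:
            epochs = cfg.epochs if not self.fitted else cfg.epochs_incremental

        if not self.fitted:
            self._init_codebook(X)

        N = X.shape[0]
        cap = min(cfg.max_codes, max(cfg.n_init, N // cfg.points_per_code))
        first_session = not self.fitted
        pca_epoch = int(cfg.pca_init_frac * epochs) if first_session else -1

        for epoch in range(epochs):
            if epoch == pca_epoch:
                # Seed the layout from the codebook's leading principal
                # plane once the codebook has grown into the data.  This
                # happens only within the very first session, before any
                # cross-session structure exists to preserve; all later
                # sessions fine-tune the carried-over layout.
                self._pca_init_layout()
            progress = epoch / max(epochs - 1, 1)
            decay = 1.0 - 0.9 * progress  # linear 1 -> 0.1

            d2 = self._sq_dists(X, self.C)
            order = np.argsort(d2, axis=1, kind="stable")
            win = order[:, 0]
            run = order[:, 1] if self.C.shape[0] > 1 else win
            dn = np.sqrt(np.maximum(d2[np.arange(N), win], 0.0))

            # --- growth: spawn coding vectors at poorly quantized inputs
            if self.C.shape[0] < cap:
                self._grow(X, dn, win, cap)
                # refresh assignment only for unchanged codes is cheap enough
                d2 = self._sq_dists(X, self.C)
                order = np.argsort(d2, axis=1, kind="stable")
                win = order[:, 0]
                run = order[:, 1] if self.C.shape[0] > 1 else win

            # --- vector quantization: pull winners toward their cell means
            K = self.C.shape[0]
            counts = np.bincount(win, minlength=K).astype(float)
            sums = np.zeros((K, self.D))
            np.add.at(sums, win, X)
            occupied = counts > 0
            means = np.where(
                occupied[:, None], sums / np.maximum(counts, 1.0)[:, None], self.C
            )
            self.C += cfg.vq_lr * decay * (means - self.C)

            # --- self-organization: Hebbian edge reinforcement with decay
            self.E *= cfg.edge_decay
            pairs = np.stack([win, run], axis=1)
            hits = np.zeros((K, K))
            np.add.at(hits, (pairs[:, 0], pairs[:, 1]), 1.0)
            hits = (hits + hits.T) / N
            np.fill_diagonal(hits, 0.0)
            self.E += hits

            # graph smoothing keeps connected codes coherent
            if cfg.graph_smooth > 0 and K > 1:
                deg = self.E.sum(axis=1)
                nz = deg > 0
                nbr_mean = np.zeros_like(self.C)
                nbr_mean[nz] = (self.E @ self.C)[nz] / deg[nz, None]
                self.C[nz] += cfg.graph_smooth * decay * (nbr_mean[nz] - self.C[nz])

            # --- dimensionality reduction: cross-entropy layout step
            W = self._layout_weights()
            for _ in range(cfg.layout_steps):
                self._layout_step(cfg.layout_lr * decay, W)
            self.objective_history_.append(self._cross_entropy(W))

        self._prune_edges()
        self.fitted = True
        self.n_sessions += 1
        return self

    def _init_codebook(self, X: np.ndarray) -> None:
        cfg = self.config
        n0 = min(cfg.n_init, X.shape[0])
        idx = self._rng.choice(X.shape[0], size=n0, replace=False)
        jitter = 1e-6 * (np.ptp(X, axis=0) + 1.0)
        self.C = X[idx] + self._rng.normal(0.0, 1.0, size=(n0, self.D)) * jitter
        self.Y = self._rng.normal(0.0, 0.1, size=(n0, 2))
        self.E = np.zeros((n0, n0))
        self.birth_session = np.zeros(n0, dtype=int)

    def _grow(self, X: np.ndarray, dn: np.ndarray, win: np.ndarray, cap: int) -> None:
        """Spawn new coding vectors at inputs whose quantization error
        exceeds growth_coeff times the mean error."""
        cfg = self.config
        thresh = cfg.growth_coeff * dn.mean()
        cand = np.nonzero(dn > thresh)[0]
        if cand.size == 0:
            return
        cand = cand[np.argsort(dn[cand], kind="stable")[::-1]]
        budget = min(cfg.grow_cap, cap - self.C.shape[0])
        chosen: List[int] = []
        for i in cand:
            if len(chosen) >= budget:
                break
            # keep spawned points mutually separated
            if all(
                np.linalg.norm(X[i] - X[j]) > 0.5 * thresh for j in chosen
            ):
                chosen.append(int(i))
        if not chosen:
            return
        yscale = max(0.01, 0.01 * self._bbox_diag(self.Y))
        for i in chosen:
            parent = int(win[i])
            self.C = np.vstack([self.C, X[i][None, :]])
            y_new = self.Y[parent] + self._rng.normal(0.0, yscale, size=2)
            self.Y = np.vstack([self.Y, y_new[None, :]])
            K = self.C.shape[0]
            E_new = np.zeros((K, K))
            E_new[:-1, :-1] = self.E
            w0 = self.E.max() if self.E.size and self.E.max() > 0 else 1.0
            E_new[-1, parent] = E_new[parent, -1] = 0.5 * w0
            self.E = E_new
            self.birth_session = np.append(self.birth_session, self.n_sessions)

    def _pca_init_layout(self) -> None:
        K = self.C.shape[0]
        if K < 3:
            return
        Cc = self.C - self.C.mean(axis=0)
        _, _, vt = np.linalg.svd(Cc, full_matrices=False)
        scores = Cc @ vt[:2].T
        scale = np.abs(scores).max()
        if scale > 0:
            self.Y = 5.0 * scores / scale
        else:  # pragma: no cover - degenerate codebook
            self.Y = self._rng.normal(0.0, 0.1, size=(K, 2))

    def _layout_weights(self) -> np.ndarray:
        """Effective neighborhood weights driving the layout: the Hebbian
        edge weights blended with an adaptive-kernel codebook kNN term.

        The kNN term assigns each coding vector's few nearest codebook
        neighbors a weight exp(-(d - rho)/rho) (rho = distance to the
        single nearest code), symmetrized by maximum.  It supplies a
        distance-sensitive attraction between regions the Hebbian graph
        leaves disconnected, so their relative placement in 2D reflects
        their input-space proximity.
        """
        cfg = self.config
        K = self.C.shape[0]
        W = self.E.copy()
        if cfg.knn_edges <= 0 or K < 3:
            return W
        d = np.sqrt(self._sq_dists(self.C, self.C))
        order = np.argsort(d, axis=1, kind="stable")
        k = min(cfg.knn_edges, K - 1)
        idx = np.arange(K)
        nbr = order[:, 1 : k + 1]
        dn = d[idx[:, None], nbr]
        rho = dn[:, 0]  # distance to the single nearest code
        # per-code bandwidth: mean excess distance over the k neighbors
        sigma = np.maximum(np.mean(dn - rho[:, None], axis=1), 1e-12)
        s = np.exp(-np.maximum(dn - rho[:, None], 0.0) / sigma[:, None])
        S = np.zeros((K, K))
        np.maximum.at(S, (idx[:, None].repeat(k, 1), nbr), s)
        S = np.maximum(S, S.T)
        wmax = self.E.max() if self.E.max() > 0 else 1.0
        return W + cfg.knn_weight * wmax * S

    def _layout_step(self, lr: float, W: Optional[np.ndarray] = None) -> None:
        """One SGD pass of the cross-entropy layout: attraction along
        edges proportional to normalized weight, repulsion against
        negative samples."""
        cfg = self.config
        K = self.Y.shape[0]
        if K < 2:
            return
        if W is None:
            W = self.E
        wmax = W.max()
        if wmax <= 0:
            return
        # codes consolidated in earlier sessions move on a damped schedule
        plastic = np.where(
            self.birth_session < self.n_sessions, cfg.consolidation, 1.0
        )[:, None]
        ii, jj = np.nonzero(np.triu(W, k=1))
        if ii.size:
            w = W[ii, jj] / wmax
            diff = self.Y[ii] - self.Y[jj]
            d2 = np.sum(diff**2, axis=1)
            # gradient of  w * log(1 + d^2)
            g = np.clip((2.0 * w / (1.0 + d2))[:, None] * diff, -4.0, 4.0)
            upd = np.zeros_like(self.Y)
            np.add.at(upd, ii, -g)
            np.add.at(upd, jj, g)
            self.Y += lr * plastic * upd
        # negative sampling: each code repels a few random codes
        neg = self._rng.integers(0, K, size=(K, cfg.negative_samples))
        diff = self.Y[:, None, :] - self.Y[neg]
        d2 = np.sum(diff**2, axis=2)
        mask = neg != np.arange(K)[:, None]
        # gradient of  -log(1 - q), q = 1/(1+d^2)
        g = (2.0 * cfg.repulsion / ((d2 + 1e-3) * (1.0 + d2)))[:, :, None] * diff
        g = np.clip(g, -4.0, 4.0) * mask[:, :, None]
        self.Y += lr * plastic * g.sum(axis=1)
        if cfg.global_weight > 0:
            self._global_step(cfg.global_weight * lr, plastic)

    def _global_step(self, lr: float, plastic: np.ndarray) -> None:
        """Weak stress-matching force: scale-normalized 2D inter-code
        distances are nudged toward the scale-normalized input-space
        distances.  The neighborhood cross entropy preserves topology but
        leaves the relative placement of mutually distant regions almost
        free; this term calibrates those global distance ratios without
        overriding the local structure (it is an order of magnitude
        weaker than the cross-entropy forces)."""
        K = self.Y.shape[0]
        if K < 3:
            return
        dH = np.sqrt(self._sq_dists(self.C, self.C))
        dY = np.sqrt(self._sq_dists(self.Y, self.Y))
        sH = dH.mean()
        sY = dY.mean()
        if sH <= 0 or sY <= 0:
            return
        rH = dH / sH
        rY = dY / sY
        # positive residual = too close in 2D -> push apart (and vice versa)
        resid = rH - rY
        np.fill_diagonal(dY, 1.0)
        coef = resid / dY  # per-pair force magnitude along the unit vector
        diffx = self.Y[:, 0][:, None] - self.Y[:, 0][None, :]
        diffy = self.Y[:, 1][:, None] - self.Y[:, 1][None, :]
        fx = (coef * diffx).mean(axis=1)
        fy = (coef * diffy).mean(axis=1)
        F = np.clip(np.stack([fx, fy], axis=1) * sY, -4.0, 4.0)
        self.Y += lr * plastic * F

    def _cross_entropy(self, W: Optional[np.ndarray] = None) -> float:
        """Mean per-pair cross entropy between the normalized neighborhood
        weights and the 2D similarities q = 1/(1 + d^2)."""
        if W is None:
            W = self.E
        K = self.Y.shape[0]
        if K < 2 or W.max() <= 0:
            return 0.0
        P = np.minimum(W / W.max(), 1.0)
        d2 = self._sq_dists(self.Y, self.Y)
        Q = 1.0 / (1.0 + d2)
        eps = 1e-12
        ce = -(P * np.log(Q + eps) + (1.0 - P) * np.log(1.0 - Q + eps))
        iu = np.triu_indices(K, k=1)
        return float(np.mean(ce[iu]))

    def _prune_edges(self) -> None:
        wmax = self.E.max() if self.E.size else 0.0
        if wmax > 0:
            self.E[self.E < self.config.prune_frac * wmax] = 0.0

    # ------------------------------------------------------------------ #
    # inference
    # ------------------------------------------------------------------ #

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map inputs to 2D through the codebook.

        Each input is assigned to its nearest coding vector and placed at
        an inverse-distance-weighted blend of the layout positions of that
        code and its closest graph neighbors; an input coinciding with a
        coding vector maps exactly to that code's layout vector.
        """
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.D:
            raise ValueError(f"X must be (N, {self.D})")
        d2 = self._sq_dists(X, self.C)
        d = np.sqrt(np.maximum(d2, 0.0))
        win = np.argmin(d2, axis=1)
        out = np.empty((X.shape[0], 2))
        k = self.config.transform_k
        for r in range(X.shape[0]):
            j0 = win[r]
            if d[r, j0] == 0.0:
                out[r] = self.Y[j0]
                continue
            nbrs = np.nonzero(self.E[j0])[0]
            pool = np.concatenate([[j0], nbrs])
            if pool.size > k:
                keep = np.argsort(d[r, pool], kind="stable")[:k]
                pool = pool[keep]
            w = 1.0 / (d[r, pool] + 1e-12)
            w /= w.sum()
            out[r] = w @ self.Y[pool]
        return out

    def quantization_error(self, X: np.ndarray) -> float:
        """Mean distance from inputs to their nearest coding vector."""
        d2 = self._sq_dists(np.asarray(X, dtype=float), self.C)
        return float(np.mean(np.sqrt(np.maximum(d2.min(axis=1), 0.0))))

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #

    def to_dict(self) -> dict:
        ii, jj = np.nonzero(np.triu(self.E, k=1))
        return {
            "D": self.D,
            "seed": self.seed,
            "config": asdict(self.config),
            "C": self.C.tolist(),
            "Y": self.Y.tolist(),
            "edges": [
                [int(a), int(b), float(self.E[a, b])] for a, b in zip(ii, jj)
            ],
            "birth_session": self.birth_session.tolist(),
            "fitted": self.fitted,
            "n_sessions": self.n_sessions,
            "objective_history": self.objective_history_,
            "rng_state": self._rng.bit_generator.state,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SongModel":
        model = cls(
            D=payload["D"],
            config=SongConfig(**payload["config"]),
            seed=payload["seed"],
        )
        model.C = np.asarray(payload["C"], dtype=float).reshape(-1, payload["D"])
        model.Y = np.asarray(payload["Y"], dtype=float).reshape(-1, 2)
        K = model.C.shape[0]
        model.E = np.zeros((K, K))
        for a, b, w in payload["edges"]:
            model.E[a, b] = model.E[b, a] = w
        model.birth_session = np.asarray(payload["birth_session"], dtype=int)
        model.fitted = payload["fitted"]
        model.n_sessions = payload["n_sessions"]
        model.objective_history_ = list(payload["objective_history"])
        model._rng.bit_generator.state = payload["rng_state"]
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    def load(path) -> "SongModel":
        with open(path) as fh:
            return SongModel.from_dict(json.load(fh))

    load = staticmethod(load)

    # ------------------------------------------------------------------ #

    @staticmethod
    def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Pairwise squared Euclidean distances via the expanded form."""
        aa = np.sum(A * A, axis=1)[:, None]
        bb = np.sum(B * B, axis=1)[None, :]
        return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)

    @staticmethod
    def _bbox_diag(Y: np.ndarray) -> float:
        if Y.shape[0] < 2:
            return 0.0
        return float(np.linalg.norm(np.ptp(Y, axis=0)))
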