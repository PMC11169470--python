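# Methods

## The problem setting

A longitudinal experiment delivers, at each sampling timepoint
*i* = 1..n, a batch ("increment") I_i of high-dimensional observations:
FFT-featurized 4-s MEA segments for organoid recordings, or points
sampled along a known nonlinear trajectory in the simulation bench. The
goal is a 2D visualization of the accumulated data whose per-increment
medians, traced chronologically, draw the progression trajectory T^L of
the underlying system — and which *evolves consistently*: the
visualization produced after timepoint i must keep the structure and
orientation of the one produced after timepoint i−1, so partial results
of an ongoing experiment remain interpretable.

## Trajectory simulator

A random line L(t) = d·t + p in D dimensions (default D = 100) is made
nonlinear by squaring the components of a random subset of dimensions
(each dimension squared with probability 0.5 by default):
T(t)_j = (d_j t + p_j)^{a_j}, a_j ∈ {1, 2}. Defaults p ~ U(−1, 1) and
d ~ U(0, 0.01) keep components of order 1–10² over t ∈ [0, 500), a
scale on which squaring is a visible but not explosive nonlinearity.
With non-negative gradients the trajectory progresses monotonically —
the simulated analogue of gradually maturing electrical activity.

Increment i samples one point per integer t in
[100(i−1), 100i − δ): exactly 100 − δ points. The sampling gap
δ ∈ [0, 99] models time between recording sessions; δ = 99 leaves a
single point per increment, which is replicated into 100 points
perturbed by N(0, 0.001²) — replication rather than interpolation, so
no artificial continuity is created across a gap.

Measurement noise is λ·φ with φ ~ N(0, SD_j²) independently per
dimension, where SD_j defaults to the sample SD of the noiseless
trajectory in dimension j over the full pseudo-time range; λ = 0.2 then
reads "20% noise" on every dimension regardless of its scale.

Pairs of similar trajectories are built by convex combination of two
principals *after* exponentiation: T3 = αT1 + (1−α)T2 and
T4 = (1−α)T1 + αT2, α ∈ [0, 1]. The principal pair shares intercepts
and the squared-dimension pattern (so both start at the same point) but
has independent gradients, diverging as t grows.

## The embedding

The model state is θ = {C, E, Y}: coding vectors C (K×D), symmetric
non-negative edge weights E (K×K, zero diagonal), and layout vectors Y
(K×2) in bijection with C. One training session interleaves, per epoch:

1. **Vector quantization with growth.** Inputs are assigned to their
   nearest coding vector (ties broken toward the lowest index, for
   determinism); each occupied code moves toward its cell mean with a
   linearly decaying learning rate (0.4 → 0.04). Codes are spawned at
   inputs whose quantization error exceeds `growth_coeff` (1.5) times
   the mean error, at most 8 per epoch, mutually separated, up to a
   capacity of N/`points_per_code` (N/4) bounded by `max_codes` (600).
   A new code inherits its parent's layout position plus ~1% jitter and
   a half-strength edge to it, so growth never tears the layout.
2. **Self-organization.** For every input the winner/runner-up code
   pair receives a Hebbian edge reinforcement (+1/N), all edges decay
   by 0.97 per epoch, and edges below 10⁻³ of the maximum weight are
   pruned at session end. A mild graph smoothing (0.02) pulls connected
   codes toward each other's mean, keeping chains coherent.
3. **Cross-entropy layout.** The layout weights are the Hebbian edges
   blended with an adaptive-kernel codebook-kNN term (10 neighbors,
   weight exp(−(d−ρ)/σ) with ρ the nearest-code distance and σ the mean
   excess distance, symmetrized; relative weight 0.3). Y follows one
   SGD pass per epoch: attraction 2w·Δ/(1+‖Δ‖²) along weighted edges,
   repulsion 2/((‖Δ‖²+10⁻³)(1+‖Δ‖²)) against 10 negative samples per
   code (weight 2.0), gradients clipped to ±4, learning rate decaying
   from 0.25.

Two mechanisms give the embedding reliable *global* geometry, which the
purely topological cross-entropy objective does not constrain:

* **A global distance-matching force.** After the cross-entropy forces,
  every code receives the mean over all other codes of
  (d_H/s̄_H − d_Y/s̄_Y) along the 2D direction between them (scale-free:
  both spaces are normalized by their mean pairwise distance). This
  weak stress term calibrates the relative placement of regions the
  neighborhood graph leaves disconnected — without it, the relative
  distances between separate trajectory chains (and hence any distance
  ranking computed from the visualization) are close to arbitrary.
* **Consolidation.** Codes created in earlier sessions move with a
  layout learning rate damped by ×0.05, while codes born in the current
  session stay fully plastic. New data therefore extends outward from a
  stable scaffold instead of re-equilibrating the whole picture; this
  is what keeps orientation across sessions and lets the traced
  trajectory actually *extend* rather than saturate at the repulsion
  equilibrium radius.

Within the very first session — before any cross-session structure
exists — the layout is re-seeded halfway through from the codebook's
two leading principal components (scaled to ±5). Later sessions only
fine-tune the carried-over Y.

`transform` maps an input through its nearest code: an inverse-distance
weighted blend of the layout positions of that code and its closest
graph neighbors (3 in total); an input equal to a coding vector maps
exactly to that code's layout vector. The map is deterministic given θ.

All stochastic steps draw from one root generator stored in the model;
a serialized model (JSON: C, Y, sparse edge triplets, hyperparameters,
generator state) restores bit-exactly, and resuming training from a
checkpoint reproduces an unbroken run exactly.

## Sessions, medians, distances

Session i fine-tunes on D_i = I_1 ∪ … ∪ I_i — full replay of all stored
increments, the straightforward defense against catastrophic
forgetting (a rehearsal subset would trade memory for fidelity; not
implemented). First sessions run 150 epochs, incremental sessions 60.
Units may miss timepoints; their increments simply keep consecutive
numbering, and jointly modeled units are aligned by arrival order.

The traced trajectory uses the coordinate-wise (marginal) median of
each increment's 2D points — robust to outlying segments; a geometric
(Weiszfeld) median is available as an option. The distance between two
traced trajectories with equal increment counts n is the mean Euclidean
distance between corresponding medians; comparing unequal counts is
refused unless truncation to the shared prefix is explicitly requested,
and distances are reported in raw embedding units (only orderings and
ratios are meaningful).

Orientation preservation between consecutive visualizations is scored
as the mean displacement of shared points normalized by the current
bounding-box diagonal, with the Procrustes disparity reported alongside
to separate "moved rigidly" from "changed shape".

## MEA preprocessing and spike detection

Recordings (m×S µV, default 9 electrodes at 25 kHz) are high-pass
filtered (3rd-order Butterworth, 300 Hz, zero-phase by default to avoid
phase-distorting spike shapes), cut into non-overlapping 4-s windows
(trailing partial window discarded), and each window is reduced to a
single feature vector: per channel the FFT amplitude spectrum's first
half (DC included; the signal is real so the second half is redundant),
channels concatenated to preserve per-electrode information, then
adjacent-bin averaging down to exactly k = 1000 features (truncation
and max-pooling are selectable; averaging is deterministic,
data-independent and preserves spectral ordering). Features from one
timepoint form one increment; within a unit, timepoints are renumbered
consecutively so missed sessions do not leave gaps.

The baseline spike detector subtracts the reference channel (if any),
band-passes 300–1000 Hz, thresholds each channel at
−4.0 × median(|x|) — the "median sigma", implemented literally, with
the MAD/0.6745 Gaussian-SD variant as an option — and counts
negative-going crossings, collapsing crossings within a 1 ms refractory
window. The threshold scales with the signal, so detection is exactly
scale-equivariant.

## Surrogate recordings

Each surrogate channel is Gaussian noise (5 µV SD) plus Poisson-timed
biphasic spikes (difference of Gaussians, ~1 ms, 50 µV trough) at a
per-timepoint rate; a monotone rate schedule (1 → 10 Hz over five
timepoints) emulates maturation. Defaults use 5 kHz sampling and ≤60 s
recordings to keep end-to-end runs light; 25 kHz mirrors the real
acquisition. The surrogates deliberately omit bursting, synchrony and
electrode cross-talk, so pipeline tests on them demonstrate mechanics
(feature extraction, incremental embedding, trend recovery), not
biological realism: a passing test means the pipeline recovers a known
monotone drift from spectrally realistic segments, nothing more.

## Validation conditions and problem sizes

The stochastic properties are validated over a fixed panel of ten seeds
at the study defaults (D = 100, n = 5 increments, 100 − δ points each):
trend capture at λ = 0 and λ = 0.2 with δ ∈ {0, 25, 50} (the traced
distance from the first median must grow for ≥4 of 5 increments, in ≥8
of 10 seeds); five-cluster structure at δ = 99 with λ = 0.2 (silhouette
over increment labels > 0.5 — vector quantization denoises the
expanded singleton clusters, whose raw high-dimensional silhouette
under that noise is only ≈0.47); α-ordering recovery for
α ∈ {0.6, 0.7, 0.8, 0.9} (both secondaries ranked nearer their
principals, margin increasing with α); and the carry-over vs
per-session-reset ablation. These panel sizes keep the full suite
around ten minutes on one core while leaving the stochastic gates
meaningful.

## Known limitations

* Embedding-unit distances are not comparable across independently
  trained models; joint modeling is the only supported route to
  cross-unit comparison.
* The global stress force assumes the input-space mean pairwise
  distance is a meaningful scale; data with wildly heterogeneous
  cluster scales may see mid-range distortion.
* `transform` places inputs far outside the codebook's support at their
  nearest cell — extrapolation is not attempted.
* No artifact rejection beyond the high-pass filter, no spike sorting,
  no per-well normalization; burst/synchrony statistics are out of
  scope.
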