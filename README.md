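# ilvis — incrementally learned visualization of longitudinal trajectories

`ilvis` is a pipeline for visualizing how a high-dimensional biological
system changes over the course of a longitudinal experiment. It was
built for multi-electrode-array (MEA) recordings of cortical organoids —
where each sampling timepoint yields hundreds of high-dimensional
spectral feature vectors and the question is how the electrophysiological
state *progresses* across months — but it applies to any experiment that
delivers batches of high-dimensional observations at successive
timepoints.

Classical embeddings (t-SNE, UMAP) are non-parametric: re-running them
after each new batch produces visualizations that cannot be compared
with each other. `ilvis` instead maintains a *parametric* embedding in
the style of SONG (self-organizing topology-preserving embeddings) whose
parameters

&theta; = {C, E, Y}

are retained and fine-tuned — never re-initialized — as data arrives:
`C` is a growing codebook of high-dimensional coding vectors obtained by
vector quantization, `E` a self-organized edge-weight matrix over the
codebook approximating the input topology, and `Y` a set of 2D layout
vectors in bijection with `C`, optimized by stochastic gradient descent
on a cross-entropy objective between the graph neighborhood distribution
and the 2D similarities (with an auxiliary global distance-matching
force; see `docs/methods.md`).

At session *i* the model is fine-tuned on the union of all increments
observed so far, D_i = I_1 ∪ … ∪ I_i (full replay prevents catastrophic
forgetting), and a partial visualization V_i is produced. Tracing the
2D median of each increment chronologically yields the progression
trajectory T^L; for two traced trajectories A, B with n increments the
dissimilarity is the mean Euclidean distance between corresponding
medians,

D(A, B) = (1/n) Σᵢ ‖mᵢᴬ − mᵢᴮ‖ .

Modeling several units (organoids, treatments) *jointly* in one shared
embedding makes these distances and the trajectory directions mutually
comparable.

The package also ships:

* a simulator of random nonlinear high-dimensional trajectories with
  controllable sampling gaps (δ), noise level (λ) and pairwise
  similarity (α) — the validation bench on which every pipeline property
  is tested, since ground-truth progression trajectories are known;
* an MEA preprocessing chain (3rd-order 300 Hz high-pass Butterworth,
  4-s non-overlapping segmentation, FFT amplitude-spectrum features
  reduced to 1000 per segment);
* a conventional threshold-crossing spike detector
  (−4.0 × median(|x|), 300–1000 Hz band) as a baseline;
* a surrogate MEA generator (Poisson-timed biphasic spikes in Gaussian
  noise with a maturation rate schedule) so the full pipeline runs
  end-to-end without any experimental data.

## Worked example

Simulate four 100-dimensional trajectories — a shared-origin diverging
pair T1, T2 plus the compositions T3 = 0.8·T1 + 0.2·T2 and
T4 = 0.2·T1 + 0.8·T2 — then model them jointly for five incremental
sessions, and rank their traced 2D trajectories by distance to T1:

```bash
ilvis simulate -D 100 -n 5 --alpha 0.8 --seed 1 --out sim
ilvis fit --increments sim/increments_T1.csv --increments sim/increments_T2.csv \
          --increments sim/increments_T3.csv --increments sim/increments_T4.csv \
          --out fit --seed 1
ilvis distance --medians fit/medians.csv --reference T1 --out distances.csv
ilvis plot --viz fit/V_5.csv --out v5.png
```

which prints

```
wrote 4 trajectory increment file(s) to sim
ran 5 sessions; outputs in fit
| label | distance | rank |
| --- | --- | --- |
| T1 | 0 | - |
| T3 | 5.354 | 1 |
| T4 | 25.85 | 2 |
| T2 | 31.71 | 3 |
```

T3, built to resemble T1 (α = 0.8), is traced closest to it; T4, built
to resemble T2, ranks far from T1 — the embedding has preserved the
similarity structure of the high-dimensional trajectories. Distances
are in embedding units; only their ordering and ratios are meaningful.
`v5.png` shows all four traced trajectories fanning out of their common
origin, newer increments drawn more intensely, with T3 hugging T1 and
T4 hugging T2.

The same flow works on recordings: `ilvis preprocess` turns HDF5
recordings into segment feature CSVs (`ilvis detect-spikes` gives the
conventional per-channel spike counts), and the resulting per-timepoint
increments feed `ilvis fit` unchanged.

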