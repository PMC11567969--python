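# Methods

## Model

The simulator is the standard randomly connected rate network. Each of the
`N` units carries an activity variable `x_i(t)` obeying

    tau * dx_i/dt = -x_i + sum_j J_ij * tanh(x_j) + H_i^wn + H_i^ext

with coupling `J_ij ~ N(0, g^2/N)` i.i.d. (row = postsynaptic: the
recurrent term is `J @ tanh(x)`). For gain `g < 1` the autonomous network
decays to silence; for `g > 1` it self-sustains irregular, chaotic
activity. All driven experiments run at `g = 1.3`, inside the chaotic
regime. Integration is forward Euler with `dt = tau/10` (`tau = 0.5 s`,
`dt = 0.05 s`); halving `dt` changes a 10-tau trajectory by under 5%
relative L2 norm, which we treat as sufficient accuracy for statistics
that are themselves averages over trials and seeds.

`H^wn` is low-pass-filtered white noise implemented as a stationary AR(1)
process, `H(t) = h0*eta(t) + [H(t-1) - h0*eta(t)] * a` with per-step decay
`a = exp(-dt/tau_wn)`, so `tau_wn` is a genuine correlation time (lag-1
autocorrelation equals `a`). A `literal_noise_exponent` flag switches to
the raw decay `exp(-tau_wn)` for literal reproduction of the alternative
convention. The default noise amplitude in the reference experiments is
`h0 = 0.05` — small relative to the chaotic fluctuations, consistent with
the observation that trial variability here is a property of the
deterministic dynamics, not of injected noise.

External drive enters through nonnegative input projections. For the
DBS-like paradigm a random subset (fraction 0.3 by default) of neurons
receives half-Gaussian weights `|N(0, sigma^2)|` (mean `sigma*sqrt(2/pi)`;
we use the exact half-normal throughout, not the `mean ~ sigma`
approximation). For the 8-channel orientation paradigm each channel
independently targets 10% of the network, so channel input sets overlap
(mixed selectivity). The spatial variant places neurons on a square grid:
input neurons are drawn iteratively without replacement with sampling
weight `q_i = 1 - d_i/sum(d)` renormalized over the remaining pool, and
selected neurons get weight `exp(-d_i^2 / 2 sigma^2) + eta`,
`eta ~ N(0, 0.05^2)`, clipped at zero.

Stimuli are square waves on half-open intervals `[onset, onset+duration)`.
Trials are sliced out of one continuous simulation — the state is *not*
reset between trials, which is what makes the pre-stimulus state of each
trial a meaningful, history-dependent quantity (a reset-per-trial mode
exists for controlled comparisons). Recording is at 10 Hz (every second
Euler step).

## Trial-variability statistics

The central statistic is the normalized trial variance

    V = (1/N_T) * sum_j ||R_j - Rbar||_F^2 / ||Rbar||_F^2

over a neurons-x-time window, its per-frame version `V(t)` and its
per-neuron version. `V` is scale-invariant and undefined when the mean
response is identically zero; undefined values raise
(`UndefinedVarianceError`) or propagate as NaN — they are never reported
as 0, which matters for silent networks. Preprocessing (for
fluorescence-like traces) is per-trace linear detrend followed by z-score
with a guarded division (constant traces map to zeros).

Relaxation time constants are least-squares fits of `a + b*exp(-t/tau)`
to the onset->offset descent of `V(t)` and the post-offset rise, with
three tau multi-starts and bounded tau. Because `V(t)` between trials is
stationary, the rise recovers toward the pre-stimulus baseline; the rise
fit therefore pins its asymptote at that baseline. This matters: with the
desk-scale inter-trial intervals the recovery is far from saturated at
the end of the post window, and a free-asymptote fit is unidentifiable
(tau escapes to its bound). The relaxation experiment accordingly uses
longer sessions (9-12 s ITI, 8 s post window) than the quenching
experiment (5-8 s ITI).

## State-space analyses

The energy proxy of a visited population state is its one-step speed
`||x(t+dt) - x(t)||_2` under the deterministic dynamics: slow regions are
attractor wells. Sampled states are embedded in 2-D by classical
(Torgerson) MDS on the dissimilarity `delta = 1 - r` (Pearson). We use
`1 - r` rather than the literal `-r` because `-r` is negative for
correlated pairs and breaks the metric embedding; the two are monotone
equivalent, and a `literal_negative_corr` flag restores the literal form.
Classical MDS is chosen over iterative SMACOF for determinism; Kruskal
stress-1 is reported as a diagnostic. Energies above the 99th percentile
are dropped as outliers (rule: singular fast states distort the surface),
the rest are linearly interpolated onto a regular grid, smoothed with a
2-D Gaussian via normalized (NaN-aware) convolution, and left undefined
outside the convex hull of the samples.

The behavior readout is the second principal component of the
time-concatenated population activity (PCA fitted globally so the readout
is comparable across trials; sign fixed by making each component's first
nonzero loading positive). Initial states are the 20-frame pre-stimulus
readout windows, clustered by Euclidean k-means with k = 2, at most 100
iterations, 10 restarts, best inertia kept, seeded for determinism.

## Decoding

Each trial is one decoding unit: features concatenate the selected
neurons' activity over the 1-s post-onset window. The decoder is KNN
(default K = 1) under leave-one-trial-out cross-validation, with fixed
tie-breaking (lowest trial index on distance ties, lowest label on vote
ties) so results are bit-reproducible. The PCA-dimension sweep refits the
basis inside every fold by default (leakage-safe; a `global_fit` flag
gives the literal single-fit variant) and exploits subspace nesting by
fitting once at the largest component count per fold. The
reliability-ranked sweep splits trials class-stratified into disjoint
evaluation and decoding sets (default 50/50), ranks neurons by
evaluation-set single-neuron variability ascending, and compares against
random orderings at matched pool sizes — measuring reliability on
held-out trials is what prevents selection leakage. Note that under
leave-one-trial-out with balanced classes the chance level is
`(n_per - 1)/(N_T - 1)`, slightly below `1/K`, because the held-out
trial's own label has one fewer representative among the candidates.

## Surrogate behavioral data

The calcium surrogate convolves rectified rates with a single-exponential
indicator kernel (default decay 0.7 s, GCaMP6f-like; a parameter, not a
claim) and adds a linear photobleaching trend and Gaussian noise — exactly
the artifacts the preprocessing removes. Pupil landmarks are four points
at the axis extremes of an ellipse plus labeling jitter; the fit minimizes
`sum_i (d_i^2 - d^2)^2` over center and radial parameter `d` and reports
both the fitted radius and `diameter = 2d` (the naming in the source
formulation conflates the two; the returned object is explicit). Pupil
area is the ellipse approximation `pi*(p1/2)*(p2/2)` from the two
opposite-landmark pair distances. Motion energy is the Frobenius norm of
successive frame differences; locomotion labeling is unsupervised 1-D
two-class k-means on per-trial energies (the in vivo analogue was manual
inspection, so the default is deliberately assumption-light), with a
fixed-threshold mode.

## Reference experiment conditions

`mesovar.experiments` freezes the reference conditions used by the test
suite and the reproduction script:

- critical gain: N = 1000, noise off, random initial state, 200 tau per
  run, silent if post-transient activity std < 1e-3, per-seed bisection on
  a 0.6-1.6 bracket (7 iterations), 20 seeds averaged. Runs are batched
  across seeds in float32 (one batched matmul per Euler step); the
  classification threshold separates decaying from sustained activity by
  many orders of magnitude, so precision is not limiting.
- pulse (DBS-like) sessions: N = 300, 12 trials, amplitude grid 1-5
  (base 2), input fraction 0.3, sigma 1, ITI 5-8 s (9-12 s for the
  relaxation experiment).
- orientation sessions: N = 800, 8 channels x 20 trials, amplitude 4,
  input fraction 0.1 per channel (a scaled-down N = 200/300 variant backs
  the quick unit-test fixtures).
- spatial sessions: 20 x 20 grid, Gaussian input footprint sigma = 3 grid
  units, 15% input neurons, field-of-view radii 1-17.
- planted-reliability tensors: 100 neurons, 10% reliable, 4 classes x 12
  trials.

Amplitudes and `h0` are model-unit choices (the in vivo stimulation units
do not translate): they were picked once to sit in the moderate regime —
strong enough to quench variability, far from saturating `tanh` — and the
amplitude grid is linear so the log-linear variance fit is a nontrivial
claim.

## What the synthetic data does and does not show

The generators emulate the statistical structure the analyses consume
(chaotic background, quenched attractor dynamics, bleaching/noise
measurement artifacts, planted reliable subpopulations, bimodal motion
energy), not the biology around it: no cell-extraction errors, no
correlated measurement noise across neurons, no hemodynamic or motion
artifacts, no real orientation tuning curves, and scaled-down intervals
(seconds rather than minutes) and population sizes (hundreds rather than
hundreds of thousands). Passing tests therefore certify the algorithms
and the model-level phenomena, not in vivo effect sizes; the in vivo
regression R² values and neuron counts from large-scale recordings are
out of reach by construction.

## Numerical choices and degenerate inputs

- Undefined variance (zero-norm mean response) raises or yields NaN,
  never 0.
- KNN ties and k-means/PCA randomness are pinned (stable sorts, seeded
  restarts) so every decoding and clustering result is reproducible
  bit-for-bit under a fixed seed.
- Exponential fits are bounded (`dt/10 <= tau <= 10 * segment span`) with
  three multi-starts; non-convergence is flagged in the result, not
  raised.
- Collinear embeddings, all-identical cluster inputs, empty radii,
  singleton classes and constant traces are flagged (NaN / degenerate
  flags) rather than raised wherever the quantity is partial; structural
  misuse (shape mismatches, empty subsets, invalid windows) raises.

## Known limitations

- The forward-Euler integrator is first-order; dt is configurable but no
  higher-order scheme is provided.
- The energy landscape is a 2-D visualization proxy; well depth depends on
  the embedding and grid resolution and is meaningful comparatively, not
  absolutely.
- `fit_relaxation_constants` assumes a single-exponential segment; traces
  with multiple timescales fold them into one constant.
- The OSI convention treats stimulus classes as orientations equally
  spaced over 180°; direction-selective analyses would need a different
  mapping.
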