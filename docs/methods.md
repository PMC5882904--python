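# Methods

This note documents the models implemented in `gcbold`, the parameter
choices that matter, and what the synthetic benchmarks do and do not show.

## Conditional multivariate Granger causality

For an n-channel series the strength of the directed influence j → i is the
log ratio of the target channel's residual variance in two VAR(P) fits: a
*restricted* model over all channels except j, and an *unrestricted* model
over all n channels. Because every other channel enters both fits, the
measure is conditioned on the rest of the network: influence mediated by a
third region is absorbed by the conditioning set and does not register as a
direct j → i link (the chain test `x → z → y` in the suite demonstrates
this — the trivariate estimate of x → y is ~0 while the bivariate one is
clearly positive).

Estimation details:

* **Estimators.** Default is a multichannel Burg recursion of the
  Nuttall–Strand type: at each stage the partial-correlation matrix Δ
  minimizes the sum of forward and backward prediction-error powers
  weighted by the previous stage's error covariances, which yields the
  Sylvester equation `F P_f⁻¹ Δ + Δ P_b⁻¹ B = 2 C` (F, B, C: sample
  moments of forward errors, delayed backward errors and their cross
  products), followed by the Whittle coefficient update. Lagged least
  squares (`method="ols"`) is also provided; on long stationary series the
  two agree to ~1e-3 and both agree with the Yule–Walker population values
  for simulated VAR ground truth. Burg can produce marginally negative GC
  values; these are clipped at zero (logged at debug level) so GC matrices
  are nonnegative by contract.
* **Segments.** Lagged predictors are never assembled across segment
  boundaries; residual moments pool over segments. One subject's multiple
  scanning sessions are therefore one fit with all datapoints counted, not
  a concatenation artefact. Channels are demeaned per segment.
* **Alignment.** Restricted and unrestricted fits use identical effective
  samples (first P observations of each segment excluded from both), so
  the variance ratio compares like with like.
* **Orientation.** `GcMatrix.values[i, j]` is j → i (rows = target,
  columns = source). All consumers go through `strength(source, target)`.
* Zero-lag (instantaneous) terms are not modelled; only lagged predictors
  enter either VAR.

The default order P = 3 is the value selected by the figure-of-merit
criterion (mean of recovery AUC and top-1% PPV, `benchmark.select_order`)
on full-scale synthetic sweeps, and is applied unchanged to in-vivo-style
analyses. At 116 ROIs this puts the model at 116·116·3 + 116·117/2 = 47 154
parameters against 556 800 datapoints for four 1200-volume sessions,
roughly 12 datapoints per parameter.

## Ground-truth networks

Benchmark graphs are drawn uniformly from all simple digraphs with a fixed
number of directed edges: n_e ordered pairs chosen without replacement from
the N(N−1) admissible pairs. Self-loops are excluded (the possible-edge
count N(N−1) already excludes them); directed cycles and reciprocal pairs
are allowed and each direction counts as its own edge for both generation
and scoring. The 20-node sweep uses 23 edge counts from 2 to 380 whose
densities are approximately log-equidistant in [0.005, 1]; other sizes get
an analogous schedule by rounding log-spaced densities.

## Node dynamics: Izhikevich columns

Each node is a column of Izhikevich neurons (`dv/dt = 0.04v² + 5v + 140 − u
+ I`, `du/dt = a(bv − u)`, reset at 30 mV), 80% regular-spiking excitatory
and 20% fast-spiking inhibitory with the canonical heterogeneity, dense
random intra-column weights (excitatory positive, inhibitory negative,
normalized so expected total input is independent of column size) and
independent Gaussian noise drive per neuron per 1 ms step. Columns run at
dt = 1 ms with two half-steps for the stiff quadratic update; population
rates are read out in 10 ms bins. The desk preset uses 50-neuron columns
(isolated columns fire at ~5 Hz, driven ones at ~10–30 Hz), the full preset
100 neurons.

**Inter-node coupling.** A directed edge j → i injects the
low-pass-filtered (τ = 0.1 s) population rate of column j, delayed by the
bundle latency, as a common current into column i's excitatory pool, scaled
by `inter_gain` (0.5) through a soft saturation `g·S₀·tanh(Σs/S₀)`
(S₀ = 60 Hz) so that columns with many in-edges stay stable at every
density of the sweep.

**Bundle latency.** The effective inter-node latency defaults to 0.35 s
(`conduction_delay`) plus the ~0.1 s synaptic integration. This is an
*effective pathway* latency, not a single axonal conduction delay: each
edge stands for a compound, polysynaptic fibre bundle whose influence
accumulates over hundreds of milliseconds. The choice is also dictated by
the physics of the readout: with volumes sampled every 0.72 s, an
inter-node latency of a few milliseconds places essentially all transferred
information inside a single repetition time, where it appears as
instantaneous correlation that no lagged VAR can attribute a direction to
(measured end-to-end, direction recovery is then at chance). Latencies that
are an appreciable fraction of the TR are the regime in which
BOLD-level Granger causality is well defined, and they are what this
simulator is calibrated to. Calibration used two-node direction-recovery
and physiological firing ranges only, before any benchmark sweep was run.

**Linear surrogate.** `simulate_var_surrogate_activity` provides a VAR(1)
rate process on the same 10 ms grid (self-coefficient 0.6, edge coupling
0.25 normalized by in-degree, spectral radius capped at 0.95) for fast
harness tests; it feeds the identical Balloon stage.

## Haemodynamics: the Balloon model

Firing rates drive the four-state Balloon system (vasodilatory signal s,
inflow f, venous volume v, deoxyhaemoglobin q) with the standard published
constants κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, E₀ = 0.34,
V₀ = 0.02, k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2, and oxygen extraction
E(f) = 1 − (1 − E₀)^(1/f). The drive is the node's relative rate
fluctuation `drive_gain · (r − r̄)/r̄` (gain 0.4), so a silent or constant
node rests exactly at the haemodynamic fixed point (f = v = q = 1, s = 0,
BOLD = 0). Integration is fixed-step RK4 on the 10 ms neural grid —
verified against an adaptive-step reference to ~1e-4 relative error and
converged to <1e-3 relative RMS under step halving — then decimated at the
scanner TR after a 20 s burn-in. States are reported at bin start, so
sample times are exact. Optional white measurement noise at a configurable
SNR is off by default. HRF parameters are identical across nodes; per-node
HRF variability is not modelled.

## Recovery benchmarking

For each realization the full GC matrix is scored against the generating
graph: ROC-AUC over all N(N−1) ordered pairs (ties count ½; each direction
of a reciprocal pair is its own candidate) and the precision of the
k = max(1, ⌊fraction·N(N−1)⌋) strongest links (default 1%), with ties
broken deterministically by (source, target) index. Sweeps aggregate
median, quartiles and extremes per density. The desk preset (8 networks ×
3 realizations, 50-neuron columns, 1200 volumes at TR 0.72 s) reproduces
the qualitative full-scale picture — near-perfect recovery at low density
(median AUC and top-1% PPV ≈ 1 at density ~0.016), high AUC at density
0.05, and degradation as density grows — at roughly 15 s of compute per
realization. Order selection averages the merit (AUC + PPV)/2 over
realizations within each density, then over densities with equal weight;
ties go to the smaller order.

## In-vivo analysis path

Sessions are delimited text (header of ROI labels, one row per volume, TR
from a JSON sidecar). The stationarity pre-check cuts each ROI's series
into 3-minute windows (250 volumes at TR 0.72 s) and runs a two-sample
Kolmogorov–Smirnov test per window. By default each window is compared
against the *complement* of its series: comparing against the pooled series
that contains the window biases the test conservative (the measured
false-flag rate on i.i.d. data is well under 1% at α = 5%), whereas the
complement comparison keeps the nominal α, which is what makes the flagged
fraction interpretable. The pooled variant remains available
(`compare="full"`). The check is advisory — fractions are reported, no ROI
is dropped automatically.

Per subject, all sessions pool into one segment-aware fit (G_k); subjects
aggregate by elementwise median (G); thresholding at the top 1% happens
after the median, never per subject. The normalized causality flow
F = (G − Gᵀ)/(G + Gᵀ) is antisymmetric with entries in [−1, 1]; pairs with
G_ij + G_ji = 0 are assigned F = 0 (no evidence either way), which
preserves both properties. A packaged AAL-116 label table (name,
hemisphere, lobe) supports intra- vs inter-hemisphere summaries of the
thresholded edge list.

## Numerical and degenerate-input conventions

* Burg stages symmetrize the running error covariances and raise a clear
  estimation error on singular stages; OLS warns on rank-deficient designs.
* GC values are clipped at 0; the diagonal is identically 0.
* Constant (zero-variance) ROIs are flagged on read but kept.
* `k ≥ 1` is enforced in every top-fraction selection so tiny networks
  never select zero links.
* All stochastic stages take a `numpy.random.Generator`; benchmark sweeps
  derive every cell's seed from one master seed via `SeedSequence`, so runs
  are exactly reproducible and cacheable per (density, network,
  realization, seed).

## Limitations

* The spiking and haemodynamic parameterizations are this package's own
  defaults, exposed in configuration; they were chosen for stability,
  physiological plausibility and a detectable directed-transfer regime at
  TR = 0.72 s, not fitted to any particular dataset.
* Passing desk-scale benchmarks shows the estimator recovers ground truth
  under *this* generative model — identical HRFs across nodes, stationary
  dynamics, no measurement noise by default, no motion or physiological
  artefacts. Real fMRI violates all of these to some degree; the top-1%
  thresholding strategy is precisely a hedge against that gap.
* Frequency-domain, state-space and nonlinear Granger variants are out of
  scope, as are NIfTI ingestion and any image preprocessing; inputs are
  ROI-by-time text matrices.
* At densities ≥ 0.2 the desk-scale generator's per-edge coupling is
  diluted by the saturating bundle transfer, and recovery degrades more
  steeply than at full scale; the desk preset is calibrated for the sparse
  regimes where the top-1% strategy operates.
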