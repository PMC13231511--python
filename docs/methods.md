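# Methods

This note documents the models, conventions and design choices behind
`fightdyn`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A capture event is logged by a tri-axial jerk accelerometer mounted on the
fishing line. Every 2 s the tag reports four values: the mean jerk (rate of
change of acceleration, g s⁻¹) along its X, Y and Z axes and the activity
vector sum (ActVSum), the vectorial magnitude of jerk scaled to the tag range
[0, 2] g s⁻¹. Times are stored relative to hook-up (first logged sample is
t = 0); the reader rejects spacing that deviates from the cadence by more
than 1% rather than interpolating, because the tag logs on a fixed schedule —
a gap indicates a logging fault, not missing data to impute. Values stay in
tag units (g s⁻¹) internally; conversion to SI jerk (m s⁻³) by the standard
gravity 9.81 is an explicit helper (`jerk_to_si`), never applied implicitly.

Body mass (kg) is estimated from fork length FL and girth (cm) as
mass = FL · girth² / 27120.

## Summary fight metrics

Per fish, from the ActVSum channel:

- **mean, CV** — arithmetic mean; coefficient of variation with the sample
  SD (denominator n − 1).
- **total effort** — cumulative sum of ActVSum samples.
- **bursts** — maximal runs of consecutive samples strictly above a
  threshold (default 1.25 g s⁻¹), counted by run-length encoding. "Exceeded"
  is read as strict inequality; a single sample above threshold is a burst.
  Both the threshold and a minimum run length are configurable because the
  default threshold is a conservative choice pending field validation.
- **early/late intensity** — mean ActVSum over the first and last ⌊n/3⌋
  samples (minimum 1). Thirds are sample counts, equivalent to wall-clock
  thirds at uniform cadence.
- **fatigue index** — let p be the first global maximum of ActVSum. If at
  least 3 samples follow p, fit ordinary least squares to ActVSum versus
  sample index over p..n−1 (peak included) and report max(0, −slope), in
  g s⁻¹ per sample step; otherwise 0. The index is reported as a
  non-negative decline rate; the per-sample-step unit matches the magnitude
  scale on which the index is conventionally reported (≈0–0.5).

Fight duration is kept as a side column but excluded from the PCA input
because of its strong correlation with the other metrics.

## Processing variants and DTW

Twelve series variants feed the DTW engine: {raw, high-pass, first
derivative} × {X, Y, Z, XYZ}.

- **High-pass** subtracts a centred rolling mean over ±2 s (all samples
  within half the 4-s window, inclusive; shrinking windows at the edges). A
  Butterworth-type IIR design is ill-posed here: at a 2-s cadence the
  Nyquist frequency coincides with the 4-s band edge. Mean subtraction is
  well-defined, linear, and removes exactly the locally-smooth component.
  The operator is only approximately idempotent: its frequency response
  (1 + 2cosθ)/3 vanishes at period 3 samples (6 s) and reaches ±1/3 toward
  the band edges.
- **Derivative** is the forward difference divided by the cadence — snap,
  in g s⁻² tag units — applied to raw axes without prior smoothing.
- **XYZ** applies the transform per axis and assembles 3-vectors.

DTW uses the symmetric step pattern with double-weighted diagonal:

    g(i,j) = min( g(i−1,j) + d(i,j), g(i,j−1) + d(i,j), g(i−1,j−1) + 2·d(i,j) )

with local distance |aᵢ − bⱼ| (univariate) or the Euclidean norm of the
component difference (multivariate; axes share units, so no per-axis
re-scaling). No windowing constraint or open ends: fights are at most ~90
samples, so the full O(NM) table is cheap. The unnormalized cumulative cost
is the default dissimilarity; the length-normalized cost distance/(N+M) is
computed and stored alongside. Path tie-breaks prefer the diagonal, then
the step consuming the first series. The pairwise matrix computes each of
the n(n−1)/2 alignments once; the step pattern is symmetric in its
arguments, so d(i,j) = d(j,i) exactly.

## Ordination

- **PCA** (summary pipeline): eigendecomposition of the covariance of the
  z-scored metric matrix (equivalently, correlation-matrix PCA). Sign
  convention: the largest-magnitude loading of each component is positive.
- **PCoA** (DTW pipelines): classical scaling — double-center −½·J D² J,
  eigendecompose, scale eigenvectors by √λ. Negative eigenvalues (DTW
  distances are not Euclidean) are dropped without Lingoes/Cailliez
  correction, and variance fractions are taken over the positive
  eigenvalues only. Both conventions exist in the literature; this one is
  recorded in the run metadata.

The first three dimensions are retained from either ordination.

## Clustering and the gap statistic

Ward agglomeration uses the Lance–Williams update applied to the input
distances **as-is** (the un-squared "Ward D" convention, distinct from the
squared-distance variant implemented by `scipy.cluster.hierarchy`):

    d(k, i∪j) = [(nᵢ+nₖ)d(k,i) + (nⱼ+nₖ)d(k,j) − nₖ d(i,j)] / (nᵢ+nⱼ+nₖ)

Ties merge the pair with lexicographically smallest cluster ids; flat labels
come from cutting the tree after n − k merges.

The number of clusters is chosen by the gap statistic on the retained
Dim1–Dim3 scores: W_k is the pooled within-cluster dispersion
Σ_r Σ_{pairs in r} d²/(2n_r) (squared-pairwise convention), reference sets
are drawn uniformly over each feature's observed range (B = 100 bootstrap
replicates; 50 in reduced mode), se(k) = sd_B(log W*) · √(1 + 1/B), and the
chosen k is the smallest k with gap(k) ≥ gap(k+1) − se(k+1), falling back to
argmax gap. k = 1 is a valid outcome, reported as "no discrete clusters".
Reference clustering reuses the same Ward routine so observed and reference
dispersions are comparable. k_max defaults to min(6, n−1), sized to a
~14-fish cohort.

## Bayesian physiology linkage

For fish i, the bivariate response yᵢ = (blood pH, lactate), each
rank-normalized:

    yᵢ = β₀ + β_dim Dᵢ + β_cov Xᵢ + εᵢ,   εᵢ ~ N₂(0, Σ)

Dᵢ are the three retained ordination scores; Xᵢ is a coho indicator
(chinook reference), z-scored body mass and water temperature, plus z-scored
fight duration **only** for the summary-metrics pipeline (summary statistics
collapse temporal information; DTW pipelines carry duration implicitly).
Σ has residual SDs σ₁, σ₂ and residual correlation ρ.

Responses are normalized by the rank-based inverse-normal (ordered-quantile)
transform: tie-averaged rank r among n maps to Φ⁻¹((r − 0.5)/n). The 0.5
offset is used rather than Blom's 3/8 for simplicity; the fitted mapping is
stored and inverted by monotone interpolation (linear extrapolation at the
tails) when predictions are back-transformed.

**Priors** (the responses are normalized and covariates standardized, so
these are weakly informative on that scale): coefficients and intercepts
N(0, 5); residual SDs half-Student-t(3, 0, 2.5); ρ uniform on (−1, 1).

**Sampling.** The posterior is sampled with an affine-invariant ensemble
sampler (emcee) using a 0.8/0.2 mixture of differential-evolution and
DE-snooker moves, which mix far better than the stretch move in this
~20-dimensional posterior. Residual SDs are sampled on the log scale and ρ
via atanh, with the appropriate Jacobians. The ensemble has at least
2·ndim + 2 walkers, initialized with small jitter around the least-squares
solution; `warmup` steps are discarded and `draws` steps retained per
walker. Walkers play the role of chains in split-R̂ and effective-sample-size
diagnostics (the chains/warmup/draws vocabulary of single-chain samplers
maps onto walkers/burn-in/retained steps). R̂ > 1.05 on any parameter
attaches a non-fatal convergence warning. Runs are fully reproducible under
a seed.

**Model scoring.**

- *K-fold IC*: rows are partitioned into 10 balanced folds (sizes differ by
  ≤ 1; with n = 14 folds hold 1–2 fish) under a seeded permutation. Each
  fold is scored by the log pointwise predictive density of its held-out
  rows under the model refit on the remainder (log of the mean per-draw
  bivariate normal density); IC = −2 Σ lppd. Lower is better.
- *Bayesian R²*: per draw and response, Var(linear predictor) /
  (Var(linear predictor) + σ²), summarized by the posterior median; the
  model-level value is the mean of the two responses' medians (a one-number
  aggregation rule recorded in the output metadata).
- *Significance*: a coefficient is credible when its central 95% interval
  excludes zero.
- *Vector fitting*: each physiology variable is regressed (with intercept)
  on the three retained scores; r² is the squared multiple correlation, the
  direction is the normalized coefficient vector, and significance comes
  from permuting the variable across fish (999 permutations;
  p = (1 + #{r²* ≥ r²})/(1 + 999) ≥ 1/1000).

## Pipeline comparison

Thirteen pipelines (summary + 12 DTW variants) run end to end; the
comparison table reports cumulative variance of Dim1–Dim3 (descriptive
only), K-fold IC (the ranking criterion, ascending), Bayesian R², credible
dimensions/covariates and the chosen cluster count. A failed pipeline keeps
its row with NaN scores and never disturbs the others. A master seed fans
out per-pipeline sub-seeds via a CRC of the pipeline name, so adding a
pipeline does not shift the others' results.

Two effort modes: **reduced** (default; 500 warm-up + 500 retained steps,
50 gap bootstraps, 199 permutations) and **paper-scale** behind
`--paper-settings` (3000 + 1000 steps, 100 bootstraps, 999 permutations).
The reduced mode exists so that a full 13-pipeline comparison, including
10-fold refits for every pipeline, completes in a few minutes on one core;
with the initialization at the least-squares solution the posterior-mean
summaries are already stable at that budget, while tail quantiles and
diagnostics tighten under the full settings.

## Synthetic capture events

The generator emulates the target study conditions: 14 fish, fight
durations uniform on 57–177 s at 2-s cadence, ActVSum in [0, 2] g s⁻¹ with
a cross-fish mean near 1 g s⁻¹, per-fish inter-axis correlation targets
drawn from 0.6–0.94, ~3–12 bursts per fight, water temperature uniform on
12–18 °C, lactate centred near 16.5 mmol L⁻¹ and blood pH near 7.67.

Structure per fish: a shared burst envelope (exponentially decaying pulses
at Poisson times, rate 4 min⁻¹, decay 8 s) drives all three axes on a
0.44 g s⁻¹ baseline, the whole deterministic component fading linearly over
the fight by a per-fish factor drawn from 0.1–0.5 (fish tire, giving
early > late intensity and a positive fatigue index, and coupling the phase
metrics to the rest — which is also why three principal components carry
most of the summary-metric variance); correlated AR(1) noise (SD 0.22, lag
coefficient 0.3) tops the axes up to the fish's target inter-axis
correlation, solving the mixture equation for the noise cross-correlation
given the realized envelope and signal variances. The Y axis additionally carries a short-period (8-s)
oscillation whose amplitude is a per-fish latent u ~ U(0, 1) — a period
chosen to survive the 4-s high-pass. Physiology responds linearly to a
disturbance score combining that latent (γ_signal), z-scored cumulative
effort (γ_effort; effort is duration-driven, so every DTW pipeline carries
part of this term) and z-scored temperature (γ_temp); lactate adds the
disturbance to its baseline, pH subtracts a scaled version. The generative
truth (latents, coefficients, signal axis) is returned with the dataset for
recovery tests.

What the generator does **not** emulate: tag rotation on the swivel (an
optional random Y–Z rotation exists but defaults off, since the analysis
treats axes as logged), the tag's 0.4 g s⁻¹ ActVSum quantization (optional,
default off, because the printed resolution is inconsistent with reported
ActVSum means), hydrodynamics, species-specific behaviour, or any
depth/gear effects. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistical machinery under a plausible
generative model — not field validity of any biological conclusion.

## Problem sizes and calibration checks

The test suite exercises, among others: exact agreement of the DTW program
with path enumeration on 200 random pairs (lengths 2–12); PCoA recovery of
Euclidean geometry (n ≤ 12) to 1e-8; exact Ward/Lance–Williams agreement on
50 random 8-point configurations; gap-statistic recovery of three σ = 0.05
blobs (n = 60, B = 50) in ≥ 18/20 seeds; posterior recovery at n = 200 over
20 replicates (mean absolute coefficient bias < 0.1, 95%-interval coverage
within [0.85, 1]); K-fold IC preferring true over permuted predictors at
n = 100 in ≥ 8/10 replicates; and the constructed Y-over-X pipeline
ordering at n = 28 in ≥ 8/10 seeds. The 28-fish cohort for the ordering
check is deliberate: at n = 14 the K-fold IC's own sampling noise (a single
poorly-predicted held-out fish can shift the IC by hundreds of units)
swamps any real ordering for either axis.

## Known limitations

- With n = 14 and 7–8 design columns the posterior is prior-sensitive and
  credible intervals are wide; the K-fold IC is a high-variance estimate at
  this scale and should be read comparatively, not absolutely.
- The un-squared Ward convention and the dropped-negative-eigenvalue PCoA
  are conventions, not canon; both are flagged in output metadata.
- The exact high-pass filter and normalization transform used by other
  implementations of this workflow are not claimed to be equivalent to the
  ones documented here.
- DTW distances are not metrics in the mathematical sense (the triangle
  inequality can fail), which is one reason PCoA eigenvalues can be
  negative.
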