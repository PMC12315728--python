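# Methods

## Model

The package implements a linear generative model of regional resting-state
BOLD activity on a structural connectome.  Each region's signal decays
toward a connectome-weighted average of its neighbors, with the interaction
filtered by a Gamma-shaped ensemble impulse response
f(t) = (t/τ²)e^(−t/τ):

    dx/dt = −(1/τ) f ⋆ (L(α) x) + p(t),     L(α) = I − αC.

The two global parameters are the coupling constant α (unitless) and the
neural time constant τ (seconds); p(t) is white driving noise with scale σ.
Because f has the closed-form transform F(ω) = 1/(1 + jωτ)², the
steady-state signal spectrum and the model cross-spectral density (CSD) are
closed-form sums over the Laplacian eigenmodes; no time-domain simulation is
needed for fitting.  Assumptions worth stating explicitly:

- **Symmetric connectome.** The Laplacian must be Hermitian; directed
  connectomes are out of scope.
- **Spatially uniform parameters.** One (α, τ) pair for the whole brain;
  regional heterogeneity is absorbed by the eigenmode structure.
- **Excluded global mode.** The eigenmode sum starts at the second-lowest
  λ(α) after ascending sort.  The excluded mode is the most global one
  (largest connectome eigenvalue); dropping it parallels global-signal
  regression in empirical pipelines.  We apply the same exclusion to the
  CSD for internal consistency.
- **Scale indifference.** Both fitting objectives are Pearson correlations,
  so σ and any global scaling of the data are unidentifiable; σ defaults to
  1 and is exposed only for forward simulation.

## Coupling-scale convention

Connectome weights are first normalized by the sum of all entries
(`normalize_connectome`), which fixes the arbitrary tractography units but
leaves the spectral radius of C at O(1/N) — in that raw convention any
plausible α leaves L ≈ I and the model essentially uncoupled.  All
model-facing workflows therefore rescale C to unit spectral radius
(`scale_to_critical_coupling`), after which α reads as a *fraction of the
critical coupling*: L(α) loses positive definiteness exactly at α = 1.
Stability of the Gamma-filtered dynamics additionally requires
λ_k = 1 − αμ_k < 2 for every mode (a Routh–Hurwitz condition of the
third-order mode dynamics), i.e. α < 1/|μ_min|; the synthetic cohort keeps a
15% margin to this bound.

## Empirical comparators

The fitting cost is cost(α, τ) = |1 − spectral r| + |1 − FC r|.  What each
term compares against is configurable and deliberately paired:

- `fc_mode="at_peak"` compares the model CSD slice C_X(ω₀) against the
  percolation-thresholded real empirical CSD slice at the subject's
  peak-energy frequency ω₀ (the frequency maximizing the pairwise sum of
  |CSD|).  `fc_mode="integral"` compares the frequency-integrated model CSD
  (zero-lag FC) against the thresholded Pearson FC.
- `psd_mode="csd_diagonal"` compares power to Welch power.
  `psd_mode="signal_magnitude"` uses the coherent amplitude |X(ω)| under
  uniform driving; since that is an amplitude, the empirical comparator is
  the square root of the Welch PSD.

For parameter-recovery studies on synthetic data we default to
`integral` + `csd_diagonal`, because those are the definitions whose Welch
estimators are statistically consistent with the generated process: the cost
is then exactly zero at the generating parameters in the noiseless limit.
The `at_peak` + `signal_magnitude` pairing (the default of the estimator,
matching common practice on real recordings) is supported and tested but is
a poorer recovery instrument at 600-sample series — a single Welch CSD slice
is very noisy.

Welch estimation uses Hann tapers, 50% overlap, per-segment mean removal,
one-sided density scaling (so the PSD integrates to the variance), and a
default segment of min(T, 64) samples.  Cohort workflows at TR = 0.6 s and
T = 600 use 128-sample segments (8 averages, Δf = 0.013 Hz); recovery tests
spanning τ up to 3 s use 256 samples so the spectral knee λ/(2πτ) ≈ 0.01 Hz
is resolved.

## Eigenmode weighting (graph Fourier weights)

GFW_k = |(Uᴴ FC U)_kk| measures how strongly eigenmode k participates in
empirical FC; weights are rescaled to max 1 (only ratios matter under a
correlation cost) and are normally precomputed from cohort-mean FC and the
mean connectome's eigenvectors.  In the forward model the weight w_k
multiplies mode k's outer-product term, hence w_k² in the CSD.

## Fitting

Constrained minimization by L-BFGS-B with lower bounds 0 (time constants
floored at 10⁻⁶ s), upper bounds α ≤ 5, τ ≤ 20 s, at most 50 iterations and
tolerance 10⁻⁶, restarted from 5 Latin-hypercube points over
α ∈ [0.1, 1.5], τ ∈ [0.3, 5] s (the cost is mildly non-convex); the best
restart is kept and all reported metrics are recomputed at the optimum.
Non-finite forward output maps to a large penalty (10⁶) so the optimizer
never sees NaNs.  Fits are deterministic given the configuration seed.

The affine-invariant SPD geodesic ‖log(A^(−1/2) B A^(−1/2))‖_F is reported
as an additional distance between model and empirical FC but never enters
the cost.  Thresholded empirical FC matrices can be indefinite, so the
reporting path lifts both matrices just past positive definiteness with an
adaptive ridge; the standalone function uses the documented default ridge of
10⁻⁶ × mean diagonal.

## Time-domain simulator

The convolution dynamics are realized exactly as a 3N-dimensional linear
state space (the Gamma kernel is a critically damped second-order filter):
y = f ⋆ (Lx) obeys ÿ + (2/τ)ẏ + y/τ² = Lx/τ², and ẋ = −y/τ + p.  The state
is advanced by expm(A·dt) per step with white noise injected into the x
block (exponential-Euler; first-order in the noise, exact in the drift).
Instability (any state eigenvalue with positive real part) is detected
before integration and reported with the offending eigenvalue.  The
frequency response of this realization equals (jωI + F(ω)L/τ)⁻¹ to machine
precision, which the tests exploit as an oracle.

## Synthetic data: what it emulates and what it does not

`synthetic_connectome` draws two-hemisphere, modular, log-normally weighted
graphs: dense strong within-module edges (three modules per hemisphere by
default), frequent homologous interhemispheric edges, a weak spanning
backbone guaranteeing connectivity, then sum-normalization.  The modular
concentration puts several community eigenvalues near the spectral radius,
as community structure does in real streamline-weighted connectomes — this
is what makes coupling at α ≈ 0.8 dynamically meaningful.

`synthetic_bold` integrates the state space at dt = TR/5 with 30τ of burn-in,
decimates to TR, and adds observation noise of 0.2 × the per-region signal
SD.  A second backend synthesizes stationary Gaussian series directly from
the closed-form transfer function on an FFT grid; it is the only route that
supports nonuniform eigenmode participation and generates data exactly
within the fitted model class (no k = 1 mode).

Default cohort: 20 subjects, 30 regions, TR 0.6 s, 600 samples;
α ~ N(0.8, 0.15) clipped to [0.4, 0.92] and per-subject stability margins,
τ ~ N(2.0, 0.5) s clipped to [0.8, 4.0] s.  The α spread is wider than the
across-subject spread reported for real cohorts (≈0.09) so that regressing
fitted on true α across 20 subjects is statistically meaningful.

The generator does **not** emulate hemodynamic response variability, motion
or physiological artifacts, scanner drift, or regional parameter
heterogeneity.  A green recovery test therefore establishes estimator
consistency and identifiability under the model's own assumptions, not
robustness to real-world confounds.

Known identifiability limits of this world (documented, not hidden): α
carries little information when true coupling is weak (α* ≲ 0.4) or when τ
is large enough that the spectral knee leaves the 0.01–0.25 Hz band; in
those corners single-subject α errors approach 100% while τ remains tightly
recoverable from the spectra.

## Null models

Degree-preserving randomization performs Maslov–Sneppen double-edge swaps
(default 10 per edge) with each edge's weight travelling with it; swaps that
would disconnect the graph, create self-loops, or duplicate edges are
rejected, so the binary degree sequence is preserved exactly and the graph
stays connected.  Region permutation relabels time series (or conjugates
matrices) by one uniform permutation, which preserves eigenvalue spectra
while destroying regional correspondence.  Ensembles of fits under either
null are compared with true fits by two-sample two-tailed t-tests; the
degenerate zero-pooled-variance case returns t = 0, p = 1 when the means
coincide and is an error otherwise.

## Numerical conventions

- Eigenvalues λ(α) sorted ascending (equivalently connectome eigenvalues μ
  descending, an α-independent order); ties broken stably by original index;
  each eigenvector column's largest-magnitude entry is made positive.
- The percolation threshold is found by bisection over the sorted distinct
  off-diagonal magnitudes with a connected-components check; it equals the
  maximum-spanning-tree bottleneck (tested against an independent MST
  implementation).  Thresholding acts on |FC|; signed values are kept.
- Frequency integrals use trapezoidal weights on the analysis grid; a
  single-frequency grid returns the slice unscaled.
- "Typical connection weight" for homologous-edge augmentation is the mean
  of nonzero entries; augmentation happens before re-normalization.
- All randomness flows from user-supplied seeds through
  `numpy.random.default_rng`; cohort generation derives per-subject seeds
  from a single master seed.
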