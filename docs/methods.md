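# Methods

This note documents the models implemented in `primsel`, the fitting and
scoring procedures, the numerical choices that shape the results, what the
synthetic benchmark does and does not emulate, and the known limitations.

## Generative models

All four blind-source-separation families share the observation model
`X = reconstruction(Θ) + ε` with i.i.d. Gaussian noise of standard
deviation σ_n, over a J×T signal matrix (J trials/signals, T time points
on the grid t_m = m/fs seconds).  Data are centered per signal before
fitting; the removed row means are stored on the fitted model so
reconstructions can be mapped back to signal units.

* **pPCA** — instantaneous mixture `W S`; sources i.i.d. N(μ, σ²), weights
  i.i.d. N(0, σ_w²).
* **ICA** — as pPCA, but each source value has density
  `p(s) ∝ exp(−(s−μ)²/(2σ²) + λ G(s−μ))` with contrast `G(u) = log cosh u`.
  The normalizer `Z(μ,σ,λ)` is evaluated by adaptive quadrature
  (relative tolerance 1e−10) over a range covering both the Gaussian core
  and the exponential tilt (±(12σ + |λ|σ²)); it is translation-invariant
  in μ.  λ = 0 recovers pPCA exactly.
* **SIM** — smooth instantaneous mixture: each source row is a draw from a
  Gaussian process with the wave kernel
  `k(t,t′) = σ² sinc(2 f₀|t−t′|)` (normalized sinc), the covariance of an
  ideal low-pass process with cutoff f₀ Hz.  The kernel amplitude is tied
  to the source-prior variance σ² so that f₀ = ∞ (diagonal covariance)
  reproduces pPCA exactly — SIM nests pPCA.
* **AMM** — anechoic mixture: `X_jt = Σ_i W_ji S_i(t − τ_ji)` with the SIM
  source prior plus an exponential delay prior with mean γ samples,
  `p(τ) = (1/γ) e^{−τ/γ}` (mean-γ convention), favouring delays sparsely
  different from zero.

Delayed evaluation uses periodic band-limited (Whittaker–Shannon)
interpolation implemented in the DFT domain; integer delays reduce to
exact circular shifts and fractional delays are differentiable in τ.  For
even T the Nyquist bin is multiplied by cos(πτ) to keep the output real;
note that the adjoint-composition identity `R(a)ᵀR(b) = R(b−a)` then fails
at the Nyquist bin, which the normal-equation and Hessian assemblies
account for explicitly.

### Wave-kernel Gram matrix and jitter

The sampled sinc Gram matrix is severely rank-deficient whenever
f₀ ≪ fs/2 (its numerical rank is ≈ 2·f₀·T/fs + 1).  A diagonal jitter is
added before factorization.  The jitter is a modelling quantity, not just
a numerical one: it is the prior variance of out-of-band source
fluctuations, i.e. it decides how *soft* the band-limitedness constraint
is.  The default is `1e−4 × amplitude` (out-of-band sd = 1% of source sd),
escalating tenfold on factorization failure up to `1e−2 × amplitude`.
A much smaller jitter turns the smoothness preference into a near-hard
constraint that vetoes realistic signals — filtered trajectories are only
approximately band-limited, with relative out-of-band energy around
1e−5…1e−3 — and measurably distorts model comparison on such data.

## Fitting

Each candidate (family, I, f₀) is fitted in two phases.

**Phase 1 — algorithmic initialization.**  Truncated SVD of the centered
data with the energy split symmetrically between weights and sources
(pPCA/SIM); SVD followed by a FastICA rotation of the source space (ICA);
SVD plus a per-(signal, source) integer delay chosen by circular
cross-correlation (AMM).  Deterministic given the seed.

**Phase 2 — MAP optimization with empirical-Bayes updates.**  The Θ-step
minimizes the negative log joint at fixed Φ by alternating exact Gaussian
conditional solves — ridge regression per signal row for W, and the full
(I·T)-dimensional Gaussian normal equations for S (solved in the separable
eigenbasis for instantaneous families, densely from circulant blocks for
AMM) — with a joint L-BFGS-B polish over the flattened parameters (bounds
τ ∈ [0, T−1]; analytic gradients except the delay components, which use
central differences of step 1e−4 samples).  The conditional solves are
essential: quasi-Newton iterations alone converge too slowly in the stiff
out-of-band directions of low-f₀ kernels, and the resulting
under-optimized fits systematically distort the evidence comparison.

For AMM two additional likelihood-aware moves run inside the Θ-step, both
safeguarded to only ever lower the objective:

* a greedy integer-lag rescan of each (τ_ji, W_ji) pair over all circular
  lags (the objective is highly non-convex in the delays; gradient steps
  only refine them locally);
* a global per-source shift along the likelihood-invariant direction
  `(S_i, τ_{·i}) → (R(d) S_i, τ_{·i} − d mod T)`.  The reconstruction is
  unchanged but the smoothness prior is not: it anchors each source at the
  shift where the source has no wrap-around discontinuity inside the
  window.  This also resolves the delay/shift identifiability freedom —
  with a smoothness prior that direction is *not* flat, so no explicit
  re-anchoring of delays is applied (forcing min_j τ_ji = 0 would drag the
  wrap discontinuity into the source and be vetoed by the prior).

The Φ-step uses closed-form moment updates: σ_n² ← mean squared residual
(floored at 1e−8), σ_w² ← mean(W²), μ ← mean(S), σ² ← mean((S−μ)²)
(the wave kernel's diagonal equals its amplitude, so this is an unbiased
amplitude estimator that is insensitive to the kernel's near-null
directions), γ ← mean(τ) floored at 0.5, and λ by a grid search over
[−3, 3] maximizing the ICA source log-prior.  Every Φ candidate is
accepted only if it does not increase the negative log joint, so the
objective trace is non-increasing by construction.

The outer [Θ-step; Φ-step] alternation is deliberately capped (default 4
rounds).  Iterating it to convergence is ill-posed: under repeated
re-estimation of the prior scales the joint MAP objective drifts downward
without bound (a slow variance-collapse degeneracy — sources shrink, the
source-prior scale follows, weights grow), so "outer convergence" is not a
meaningful target.  The default realizes the two-phase procedure plus
refinement rounds that re-optimize Θ under the re-estimated Φ, which makes
the Laplace expansion point a genuine minimum of the scored objective;
anechoic fits need the extra rounds for the noise scale to co-adapt with
the delay estimates.  The `converged` flag reports Θ-step convergence.

## Scoring and selection

The evidence of a fitted candidate is approximated by
`LAP = loglik + logprior + (F/2)·log 2π − ½·log|H|` with
`F = J·I + I·T (+ J·I for AMM)`; hyperparameters are excluded from F.
`H` is assembled from analytic blocks (weight–weight, source–source,
weight–source, including the circulant shifted-source couplings for AMM)
with central finite differences for all delay-involving blocks, then
symmetrized.  `log|H|` uses eigenvalues clipped from below at
`1e−8 × max(eig)`, which regularizes residual flat directions (e.g. soft
identifiability violations) instead of letting them produce an infinite
posterior volume.  BIC uses N = J·T total scalar observations.

`select_model` scans the candidate grid, records per-candidate failures
without aborting, and picks per-criterion winners with a relative tie
tolerance of 1e−6.  Ties resolve toward parsimony: fewer sources, then the
simpler family (pPCA < ICA < SIM < AMM), then the smaller cutoff.  The
family order matters on noiseless rank-I data, where every instantaneous
family reconstructs to the noise floor and BIC/AIC are exact ties; the
least-assuming family (pPCA) then wins, which is also the behaviour that
makes BIC/AIC blind to soft constraints.  pPCA is the f₀ = ∞ member of
the SIM column and is scored once.

## Synthetic benchmark

The generator emulates kinematic-like trajectories: per source, 100
standard-normal samples low-pass filtered by a 6th-order Butterworth
(zero-phase, forward–backward) at 5 or 10 Hz, at fs = 100 Hz (1 s
duration); weights uniform on [−10, 10]; AMM delays exponential with mean
20 samples, kept continuous and reduced mod T (periodic shifts make
delays equivalent mod T); multiplicative signal-dependent Gaussian noise
with sd = α·|x(t)|.  The slope α is calibrated by incrementing from zero
until the realized noise level 1−R² (total-variation-based multivariate
R²) stays within ±0.01 of the target for 10 consecutive increments; the
increment adapts to the level-vs-α slope and each level estimate averages
enough fresh draws that its Monte-Carlo sd is below a third of the
tolerance, otherwise the 10-in-a-row stopping rule is unreachable on
small or steep datasets.  The full factorial design is 2 families × 2
cutoffs × 4 source counts × 3 noise levels = 48 conditions, each at
J ∈ {5, 10, 25} trials with 20 replicates, with per-dataset child seeds
derived deterministically from the master seed.

What the generator does **not** emulate: motion capture and skeleton
fitting, Euler-angle computation, gait-cycle extraction or time
normalization of real recordings; real kinematic data are also not
periodic, not exactly band-limited and not corrupted by exactly
signal-proportional noise.  Passing benchmark tests therefore demonstrates
internal consistency of criterion and generator, not performance on any
particular recording system.

### Scaled-down study sizes

The replication experiments run at reduced scale, chosen once: generating
source counts I ∈ {1, 2} with the analysis source count fixed at the
generating one; 12 datasets per smoothness cell (3 replicates × 2 cutoffs
× 2 source counts) with the full f₀ grid {1…15 Hz, ∞}; 10 datasets for
model-type detection with the grid {5, 10} Hz and all four analysis
families.

## Behaviour on the benchmark, and limitations

* On noisy data the LAP score is unimodal in f₀ with its peak at (or one
  step above) the generating cutoff, and LAP identifies the SIM family
  where BIC and AIC fall back to pPCA.  The residual positive bias of the
  selected cutoff traces to the generator: a zero-phase Butterworth has a
  transition band extending above its nominal cutoff (wider at 10 Hz than
  at 5 Hz), and the brickwall wave kernel must cover that band to explain
  the signal, so the evidence peak sits where the rolloff crosses the
  noise floor.
* On exactly noiseless data the residual hits the σ_n² floor of 1e−8 and
  the likelihood precision (~1e8) amplifies every remaining spectral
  detail; cutoff selection then chases the filter rolloff further upward
  (bias ≈ +1–2 Hz beyond the noisy case, up to the grid cap for 10 Hz
  generators).  This is a property of evidence comparison at effectively
  infinite SNR, not of the approximation itself (the analytic oracles hold
  to 1e−6 and better).
* Single-source anechoic recovery is exact (delay differences recovered to
  well under one sample on noiseless data).  Multi-source (I ≥ 2) anechoic
  mixtures often converge to entangled local minima under the simple
  SVD-plus-cross-correlation initializer; a dedicated anechoic demixing
  initializer (time-frequency based) would be required for reliable
  multi-source delay recovery and is out of scope here.  Model-*type*
  detection on anechoic data is unaffected (instantaneous competitors fit
  such data far worse).
* The ICA family's λ is fitted by maximizing the source prior, which gives
  ICA a small evidence advantage over pPCA on any finite sample; on
  noiseless smooth data it occasionally edges out the SIM candidates
  whose exact-cutoff kernels pay for the generator's rolloff.
* Scale freedom between W and S is broken only softly by the priors; the
  moment-based Φ updates track the chosen scale rather than fixing it.
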