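# Methods

## Model and algorithm

The observed signals are assumed to follow the noiseless linear ICA model
**X** = **A S**, with **X**, **S** ∈ ℝ^(N×M), an invertible mixing matrix
**A** ∈ ℝ^(N×N), and rows of **S** that are normalized, mutually
independent, sample-i.i.d., and non-Gaussian (no symmetric Bernoulli
source). Channels are rows throughout. The number of components is fixed
at N.

Separation proceeds on whitened data X̃ (zero mean, covariance X̃X̃ᵀ/M = I).
For each component i = 1…N:

1. Draw L initial directions from the standard Gaussian, project off the
   span of the accepted rows (the projector E = WᵀW), and normalize.
   Directions that vanish after projection (norm ≤ 10⁻¹²) are resampled
   from the same substream — a probability-zero event for Gaussian draws.
2. Iterate the cubic fixed-point update
   w ← X̃(y∘y∘y)ᵀ/M − 3w, y = wᵀX̃, followed by deflation (w ← w − E w)
   and normalization, for at most K cycles.
3. Score every *converged* candidate by Υ(α) = α − 2 log(α/2 + 1) of its
   estimated excess kurtosis α = Σy⁴/M − 3 and append the argmax to W,
   breaking ties by lowest restart index so the reduction is a
   deterministic function of the candidate list.

If every restart of a step fails to converge, the step is retried once
with a fresh batch of substreams; a second total failure raises an error
naming the component. Non-converged candidates never enter the argmax:
their α sits on no extremum and is not meaningful.

**Convergence rule.** A fixed point of the cubic update is only defined up
to sign (the update is odd in w), so the stopping rule is
min(‖w − w_prev‖, ‖w + w_prev‖) ≤ ε — direction fixed up to sign, the
standard criterion for this iteration.

**Reproducibility.** Restarts within a step are independent tasks. Each
(component, restart, attempt) triple seeds its own `SeedSequence`
substream of the master seed, so the result is bit-identical whether the
tasks run serially or under any joblib worker count.

## Parameters

| name | meaning | default | rationale |
|------|---------|---------|-----------|
| L | restarts per deflation step | 64 (API); `round(cores × R)` in the CLI | more restarts only improve the chance of hitting the global extremum; tying L to the core count makes the parallel scheme free |
| R | overhead rate | 1 | L beyond the core count costs proportionally more time |
| K | max fixed-point cycles per restart | 30 | individual restart failures are harmless, so a small budget suffices |
| ε | convergence threshold | 10⁻⁶ | below this, further tightening does not change which extremum is found |
| rank_tolerance | relative covariance eigenvalue cutoff | 10⁻¹⁰ | rank deficiency must raise, not silently reduce N |
| ε (success) | divergence defining "same solution" | 0.001 | well below the δ of distinct extrema, well above convergence noise |
| L_max | restarts retained for estimating μ̄ᵢ | 1000 | resolves success rates down to 10⁻³ |
| cond_cap | condition-number cap for synthetic mixing | 100 | keeps the benchmark mixtures invertible but non-trivial |

## Whitening

Whitening uses the SVD of the centered data rather than an explicit
covariance eigendecomposition (better conditioning), with the covariance
normalized by M — the same moment convention as the kurtosis estimator.
The transform is PCA whitening, T = Λ^(−1/2)Uᵀ; when the covariance
spectrum is (near-)degenerate, as for mixtures of equal-variance
uncorrelated sources, U — and hence the whitened frame — is an arbitrary
rotation of the source frame. All recovery metrics therefore compare
directions through the composite map W·T·A, never against raw coordinates.

## Evaluation statistics

Runs are aligned by sorting each run's rows by Υ(α) descending — rank
alignment, exactly as the fluctuation metric is defined, not an optimal
assignment. Missing components (a run that produced fewer rows) enter
every pairwise comparison with the maximal divergence 1. The success-rate
regression is unweighted OLS in log₁₀–log₁₀ space. A component whose
restarts all diverged is reported as NaN and excluded from the regression
and failure-rate vectors.

## Synthetic benchmark generator

Sources are drawn i.i.d. per sample from families with known analytic
excess kurtosis κ — Laplace (3), uniform (−1.2), Gaussian (0), generalized
Gaussian with shape β (Γ(5/β)Γ(1/β)/Γ(3/β)² − 3), Student t with df > 4
(6/(df − 4); the restriction keeps κ finite), and a symmetric two-Gaussian
mixture with half-separation a (−2a⁴/(1 + a²)², from the mixture moments) —
then exactly standardized per row. The symmetric Bernoulli family (κ = −2,
the boundary where Υ is undefined) exists only behind an explicit
`allow_excluded` flag for negative tests. Mixing matrices are Gaussian
draws redrawn until their condition number is at most `cond_cap`.

What the generator emulates is the generative model the uniqueness theory
assumes: independent, sample-i.i.d., non-Gaussian rows under invertible
mixing. It deliberately does not emulate real electrophysiological data:
no temporal autocorrelation, no nonstationarity, no sensor noise, no
volume-conduction forward model. Passing tests therefore demonstrate the
algorithmic guarantees (ordering, uniqueness, recovery) under the model's
assumptions, not separation quality on real recordings.

## Problem sizes used in the test suite

End-to-end checks run at sizes where the statistical guarantees are
already sharp: ordered recovery on 3-source mixtures at M = 10⁵ with
L = 64 over 20 seeds; brute-force grid comparison for N = 2 at M = 2×10⁴
over 10 seeds with a 3600-point angle grid; stability of a 5-source
super-Gaussian mixture (generalized-Gaussian shapes 0.7–1.5, κ from ≈8 to
≈0.76) at M = 5×10⁴ with T = 10 runs; distributional property tests at
M = 10⁶. These are the package's chosen benchmark conditions; larger M
only tightens the sample estimates.

## Numerical choices and degenerate inputs

- Υ is evaluated as α − 2·log1p(α/2) for accuracy near α = 0, and raises
  for α ≤ −2.
- Candidate selection excludes non-finite α and α ≤ −2 (a sample row can
  only reach α = −2 if it is exactly two-valued).
- The forced final component (1-D residual subspace) converges in one
  cycle: the deflated update collapses to ± the remaining direction.
- Sample covariance eigenvalues below 10⁻¹⁰ of the largest raise a rank
  error naming the number of deficient dimensions.
- Delimited text is the canonical interchange format; `.npy` is accepted
  as a binary container for large M. Output formatting is deterministic,
  so identical seeds produce byte-identical run directories.

## Known limitations

- Kurtosis is the only contrast; the robust nonlinearities of other
  FastICA variants (tanh, gauss) and symmetric (non-deflation) estimation
  are out of scope.
- Deflation accumulates estimation error into later components; the
  ordering only mitigates the *selection* instability, not this error
  accumulation.
- Sources with nearly equal Υ(κ) can swap ranks between runs through
  sampling noise in α; rank alignment then overstates the fluctuation.
- Heavy-tailed sources (Student t with df near 4) have high-variance
  kurtosis estimates; ordering among them is only as stable as those
  estimates.
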