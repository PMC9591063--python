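# orderica

Unique, globally ordered blind source separation for multichannel signals
(the *ordering ICA*), with run-to-run stability statistics and a
ground-truthed synthetic benchmark generator.

## The problem

Independent component analysis (ICA) recovers unobserved sources **S** from
linear mixtures **X** = **A S** (N channels × M samples) by maximizing the
non-Gaussianity of the unmixed rows. It is the standard tool for separating
EEG recordings into physiological and artifact components. Classical
deflation FastICA, however, converges to whichever local extremum of the
kurtosis its random initialization falls into, so the solution — and the
order of its components — changes from run to run. That fluctuation
undermines downstream analysis.

The ordering ICA removes the ambiguity. At each deflation step it launches
*L* independent restarts of the kurtosis fixed-point iteration, scores each
converged candidate *w* (with unmixed row *y = wᵀX̃* and estimated excess
kurtosis α = Σₘy⁴ₘ/M − 3) by the convex transform

    Υ(α) = α − 2·log(α/2 + 1),        Υ ≥ 0,  Υ(0) = 0,

and keeps the candidate with the largest Υ. Because Υ is convex, its
constrained global maximum is attained at one of the local extrema of α —
exactly the fixed points the restarts find. Given enough restarts the
components come out in descending order of Υ(κᵢ) of the true sources and
the separating matrix **W** is unique up to sign, provided no source is a
symmetric Bernoulli variable (excess kurtosis −2, where Υ is undefined).
Restarts are embarrassingly parallel, and each (component, restart) pair
draws from its own seeded substream, so results are bit-reproducible for
any worker count.

The package also implements the statistics that quantify this uniqueness:
the sign-invariant divergence δ = 1 − |cos| between matched components of
repeated runs and its pairwise mean δ̄(i); the single-restart success rate
μ̄ᵢ = #{candidates within δ < ε of the best}/L_max; the failure rates
νᵢᵉᵃᶜʰ = (1 − μᵢ)ᴸ and their cumulative recurrence; the log–log regression
log₁₀μ = β̂₁ + β̂₂·log₁₀Υ; and the analytic bound (1 − 10⁻¹·⁵)ᴸ for strongly
non-Gaussian components (Υ > 10).

## Worked example

```python
import orderica as oi

# three sources with known excess kurtosis: Laplace (3), uniform (-1.2),
# Gaussian (0), mixed by a random well-conditioned matrix
x, truth = oi.make_dataset(["laplace", "uniform", "gaussian"],
                           n_samples=100_000, seed=3)
res = oi.run_ordering_ica(x, l_candidates=64, seed=3, whiten_input=True)
print("alpha   ", res.alphas)
print("Upsilon ", res.upsilons)
scores, order_ok = oi.recovery_score(res, truth)
print("recovery", scores, "ordered:", order_ok)
```

prints

```
alpha    [ 3.13049732 -1.20242314 -0.01110167]
Upsilon  [1.24638648e+00 6.36225368e-01 3.09262601e-05]
recovery [0.99991671 0.99998578 0.99988577] ordered: True
```

The components come out in descending Υ — Laplace first (α ≈ 3), uniform
second (α ≈ −1.2), Gaussian last (α ≈ 0) — and each estimated unmixing
direction is within |cosine| ≥ 0.999 of its true source, i.e. the mixture
is separated and the extraction order matches the theory.

The same pipeline is available from the shell:

```bash
orderica simulate --families laplace,uniform,gaussian --samples 100000 \
         --seed 3 --output-dir sim/
orderica run --input sim/X.csv --candidates 64 --seed 3 --output run0/
orderica run --input sim/X.csv --candidates 64 --seed 4 --output run1/
orderica fluctuation run0 run1 --output delta.csv
orderica success-rate --input sim/X.csv --l-max 1000 --candidates 64 \
         --output succ/
```

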