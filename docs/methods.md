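# Methods

## Model and assumptions

The process is the frequency-dependent Moran model: a well-mixed population
of fixed size `N ≥ 2` with two strategies `A` and `B`, payoffs from a
symmetric 2×2 game `(a, b; c, d)` with self-interaction excluded (division by
`N − 1`), and the exponential payoff-to-fitness mapping `f = exp(β·π)`.  The
exponential mapping keeps fitness positive for arbitrary payoff signs and any
selection intensity `β ≥ 0`, and turns the product of transition ratios that
appears in the fixation probability into a sum of payoff differences:
`γ^i = T^{i−}/T^{i+} = exp(β(π_B^i − π_A^i))`.  The mapping is recorded as a
named constant on `ModelParams`; no linear mapping is offered (a constant
background fitness `f₀` would cancel from every ratio under the exponential
mapping and is therefore not a parameter).

Each step draws one birth proportional to fitness and one uniform death, so
the state `i` (number of `A` players) changes by at most one: the chain is a
birth–death process, absorbing at `0` and `N` when the mutation probability
`μ` is zero, ergodic with reflecting-ish boundaries (`T^{0+} = T^{N−} = μ`)
when `μ > 0`.  Mutation acts on the offspring: with probability `μ` the
offspring is of the type *not* chosen for birth.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `N` | population size | — | integer ≥ 2; all vectors are indexed 0..N |
| `beta` | selection intensity | 0 | `β = 0` is neutral drift; `βN ≫ 1` is strong selection |
| `mu` | mutation probability per birth | 0 | must be > 0 for stationary questions, 0 for fixation questions |
| `epsilon` | stopping tolerance | 0.01 | absolute for the Chebyshev rule, relative for the moving-average rule, KL threshold for stationarity |
| `delta` | allowed failure probability | 0.01 | Chebyshev rule only |
| `r0` | initial realisations / warm-in steps | 100 | stationary estimation scales it to `100·N` |
| `batch_size` | realisations (steps) added per stopping check | 100 | stationary estimation scales it to `10⁵·N` |
| `max_steps` | per-realisation cap (total-run cap for stationarity) | 10⁸ | breach raises a budget error rather than silently truncating |
| `total_step_cap` | overall budget for conditional-time sampling | 10⁸ | guards the regime where fixation is too rare to condition on |

The simulation defaults (`r0 = 100`, `batch_size = 100`, `ε = 0.01`) are the
standard operating point for fixation experiments; the stationary-estimation
defaults grow with `N` because the mixing time does.

## Direct method

All direct routines are O(N) single-loop evaluations of the closed-form
solution of the Master equation:

* `fixation_probability` keeps a running product of `γ^i` and reduces with
  compensated (`math.fsum`) summation.  A `log_domain=True` mode accumulates
  `log γ` and reduces with log-sum-exp, usable when the products leave double
  range (at `β = 100` on modest payoff differences `γ` alone reaches ~10⁸⁴;
  the plain mode raises `GammaOverflowError` naming the alternative rather
  than returning infinities).  The O(N²) double-loop variant is retained
  solely as a test oracle.
* `unconditional_fixation_time` uses
  `τ¹ = φ_A¹ Σ_l R^l / T^{(N−l)+}` with the recursion
  `R^{l+1} = 1 + γ^{N−l} R^l`, all-positive arithmetic.
* `conditional_fixation_time` uses `τ_A¹ = Σ_l ψ_A^l R^l / T^{(N−l)+}` with
  `ψ_A^l = φ_A^{N−l}`.  The ψ values are computed as prefix sums of the
  memorised γ-products, `ψ_A^l = φ_A¹ · S_{N−l}` — algebraically identical to
  the running-subtraction recursion `ψ^h = ψ^{h−1} − φ¹·Πγ`, but
  subtraction-free.  This matters: for the bistability game at `N = 500`,
  `β = 1` the fixation probabilities span ~56 orders of magnitude and the
  subtraction form returns large negative garbage, while the prefix-sum form
  agrees with the matrix method to ~14 digits.
* `stationary_distribution` accumulates the detailed-balance log-ratios
  `Σ log(T^{i+}/T^{(i+1)−})` and normalises with a softmax, which is the
  same two-pass product-then-normalise algorithm expressed in the log domain
  so that strong selection cannot overflow the unnormalised products.
* `weak_selection_D` returns the first-order payoff-difference sum
  `D = Σ_{k<N} Σ_{i≤k} (π_A^i − π_B^i)` and the sign condition `D > 0`
  (selection favors invasion of `A` for small `β`).  Only the sign is
  normative: the magnitude of the O(β) coefficient of `φ_A¹(β) − 1/N`
  depends on a mapping-dependent prefactor that the sign condition does not
  need.

## Matrix method

The transition matrix is tridiagonal, so each quantity is a banded linear
solve over the transient states: `(Q − I)φ̃ = −v₂` for fixation
probabilities, `(Q − I)τ̃ = −1` for unconditional times, the same system on
the fixation-conditioned (Doob-transformed) kernel
`T_A^{i±} = (φ^{i±1}/φ^i) T^{i±}` for conditional times, and — fixing
`p⁰ = 1` — the partitioned system `C p* = −v₂` on `(T − I)ᵀ` for the
stationary distribution.  Only the three bands are stored; nothing is ever
materialised as a dense matrix.

**Solver.**  These systems become spectacularly ill-conditioned under
selection: the condition number of `I − Q` is of the order of the mean
absorption time, which for the coexistence game at `N = 500`, `β = 1` is
~10⁵⁶.  A textbook partially-pivoted banded LU (`scipy.linalg.solve_banded`)
then returns pure noise — negative "probabilities" with relative error 1.
All four systems are, however, tridiagonal M-matrices whose diagonal is
*exactly* `T^{i+} + T^{i−}` and whose right-hand sides are nonnegative, so
Thomas elimination can be written subtraction-free: writing the pivot as
`d_j = up_j + e_j` and updating the dominance surplus as
`e_j = down_j · e_{j−1} / d_{j−1}` involves only sums, products and quotients
of positive numbers.  Forward and backward substitution with a nonnegative
right-hand side are likewise subtraction-free.  Every intermediate therefore
carries a small componentwise relative error regardless of conditioning, and
the two exact methods agree to ≤ 2·10⁻¹³ elementwise over the full canonical
sweep (N up to 500, β up to 1), including fixation probabilities of order
10⁻⁵⁶.  No pivoting is required (the matrices are diagonally dominant), and
no iterative refinement is used.

A dense pathway for chains whose transition matrix is not banded
(Wright–Fisher-type models) is a natural extension seam but is intentionally
not implemented.

## Simulation

`naive_step` draws one birth and one death event.  Because most steps change
nothing, the production sampler is the jump-chain form: the holding time
until the next change is geometric with success probability
`1 − k` where `k = m_b·m_d + (1−m_b)(1−m_d)` is the stay probability, and the
direction of the change is up with probability `f_A/(f_A+f_B)`.  The
geometric convention is "number of trials up to and including the change"
(support 1, 2, …), which makes the elapsed-step accounting exactly
distributionally equivalent to iterating naive steps — verified by a
chi-square test on (direction, holding-time) at 10⁵ samples.  The same
acceleration applies under mutation, where at a monomorphic boundary the
per-step change probability is exactly `μ` (note that `μ = 1` does *not*
remove staying: picking different types for birth and death with a mutated
offspring can reproduce the dead individual's type).

Stopping rules:

* **Fixation probability** — Chebyshev: sampling continues until the
  realisation count exceeds `X̄(1−X̄)/(δ·ε²)`, guaranteeing
  `P(|X̄ − φ| ≥ ε) ≤ δ` for the Bernoulli indicator.  The bound is
  conservative, so observed coverage is well above `1 − δ`.  The count is
  capped above by `r0 + 0.25/(δε²)` plus one batch, independent of `N`.
* **Fixation times** — moving average: after `r0` realisations the cumulative
  mean is recomputed per batch and sampling stops when its relative change
  drops to `ε`.  In conditional mode only fixation runs are retained; `r0`
  and `batch_size` count retained runs, discarded runs are reported, and a
  separate total-step budget aborts informatively when fixation is too rare.
* **Stationary distribution** — one long run accumulating a *time-weighted*
  occupancy histogram: a holding time of `g` steps credits the pre-jump
  state with `g` counts.  Without this weighting the histogram would
  estimate the jump-chain distribution, which is wrong.  Cumulative
  snapshots taken every `batch_size` effective steps are compared with the
  Kullback-Leibler divergence `D_KL(new‖old)` (natural log); the run stops at
  `D_KL ≤ ε` or is flagged unconverged at the step cap.  Snapshots are
  cumulative from the start rather than windowed, matching the
  interpretation of the histogram as "the distribution at step t·k"; a
  windowed variant would be a straightforward extension.  For the KL
  comparison both histograms receive one pseudo-count per cell before
  normalising, so early empty states cannot produce divisions by zero; the
  returned distribution is the raw normalised histogram.

Randomness comes from a single seedable `numpy.random.Generator` per run
(PCG64).  Given the same seed and configuration every estimator is
bit-reproducible.

## What the simulator's defaults emulate — and what they do not

The canonical games (dominance `(1,1,0,0)`, coexistence `(0,1,1,0)`,
bistability `(1,0,0,1)`) span the three qualitative regimes of 2×2 dynamics
and are the fixtures for all cross-method validation.  Passing tests show
that the three method families agree *on this model*: a one-dimensional,
well-mixed, discrete-time chain.  They say nothing about structured
populations, more than two strategies, or continuous time.  Two documented
hard regimes are reproduced rather than hidden: conditional-time estimation
discards almost all runs when the mutant is strongly disfavored, and the
single-run stationary estimator fails (unconverged flag or large divergence
from the exact answer) for the bistability game under strong selection and
low mutation, where the chain sits at one boundary for ~1/μ steps at a time.
Averaging several runs from dispersed initial conditions would mitigate
this; it is not implemented.

## Problem sizes used in the tests

Unit tests run at `N ≤ 60` with statistical checks at 2–4·10⁴ samples; the
end-to-end checks use the canonical sweep up to `N = 500`, 200 meta-replicates
for stopping-rule coverage, 10⁵ samples for the jump-chain equivalence
chi-square, and a stationary run at `N = 20`, `μ = 0.1`, `β = 0.1` that
converges within ~4·10⁶ effective steps.  The whole suite takes well under a
minute on one CPU.

## Known limitations

* Fixation times overflow double precision around `τ ~ 10³⁰⁸`; the direct and
  matrix methods raise or return `inf` there.  The log-domain mode covers the
  fixation *probability* at arbitrary `β`, but no log-domain time computation
  is provided.
* The direct conditional time is reported for the single-mutant start state
  only; the matrix method returns the whole vector.
* The stationary simulation uses one trajectory; multi-start averaging for
  metastable regimes is out of scope.
* The CLI accepts only the flat key=value config format; no YAML.
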