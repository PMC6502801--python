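# moranfix

Exact, matrix-based and Monte Carlo computation of **fixation probabilities,
fixation times and stationary distributions** for the Moran process with a
symmetric 2×2 game in a finite, well-mixed population.

Evolutionary game dynamics in finite populations is the workhorse model for
questions like *"will a single mutant strategy take over?"* and *"where does
a mutating population spend its time in the long run?"*. The answers are
simple in principle — they solve a one-dimensional birth–death Markov chain —
but in practice every research group recomputes them with ad-hoc code that is
either quadratic-time, numerically fragile under strong selection, or
simulated without a defensible stopping rule. `moranfix` packages the three
standard method families behind one consistent interface so that each can be
checked against the others:

* **direct** — O(N) closed-form recursions;
* **matrix** — O(N) banded solves on the tridiagonal transient-state system;
* **simulation** — accelerated Monte Carlo with principled stopping criteria.

It is aimed at researchers and students in evolutionary game theory and
population genetics who need trustworthy reference values, and at
simulation authors who want an exact oracle to validate against.

## Model

A population of `N` individuals carries two strategies, `A` and `B`, with
payoff matrix

```
        A  B
   A  ( a  b )
   B  ( c  d )
```

The state is `i`, the number of `A` players. Average payoffs exclude
self-interaction,

    π_A^i = (a(i−1) + b(N−i)) / (N−1),    π_B^i = (c·i + d(N−i−1)) / (N−1),

and map to fitness exponentially, `f = exp(β·π)`, where `β ≥ 0` is the
selection intensity (`β = 0` is neutral drift). Each time step one individual
reproduces proportional to fitness and one dies uniformly at random, giving
one-step probabilities `T^{i±}` and the transition ratio
`γ^i = T^{i−}/T^{i+} = exp(β(π_B^i − π_A^i))`.

Key quantities:

* fixation probability of a single mutant,
  `φ_A^1 = ( Σ_{k=0}^{N−1} Π_{i=1}^{k} γ^i )^{−1}`;
* unconditional fixation time `τ^1` (expected steps to either absorbing
  state) and conditional fixation time `τ_A^1` (expected steps to all-`A`,
  averaged over runs that fixate);
* with mutation probability `μ > 0` the boundaries are no longer absorbing
  and the long-run behaviour is the stationary distribution `p^k`, obtained
  from detailed balance.

## Worked example

```python
from moranfix import (Game, ModelParams, fixation_probability,
                      unconditional_fixation_time, conditional_fixation_time,
                      estimate_fixation_probability, StoppingConfig)

game = Game(1, 1, 0, 0)            # dominance: A always earns more than B
params = ModelParams(N=50, beta=0.1)

print(fixation_probability(params, game))       # 0.09580813208007742
print(unconditional_fixation_time(params, game))  # 298.5820247072596
print(conditional_fixation_time(params, game))    # 1896.7082754194191

est = estimate_fixation_probability(
    params, game, StoppingConfig(epsilon=0.01, delta=0.01, seed=1))
print(est.mean, est.n_realisations)             # 0.09911633109619687 89400
```

A single `A` mutant in a population of 49 `B`s fixates with probability
≈ 0.0958 — almost five times the neutral value `1/N = 0.02`, because the
dominance game favors `A` at every mixed state. Absorption takes ≈ 299 steps
on average, but the runs that actually end in fixation take ≈ 1897 steps:
conditioning on fixation forces the walk all the way up to `i = N`. The
Monte Carlo estimate agrees to within its requested tolerance
(`ε = 0.01` with failure probability `δ = 0.01`, which the Chebyshev
stopping rule bought with 89 400 realisations).

The same computations are available from the shell:

```bash
moranfix fix-prob --N 50 --beta 0.1 --game dominance --method all --seed 1
moranfix fix-time --conditional --N 50 --beta 0.1 --game 1,1,0,0 --method direct
moranfix stationary --N 50 --beta 0.1 --mu 0.05 --game dominance --method matrix
moranfix validate --max-n 50 --out report.tsv
```

`--method all` emits one record per method so the exact routes can be
compared directly; `validate` sweeps the three canonical games (dominance,
coexistence, bistability) over grids of `N` and `β` and tabulates
simulation-versus-direct and direct-versus-matrix errors.

## Scope

The package deliberately covers the discrete-time Moran process in a
well-mixed population with two strategies. Wright–Fisher dynamics,
graph-structured populations, pairwise-comparison (Fermi) updating and
continuous-time (Gillespie) simulation are out of scope; see
`docs/methods.md` for the methods, numerical choices and limitations.
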