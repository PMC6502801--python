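"""Monte Carlo simulation of the Moran process with principled stopping rules.

Single steps (:func:`naive_step`) draw one birth and one death event.  Most
steps change nothing, so :func:`multi_step` samples the holding time until
the next state change from a geometric distribution and then the jump
direction — distributionally identical to iterating naive steps, but the
cost per *event* no longer depends on how often the chain stays put.  The
same trick applies under mutation (:func:`multi_step_mutation`), where at
the monomorphic boundaries the per-step change probability is just ``mu``.

Stopping rules:

* fixation probability — Chebyshev bound on a Bernoulli mean: keep sampling
  until the realisation count exceeds ``Xbar (1 - Xbar) / (delta eps^2)``;
* fixation times — moving average of the cumulative mean, stop when the
  relative change per batch drops below ``eps``;
* stationary distribution — Kullback-Leibler divergence between successive
  snapshots of the time-weighted occupancy histogram drops below ``eps``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .core import (
    Game,
    ModelParams,
    ParameterError,
    build_kernel,
    payoffs,
)

__all__ = [
    "SimState",
    "StepProbabilities",
    "StoppingConfig",
    "Estimate",
    "StationaryEstimate",
    "SimulationBudgetError",
    "step_probabilities",
    "naive_step",
    "multi_step",
    "multi_step_mutation",
    "sample_fixation_event",
    "required_realisations",
    "estimate_fixation_probability",
    "estimate_fixation_time",
    "kl_divergence",
    "smoothed_histogram",
    "estimate_stationary_distribution",
    "stationary_stopping",
]


@dataclass(frozen=True)
class SimState:
    """Number of A-individuals and elapsed time steps of one realisation."""

    n_A: int
    t: int = 0


@dataclass(frozen=True)
class StepProbabilities:
    """One-step event probabilities at the current state (no mutation).

    ``m_b``: an A is chosen for birth; ``m_d``: an A is chosen for death;
    ``stay_prob = m_b m_d + (1-m_b)(1-m_d)``; ``jump_prob = 1 - stay_prob``.
    Given a jump, the state increases with probability ``f_A/(f_A+f_B)``.
    """

    m_b: float
    m_d: float
    stay_prob: float
    jump_prob: float


class SimulationBudgetError(RuntimeError):
    """A realisation (or run) exceeded its step budget before stopping.

    Carries whatever partial counts were accumulated so the caller can
    decide whether to enlarge the budget or accept the truncation.
    """

    def __init__(self, message: str, *, steps: int, n_realisations: int = 0):
        super().__init__(message)
        self.steps = steps
        self.n_realisations = n_realisations


@dataclass(frozen=True)
class StoppingConfig:
    """Tolerances and budgets for the Monte Carlo estimators.

    ``sigma2 = delta * epsilon**2`` is the Chebyshev variance target for the
    fixation-probability rule.  ``max_steps`` caps a single realisation (or,
    for the stationary estimator, the whole run); ``total_step_cap`` guards
    the conditional-time estimator against games where fixation is so rare
    that discarded realisations dominate.
    """

    epsilon: float = 0.01
    delta: float = 0.01
    r0: int = 100
    batch_size: int = 100
    max_steps: int = 10**8
    total_step_cap: int = 10**8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.epsilon > 0.0):
            raise ParameterError("epsilon must be > 0")
        if not (0.0 < self.delta < 1.0):
            raise ParameterError("delta must be in (0, 1)")
        if self.r0 < 1 or self.batch_size < 1:
            raise ParameterError("r0 and batch_size must be >= 1")
        if self.max_steps <= 0 or self.total_step_cap <= 0:
            raise ParameterError("step budgets must be > 0")

    @property
    def sigma2(self) -> float:
        return self.delta * self.epsilon**2


@dataclass(frozen=True)
class Estimate:
    """Monte Carlo estimate with its stopping diagnostics."""

    mean: float
    n_realisations: int
    variance_estimate: float
    converged: bool
    total_steps: int
    n_discarded: int = 0


@dataclass(frozen=True)
class StationaryEstimate:
    """Time-weighted occupancy estimate of the stationary distribution."""

    distribution: np.ndarray
    total_steps: int
    converged: bool
    kl: float
    n_snapshots: int


def _rng_from(config: StoppingConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def step_probabilities(n_A: int, params: ModelParams, game: Game) -> StepProbabilities:
    """Birth/death/stay probabilities of one naive Moran step at ``n_A``."""
    N = params.N
    if not (0 <= n_A <= N):
        raise ParameterError(f"n_A must be in [0, {N}], got {n_A}")
    if n_A == 0:
        m_b = 0.0
    elif n_A == N:
        m_b = 1.0
    else:
        pi_A, pi_B = payoffs(n_A, game, N)
        x = params.beta * (pi_B - pi_A)
        # m_b = n_A f_A / (n_A f_A + (N - n_A) f_B), overflow-safe either way
        if x <= 0.0:
            m_b = n_A / (n_A + (N - n_A) * math.exp(x))
        else:
            e = math.exp(-x)
            m_b = n_A * e / (n_A * e + (N - n_A))
    m_d = n_A / N
    stay = m_b * m_d + (1.0 - m_b) * (1.0 - m_d)
    return StepProbabilities(m_b=m_b, m_d=m_d, stay_prob=stay, jump_prob=1.0 - stay)


def naive_step(state: SimState, params: ModelParams, game: Game, rng: np.random.Generator) -> SimState:
    """One Moran step: fitness-proportional birth, uniform death."""
    p = step_probabilities(state.n_A, params, game)
    birth_A = rng.random() < p.m_b
    death_A = rng.random() < p.m_d
    n_A = state.n_A + (birth_A and not death_A) - (death_A and not birth_A)
    return SimState(n_A=n_A, t=state.t + 1)


def multi_step(state: SimState, params: ModelParams, game: Game, rng: np.random.Generator) -> SimState:
    """Advance to the next state change, skipping the no-change steps.

    The number of steps up to and including the change is geometric with
    success probability ``jump_prob`` (support 1, 2, ...); the direction of
    the change is up with probability ``f_A/(f_A+f_B)``.
    """
    p = step_probabilities(state.n_A, params, game)
    if p.jump_prob <= 0.0:
        raise ParameterError(f"state n_A={state.n_A} is absorbing; multi_step needs 0 < n_A < N")
    g = int(rng.geometric(p.jump_prob))
    up_given_jump = p.m_b * (1.0 - p.m_d) / p.jump_prob
    n_A = state.n_A + (1 if rng.random() < up_given_jump else -1)
    return SimState(n_A=n_A, t=state.t + g)


def multi_step_mutation(
    state: SimState, params: ModelParams, game: Game, rng: np.random.Generator
) -> SimState:
    """Jump-chain step under the mutation kernel.

    The per-step change probability is ``T^{k+} + T^{k-}`` of the kernel
    with mutation (at ``n_A = 0`` this is exactly ``mu``); holding times are
    geometric, direction up with probability ``T^{k+}/(T^{k+}+T^{k-})``.
    """
    if params.mu <= 0.0:
        raise ParameterError("multi_step_mutation requires mu > 0")
    from .core import transition_probabilities_with_mutation

    up, down = transition_probabilities_with_mutation(state.n_A, params, game)
    jump = up + down
    g = int(rng.geometric(jump))
    n_A = state.n_A + (1 if rng.random() < up / jump else -1)
    return SimState(n_A=n_A, t=state.t + g)


def _jump_arrays(params: ModelParams, game: Game, with_mutation: bool) -> tuple[np.ndarray, np.ndarray]:
    # per-state change probability and P(up | change), precomputed once per run
    kernel = build_kernel(params, game, with_mutation=with_mutation)
    jump = kernel.up + kernel.down
    with np.errstate(invalid="ignore", divide="ignore"):
        p_up = np.where(jump > 0.0, kernel.up / np.where(jump > 0, jump, 1.0), 0.0)
    return jump, p_up


def sample_fixation_event(
    params: ModelParams,
    game: Game,
    rng: np.random.Generator,
    max_steps: int = 10**8,
    _jump: np.ndarray | None = None,
    _p_up: np.ndarray | None = None,
) -> tuple[int, int]:
    """One realisation from ``n_A = 1`` to absorption.

    Returns ``(I, steps)`` with ``I = 1`` iff A fixates.  Raises
    :class:`SimulationBudgetError` if the realisation exceeds ``max_steps``.
    """
    if params.mu != 0.0:
        raise ParameterError("fixation sampling requires mu = 0")
    if _jump is None or _p_up is None:
        _jump, _p_up = _jump_arrays(params, game, with_mutation=False)
    N = params.N
    n_A = 1
    t = 0
    geometric = rng.geometric
    uniform = rng.random
    while 0 < n_A < N:
        t += int(geometric(_jump[n_A]))
        if t > max_steps:
            raise SimulationBudgetError(
                f"realisation exceeded max_steps={max_steps} before absorption",
                steps=t,
            )
        n_A += 1 if uniform() < _p_up[n_A] else -1
    return (1 if n_A == N else 0), t


def required_realisations(mean_estimate: float, config: StoppingConfig) -> int:
    """Chebyshev realisation threshold ``ceil(Xbar (1 - Xbar) / (delta eps^2))``."""
    if not (0.0 <= mean_estimate <= 1.0):
        raise ParameterError("mean_estimate must be a probability")
    return math.ceil(mean_estimate * (1.0 - mean_estimate) / config.sigma2)


def estimate_fixation_probability(
    params: ModelParams,
    game: Game,
    config: StoppingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Estimate:
    """Estimate the fixation probability with the Chebyshev stopping rule.

    Generates ``r0`` realisations of the fixation indicator, then batches of
    ``batch_size`` until the count exceeds ``Xbar (1 - Xbar) / sigma^2``.
    """
    config = config or StoppingConfig()
    rng = _rng_from(config, rng)
    jump, p_up = _jump_arrays(params, game, with_mutation=False)
    successes = 0
    k = 0
    total_steps = 0

    def _run_batch(n: int) -> None:
        nonlocal successes, k, total_steps
        for _ in range(n):
            try:
                ind, steps = sample_fixation_event(
                    params, game, rng, config.max_steps, _jump=jump, _p_up=p_up
                )
            except SimulationBudgetError as exc:
                raise SimulationBudgetError(
                    f"realisation {k + 1} exceeded max_steps={config.max_steps}; "
                    f"partial estimate {successes}/{k}",
                    steps=exc.steps,
                    n_realisations=k,
                ) from exc
            successes += ind
            k += 1
            total_steps += steps

    _run_batch(config.r0)
    while k <= required_realisations(successes / k, config):
        _run_batch(config.batch_size)
    mean = successes / k
    return Estimate(
        mean=mean,
        n_realisations=k,
        variance_estimate=mean * (1.0 - mean),
        converged=True,
        total_steps=total_steps,
    )


def estimate_fixation_time(
    params: ModelParams,
    game: Game,
    config: StoppingConfig | None = None,
    conditional: bool = False,
    rng: np.random.Generator | None = None,
) -> Estimate:
    """Estimate a fixation time with the moving-average stopping rule.

    The cumulative mean over all retained realisations is recomputed after
    every batch; sampling stops once its relative change drops to ``eps``.
    With ``conditional=True`` only realisations that fixate are retained
    (extinction runs are counted in ``n_discarded`` and their steps in
    ``total_steps``); ``r0`` and ``batch_size`` count retained realisations.
    """
    config = config or StoppingConfig()
    rng = _rng_from(config, rng)
    jump, p_up = _jump_arrays(params, game, with_mutation=False)
    times: list[int] = []
    n_discarded = 0
    total_steps = 0

    def _retain(n: int) -> None:
        nonlocal n_discarded, total_steps
        got = 0
        while got < n:
            if total_steps > config.total_step_cap:
                raise SimulationBudgetError(
                    f"total step budget {config.total_step_cap} exhausted with only "
                    f"{len(times)} retained realisations ({n_discarded} discarded); "
                    "the fixation probability may be too low for conditional sampling",
                    steps=total_steps,
                    n_realisations=len(times),
                )
            ind, steps = sample_fixation_event(
                params, game, rng, config.max_steps, _jump=jump, _p_up=p_up
            )
            total_steps += steps
            if conditional and ind == 0:
                n_discarded += 1
                continue
            times.append(steps)
            got += 1

    _retain(config.r0)
    tau_start = float(np.mean(times))
    while True:
        _retain(config.batch_size)
        tau_next = float(np.mean(times))
        if abs(tau_next - tau_start) / tau_next <= config.epsilon:
            break
        tau_start = tau_next
    arr = np.asarray(times, dtype=float)
    return Estimate(
        mean=float(arr.mean()),
        n_realisations=len(times),
        variance_estimate=float(arr.var(ddof=1)) if len(times) > 1 else 0.0,
        converged=True,
        total_steps=total_steps,
        n_discarded=n_discarded,
    )


def kl_divergence(p_new: np.ndarray, p_old: np.ndarray) -> float:
    """Kullback-Leibler divergence ``D_KL(p_new || p_old)`` in nats.

    Both arguments must be nonnegative vectors of the same length summing to
    one.  Cells with ``p_new = 0`` contribute zero; a cell with
    ``p_new > 0 = p_old`` yields ``inf`` — smooth the inputs first (see
    :func:`smoothed_histogram`) when comparing empirical histograms.
    """
    p_new = np.asarray(p_new, dtype=float)
    p_old = np.asarray(p_old, dtype=float)
    if p_new.shape != p_old.shape:
        raise ParameterError("distributions must have the same length")
    if np.any(p_new < 0.0) or np.any(p_old < 0.0):
        raise ParameterError("distributions must be nonnegative")
    for p in (p_new, p_old):
        if abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("distributions must sum to 1")
    return float(rel_entr(p_new, p_old).sum())


def smoothed_histogram(counts: np.ndarray) -> np.ndarray:
    """Normalise a visit-count histogram after adding one pseudo-count per cell.

    The pseudo-counts keep empty states out of the zero-denominator regime of
    the KL divergence without materially distorting long runs.
    """
    counts = np.asarray(counts, dtype=float)
    smoothed = counts + 1.0
    return smoothed / smoothed.sum()


def stationary_stopping(N: int, seed: int | None = None) -> StoppingConfig:
    """Default stopping configuration for the stationary estimator.

    Budgets scale with the population size: ``r0 = 100 N`` warm-up steps,
    snapshots compared every ``10^5 N`` steps, tolerance ``1e-4``.
    """
    return StoppingConfig(
        epsilon=1e-4,
        r0=100 * N,
        batch_size=10**5 * N,
        max_steps=10**8,
        seed=seed,
    )


def estimate_stationary_distribution(
    params: ModelParams,
    game: Game,
    config: StoppingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> StationaryEstimate:
    """Estimate the stationary distribution from one long mutation run.

    Accumulates a time-weighted occupancy histogram with the jump-chain
    acceleration (a holding time of ``g`` steps credits the pre-jump state
    with ``g`` counts).  After ``r0`` warm-in steps, cumulative snapshots are
    compared every ``batch_size`` effective steps; the run stops when
    ``D_KL(new || old)`` on the smoothed snapshots drops to ``epsilon``, or
    is flagged unconverged when ``max_steps`` is exhausted first (expected
    for bistable games under strong selection, where boundary-to-boundary
    transitions are rare).
    """
    if params.mu <= 0.0:
        raise ParameterError("stationary estimation requires mu > 0")
    config = config or stationary_stopping(params.N)
    rng = _rng_from(config, rng)
    jump, p_up = _jump_arrays(params, game, with_mutation=True)
    N = params.N
    counts = np.zeros(N + 1)
    n_A = 1  # a single mutant, as in the fixation experiments
    t = 0
    geometric = rng.geometric
    uniform = rng.random

    def _advance_until(target: int) -> None:
        nonlocal n_A, t
        while t < target:
            g = int(geometric(jump[n_A]))
            counts[n_A] += g
            t += g
            n_A += 1 if uniform() < p_up[n_A] else -1

    _advance_until(config.r0)
    previous = smoothed_histogram(counts)
    kl = math.inf
    n_snapshots = 0
    converged = False
    while t < config.max_steps:
        _advance_until(t + config.batch_size)
        snapshot = smoothed_histogram(counts)
        kl = kl_divergence(snapshot, previous)
        previous = snapshot
        n_snapshots += 1
        if kl <= config.epsilon:
            converged = True
            break
    return StationaryEstimate(
        distribution=counts / counts.sum(),
        total_steps=t,
        converged=converged,
        kl=kl,
        n_snapshots=n_snapshots,
    )
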