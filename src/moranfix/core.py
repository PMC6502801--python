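"""Model types and transition structure of the Moran process with a 2x2 game.

A well-mixed population of ``N`` individuals carries two strategies, A and B.
The state of the process is ``i``, the number of A-individuals, ``i`` in
``{0, ..., N}``.  Payoffs come from the symmetric game

    ( a  b )
    ( c  d )

with self-interaction excluded, and are turned into fitness through the
exponential mapping ``f = exp(beta * pi)``, so fitness stays positive for any
payoff sign and any selection intensity ``beta >= 0``.  Each time step one
individual is chosen for birth proportional to fitness and one uniformly at
random for death, so ``i`` moves by at most one: the chain is a birth-death
process with tridiagonal transition structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "Game",
    "ModelParams",
    "PayoffPair",
    "FitnessPair",
    "TransitionKernel",
    "ParameterError",
    "GammaOverflowError",
    "payoffs",
    "fitness",
    "transition_probabilities",
    "transition_probabilities_with_mutation",
    "transition_ratio",
    "log_transition_ratio",
    "build_kernel",
]

#: the only payoff-to-fitness mapping implemented; kept as a named constant so
#: alternatives (e.g. linear) could be added without changing call sites.
EXPONENTIAL_MAPPING = "exponential"


class ParameterError(ValueError):
    """Invalid model parameter (N < 2, beta < 0, mu outside [0, 1], ...)."""


class GammaOverflowError(OverflowError):
    """A product of transition ratios left double-precision range.

    Raised by the plain-arithmetic routines under strong selection; callers
    should switch to the log-domain variants (``log_transition_ratio``,
    ``fixation_probability(..., log_domain=True)``).
    """


@dataclass(frozen=True)
class Game:
    """Payoff matrix of a symmetric 2x2 game.

    ``a``: A vs A, ``b``: A vs B, ``c``: B vs A, ``d``: B vs B.
    Negative payoffs are allowed; the exponential fitness mapping keeps
    fitness positive.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"payoff {name!r} must be finite, got {v}")


@dataclass(frozen=True)
class ModelParams:
    """Population size, selection intensity and mutation probability.

    ``beta = 0`` is neutral drift; ``mu = 0`` makes the monomorphic states
    absorbing (fixation questions), ``mu > 0`` removes absorption
    (stationary-distribution questions).
    """

    N: int
    beta: float = 0.0
    mu: float = 0.0
    fitness_mapping: str = field(default=EXPONENTIAL_MAPPING)

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ParameterError(f"population size N must be an integer >= 2, got {self.N}")
        if not (self.beta >= 0.0):
            raise ParameterError(f"selection intensity beta must be >= 0, got {self.beta}")
        if not (0.0 <= self.mu <= 1.0):
            raise ParameterError(f"mutation probability mu must be in [0, 1], got {self.mu}")
        if self.fitness_mapping != EXPONENTIAL_MAPPING:
            raise ParameterError(
                f"only the {EXPONENTIAL_MAPPING!r} payoff-to-fitness mapping is implemented"
            )


class PayoffPair(NamedTuple):
    pi_A: float
    pi_B: float


class FitnessPair(NamedTuple):
    f_A: float
    f_B: float


def payoffs(i: int, game: Game, N: int) -> PayoffPair:
    """Average payoffs of one A- and one B-individual at state ``i``.

    Self-interaction is excluded, hence the division by ``N - 1``:

        pi_A = (a (i-1) + b (N-i)) / (N-1)
        pi_B = (c i + d (N-i-1)) / (N-1)

    ``pi_A`` is meaningful only for ``i >= 1`` and ``pi_B`` only for
    ``i <= N-1``; outside that range the value is returned but unused by any
    transition formula (the corresponding type has zero individuals).
    """
    if N < 2:
        raise ParameterError(f"N must be >= 2, got {N}")
    if not (0 <= i <= N):
        raise ParameterError(f"state index i must be in [0, {N}], got {i}")
    pi_A = (game.a * (i - 1) + game.b * (N - i)) / (N - 1)
    pi_B = (game.c * i + game.d * (N - i - 1)) / (N - 1)
    return PayoffPair(pi_A, pi_B)


def fitness(i: int, params: ModelParams, game: Game) -> FitnessPair:
    """Exponential payoff-to-fitness mapping ``f = exp(beta * pi)`` at state ``i``."""
    pi_A, pi_B = payoffs(i, game, params.N)
    return FitnessPair(math.exp(params.beta * pi_A), math.exp(params.beta * pi_B))


def _selection_shares(i: int, params: ModelParams, game: Game) -> tuple[float, float]:
    # probability shares of picking an A (resp. B) parent for birth,
    # computed with the max exponent factored out so large beta cannot overflow
    N = params.N
    pi_A, pi_B = payoffs(i, game, N)
    xA = params.beta * pi_A
    xB = params.beta * pi_B
    m = max(xA, xB)
    wA = i * math.exp(xA - m)
    wB = (N - i) * math.exp(xB - m)
    tot = wA + wB
    return wA / tot, wB / tot


def transition_probabilities(i: int, params: ModelParams, game: Game) -> tuple[float, float]:
    """Mutation-free one-step probabilities ``(T^{i+}, T^{i-})``.

        T^{i+} = i f_A / (i f_A + (N-i) f_B) * (N-i)/N
        T^{i-} = (N-i) f_B / (i f_A + (N-i) f_B) * i/N

    States 0 and N are absorbing (both probabilities zero there).
    """
    N = params.N
    if i == 0 or i == N:
        # avoids evaluating payoffs of an absent type
        return 0.0, 0.0
    sA, sB = _selection_shares(i, params, game)
    up = sA * (N - i) / N
    down = sB * i / N
    return up, down


def transition_probabilities_with_mutation(
    k: int, params: ModelParams, game: Game
) -> tuple[float, float]:
    """One-step probabilities ``(T^{k+}, T^{k-})`` with mutation rate ``mu``.

    A birth-death event without mutation (weight ``1 - mu``) moves the state
    as in the mutation-free process; with probability ``mu`` the offspring
    mutates, so picking the *same* type for birth and death flips the state:

        T^{k+} = sA (N-k)/N (1-mu) + sB (N-k)/N mu
        T^{k-} = sB k/N     (1-mu) + sA k/N     mu

    where ``sA = k f_A / (k f_A + (N-k) f_B)`` and ``sB = 1 - sA``.  For
    ``mu > 0`` the boundaries are reflecting: ``T^{0+} = T^{N-} = mu``.
    """
    N = params.N
    mu = params.mu
    if k == 0:
        return mu, 0.0
    if k == N:
        return 0.0, mu
    sA, sB = _selection_shares(k, params, game)
    up = sA * (N - k) / N * (1.0 - mu) + sB * (N - k) / N * mu
    down = sB * k / N * (1.0 - mu) + sA * k / N * mu
    return up, down


def log_transition_ratio(i: int, params: ModelParams, game: Game) -> float:
    """``log gamma^i = beta (pi_B^i - pi_A^i)``, exact in the log domain.

    Never overflows; the workhorse for strong selection, where ``gamma``
    itself can exceed double range (e.g. ~1e84 for beta = 100 on modest
    payoff differences).
    """
    N = params.N
    if not (1 <= i <= N - 1):
        raise ParameterError(f"transition ratio needs an interior state, got i={i}, N={N}")
    pi_A, pi_B = payoffs(i, game, N)
    return params.beta * (pi_B - pi_A)


def transition_ratio(i: int, params: ModelParams, game: Game) -> float:
    """Transition ratio ``gamma^i = T^{i-}/T^{i+} = exp(beta (pi_B - pi_A))``.

    Raises :class:`GammaOverflowError` when the value exceeds double range;
    use :func:`log_transition_ratio` in that regime.
    """
    lg = log_transition_ratio(i, params, game)
    try:
        return math.exp(lg)
    except OverflowError as exc:
        raise GammaOverflowError(
            f"gamma^{i} = exp({lg:.6g}) overflows double precision; "
            "use log_transition_ratio instead"
        ) from exc


@dataclass(frozen=True)
class TransitionKernel:
    """Per-state transition probabilities of the chain, vectors indexed 0..N.

    ``gamma[i] = down[i]/up[i]`` is defined for interior states only and is
    NaN at the boundaries.  ``stay = 1 - up - down`` elementwise.
    """

    up: np.ndarray
    down: np.ndarray
    stay: np.ndarray
    gamma: np.ndarray
    mutation_included: bool

    @property
    def N(self) -> int:
        return len(self.up) - 1


def build_kernel(params: ModelParams, game: Game, with_mutation: bool = False) -> TransitionKernel:
    """Vectorise the one-step probabilities over all states 0..N."""
    N = params.N
    up = np.zeros(N + 1)
    down = np.zeros(N + 1)
    prob = (
        transition_probabilities_with_mutation if with_mutation else transition_probabilities
    )
    for i in range(N + 1):
        up[i], down[i] = prob(i, params, game)
    stay = 1.0 - up - down
    gamma = np.full(N + 1, np.nan)
    interior = slice(1, N)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma[interior] = down[interior] / up[interior]
    return TransitionKernel(up=up, down=down, stay=stay, gamma=gamma, mutation_included=with_mutation)
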