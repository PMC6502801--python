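"""Direct analytical computations for the Moran birth-death chain.

Everything in this module follows from the closed-form solution of the
one-dimensional Master equation.  With ``gamma^i = T^{i-}/T^{i+}`` the
fixation probability of a single A-mutant is

    phi_A^1 = 1 / sum_{k=0}^{N-1} prod_{i=1}^{k} gamma^i

and the expected fixation times have equivalent single-loop reformulations
built on the recursions

    R^{l+1}   = 1 + gamma^{N-l} R^l,                R^1 = 1
    psi_A^h   = psi_A^{h-1} - phi_A^1 prod_{m<=N-h} gamma^m,   psi_A^1 = phi_A^{N-1}

which bring the naive O(N^2)/O(N^3) evaluations down to O(N).  All running
sums use compensated (``math.fsum``) summation.  Products of ``gamma`` can
leave double range under strong selection; the fixation probability offers a
log-domain mode for that regime, the time routines raise
:class:`~moranfix.core.GammaOverflowError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .core import (
    Game,
    GammaOverflowError,
    ModelParams,
    ParameterError,
    build_kernel,
    log_transition_ratio,
    payoffs,
    transition_probabilities,
    transition_ratio,
)

__all__ = [
    "WeakSelectionResult",
    "fixation_probability_naive",
    "fixation_probability",
    "fixation_probabilities_all_states",
    "unconditional_fixation_time",
    "conditional_fixation_time",
    "stationary_distribution",
    "weak_selection_D",
]


def _require_no_mutation(params: ModelParams, what: str) -> None:
    if params.mu != 0.0:
        raise ParameterError(f"{what} is defined for the mutation-free process (mu = 0)")


def fixation_probability_naive(params: ModelParams, game: Game) -> float:
    """Doubly nested evaluation of the fixation-probability sum.

    Recomputes the transition ratio inside both loops (N(N-1)/2 evaluations,
    O(N^2)).  Retained purely as an independent oracle for the O(N) version.
    """
    _require_no_mutation(params, "fixation probability")
    N = params.N
    terms = []
    for k in range(N):
        prod = 1.0
        for i in range(1, k + 1):
            prod *= transition_ratio(i, params, game)
        terms.append(prod)
    total = math.fsum(terms)
    if math.isinf(total):
        raise GammaOverflowError(
            "the gamma-product sum overflowed; use fixation_probability(log_domain=True)"
        )
    return 1.0 / total


def fixation_probability(params: ModelParams, game: Game, log_domain: bool = False) -> float:
    """Fixation probability ``phi_A^1`` of a single A-mutant, in O(N).

    The plain mode keeps a running product of transition ratios and a
    compensated sum.  ``log_domain=True`` accumulates ``log gamma`` and
    reduces with log-sum-exp, remaining usable at selection intensities where
    the products overflow (the result may underflow to 0.0, which is the
    correct double-precision answer).
    """
    _require_no_mutation(params, "fixation probability")
    N = params.N
    if log_domain:
        log_cum = np.empty(N)  # log of prod_{i<=k} gamma^i for k = 0..N-1
        log_cum[0] = 0.0
        acc = 0.0
        for k in range(1, N):
            acc += log_transition_ratio(k, params, game)
            log_cum[k] = acc
        return float(math.exp(-logsumexp(log_cum)))
    prod = 1.0
    terms = [1.0]
    for k in range(1, N):
        prod *= transition_ratio(k, params, game)
        if math.isinf(prod):
            raise GammaOverflowError(
                "running gamma-product overflowed; use log_domain=True"
            )
        terms.append(prod)
    return 1.0 / math.fsum(terms)


def fixation_probabilities_all_states(
    params: ModelParams, game: Game, log_domain: bool = False
) -> np.ndarray:
    """Fixation probabilities ``phi_A^i`` for every start state ``i = 0..N``.

    phi_A^i = sum_{k<i} prod_{m<=k} gamma^m / sum_{k<N} prod_{m<=k} gamma^m,

    so phi^0 = 0, phi^N = 1 and the vector is nondecreasing.
    """
    _require_no_mutation(params, "fixation probability")
    N = params.N
    if log_domain:
        log_cum = np.empty(N)
        log_cum[0] = 0.0
        acc = 0.0
        for k in range(1, N):
            acc += log_transition_ratio(k, params, game)
            log_cum[k] = acc
        # log of partial sums S_i = sum_{k<i} prod gamma, i = 1..N
        log_S = np.array([logsumexp(log_cum[:i]) for i in range(1, N + 1)])
        phi = np.zeros(N + 1)
        phi[1:] = np.exp(log_S - log_S[-1])
        phi[N] = 1.0
        return phi
    prods = np.empty(N)
    prods[0] = 1.0
    prod = 1.0
    for k in range(1, N):
        prod *= transition_ratio(k, params, game)
        prods[k] = prod
    if not np.all(np.isfinite(prods)):
        raise GammaOverflowError("gamma-products overflowed; use log_domain=True")
    S = np.concatenate(([0.0], np.cumsum(prods)))
    return S / S[-1]


def unconditional_fixation_time(params: ModelParams, game: Game) -> float:
    """Expected steps to absorption (either boundary) from one A-mutant.

    Uses the O(N) reformulation

        tau^1 = phi_A^1 * sum_{l=1}^{N-1} R^l / T^{(N-l)+}

    with the recursion R^{l+1} = 1 + gamma^{N-l} R^l, R^1 = 1.
    """
    _require_no_mutation(params, "fixation time")
    N = params.N
    phi1 = fixation_probability(params, game)
    terms = []
    R = 1.0
    for l in range(1, N):
        up, _ = transition_probabilities(N - l, params, game)
        terms.append(R / up)
        if l < N - 1:
            R = 1.0 + transition_ratio(N - l, params, game) * R
            if math.isinf(R):
                raise GammaOverflowError("R-recursion overflowed under strong selection")
    return phi1 * math.fsum(terms)


def conditional_fixation_time(params: ModelParams, game: Game) -> float:
    """Expected steps to fixation from one A-mutant, given fixation occurs.

    Uses the O(N) reformulation

        tau_A^1 = sum_{l=1}^{N-1} psi_A^l R^l / T^{(N-l)+}

    where ``psi_A^l = phi_A^{N-l}``.  The psi values are obtained from the
    memorised gamma-products as prefix sums, ``psi_A^l = phi_A^1 S_{N-l}``
    with ``S_i = sum_{k<i} prod_{m<=k} gamma^m`` — algebraically identical to
    the running-subtraction recursion ``psi^h = psi^{h-1} - phi^1 prod gamma``
    but free of the catastrophic cancellation that recursion suffers when
    ``phi_A^i`` spans many orders of magnitude (bistable games under strong
    selection).
    """
    _require_no_mutation(params, "fixation time")
    N = params.N
    # memorised cumulative gamma-products: gprod[k] = prod_{m=1}^{k} gamma^m
    gprod = np.empty(N)
    gprod[0] = 1.0
    for m in range(1, N):
        gprod[m] = gprod[m - 1] * transition_ratio(m, params, game)
    if not np.all(np.isfinite(gprod)):
        raise GammaOverflowError("gamma-products overflowed under strong selection")
    S = np.cumsum(gprod)  # S[i-1] = sum_{k<i} prod gamma, all-positive sums
    phi1 = 1.0 / S[-1]
    terms = []
    R = 1.0
    for l in range(1, N):
        up, _ = transition_probabilities(N - l, params, game)
        psi = phi1 * S[N - l - 1]  # phi_A^{N-l}
        terms.append(psi * R / up)
        if l < N - 1:
            R = 1.0 + transition_ratio(N - l, params, game) * R
            if math.isinf(R):
                raise GammaOverflowError("R-recursion overflowed under strong selection")
    return math.fsum(terms)


def stationary_distribution(params: ModelParams, game: Game) -> np.ndarray:
    """Stationary distribution ``p^k`` of the mutation-selection chain.

    Detailed balance gives p^k = p^0 prod_{i<k} T^{i+}/T^{(i+1)-}; the
    unnormalised products are accumulated in a first pass (in the log domain,
    so strong selection cannot overflow) and normalised in a second.
    Requires ``mu > 0`` — without mutation the chain is absorbing and no
    stationary distribution over all states exists.
    """
    if params.mu <= 0.0:
        raise ParameterError("stationary distribution requires mu > 0")
    kernel = build_kernel(params, game, with_mutation=True)
    N = params.N
    with np.errstate(divide="ignore"):
        log_ratio = np.log(kernel.up[:N]) - np.log(kernel.down[1:])
    log_p = np.concatenate(([0.0], np.cumsum(log_ratio)))
    return softmax(log_p)


@dataclass(frozen=True)
class WeakSelectionResult:
    """Sign condition for invasion under weak selection.

    ``D = sum_{k=0}^{N-1} sum_{i=1}^{k} (pi_A^i - pi_B^i)``; selection favors
    the invasion of A (phi_A^1 > 1/N for small beta) exactly when D > 0.
    """

    D: float
    favored: bool


def weak_selection_D(params: ModelParams, game: Game) -> WeakSelectionResult:
    """First-order payoff-difference sum governing weak-selection invasion."""
    _require_no_mutation(params, "weak-selection condition")
    N = params.N
    diffs = np.empty(N)  # pi_A^i - pi_B^i for i = 1..N-1 (index 0 unused)
    diffs[0] = 0.0
    for i in range(1, N):
        pi_A, pi_B = payoffs(i, game, N)
        diffs[i] = pi_A - pi_B
    inner = np.cumsum(diffs)  # inner[k] = sum_{i<=k} diff_i
    D = float(math.fsum(inner[: N]))  # k = 0..N-1 (k=0 term is 0)
    return WeakSelectionResult(D=D, favored=D > 0.0)
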