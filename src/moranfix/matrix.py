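"""Matrix-based numerics on the tridiagonal transient-state system.

The transition matrix of the birth-death chain is tridiagonal, so every
quantity reduces to a banded linear solve over the transient states:

* fixation probabilities: ``(Q - I) phi~ = -v2``
* unconditional fixation times: ``(Q - I) tau~ = -1``
* conditional fixation times: same system on the fixation-conditioned
  (Doob-transformed) kernel ``T_A^{i+-} = (phi^{i+-1}/phi^i) T^{i+-}``
* stationary distribution with mutation: set ``p^0 = 1``, solve the
  partitioned system ``C p* = -v2`` on ``(T - I)^T``, then normalise.

Only the three bands are ever stored and every solve is a Thomas (tridiagonal
LU) recursion, so time and memory stay O(N).  The systems are M-matrices
(``I - Q`` has diagonal exactly ``T^+ + T^-`` and nonpositive off-diagonals)
with nonnegative right-hand sides, which permits a subtraction-free
elimination: tracking the pivot surplus ``e_i = d_i - T^{i+}`` instead of the
pivot itself involves only products and sums of positive numbers.  The
computed solution is therefore componentwise accurate even when the system is
spectacularly ill-conditioned (coexistence games under strong selection have
condition numbers of order of the mean fixation time, e.g. ~1e56 for N = 500,
beta = 1, where textbook partially-pivoted LU returns pure noise).  No
pivoting is needed: the matrices are (weakly) diagonally dominant.

A dense pathway (needed e.g. for Wright-Fisher-type chains whose transition
matrix is not banded) is deliberately not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Game, ModelParams, ParameterError, TransitionKernel, build_kernel

__all__ = [
    "TridiagonalSystem",
    "ConditionedKernel",
    "build_transient_system",
    "fixation_probability_matrix",
    "unconditional_time_matrix",
    "condition_kernel",
    "conditional_time_matrix",
    "stationary_distribution_matrix",
]


@dataclass(frozen=True)
class TridiagonalSystem:
    """Bands of the transient-state transition matrix Q (states 1..N-1).

    ``diag[j]`` is the stay-probability of state ``j+1``; ``sub``/``sup``
    hold the down/up couplings between neighbouring transient states.  The
    probability mass leaking to the absorbing boundaries is recorded in
    ``v1_first`` (state 1 -> 0) and ``v2_last`` (state N-1 -> N), so each
    row of Q plus its leak sums to one.
    """

    sub: np.ndarray  # length N-2: Q[j+1, j] = T^{(j+2)-}
    diag: np.ndarray  # length N-1: Q[j, j] = T^{(j+1)o}
    sup: np.ndarray  # length N-2: Q[j, j+1] = T^{(j+1)+}
    v1_first: float  # T^{1-}
    v2_last: float  # T^{(N-1)+}

    @property
    def size(self) -> int:
        return len(self.diag)


def build_transient_system(kernel: TransitionKernel) -> TridiagonalSystem:
    """Extract the bands of Q and the boundary-leak entries from a kernel."""
    N = kernel.N
    return TridiagonalSystem(
        sub=kernel.down[2:N].copy(),
        diag=kernel.stay[1:N].copy(),
        sup=kernel.up[1 : N - 1].copy(),
        v1_first=float(kernel.down[1]),
        v2_last=float(kernel.up[N - 1]),
    )


def _solve_i_minus_q(up: np.ndarray, down: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve (I - Q) x = rhs over the transient states, subtraction-free.

    ``up[j]``/``down[j]`` are the full one-step probabilities of transient
    state ``j+1`` (boundary leaks included), so the diagonal of ``I - Q`` is
    ``up + down`` and the off-diagonals are ``-down`` (sub) and ``-up``
    (super).  ``rhs`` must be nonnegative.  Thomas elimination with the pivot
    written as ``d_j = up_j + e_j`` and the surplus recursion
    ``e_j = down_j e_{j-1} / d_{j-1}`` (``e_0 = down_0``) never subtracts,
    giving componentwise relative accuracy independent of conditioning.
    """
    M = len(rhs)
    if np.any(rhs < 0.0):
        raise ParameterError("the subtraction-free solve requires a nonnegative rhs")
    d = np.empty(M)
    y = np.empty(M)
    e = down[0]
    d[0] = up[0] + e
    y[0] = rhs[0]
    for j in range(1, M):
        if d[j - 1] <= 0.0:
            raise ArithmeticError(
                f"singular transient system at state {j}; "
                "some interior state has zero total jump probability"
            )
        e = down[j] * e / d[j - 1]
        d[j] = up[j] + e
        y[j] = rhs[j] + down[j] * y[j - 1] / d[j - 1]
    x = np.empty(M)
    x[M - 1] = y[M - 1] / d[M - 1]
    for j in range(M - 2, -1, -1):
        x[j] = (y[j] + up[j] * x[j + 1]) / d[j]
    return x


def fixation_probability_matrix(params: ModelParams, game: Game) -> np.ndarray:
    """Fixation probabilities for all start states via (Q - I) phi~ = -v2."""
    if params.mu != 0.0:
        raise ParameterError("fixation probabilities require mu = 0")
    kernel = build_kernel(params, game, with_mutation=False)
    N = params.N
    rhs = np.zeros(N - 1)
    rhs[-1] = kernel.up[N - 1]  # -v2, sign-flipped with the system
    interior = _solve_i_minus_q(kernel.up[1:N], kernel.down[1:N], rhs)
    return np.concatenate(([0.0], interior, [1.0]))


def unconditional_time_matrix(params: ModelParams, game: Game) -> np.ndarray:
    """Expected absorption times for all start states via (Q - I) tau~ = -1."""
    if params.mu != 0.0:
        raise ParameterError("fixation times require mu = 0")
    kernel = build_kernel(params, game, with_mutation=False)
    N = params.N
    interior = _solve_i_minus_q(kernel.up[1:N], kernel.down[1:N], np.ones(N - 1))
    return np.concatenate(([0.0], interior, [0.0]))


@dataclass(frozen=True)
class ConditionedKernel:
    """Transition probabilities of the chain conditioned on fixation of A.

    ``up_cond[i] = (phi^{i+1}/phi^i) T^{i+}`` and
    ``down_cond[i] = (phi^{i-1}/phi^i) T^{i-}`` for interior ``i``; the
    conditioning preserves the total jump probability at every state.
    """

    up_cond: np.ndarray
    down_cond: np.ndarray


def condition_kernel(kernel: TransitionKernel, phi: np.ndarray) -> ConditionedKernel:
    """Weight the kernel by fixation-probability ratios (Doob transform)."""
    N = kernel.N
    if kernel.mutation_included:
        raise ParameterError("conditioning is defined for the mutation-free kernel")
    if np.any(phi[1:] <= 0.0):
        raise ParameterError("conditioning requires phi^i > 0 at every interior state")
    up_cond = np.zeros(N + 1)
    down_cond = np.zeros(N + 1)
    i = np.arange(1, N)
    up_cond[i] = phi[i + 1] / phi[i] * kernel.up[i]
    down_cond[i] = phi[i - 1] / phi[i] * kernel.down[i]
    return ConditionedKernel(up_cond=up_cond, down_cond=down_cond)


def conditional_time_matrix(params: ModelParams, game: Game) -> np.ndarray:
    """Expected fixation times conditioned on reaching all-A, all start states.

    Solves ``(Q_A - I) tau_A~ = -1`` on the conditioned kernel.  Entry 0 of
    the returned vector is set to 0.0 but is unused (state 0 never fixates);
    ``tau_A^N = 0`` by definition.
    """
    if params.mu != 0.0:
        raise ParameterError("fixation times require mu = 0")
    kernel = build_kernel(params, game, with_mutation=False)
    phi = fixation_probability_matrix(params, game)
    cond = condition_kernel(kernel, phi)
    N = params.N
    interior = _solve_i_minus_q(cond.up_cond[1:N], cond.down_cond[1:N], np.ones(N - 1))
    return np.concatenate(([0.0], interior, [0.0]))


def stationary_distribution_matrix(params: ModelParams, game: Game) -> np.ndarray:
    """Stationary distribution via the partitioned left-eigenvector system.

    ``(T - I)^T`` is singular; fixing ``p^0 = 1`` and dropping its row and
    column leaves the nonsingular tridiagonal block C over states 1..N with
    ``C[i, j] = (T - I)[j+1, i+1]`` and right-hand side
    ``-v2 = -(T^{0+}, 0, ..., 0)^T``.  The sign-flipped block ``-C`` is again
    an M-matrix with diagonal exactly ``T^{k+} + T^{k-}``, solved by the same
    subtraction-free Thomas recursion (here the surplus is
    ``e_i = d_i - T^{k+}`` with multiplier entries ``T^{(k-1)+}`` below and
    ``T^{(k+1)-}`` above).  The solution is prepended with ``p^0 = 1`` and
    normalised.
    """
    if params.mu <= 0.0:
        raise ParameterError("stationary distribution requires mu > 0")
    kernel = build_kernel(params, game, with_mutation=True)
    N = params.N
    up, down = kernel.up, kernel.down
    M = N  # block C spans states 1..N
    d = np.empty(M)
    y = np.empty(M)
    # state k = j + 1; -C has diag up[k]+down[k], sub -up[k-1], sup -down[k+1]
    e = down[1]
    d[0] = up[1] + e
    y[0] = up[0]  # rhs of -C x = v2 is (T^{0+}, 0, ..., 0)
    for j in range(1, M):
        k = j + 1
        e = down[k] * e / d[j - 1]
        d[j] = up[k] + e
        y[j] = up[k - 1] * y[j - 1] / d[j - 1]
    p_star = np.empty(M)
    p_star[M - 1] = y[M - 1] / d[M - 1]
    for j in range(M - 2, -1, -1):
        p_star[j] = (y[j] + down[j + 2] * p_star[j + 1]) / d[j]
    p = np.concatenate(([1.0], p_star))
    return p / p.sum()
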