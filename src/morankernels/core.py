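"""Core selection–mutation analytics for the Moran process.

The model: a well-mixed population of constant size ``N``.  At each event one
individual reproduces with probability proportional to its fitness
``exp(beta * payoff)`` and the copy replaces an individual drawn uniformly at
random (the parent itself may die).  Payoffs come from pairwise or group
interactions excluding self-interaction.  Mutation is described by a
row-stochastic *kernel*: row ``a`` gives the probability that an offspring of
an ``a``-parent is of each type, with the diagonal carrying the no-mutation
mass.

In the rare-mutation limit the population is monomorphic almost all of the
time and the dynamics collapses to a Markov chain over monomorphic states
whose off-diagonal transition rates are (mutation probability a -> b) times
(fixation probability of a single b mutant among N-1 residents of type a).
This module provides exact fixation probabilities under the exponential
payoff-to-fitness mapping, the embedded chain for arbitrary kernels, its
stationary distribution, the strong-selection (beta -> infinity) limit, and
the 2x2 long-run abundance condition including the mutation-reversal result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

__all__ = [
    "PayoffMatrix",
    "PopulationConfig",
    "MutationKernel",
    "FixationResult",
    "EmbeddedChain",
    "StationaryDistribution",
    "expected_payoffs",
    "fixation_probability",
    "log_fixation_probability",
    "strong_selection_fixation",
    "build_embedded_chain",
    "stationary_distribution",
    "abundance_condition_2x2",
    "abundance_condition_2x2_closed_form",
    "reversal_ratio",
    "uniform_kernel",
    "small_mutation_validity",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PayoffMatrix:
    """Square payoff matrix; entry (i, j) is the payoff of strategy i against j."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("payoff matrix must be square")
        if values.shape[0] < 2:
            raise ValueError("need at least two strategies")
        if not np.all(np.isfinite(values)):
            raise ValueError("payoff entries must be finite")
        if len(self.labels) != values.shape[0]:
            raise ValueError("label count must match matrix dimension")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("strategy labels must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def restrict(self, labels: Sequence[str]) -> "PayoffMatrix":
        idx = [self.index(l) for l in labels]
        return PayoffMatrix(self.values[np.ix_(idx, idx)], tuple(labels))


@dataclass(frozen=True)
class PopulationConfig:
    """Population size N and intensity of selection beta (>= 0)."""

    N: int
    beta: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError("population size N must be an integer >= 2")
        object.__setattr__(self, "N", int(self.N))
        if not (self.beta >= 0) or not math.isfinite(self.beta):
            raise ValueError("beta must be a finite nonnegative real")


@dataclass(frozen=True)
class MutationKernel:
    """Row-stochastic per-reproduction mutation probabilities.

    Row ``a`` is the distribution of the offspring type for an ``a`` parent;
    the diagonal holds the no-mutation mass.  The off-diagonal support must be
    strongly connected so that the resulting Moran chain is ergodic.  ``rate``
    is the overall mutation scale mu used by the simulator (informational for
    hand-built kernels).
    """

    matrix: np.ndarray
    labels: tuple[str, ...]
    rate: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mutation kernel must be square")
        if len(self.labels) != m.shape[0]:
            raise ValueError("label count must match kernel dimension")
        if np.any(m < -1e-15) or np.any(m > 1 + 1e-12):
            raise ValueError("kernel entries must lie in [0, 1]")
        rowsum = m.sum(axis=1)
        bad = np.nonzero(np.abs(rowsum - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                "kernel rows must sum to 1; offending rows: "
                + ", ".join(f"{self.labels[i]} (sum={rowsum[i]:.12g})" for i in bad)
            )
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        _check_strongly_connected(off, self.labels, what="mutation kernel")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FixationResult:
    """Fixation probability rho of a single mutant lineage."""

    rho: float
    invader: str = ""
    resident: str = ""

    def __post_init__(self) -> None:
        if not (-1e-15 <= self.rho <= 1 + 1e-12):
            raise ValueError("fixation probability must lie in [0, 1]")


@dataclass(frozen=True)
class EmbeddedChain:
    """Rare-mutation Markov chain over monomorphic states.

    Off-diagonal entries are ``scale * M[a, b] * rho(b invades a)``; the
    diagonal completes each row to 1.  The stationary distribution is
    invariant to the (arbitrary, positive) ``scale``.
    """

    T: np.ndarray
    labels: tuple[str, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < -1e-14):
            raise ValueError("transition probabilities must be nonnegative")
        if np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n(self) -> int:
        return self.T.shape[0]


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run abundance vector over monomorphic states; sums to one."""

    pi: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if pi.ndim != 1 or pi.size != len(self.labels):
            raise ValueError("pi must be a vector aligned with labels")
        if np.any(pi < -1e-10):
            raise ValueError("stationary probabilities must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("stationary distribution must sum to 1")

    def __getitem__(self, label: str) -> float:
        return float(self.pi[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {l: float(p) for l, p in zip(self.labels, self.pi)}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _check_strongly_connected(off: np.ndarray, labels: Sequence[str], what: str) -> None:
    n_comp, comp = connected_components(
        csr_matrix(off > 0), directed=True, connection="strong"
    )
    if n_comp > 1:
        groups: dict[int, list[str]] = {}
        for lab, c in zip(labels, comp):
            groups.setdefault(int(c), []).append(lab)
        detail = "; ".join("{" + ", ".join(g) + "}" for g in groups.values())
        raise ValueError(
            f"{what} is not strongly connected (required for ergodicity); "
            f"components: {detail}"
        )


def _payoff_deltas_2x2(a: float, b: float, c: float, d: float, N: int) -> np.ndarray:
    """pi_A(i) - pi_B(i) for i = 1..N-1, self-interaction excluded."""
    i = np.arange(1, N)
    pa = (a * (i - 1) + b * (N - i)) / (N - 1)
    pb = (c * i + d * (N - i - 1)) / (N - 1)
    return pa - pb


DeltaFn = Callable[[int, int, int], np.ndarray]
"""(invader_index, resident_index, N) -> payoff-difference vector of length N-1."""


def _matrix_delta_fn(game: PayoffMatrix) -> DeltaFn:
    V = game.values

    def deltas(inv: int, res: int, N: int) -> np.ndarray:
        return _payoff_deltas_2x2(V[inv, inv], V[inv, res], V[res, inv], V[res, res], N)

    return deltas


def _log_rho_from_deltas(deltas: np.ndarray, beta: float, N: int) -> float:
    """log of 1 / (1 + sum_k exp(-beta * S_k)), S_k cumulative payoff differences.

    Computed entirely in log space; safe for beta * |payoff| * N up to ~1e4.
    """
    if beta == 0.0:
        return -math.log(N)
    S = np.cumsum(deltas)
    terms = np.concatenate(([0.0], -beta * S))
    return -float(logsumexp(terms))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def expected_payoffs(
    game: PayoffMatrix, i: int, N: int, strategy_a: int = 0, strategy_b: int = 1
) -> tuple[float, float]:
    """Expected payoffs (pi_A(i), pi_B(i)) with i players of type A among N.

    Each individual interacts with the other N-1 individuals (no
    self-interaction): pi_A = (a(i-1) + b(N-i)) / (N-1) and
    pi_B = (c i + d(N-i-1)) / (N-1).
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if not 0 <= i <= N:
        raise ValueError(f"count i={i} out of range [0, {N}]")
    V = game.values
    a, b = V[strategy_a, strategy_a], V[strategy_a, strategy_b]
    c, d = V[strategy_b, strategy_a], V[strategy_b, strategy_b]
    pa = (a * (i - 1) + b * (N - i)) / (N - 1)
    pb = (c * i + d * (N - i - 1)) / (N - 1)
    return float(pa), float(pb)


def log_fixation_probability(
    game: PayoffMatrix, invader: int | str, resident: int | str, pop: PopulationConfig
) -> float:
    """Natural log of the fixation probability of one invader among residents."""
    inv = game.index(invader) if isinstance(invader, str) else invader
    res = game.index(resident) if isinstance(resident, str) else resident
    if inv == res:
        raise ValueError("invader and resident must differ")
    deltas = _matrix_delta_fn(game)(inv, res, pop.N)
    return _log_rho_from_deltas(deltas, pop.beta, pop.N)


def fixation_probability(
    game: PayoffMatrix, invader: int | str, resident: int | str, pop: PopulationConfig
) -> FixationResult:
    """Fixation probability of a single invader in a resident population.

    Under the exponential fitness mapping f = exp(beta * payoff) the
    backward/forward ratio of the birth-death chain at state i is
    exp(-beta * (pi_inv(i) - pi_res(i))), so
    rho = 1 / (1 + sum_{k=1}^{N-1} exp(-beta * S_k)) with S_k the cumulative
    payoff-difference sum.  beta = 0 returns exactly 1/N.
    """
    inv = game.index(invader) if isinstance(invader, str) else invader
    res = game.index(resident) if isinstance(resident, str) else resident
    if inv == res:
        raise ValueError("invader and resident must differ")
    if pop.beta == 0.0:
        rho = 1.0 / pop.N
    else:
        rho = math.exp(log_fixation_probability(game, inv, res, pop))
    return FixationResult(rho=rho, invader=game.labels[inv], resident=game.labels[res])


def strong_selection_fixation(
    game: PayoffMatrix | None,
    invader: int | str,
    resident: int | str,
    N: int,
    *,
    deltas: np.ndarray | None = None,
    payoff_scale: float | None = None,
) -> FixationResult:
    """Exact beta -> infinity limit of the fixation probability.

    With S_k the cumulative payoff-difference sums, rho -> 0 if any S_k < 0,
    otherwise rho -> 1 / (1 + #{k : S_k = 0}).  Equality of S_k with zero is
    decided at tolerance 1e-12 * max(1, payoff scale): neutral paths arise
    from exactly equal payoffs, not near-equality.
    """
    labels = ("", "")
    if deltas is None:
        if game is None:
            raise ValueError("either a game or explicit payoff deltas are required")
        inv = game.index(invader) if isinstance(invader, str) else invader
        res = game.index(resident) if isinstance(resident, str) else resident
        if inv == res:
            raise ValueError("invader and resident must differ")
        deltas = _matrix_delta_fn(game)(inv, res, N)
        labels = (game.labels[inv], game.labels[res])
        if payoff_scale is None:
            payoff_scale = float(np.max(np.abs(game.values)))
    if payoff_scale is None:
        payoff_scale = float(np.max(np.abs(deltas))) if len(deltas) else 1.0
    tol = 1e-12 * max(1.0, payoff_scale)
    S = np.cumsum(deltas)
    if np.any(S < -tol):
        rho = 0.0
    else:
        rho = 1.0 / (1.0 + int(np.count_nonzero(np.abs(S) <= tol)))
    return FixationResult(rho=rho, invader=labels[0], resident=labels[1])


def build_embedded_chain(
    game: PayoffMatrix | DeltaFn,
    kernel: MutationKernel,
    pop: PopulationConfig,
    *,
    scale: float = 1.0,
    strong_selection: bool = False,
    payoff_scale: float | None = None,
    labels: Sequence[str] | None = None,
) -> EmbeddedChain:
    """Assemble the rare-mutation Markov chain over monomorphic states.

    Off-diagonal entries are ``scale * M[a, b] * rho(b invades N-1 a's)``;
    the diagonal completes each row.  ``game`` may be a payoff matrix or a
    callable ``(invader_index, resident_index, N) -> payoff-difference
    vector`` for group games.  The stationary distribution is invariant to
    ``scale`` (any choice keeping rows valid).
    """
    if isinstance(game, PayoffMatrix):
        if kernel.n != game.n:
            raise ValueError("kernel dimension must equal game dimension")
        delta_fn = _matrix_delta_fn(game)
        labels = game.labels
        if payoff_scale is None:
            payoff_scale = float(np.max(np.abs(game.values)))
    else:
        delta_fn = game
        if labels is None:
            labels = kernel.labels
        if len(labels) != kernel.n:
            raise ValueError("kernel dimension must equal the number of strategies")
    m = kernel.n
    M = kernel.matrix
    T = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b or M[a, b] == 0.0:
                continue
            d = delta_fn(b, a, pop.N)
            if strong_selection:
                rho = strong_selection_fixation(
                    None, b, a, pop.N, deltas=d, payoff_scale=payoff_scale
                ).rho
            elif pop.beta == 0.0:
                rho = 1.0 / pop.N
            else:
                rho = math.exp(_log_rho_from_deltas(d, pop.beta, pop.N))
            T[a, b] = scale * M[a, b] * rho
    offsum = T.sum(axis=1)
    if np.any(offsum > 1.0 + 1e-12):
        raise RuntimeError(
            "scaled off-diagonal row sums exceed 1; choose a smaller scale"
        )
    np.fill_diagonal(T, 1.0 - offsum)
    return EmbeddedChain(T=T, labels=tuple(labels), scale=scale)


def stationary_distribution(chain: EmbeddedChain) -> StationaryDistribution:
    """Unique left fixed vector of the chain, normalized to sum to one.

    Solved deterministically as a null-space (SVD) problem on an internally
    rescaled copy of the chain for conditioning; raises if the chain is
    reducible or the null space is not one-dimensional.
    """
    T = chain.T.copy()
    off = T.copy()
    np.fill_diagonal(off, 0.0)
    _check_strongly_connected(off, chain.labels, what="embedded chain")
    # rescale off-diagonal rates so rank detection is well conditioned;
    # the stationary vector is invariant to this
    mx = off.sum(axis=1).max()
    if mx > 0 and (mx < 0.1 or mx > 0.9):
        off *= 0.5 / mx
        T = off
        np.fill_diagonal(T, 1.0 - off.sum(axis=1))
    ns = null_space(T.T - np.eye(chain.n))
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError(
            f"stationary distribution is numerically ambiguous "
            f"(null space dimension {ns.shape[1]})"
        )
    v = ns[:, 0]
    v = v * math.copysign(1.0, v.sum())
    if v.min() < -1e-10:
        raise np.linalg.LinAlgError("null-space vector has negative entries")
    v = np.clip(v, 0.0, None)
    pi = v / v.sum()
    if not np.allclose(pi @ chain.T, pi, atol=1e-10):
        raise np.linalg.LinAlgError("stationary residual exceeds tolerance")
    return StationaryDistribution(pi=pi, labels=chain.labels)


# ---------------------------------------------------------------------------
# 2x2 abundance analysis
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-12


def abundance_condition_2x2(
    game: PayoffMatrix,
    pop: PopulationConfig,
    mu_ab: float,
    mu_ba: float,
) -> int:
    """Long-run abundance ranking of strategy A (index 0) vs B (index 1).

    Exact route: in the rare-mutation limit the two-state stationary
    distribution satisfies pi_A / pi_B = (mu_BA rho_A) / (mu_AB rho_B), so A
    is more abundant iff mu_BA rho_A > mu_AB rho_B.  Returns +1 (A more
    abundant), -1 (B more abundant) or 0 (tie).
    """
    if game.n != 2:
        raise ValueError("abundance condition is defined for 2x2 games")
    if not (mu_ab > 0 and mu_ba > 0):
        raise ValueError("mutation probabilities must be positive")
    if pop.beta == 0.0:
        margin = math.log(mu_ba) - math.log(mu_ab)
    else:
        lr_a = log_fixation_probability(game, 0, 1, pop)
        lr_b = log_fixation_probability(game, 1, 0, pop)
        margin = (math.log(mu_ba) + lr_a) - (math.log(mu_ab) + lr_b)
    if abs(margin) <= _TIE_TOL * max(1.0, pop.beta * float(np.max(np.abs(game.values))) * pop.N):
        return 0
    return 1 if margin > 0 else -1


def abundance_condition_2x2_closed_form(
    game: PayoffMatrix,
    pop: PopulationConfig,
    mu_ab: float,
    mu_ba: float,
    *,
    large_N: bool = False,
) -> int:
    """Closed-form abundance ranking.

    Under the exponential mapping the fixation-probability ratio is exactly
    ln(rho_A / rho_B) = beta * [(N-2)(a-d) + N(b-c)] / 2, so A is more
    abundant iff beta * [(N-2)(a-d) + N(b-c)] / 2 > ln(mu_AB / mu_BA).
    With ``large_N`` the left side simplifies to beta * N * (a+b-c-d) / 2,
    which at equal mutation rates is the risk-dominance condition
    a + b > c + d.  N and beta enter linearly; the mutation ratio enters
    logarithmically.
    """
    if game.n != 2:
        raise ValueError("abundance condition is defined for 2x2 games")
    if not (mu_ab > 0 and mu_ba > 0):
        raise ValueError("mutation probabilities must be positive")
    a, b = game.values[0, 0], game.values[0, 1]
    c, d = game.values[1, 0], game.values[1, 1]
    N, beta = pop.N, pop.beta
    if large_N:
        lhs = beta * N * (a + b - c - d) / 2.0
    else:
        lhs = beta * ((N - 2) * (a - d) + N * (b - c)) / 2.0
    margin = lhs - math.log(mu_ab / mu_ba)
    if abs(margin) <= _TIE_TOL * max(1.0, abs(lhs)):
        return 0
    return 1 if margin > 0 else -1


def reversal_ratio(
    game: PayoffMatrix, pop: PopulationConfig, *, tol: float = 1e-10
) -> float:
    """Critical mutation ratio q* = mu_AB / mu_BA at which the ranking flips.

    Found by bisection on log q of the exact-route margin; for q < q*
    strategy A is more abundant, for q > q* strategy B is.  Any game-side
    disadvantage can be reversed by choosing the ratio on the right side of
    q* (only for finite selection intensity).
    """
    if pop.beta <= 0:
        raise ValueError("reversal requires positive selection intensity")
    lr_a = log_fixation_probability(game, 0, 1, pop)
    lr_b = log_fixation_probability(game, 1, 0, pop)
    diff = lr_a - lr_b  # root of margin(logq) = diff - logq

    def margin(logq: float) -> float:
        return diff - logq

    lo, hi = -1.0, 1.0
    while margin(lo) < 0:
        lo *= 2.0
        if lo < -1e6:
            raise RuntimeError("bisection bracket not found")
    while margin(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("bisection bracket not found")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if margin(mid) > 0:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# kernels and diagnostics
# ---------------------------------------------------------------------------


def uniform_kernel(
    n: int, rate: float, labels: Sequence[str] | None = None
) -> MutationKernel:
    """Uniform kernel: diagonal 1 - mu, every other strategy mu / (n-1)."""
    if n < 2:
        raise ValueError("kernel needs at least two strategies")
    if not 0 < rate < 1:
        raise ValueError("mutation rate must lie in (0, 1)")
    M = np.full((n, n), rate / (n - 1))
    np.fill_diagonal(M, 1.0 - rate)
    if labels is None:
        labels = tuple(f"S{i}" for i in range(n))
    return MutationKernel(matrix=M, labels=tuple(labels), rate=rate)


def small_mutation_validity(N: int, mu: float, *, threshold: float = 0.1) -> bool:
    """Heuristic check that mutations are rare relative to fixation.

    A neutral fixation sweep takes on the order of N*(N-1) birth-death
    events, while mutations arrive every ~1/mu events; the rare-mutation
    analytics is trusted when (expected fixation time) * mu < ``threshold``.
    Emits a warning and returns False outside that region.
    """
    load = N * (N - 1) * mu
    if load >= threshold:
        warnings.warn(
            f"mutation rate mu={mu:g} may be too large for the rare-mutation "
            f"approximation at N={N} (N(N-1)*mu = {load:.3g} >= {threshold})",
            stacklevel=2,
        )
        return False
    return True
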