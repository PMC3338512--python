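"""Optional public goods games with punishment.

Groups of ``n_group`` individuals are sampled without replacement from a
well-mixed population of size ``N``.  Group members may contribute to a
common pot (cooperators, base ``C``), participate without contributing
(defectors, ``D``) or abstain (loners, ``L``, who receive the fixed payoff
``sigma``).  Contributions of ``c_invest`` each are multiplied by ``r_mult``
and shared equally among all participants.  If a group contains fewer than
two participants no game takes place and the would-be participant also
receives ``sigma``.  After the interaction, punishment is applied: an
individual carrying a punishment flag against a base type fines every other
group member of that type (the target loses ``fine`` per punisher, the
punisher pays ``fine_cost`` per target).

Two strategy spaces are provided:

* the four classic types C, D, P (cooperator that punishes defectors) and L
  with the uniform kernel or the loner-exit kernel (mutations out of the
  loner state deflated by a factor ``alpha``), including the closed-form
  strong-selection stationary distributions; and
* the 24-strategy space crossing base in {C, D, L} with three independent
  punishment flags (against C, D and L; labels like ``D-NNP``), which
  admits antisocial punishment, together with its position-wise
  (bitwise-like) mutation kernel.

All expected payoffs are exact hypergeometric expectations over group
compositions — no Monte Carlo.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from math import comb

import numpy as np
import pandas as pd

from .core import (
    EmbeddedChain,
    MutationKernel,
    PopulationConfig,
    StationaryDistribution,
    build_embedded_chain,
    stationary_distribution,
    strong_selection_fixation,
    uniform_kernel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PGGParams",
    "RandNowakStrategy",
    "STRATEGIES_24",
    "LABELS_24",
    "LABELS_4",
    "pgg4_payoffs",
    "pgg4_delta_fn",
    "rand_nowak_payoffs",
    "rand_nowak_delta_fn",
    "loner_kernel",
    "bitwise_like_kernel_24",
    "strong_selection_rho_4",
    "strong_selection_stationary_4",
    "stationary_closed_form_uniform",
    "stationary_closed_form_loner",
    "sociality_condition",
    "is_self_punishing",
    "report_distribution_24",
    "default_pgg_params",
]


@dataclass(frozen=True)
class PGGParams:
    """Parameters of the optional public goods game with punishment.

    ``fine`` is the amount a punished individual loses per punisher and
    ``fine_cost`` what each punisher pays per target (the classic fine /
    cost pair; the fine is *not* the intensity of selection, which keeps
    the name beta throughout the package).  ``alpha`` in (0, 1] deflates
    mutation rates out of the loner state in the loner-exit kernel.
    """

    N: int = 100
    n_group: int = 5
    c_invest: float = 1.0
    r_mult: float = 3.0
    sigma: float = 1.0
    fine: float = 1.0
    fine_cost: float = 0.3
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 2 <= self.n_group <= self.N:
            raise ValueError("need 2 <= n_group <= N")
        if not self.r_mult > 1:
            raise ValueError("r_mult must exceed 1")
        if not self.c_invest > 0:
            raise ValueError("c_invest must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.sigma < (self.r_mult - 1) * self.c_invest):
            warnings.warn(
                "sigma outside (0, (r-1)c): loners do not sit strictly between "
                "all-defect and all-cooperate group payoffs",
                stacklevel=2,
            )

    @property
    def payoff_scale(self) -> float:
        """Magnitude bound on single-round payoffs, for neutrality tolerances."""
        n = self.n_group
        return max(
            self.r_mult * self.c_invest * n,
            self.sigma,
            n * (self.fine + self.fine_cost),
        )


@dataclass(frozen=True)
class RandNowakStrategy:
    """Strategy of the 24-strategy space: base type plus punishment flags.

    ``base`` is the participation/contribution choice in {C, D, L};
    ``punish`` holds three booleans for punishing cooperators, defectors
    and loners, in that order.  The canonical label is e.g. ``C-NPN``
    (cooperator punishing defectors) or ``L-PNN`` (loner punishing
    cooperators).
    """

    base: str
    punish: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if self.base not in ("C", "D", "L"):
            raise ValueError("base must be one of C, D, L")
        if len(self.punish) != 3:
            raise ValueError("punish must hold three flags (targets C, D, L)")

    @property
    def label(self) -> str:
        flags = "".join("P" if f else "N" for f in self.punish)
        return f"{self.base}-{flags}"

    @classmethod
    def from_label(cls, label: str) -> "RandNowakStrategy":
        base, _, flags = label.partition("-")
        if len(flags) != 3 or any(f not in "NP" for f in flags):
            raise ValueError(f"malformed strategy label {label!r}")
        return cls(base=base, punish=tuple(f == "P" for f in flags))

    def punishes(self, target_base: str) -> bool:
        return self.punish["CDL".index(target_base)]

    @property
    def participates(self) -> bool:
        return self.base != "L"

    @property
    def contributes(self) -> bool:
        return self.base == "C"


#: 24 strategies in lexicographic (base, flags) order: C-NNN .. L-PPP.
STRATEGIES_24: tuple[RandNowakStrategy, ...] = tuple(
    RandNowakStrategy(base=b, punish=(pc, pd_, pl))
    for b in ("C", "D", "L")
    for pc, pd_, pl in product((False, True), repeat=3)
)
LABELS_24: tuple[str, ...] = tuple(s.label for s in STRATEGIES_24)

#: The four classic types expressed inside the 24-strategy space.
LABELS_4: tuple[str, ...] = ("C", "D", "P", "L")
_FOUR_AS_24 = {
    "C": RandNowakStrategy("C", (False, False, False)),
    "D": RandNowakStrategy("D", (False, False, False)),
    "P": RandNowakStrategy("C", (False, True, False)),
    "L": RandNowakStrategy("L", (False, False, False)),
}


# ---------------------------------------------------------------------------
# exact group payoffs
# ---------------------------------------------------------------------------


def _focal_group_payoff(
    focal: RandNowakStrategy,
    co_players: tuple[tuple[RandNowakStrategy, int], ...],
    p: PGGParams,
) -> float:
    """Payoff of the focal individual in one explicit group composition."""
    n_part = int(focal.participates) + sum(
        k for s, k in co_players if s.participates
    )
    n_contrib = int(focal.contributes) + sum(
        k for s, k in co_players if s.contributes
    )
    if not focal.participates or n_part < 2:
        g = p.sigma
    else:
        g = p.r_mult * p.c_invest * n_contrib / n_part
        if focal.contributes:
            g -= p.c_invest
    # punishment stage: based on expressed base types, applied per group
    for s, k in co_players:
        if s.punishes(focal.base):
            g -= k * p.fine
        if focal.punishes(s.base):
            g -= k * p.fine_cost
    return g


def _dimorphic_payoffs(
    p: PGGParams,
    resident: RandNowakStrategy,
    invader: RandNowakStrategy,
    i: int,
    N: int,
) -> tuple[float, float]:
    """(pi_invader(i), pi_resident(i)) with i invaders among N, exact.

    Co-players are the other n_group - 1 members of a group drawn without
    replacement, so the number of invader co-players is hypergeometric.
    """
    if not 0 < i < N:
        raise ValueError("invader count must satisfy 0 < i < N")
    if N < p.n_group:
        raise ValueError("population smaller than the interaction group")
    m = p.n_group - 1
    denom = comb(N - 1, m)
    g_inv = [
        _focal_group_payoff(invader, ((invader, j), (resident, m - j)), p)
        for j in range(m + 1)
    ]
    g_res = [
        _focal_group_payoff(resident, ((invader, j), (resident, m - j)), p)
        for j in range(m + 1)
    ]
    pi_inv = sum(
        comb(i - 1, j) * comb(N - i, m - j) * g_inv[j]
        for j in range(m + 1)
        if j <= i - 1 and m - j <= N - i
    ) / denom
    pi_res = sum(
        comb(i, j) * comb(N - 1 - i, m - j) * g_res[j]
        for j in range(m + 1)
        if j <= i and m - j <= N - 1 - i
    ) / denom
    return float(pi_inv), float(pi_res)


def pgg4_payoffs(
    params: PGGParams, resident: str, invader: str, i: int, N: int | None = None
) -> tuple[float, float]:
    """Exact expected payoffs (invader, resident) in the 4-strategy game.

    ``resident`` and ``invader`` are labels among C, D, P, L; ``i`` is the
    invader count.  A lone would-be participant receives sigma.
    """
    N = params.N if N is None else N
    return _dimorphic_payoffs(params, _FOUR_AS_24[resident], _FOUR_AS_24[invader], i, N)


def rand_nowak_payoffs(
    params: PGGParams,
    resident: RandNowakStrategy | str,
    invader: RandNowakStrategy | str,
    i: int,
    N: int | None = None,
) -> tuple[float, float]:
    """Exact expected payoffs (invader, resident) in the 24-strategy game."""
    N = params.N if N is None else N
    if isinstance(resident, str):
        resident = RandNowakStrategy.from_label(resident)
    if isinstance(invader, str):
        invader = RandNowakStrategy.from_label(invader)
    return _dimorphic_payoffs(params, resident, invader, i, N)


def _delta_fn_for(params: PGGParams, strategies: tuple[RandNowakStrategy, ...]):
    """Payoff-difference callable for the embedded-chain builder.

    Precomputes, per ordered pair, the focal payoffs for every co-player
    composition, then folds them with hypergeometric weights for all
    invader counts at once.
    """
    m = params.n_group - 1

    @lru_cache(maxsize=None)
    def pair_tables(inv: int, res: int) -> tuple[np.ndarray, np.ndarray]:
        s_inv, s_res = strategies[inv], strategies[res]
        g_inv = np.array(
            [
                _focal_group_payoff(s_inv, ((s_inv, j), (s_res, m - j)), params)
                for j in range(m + 1)
            ]
        )
        g_res = np.array(
            [
                _focal_group_payoff(s_res, ((s_inv, j), (s_res, m - j)), params)
                for j in range(m + 1)
            ]
        )
        return g_inv, g_res

    @lru_cache(maxsize=8)
    def weights(N: int) -> tuple[np.ndarray, np.ndarray]:
        denom = comb(N - 1, m)
        W_inv = np.zeros((N - 1, m + 1))  # focal invader, i = 1..N-1
        W_res = np.zeros((N - 1, m + 1))  # focal resident
        for row, i in enumerate(range(1, N)):
            for j in range(m + 1):
                if j <= i - 1 and m - j <= N - i:
                    W_inv[row, j] = comb(i - 1, j) * comb(N - i, m - j) / denom
                if j <= i and m - j <= N - 1 - i:
                    W_res[row, j] = comb(i, j) * comb(N - 1 - i, m - j) / denom
        return W_inv, W_res

    def deltas(inv: int, res: int, N: int) -> np.ndarray:
        g_inv, g_res = pair_tables(inv, res)
        W_inv, W_res = weights(N)
        return W_inv @ g_inv - W_res @ g_res

    return deltas


def pgg4_delta_fn(params: PGGParams):
    """Payoff-difference callable over (C, D, P, L) for the chain builder."""
    return _delta_fn_for(params, tuple(_FOUR_AS_24[l] for l in LABELS_4))


def rand_nowak_delta_fn(params: PGGParams):
    """Payoff-difference callable over the 24 strategies for the chain builder."""
    return _delta_fn_for(params, STRATEGIES_24)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def loner_kernel(alpha: float, rate: float) -> MutationKernel:
    """4-strategy kernel (order C, D, P, L) with deflated loner exits.

    Rows C, D, P are uniform (mu/3 to each other type); the loner row's
    off-diagonal entries are multiplied by alpha, the diagonal absorbing
    the difference, so the total mutation mass out of L is alpha * mu.
    alpha = 1 recovers the uniform kernel exactly.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if not 0 < rate < 1:
        raise ValueError("mutation rate must lie in (0, 1)")
    M = np.full((4, 4), rate / 3.0)
    np.fill_diagonal(M, 1.0 - rate)
    M[3, :3] *= alpha
    M[3, 3] = 1.0 - alpha * rate
    return MutationKernel(matrix=M, labels=LABELS_4, rate=rate)


def bitwise_like_kernel_24(rate: float) -> MutationKernel:
    """Position-wise kernel on the 24-strategy space.

    Two strategies are neighbours iff they differ in exactly one of the
    four positions (base or one punishment flag); the base contributes two
    neighbours and each flag one, so every strategy has exactly five
    neighbours, each reached with probability mu/5.
    """
    if not 0 < rate < 1:
        raise ValueError("mutation rate must lie in (0, 1)")
    n = len(STRATEGIES_24)
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            sa, sb = STRATEGIES_24[a], STRATEGIES_24[b]
            diffs = int(sa.base != sb.base) + sum(
                x != y for x, y in zip(sa.punish, sb.punish)
            )
            if diffs == 1:
                M[a, b] = rate / 5.0
    np.fill_diagonal(M, 1.0 - rate)
    return MutationKernel(matrix=M, labels=LABELS_24, rate=rate)


# ---------------------------------------------------------------------------
# strong selection in the 4-strategy system
# ---------------------------------------------------------------------------


def strong_selection_rho_4(params: PGGParams, N: int | None = None) -> np.ndarray:
    """Matrix of beta -> infinity fixation probabilities, rho[res, inv]."""
    N = params.N if N is None else N
    delta_fn = pgg4_delta_fn(params)
    rho = np.zeros((4, 4))
    for res in range(4):
        for inv in range(4):
            if inv == res:
                continue
            d = delta_fn(inv, res, N)
            rho[res, inv] = strong_selection_fixation(
                None, inv, res, N, deltas=d, payoff_scale=params.payoff_scale
            ).rho
    return rho


def _expected_rho_pattern(N: int) -> np.ndarray:
    """Strong-selection transition template of the classic parameter regime.

    Defection invades and replaces cooperation, loners replace defectors,
    punishers and cooperators drift neutrally (rho = 1/N), and entering the
    game from the loner state costs one neutral step (rho = 1/2); all other
    invasions fail.
    """
    rho = np.zeros((4, 4))
    i = {l: k for k, l in enumerate(LABELS_4)}
    rho[i["C"], i["D"]] = 1.0
    rho[i["C"], i["P"]] = 1.0 / N
    rho[i["P"], i["C"]] = 1.0 / N
    rho[i["D"], i["L"]] = 1.0
    rho[i["L"], i["C"]] = 0.5
    rho[i["L"], i["P"]] = 0.5
    return rho


def stationary_closed_form_uniform(N: int) -> StationaryDistribution:
    """Strong-selection stationary distribution under uniform mutations.

    pi = (2, 2, N + 2, 2) / (N + 8) in the order (C, D, P, L): altruistic
    punishers predominate for any N.
    """
    pi = np.array([2.0, 2.0, N + 2.0, 2.0]) / (N + 8.0)
    return StationaryDistribution(pi=pi, labels=LABELS_4)


def stationary_closed_form_loner(N: int, alpha: float) -> StationaryDistribution:
    """Strong-selection stationary distribution under the loner-exit kernel.

    pi = (2 alpha, 2 alpha, (N + 2) alpha, 2) / (alpha (N + 6) + 2); at
    alpha = 1 this reduces to the uniform-kernel result, and as alpha -> 0
    the loner state absorbs the stationary mass.
    """
    z = alpha * (N + 6.0) + 2.0
    pi = np.array([2.0 * alpha, 2.0 * alpha, (N + 2.0) * alpha, 2.0]) / z
    return StationaryDistribution(pi=pi, labels=LABELS_4)


def strong_selection_stationary_4(
    params: PGGParams, kernel_kind: str = "uniform", N: int | None = None
) -> StationaryDistribution:
    """Stationary distribution of the 4-strategy system at beta -> infinity.

    Uses the closed form when the pairwise strong-selection fixation
    probabilities exhibit the classic transition structure; otherwise falls
    back to the generic embedded-chain route (with a logged notice).
    """
    if kernel_kind not in ("uniform", "loner"):
        raise ValueError("kernel_kind must be 'uniform' or 'loner'")
    N = params.N if N is None else N
    alpha = params.alpha
    rho = strong_selection_rho_4(params, N)
    in_regime = np.allclose(rho, _expected_rho_pattern(N), atol=1e-12)
    if in_regime:
        if kernel_kind == "uniform":
            return stationary_closed_form_uniform(N)
        return stationary_closed_form_loner(N, alpha)
    logger.warning(
        "strong-selection transition structure outside the closed-form regime; "
        "using the generic embedded-chain route"
    )
    mu = 1e-3  # arbitrary: the stationary vector is invariant to the scale
    kernel = (
        uniform_kernel(4, mu, LABELS_4)
        if kernel_kind == "uniform"
        else loner_kernel(alpha, mu)
    )
    chain = build_embedded_chain(
        pgg4_delta_fn(params),
        kernel,
        PopulationConfig(N=N, beta=1.0),
        strong_selection=True,
        payoff_scale=params.payoff_scale,
        labels=LABELS_4,
    )
    return stationary_distribution(chain)


def sociality_condition(params: PGGParams, N: int | None = None) -> bool:
    """Is playing the game more abundant than abstaining at strong selection?

    Evaluates the closed-form inequality alpha (N + 6) > 2 implied by the
    loner-kernel stationary distribution and, independently, compares the
    stationary masses computed by the generic embedded-chain route; the two
    must agree (an internal consistency error otherwise).
    """
    N = params.N if N is None else N
    closed = params.alpha * (N + 6.0) > 2.0
    mu = 1e-3
    chain = build_embedded_chain(
        pgg4_delta_fn(params),
        loner_kernel(params.alpha, mu),
        PopulationConfig(N=N, beta=1.0),
        strong_selection=True,
        payoff_scale=params.payoff_scale,
        labels=LABELS_4,
    )
    pi = stationary_distribution(chain)
    generic = (pi["C"] + pi["D"] + pi["P"]) > pi["L"]
    if closed != generic:
        raise RuntimeError(
            "closed-form sociality condition disagrees with the generic "
            f"stationary route (closed={closed}, generic={generic})"
        )
    return closed


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def is_self_punishing(strategy: RandNowakStrategy | str) -> bool:
    """Whether the punishment flags target the strategy's own base type."""
    if isinstance(strategy, str):
        strategy = RandNowakStrategy.from_label(strategy)
    return strategy.punishes(strategy.base)


def report_distribution_24(
    dist: StationaryDistribution, exclude_self_punishers: bool = True
) -> pd.DataFrame:
    """Ranked abundance table over the 24 strategies.

    Self-punishing strategies (e.g. C-P.., whose stationary frequency is
    very low) can be dropped from the *display*; they always remain part of
    the computation, so the probabilities of the full distribution still
    sum to one.
    """
    if set(dist.labels) != set(LABELS_24):
        raise ValueError("distribution must cover the 24-strategy space")
    df = pd.DataFrame(
        {
            "strategy": dist.labels,
            "abundance": dist.pi,
            "self_punishing": [is_self_punishing(l) for l in dist.labels],
        }
    )
    if exclude_self_punishers:
        df = df[~df.self_punishing]
    return df.sort_values("abundance", ascending=False, ignore_index=True)


def default_pgg_params() -> PGGParams:
    """Reference parameter set: N=100 groups of 5, r=3, c=1, sigma=1,
    fine 1 at cost 0.3."""
    return PGGParams()
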