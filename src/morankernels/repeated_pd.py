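"""Repeated prisoner's dilemma with deterministic memory-one strategies.

Each strategy is a three-bit automaton ``(first_move, reply_to_C,
reply_to_D)`` with 0 = cooperate and 1 = defect, giving the eight
deterministic strategies that condition on the opponent's last move only:

====  ======  ==========================================
code  name    behaviour
====  ======  ==========================================
000   ALLC    always cooperate
001   TFT     tit for tat
010   ATFT    cooperate first, then reverse the opponent's last move
011   NALLD   cooperate once, then always defect
100   SALLC   defect once, then always cooperate
101   STFT    defect once, then copy the opponent's last move
110   ASTFT   defect once, then reverse the opponent's last move
111   ALLD    always defect
====  ======  ==========================================

Play between two such automata is eventually periodic with a short
pre-period; payoffs of the repeated game with continuation probability
``w < 1`` are the (1 - w)-normalised discounted sums, computed in closed
form from the detected cycle (no truncation).  The natural mutation
structure of the binary coding is the bitwise kernel in which each strategy
has exactly the three Hamming-1 neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import MutationKernel, PayoffMatrix

__all__ = [
    "MemoryOneStrategy",
    "RepeatedGameSpec",
    "PlayTrace",
    "STRATEGIES",
    "STRATEGY_NAMES",
    "play",
    "discounted_payoff",
    "payoff_matrix_8",
    "bitwise_kernel",
    "is_fully_cooperative",
    "fully_cooperative_labels",
    "default_repeated_game",
    "REFERENCE_POPULATION_SIZE",
]

C, D = 0, 1

_NAMES = ("ALLC", "TFT", "ATFT", "NALLD", "SALLC", "STFT", "ASTFT", "ALLD")


@dataclass(frozen=True)
class MemoryOneStrategy:
    """Deterministic memory-one strategy coded as three bits."""

    code: tuple[int, int, int]
    name: str

    def __post_init__(self) -> None:
        if len(self.code) != 3 or any(b not in (0, 1) for b in self.code):
            raise ValueError("strategy code must be three bits in {0, 1}")

    @property
    def first_move(self) -> int:
        return self.code[0]

    def reply(self, opponent_last: int) -> int:
        return self.code[1] if opponent_last == C else self.code[2]

    @property
    def bits(self) -> str:
        return "".join(str(b) for b in self.code)


#: The eight strategies in binary-code order (000 .. 111).
STRATEGIES: tuple[MemoryOneStrategy, ...] = tuple(
    MemoryOneStrategy(code=((i >> 2) & 1, (i >> 1) & 1, i & 1), name=_NAMES[i])
    for i in range(8)
)
STRATEGY_NAMES: tuple[str, ...] = _NAMES


def strategy_by_name(name: str) -> MemoryOneStrategy:
    for s in STRATEGIES:
        if s.name == name:
            return s
    raise KeyError(f"unknown strategy {name!r}")


@dataclass(frozen=True)
class RepeatedGameSpec:
    """One-shot prisoner's dilemma payoffs plus continuation probability w.

    The one-shot entries must satisfy the dilemma ordering T > R > P > S;
    2R > T + S (mutual cooperation beats alternation) is checked with a
    warning only.
    """

    R: float
    S: float
    T: float
    P: float
    w: float

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError("prisoner's dilemma requires T > R > P > S")
        if not 0.0 <= self.w < 1.0:
            raise ValueError("continuation probability w must lie in [0, 1)")
        if not 2 * self.R > self.T + self.S:
            warnings.warn("2R <= T + S: alternating exploitation beats mutual "
                          "cooperation", stacklevel=2)

    def one_shot(self) -> PayoffMatrix:
        return PayoffMatrix(
            values=np.array([[self.R, self.S], [self.T, self.P]]),
            labels=("C", "D"),
        )

    def round_payoff(self, own: int, other: int) -> float:
        return ((self.R, self.S), (self.T, self.P))[own][other]


@dataclass(frozen=True)
class PlayTrace:
    """Eventually periodic joint action sequence of a strategy pair.

    ``preperiod`` and ``cycle`` are lists of joint actions (a1, a2); the
    cycle is minimal.  Because the joint last-action state space has four
    states plus the opening move, preperiod + cycle never exceeds five
    rounds.
    """

    preperiod: tuple[tuple[int, int], ...]
    cycle: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.cycle:
            raise ValueError("cycle must be non-empty")
        if len(self.preperiod) + len(self.cycle) > 5:
            raise ValueError("trace longer than the joint state space allows")

    def round(self, t: int) -> tuple[int, int]:
        if t < len(self.preperiod):
            return self.preperiod[t]
        return self.cycle[(t - len(self.preperiod)) % len(self.cycle)]


def play(s1: MemoryOneStrategy, s2: MemoryOneStrategy) -> PlayTrace:
    """Deterministic play of two automata; returns pre-period and minimal cycle.

    Iterates the joint action map from the opening moves until a joint
    action repeats; since the next joint action depends only on the current
    one, the first repetition closes the (minimal) cycle.
    """
    state = (s1.first_move, s2.first_move)
    seen: dict[tuple[int, int], int] = {}
    seq: list[tuple[int, int]] = []
    while state not in seen:
        seen[state] = len(seq)
        seq.append(state)
        state = (s1.reply(state[1]), s2.reply(state[0]))
    start = seen[state]
    return PlayTrace(preperiod=tuple(seq[:start]), cycle=tuple(seq[start:]))


def discounted_payoff(
    trace: PlayTrace, spec: RepeatedGameSpec, perspective: str = "first"
) -> float:
    """(1 - w)-normalised discounted payoff of the repeated game, closed form.

    Equals (1 - w) * sum_t w^t pi_t with pi_t the per-round payoff: a finite
    sum over the pre-period plus the cycle sum times w^p / (1 - w^L).  A
    constant per-round payoff p therefore yields exactly p for every w.
    """
    if perspective not in ("first", "second"):
        raise ValueError("perspective must be 'first' or 'second'")
    if not 0.0 <= spec.w < 1.0:
        raise ValueError("continuation probability w must lie in [0, 1)")
    w = spec.w

    def payoff(joint: tuple[int, int]) -> float:
        a, b = joint
        return spec.round_payoff(a, b) if perspective == "first" else spec.round_payoff(b, a)

    total = 0.0
    wt = 1.0
    for joint in trace.preperiod:
        total += wt * payoff(joint)
        wt *= w
    L = len(trace.cycle)
    cyc = 0.0
    ws = 1.0
    for joint in trace.cycle:
        cyc += ws * payoff(joint)
        ws *= w
    total += wt * cyc / (1.0 - w**L)
    return (1.0 - w) * total


def payoff_matrix_8(spec: RepeatedGameSpec) -> PayoffMatrix:
    """8x8 repeated-game payoff matrix in binary-code (table) order.

    Entry (i, j) is the discounted payoff of strategy i against strategy j
    from the row player's perspective.
    """
    n = len(STRATEGIES)
    V = np.empty((n, n))
    for i, si in enumerate(STRATEGIES):
        for j, sj in enumerate(STRATEGIES):
            V[i, j] = discounted_payoff(play(si, sj), spec, "first")
    return PayoffMatrix(values=V, labels=STRATEGY_NAMES)


def bitwise_kernel(rate: float) -> MutationKernel:
    """Bitwise mutation kernel on the 3-cube of strategy codes.

    Off-diagonal entry mu/3 exactly when the two codes differ in one bit;
    diagonal 1 - mu.  Every strategy has exactly three neighbours, and the
    kernel is symmetric and connected.
    """
    if not 0 < rate < 1:
        raise ValueError("mutation rate must lie in (0, 1)")
    n = 8
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if bin(i ^ j).count("1") == 1:
                M[i, j] = rate / 3.0
    np.fill_diagonal(M, 1.0 - rate)
    return MutationKernel(matrix=M, labels=STRATEGY_NAMES, rate=rate)


def is_fully_cooperative(strategy: MemoryOneStrategy) -> bool:
    """Whether self-play settles into permanent mutual cooperation.

    Computed from the self-play trace: the strategy is fully cooperative
    when its minimal self-play cycle is all (C, C).
    """
    trace = play(strategy, strategy)
    return all(joint == (C, C) for joint in trace.cycle)


def fully_cooperative_labels() -> tuple[str, ...]:
    """Names of the strategies that cooperate with themselves in the long run."""
    return tuple(s.name for s in STRATEGIES if is_fully_cooperative(s))


#: One-shot payoffs and continuation probability of the reference
#: parameterisation (Axelrod values R=3, S=0, T=5, P=1 with w = 0.9).
def default_repeated_game() -> RepeatedGameSpec:
    return RepeatedGameSpec(R=3.0, S=0.0, T=5.0, P=1.0, w=0.9)


#: Population size used in the reference abundance computations.
REFERENCE_POPULATION_SIZE = 100
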