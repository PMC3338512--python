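"""Monte Carlo Moran simulation at finite mutation rates.

Validates the rare-mutation analytics and explores the larger-mu regime.
Each birth-death event: one individual reproduces with probability
proportional to count * exp(beta * expected payoff), the offspring mutates
according to the kernel row of its parent, and the individual to be removed
is drawn uniformly from all N individuals *before* the offspring is added
(the parent itself may die).  Runs start from a composition drawn uniformly
at random over the integer simplex; abundance is averaged over a trailing
window of each run and across independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import comb

import numpy as np
from numba import njit

from .core import MutationKernel, PayoffMatrix, PopulationConfig, small_mutation_validity
from .public_goods import PGGParams, RandNowakStrategy, _focal_group_payoff

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "run_moran",
    "run_moran_pgg",
    "pgg_payoff_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation sizes: runs, generations (N events each), mu, window, seed."""

    runs: int
    generations: int
    mu: float
    window_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1 or self.generations < 1:
            raise ValueError("runs and generations must be at least 1")
        if not 0 < self.mu < 1:
            raise ValueError("mu must lie in (0, 1)")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationResult:
    """Run- and time-averaged strategy frequencies with across-run errors."""

    mean_abundance: np.ndarray
    stderr: np.ndarray
    labels: tuple[str, ...]
    seed_used: int

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.mean_abundance)) - 1.0) > 1e-9:
            raise ValueError("mean abundance must sum to 1")


@njit(cache=False)
def _moran_matrix_core(A, kern_cum, counts, beta, n_events, window_start, seed):
    np.random.seed(seed)
    k = counts.shape[0]
    N = 0
    for j in range(k):
        N += counts[j]
    acc = np.zeros(k)
    w = np.empty(k)
    for t in range(n_events):
        tot = 0.0
        for j in range(k):
            if counts[j] > 0:
                s = 0.0
                for l in range(k):
                    s += A[j, l] * counts[l]
                s = (s - A[j, j]) / (N - 1)
                w[j] = counts[j] * np.exp(beta * s)
            else:
                w[j] = 0.0
            tot += w[j]
        r = np.random.random() * tot
        parent = 0
        csum = w[0]
        while csum < r and parent < k - 1:
            parent += 1
            csum += w[parent]
        u = np.random.random()
        off = 0
        while kern_cum[parent, off] < u and off < k - 1:
            off += 1
        r = np.random.random() * N
        dead = 0
        csum = counts[0]
        while csum < r and dead < k - 1:
            dead += 1
            csum += counts[dead]
        counts[dead] -= 1
        counts[off] += 1
        if t >= window_start:
            for j in range(k):
                acc[j] += counts[j]
    return acc / ((n_events - window_start) * N)


@njit(cache=False)
def _moran_table_core(paytab, strides, kern_cum, counts, beta, n_events,
                      window_start, seed):
    np.random.seed(seed)
    k = counts.shape[0]
    N = 0
    for j in range(k):
        N += counts[j]
    acc = np.zeros(k)
    w = np.empty(k)
    for t in range(n_events):
        idx = 0
        for j in range(k - 1):
            idx += counts[j] * strides[j]
        tot = 0.0
        for j in range(k):
            if counts[j] > 0:
                w[j] = counts[j] * np.exp(beta * paytab[idx, j])
            else:
                w[j] = 0.0
            tot += w[j]
        r = np.random.random() * tot
        parent = 0
        csum = w[0]
        while csum < r and parent < k - 1:
            parent += 1
            csum += w[parent]
        u = np.random.random()
        off = 0
        while kern_cum[parent, off] < u and off < k - 1:
            off += 1
        r = np.random.random() * N
        dead = 0
        csum = counts[0]
        while csum < r and dead < k - 1:
            dead += 1
            csum += counts[dead]
        counts[dead] -= 1
        counts[off] += 1
        if t >= window_start:
            for j in range(k):
                acc[j] += counts[j]
    return acc / ((n_events - window_start) * N)


def _random_composition(rng: np.random.Generator, N: int, k: int) -> np.ndarray:
    """Uniform draw over the integer compositions of N into k parts."""
    cuts = np.sort(rng.choice(N + k - 1, size=k - 1, replace=False))
    full = np.concatenate(([-1], cuts, [N + k - 1]))
    return (np.diff(full) - 1).astype(np.int64)


def _prepare(kernel: MutationKernel, pop: PopulationConfig, sim: SimulationConfig):
    if kernel.rate is not None and abs(kernel.rate - sim.mu) > 1e-12:
        raise ValueError(
            f"kernel rate {kernel.rate} inconsistent with sim.mu {sim.mu}"
        )
    small_mutation_validity(pop.N, sim.mu)
    kern_cum = np.cumsum(kernel.matrix, axis=1)
    n_events = sim.generations * pop.N
    window_start = int(round((1.0 - sim.window_fraction) * n_events))
    ss = np.random.SeedSequence(sim.seed)
    run_seeds = (ss.generate_state(sim.runs, dtype=np.uint32) % (2**31)).astype(
        np.int64
    )
    rng = np.random.default_rng(ss.spawn(1)[0])
    return kern_cum, n_events, window_start, run_seeds, rng


def _collect(per_run: np.ndarray, labels, seed: int) -> SimulationResult:
    mean = per_run.mean(axis=0)
    mean = mean / mean.sum()
    if per_run.shape[0] > 1:
        stderr = per_run.std(axis=0, ddof=1) / np.sqrt(per_run.shape[0])
    else:
        stderr = np.full(per_run.shape[1], np.nan)
    return SimulationResult(
        mean_abundance=mean, stderr=stderr, labels=tuple(labels), seed_used=seed
    )


def run_moran(
    game: PayoffMatrix,
    kernel: MutationKernel,
    pop: PopulationConfig,
    sim: SimulationConfig,
    *,
    initial_counts: np.ndarray | None = None,
) -> SimulationResult:
    """Simulate the Moran process for a matrix game.

    Fitness is recomputed from the current composition at every event
    (pairwise payoffs excluding self-interaction, exponential mapping).
    Identical configurations and seeds give bitwise-identical results.
    ``initial_counts`` overrides the random initial composition, e.g. a
    monomorphic start for empirical fixation checks.
    """
    if game.n != kernel.n:
        raise ValueError("game and kernel dimensions differ")
    kern_cum, n_events, window_start, run_seeds, rng = _prepare(kernel, pop, sim)
    per_run = np.empty((sim.runs, game.n))
    for r in range(sim.runs):
        if initial_counts is None:
            counts = _random_composition(rng, pop.N, game.n)
        else:
            counts = np.asarray(initial_counts, dtype=np.int64).copy()
            if counts.sum() != pop.N:
                raise ValueError("initial counts must sum to N")
        per_run[r] = _moran_matrix_core(
            game.values, kern_cum, counts, pop.beta, n_events, window_start,
            int(run_seeds[r]),
        )
    return _collect(per_run, game.labels, sim.seed)


def pgg_payoff_table(
    params: PGGParams, strategies: tuple[RandNowakStrategy, ...], N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact expected payoff of each type for every population composition.

    Returns ``(table, strides)``: the payoff vector of composition
    ``counts`` lives at flat index ``sum(counts[j] * strides[j], j < k-1)``
    (the last count is implied by N).  Expectations are hypergeometric over
    the co-player draw; compositions where a type is absent leave zeros.
    """
    k = len(strategies)
    m = params.n_group - 1
    strides = np.array([(N + 1) ** j for j in range(k - 1)], dtype=np.int64)
    table = np.zeros(((N + 1) ** (k - 1), k))
    co_comps = [
        comp
        for comp in product(range(m + 1), repeat=k)
        if sum(comp) == m
    ]
    # focal payoff per (focal strategy, co-player composition)
    g = {
        (f, comp): _focal_group_payoff(
            strategies[f],
            tuple((strategies[j], comp[j]) for j in range(k) if comp[j] > 0),
            params,
        )
        for f in range(k)
        for comp in co_comps
    }
    denom = comb(N - 1, m)

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    for counts in compositions(N, k):
        idx = sum(counts[j] * int(strides[j]) for j in range(k - 1))
        for f in range(k):
            if counts[f] == 0:
                continue
            avail = list(counts)
            avail[f] -= 1
            total = 0.0
            for comp in co_comps:
                wgt = 1
                ok = True
                for j in range(k):
                    if comp[j] > avail[j]:
                        ok = False
                        break
                    wgt *= comb(avail[j], comp[j])
                if ok:
                    total += wgt * g[(f, comp)]
            table[idx, f] = total / denom
    return table, strides


def run_moran_pgg(
    params: PGGParams,
    strategies: tuple[RandNowakStrategy, ...],
    labels: tuple[str, ...],
    kernel: MutationKernel,
    pop: PopulationConfig,
    sim: SimulationConfig,
    *,
    initial_counts: np.ndarray | None = None,
) -> SimulationResult:
    """Simulate the Moran process for an optional public goods game.

    Uses an exact per-composition expected-payoff table (feasible for the
    4-strategy system) shared with the same event core as matrix games.
    """
    k = len(strategies)
    if kernel.n != k:
        raise ValueError("kernel dimension must match the strategy count")
    if k > 4:
        raise ValueError("payoff table is only feasible for up to 4 types")
    kern_cum, n_events, window_start, run_seeds, rng = _prepare(kernel, pop, sim)
    table, strides = pgg_payoff_table(params, strategies, pop.N)
    per_run = np.empty((sim.runs, k))
    for r in range(sim.runs):
        if initial_counts is None:
            counts = _random_composition(rng, pop.N, k)
        else:
            counts = np.asarray(initial_counts, dtype=np.int64).copy()
            if counts.sum() != pop.N:
                raise ValueError("initial counts must sum to N")
        per_run[r] = _moran_table_core(
            table, strides, kern_cum, counts, pop.beta, n_events, window_start,
            int(run_seeds[r]),
        )
    return _collect(per_run, labels, sim.seed)
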