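"""Core Moran analytics: payoffs, fixation, embedded chain, abundance."""

import math

import numpy as np
import pytest

from morankernels import core
from morankernels.core import (
    EmbeddedChain,
    MutationKernel,
    PayoffMatrix,
    PopulationConfig,
    abundance_condition_2x2,
    abundance_condition_2x2_closed_form,
    build_embedded_chain,
    expected_payoffs,
    fixation_probability,
    reversal_ratio,
    stationary_distribution,
    strong_selection_fixation,
    uniform_kernel,
)

from conftest import random_2x2


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def enumeration_payoffs(V, i, N):
    """Average payoff over explicit enumeration of the N-1 co-players."""
    pops = ["A"] * i + ["B"] * (N - i)
    pay = {"A": {"A": V[0, 0], "B": V[0, 1]}, "B": {"A": V[1, 0], "B": V[1, 1]}}

    def mean_payoff(k):
        me = pops[k]
        others = pops[:k] + pops[k + 1:]
        return sum(pay[me][o] for o in others) / len(others)

    pa = np.mean([mean_payoff(k) for k in range(i)]) if i else np.nan
    pb = np.mean([mean_payoff(k) for k in range(i, N)]) if i < N else np.nan
    return pa, pb


def linear_system_fixation(game, pop, dps=None):
    """Absorption probability of the birth-death Moran chain.

    States i = 0..N count invaders; at state i the forward/backward
    probabilities are fitness-weighted reproduction times uniform death.
    Solves the interior tridiagonal linear system for absorption at i = N
    (Thomas elimination) in ``dps``-digit arithmetic: under strong drift
    the system's condition number reaches ~1e16, so double precision
    cannot certify a 1e-10 comparison.
    """
    import mpmath

    N, beta = pop.N, pop.beta
    if dps is None:
        # the eliminated system spans exp(+-beta * sum |payoff differences|)
        drift = sum(
            abs(expected_payoffs(game, i, N)[0] - expected_payoffs(game, i, N)[1])
            for i in range(1, N)
        )
        dps = 60 + int(beta * drift / math.log(10))
    with mpmath.workdps(dps):
        tp = [mpmath.mpf(0)] * (N + 1)
        tm = [mpmath.mpf(0)] * (N + 1)
        for i in range(1, N):
            pa, pb = expected_payoffs(game, i, N)
            fa = mpmath.e ** (mpmath.mpf(beta) * mpmath.mpf(pa))
            fb = mpmath.e ** (mpmath.mpf(beta) * mpmath.mpf(pb))
            tot = i * fa + (N - i) * fb
            tp[i] = (i * fa / tot) * mpmath.mpf(N - i) / N
            tm[i] = ((N - i) * fb / tot) * mpmath.mpf(i) / N
        # rows: (tp+tm) x_i - tm x_{i-1} - tp x_{i+1} = 0, x_0 = 0, x_N = 1
        diag = [tp[i] + tm[i] for i in range(1, N)]
        lower = [-tm[i] for i in range(2, N)]
        upper = [-tp[i] for i in range(1, N - 1)]
        rhs = [mpmath.mpf(0)] * (N - 1)
        rhs[-1] = tp[N - 1]
        for r in range(1, N - 1):
            w = lower[r - 1] / diag[r - 1]
            diag[r] -= w * upper[r - 1]
            rhs[r] -= w * rhs[r - 1]
        x = [mpmath.mpf(0)] * (N - 1)
        x[-1] = rhs[-1] / diag[-1]
        for r in range(N - 3, -1, -1):
            x[r] = (rhs[r] - upper[r] * x[r + 1]) / diag[r]
        return float(x[0])


# ---------------------------------------------------------------------------
# expected payoffs
# ---------------------------------------------------------------------------


def test_expected_payoffs_constant_game():
    game = PayoffMatrix(values=np.ones((2, 2)), labels=("A", "B"))
    for i in range(0, 7):
        assert expected_payoffs(game, i, 6) == (1.0, 1.0)


def test_expected_payoffs_boundary_all_a(rng):
    game = random_2x2(rng)
    pa, _ = expected_payoffs(game, game_n := 8, game_n)
    assert pa == pytest.approx(game.values[0, 0])


def test_expected_payoffs_match_enumeration(rng):
    N = 6
    for _ in range(20):
        game = random_2x2(rng)
        for i in range(1, N):
            pa, pb = expected_payoffs(game, i, N)
            ea, eb = enumeration_payoffs(game.values, i, N)
            assert pa == pytest.approx(ea, abs=1e-12)
            assert pb == pytest.approx(eb, abs=1e-12)


def test_expected_payoffs_domain_errors(rng):
    game = random_2x2(rng)
    with pytest.raises(ValueError):
        expected_payoffs(game, 3, 2)
    with pytest.raises(ValueError):
        expected_payoffs(game, -1, 6)


# ---------------------------------------------------------------------------
# fixation probability
# ---------------------------------------------------------------------------


def test_neutral_fixation_is_exactly_one_over_N(rng):
    game = random_2x2(rng)
    for N in (2, 10, 100, 10_000):
        pop = PopulationConfig(N=N, beta=0.0)
        assert fixation_probability(game, 0, 1, pop).rho == 1.0 / N


def test_equal_payoff_game_is_neutral_at_any_beta():
    game = PayoffMatrix(values=np.full((2, 2), 3.7), labels=("A", "B"))
    for beta in (0.1, 1.0, 10.0):
        rho = fixation_probability(game, 0, 1, PopulationConfig(N=1000, beta=beta)).rho
        assert rho == pytest.approx(1e-3, rel=1e-12)


def test_fixation_N2_single_term(rng):
    game = random_2x2(rng)
    beta = 0.7
    pop = PopulationConfig(N=2, beta=beta)
    pa, pb = expected_payoffs(game, 1, 2)
    expected = 1.0 / (1.0 + math.exp(-beta * (pa - pb)))
    assert fixation_probability(game, 0, 1, pop).rho == pytest.approx(expected, rel=1e-14)


def test_fixation_matches_linear_system_oracle(rng):
    for _ in range(100):
        game = random_2x2(rng)
        N = int(rng.integers(3, 51))
        beta = float(rng.choice([0.1, 1.0, 10.0]))
        pop = PopulationConfig(N=N, beta=beta)
        rho = fixation_probability(game, 0, 1, pop).rho
        assert abs(rho - linear_system_fixation(game, pop)) <= 1e-10


def test_fixation_no_overflow_at_extreme_selection():
    game = PayoffMatrix(values=[[10.0, 0.0], [0.0, 10.0]], labels=("A", "B"))
    rho = fixation_probability(game, 0, 1, PopulationConfig(N=1000, beta=10.0)).rho
    assert 0.0 <= rho <= 1.0 and np.isfinite(rho)


def test_fixation_same_strategy_rejected(rng):
    game = random_2x2(rng)
    with pytest.raises(ValueError):
        fixation_probability(game, 0, 0, PopulationConfig(N=10, beta=1.0))


# ---------------------------------------------------------------------------
# embedded chain
# ---------------------------------------------------------------------------


def test_two_state_chain_matches_rare_mutation_structure(rng):
    game = random_2x2(rng)
    pop = PopulationConfig(N=20, beta=0.5)
    mu_ab, mu_ba = 2e-3, 5e-4
    M = np.array([[1 - mu_ab, mu_ab], [mu_ba, 1 - mu_ba]])
    kernel = MutationKernel(matrix=M, labels=game.labels)
    chain = build_embedded_chain(game, kernel, pop)
    rho_b = fixation_probability(game, 1, 0, pop).rho
    rho_a = fixation_probability(game, 0, 1, pop).rho
    assert chain.T[0, 1] == pytest.approx(mu_ab * rho_b, rel=1e-14)
    assert chain.T[1, 0] == pytest.approx(mu_ba * rho_a, rel=1e-14)
    assert np.allclose(chain.T.sum(axis=1), 1.0)


def test_neutral_uniform_kernel_gives_equal_off_diagonals(rng):
    game = PayoffMatrix(values=rng.uniform(0, 10, (4, 4)), labels=tuple("WXYZ"))
    chain = build_embedded_chain(
        game, uniform_kernel(4, 0.01, game.labels), PopulationConfig(N=30, beta=0.0)
    )
    off = chain.T[~np.eye(4, dtype=bool)]
    assert np.allclose(off, off[0])


def test_stationary_invariant_to_row_scale(rng):
    game = PayoffMatrix(values=rng.uniform(0, 10, (3, 3)), labels=("X", "Y", "Z"))
    kernel = uniform_kernel(3, 0.05, game.labels)
    pop = PopulationConfig(N=40, beta=1.0)
    pi1 = stationary_distribution(build_embedded_chain(game, kernel, pop, scale=1.0))
    pi2 = stationary_distribution(build_embedded_chain(game, kernel, pop, scale=0.31))
    assert np.allclose(pi1.pi, pi2.pi, atol=1e-12)


def test_chain_rejects_oversized_scale(rng):
    game = PayoffMatrix(values=rng.uniform(0, 10, (3, 3)), labels=("X", "Y", "Z"))
    kernel = uniform_kernel(3, 0.5, game.labels)
    with pytest.raises(RuntimeError):
        build_embedded_chain(game, kernel, PopulationConfig(N=5, beta=0.0), scale=15.0)


# ---------------------------------------------------------------------------
# stationary distribution
# ---------------------------------------------------------------------------


def test_two_state_stationary_matches_closed_form(rng):
    for _ in range(100):
        game = random_2x2(rng, low=0.0, high=4.0)
        pop = PopulationConfig(N=int(rng.integers(3, 40)), beta=float(rng.uniform(0, 2)))
        mu_ab, mu_ba = rng.uniform(1e-4, 1e-2, size=2)
        M = np.array([[1 - mu_ab, mu_ab], [mu_ba, 1 - mu_ba]])
        chain = build_embedded_chain(game, MutationKernel(M, game.labels), pop)
        pi = stationary_distribution(chain)
        rho_a = fixation_probability(game, 0, 1, pop).rho
        rho_b = fixation_probability(game, 1, 0, pop).rho
        closed = mu_ba * rho_a / (mu_ba * rho_a + mu_ab * rho_b)
        assert pi.pi[0] == pytest.approx(closed, abs=1e-12)
        assert pi.pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pi.pi @ chain.T, pi.pi, atol=1e-10)


def test_doubly_symmetric_chain_is_uniform(rng):
    n = 5
    W = rng.uniform(0.001, 0.01, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    T = W.copy()
    np.fill_diagonal(T, 1 - W.sum(axis=1))
    pi = stationary_distribution(EmbeddedChain(T=T, labels=tuple("ABCDE")))
    assert np.allclose(pi.pi, 1 / n, atol=1e-12)


def test_cycle_chain_is_uniform():
    n = 6
    T = 0.9 * np.eye(n) + 0.1 * np.roll(np.eye(n), 1, axis=1)
    pi = stationary_distribution(EmbeddedChain(T=T, labels=tuple("ABCDEF")))
    assert np.allclose(pi.pi, 1 / n, atol=1e-12)


def test_reducible_chain_raises_with_state_names():
    # dominance at strong selection severs the A <- B path
    game = PayoffMatrix(values=[[5.0, 5.0], [1.0, 1.0]], labels=("GOOD", "BAD"))
    chain = build_embedded_chain(
        game,
        uniform_kernel(2, 0.01, game.labels),
        PopulationConfig(N=10, beta=1.0),
        strong_selection=True,
    )
    with pytest.raises(ValueError, match="GOOD"):
        stationary_distribution(chain)


# ---------------------------------------------------------------------------
# mutation kernel validation
# ---------------------------------------------------------------------------


def test_kernel_rejects_non_stochastic_row():
    M = np.array([[0.98, 0.0], [0.01, 0.99]])
    with pytest.raises(ValueError, match="row"):
        MutationKernel(matrix=M, labels=("A", "B"))


def test_kernel_rejects_disconnected_support():
    M = np.eye(4)
    M[0, 1] = M[1, 0] = 0.01
    M[2, 3] = M[3, 2] = 0.01
    np.fill_diagonal(M, 0.99)
    with pytest.raises(ValueError, match="connected"):
        MutationKernel(matrix=M, labels=("A", "B", "C", "D"))


def test_kernel_rejects_one_way_support():
    # A -> B reachable but not B -> A: not strongly connected
    M = np.array([[0.99, 0.01], [0.0, 1.0]])
    with pytest.raises(ValueError, match="connected"):
        MutationKernel(matrix=M, labels=("A", "B"))


# ---------------------------------------------------------------------------
# 2x2 abundance condition
# ---------------------------------------------------------------------------


def test_equal_mutations_recover_risk_dominance(rng):
    pop = PopulationConfig(N=1000, beta=0.5)
    checked = 0
    while checked < 50:
        game = random_2x2(rng)
        a, b = game.values[0]
        c, d = game.values[1]
        if abs(a + b - c - d) < 0.05:
            continue
        expected = 1 if a + b > c + d else -1
        assert abundance_condition_2x2(game, pop, 1e-3, 1e-3) == expected
        assert abundance_condition_2x2_closed_form(game, pop, 1e-3, 1e-3) == expected
        checked += 1


def test_fully_symmetric_game_ties():
    game = PayoffMatrix(values=[[2.0, 5.0], [5.0, 2.0]], labels=("A", "B"))
    pop = PopulationConfig(N=50, beta=1.0)
    assert abundance_condition_2x2(game, pop, 1e-3, 1e-3) == 0


def test_exact_and_closed_form_routes_agree(rng):
    for _ in range(50):
        game = random_2x2(rng)
        pop = PopulationConfig(N=int(rng.integers(100, 500)), beta=float(rng.uniform(0.01, 1)))
        mu_ab, mu_ba = rng.uniform(1e-4, 1e-2, size=2)
        assert abundance_condition_2x2(game, pop, mu_ab, mu_ba) == (
            abundance_condition_2x2_closed_form(game, pop, mu_ab, mu_ba)
        )


def test_nonpositive_mutation_rejected(rng):
    game = random_2x2(rng)
    with pytest.raises(ValueError):
        abundance_condition_2x2(game, PopulationConfig(N=10, beta=1.0), 0.0, 1e-3)


def test_mutation_ratio_reverses_any_disadvantage(rng):
    """A finite mutation-probability ratio flips the abundance ranking."""
    checked = 0
    while checked < 25:
        game = random_2x2(rng, low=0.0, high=2.0)
        a, b = game.values[0]
        c, d = game.values[1]
        if abs(a + b - c - d) < 0.05:
            continue
        pop = PopulationConfig(N=20, beta=float(rng.uniform(0.05, 5.0)))
        qstar = reversal_ratio(game, pop)
        for q, expected in ((qstar / 4, 1), (qstar * 4, -1)):
            mu_ab = min(1e-3, 1e-3 * q)
            mu_ba = mu_ab / q
            assert abundance_condition_2x2(game, pop, mu_ab, mu_ba) == expected
        checked += 1


# ---------------------------------------------------------------------------
# strong selection limit
# ---------------------------------------------------------------------------


def test_strong_selection_neutral_pair_gives_one_over_N():
    game = PayoffMatrix(values=np.full((2, 2), 2.0), labels=("A", "B"))
    assert strong_selection_fixation(game, 0, 1, 25).rho == pytest.approx(1 / 25)


def test_strong_selection_dominant_invader_fixes():
    game = PayoffMatrix(values=[[5.0, 5.0], [1.0, 1.0]], labels=("A", "B"))
    assert strong_selection_fixation(game, 0, 1, 25).rho == 1.0


def test_strong_selection_disfavoured_invader_never_fixes():
    game = PayoffMatrix(values=[[1.0, 1.0], [5.0, 5.0]], labels=("A", "B"))
    assert strong_selection_fixation(game, 0, 1, 25).rho == 0.0
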