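# Methods

## Process definition

The population has constant size `N`. One birth–death event consists of:

1. **Reproduction.** An individual is chosen with probability proportional
   to `count × exp(beta · payoff)`. Payoffs are expected values against the
   other `N − 1` individuals (self-interaction excluded): in a matrix game
   with two types present, `π_A(i) = (a(i−1) + b(N−i))/(N−1)` and
   `π_B(i) = (c·i + d(N−i−1))/(N−1)`.
2. **Mutation.** The offspring's type is drawn from the kernel row of its
   parent. A kernel is row-stochastic with the diagonal carrying the
   no-mutation mass; its off-diagonal support must be strongly connected
   (checked at construction) so the full process is ergodic.
3. **Death.** The removed individual is drawn uniformly from all `N`
   individuals *before* the offspring is added — the parent itself may die.
   This convention makes the birth–death ratio at interior states equal to
   `f_res/f_inv` exactly, which is what the classic fixation formula
   assumes.

## Rare-mutation (embedded-chain) analytics

When the expected time between mutations greatly exceeds fixation times,
the population hops between monomorphic states. The embedded chain has
off-diagonal entries `scale · M[a,b] · ρ(b invades a)` with an arbitrary
positive `scale` (default 1; the stationary vector is provably invariant to
it, and the test suite checks this). Kernel rows are used as *absolute*
per-reproduction probabilities, not renormalised per row — this is what
makes kernels with different total mutation mass per row (the loner-exit
kernel) meaningful.

Fixation probabilities under the exponential mapping are computed as
`ρ = 1/(1 + Σ_k exp(−β S_k))` via `logsumexp` over `[0, −βS_1, …, −βS_{N−1}]`,
so no overflow occurs for `β·|payoff|·N` up to ~1e4. `β = 0` returns
exactly `1/N` (special-cased, not a numerical limit). Note the ratio
identity `ln(ρ_A/ρ_B) = β[(N−2)(a−d) + N(b−c)]/2` is exact for every `N`
under this mapping — the "approximate" closed-form abundance route differs
from the exact route only in presentation, and its large-`N` simplification
`βN(a+b−c−d)/2 > ln(μ_AB/μ_BA)` recovers risk dominance at equal mutation
rates.

The stationary distribution is solved deterministically as a null-space
(SVD) problem after a conditioning rescale of the off-diagonal rates; a
null space of dimension ≠ 1, negative entries beyond 1e−10, or a residual
`‖πT − π‖ > 1e−10` raise instead of returning an arbitrary vector.
Reducibility is detected graph-theoretically and the error names the
components. Chains can become *numerically* reducible when a fixation
probability underflows (β·N·payoff spread ≳ 700); this is reported, not
masked — at such parameters the surviving state holds all mass to double
precision anyway.

## Strong selection

The `β → ∞` limit is exact: `ρ → 0` if any cumulative payoff-difference sum
`S_k < 0`, else `ρ = 1/(1 + #{k : S_k = 0})`. Equality is decided at
tolerance `1e−12 · max(1, payoff scale)`: neutral paths in these games come
from *exactly* equal payoffs (e.g. punishers and cooperators in a
defector-free population), not near-ties. Convergence of finite-β numerics
to this limit is governed by the smallest nonzero `|S_k|`; in the public
goods game the first interior payoff differences scale like `n_group/N`, so
finite-β checks of the limit are run at small `N` where moderate β is
already asymptotic.

## Repeated prisoner's dilemma

The eight deterministic memory-one strategies are three-bit automata
(opening move, reply to C, reply to D); ATFT/ASTFT denote the
"reverse the opponent's last move" variants. Joint play is found by
iterating the joint action map until the first repeated joint action — this
yields the minimal cycle, and pre-period + cycle never exceed 5 rounds.
Discounted payoffs `(1−w)Σ w^t π_t` are closed-form (pre-period sum plus
geometric cycle sum); the one-shot payoffs default to (R, S, T, P) =
(3, 0, 5, 1) with `w = 0.9`, `N = 100`, and the dilemma ordering
`T > R > P > S` is enforced (`2R > T + S` warns only).

"Fully cooperative" strategies are classified from self-play traces (cycle
all mutual cooperation): ALLC, TFT and SALLC. The bitwise kernel weakly
reduces the stationary time spent on these states across the
selection-dominated range of intensities (β ∈ [0.05, 10] in the tests).
For β ≲ 0.05 both kernels sit near the neutral occupancy 3/8 and the sign
of the (second-order) difference can invert — the comparison is only
meaningful where selection differentiates the kernels.

## Optional public goods games

Groups of `n_group` (default 5) are drawn without replacement from the
population; expected payoffs are exact hypergeometric sums over co-player
compositions (no Monte Carlo anywhere in the analytics). Conventions:

* a group with fewer than two participants plays no game; the would-be
  participant receives the loner payoff σ;
* punishment is applied per group based on expressed base type, whether or
  not the public goods round itself took place: each punisher pays
  `fine_cost` per target, each target loses `fine` per punisher;
* in the 24-strategy space a "self-punishing" strategy is one whose flag
  targets its own base type; such strategies are (optionally) dropped from
  *display* tables only, never from computations.

Default parameters: `N = 100`, `n_group = 5`, `c = 1`, `r = 3`, `σ = 1`,
`fine = 1`, `fine_cost = 0.3`. The strong-selection transition structure
(D replaces C, L replaces D, C↔P neutral at 1/N, L→{C, P} at 1/2 via one
neutral step) is *detected* from the computed fixation probabilities before
the closed forms `π = (2, 2, N+2, 2)/(N+8)` (uniform) and
`π = (2α, 2α, (N+2)α, 2)/(α(N+6)+2)` (loner-exit) are used; outside that
regime the generic embedded-chain route is taken with a logged notice. The
sociality condition `α(N+6) > 2` is always cross-checked against the
generic route. The fine is never called β to avoid clashing with the
selection intensity.

## Simulator

`run_moran` simulates the exact event loop above (numba-compiled), with
mutation applied to the offspring at copying time. Initial compositions are
drawn uniformly over the integer simplex of compositions (not over
assignments); a monomorphic start is available for empirical fixation
checks. Abundance is averaged over a trailing window (default: second half)
of each run and across runs; standard errors are computed across
independent runs only, since within-run samples are autocorrelated. Each
run gets a child seed from a root `SeedSequence`, so results are
reproducible and independent of execution order. A heuristic validity
warning fires when `N(N−1)·μ ≥ 0.1` (fixation no longer clearly faster than
mutation arrivals).

Simulation-versus-analytics agreement checks use scaled-down problem sizes
chosen from mixing-time reasoning (N = 12–16, μ = 4–5·10⁻⁴, 50 runs of
5–6·10⁴ generations: fixation sweeps ≪ 1/μ events, ≥ ~20 monomorphic
transitions per run). What passing shows: the event loop, fitness mapping,
kernel application and the rare-mutation reduction are mutually consistent
within Monte Carlo error. What it does not show: behaviour at large μ
(where the embedded chain is not valid and only the simulator applies), or
anything about non-well-mixed (spatial/group-structured) populations, which
are out of scope, as are frequency-dependent or time-varying kernels and
stochastic repeated-game strategies.

## Known limitations

* The closed-form strong-selection results cover the 4-strategy public
  goods system in its classic parameter regime; elsewhere the generic route
  is used automatically.
* The exact per-composition payoff table used by the public goods simulator
  scales as `(N+1)^(k−1)` and is practical only for the 4-type system;
  matrix games have no such limit.
* Extremely strong selection with finite β can underflow fixation
  probabilities (see above); the dedicated β → ∞ routine should be used in
  that regime.
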