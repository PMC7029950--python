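# Methods

## Model and assumptions

`neutraldebt` treats every species as an independent continuous-time Markov
chain on its local abundance.  Time is measured in units of the intrinsic
demographic rate: per-capita birth and death rates are both 1, so pure
drift is a critical branching process and all rates below are dimensionless
ratios to it.

* **Emigration** `u` (default 0, must satisfy `0 ≤ u < 1`): removes a
  fraction of the reproductive output, making the upward rate from
  abundance `n ≥ 1` equal to `n(1−u)`.  The chain is then subcritical and
  extinction is certain without immigration.
* **Immigration** `v` (default 0, `v ≥ 0`): in the *proposed* variant a
  migrant establishes only when the species is locally absent (rate `v` out
  of state 0 only) — a strict competitive-exclusion/rescue-effect
  assumption.  The *full-immigration* variant adds `v` to every upward
  rate (the classical linear birth–death–immigration chain); it carries no
  emigration term in the published comparison and is reconstructed here
  from its verbal description, so it should be treated as provisional.  An
  optional `u` extension hook exists for sensitivity analysis.

Species do not interact; community quantities are sums of single-species
expectations.  No spatial structure beyond areas entering the logseries
parameters; areas are dimensionless multiples of the logseries scale `ω`.

## Single-species solvers

Three mutually checking routes compute the empty-state probability
`p0(t | j0)`:

1. **Closed forms.**  For `v = 0`, `p0 = q_u(t)^{j0}` with
   `q_u(t) = (1−e^{−ut})/(1−(1−u)e^{−ut})` (drift limit `t/(1+t)`); the
   generating function `H(z,t)` is also available in closed form.  For the
   full-immigration chain, independence of founder lines and
   Poisson-immigration lines gives
   `p0 = q_u(t)^{j0}·((1−(1−u)e^{−ut})/u)^{−v/(1−u)}`, with `u → 0` limit
   `(t/(1+t))^{j0}(1+t)^{−v}`.  Rates below `1e−12` switch to the `u = 0`
   branch to avoid catastrophic cancellation, and `1−e^{−ut}` is always
   computed via `expm1`.
2. **Truncated matrix exponential.**  The generator on states `0..m` is
   tridiagonal; a birth–death chain is similar to a symmetric tridiagonal
   matrix through `D = diag(√π)` with `π_{n+1}/π_n = up_n/down_{n+1}`, so
   `exp(G t)` is evaluated from `scipy.linalg.eigh_tridiagonal` in
   `O(m²)`–`O(m³)` once, then any entry at any time in `O(m)`.  This is
   numerically identical to a dense `expm` (asserted in the tests) but
   fast enough for `m` in the thousands.  Round-off in entry `(i, j)` is
   amplified by `√(π_i/π_j)`; the solver tracks `log π`, refuses entries
   whose estimated error exceeds `1e−9`, and falls back to a banded-LSODA
   integration of the master equation (rtol `1e−10`, atol `1e−12`).
   When `v = 0` state 0 is absorbing: the transient block on `1..m` is
   decomposed instead and `p0` recovered as the integrated flux through
   state 1 (exact for the leaky system) — equivalently one minus the
   survival mass for the reflecting system.
3. **Renewal decomposition** (proposed variant, `v > 0`).  Started from
   `j > 0` the chain is immigration-free until it first empties, and the
   first-passage CDF is the `v = 0` closed form, so
   `p0(t|j) = F(t|j) + ∫₀ᵗ F(s|j)·[p1(t−s|0) − v·p0(t−s|0)] ds`.
   This identity is exact and is what lets community sums cover the entire
   abundance distribution (below).

**Truncation boundary.**  The printed coefficient matrix keeps the top
state's birth rate `m(1−u)` on the diagonal with no destination — a
*leaky* truncation whose total mass genuinely decays; the *reflecting*
alternative removes it and conserves mass.  Both are implemented (leaky is
the default, faithful to the printed matrix); at a converged `m` they agree
on `p0` to below `1e−8`, which the acceptance suite asserts.  Convergence
uses an `m`-doubling schedule on the `p0` trajectory (default tolerance
`1e−8`, ceiling `m = 5000`); non-convergence raises with the retained mass
as a diagnostic.  Probabilities below `−1e−10` raise; smaller negative
round-off is clipped to zero.

## Community layer

The regional pool of area `A` holds `S0` species whose abundance in any
sampled area `X` follows the area-based logseries with
`α_X = 1/ln(1 + X/ω)` and base `x_X = X/(ω+X)`; sampling a local area `a`
keeps the regional prefactor: `φ(n|α_a,α_A) = (α_A/n)·x_a^n`, total mass
`α_A/α_a ≤ 1`.  The zero class is not part of the logseries; the endemic
extinction of destroying area `b` is *defined* as the complement of the
`n ≥ 1` mass of the remaining-area distribution, `1 − α_A/α_{A−b}`, and
verified against explicit series summation.  A zero-truncated negative
binomial is provided solely to verify the `k → 0` logseries limit.
Expected species counts remain real numbers throughout; nothing is rounded.

Stored spectra truncate where the neglected tail holds less than `1e−9` of
total richness, but every loss computation avoids that truncation entirely:

* `v = 0`: `E(t) = Σ_j S_j q^j = −S_eff·α_A·ln(1 − x_a·q_u(t))` (exact).
* full immigration: `E(t) = g(t)·E_{v=0}(t)` with the closed-form
  no-immigrant-line factor `g` (exact).
* proposed, `v > 0`: summing the renewal identity over the spectrum turns
  the community loss into a single convolution
  `E(t) = E₀(t) + ∫₀ᵗ E₀(s)·dp0(t−s|0)/dt ds` with `E₀` the closed-form
  `v = 0` loss and the kernel from a small converged truncated generator
  started empty.  Trapezoid quadrature on a uniform grid (40 points per
  time unit, floor 2048, cap 131072, FFT convolution); agreement with the
  direct per-class matrix sum is ~`1e−5` relative and improves with the
  grid, which the tests assert.

## Habitat destruction

At time τ an area `b` is destroyed: the local spectrum is re-sampled as the
survivor fraction `S_b/S0` times its original shape, which discards the
drift accumulated on `[0, τ)` (faithful to the printed post-destruction
formula; propagating the drifted distribution through τ is out of scope).
Both one-sided values at τ are recorded; the jump is the endemic-driven
imminent extinction.  Plotted loss is referenced to the initial richness
`S(0|a)` throughout (the figure-axis convention), so the jump appears as an
upward step; credit detection is invariant to that reference constant.

**Clock convention.**  The printed post-destruction loss reuses `p0(t)` on
the global clock even though the spectrum resets at τ; both `global`
(default) and `reset` conventions are implemented and every scenario bundle
records the summary of both, because the source is ambiguous.  With a
parameter shift at τ the global clock produces an additional discontinuity
(the new parameters are evaluated at the elapsed global time); that is
inherent to the convention, not a bug.

**Credits.**  A species credit is operationalized as a maximal interval on
which the loss strictly decreases; an interval only counts when its total
drop exceeds `1e−4` of the loss scale, so quadrature-level wiggle on a flat
asymptote is never reported as a credit.

## Canonical scenarios and what they show

`neutraldebt fixtures` emits the scenario families used for regression:
destroyed-area sweep (`b ∈ {20,50,80}`, `a=1`, `u=0.01`, `v=0.02`),
SAD-shape sweep (`ω ∈ {0.001,0.01,0.1}`), emigration sweep
(`u ∈ {0,0.01,0.1,0.2}` at `v=0.01`), immigration sweep
(`v ∈ {0.02,0.1,0.2}` at `u=0.02`), intact-area sweep
(`a ∈ {1..50}`), and an emigration-drop scenario (`u: 0.1 → 0` at τ).
Shared geometry: `A=100`, `S0=1000`, `τ=20`, horizon 100 (time step 0.25),
chosen so each curve is resolved through its jump and early relaxation
while the whole fixture set runs in minutes on one CPU.  Two deliberate
departures:

* The immigration sweep runs to `t = 4000` (coarse late grid) because the
  full-immigration loss `g(t)·E₀(t) → 0` peaks at `t ≈ 140` for `v = 0.2`
  but only at `t ≈ 2900` for `v = 0.1`; a shorter horizon would miss the
  `v = 0.1` credit entirely.
* The emigration-drop scenario uses `ω = 1` (no parameters are printed for
  it in the source).  With the `ω = 0.001` heavy tail the post-drop gain is
  deferred beyond any practical horizon because abundant classes keep
  dying by drift; a light-tailed community expresses the species gain
  within `t ≤ 400`, which is the phenomenon the scenario exists to
  demonstrate.

**Finding.**  In the immigration sweep the *proposed* model's exact
community loss (heavy tail summed in full) is monotone non-decreasing to
its asymptote `S(0|a) − S_τ·(1 − π₀)` — no immigration-credit interval
exists for `v ∈ {0.1, 0.2}`, although individual rare classes do overshoot
(`p0(t|1)` peaks above its stationary value `π₀ = 1/(1 − v·ln(u)/(1−u))`).
The credits in that scenario belong to the full-immigration comparison
curves, which must peak because their loss decays to zero.  A dedicated
test documents the proposed-variant behaviour.  Relatedly, the
full-immigration chain with unit birth/death is *critical*: its mean
abundance grows like `j0 + v·t` and it has no stationary distribution, so
late-time "plateaus" of that variant are transient.

## What the scenario generator does not emulate

Scenarios are expectations of an idealized neutral community: no
demographic covariance between species, no spatial aggregation or
fragmentation geometry, no parameter fitting to data, and no alternative
abundance models (the trajectory layer accepts any spectrum, so a Poisson
lognormal could be substituted).  Passing tests therefore show internal
consistency of the model and its solvers, not agreement with empirical
relaxation data.

## Known limitations

* The renewal route applies only to state-0 immigration; the
  full-immigration variant relies on its closed form (exact) or truncated
  sums with an explicit tail bound.
* Spectral accuracy degrades for entries far down the stationary-weight
  profile (amplification guard at `1e−9`); such calls fall back to the
  stiff integrator, which is slower.
* Truncation convergence for critical chains (`u = 0`) over very long
  horizons needs `m` that grows with the horizon; the default ceiling 5000
  covers horizons up to roughly `t ≈ 500` for the empty-start kernel.
* Expected trajectories say nothing about fluctuations between replicate
  communities; the Gillespie module simulates single species, not a
  multi-species community.
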