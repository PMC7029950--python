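# neutraldebt

A time-dependent stochastic neutral model of **local extinction debt**:
how fast species are lost from a habitat after disturbance, and when
dispersal can turn losses into **species credits** (net gains).

## Who this is for

Quantitative and theoretical ecologists studying delayed biodiversity loss
(extinction debt) after habitat destruction, and anyone who needs a
well-tested continuous-time birth–death–immigration solver with community
(species-abundance-distribution) bookkeeping on top.

## The model

Each species evolves independently as a continuous-time Markov chain on its
abundance *n*, with intrinsic birth and death rates both equal to 1 (random
drift), per-capita emigration *u* and immigration *v* that acts **only on
the empty state** (a strict rescue effect):

```
dp0/dt = p1 − v·p0
dpn/dt = (n+1)·p_{n+1} + (n−1)(1−u)·p_{n−1} − n(2−u)·pn ,   n ≥ 1
```

The extinction probability `p0(t | j)` has closed forms when `v = 0`
(`(t/(1+t))^j` for pure drift; `((1−e^{−ut})/(1−(1−u)e^{−ut}))^j` with
emigration) and is otherwise obtained from the truncated generator matrix
`G_m` via `X_m(t) = exp(G_m t)·X_m(0)`, evaluated through the symmetrized
tridiagonal eigendecomposition.  A comparison "full immigration" variant
(up-rate `n + v` in every state) is included, together with its closed form
`p0(t|j) = (t/(1+t))^j (1+t)^{−v}`.

The regional community of area *A* carries `S(0|A)` species with an
area-based Fisher's logseries abundance distribution
(`α_X = 1/ln(1 + X/ω)`).  Sampling a local area *a*, destroying an area *b*
at time τ (removing the endemic fraction `1 − α_A/α_{A−b}`), and relaxing
each abundance class through `p0(t | j)` yields expected richness and loss
trajectories

```
E(t | a) = Σ_j S_j · p0(t | j),
```

with the heavy logseries tail summed exactly (closed forms for `v = 0`, a
first-passage renewal convolution for state-0 immigration).  Everything is
cross-checked against an exact-event Gillespie simulator and a stiff ODE
integrator of the master equation.

## Worked example

```python
import numpy as np
from neutraldebt import (ModelParams, extinction_prob, LogseriesCommunity,
                         DestructionScenario, local_loss_with_destruction)

p = ModelParams(u=0.01, v=0.02)          # emigration 0.01, immigration 0.02
for t in (1, 10, 100):
    print(f"p0({t:>3} | j0=3) = {extinction_prob(p, 3, float(t)):.6f}")

comm = LogseriesCommunity(omega=0.001, A=100.0, S0=1000.0)
scenario = DestructionScenario(
    community=comm, a=10.0, b=50.0, tau=20.0,   # half the region destroyed at t=20
    params_before=p,
    time_grid=np.arange(0.0, 100.25, 0.25),
)
traj = local_loss_with_destruction(scenario)
print(f"initial local richness S(0|a) = {traj.reference_richness:.1f}")
print(f"imminent extinction at tau=20: {traj.imminent_extinction:.1f} species")
print(f"loss at t=100: {traj.loss[-1]:.1f} species")
```

prints

```
p0(  1 | j0=3) = 0.125198
p0( 10 | j0=3) = 0.732793
p0(100 | j0=3) = 0.907675
initial local richness S(0|a) = 800.0
imminent extinction at tau=20: 32.6 species
loss at t=100: 437.0 species
```

A species starting from 3 individuals is 73% likely to be locally absent by
t = 10 under these rates.  The local plot of area 10 holds 800 of the 1000
regional species; destroying half the region instantly removes 32.6 of them
(the species endemic to the destroyed area), and drift continues to erode
richness afterwards, for 437 species lost by t = 100.

A command-line interface covers the same ground:

```sh
neutraldebt solve --u 0.01 --v 0.02 --j0 3 --t-max 100      # p0 curve (CSV)
neutraldebt fixtures --outdir fixtures                      # canonical scenarios
neutraldebt trajectory fixtures/fig4_v0.2.yaml --outdir out # run one scenario
neutraldebt validate --out validation.json                  # oracle cross-check
```

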