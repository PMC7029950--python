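"""Independent verification engines for the single-species chain.

Nothing here is used by the production solvers: the exact-event stochastic
simulator and the stiff dense integrator of the truncated master equation
exist so that the closed forms and the spectral matrix-exponential route
can be checked against implementations that share none of their code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import numpy.typing as npt

from .sbd import (
    Boundary,
    InvalidParameterError,
    ModelParams,
    NeutralDebtError,
    ODE_ATOL,
    ODE_RTOL,
    _ode_distribution,
    build_generator,
    extinction_prob,
)

__all__ = ["SimConfig", "GillespieResult", "gillespie_p0", "dense_ode_p0", "validation_report"]


class EventCapError(NeutralDebtError):
    """A replicate exceeded the per-replicate event budget."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a Gillespie estimation run.

    Replicates are advanced in lock-step from a single PCG64 stream seeded
    by ``seed``; identical configurations reproduce identical estimates
    bit-for-bit.
    """

    params: ModelParams
    j0: int
    record_times: tuple[float, ...]
    n_reps: int = 20_000
    seed: int = 0
    event_cap: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")
        if self.j0 < 0:
            raise InvalidParameterError("initial abundance must be >= 0")
        times = tuple(float(t) for t in self.record_times)
        if not times or any(t < 0 for t in times) or list(times) != sorted(set(times)):
            raise InvalidParameterError("record_times must be sorted, unique, non-negative")
        object.__setattr__(self, "record_times", times)


@dataclass
class GillespieResult:
    """Empty-state frequencies with binomial standard errors."""

    times: npt.NDArray[np.float64]
    p0_hat: npt.NDArray[np.float64]
    se: npt.NDArray[np.float64]
    n_reps: int
    meta: dict = field(default_factory=dict)


def _up_rates(params: ModelParams, n: npt.NDArray[np.int64]) -> npt.NDArray[np.float64]:
    if params.variant == "full_immigration":
        return n * (1.0 - params.u) + params.v
    return np.where(n > 0, n * (1.0 - params.u), params.v)


def gillespie_p0(config: SimConfig) -> GillespieResult:
    """Monte-Carlo estimate of p0(t | j0) at each record time.

    Exact-event simulation of the chain (up-rate ``n (1 - u)`` for ``n >= 1``
    and ``v`` from the empty state -- or ``n (1 - u) + v`` everywhere for the
    full-immigration variant; down-rate ``n``).  Replicates that would cross
    a record time are frozen there and re-drawn afterwards, which is valid
    by the memorylessness of the exponential waiting times.
    """
    params = config.params
    rng = np.random.default_rng(config.seed)
    n = np.full(config.n_reps, config.j0, dtype=np.int64)
    t = np.zeros(config.n_reps)
    events = np.zeros(config.n_reps, dtype=np.int64)

    p0_hat = np.empty(len(config.record_times))
    se = np.empty(len(config.record_times))
    for k, t_rec in enumerate(config.record_times):
        while True:
            up = _up_rates(params, n)
            down = n.astype(float)
            total = up + down
            active = (t < t_rec) & (total > 0.0)
            if not active.any():
                t = np.maximum(t, t_rec)
                break
            idx = np.nonzero(active)[0]
            dt = rng.exponential(1.0, idx.size) / total[idx]
            t_new = t[idx] + dt
            crossed = t_new >= t_rec
            # events beyond the record time are discarded (memoryless clock)
            t[idx[crossed]] = t_rec
            fire = idx[~crossed]
            if fire.size:
                u01 = rng.random(fire.size)
                births = u01 < up[fire] / total[fire]
                n[fire] += np.where(births, 1, -1)
                t[fire] = t_new[~crossed]
                events[fire] += 1
                if events.max() > config.event_cap:
                    raise EventCapError(
                        f"a replicate exceeded {config.event_cap} events; "
                        "raise event_cap or shorten the horizon"
                    )
        p = float(np.mean(n == 0))
        p0_hat[k] = p
        se[k] = float(np.sqrt(p * (1.0 - p) / config.n_reps))
    return GillespieResult(
        times=np.asarray(config.record_times),
        p0_hat=p0_hat,
        se=se,
        n_reps=config.n_reps,
        meta={"rng": "numpy PCG64", "seed": config.seed, "max_events": int(events.max())},
    )


def dense_ode_p0(
    params: ModelParams,
    j0: int,
    m: int,
    time_grid: Sequence[float] | npt.NDArray[np.float64],
    boundary: Boundary = "leaky",
    rtol: float = ODE_RTOL,
    atol: float = ODE_ATOL,
) -> npt.NDArray[np.float64]:
    """p0(t | j0) by stiff integration of the truncated master equation.

    Independent of the spectral matrix-exponential route; the two must
    agree to the convergence tolerance at a converged truncation.
    """
    ts = np.asarray(time_grid, dtype=float)
    if j0 > m:
        raise InvalidParameterError(f"j0={j0} outside the truncation 0..{m}")
    gen = build_generator(params, m, boundary=boundary)
    return _ode_distribution(gen, j0, ts)[:, 0]


def validation_report(
    parameter_sets: Sequence[ModelParams],
    j0: int,
    times: Sequence[float],
    n_reps: int = 20_000,
    seed: int = 0,
    m: int = 256,
    path: str | Path | None = None,
) -> dict:
    """Closed-form / matrix / ODE / Gillespie comparison table (JSON-able)."""
    rows = []
    ts = np.asarray(times, dtype=float)
    for i, params in enumerate(parameter_sets):
        matrix = np.atleast_1d(
            extinction_prob(ModelParams(params.u, params.v, "proposed"), j0, ts, m=m)
            if params.variant == "proposed"
            else extinction_prob(params, j0, ts)
        )
        ode = dense_ode_p0(params, j0, m, ts)
        sim = gillespie_p0(
            SimConfig(params=params, j0=j0, record_times=tuple(ts), n_reps=n_reps, seed=seed + i)
        )
        row = {
            "u": params.u, "v": params.v, "variant": params.variant, "j0": j0,
            "times": ts.tolist(),
            "matrix_p0": matrix.tolist(),
            "ode_p0": ode.tolist(),
            "gillespie_p0": sim.p0_hat.tolist(),
            "gillespie_se": sim.se.tolist(),
            "max_abs_matrix_vs_ode": float(np.max(np.abs(matrix - ode))),
            "max_z_matrix_vs_gillespie": float(
                np.max(np.abs(matrix - sim.p0_hat) / np.maximum(sim.se, 1e-12))
            ),
        }
        rows.append(row)
    report = {"j0": j0, "n_reps": n_reps, "seed": seed, "rows": rows}
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
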