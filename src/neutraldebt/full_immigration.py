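"""Comparison model with immigration available in every abundance state.

In the proposed model a migrant can establish only when the species is
locally absent.  The comparison ("full immigration") model instead lets
immigration contribute to every upward transition: from abundance ``n`` the
up-rate is ``n + v`` and the down-rate is ``n`` -- the classical linear
birth-death-immigration chain.  The published source states only the verbal
description of this variant; the concrete transition rates used here are
that standard chain, and should be treated as a reconstruction (an optional
emigration term ``u``, default 0, is provided as an extension hook: up-rate
``n (1 - u) + v``).

Because immigrants found mutually independent lines, the model factorizes:
the ``j0`` founders survive as a critical (or subcritical, ``u > 0``)
branching process while immigration arrivals form a Poisson process whose
lines die independently.  This yields the closed form

    p0(t | j0) = q_u(t)^{j0} * ((1 - (1 - u) e^{-ut}) / u)^{-v / (1 - u)}

with the ``u -> 0`` limit ``(t / (1 + t))^{j0} (1 + t)^{-v}``.  With unit
birth and death rates the chain is *critical*: the expected abundance grows
like ``j0 + v t`` and ``p0(t) -> 0`` -- there is no stationary law.  The
closed form doubles as the independent oracle for the matrix route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .sbd import (
    Boundary,
    GeneratorMatrix,
    InvalidParameterError,
    ModelParams,
    SMALL_U,
    build_generator,
    extinction_prob,
)

__all__ = [
    "build_full_immigration_generator",
    "full_extinction_closed",
    "ModelComparison",
    "compare_models",
]


def build_full_immigration_generator(
    v: float, m: int, u: float = 0.0, boundary: Boundary = "leaky"
) -> GeneratorMatrix:
    """Truncated generator with up-rate ``n (1 - u) + v``, down-rate ``n``.

    With ``v = 0`` and ``u = 0`` this coincides with the proposed model's
    drift-only generator.
    """
    params = ModelParams(u=u, v=v, variant="full_immigration")
    return build_generator(params, m, boundary=boundary)


def full_extinction_closed(
    v: float, j0: int, t: npt.ArrayLike, u: float = 0.0
) -> npt.NDArray[np.float64]:
    """Closed-form p0(t | j0) of the birth-death-immigration chain.

    Founder lines and Poisson-immigration lines are independent;
    ``P(empty) = P(founders' lines extinct) * P(no immigrant line alive)``.
    """
    if j0 < 0:
        raise InvalidParameterError(f"initial abundance must be >= 0, got {j0}")
    if v < 0:
        raise InvalidParameterError(f"immigration rate must be >= 0, got {v}")
    t = np.asarray(t, dtype=float)
    if u < SMALL_U:
        founders = (t / (1.0 + t)) ** j0
        immigrants = (1.0 + t) ** (-v)
    else:
        e = np.exp(-u * t)
        q = -np.expm1(-u * t) / (1.0 - (1.0 - u) * e)
        founders = q ** j0
        immigrants = ((1.0 - (1.0 - u) * e) / u) ** (-v / (1.0 - u))
    return founders * immigrants


@dataclass
class ModelComparison:
    """Paired extinction-probability trajectories of two parameterizations."""

    times: npt.NDArray[np.float64]
    p0_a: npt.NDArray[np.float64]
    p0_b: npt.NDArray[np.float64]

    @property
    def sup_distance(self) -> float:
        return float(np.max(np.abs(self.p0_a - self.p0_b)))


def compare_models(
    params_a: ModelParams,
    params_b: ModelParams,
    j0: int,
    time_grid: npt.ArrayLike,
) -> ModelComparison:
    """p0(t | j0) under two parameter sets on a shared time grid.

    Plumbing for the dashed-versus-solid figure comparisons (the published
    full-immigration curves ignore emigration, so pair a proposed-model
    parameter set against ``ModelParams(v=v, variant="full_immigration")``).
    """
    ts = np.asarray(time_grid, dtype=float)
    if ts.ndim != 1 or ts.size == 0:
        raise InvalidParameterError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(ts) <= 0) or ts[0] < 0:
        raise InvalidParameterError("time grid must be non-negative and strictly increasing")
    p0_a = np.atleast_1d(extinction_prob(params_a, j0, ts))
    p0_b = np.atleast_1d(extinction_prob(params_b, j0, ts))
    return ModelComparison(times=ts, p0_a=p0_a, p0_b=p0_b)
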