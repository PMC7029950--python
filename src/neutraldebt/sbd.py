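"""Single-species stochastic dispersal-birth-death (SBD) dynamics.

The model is a continuous-time Markov chain on the abundance of one focal
species.  Per-capita birth and death rates are both equal to 1 (random
drift); emigration removes a fraction ``u`` of the reproductive output, so
the upward rate from abundance ``n >= 1`` is ``n * (1 - u)`` while the
downward rate is ``n``.  Immigration at rate ``v`` acts *only* on the empty
state (a strict rescue effect: a migrant can establish only when no
conspecific is present), giving the master equation

    dp0/dt = p1 - v * p0
    dpn/dt = (n + 1) p_{n+1} + (n - 1)(1 - u) p_{n-1} - n (2 - u) pn,  n >= 1
             (+ v p0 feeding state 1)

The chain is solved three ways, cross-checked against each other:

* closed forms when ``v = 0`` (the empty state is then absorbing and the
  chain is a linear branching process);
* a truncated generator matrix whose exponential is evaluated through the
  symmetrized (birth-death chains are reversible up to the boundary)
  tridiagonal eigendecomposition -- numerically identical to ``expm`` but
  orders of magnitude faster at the truncation sizes the heavy-tailed
  community spectra require;
* a renewal (first-passage) decomposition for ``v > 0``: started from
  ``j > 0`` the process is immigration-free until it first empties, so

      p0(t | j) = int_0^t dF(s | j) * p0(t - s | 0)

  with ``F(s | j)`` the closed-form extinction CDF of the ``v = 0`` chain.

Truncating the infinite chain at abundance ``m`` leaves a choice at the top
state: the printed coefficient matrix keeps the birth rate ``m (1 - u)`` in
the diagonal with no destination state ("leaky": probability escaping above
``m`` is dropped), the alternative removes it ("reflecting": mass is
conserved exactly).  Both are implemented; convergence in ``m`` makes them
agree on the extinction probability, which is what all downstream
quantities consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import numpy.typing as npt
import scipy.linalg
import scipy.integrate

__all__ = [
    "NeutralDebtError",
    "InvalidParameterError",
    "TruncationConvergenceError",
    "NumericalError",
    "ModelParams",
    "GeneratorMatrix",
    "StateDistribution",
    "build_generator",
    "solve_distribution",
    "extinction_prob",
    "extinction_prob_profile",
    "survival_prob",
    "converge_truncation",
    "pgf_closed_form",
    "extinction_cdf_closed",
    "stationary_empty_prob",
]

# ---------------------------------------------------------------------------
# Package-wide numerical policy
# ---------------------------------------------------------------------------

#: default convergence tolerance on p0(t)
DEFAULT_TOL = 1e-8
#: ceiling for the truncation-doubling schedule
DEFAULT_M_MAX = 5000
#: emigration rates below this use the u = 0 closed forms (the u > 0 forms
#: suffer catastrophic cancellation as u -> 0)
SMALL_U = 1e-12
#: probabilities in [NEG_CLIP, 0) are rounded up to 0; anything below
#: NEG_RAISE is treated as a numerical failure
NEG_CLIP = -1e-12
NEG_RAISE = -1e-10
#: stiff ODE fallback tolerances
ODE_RTOL = 1e-10
ODE_ATOL = 1e-12


class NeutralDebtError(Exception):
    """Base class for errors raised by this package."""


class InvalidParameterError(NeutralDebtError, ValueError):
    """A rate, area or truncation parameter is outside its domain."""


class TruncationConvergenceError(NeutralDebtError):
    """The truncation-doubling schedule hit its ceiling without converging."""


class NumericalError(NeutralDebtError):
    """A solution violated a numerical sanity bound (negative mass etc.)."""


Variant = Literal["proposed", "full_immigration"]
Boundary = Literal["leaky", "reflecting"]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Dispersal rates of the single-species chain.

    Parameters
    ----------
    u
        Per-capita emigration rate (dimensionless, ``0 <= u < 1``).  The
        effective birth rate from abundance ``n`` is ``n * (1 - u)``.
    v
        Immigration rate (``v >= 0``).  In the ``proposed`` variant it acts
        only on the empty state; in the ``full_immigration`` variant it is
        added to every upward rate.
    variant
        ``"proposed"`` (state-0-only immigration) or ``"full_immigration"``.
    """

    u: float = 0.0
    v: float = 0.0
    variant: Variant = "proposed"

    def __post_init__(self) -> None:
        if not (self.u >= 0.0):
            raise InvalidParameterError(f"emigration rate u must be >= 0, got {self.u}")
        if self.u >= 1.0:
            raise InvalidParameterError(
                f"emigration rate u must be < 1 so the birth rate n(1-u) stays "
                f"non-negative, got {self.u}"
            )
        if not (self.v >= 0.0):
            raise InvalidParameterError(f"immigration rate v must be >= 0, got {self.v}")
        if self.variant not in ("proposed", "full_immigration"):
            raise InvalidParameterError(f"unknown model variant {self.variant!r}")


# ---------------------------------------------------------------------------
# Closed forms (v = 0)
# ---------------------------------------------------------------------------


def _hitting_cdf_single(u: float, t: npt.ArrayLike) -> npt.NDArray[np.float64]:
    """CDF of the time to extinction starting from one individual, v = 0.

    ``u = 0``:  t / (1 + t)        (critical branching)
    ``u > 0``:  (1 - e^{-ut}) / (1 - (1 - u) e^{-ut})   (subcritical)
    """
    t = np.asarray(t, dtype=float)
    if u < SMALL_U:
        return t / (1.0 + t)
    e = np.exp(-u * t)
    return -np.expm1(-u * t) / (1.0 - (1.0 - u) * e)


def extinction_cdf_closed(u: float, j0: int, t: npt.ArrayLike) -> npt.NDArray[np.float64]:
    """Closed-form p0(t | j0) for the immigration-free chain (v = 0).

    Equals ``q_u(t) ** j0`` where ``q_u`` is the single-ancestor extinction
    CDF; the ``j0`` initial individuals found independent lines.  For
    ``j0 = 0`` the empty state is absorbing and p0 is identically 1.
    """
    if j0 < 0:
        raise InvalidParameterError(f"initial abundance must be >= 0, got {j0}")
    t = np.asarray(t, dtype=float)
    if j0 == 0:
        return np.ones_like(t)
    return _hitting_cdf_single(u, t) ** j0


def pgf_closed_form(u: float, z: npt.ArrayLike, t: npt.ArrayLike, j0: int) -> npt.NDArray[np.float64]:
    """Probability generating function H(z, t) of the v = 0 chain.

    ``H(z, t) = sum_n z**n p_n(t)`` for the chain started at ``j0``; each
    founding individual contributes an independent factor, so H is the
    single-ancestor PGF raised to ``j0``:

    u > 0:  ((1-(1-u)z-(1-z)e^{-ut}) / (1-(1-u)(z+(1-z)e^{-ut})))**j0
    u = 0:  ((t - t z + z) / (t - t z + 1))**j0

    ``H(1, t) = 1`` and ``H(0, t) = p0(t | j0)``.
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(z < 0.0) or np.any(z > 1.0):
        raise InvalidParameterError("PGF argument z must lie in [0, 1]")
    if u < 0 or u >= 1:
        raise InvalidParameterError(f"emigration rate u must be in [0, 1), got {u}")
    if j0 < 0:
        raise InvalidParameterError(f"initial abundance must be >= 0, got {j0}")
    if u < SMALL_U:
        base = (t - t * z + z) / (t - t * z + 1.0)
    else:
        e = np.exp(-u * t)
        num = 1.0 - (1.0 - u) * z - (1.0 - z) * e
        den = 1.0 - (1.0 - u) * (z + (1.0 - z) * e)
        base = num / den
    return base ** j0


def stationary_empty_prob(params: ModelParams) -> float:
    """Long-run probability of the empty state for the proposed chain.

    With state-0-only immigration and ``u > 0`` the chain is positive
    recurrent with stationary weights ``pi_0 = 1`` and
    ``pi_n = v (1-u)^{n-1} / n``; summing the geometric-log series gives

        p0(inf) = 1 / (1 - v ln(u) / (1 - u)).

    For ``u = 0`` (null-recurrent) or ``v = 0`` (absorbing) the limit is
    0-measure occupation and 1 respectively.
    """
    if params.variant != "proposed":
        raise InvalidParameterError("stationary_empty_prob applies to the proposed variant")
    if params.v == 0.0:
        return 1.0
    if params.u < SMALL_U:
        return 0.0
    return 1.0 / (1.0 - params.v * math.log(params.u) / (1.0 - params.u))


# ---------------------------------------------------------------------------
# Generator matrix
# ---------------------------------------------------------------------------


@dataclass
class GeneratorMatrix:
    """Truncated tridiagonal generator of the abundance chain.

    The chain lives on states ``0..m``.  ``up[n]`` is the rate ``n -> n+1``
    (for ``n = m`` it is the rate escaping above the truncation: retained in
    the diagonal under the leaky boundary, removed under the reflecting
    one), ``down[n]`` the rate ``n -> n-1``.  Stored in source-column
    convention: ``dX/dt = G X`` with ``X = (p0, ..., pm)``.
    """

    m: int
    params: ModelParams
    boundary: Boundary
    up: npt.NDArray[np.float64]
    down: npt.NDArray[np.float64]
    _solver: "_SpectralSolver | None" = field(default=None, repr=False, compare=False)

    @property
    def diag(self) -> npt.NDArray[np.float64]:
        d = -(self.up + self.down)
        if self.boundary == "reflecting":
            d = d.copy()
            d[-1] = -self.down[-1]
        return d

    def to_dense(self) -> npt.NDArray[np.float64]:
        G = np.diag(self.diag)
        idx = np.arange(self.m)
        G[idx + 1, idx] = self.up[:-1]
        G[idx, idx + 1] = self.down[1:]
        return G

    def column_sums(self) -> npt.NDArray[np.float64]:
        """Zero in every interior column; ``-up[m]`` at the top for leaky."""
        s = np.zeros(self.m + 1)
        if self.boundary == "leaky":
            s[-1] = -self.up[-1]
        return s

    def solver(self) -> "_SpectralSolver":
        if self._solver is None:
            self._solver = _SpectralSolver(self)
        return self._solver


def build_generator(params: ModelParams, m: int, boundary: Boundary = "leaky") -> GeneratorMatrix:
    """Build the truncated generator for either model variant.

    For the proposed variant the printed coefficient matrix is reproduced
    exactly under ``boundary="leaky"``: row 0 is ``(-v, 1, 0, ...)``, row
    ``n`` has sub-diagonal ``(n-1)(1-u)``, diagonal ``-n(2-u)`` and
    super-diagonal ``n+1``; probability can escape only through the top
    state (column ``m`` sums to ``-m(1-u)``).  ``boundary="reflecting"``
    instead drops the top birth rate (diagonal ``-m``), conserving mass.

    The full-immigration variant adds ``v`` to every upward rate
    (``up[n] = n(1-u) + v``; the published comparison model has no
    emigration, i.e. ``u = 0``).
    """
    if not isinstance(m, (int, np.integer)) or m <= 1:
        raise InvalidParameterError(f"truncation bound m must be an integer > 1, got {m}")
    if boundary not in ("leaky", "reflecting"):
        raise InvalidParameterError(f"unknown truncation boundary {boundary!r}")
    n = np.arange(m + 1, dtype=float)
    if params.variant == "proposed":
        up = n * (1.0 - params.u)
        up[0] = params.v
    else:
        up = n * (1.0 - params.u) + params.v
    down = n.copy()
    if boundary == "reflecting":
        up = up.copy()
        up[-1] = 0.0
    return GeneratorMatrix(m=int(m), params=params, boundary=boundary, up=up, down=down)


# ---------------------------------------------------------------------------
# State distribution
# ---------------------------------------------------------------------------


@dataclass
class StateDistribution:
    """Truncated abundance distribution ``(p_0(t), ..., p_m(t))``."""

    probs: npt.NDArray[np.float64]
    m: int
    t: float
    j0: int

    def __post_init__(self) -> None:
        self.probs = _clip_probs(np.asarray(self.probs, dtype=float))
        total = float(self.probs.sum())
        if total > 1.0 + 1e-9:
            raise NumericalError(f"probability mass {total} exceeds 1")

    @property
    def p0(self) -> float:
        return float(self.probs[0])

    @property
    def mass(self) -> float:
        """Total retained mass (< 1 signals leakage through the truncation)."""
        return float(self.probs.sum())


def _clip_probs(p: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    low = p.min() if p.size else 0.0
    if low < NEG_RAISE:
        raise NumericalError(
            f"probability entry {low} below the tolerance {NEG_RAISE}; "
            "truncation too small or solver failure"
        )
    p = np.clip(p, 0.0, None)
    hi = p.max() if p.size else 0.0
    if hi > 1.0 + 1e-9:
        raise NumericalError(f"probability entry {hi} exceeds 1")
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# Spectral matrix-exponential engine
# ---------------------------------------------------------------------------


class _SpectralSolver:
    """exp(G t) actions via the symmetrized tridiagonal eigendecomposition.

    A birth-death generator is similar to a symmetric tridiagonal matrix
    through ``D = diag(sqrt(pi))`` with ``pi_{n+1}/pi_n = up_n / down_{n+1}``
    (valid for both boundary conventions: the similarity only constrains the
    off-diagonals).  Entries of ``exp(G t)`` are then

        [exp(G t)]_{i j} = sqrt(pi_i / pi_j) * sum_l U_{il} U_{jl} e^{w_l t}

    When ``v = 0`` state 0 is absorbing and disconnected from above, so the
    transient block on ``1..m`` is decomposed instead and ``p0`` recovered as
    ``integral of the flux down[1] * p1`` (exact for the leaky system, whose
    total mass genuinely decays) -- equivalently ``1 - survival`` for the
    reflecting system.

    Round-off in an entry is amplified by ``sqrt(pi_i / pi_j)``; the solver
    tracks ``log pi`` and refuses to report entries whose estimated error
    exceeds ``err_cap`` (callers fall back to the banded stiff ODE route).
    """

    err_cap = 1e-9

    def __init__(self, gen: GeneratorMatrix) -> None:
        self.gen = gen
        m = gen.m
        self.absorbing = gen.up[0] == 0.0  # v = 0: decompose states 1..m
        lo = 1 if self.absorbing else 0
        up = gen.up[lo:]
        down = gen.down[lo:]
        diag = gen.diag[lo:]
        off = np.sqrt(up[:-1] * down[1:])
        with np.errstate(divide="ignore"):
            self.logpi = np.concatenate(
                [[0.0], np.cumsum(np.log(up[:-1]) - np.log(down[1:]))]
            )
        self.w, self.U = scipy.linalg.eigh_tridiagonal(diag, off)
        self.lo = lo

    # -- internal helpers ---------------------------------------------------

    def _amp(self, i: int, j: int) -> float:
        """Round-off amplification factor for entry (i, j) of exp(Gt)."""
        return math.exp(0.5 * (self.logpi[i] - self.logpi[j]))

    def _check(self, i: int, j: int) -> None:
        if 1e-15 * self._amp(i, j) > self.err_cap:
            raise NumericalError(
                "spectral round-off amplification too large for entry "
                f"({i + self.lo}, {j + self.lo}); use the ODE fallback"
            )

    def entry(self, i: int, j: int, ts: npt.ArrayLike) -> npt.NDArray[np.float64]:
        """[exp(G t)]_{i, j} over times ts (indices on the full 0..m chain)."""
        ts = np.asarray(ts, dtype=float)
        ii, jj = i - self.lo, j - self.lo
        self._check(ii, jj)
        coef = self.U[ii] * self.U[jj]
        out = np.empty(ts.size)
        chunk = max(1, 8_000_000 // max(self.w.size, 1))  # bound exp() workspace
        for k in range(0, ts.size, chunk):
            out[k : k + chunk] = np.exp(np.outer(ts[k : k + chunk], self.w)) @ coef
        return out * self._amp(ii, jj)

    def p0_from(self, j0: int, ts: npt.ArrayLike) -> npt.NDArray[np.float64]:
        """p0(t | j0) over times ts."""
        ts = np.asarray(ts, dtype=float)
        if not self.absorbing:
            return self.entry(0, j0, ts)
        if j0 == 0:
            return np.ones_like(ts)
        jj = j0 - 1
        self._check(0, jj)
        # p0(t) = down[1] * int_0^t p1(s) ds; p1 = sum_l coef_l e^{w s}
        coef = self.U[0] * self.U[jj] * self._amp(0, jj) * self.gen.down[1]
        expw = np.exp(np.outer(ts, self.w))
        return (expw - 1.0) @ (coef / self.w)

    def p0_profile(self, ts: npt.ArrayLike, j_max: int | None = None) -> npt.NDArray[np.float64]:
        """p0(t | j) for all j = 0..j_max at once; shape (len(ts), j_max + 1).

        ``j_max`` defaults to the largest initial abundance whose spectral
        round-off amplification stays below ``err_cap``.
        """
        ts = np.asarray(ts, dtype=float)
        n_states = self.logpi.size
        amp_log = 0.5 * (self.logpi[0] - self.logpi)
        safe = amp_log < math.log(self.err_cap / 1e-15)
        j_safe = int(np.nonzero(safe)[0].max()) if safe.any() else 0
        if j_max is None:
            j_max = j_safe + self.lo
        if j_max - self.lo > j_safe:
            raise NumericalError(
                f"p0 profile requested up to j={j_max} but spectral round-off "
                f"is acceptable only up to j={j_safe + self.lo}"
            )
        cols = slice(0, j_max + 1 - self.lo)
        amp = np.exp(amp_log[cols])
        if not self.absorbing:
            coef = self.U[cols] * self.U[0][None, :]
            return np.exp(np.outer(ts, self.w)) @ coef.T * amp[None, :]
        coef = (self.U[cols] * self.U[0][None, :]) * self.gen.down[1]  # rows j-1
        expw = (np.exp(np.outer(ts, self.w)) - 1.0) / self.w[None, :]
        out = expw @ coef.T * amp[None, :]
        return np.concatenate([np.ones((ts.size, 1)), out], axis=1)

    def propagate(self, j0: int, ts: npt.ArrayLike) -> npt.NDArray[np.float64]:
        """Full distribution rows: shape (len(ts), m + 1)."""
        ts = np.asarray(ts, dtype=float)
        if self.absorbing and j0 == 0:
            res = np.zeros((ts.size, self.gen.m + 1))
            res[:, 0] = 1.0
            return res
        jj = j0 - self.lo
        amp_log = 0.5 * (self.logpi - self.logpi[jj])
        bad = 1e-15 * np.exp(np.minimum(amp_log, 700.0)) > self.err_cap
        if bad.any():
            raise NumericalError(
                "spectral round-off amplification too large for the full "
                f"distribution from j0={j0}; use the ODE fallback"
            )
        coef = self.U * self.U[jj][None, :]
        out = np.exp(np.outer(ts, self.w)) @ coef.T
        out = out * np.exp(amp_log)[None, :]
        if not self.absorbing:
            return out
        p0 = self.p0_from(j0, ts)
        return np.concatenate([p0[:, None], out], axis=1)


def _ode_distribution(gen: GeneratorMatrix, j0: int, ts: np.ndarray) -> np.ndarray:
    """Stiff banded-Jacobian integration of the truncated master equation."""
    m = gen.m
    diag, up, down = gen.diag, gen.up, gen.down

    def rhs(t: float, p: np.ndarray) -> np.ndarray:
        dp = diag * p
        dp[1:] += up[:-1] * p[:-1]
        dp[:-1] += down[1:] * p[1:]
        return dp

    # banded Jacobian in LSODA packing: super-, main-, sub-diagonal rows
    ab = np.zeros((3, m + 1))
    ab[0, 1:] = down[1:]
    ab[1, :] = diag
    ab[2, :-1] = up[:-1]

    def jac(t: float, p: np.ndarray) -> np.ndarray:
        return ab

    y0 = np.zeros(m + 1)
    y0[j0] = 1.0
    t_end = float(ts.max()) if ts.size else 0.0
    if t_end == 0.0:
        return np.tile(y0, (ts.size, 1))
    sol = scipy.integrate.solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", t_eval=ts, rtol=ODE_RTOL,
        atol=ODE_ATOL, jac=jac, lband=1, uband=1,
    )
    if not sol.success:
        raise NumericalError(f"master-equation integration failed: {sol.message}")
    return sol.y.T


def solve_distribution(gen: GeneratorMatrix, j0: int, t: float) -> StateDistribution:
    """Distribution ``X_m(t) = exp(G_m t) delta(n - j0)`` of the truncated chain."""
    if not 0 <= j0 <= gen.m:
        raise InvalidParameterError(
            f"initial abundance j0={j0} outside the truncation 0..{gen.m}"
        )
    if t < 0:
        raise InvalidParameterError(f"time must be >= 0, got {t}")
    ts = np.array([float(t)])
    if t == 0.0:
        probs = np.zeros(gen.m + 1)
        probs[j0] = 1.0
        return StateDistribution(probs=probs, m=gen.m, t=0.0, j0=j0)
    try:
        probs = gen.solver().propagate(j0, ts)[0]
    except NumericalError:
        probs = _ode_distribution(gen, j0, ts)[0]
    return StateDistribution(probs=probs, m=gen.m, t=float(t), j0=j0)


# ---------------------------------------------------------------------------
# Extinction probability and truncation convergence
# ---------------------------------------------------------------------------


def _p0_matrix(
    params: ModelParams,
    j0: int,
    ts: np.ndarray,
    m: int,
    boundary: Boundary = "leaky",
) -> np.ndarray:
    gen = build_generator(params, m, boundary=boundary)
    try:
        return gen.solver().p0_from(j0, ts)
    except NumericalError:
        return _ode_distribution(gen, j0, ts)[:, 0]


def converge_truncation(
    params: ModelParams,
    j0: int,
    t_max: float,
    tol: float = DEFAULT_TOL,
    m0: int | None = None,
    m_max: int = DEFAULT_M_MAX,
    n_grid: int = 17,
    boundary: Boundary = "leaky",
) -> int:
    """Smallest tested truncation ``m`` with ``|p0^(m) - p0^(2m)| < tol``.

    The schedule doubles ``m`` from an initial guess and compares the
    extinction-probability trajectory on a grid spanning ``(0, t_max]``; the
    guarantee is on ``p0``, not on retained mass (the leaky boundary sheds
    mass by construction).
    """
    if tol <= 0:
        raise InvalidParameterError("tolerance must be positive")
    if j0 == 0 and params.v == 0.0 and params.variant == "proposed":
        return max(2, m0 or 2)  # absorbing: p0 == 1 for every m
    ts = np.linspace(0.0, float(t_max), n_grid)[1:]
    m = m0 or max(32, 2 * j0)
    if m <= j0:
        m = 2 * j0
    p_prev = _p0_matrix(params, j0, ts, m, boundary)
    while 2 * m <= m_max:
        p_next = _p0_matrix(params, j0, ts, 2 * m, boundary)
        if np.max(np.abs(p_next - p_prev)) < tol:
            return m
        m *= 2
        p_prev = p_next
    gen = build_generator(params, m, boundary=boundary)
    mass = solve_distribution(gen, j0, float(t_max)).mass
    raise TruncationConvergenceError(
        f"p0 not converged to {tol} by m={m} (ceiling {m_max}); retained "
        f"mass at t={t_max} was {mass:.6f}"
    )


def extinction_prob(
    params: ModelParams,
    j0: int,
    t: npt.ArrayLike,
    tol: float = DEFAULT_TOL,
    m: int | None = None,
) -> npt.NDArray[np.float64] | float:
    """Time-dependent extinction (empty-state) probability p0(t | j0).

    Dispatches on the parameters: closed forms when ``v = 0`` (and for the
    full-immigration variant, where the branching + Poisson-immigration
    decomposition gives ``p0 = q_u(t)^{j0} * ((1-(1-u)e^{-ut})/u)^{-v/(1-u)}``),
    otherwise the truncated matrix exponential at a converged truncation.
    For ``v > 0`` "extinct at t" means *currently empty*: immigration can
    refill the state later.
    """
    scalar = np.isscalar(t)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ts < 0):
        raise InvalidParameterError("time must be >= 0")
    if j0 < 0:
        raise InvalidParameterError(f"initial abundance must be >= 0, got {j0}")

    if params.variant == "full_immigration":
        from .full_immigration import full_extinction_closed

        out = full_extinction_closed(params.v, j0, ts, u=params.u)
    elif params.v == 0.0:
        out = extinction_cdf_closed(params.u, j0, ts)
    else:
        m_use = m if m is not None else converge_truncation(params, j0, float(ts.max() or 1.0), tol=tol)
        out = np.clip(_p0_matrix(params, j0, ts, m_use), 0.0, 1.0)
    return float(out[0]) if scalar else out


def survival_prob(
    params: ModelParams,
    j0: int,
    t: npt.ArrayLike,
    tol: float = DEFAULT_TOL,
    m: int | None = None,
) -> npt.NDArray[np.float64] | float:
    """P(abundance > 0 at t) = 1 - p0(t | j0)."""
    return 1.0 - extinction_prob(params, j0, t, tol=tol, m=m)


def extinction_prob_profile(
    params: ModelParams,
    times: Sequence[float] | npt.NDArray[np.float64],
    m: int,
    j_max: int | None = None,
    boundary: Boundary = "leaky",
) -> npt.NDArray[np.float64]:
    """Matrix of p0(t | j) for all initial abundances j = 0..j_max.

    One eigendecomposition of the truncated generator serves every initial
    condition simultaneously (row 0 of ``exp(G t)`` across columns).
    Shape ``(len(times), j_max + 1)``.
    """
    ts = np.asarray(times, dtype=float)
    gen = build_generator(params, m, boundary=boundary)
    return np.clip(gen.solver().p0_profile(ts, j_max=j_max), 0.0, 1.0)
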