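"""Area-based Fisher's logseries community model.

The regional species pool of area ``A`` carries ``S0`` species whose
abundances follow a logseries: the abundance of a species in any sampled
area ``X`` has mass

    phi(n | alpha_X) proportional to (1/n) * x_X**n,   n >= 1,

where ``x_X = X / (omega + X)`` and ``alpha_X = 1 / ln(1 + X / omega)``.
``omega`` sets how quickly richness accumulates with area (smaller omega,
heavier rare-species tail, more species per unit area).  Sampling a local
area ``a`` inside the region keeps the regional prefactor:

    phi(n | alpha_a, alpha_A) = (alpha_A / n) * (1 - e^{-1/alpha_a})**n,

whose total mass over ``n >= 1`` is ``alpha_A / alpha_a <= 1`` -- the
deficit is the chance the species does not occur in the sample at all.
Destroying a sub-area ``b`` removes the species endemic to it: a species
survives regionally with probability equal to its occurrence in the
remaining ``A - b``, so the endemic-extinction fraction is

    phi(0 | alpha_{A-b}, alpha_A) = 1 - alpha_A / alpha_{A-b},

defined here (the logseries itself has no ``n = 0`` class) as the
complement of the ``n >= 1`` mass of the remaining-area distribution.

Expected species counts are real-valued expectations throughout; nothing is
rounded to integers.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import numpy.typing as npt
from scipy.special import gammaln

from .sbd import InvalidParameterError

__all__ = [
    "LogseriesCommunity",
    "AbundanceSpectrum",
    "phi_local",
    "empty_fraction",
    "local_spectrum",
    "truncated_nb_pmf",
]

#: default relative tail mass (of total richness) left outside J_max
TAIL_EPS = 1e-9


@dataclass(frozen=True)
class LogseriesCommunity:
    """Regional community: logseries scale ``omega``, area ``A``, richness ``S0``."""

    omega: float
    A: float
    S0: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise InvalidParameterError(f"omega must be > 0, got {self.omega}")
        if self.A <= 0:
            raise InvalidParameterError(f"regional area must be > 0, got {self.A}")
        if self.S0 <= 0:
            raise InvalidParameterError(f"initial richness must be > 0, got {self.S0}")

    def alpha(self, X: float) -> float:
        """Logseries parameter ``alpha_X = 1 / ln(1 + X / omega)``."""
        if X <= 0:
            raise InvalidParameterError(f"area must be > 0, got {X}")
        return 1.0 / math.log1p(X / self.omega)

    def x(self, X: float) -> float:
        """Logseries base ``x_X = X / (omega + X) = 1 - e^{-1/alpha_X}``."""
        if X <= 0:
            raise InvalidParameterError(f"area must be > 0, got {X}")
        return X / (self.omega + X)


def phi_local(
    n: npt.ArrayLike, a: float, community: LogseriesCommunity
) -> npt.NDArray[np.float64] | float:
    """Expected abundance mass ``phi(n | alpha_a, alpha_A)`` for ``n >= 1``.

    ``(alpha_A / n) * x_a**n``; for ``a = A`` this is the regional logseries
    itself, which normalizes to 1.  The zero class is handled separately by
    :func:`empty_fraction`.
    """
    scalar = np.isscalar(n)
    n_arr = np.atleast_1d(np.asarray(n))
    if np.any(n_arr < 1) or np.any(n_arr != np.floor(n_arr)):
        raise InvalidParameterError("abundance classes must be integers >= 1 (use empty_fraction for n = 0)")
    if not 0 < a <= community.A:
        raise InvalidParameterError(f"local area must satisfy 0 < a <= A, got a={a}")
    out = community.alpha(community.A) / n_arr.astype(float) * community.x(a) ** n_arr
    return float(out[0]) if scalar else out


def empty_fraction(X_remaining: float, community: LogseriesCommunity) -> float:
    """Probability a regional species has no individuals in the remaining area.

    ``phi(0 | alpha_{A-b}, alpha_A) = 1 - alpha_A / alpha_{A-b}`` with
    ``X_remaining = A - b``; equivalently one minus the summed ``n >= 1``
    mass of the remaining-area distribution.  Degenerate geometries: no
    destruction gives 0, total destruction gives 1.
    """
    if X_remaining >= community.A:
        return 0.0
    if X_remaining <= 0:
        return 1.0
    return 1.0 - community.alpha(community.A) / community.alpha(X_remaining)


@dataclass
class AbundanceSpectrum:
    """Expected species counts ``S_j`` by abundance class ``j = 1..j_max``.

    ``counts[i]`` is the expected number of species with abundance ``i + 1``.
    Logseries-derived spectra additionally carry their analytic form
    ``S_j = s_coef * y**j / j`` (``s_coef = S_eff * alpha_A``, ``y = x_a``),
    which downstream code uses for exact tail sums; ad-hoc spectra leave
    those fields ``None``.
    """

    counts: npt.NDArray[np.float64]
    area: float | None = None
    s_coef: float | None = None
    y: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise InvalidParameterError("spectrum counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise InvalidParameterError("expected species counts must be >= 0")

    @property
    def j_max(self) -> int:
        return int(self.counts.size)

    @property
    def abundances(self) -> npt.NDArray[np.int64]:
        return np.arange(1, self.j_max + 1)

    @property
    def total_richness(self) -> float:
        """Exact total ``sum_{j>=1} S_j`` (analytic when available)."""
        if self.s_coef is not None and self.y is not None:
            return -self.s_coef * math.log1p(-self.y)
        return float(self.counts.sum())

    @classmethod
    def from_counts(cls, counts_by_abundance: dict[int, float]) -> "AbundanceSpectrum":
        """Build an ad-hoc spectrum from ``{abundance: expected count}``."""
        jmax = max(counts_by_abundance)
        counts = np.zeros(jmax)
        for j, s in counts_by_abundance.items():
            if j < 1:
                raise InvalidParameterError("abundance classes must be >= 1")
            counts[j - 1] = s
        return cls(counts=counts)

    def scaled(self, factor: float) -> "AbundanceSpectrum":
        """Spectrum with every expected count multiplied by ``factor``."""
        return AbundanceSpectrum(
            counts=self.counts * factor,
            area=self.area,
            s_coef=None if self.s_coef is None else self.s_coef * factor,
            y=self.y,
            meta=dict(self.meta),
        )

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (abundance class, expected species count).

        The header comment records the generating parameters.
        """
        buf = io.StringIO()
        if self.meta:
            items = ", ".join(f"{k}={v}" for k, v in sorted(self.meta.items()))
            buf.write(f"# {items}\n")
        buf.write("abundance,expected_species\n")
        for j, s in zip(self.abundances, self.counts):
            buf.write(f"{j},{float(s)!r}\n")
        Path(path).write_text(buf.getvalue())


def _logseries_j_max(y: float, eps: float) -> int:
    """Smallest J with relative tail mass of sum y^j / j below ``eps``.

    Uses the geometric bound ``tail(J) <= y^{J+1} / ((J+1)(1-y))`` against
    the exact total ``-ln(1-y)``.
    """
    total = -math.log1p(-y)
    target = eps * total
    J = 64
    while True:
        bound = math.exp((J + 1) * math.log(y)) / ((J + 1) * (1.0 - y))
        if bound < target:
            return J
        J *= 2
        if J > 50_000_000:  # pragma: no cover - defensive
            raise InvalidParameterError("logseries tail does not truncate; check omega")


def local_spectrum(
    a: float,
    community: LogseriesCommunity,
    at: str = "initial",
    b: float = 0.0,
    tail_eps: float = TAIL_EPS,
) -> AbundanceSpectrum:
    """Expected abundance spectrum of an intact local area ``a``.

    ``at="initial"`` gives ``S_j = S0 * phi(j | alpha_a, alpha_A)``;
    ``at="post_destruction"`` rescales by the regional survivor fraction
    after destroying area ``b``:
    ``S_j = S0 (1 - phi(0 | alpha_{A-b}, alpha_A)) phi(j | alpha_a, alpha_A)``.
    The truncation ``j_max`` is adaptive: the neglected tail holds less than
    ``tail_eps`` of the total richness.
    """
    if not 0 < a <= community.A:
        raise InvalidParameterError(f"local area must satisfy 0 < a <= A, got a={a}")
    if at == "initial":
        if b:
            raise InvalidParameterError("b is only meaningful with at='post_destruction'")
        s_eff = community.S0
    elif at == "post_destruction":
        if not 0 <= b < community.A:
            raise InvalidParameterError(f"destroyed area must satisfy 0 <= b < A, got b={b}")
        if a + b > community.A:
            raise InvalidParameterError(
                f"intact area a={a} plus destroyed area b={b} exceeds the region A={community.A}"
            )
        s_eff = community.S0 * (1.0 - empty_fraction(community.A - b, community))
    else:
        raise InvalidParameterError(f"unknown spectrum epoch {at!r}")
    y = community.x(a)
    s_coef = s_eff * community.alpha(community.A)
    jmax = _logseries_j_max(y, tail_eps)
    j = np.arange(1, jmax + 1, dtype=float)
    counts = s_coef * np.exp(j * math.log(y) - np.log(j))
    meta = {
        "omega": community.omega, "A": community.A, "a": a, "b": b,
        "S0": community.S0, "epoch": at,
    }
    return AbundanceSpectrum(counts=counts, area=a, s_coef=s_coef, y=y, meta=meta)


def truncated_nb_pmf(
    n: npt.ArrayLike, A: float, k: float, omega: float
) -> npt.NDArray[np.float64] | float:
    """Zero-truncated negative-binomial abundance model on ``n >= 1``.

    ``C * Gamma(k+n)/(Gamma(k) n!) * (omega/(omega+A))**k (A/(omega+A))**n``
    with ``C = (1 - (omega/(omega+A))**k)**-1``.  Its ``k -> 0`` limit is
    the logseries ``phi(n | A, omega)``, which this function exists to
    verify numerically.
    """
    if k <= 0:
        raise InvalidParameterError("k must be > 0; use the logseries for the k -> 0 limit")
    if A <= 0 or omega <= 0:
        raise InvalidParameterError("areas and omega must be positive")
    scalar = np.isscalar(n)
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(n_arr < 1) or np.any(n_arr != np.floor(n_arr)):
        raise InvalidParameterError("abundance classes must be integers >= 1")
    log_ratio_zero = k * math.log(omega / (omega + A))
    logC = -math.log(-math.expm1(log_ratio_zero))
    logp = (
        logC
        + gammaln(k + n_arr) - gammaln(k) - gammaln(n_arr + 1.0)
        + log_ratio_zero
        + n_arr * math.log(A / (omega + A))
    )
    out = np.exp(logp)
    return float(out[0]) if scalar else out
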