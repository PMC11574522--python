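"""Two-state telegraph model of transcription: rates, stationary distributions, burst statistics.

The telegraph model describes a promoter switching between an inactive (OFF) and an
active (ON) state.  mRNA is produced only while ON (rate ``k_eject``) and each mRNA
molecule decays independently (rate ``k_decay``).  The stationary mRNA copy-number
distribution of a single allele is the Beta-Poisson law: a Poisson whose intensity
``lam * p`` is modulated by promoter activity ``p ~ Beta(a, b)``, with the
dimensionless parameters ``a = k_on/k_decay``, ``b = k_off/k_decay`` and
``lam = k_eject/k_decay``.

Two independent implementations of the stationary law are provided:

* :func:`steady_state_closed_form` — the Beta-Poisson integral evaluated by
  log-space Gauss-Jacobi quadrature (exact per copy number, no truncation bias);
* :func:`cme_steady_state` — the stationary solution of the truncated chemical
  master equation over the joint (gene state, copy number) space, obtained by a
  sparse linear solve.

They serve as mutual oracles: agreement to 1e-8 is asserted in the test suite.
All rates are expressed per minute throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.special import betaln, gammaln, logsumexp, roots_genlaguerre, roots_hermitenorm, roots_jacobi  # noqa: F401

__all__ = [
    "TelegraphRates",
    "DimensionlessRates",
    "CountDistribution",
    "BurstStatistics",
    "TruncationError",
    "steady_state_closed_form",
    "cme_steady_state",
    "convolve_alleles",
    "burst_statistics",
    "decay_from_halflife",
    "decay_to_halflife",
    "betapoisson_logpmf",
    "telegraph_moments",
]

LN2 = math.log(2.0)

#: tail mass beyond the truncation bound must stay below this at construction
TAIL_TOL = 1e-8

# Gauss-Jacobi weights overflow once the total Jacobi weight mass
# 2**(a+b-1) * B(a, b) approaches the double-precision limit; beyond it the
# Beta mixing density is sharply concentrated and Poisson-mixture limits are used.
_LOG_MU0_MAX = 650.0


class TruncationError(RuntimeError):
    """Raised when the requested support cannot hold the distribution's mass."""

    def __init__(self, message: str, required_n_max: int | None = None):
        super().__init__(message)
        self.required_n_max = required_n_max


def _require_positive(name: str, value: float) -> None:
    if not (np.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class TelegraphRates:
    """The four kinetic rates of one gene's telegraph model, per minute.

    ``k_on`` is the promoter activation rate (burst frequency), ``k_off`` the
    inactivation rate, ``k_eject`` the mRNA production rate while active and
    ``k_decay`` the per-molecule mRNA degradation rate.
    """

    k_on: float
    k_off: float
    k_eject: float
    k_decay: float

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_eject", "k_decay"):
            _require_positive(name, getattr(self, name))

    def dimensionless(self) -> "DimensionlessRates":
        return DimensionlessRates(
            a=self.k_on / self.k_decay,
            b=self.k_off / self.k_decay,
            lam=self.k_eject / self.k_decay,
        )

    @classmethod
    def from_dimensionless(cls, dimless: "DimensionlessRates", k_decay: float) -> "TelegraphRates":
        _require_positive("k_decay", k_decay)
        return cls(
            k_on=dimless.a * k_decay,
            k_off=dimless.b * k_decay,
            k_eject=dimless.lam * k_decay,
            k_decay=k_decay,
        )


@dataclass(frozen=True)
class DimensionlessRates:
    """Telegraph rates nondimensionalized by the decay rate."""

    a: float
    b: float
    lam: float

    def __post_init__(self):
        for name in ("a", "b", "lam"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class BurstStatistics:
    """Derived bursting quantities: size (eject/OFF), frequency (ON rate), mean expression."""

    burst_size: float
    frequency: float
    mean_expression: float


class CountDistribution:
    """A truncated mRNA copy-number probability vector P(0..n_max)."""

    def __init__(self, probs: np.ndarray, tail_mass: float = 0.0, normalize: bool = True):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("probs must be a non-empty 1-D vector")
        if np.any(probs < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        probs = np.clip(probs, 0.0, None)
        total = probs.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("probability vector has no mass")
        self.raw_sum = float(total)
        self.tail_mass = float(tail_mass)
        self.probs = probs / total if normalize else probs

    @property
    def n_max(self) -> int:
        return self.probs.size - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def var(self) -> float:
        m = self.mean()
        return float((self.support.astype(float) ** 2) @ self.probs - m * m)

    def fano(self) -> float:
        return self.var() / self.mean()

    def total_variation(self, other: "CountDistribution") -> float:
        n = max(self.probs.size, other.probs.size)
        p = np.zeros(n)
        q = np.zeros(n)
        p[: self.probs.size] = self.probs
        q[: other.probs.size] = other.probs
        return 0.5 * float(np.abs(p - q).sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("n\tprobability\n")
            for n, p in enumerate(self.probs):
                fh.write(f"{n}\t{p:.17g}\n")

    def __repr__(self):
        return f"CountDistribution(n_max={self.n_max}, mean={self.mean():.4g})"


def decay_from_halflife(t_half: float) -> float:
    """Decay rate per minute from an mRNA half-life in minutes: ln(2)/t_half."""
    _require_positive("t_half", t_half)
    return LN2 / t_half


def decay_to_halflife(k_decay: float) -> float:
    """Half-life in minutes from a per-minute decay rate: ln(2)/k_decay."""
    _require_positive("k_decay", k_decay)
    return LN2 / k_decay


def telegraph_moments(a: float, b: float, lam: float) -> tuple[float, float]:
    """Stationary mean and variance of a single allele's copy number.

    mean = lam * a / (a + b);
    var  = mean + lam**2 * a * b / ((a + b)**2 * (a + b + 1)).
    """
    mean = lam * a / (a + b)
    var = mean + lam * lam * a * b / ((a + b) ** 2 * (a + b + 1.0))
    return mean, var


def _logpmf_gauss_jacobi(a: float, b: float, lam: float, n: np.ndarray, n_nodes: int) -> np.ndarray:
    # integral over p in (0,1) of Poisson(n; lam p) with Beta(a, b) weight,
    # mapped to the Jacobi weight (1-x)^(b-1) (1+x)^(a-1) on (-1, 1)
    x, w = roots_jacobi(n_nodes, b - 1.0, a - 1.0)
    p = 0.5 * (1.0 + x)
    log_w = np.log(w) + (1.0 - a - b) * LN2 - betaln(a, b)
    log_p = np.log(p)
    # log Poisson(n; lam p) summed against quadrature weights, in log space;
    # manual streaming logsumexp: this is the inner loop of the MCMC likelihood
    terms = np.multiply.outer(n, math.log(lam) + log_p)
    terms += log_w - lam * p
    mx = terms.max(axis=1)
    np.exp(terms - mx[:, None], out=terms)
    return mx + np.log(terms.sum(axis=1)) - gammaln(n + 1.0)


def _logpmf_negative_binomial(a: float, b: float, lam: float, n: np.ndarray) -> np.ndarray:
    # bursty limit b >> a: Beta(a,b) ~ Gamma(a, 1/(a+b)) so the intensity is
    # Gamma(a, lam/(a+b)) and counts are negative binomial with r=a
    s = lam / (a + b)
    log_q = math.log(s) - math.log1p(s)   # log(s/(1+s))
    log_1mq = -math.log1p(s)
    return gammaln(n + a) - gammaln(a) - gammaln(n + 1.0) + a * log_1mq + n * log_q


def _logpmf_laguerre(a: float, b: float, lam: float, n: np.ndarray, n_nodes: int = 40) -> np.ndarray:
    # near-always-ON limit a >> b: q = 1 - p ~ Gamma(b, 1/(a+b)); integrate
    # Poisson(n; lam (1 - q)) against the Gamma density with generalized
    # Gauss-Laguerre nodes (weight q^(b-1) e^(-q))
    x, w = roots_genlaguerre(n_nodes, b - 1.0)
    q = x / (a + b)
    keep = q < 1.0 - 1e-12
    q, w = q[keep], w[keep]
    inten = lam * (1.0 - q)
    log_w = np.log(w) - gammaln(b)
    terms = log_w[None, :] + n[:, None] * np.log(inten)[None, :] - inten[None, :]
    return logsumexp(terms, axis=1) - gammaln(n + 1.0)


def _logpmf_hermite(a: float, b: float, lam: float, n: np.ndarray, n_nodes: int = 31) -> np.ndarray:
    # both a and b large: Beta(a,b) ~ Normal(mu, sd); Gauss-Hermite quadrature
    mu = a / (a + b)
    sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
    x, w = roots_hermitenorm(n_nodes)
    p = np.clip(mu + sd * x, 1e-300, 1.0)
    log_w = np.log(w) - 0.5 * math.log(2.0 * math.pi)
    terms = log_w[None, :] + n[:, None] * np.log(lam * p)[None, :] - lam * p[None, :]
    return logsumexp(terms, axis=1) - gammaln(n + 1.0)


def betapoisson_logpmf(
    a: float, b: float, lam: float, n: np.ndarray, n_nodes: int | None = None
) -> np.ndarray:
    """Log stationary pmf of a single telegraph allele at copy numbers ``n``.

    ``n_nodes=None`` selects an accuracy-oriented node count scaled with ``lam``
    and the largest requested copy number (used by the closed-form oracle);
    a fixed small node count (e.g. 60) is appropriate inside MCMC loops.
    Parameter corners where the Jacobi weights would overflow fall back to
    Poisson-mixture limits of the Beta law (negative-binomial for b >> a,
    Gamma-ON for a >> b, normal for a, b both large).
    """
    for name, val in (("a", a), ("b", b), ("lam", lam)):
        _require_positive(name, val)
    n = np.asarray(n, dtype=float)
    log_mu0 = (a + b - 1.0) * LN2 + betaln(a, b)
    if log_mu0 < _LOG_MU0_MAX:
        if n_nodes is None:
            n_nodes = int(max(120, min(4000, 2.0 * (lam + (n.max() if n.size else 0.0)))))
        return _logpmf_gauss_jacobi(a, b, lam, n, n_nodes)
    if a <= b and a < 200.0:
        return _logpmf_negative_binomial(a, b, lam, n)
    if b < a and b < 200.0:
        return _logpmf_laguerre(a, b, lam, n)
    return _logpmf_hermite(a, b, lam, n)


def _default_n_max(a: float, b: float, lam: float) -> int:
    mean, var = telegraph_moments(a, b, lam)
    return max(8, int(math.ceil(mean + 10.0 * math.sqrt(var))))


def steady_state_closed_form(
    rates: TelegraphRates | DimensionlessRates, n_max: int | None = None
) -> CountDistribution:
    """Stationary copy-number distribution of one allele, via the Beta-Poisson closed form.

    The pmf is exact per copy number (no truncation bias); the vector is
    normalized over ``0..n_max`` after verifying that the tail mass beyond
    ``n_max`` is below 1e-8, otherwise a :class:`TruncationError` naming a
    sufficient ``n_max`` is raised.  With ``n_max=None`` the bound is chosen
    adaptively from the analytic moments and doubled until the tail criterion
    holds.
    """
    d = rates.dimensionless() if isinstance(rates, TelegraphRates) else rates
    adaptive = n_max is None
    if not adaptive and n_max < 0:
        raise ValueError(f"n_max must be >= 0, got {n_max}")
    bound = _default_n_max(d.a, d.b, d.lam) if adaptive else int(n_max)
    for _ in range(40):
        logp = betapoisson_logpmf(d.a, d.b, d.lam, np.arange(bound + 1))
        probs = np.exp(logp)
        tail = max(0.0, 1.0 - probs.sum())
        if tail < TAIL_TOL:
            return CountDistribution(probs, tail_mass=tail)
        if not adaptive:
            # find a sufficient bound to report
            needed = bound
            t = tail
            while t >= TAIL_TOL and needed < 10_000_000:
                needed = max(needed * 2, needed + 8)
                lp = betapoisson_logpmf(d.a, d.b, d.lam, np.arange(needed + 1))
                t = max(0.0, 1.0 - np.exp(lp).sum())
            raise TruncationError(
                f"tail mass {tail:.3g} beyond n_max={bound} exceeds {TAIL_TOL}; "
                f"n_max={needed} is sufficient",
                required_n_max=needed,
            )
        bound = max(bound * 2, bound + 8)
    raise TruncationError("adaptive truncation failed to converge")


def _cme_generator(a: float, b: float, lam: float, n_max: int) -> sparse.csr_matrix:
    # states indexed 2n + g with g in {0: OFF, 1: ON}; transitions:
    # OFF->ON at a, ON->OFF at b, ON: n->n+1 at lam, any: n->n-1 at n
    size = 2 * (n_max + 1)
    rows, cols, vals = [], [], []

    def add(i, j, r):
        rows.append(j)
        cols.append(i)
        vals.append(r)      # column i loses, row j gains (generator A with A@pi = dpi/dt)

    diag = np.zeros(size)
    for n in range(n_max + 1):
        off = 2 * n
        on = 2 * n + 1
        add(off, on, a)
        diag[off] -= a
        add(on, off, b)
        diag[on] -= b
        if n < n_max:
            add(on, on + 2, lam)
            diag[on] -= lam
        if n > 0:
            add(off, off - 2, n * 1.0)
            diag[off] -= n
            add(on, on - 2, n * 1.0)
            diag[on] -= n
    rows.extend(range(size))
    cols.extend(range(size))
    vals.extend(diag)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(size, size))


def cme_steady_state(
    rates: TelegraphRates | DimensionlessRates, n_max: int | None = None
) -> CountDistribution:
    """Stationary distribution from the truncated chemical master equation.

    Solves the linear stationary system of the 2(n_max+1)-state master equation
    (gene state x copy number) with a normalization constraint and marginalizes
    the gene state.  Independent of :func:`steady_state_closed_form`; the two
    agree to 1e-8 on the tested parameter grid.  Truncation-tail mass is
    estimated by geometric extrapolation of the last two support points.
    """
    d = rates.dimensionless() if isinstance(rates, TelegraphRates) else rates
    adaptive = n_max is None
    if not adaptive and n_max < 0:
        raise ValueError(f"n_max must be >= 0, got {n_max}")
    bound = _default_n_max(d.a, d.b, d.lam) if adaptive else int(n_max)
    for _ in range(40):
        A = _cme_generator(d.a, d.b, d.lam, bound).tolil()
        size = A.shape[0]
        # replace the first balance equation with the normalization sum(pi) = 1
        A[0, :] = 1.0
        rhs = np.zeros(size)
        rhs[0] = 1.0
        pi = spsolve(A.tocsr(), rhs)
        if not np.all(np.isfinite(pi)):
            raise ArithmeticError(
                f"singular or ill-conditioned CME system at a={d.a}, b={d.b}, "
                f"lam={d.lam}, n_max={bound}"
            )
        marg = pi[0::2] + pi[1::2]
        neg = marg.min()
        if neg < -1e-9:
            raise ArithmeticError(
                f"CME solution has negative probabilities (min {neg:.3g}); "
                f"system ill-conditioned at a={d.a}, b={d.b}, lam={d.lam}"
            )
        marg = np.clip(marg, 0.0, None)
        tail = _geometric_tail(marg)
        if tail < TAIL_TOL:
            return CountDistribution(marg, tail_mass=tail)
        if not adaptive:
            raise TruncationError(
                f"estimated tail mass {tail:.3g} beyond n_max={bound} exceeds {TAIL_TOL}; "
                f"n_max={2 * bound} should be retried",
                required_n_max=2 * bound,
            )
        bound = max(bound * 2, bound + 8)
    raise TruncationError("adaptive truncation failed to converge")


def _geometric_tail(marg: np.ndarray) -> float:
    if marg.size < 2 or marg[-1] <= 0:
        return 0.0
    if marg[-2] <= 0:
        return float(marg[-1])
    r = marg[-1] / marg[-2]
    if r >= 1.0:
        return math.inf
    return float(marg[-1] * r / (1.0 - r))


def convolve_alleles(dist: CountDistribution, n_alleles: int) -> CountDistribution:
    """Copy-number distribution of ``n_alleles`` independent, identical alleles.

    The n-fold discrete self-convolution; support extends accordingly.  Allele
    counts outside {1, 2, 4, 8, 16} are accepted with a warning (the ploidy
    grid used for sensitivity refits).
    """
    if n_alleles < 1:
        raise ValueError(f"n_alleles must be >= 1, got {n_alleles}")
    if n_alleles not in (1, 2, 4, 8, 16):
        import warnings

        warnings.warn(f"unusual allele count {n_alleles}; expected one of 1, 2, 4, 8, 16")
    if n_alleles == 1:
        return dist
    probs = dist.probs
    out = probs
    for _ in range(n_alleles - 1):
        out = np.convolve(out, probs)
    return CountDistribution(out, tail_mass=dist.tail_mass * n_alleles, normalize=False)


def burst_statistics(rates: TelegraphRates, n_alleles: int = 2) -> BurstStatistics:
    """Burst size (eject/OFF), burst frequency (ON rate) and expected mRNA per cell."""
    if n_alleles < 1:
        raise ValueError(f"n_alleles must be >= 1, got {n_alleles}")
    d = rates.dimensionless()
    mean, _ = telegraph_moments(d.a, d.b, d.lam)
    return BurstStatistics(
        burst_size=rates.k_eject / rates.k_off,
        frequency=rates.k_on,
        mean_expression=n_alleles * mean,
    )
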