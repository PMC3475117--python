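"""Bayesian allele-frequency posterior for pooled sequencing.

The population allele frequency ``f`` is discretized on a grid
``0, 1/N_d, ..., 1`` (default ``N_d = 100``, i.e. 0, 0.01, ..., 1).  For a
site with used depth ``C`` and ``n_A`` alternative reads from a pool of
``N`` chromosomes, the likelihood marginalizes over the unknown number
``k`` of alternative chromosomes sampled into the pool:

    P(n_A | f) = sum_{k=0}^{N} Binom(n_A; C, p_tilde_k) * Binom(k; N, f)

where ``p_tilde_k`` is the error-corrected read probability for a true
alternative fraction ``k/N`` (see :mod:`poolmaf.errors`).  The posterior is
``P(f | n_A) ∝ P(n_A | f) P(f)`` with one of four priors:

====================  ==========================================================
prior                 mass
====================  ==========================================================
flat, unfolded        P(0) = 1 - theta - D, P(1) = D, interior theta/(N_d - 1)
flat, folded          P(0) = P(1) = (1 - theta)/2, interior theta/(N_d - 1)
informative, unfold.  P(0) = 1 - theta*beta - D, P(1) = D, P(f) = theta/(N_d*f)
informative, folded   P(0) = P(1) = (1 - theta*beta)/2,
                      P(f) = theta/(2*N_d*f*(1-f))
====================  ==========================================================

with ``beta`` the harmonic number ``sum_{i=1}^{N_d-1} 1/i``, the unique
constant under which every variant sums exactly to one on the grid.
``theta`` is the prior nucleotide diversity and ``D`` the prior divergence
(probability that the site is fixed for the non-reference allele).  The
informative interior masses discretize the neutral site-frequency spectrum
P(f) ∝ 1/f (folded: 1/(f(1-f))).

A site is called segregating when the posterior mass on 0 < f < 1 exceeds
a threshold (default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ErrorRates, effective_read_prob, site_error_rates
from .pileup import SiteCounts

__all__ = [
    "FrequencyGrid",
    "PriorSpec",
    "Distribution",
    "SiteResult",
    "harmonic_number",
    "build_prior",
    "likelihood",
    "likelihood_curve",
    "posterior",
    "summarize",
    "call_site",
]


def harmonic_number(n: int) -> float:
    """H_n = sum_{i=1}^{n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


@dataclass(frozen=True)
class FrequencyGrid:
    """Discrete frequency grid f_i = i/N_d, i = 0..N_d."""

    n_d: int = 100

    def __post_init__(self):
        if self.n_d < 2:
            raise ValueError("frequency grid needs n_d >= 2")

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.n_d + 1) / self.n_d

    def __len__(self) -> int:
        return self.n_d + 1


@dataclass(frozen=True)
class PriorSpec:
    """Configuration of the frequency prior.

    ``kind`` is "flat" or "informative"; ``folded`` selects the variant
    that is invariant under f -> 1 - f (reference allele not assumed
    ancestral).  ``divergence`` is ignored for folded priors.
    """

    kind: str = "informative"
    folded: bool = True
    theta: float = 0.001
    divergence: float = 0.1
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)

    def __post_init__(self):
        if self.kind not in ("flat", "informative"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")


class PriorConfigError(ValueError):
    """A prior mass went negative for the given theta/divergence."""


@dataclass
class Distribution:
    """A probability vector on the frequency grid."""

    grid: FrequencyGrid
    mass: np.ndarray

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (len(self.grid),):
            raise ValueError("mass length does not match grid")

    def normalized(self) -> "Distribution":
        total = self.mass.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return Distribution(self.grid, self.mass / total)


@dataclass
class SiteResult:
    """Posterior summaries for one site."""

    chrom: str
    pos: int
    ref: str
    alt: Optional[str]
    C: int
    n_A: int
    eps_R: float
    eps_A: float
    p_f0: float
    p_f1: float
    p_seg: float
    mean_f: float
    map_f: float
    called: bool


def build_prior(spec: PriorSpec) -> Distribution:
    """Prior mass vector on the grid; sums to 1 analytically."""
    n_d = spec.grid.n_d
    f = spec.grid.values
    theta, D = spec.theta, spec.divergence
    mass = np.empty(n_d + 1)
    interior = f[1:-1]
    if spec.kind == "flat":
        mass[1:-1] = theta / (n_d - 1)
        if spec.folded:
            mass[0] = mass[-1] = (1.0 - theta) / 2.0
        else:
            mass[0] = 1.0 - theta - D
            mass[-1] = D
    else:
        beta = harmonic_number(n_d - 1)
        if spec.folded:
            mass[1:-1] = theta / (2.0 * n_d * interior * (1.0 - interior))
            mass[0] = mass[-1] = (1.0 - theta * beta) / 2.0
        else:
            mass[1:-1] = theta / (n_d * interior)
            mass[0] = 1.0 - theta * beta - D
            mass[-1] = D
    if mass[0] < 0 or mass[-1] < 0:
        which = "P(f=0)" if mass[0] < 0 else "P(f=1)"
        raise PriorConfigError(
            f"{which} is negative for theta={theta}, divergence={D}, "
            f"kind={spec.kind}, folded={spec.folded}"
        )
    return Distribution(spec.grid, mass)


def _log_binom_pmf(x: float, n: float, p: float) -> float:
    """log Binom(x; n, p), handling p in {0, 1} exactly."""
    if p <= 0.0:
        return 0.0 if x == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if x == n else -np.inf
    return (
        gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        + x * np.log(p) + (n - x) * np.log1p(-p)
    )


def likelihood(n_A: int, C: int, N: int, f: float, rates: ErrorRates) -> float:
    """P(n_A | f): the pooled-read likelihood at one grid frequency.

    Accumulated in log space (log-sum-exp over the pool composition k) so
    that deep sites do not underflow.
    """
    if not 0 <= n_A <= C:
        raise ValueError(f"need 0 <= n_A <= C, got n_A={n_A}, C={C}")
    if N < 1:
        raise ValueError("pool size N must be >= 1")
    terms = np.empty(N + 1)
    for k in range(N + 1):
        p_tilde = effective_read_prob(k / N, rates)
        terms[k] = _log_binom_pmf(n_A, C, p_tilde) + _log_binom_pmf(k, N, f)
    return float(np.exp(logsumexp(terms)))


def likelihood_curve(n_A: int, C: int, N: int, grid: FrequencyGrid,
                     rates: ErrorRates) -> np.ndarray:
    """P(n_A | f) for every f on the grid (vectorized over k and f)."""
    if not 0 <= n_A <= C:
        raise ValueError(f"need 0 <= n_A <= C, got n_A={n_A}, C={C}")
    if N < 1:
        raise ValueError("pool size N must be >= 1")
    k = np.arange(N + 1)
    p_tilde = (1.0 - rates.rho) * (k / N) + rates.alpha * (1.0 - k / N)
    with np.errstate(divide="ignore"):
        log_read = (
            gammaln(C + 1) - gammaln(n_A + 1) - gammaln(C - n_A + 1)
            + n_A * np.log(p_tilde) + (C - n_A) * np.log1p(-p_tilde)
        )
    log_read = np.where(np.isnan(log_read), -np.inf, log_read)
    f = grid.values
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pool = (
            gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)
        )[:, None] + k[:, None] * np.log(f[None, :]) \
            + (N - k)[:, None] * np.log1p(-f[None, :])
    # 0 * log 0 -> 0 at the grid endpoints
    log_pool = np.where(np.isnan(log_pool), -np.inf, log_pool)
    log_pool[0, 0] = 0.0
    log_pool[N, -1] = 0.0
    total = log_read[:, None] + log_pool
    m = total.max(axis=0)
    safe_m = np.where(np.isfinite(m), m, 0.0)
    out = np.exp(safe_m) * np.exp(total - safe_m[None, :]).sum(axis=0)
    return out


def posterior(counts: SiteCounts, prior: Distribution, N: int,
              rates: Optional[ErrorRates] = None) -> Distribution:
    """Posterior P(f | n_A) = normalized prior x likelihood.

    ``rates`` defaults to the per-site class error rates derived from the
    quality lists in ``counts``.
    """
    if rates is None:
        rates = site_error_rates(counts.quals_R, counts.quals_A)
    lik = likelihood_curve(counts.n_A, counts.C, N, prior.grid, rates)
    mass = prior.mass * lik
    total = mass.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError(
            f"posterior vanished at {counts.chrom}:{counts.pos} "
            f"(C={counts.C}, n_A={counts.n_A})"
        )
    return Distribution(prior.grid, mass / total)


def summarize(post: Distribution, threshold: float = 0.9, *,
              chrom: str = "", pos: int = 0, ref: str = "N",
              alt: Optional[str] = None, C: int = 0, n_A: int = 0,
              eps_R: float = float("nan"),
              eps_A: float = float("nan")) -> SiteResult:
    """Per-site summaries of a normalized posterior.

    ``p_seg`` is the total interior mass (both fixed classes excluded);
    the site is called when ``p_seg`` strictly exceeds the threshold.
    MAP ties break toward the smaller frequency.
    """
    mass = post.mass
    f = post.grid.values
    p_f0 = float(mass[0])
    p_f1 = float(mass[-1])
    p_seg = float(mass[1:-1].sum())
    mean_f = float(np.dot(f, mass))
    map_f = float(f[int(np.argmax(mass))])  # argmax returns first (smallest f)
    return SiteResult(
        chrom=chrom, pos=pos, ref=ref, alt=alt, C=C, n_A=n_A,
        eps_R=eps_R, eps_A=eps_A,
        p_f0=p_f0, p_f1=p_f1, p_seg=p_seg,
        mean_f=mean_f, map_f=map_f, called=p_seg > threshold,
    )


def call_site(counts: SiteCounts, prior: Distribution, N: int,
              threshold: float = 0.9,
              rates: Optional[ErrorRates] = None) -> SiteResult:
    """Convenience wrapper: error rates -> posterior -> summaries."""
    if rates is None:
        rates = site_error_rates(counts.quals_R, counts.quals_A)
    post = posterior(counts, prior, N, rates=rates)
    return summarize(
        post, threshold,
        chrom=counts.chrom, pos=counts.pos, ref=counts.ref, alt=counts.alt,
        C=counts.C, n_A=counts.n_A, eps_R=rates.eps_R, eps_A=rates.eps_A,
    )
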