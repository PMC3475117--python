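"""Two-class sequencing-error model.

Reads overlapping a site are reduced to two symbols: those matching the
reference ("R") and those carrying any alternative base ("A").  Each class
gets a single error rate, the geometric mean of the Phred-implied error
probabilities of its reads.  Bayes inversion (assuming P(A) = P(R) = 1/2)
turns the per-class rates ``eps_R``, ``eps_A`` into the misread
probabilities

    rho   = eps_R * (1 - 2*eps_A) / (1 - eps_A - eps_R)
    alpha = eps_A * (1 - 2*eps_R) / (1 - eps_A - eps_R)

so that a read drawn from a chromosome carrying the alternative allele is
observed as alternative with probability 1 - rho, and a read from a
reference chromosome is observed as alternative with probability alpha.
The error-corrected probability of observing an alternative read when the
true alternative fraction among sampled chromosomes is ``p`` is then

    p_tilde = (1 - rho) * p + alpha * (1 - p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "EPS_FLOOR",
    "EPS_CEIL",
    "DEFAULT_FALLBACK_EPS",
    "ErrorRates",
    "phred_to_error",
    "class_error_rate",
    "misread_rates",
    "effective_read_prob",
    "site_error_rates",
]

#: Clamp range for class error rates.  The floor keeps probabilities
#: strictly positive; the ceiling keeps 1 - eps_A - eps_R > 0.5 so that
#: rho and alpha stay in [0, 1].
EPS_FLOOR = 1e-6
EPS_CEIL = 0.25

#: Error rate assumed when a site carries no quality information at all.
DEFAULT_FALLBACK_EPS = 1e-3

PHRED_MIN_CODE = 33
PHRED_MAX_CODE = 126


@dataclass(frozen=True)
class ErrorRates:
    """Per-site class error rates and the derived misread probabilities."""

    eps_R: float
    eps_A: float
    rho: float
    alpha: float

    @classmethod
    def from_class_rates(cls, eps_R: float, eps_A: float) -> "ErrorRates":
        rho, alpha = misread_rates(eps_A, eps_R)
        return cls(eps_R=eps_R, eps_A=eps_A, rho=rho, alpha=alpha)


def phred_to_error(quality_char: str, offset: int = 33) -> float:
    """Convert one ASCII quality character to an error probability.

    The Phred convention maps character code ``c`` to ``10**(-(c - offset)/10)``.

    Parameters
    ----------
    quality_char:
        A single printable ASCII character (codes 33-126).
    offset:
        Encoding offset; 33 for the standard Sanger/Illumina-1.8 encoding.
    """
    code = ord(quality_char)
    if not PHRED_MIN_CODE <= code <= PHRED_MAX_CODE:
        raise ValueError(
            f"quality character code {code} outside printable range "
            f"[{PHRED_MIN_CODE}, {PHRED_MAX_CODE}]"
        )
    return 10.0 ** (-(code - offset) / 10.0)


def class_error_rate(error_probs: Sequence[float] | Iterable[float],
                     fallback: float = DEFAULT_FALLBACK_EPS) -> float:
    """Geometric mean of a class's error probabilities, clamped to
    [``EPS_FLOOR``, ``EPS_CEIL``].

    An empty class has no quality information of its own and falls back to
    ``fallback`` (callers typically pass the geometric mean over all reads
    at the site; see :func:`site_error_rates`).
    """
    probs = list(error_probs)
    if not probs:
        value = fallback
    else:
        value = math.exp(sum(math.log(p) for p in probs) / len(probs))
    return min(max(value, EPS_FLOOR), EPS_CEIL)


def misread_rates(eps_A: float, eps_R: float) -> tuple[float, float]:
    """Misread probabilities (rho, alpha) from the class error rates.

    ``rho`` is the probability that a read from an alternative-allele
    chromosome is observed as reference; ``alpha`` the probability that a
    reference read is observed as alternative.  Inputs are expected to be
    pre-clamped to at most ``EPS_CEIL`` so the denominator stays positive.
    """
    denom = 1.0 - eps_A - eps_R
    rho = eps_R * (1.0 - 2.0 * eps_A) / denom
    alpha = eps_A * (1.0 - 2.0 * eps_R) / denom
    return rho, alpha


def effective_read_prob(p: float, rates: ErrorRates) -> float:
    """Error-corrected probability of observing an alternative read.

    ``p`` is the true alternative fraction among the sampled chromosomes
    (k/N for k alternative chromosomes in a pool of N).
    """
    return (1.0 - rates.rho) * p + rates.alpha * (1.0 - p)


def site_error_rates(quals_R: Sequence[float], quals_A: Sequence[float],
                     fallback: float = DEFAULT_FALLBACK_EPS) -> ErrorRates:
    """Class error rates for one site, with the empty-class fallback rule.

    A class with no reads borrows the geometric mean over *all* reads at
    the site; if the site is empty both classes use ``fallback``.
    """
    pooled = list(quals_R) + list(quals_A)
    site_fallback = class_error_rate(pooled, fallback) if pooled else fallback
    eps_R = class_error_rate(quals_R, site_fallback)
    eps_A = class_error_rate(quals_A, site_fallback)
    return ErrorRates.from_class_rates(eps_R=eps_R, eps_A=eps_A)
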