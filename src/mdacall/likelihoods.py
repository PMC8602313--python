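"""Per-read and per-sample likelihoods for the single-cell and bulk samples.

The read observations at a candidate site are summarised as
:class:`SitePileup`.  Reads carrying a base that is neither the reference
nor the alternative allele (class ``OTHER``) are excluded from all counts:
the model is strictly biallelic per site.

The per-read model is a biallelic base-quality model: a read drawn from a
template pool with alternative-allele fraction ``rho`` shows the
alternative base with probability ``rho (1 - e) + (1 - rho) e / 3`` where
``e`` is the base-call error probability and a miscall is uniform over the
three wrong bases.  Mapping quality and read-pair evidence are deliberately
not modelled.

For the single cell the sample likelihood given a true allele frequency
``theta_s`` marginalises over the MDA-distorted observable frequency
``rho_s = k'/l`` using the amplification-bias distributions from
:mod:`mdacall.bias`.  For the bulk, which is sequenced without an
amplification step, ``rho_b = theta_b`` and the sample likelihood is a
plain product of read likelihoods on the frequency grid ``m/n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .bias import sc_freq_log_pmf


def logsumexp(a) -> float:
    """Log of the summed exponentials of ``a`` (1-d), stable in log space.

    Minimal replacement for the scipy helper: the posterior loop calls this
    on many short vectors and the array-API dispatch overhead dominates
    there.
    """
    a = np.asarray(a, dtype=float)
    m = a.max() if a.size else -np.inf
    if not np.isfinite(m):
        return float(m)  # all -inf (or contains +inf, which we never produce)
    return float(m + np.log(np.exp(a - m).sum()))

__all__ = [
    "REF",
    "ALT",
    "OTHER",
    "MIN_BASE_QUALITY",
    "MAX_BASE_ERROR",
    "BULK_GRID_MAX",
    "ReadObservation",
    "SitePileup",
    "phred_to_error",
    "read_likelihood",
    "sc_sample_likelihood",
    "sc_theta_likelihood",
    "sc_log_theta_likelihoods",
    "bulk_theta_likelihood",
    "bulk_log_grid",
    "bulk_grid_counts",
    "bulk_range_likelihood",
]

REF = "REF"
ALT = "ALT"
OTHER = "OTHER"

#: PHRED base qualities below this are filtered out upstream; the error
#: probability of retained reads is additionally capped.
MIN_BASE_QUALITY = 3
MAX_BASE_ERROR = 0.75

#: Above this bulk coverage the theta_b grid is downsampled to this many
#: equally spaced frequencies (full grids make the range sums quadratic).
BULK_GRID_MAX = 1000


def phred_to_error(quality: float) -> float:
    """Convert a PHRED base quality to an error probability, capped."""
    return min(10.0 ** (-quality / 10.0), MAX_BASE_ERROR)


@dataclass(frozen=True)
class ReadObservation:
    """One read at one site: allele class plus base-call error probability."""

    allele_class: str
    base_error_prob: float

    def __post_init__(self):
        if self.allele_class not in (REF, ALT, OTHER):
            raise ValueError(f"unknown allele class {self.allele_class!r}")
        if not 0.0 < self.base_error_prob <= MAX_BASE_ERROR:
            raise ValueError(
                f"base error probability must be in (0, {MAX_BASE_ERROR}], "
                f"got {self.base_error_prob}"
            )

    @classmethod
    def from_phred(cls, allele_class: str, quality: float) -> "ReadObservation":
        return cls(allele_class, phred_to_error(quality))


@dataclass
class SitePileup:
    """All read observations at one candidate site, both samples."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    sc_reads: list = field(default_factory=list)
    bulk_reads: list = field(default_factory=list)

    @property
    def sc_informative(self) -> list:
        return [r for r in self.sc_reads if r.allele_class != OTHER]

    @property
    def bulk_informative(self) -> list:
        return [r for r in self.bulk_reads if r.allele_class != OTHER]

    @property
    def l(self) -> int:
        """Single-cell coverage (informative reads only)."""
        return len(self.sc_informative)

    @property
    def k(self) -> int:
        """Single-cell alternative read count."""
        return sum(1 for r in self.sc_reads if r.allele_class == ALT)

    @property
    def n(self) -> int:
        """Bulk coverage (informative reads only)."""
        return len(self.bulk_informative)

    @property
    def m_observed(self) -> int:
        """Bulk alternative read count."""
        return sum(1 for r in self.bulk_reads if r.allele_class == ALT)

    def relabelled(self) -> "SitePileup":
        """Swap REF and ALT everywhere (used for symmetry checks)."""

        def flip(reads):
            out = []
            for r in reads:
                cls = {REF: ALT, ALT: REF, OTHER: OTHER}[r.allele_class]
                out.append(ReadObservation(cls, r.base_error_prob))
            return out

        return SitePileup(
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.alt_allele,
            alt_allele=self.ref_allele,
            sc_reads=flip(self.sc_reads),
            bulk_reads=flip(self.bulk_reads),
        )


def read_likelihood(obs: ReadObservation, rho: float) -> float:
    """``P(Z | rho)`` for one read under the biallelic base-quality model."""
    if obs.allele_class == OTHER:
        raise ValueError("OTHER reads carry no biallelic information")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    e = obs.base_error_prob
    if obs.allele_class == ALT:
        return rho * (1.0 - e) + (1.0 - rho) * (e / 3.0)
    return (1.0 - rho) * (1.0 - e) + rho * (e / 3.0)


def _split_errors(reads: Iterable[ReadObservation]) -> tuple[np.ndarray, np.ndarray]:
    """Error probabilities of ALT and REF reads (OTHER dropped)."""
    e_alt = np.array([r.base_error_prob for r in reads if r.allele_class == ALT])
    e_ref = np.array([r.base_error_prob for r in reads if r.allele_class == REF])
    return e_alt, e_ref


def _grid_loglik(
    e_alt: np.ndarray, e_ref: np.ndarray, rho_alt: np.ndarray, rho_ref: np.ndarray
) -> np.ndarray:
    """Log product of read likelihoods at each grid frequency.

    ``rho_alt`` and ``rho_ref`` are the alternative and reference template
    fractions per grid point, each computed directly from integer counts so
    that relabelling REF<->ALT mirrors the computation term for term.
    """
    out = np.zeros_like(rho_alt, dtype=float)
    if e_alt.size:
        out += np.log(
            rho_alt[:, None] * (1.0 - e_alt) + rho_ref[:, None] * (e_alt / 3.0)
        ).sum(axis=1)
    if e_ref.size:
        out += np.log(
            rho_ref[:, None] * (1.0 - e_ref) + rho_alt[:, None] * (e_ref / 3.0)
        ).sum(axis=1)
    return out


def sc_sample_likelihood(sc_reads: Sequence[ReadObservation], rho: float) -> float:
    """``P(Z^s | rho_s = rho)``: product over informative single-cell reads."""
    logp = 0.0
    for r in sc_reads:
        if r.allele_class == OTHER:
            continue
        p = read_likelihood(r, rho)
        if p == 0.0:
            return 0.0
        logp += np.log(p)
    return float(np.exp(logp))


def _sc_grid_loglik(sc_reads: Sequence[ReadObservation]) -> np.ndarray:
    """Log ``P(Z^s | rho_s = k'/l)`` over the full grid ``k' = 0..l``."""
    informative = [r for r in sc_reads if r.allele_class != OTHER]
    l = len(informative)
    e_alt, e_ref = _split_errors(informative)
    ks = np.arange(l + 1)
    if l == 0:
        return np.zeros(1)
    rho_alt = ks / l
    rho_ref = (l - ks) / l
    return _grid_loglik(e_alt, e_ref, rho_alt, rho_ref)


def sc_log_theta_likelihoods(sc_reads: Sequence[ReadObservation]) -> dict:
    """Log ``P(Z^s | theta_s)`` for all three true allele frequencies.

    Marginalises the read-product likelihood over the distorted observable
    frequency grid: ``sum_k P(Z^s | rho_s = k/l) P(rho_s = k/l | theta_s)``.
    The read products over the grid are shared between the three theta
    values, so the whole computation is a single O(l^2) pass.
    """
    grid = _sc_grid_loglik(sc_reads)
    l = grid.size - 1
    return {
        theta: float(logsumexp(grid + sc_freq_log_pmf(l, theta)))
        for theta in (Fraction(0), Fraction(1, 2), Fraction(1))
    }


def sc_theta_likelihood(sc_reads: Sequence[ReadObservation], theta_s) -> float:
    """``P(Z^s | theta_s)`` on the linear scale."""
    return float(np.exp(sc_log_theta_likelihoods(sc_reads)[Fraction(theta_s)]))


def bulk_theta_likelihood(
    bulk_reads: Sequence[ReadObservation], m: int, n: int
) -> float:
    """``P(Z^b | theta_b = m/n)``: product over informative bulk reads."""
    informative = [r for r in bulk_reads if r.allele_class != OTHER]
    if n != len(informative):
        raise ValueError("n must equal the number of informative bulk reads")
    if not 0 <= m <= n:
        raise ValueError("require 0 <= m <= n")
    if n == 0:
        return 1.0
    return sc_sample_likelihood(informative, m / n)


def bulk_grid_counts(n: int) -> np.ndarray:
    """The integer grid of bulk alternative counts used for ``theta_b``.

    The full grid ``0..n`` up to :data:`BULK_GRID_MAX`; above that,
    ``BULK_GRID_MAX + 1`` (approximately) equally spaced counts including
    both endpoints.
    """
    if n <= BULK_GRID_MAX:
        return np.arange(n + 1)
    return np.unique(np.round(np.linspace(0, n, BULK_GRID_MAX + 1)).astype(int))


def bulk_log_grid(bulk_reads: Sequence[ReadObservation], ms: np.ndarray) -> np.ndarray:
    """Log ``P(Z^b | theta_b = m/n)`` for each grid count ``m`` in ``ms``."""
    informative = [r for r in bulk_reads if r.allele_class != OTHER]
    n = len(informative)
    e_alt, e_ref = _split_errors(informative)
    if n == 0:
        return np.zeros(len(ms))
    rho_alt = ms / n
    rho_ref = (n - ms) / n
    return _grid_loglik(e_alt, e_ref, rho_alt, rho_ref)


def bulk_range_likelihood(
    bulk_reads: Sequence[ReadObservation], interval
) -> float:
    """``sum_m P(Z^b | theta_b = m/n)`` over grid points inside ``interval``.

    ``interval`` is a :class:`mdacall.events.ThetaInterval`; membership of a
    grid point ``m/n`` is decided exactly on rationals.  An empty grid
    intersection yields 0.
    """
    informative = [r for r in bulk_reads if r.allele_class != OTHER]
    n = len(informative)
    if n == 0:
        # no bulk frequency grid exists; the bulk factor is uninformative
        return 1.0
    ms = bulk_grid_counts(n)
    inside = np.array([interval.contains(int(m), n) for m in ms])
    if not inside.any():
        return 0.0
    return float(np.exp(logsumexp(bulk_log_grid(informative, ms[inside]))))
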