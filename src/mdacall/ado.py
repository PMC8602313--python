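"""Per-cell allele-dropout (ADO) rate estimators over truth-het sites.

Allele dropout -- one allele of a heterozygous site receiving no reads
after amplification -- can only be identified unambiguously at sites known
to be heterozygous.  Given such a ground-truth site list, three estimators
are provided, all restricted to truth-het sites with single-cell coverage
of at least one read:

* ``expected``: the mean over sites of the posterior dropout probability
  ``P(ADO_TO_REF) + P(ADO_TO_ALT)`` -- the model's expected dropout rate;
* ``mismatch``: the fraction of sites whose maximum-posterior genotype is
  homozygous, i.e. dropouts manifest as wrong genotype calls;
* ``naive``: the fraction of sites with coverage of at least seven where
  one of the two alleles has no read at all -- a model-free count that
  undercounts at low coverage, where missing an allele by chance is likely
  even without amplification bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .events import ADO_EVENTS, EventPosteriors, GenotypeCall, compound_posterior
from .likelihoods import SitePileup

__all__ = [
    "NAIVE_MIN_COVERAGE",
    "AdoReport",
    "expected_ado_rate",
    "mismatch_ado_rate",
    "naive_ado_rate",
    "ado_report",
]

#: Minimum coverage for the naive estimator: with at least seven reads and
#: no amplification bias, sampling both alleles of a het site is near
#: certain, so a fully missing allele indicates dropout.
NAIVE_MIN_COVERAGE = 7


@dataclass(frozen=True)
class AdoReport:
    """The three ADO rates of one cell over covered truth-het sites."""

    expected_rate: Optional[float]
    mismatch_rate: Optional[float]
    naive_rate: Optional[float]
    n_sites_covered: int


def expected_ado_rate(posteriors: Sequence[EventPosteriors]) -> Optional[float]:
    """Mean posterior dropout probability across covered truth-het sites."""
    if not posteriors:
        return None
    total = sum(compound_posterior(ep, ADO_EVENTS) for ep in posteriors)
    return total / len(posteriors)


def mismatch_ado_rate(calls: Sequence[GenotypeCall]) -> Optional[float]:
    """Fraction of covered truth-het sites called homozygous."""
    if not calls:
        return None
    hom = sum(1 for c in calls if c.genotype in ("hom_ref", "hom_alt"))
    return hom / len(calls)


def naive_ado_rate(pileups: Sequence[SitePileup]) -> Optional[float]:
    """Fraction of covered truth-het sites with l >= 7 and a missing allele.

    The denominator is all truth-het sites with single-cell coverage of at
    least one read, matching the other two estimators.
    """
    covered = [p for p in pileups if p.l >= 1]
    if not covered:
        return None
    dropped = sum(
        1
        for p in covered
        if p.l >= NAIVE_MIN_COVERAGE and (p.k == 0 or p.k == p.l)
    )
    return dropped / len(covered)


def ado_report(
    pileups: Sequence[SitePileup],
    posteriors: Sequence[EventPosteriors],
    calls: Sequence[GenotypeCall],
) -> AdoReport:
    """All three estimators for one cell.

    ``pileups``, ``posteriors`` and ``calls`` must refer to the same
    covered (l >= 1) truth-het sites, in any order.
    """
    if not len(pileups) == len(posteriors) == len(calls):
        raise ValueError("pileups, posteriors and calls must be parallel lists")
    if any(p.l < 1 for p in pileups):
        raise ValueError("ADO estimators are defined over sites with coverage >= 1")
    return AdoReport(
        expected_rate=expected_ado_rate(posteriors),
        mismatch_rate=mismatch_ado_rate(calls),
        naive_rate=naive_ado_rate(pileups),
        n_sites_covered=len(pileups),
    )
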