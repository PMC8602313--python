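"""The seven-event partition of the joint allele-frequency space.

A site in a single cell evaluated jointly with a bulk sample is described
by the pair ``(theta_s, theta_b)``: the true alternative-allele frequency
in the cell (one of ``{0, 1/2, 1}``) and in the bulk population (a grid
frequency ``m/n``).  The joint space ``{0, 1/2, 1} x [0, 1]`` is cut into
seven mutually exclusive single-cell events.  The cuts encode the
assumption that the bulk population consists of at most two genotype
subpopulations one mutated allele apart, and that where the single cell and
the bulk disagree the bulk -- being unamplified and a much larger sample --
is to be trusted.  For example ``theta_s = 0`` with ``theta_b in [1/2, 1)``
is impossible for a genuinely homozygous-reference cell (such a bulk
contains no hom-ref cells) and is therefore classified as the dropout of
the cell's alternative allele (``ADO_TO_REF``).

Event posteriors follow from a flat prior over the ``(theta_s, m/n)``
cells: each event likelihood is the product of the single-cell likelihood
summed over its ``theta_s`` members and the bulk likelihood summed over the
grid points in its ``theta_b`` interval, normalised over the seven events.

Genotype calls are maximum-posterior compound events: the two ADO events
imply a truly heterozygous cell (one allele dropped during amplification),
the two amplification-error events imply the homozygous genotype the bulk
supports.

At sites with zero single-cell coverage the single-cell factor of every
event is 1 (an empty read set is equally likely under every genotype), so
with imputation enabled the posterior reflects the bulk alone and imputes
the majority genotype of the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .likelihoods import (
    SitePileup,
    bulk_grid_counts,
    bulk_log_grid,
    logsumexp,
    sc_log_theta_likelihoods,
)

__all__ = [
    "EVENT_NAMES",
    "ALT_PRESENCE_EVENTS",
    "ADO_EVENTS",
    "GENOTYPE_EVENTS",
    "GENOTYPE_ORDER",
    "ThetaInterval",
    "EventRegion",
    "EventPosteriors",
    "GenotypeCall",
    "UncallableSiteError",
    "event_regions",
    "event_likelihood",
    "site_posteriors",
    "compound_posterior",
    "genotype_call",
]

EVENT_NAMES = (
    "HOM_REF",
    "ERR_ALT",
    "ADO_TO_ALT",
    "HET",
    "ADO_TO_REF",
    "ERR_REF",
    "HOM_ALT",
)

#: Events implying that the cell carries at least one alternative allele.
ALT_PRESENCE_EVENTS = frozenset(
    {"ADO_TO_REF", "ERR_REF", "HET", "ADO_TO_ALT", "HOM_ALT"}
)

#: The two allele-dropout events.
ADO_EVENTS = frozenset({"ADO_TO_REF", "ADO_TO_ALT"})

#: Events implying each diploid genotype in the cell.
GENOTYPE_EVENTS: dict[str, frozenset] = {
    "hom_ref": frozenset({"HOM_REF", "ERR_ALT"}),
    "het": frozenset({"HET", "ADO_TO_REF", "ADO_TO_ALT"}),
    "hom_alt": frozenset({"HOM_ALT", "ERR_REF"}),
}

#: Fixed tie-break order for maximum-posterior genotype calls.
GENOTYPE_ORDER = ("hom_ref", "het", "hom_alt")


class UncallableSiteError(ValueError):
    """Raised when a site cannot be evaluated (e.g. zero bulk coverage)."""


@dataclass(frozen=True)
class ThetaInterval:
    """A sub-interval of [0, 1] with explicit open/closed endpoints."""

    lo: Fraction
    hi: Fraction
    lo_closed: bool
    hi_closed: bool

    def contains(self, m: int, n: int) -> bool:
        """Exact membership of the grid frequency ``m/n``."""
        f = Fraction(m, n)
        above = f >= self.lo if self.lo_closed else f > self.lo
        below = f <= self.hi if self.hi_closed else f < self.hi
        return above and below

    def __str__(self) -> str:
        return (
            ("[" if self.lo_closed else "(")
            + f"{self.lo}, {self.hi}"
            + ("]" if self.hi_closed else ")")
        )


@dataclass(frozen=True)
class EventRegion:
    """One single-cell event: a theta_s subset times a theta_b interval."""

    name: str
    theta_s_set: frozenset
    theta_b_interval: ThetaInterval


_HALF = Fraction(1, 2)
_REGIONS = (
    EventRegion("HOM_REF", frozenset({Fraction(0)}), ThetaInterval(Fraction(0), _HALF, True, False)),
    EventRegion("ERR_ALT", frozenset({_HALF, Fraction(1)}), ThetaInterval(Fraction(0), Fraction(0), True, True)),
    EventRegion("ADO_TO_ALT", frozenset({Fraction(1)}), ThetaInterval(Fraction(0), _HALF, False, True)),
    EventRegion("HET", frozenset({_HALF}), ThetaInterval(Fraction(0), Fraction(1), False, False)),
    EventRegion("ADO_TO_REF", frozenset({Fraction(0)}), ThetaInterval(_HALF, Fraction(1), True, False)),
    EventRegion("ERR_REF", frozenset({Fraction(0), _HALF}), ThetaInterval(Fraction(1), Fraction(1), True, True)),
    EventRegion("HOM_ALT", frozenset({Fraction(1)}), ThetaInterval(_HALF, Fraction(1), False, True)),
)


@lru_cache(maxsize=4096)
def _region_grid_masks(n: int) -> tuple[np.ndarray, ...]:
    """Per-region boolean masks over the theta_b grid for bulk coverage n."""
    ms = bulk_grid_counts(n)
    return tuple(
        np.array([r.theta_b_interval.contains(int(m), n) for m in ms])
        for r in _REGIONS
    )


def event_regions() -> tuple[EventRegion, ...]:
    """The seven mutually exclusive single-cell events.

    For each fixed ``theta_s`` the theta_b intervals of the events
    containing it partition [0, 1], so the union of the regions is exactly
    ``{0, 1/2, 1} x [0, 1]``.
    """
    return _REGIONS


@dataclass
class EventPosteriors:
    """Normalised posterior over the seven events at one site."""

    site: SitePileup
    probs: Mapping[str, float]
    imputed: bool = False

    def __getitem__(self, name: str) -> float:
        return self.probs[name]


@dataclass(frozen=True)
class GenotypeCall:
    """Maximum-posterior genotype compound at one site."""

    genotype: str
    posterior: float
    alt_presence_posterior: float


def _event_log_likelihoods(
    pileup: SitePileup, impute: bool = False, allow_empty_bulk: bool = False
) -> dict[str, float]:
    l = pileup.l
    n = pileup.n
    if n == 0 and not allow_empty_bulk:
        raise UncallableSiteError(
            f"{pileup.chrom}:{pileup.pos}: no informative bulk reads"
        )
    if l == 0 and not impute:
        raise UncallableSiteError(
            f"{pileup.chrom}:{pileup.pos}: no informative single-cell reads "
            "(enable imputation to call from the bulk alone)"
        )
    # With l = 0 this yields log 1 for every theta_s: the imputation rule
    # P(Z^s | theta_s) = 1 is the natural empty-product value.
    sc_logs = sc_log_theta_likelihoods(pileup.sc_reads)

    if n == 0:
        bulk_region_logs = {r.name: 0.0 for r in _REGIONS}
    else:
        ms = bulk_grid_counts(n)
        grid_logs = bulk_log_grid(pileup.bulk_reads, ms)
        bulk_region_logs = {}
        for region, inside in zip(_REGIONS, _region_grid_masks(n)):
            bulk_region_logs[region.name] = (
                float(logsumexp(grid_logs[inside])) if inside.any() else -np.inf
            )

    out = {}
    for region in _REGIONS:
        sc_part = logsumexp([sc_logs[t] for t in sorted(region.theta_s_set)])
        out[region.name] = float(sc_part + bulk_region_logs[region.name])
    return out


def event_likelihood(
    pileup: SitePileup, region: EventRegion, impute: bool = False
) -> float:
    """Joint likelihood ``P(Z^s, Z^b | E)`` of one event (linear scale)."""
    logs = _event_log_likelihoods(pileup, impute=impute, allow_empty_bulk=True)
    return float(np.exp(logs[region.name]))


def site_posteriors(
    pileup: SitePileup, impute: bool = False, allow_empty_bulk: bool = False
) -> EventPosteriors:
    """Posterior over the seven events, normalised with log-sum-exp."""
    logs = _event_log_likelihoods(
        pileup, impute=impute, allow_empty_bulk=allow_empty_bulk
    )
    vec = np.array([logs[name] for name in EVENT_NAMES])
    marginal = logsumexp(vec)
    if not np.isfinite(marginal):
        raise UncallableSiteError(
            f"{pileup.chrom}:{pileup.pos}: zero marginal likelihood"
        )
    probs = np.exp(vec - marginal)
    return EventPosteriors(
        site=pileup,
        probs=dict(zip(EVENT_NAMES, probs.tolist())),
        imputed=(pileup.l == 0 and impute),
    )


def compound_posterior(ep: EventPosteriors, names) -> float:
    """Posterior of a compound event: sum of its member event posteriors."""
    unknown = set(names) - set(EVENT_NAMES)
    if unknown:
        raise ValueError(f"unknown event names: {sorted(unknown)}")
    return float(sum(ep.probs[name] for name in set(names)))


def genotype_call(ep: EventPosteriors) -> GenotypeCall:
    """Maximum-posterior genotype over the three genotype compounds."""
    best_name, best_p = None, -1.0
    for name in GENOTYPE_ORDER:
        p = compound_posterior(ep, GENOTYPE_EVENTS[name])
        if p > best_p:  # strict: earlier genotypes win ties
            best_name, best_p = name, p
    return GenotypeCall(
        genotype=best_name,
        posterior=best_p,
        alt_presence_posterior=compound_posterior(ep, ALT_PRESENCE_EVENTS),
    )
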