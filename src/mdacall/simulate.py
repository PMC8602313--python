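"""Generative simulator of MDA single-cell pileups with a matched bulk.

Each site gets a true diploid genotype for the cell; germline-style sites
give the bulk the same genotype, so the true bulk frequency ``theta_b`` is
0, 1/2 or 1.  Optionally a fraction of sites is designated subclonal: there
the bulk is a mixture in which a fraction of cells carries a somatic
heterozygous genotype (``theta_b = subclone_fraction / 2``) and the single
cell itself is heterozygous with that probability.

Single-cell alternative read counts are drawn directly from the
coverage-dependent amplification-bias distributions
``P(rho_s = k/l | theta_s)`` -- the compounded amplification + sequencing
error model that the caller itself uses -- so calibration tests against the
model are sharp.  A separate Polya-urn routine is provided for mechanism
tests of the beta-binomial: sequential draws with reinforcement, the urn
analogue of strand copying during amplification.

The bulk has no amplification step: the true alternative read count is
binomial at ``theta_b``, and each read is then miscalled with probability
``e`` (uniform over the three wrong bases, so 1/3 of miscalls land on the
other modelled allele and 2/3 become non-modelled ``OTHER`` bases).

All randomness flows from ``SimConfig.seed``; the same seed reproduces the
dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

from .bias import sc_freq_log_pmf
from .likelihoods import ALT, OTHER, REF, ReadObservation, SitePileup, phred_to_error

__all__ = ["SimConfig", "SimulatedDataset", "simulate_dataset", "polya_urn_counts"]

_GENOTYPES = ("hom_ref", "het", "hom_alt")
_THETA_S = {"hom_ref": Fraction(0), "het": Fraction(1, 2), "hom_alt": Fraction(1)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated dataset.

    Defaults describe a germline-style experiment: 10% of sites carry an
    alternative allele (het twice as common as hom-alt, as for typical
    germline variants), single-cell coverage 10, bulk coverage 30, and
    Q30 base calls.
    """

    n_sites: int = 10_000
    genotype_proportions: tuple[float, float, float] = (0.9, 2 / 30, 1 / 30)
    sc_coverage: float = 10
    bulk_coverage: float = 30
    coverage_model: str = "fixed"  # "fixed" or "poisson"
    base_quality: float = 30.0
    subclone_fraction: Optional[float] = None
    subclone_site_fraction: float = 0.0
    chrom: str = "sim1"
    seed: int = 0

    def __post_init__(self):
        props = self.genotype_proportions
        if len(props) != 3 or any(p < 0 for p in props) or abs(sum(props) - 1) > 1e-9:
            raise ValueError("genotype_proportions must be a 3-point simplex")
        if self.sc_coverage < 0 or self.bulk_coverage < 0:
            raise ValueError("coverages must be non-negative")
        if self.coverage_model not in ("fixed", "poisson"):
            raise ValueError("coverage_model must be 'fixed' or 'poisson'")
        if self.subclone_fraction is not None and not 0 <= self.subclone_fraction <= 1:
            raise ValueError("subclone_fraction must lie in [0, 1]")
        if not 0 <= self.subclone_site_fraction <= 1:
            raise ValueError("subclone_site_fraction must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """Simulated pileups plus the per-site truth table.

    ``truth`` columns: chrom, pos, genotype (the cell's true genotype),
    theta_b (true bulk alternative-allele frequency), l, k (realised
    amplified single-cell counts), n, m (realised informative bulk counts
    after miscalls; reads miscalled onto non-modelled bases are present in
    the pileup but excluded from n, matching the model's coverage), dropout
    (genotype het and k in {0, l}, l >= 1).
    """

    config: SimConfig
    pileups: list
    truth: pd.DataFrame


def polya_urn_counts(rng: np.random.Generator, l: int, a: float, b: float) -> int:
    """Number of "alt" draws in ``l`` sequential Polya-urn draws.

    The urn starts with weights ``a`` (alt) and ``b`` (ref); every draw
    reinforces its own colour by one, mimicking a polymerase copying a
    strand.  The count of alt draws is exactly beta-binomially distributed
    with shapes ``(a, b)``.
    """
    k = 0
    for i in range(l):
        if rng.random() < (a + k) / (a + b + i):
            k += 1
    return k


def _draw_coverage(rng: np.random.Generator, mean: float, model: str, size: int):
    if model == "fixed":
        return np.full(size, int(round(mean)), dtype=int)
    return rng.poisson(mean, size=size)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate pileups and truth for ``config.n_sites`` candidate sites."""
    rng = np.random.default_rng(config.seed)
    e = phred_to_error(config.base_quality)
    n_sites = config.n_sites

    genotypes = rng.choice(
        len(_GENOTYPES), size=n_sites, p=list(config.genotype_proportions)
    )
    subclonal = np.zeros(n_sites, dtype=bool)
    if config.subclone_fraction is not None and config.subclone_site_fraction > 0:
        subclonal = rng.random(n_sites) < config.subclone_site_fraction
        # at subclonal sites the cell is het iff it belongs to the subclone
        genotypes[subclonal] = np.where(
            rng.random(subclonal.sum()) < config.subclone_fraction, 1, 0
        )

    ls = _draw_coverage(rng, config.sc_coverage, config.coverage_model, n_sites)
    ns = _draw_coverage(rng, config.bulk_coverage, config.coverage_model, n_sites)

    # cache of the distortion pmf per (l, theta_s)
    pmf_cache: dict = {}

    pileups = []
    rows = []
    for i in range(n_sites):
        gt = _GENOTYPES[genotypes[i]]
        theta_s = _THETA_S[gt]
        if subclonal[i]:
            theta_b = config.subclone_fraction * 0.5
        else:
            theta_b = float(theta_s)
        l, n = int(ls[i]), int(ns[i])

        # single cell: amplified count drawn from the full distortion model
        if l > 0:
            key = (l, theta_s)
            if key not in pmf_cache:
                pmf = np.exp(sc_freq_log_pmf(l, theta_s))
                pmf_cache[key] = pmf / pmf.sum()
            k = int(rng.choice(l + 1, p=pmf_cache[key]))
        else:
            k = 0
        sc_reads = [ReadObservation(ALT, e) for _ in range(k)] + [
            ReadObservation(REF, e) for _ in range(l - k)
        ]

        # bulk: binomial sampling of the population, then per-read miscalls
        true_alt = int(rng.binomial(n, theta_b)) if n > 0 else 0
        bulk_reads = []
        m = 0
        n_informative = 0
        for j in range(n):
            cls = ALT if j < true_alt else REF
            if rng.random() < e:
                # miscall: uniform over the 3 wrong bases; one of them is
                # the other modelled allele, the other two are OTHER
                u = rng.random()
                if u < 1 / 3:
                    cls = REF if cls == ALT else ALT
                else:
                    cls = OTHER
            if cls == ALT:
                m += 1
            if cls != OTHER:
                n_informative += 1
            bulk_reads.append(ReadObservation(cls, e))

        pos = i + 1
        pileups.append(
            SitePileup(
                chrom=config.chrom,
                pos=pos,
                ref_allele="A",
                alt_allele="C",
                sc_reads=sc_reads,
                bulk_reads=bulk_reads,
            )
        )
        rows.append(
            {
                "chrom": config.chrom,
                "pos": pos,
                "genotype": gt,
                "theta_b": theta_b,
                "l": l,
                "k": k,
                "n": n_informative,
                "m": m,
                "dropout": bool(gt == "het" and l >= 1 and k in (0, l)),
            }
        )

    return SimulatedDataset(
        config=config, pileups=pileups, truth=pd.DataFrame(rows)
    )
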