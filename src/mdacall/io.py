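"""Input/output: alignment pileup extraction, candidate sites, pileup TSVs,
and VCF emission with PHRED-scaled event probabilities.

Coordinates are 1-based in every interface and converted to pysam's 0-based
half-open convention internally.  Candidate sites can come from a VCF (one
biallelic record per SNV; multiallelic records are split) or from a
BED-like TSV with columns ``chrom  pos  ref  alt``.

The pileup TSV is a fully self-contained per-site table so that the model
can be run without any alignment files: columns ``chrom  pos  ref  alt
sc_classes  sc_quals  bulk_classes  bulk_quals`` where the classes are a
string over ``R`` (reference), ``A`` (alternative) and ``O`` (other) and
the qualities are comma-separated PHRED values (``.`` for no reads).

Call output is VCF 4.2 with the posterior of each of the seven single-cell
events as a PHRED-scaled (``-10 log10 p``, capped) INFO field, plus the
alternative-allele-presence compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

from .events import (
    ALT_PRESENCE_EVENTS,
    EVENT_NAMES,
    EventPosteriors,
    GenotypeCall,
    UncallableSiteError,
    compound_posterior,
    genotype_call,
    site_posteriors,
)
from .likelihoods import (
    ALT,
    MIN_BASE_QUALITY,
    OTHER,
    REF,
    ReadObservation,
    SitePileup,
)

__all__ = [
    "PHRED_CAP",
    "CandidateSite",
    "CallRecord",
    "prob_to_phred",
    "phred_to_prob",
    "read_candidate_sites",
    "extract_pileup",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "call_pileups",
    "write_calls",
    "read_calls",
]

#: Cap on PHRED-scaled probabilities in the output (p >= 1e-1000).
PHRED_CAP = 10000.0

_CLASS_CODE = {REF: "R", ALT: "A", OTHER: "O"}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}
_GT_FIELD = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}


@dataclass(frozen=True)
class CandidateSite:
    """One biallelic SNV candidate."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-nucleotide alleles are supported")
        if self.ref_allele == self.alt_allele:
            raise ValueError("alternative allele must differ from the reference")


@dataclass
class CallRecord:
    """One called site: posteriors, genotype and depths."""

    site: CandidateSite
    posteriors: EventPosteriors
    genotype: GenotypeCall
    l: int
    k: int
    n: int
    m_observed: int


def prob_to_phred(p: float, cap: float = PHRED_CAP) -> float:
    """PHRED-scale a probability: ``-10 log10 p``, capped."""
    if p <= 0.0:
        return cap
    return min(-10.0 * math.log10(p), cap)


def phred_to_prob(q: float) -> float:
    """Invert :func:`prob_to_phred` (below the cap)."""
    return 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# candidate sites


def read_candidate_sites(path: str) -> list[CandidateSite]:
    """Read candidate SNVs from a VCF/BCF or a ``chrom pos ref alt`` TSV."""
    if str(path).endswith((".vcf", ".vcf.gz", ".bcf")):
        sites = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    if len(rec.ref) == 1 and len(alt) == 1 and alt != rec.ref:
                        sites.append(
                            CandidateSite(rec.chrom, rec.pos, rec.ref, alt)
                        )
        return sites
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            if chrom == "chrom":  # optional header line
                continue
            sites.append(CandidateSite(chrom, int(pos), ref, alt))
    return sites


# ---------------------------------------------------------------------------
# alignment pileup extraction


def _reads_at_site(
    af: pysam.AlignmentFile,
    site: CandidateSite,
    min_mapq: int,
    min_baseq: int,
) -> list[ReadObservation]:
    obs = []
    pos0 = site.pos - 1
    for read in af.fetch(site.chrom, pos0, pos0 + 1):
        if (
            read.is_unmapped
            or read.is_duplicate
            or read.is_secondary
            or read.is_supplementary
            or read.is_qcfail
        ):
            continue
        if read.mapping_quality < min_mapq:
            continue
        qpos = None
        for q, r in read.get_aligned_pairs(matches_only=False):
            if r == pos0:
                qpos = q
                break
        else:
            continue
        if qpos is None:
            # deletion or reference skip spanning the site
            obs.append(ReadObservation(OTHER, 0.5))
            continue
        base = read.query_sequence[qpos].upper()
        qual = read.query_qualities[qpos]
        if qual < min_baseq:
            continue
        if base == site.ref_allele.upper():
            cls = REF
        elif base == site.alt_allele.upper():
            cls = ALT
        else:
            cls = OTHER
        obs.append(ReadObservation.from_phred(cls, qual))
    return obs


def extract_pileup(
    sc_alignment: pysam.AlignmentFile,
    bulk_alignment: pysam.AlignmentFile,
    site: CandidateSite,
    min_mapq: int = 0,
    min_baseq: int = MIN_BASE_QUALITY,
) -> SitePileup:
    """Build the per-site pileup for both samples from indexed alignments.

    Duplicate, secondary, supplementary, QC-fail and unmapped reads are
    excluded; bases below ``min_baseq`` are dropped; reads with a deletion
    or reference skip at the site are classified ``OTHER``.
    """
    for af in (sc_alignment, bulk_alignment):
        if site.chrom not in af.references:
            raise IOError(
                f"contig {site.chrom!r} (site {site.chrom}:{site.pos}) "
                f"not present in alignment {af.filename!r}"
            )
    return SitePileup(
        chrom=site.chrom,
        pos=site.pos,
        ref_allele=site.ref_allele,
        alt_allele=site.alt_allele,
        sc_reads=_reads_at_site(sc_alignment, site, min_mapq, min_baseq),
        bulk_reads=_reads_at_site(bulk_alignment, site, min_mapq, min_baseq),
    )


# ---------------------------------------------------------------------------
# pileup TSV

_PILEUP_HEADER = "chrom\tpos\tref\talt\tsc_classes\tsc_quals\tbulk_classes\tbulk_quals"


def _encode_reads(reads: Sequence[ReadObservation]) -> tuple[str, str]:
    if not reads:
        return ".", "."
    classes = "".join(_CLASS_CODE[r.allele_class] for r in reads)
    quals = ",".join(
        f"{-10.0 * math.log10(r.base_error_prob):g}" for r in reads
    )
    return classes, quals


def _decode_reads(classes: str, quals: str) -> list[ReadObservation]:
    if classes == ".":
        return []
    qs = [float(q) for q in quals.split(",")]
    if len(qs) != len(classes):
        raise ValueError("class string and quality list lengths differ")
    return [
        ReadObservation.from_phred(_CODE_CLASS[c], q) for c, q in zip(classes, qs)
    ]


def write_pileup_tsv(pileups: Iterable[SitePileup], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_PILEUP_HEADER + "\n")
        for p in pileups:
            sc_c, sc_q = _encode_reads(p.sc_reads)
            b_c, b_q = _encode_reads(p.bulk_reads)
            fh.write(
                f"{p.chrom}\t{p.pos}\t{p.ref_allele}\t{p.alt_allele}\t"
                f"{sc_c}\t{sc_q}\t{b_c}\t{b_q}\n"
            )


def read_pileup_tsv(path: str) -> list[SitePileup]:
    pileups = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _PILEUP_HEADER.strip():
            raise ValueError(f"{path}: not a pileup TSV (unexpected header)")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, pos, ref, alt, sc_c, sc_q, b_c, b_q = line.split("\t")
            pileups.append(
                SitePileup(
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    sc_reads=_decode_reads(sc_c, sc_q),
                    bulk_reads=_decode_reads(b_c, b_q),
                )
            )
    return pileups


# ---------------------------------------------------------------------------
# calling and VCF emission


def call_pileups(
    pileups: Iterable[SitePileup],
    impute: bool = False,
    min_sc_cov: int = 1,
    min_bulk_cov: int = 1,
) -> list[CallRecord]:
    """Call every pileup that meets the coverage requirements.

    Sites below the bulk minimum, or below the single-cell minimum without
    imputation, are skipped (the model needs a bulk and, unless imputing,
    single-cell reads).  Calling is independent per site.
    """
    records = []
    for p in pileups:
        if p.n < max(min_bulk_cov, 1):
            continue
        if p.l < min_sc_cov and not impute:
            continue
        try:
            ep = site_posteriors(p, impute=impute)
        except UncallableSiteError:
            continue
        records.append(
            CallRecord(
                site=CandidateSite(p.chrom, p.pos, p.ref_allele, p.alt_allele),
                posteriors=ep,
                genotype=genotype_call(ep),
                l=p.l,
                k=p.k,
                n=p.n,
                m_observed=p.m_observed,
            )
        )
    return records


def _vcf_header(records: Sequence[CallRecord], contig_lengths=None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.site.chrom] = max(seen.get(rec.site.chrom, 0), rec.site.pos)
    if contig_lengths:
        seen.update(contig_lengths)
    for chrom, length in seen.items():
        header.contigs.add(chrom, length=length + 1)
    for name in EVENT_NAMES:
        header.info.add(
            f"PROB_{name}",
            1,
            "Float",
            f"PHRED-scaled posterior probability of the {name} single-cell event",
        )
    header.info.add(
        "PROB_ALT_PRESENCE",
        1,
        "Float",
        "PHRED-scaled posterior probability that the cell carries the "
        "alternative allele",
    )
    header.formats.add("GT", 1, "String", "Maximum-posterior genotype")
    header.formats.add("DP", 1, "Integer", "Informative read depth")
    header.formats.add("AD", "R", "Integer", "Informative read depth per allele")
    header.add_sample("SINGLE_CELL")
    header.add_sample("BULK")
    return header


def write_calls(
    records: Sequence[CallRecord], path: str, contig_lengths=None
) -> None:
    """Write call records, sorted by (contig, position), as VCF 4.2."""
    order: dict[str, int] = {}
    for rec in records:
        order.setdefault(rec.site.chrom, len(order))
    last = None
    for rec in records:
        key = (order[rec.site.chrom], rec.site.pos)
        if last is not None and key < last:
            raise ValueError("call records must be sorted by contig and position")
        last = key

    header = _vcf_header(records, contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in records:
            out = vf.new_record(
                contig=rec.site.chrom,
                start=rec.site.pos - 1,
                stop=rec.site.pos,
                alleles=(rec.site.ref_allele, rec.site.alt_allele),
            )
            for name in EVENT_NAMES:
                out.info[f"PROB_{name}"] = prob_to_phred(rec.posteriors[name])
            out.info["PROB_ALT_PRESENCE"] = prob_to_phred(
                compound_posterior(rec.posteriors, ALT_PRESENCE_EVENTS)
            )
            gt = _GT_FIELD[rec.genotype.genotype]
            out.samples["SINGLE_CELL"]["GT"] = gt
            out.samples["SINGLE_CELL"]["DP"] = rec.l
            out.samples["SINGLE_CELL"]["AD"] = (rec.l - rec.k, rec.k)
            out.samples["BULK"]["GT"] = (None, None)
            out.samples["BULK"]["DP"] = rec.n
            out.samples["BULK"]["AD"] = (rec.n - rec.m_observed, rec.m_observed)
            vf.write(out)


def read_calls(path: str) -> list[dict]:
    """Read a call VCF back as per-site dictionaries of linear posteriors."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            probs = {
                name: phred_to_prob(float(rec.info[f"PROB_{name}"]))
                for name in EVENT_NAMES
            }
            out.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "probs": probs,
                    "alt_presence": phred_to_prob(
                        float(rec.info["PROB_ALT_PRESENCE"])
                    ),
                    "gt": rec.samples["SINGLE_CELL"]["GT"],
                    "dp_sc": rec.samples["SINGLE_CELL"]["DP"],
                    "ad_sc": tuple(rec.samples["SINGLE_CELL"]["AD"]),
                    "dp_bulk": rec.samples["BULK"]["DP"],
                }
            )
    return out
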