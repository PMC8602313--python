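import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from mdacall.likelihoods import ALT, OTHER, REF, ReadObservation, SitePileup


def make_reads(n_ref=0, n_alt=0, n_other=0, quality=30.0):
    """Homogeneous-quality read list: REF then ALT then OTHER."""
    return (
        [ReadObservation.from_phred(REF, quality) for _ in range(n_ref)]
        + [ReadObservation.from_phred(ALT, quality) for _ in range(n_alt)]
        + [ReadObservation.from_phred(OTHER, quality) for _ in range(n_other)]
    )


def make_pileup(sc_ref=0, sc_alt=0, bulk_ref=0, bulk_alt=0, quality=30.0, pos=1):
    return SitePileup(
        chrom="chr1",
        pos=pos,
        ref_allele="A",
        alt_allele="C",
        sc_reads=make_reads(sc_ref, sc_alt, quality=quality),
        bulk_reads=make_reads(bulk_ref, bulk_alt, quality=quality),
    )


def random_pileup(rng: np.random.Generator, max_l=12, max_n=30, pos=1):
    """A random mixed-quality pileup with at least one informative read in
    each sample (all-OTHER samples are uncallable and tested separately)."""
    qualities = np.array([10.0, 20.0, 30.0, 37.0])
    l = int(rng.integers(1, max_l + 1))
    n = int(rng.integers(1, max_n + 1))

    def reads(count):
        out = []
        for _ in range(count):
            cls = [REF, ALT, OTHER][rng.integers(0, 3)]
            out.append(ReadObservation.from_phred(cls, rng.choice(qualities)))
        return out

    return SitePileup(
        chrom="chr1",
        pos=pos,
        ref_allele="A",
        alt_allele="C",
        sc_reads=reads(l) + [ReadObservation.from_phred(REF, 30.0)],
        bulk_reads=reads(n) + [ReadObservation.from_phred(REF, 30.0)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
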