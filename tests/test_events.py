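"""The seven-event partition, posteriors, genotyping and imputation."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdacall.events import (
    ADO_EVENTS,
    ALT_PRESENCE_EVENTS,
    EVENT_NAMES,
    GENOTYPE_EVENTS,
    EventPosteriors,
    UncallableSiteError,
    compound_posterior,
    event_likelihood,
    event_regions,
    genotype_call,
    site_posteriors,
)
from mdacall.likelihoods import ALT, REF, ReadObservation, SitePileup

import oracle
from conftest import make_pileup, make_reads, random_pileup

HALF = Fraction(1, 2)


class TestEventRegions:
    def test_region_definitions(self):
        by_name = {r.name: r for r in event_regions()}
        assert by_name["HOM_ALT"].theta_s_set == {Fraction(1)}
        assert str(by_name["HOM_ALT"].theta_b_interval) == "(1/2, 1]"
        assert by_name["ADO_TO_REF"].theta_s_set == {Fraction(0)}
        assert str(by_name["ADO_TO_REF"].theta_b_interval) == "[1/2, 1)"
        assert by_name["ERR_ALT"].theta_s_set == {HALF, Fraction(1)}
        assert by_name["ERR_REF"].theta_s_set == {Fraction(0), HALF}
        assert by_name["HET"].theta_s_set == {HALF}

    @given(st.integers(min_value=1, max_value=50))
    @settings(max_examples=50, derandomize=True)
    def test_regions_partition_every_grid(self, n):
        # every (theta_s, m/n) cell belongs to exactly one event
        regions = event_regions()
        for theta in (Fraction(0), HALF, Fraction(1)):
            for m in range(n + 1):
                hits = [
                    r.name
                    for r in regions
                    if theta in r.theta_s_set and r.theta_b_interval.contains(m, n)
                ]
                assert len(hits) == 1, (theta, m, n, hits)

    def test_alt_presence_complement(self):
        # the complement of the alt-presence compound is hom-ref + err-alt
        assert set(EVENT_NAMES) - ALT_PRESENCE_EVENTS == {"HOM_REF", "ERR_ALT"}


class TestEventLikelihood:
    def test_imputed_zero_coverage_scales_with_member_count(self):
        p = make_pileup(bulk_ref=5, bulk_alt=5)
        regions = {r.name: r for r in event_regions()}
        one = event_likelihood(p, regions["HET"], impute=True)
        # ERR_REF has two theta_s members but its interval is {1}; compare
        # two regions over the same interval instead: build via HOM_REF set
        lik = {name: event_likelihood(p, r, impute=True) for name, r in regions.items()}
        # ERR_ALT ({1/2,1} x {0}) must be exactly twice a single-member
        # region over the same interval would be; with unit single-cell
        # factors its likelihood is 2 * bulk({0})
        from mdacall.likelihoods import bulk_theta_likelihood

        bulk0 = bulk_theta_likelihood(p.bulk_reads, 0, p.n)
        assert lik["ERR_ALT"] == pytest.approx(2 * bulk0, rel=1e-9)
        assert one > 0

    def test_empty_grid_region_has_zero_likelihood(self):
        # HET over n=1: grid {0, 1} misses the open interval (0, 1)
        p = make_pileup(sc_ref=2, bulk_alt=1)
        regions = {r.name: r for r in event_regions()}
        assert event_likelihood(p, regions["HET"]) == 0.0

    def test_matches_exhaustive_enumeration_small(self):
        e20 = 0.01
        p = SitePileup(
            "c", 1, "A", "C",
            sc_reads=[ReadObservation(ALT, e20), ReadObservation(REF, e20)],
            bulk_reads=[ReadObservation(ALT, e20), ReadObservation(REF, e20)],
        )
        ours = site_posteriors(p)
        ref = oracle.oracle_posteriors(
            [("ALT", "0.01"), ("REF", "0.01")], [("ALT", "0.01"), ("REF", "0.01")]
        )
        for name in EVENT_NAMES:
            assert ours[name] == pytest.approx(float(ref[name]), rel=1e-10)


class TestSitePosteriors:
    def test_normalised(self, rng):
        for _ in range(50):
            ep = site_posteriors(random_pileup(rng))
            assert sum(ep.probs.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0.0 <= v <= 1.0 for v in ep.probs.values())

    def test_zero_bulk_uncallable(self):
        p = make_pileup(sc_ref=3)
        with pytest.raises(UncallableSiteError):
            site_posteriors(p)

    def test_zero_sc_requires_imputation(self):
        p = make_pileup(bulk_ref=3)
        with pytest.raises(UncallableSiteError):
            site_posteriors(p)
        ep = site_posteriors(p, impute=True)
        assert ep.imputed

    def test_relabel_symmetry_exact(self, rng):
        pairs = {
            "HOM_REF": "HOM_ALT",
            "ERR_ALT": "ERR_REF",
            "ADO_TO_ALT": "ADO_TO_REF",
            "HET": "HET",
        }
        for _ in range(100):
            p = random_pileup(rng)
            a = site_posteriors(p)
            b = site_posteriors(p.relabelled())
            for x, y in pairs.items():
                assert abs(a[x] - b[y]) < 1e-12
                assert abs(a[y] - b[x]) < 1e-12

    def test_imputation_uses_bulk_alone(self):
        # a hom-alt bulk imputes a hom-alt genotype at a zero-coverage site
        p = make_pileup(bulk_alt=50)
        ep = site_posteriors(p, impute=True)
        call = genotype_call(ep)
        assert call.genotype == "hom_alt"
        # oracle value for the hom-alt-implying posterior mass
        ref = oracle.oracle_posteriors([], [("ALT", "0.001")] * 50)
        expected = float(ref["HOM_ALT"] + ref["ERR_REF"])
        assert call.posterior == pytest.approx(expected, rel=1e-8)

    def test_matches_oracle_on_random_mixed_quality_pileups(self, rng):
        for _ in range(25):
            p = random_pileup(rng, max_l=4, max_n=3)
            ours = site_posteriors(p, impute=True)  # sc reads may all be OTHER
            to_pairs = lambda reads: [
                (r.allele_class, repr(float(r.base_error_prob))) for r in reads
            ]
            ref = oracle.oracle_posteriors(to_pairs(p.sc_reads), to_pairs(p.bulk_reads))
            for name in EVENT_NAMES:
                assert ours[name] == pytest.approx(float(ref[name]), rel=1e-8)

    def test_balanced_cell_and_intermediate_bulk_call_het(self):
        p = make_pileup(sc_ref=5, sc_alt=5, bulk_ref=15, bulk_alt=15)
        ep = site_posteriors(p)
        assert max(ep.probs, key=ep.probs.get) == "HET"

    def test_lone_alt_read_against_deep_ref_bulk_is_error(self):
        p = make_pileup(sc_alt=1, bulk_ref=50)
        ep = site_posteriors(p)
        assert max(ep.probs, key=ep.probs.get) == "ERR_ALT"
        assert genotype_call(ep).genotype == "hom_ref"


class TestCompoundsAndGenotypes:
    def test_all_events_sum_to_one(self, rng):
        ep = site_posteriors(random_pileup(rng))
        assert compound_posterior(ep, EVENT_NAMES) == pytest.approx(1.0, abs=1e-9)
        assert compound_posterior(ep, set()) == 0.0

    def test_alt_presence_complement_identity(self, rng):
        ep = site_posteriors(random_pileup(rng))
        assert compound_posterior(ep, ALT_PRESENCE_EVENTS) + compound_posterior(
            ep, {"HOM_REF", "ERR_ALT"}
        ) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_event_rejected(self, rng):
        ep = site_posteriors(random_pileup(rng))
        with pytest.raises(ValueError):
            compound_posterior(ep, {"NOT_AN_EVENT"})

    def _ep(self, probs):
        return EventPosteriors(site=None, probs=probs)

    def test_genotype_compound_sum(self):
        probs = dict.fromkeys(EVENT_NAMES, 0.0)
        probs.update({"HOM_ALT": 0.6, "ERR_REF": 0.1, "HET": 0.2, "HOM_REF": 0.1})
        call = genotype_call(self._ep(probs))
        assert call.genotype == "hom_alt"
        assert call.posterior == pytest.approx(0.7)

    def test_dropout_implies_het(self):
        # a dominant ADO_TO_REF posterior means the cell truly carries the
        # dropped alternative allele: the genotype is heterozygous
        probs = dict.fromkeys(EVENT_NAMES, 0.0)
        probs.update({"ADO_TO_REF": 0.8, "HOM_REF": 0.2})
        assert genotype_call(self._ep(probs)).genotype == "het"

    def test_three_way_tie_prefers_hom_ref(self):
        probs = dict.fromkeys(EVENT_NAMES, 0.0)
        probs.update({"HOM_REF": 1 / 3, "HET": 1 / 3, "HOM_ALT": 1 / 3})
        assert genotype_call(self._ep(probs)).genotype == "hom_ref"

    def test_ado_compound_members(self):
        assert ADO_EVENTS == {"ADO_TO_REF", "ADO_TO_ALT"}
        assert GENOTYPE_EVENTS["het"] == {"HET", "ADO_TO_REF", "ADO_TO_ALT"}
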