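"""Flank-anchored empty-site calling on constructed filled/empty locus pairs."""

import numpy as np
import pytest

from karyoscan.genome import AnnotationRecord, Genome
from karyoscan.empty_sites import (
    call_putative_empty_site,
    cluster_homologous_loci,
    confirm_empty_site,
    detect_tsd,
    extract_flanks,
    implied_max_insertion_size,
    scan_empty_sites,
)

from conftest import mutate, random_dna

FLANK = 5_000


@pytest.fixture
def locus(rng):
    """A filled donor locus (2-kb TE with an 8-bp TSD) and its empty form."""
    left = random_dna(rng, 7000)
    right = random_dna(rng, 7000)
    tsd = random_dna(rng, 8)
    te = random_dna(rng, 2000)
    donor_seq = left + tsd + te + tsd + right
    empty_seq = left + tsd + right
    donor = Genome("donor", {"chr1": donor_seq})
    te_start = len(left) + len(tsd)
    annot = AnnotationRecord("chr1", te_start, te_start + len(te), "+",
                             "famX", "famX.c1")
    return donor, annot, empty_seq, tsd, te


class TestExtractFlanks:
    def _genome(self, rng, te_len, at=50_000, contig_len=100_000):
        seq = random_dna(rng, contig_len)
        g = Genome("g", {"chr1": seq})
        rec = AnnotationRecord("chr1", at, at + te_len, "+", "fam", "fam.c1")
        return g, rec

    def test_te_at_or_below_120_bp_excluded(self, rng):
        for te_len, expected in [(119, 0), (120, 0), (121, 1)]:
            g, rec = self._genome(rng, te_len)
            assert len(extract_flanks(g, [rec])) == expected

    def test_flanks_are_5_kb_and_exclude_the_te(self, rng):
        g, rec = self._genome(rng, 500)
        (fp,) = extract_flanks(g, [rec])
        assert len(fp.left_flank) == FLANK and len(fp.right_flank) == FLANK
        assert fp.left_flank == g.contigs["chr1"][45_000:50_000]
        assert fp.right_flank == g.contigs["chr1"][50_500:55_500]
        assert not (fp.left_truncated or fp.right_truncated)

    def test_flank_truncated_at_contig_start(self, rng):
        g, _ = self._genome(rng, 500)
        rec = AnnotationRecord("chr1", 2000, 2500, "+", "fam", "fam.c1")
        (fp,) = extract_flanks(g, [rec])
        assert len(fp.left_flank) == 2000
        assert fp.left_truncated and not fp.right_truncated


class TestPutativeCalls:
    def test_clean_excision_called_at_the_junction(self, locus):
        donor, annot, empty_seq, tsd, _ = locus
        (fp,) = extract_flanks(donor, [annot])
        subject = Genome("target", {"c": empty_seq})
        call = call_putative_empty_site(fp, subject)
        assert call is not None
        assert call.status == "putative"
        # flanks abut across the single remaining TSD copy
        assert abs(call.junction_position - (7000 + len(tsd))) <= len(tsd) + 2

    def test_gap_above_20_bp_is_not_called(self, rng, locus):
        donor, annot, empty_seq, tsd, _ = locus
        (fp,) = extract_flanks(donor, [annot])
        junction = 7000 + len(tsd)
        for gap, expect_call in [(25, False), (12, True)]:
            seq = empty_seq[:junction] + random_dna(rng, gap) + \
                empty_seq[junction:]
            call = call_putative_empty_site(fp, Genome("t", {"c": seq}))
            assert (call is not None) == expect_call

    def test_filled_site_is_not_called(self, locus):
        donor, annot, *_ = locus
        (fp,) = extract_flanks(donor, [annot])
        assert call_putative_empty_site(fp, donor) is None

    def test_truncated_flank_skips_the_locus(self, rng):
        seq = random_dna(rng, 20_000)
        g = Genome("g", {"c": seq})
        rec = AnnotationRecord("c", 3000, 3500, "+", "fam", "fam.c1")
        (fp,) = extract_flanks(g, [rec])
        assert len(fp.left_flank) == 3000 < 4500
        assert call_putative_empty_site(fp, g) is None


class TestConfirmation:
    def _putative(self, locus, subject):
        donor, annot, *_ = locus
        (fp,) = extract_flanks(donor, [annot])
        call = call_putative_empty_site(fp, subject)
        assert call is not None
        return call, fp

    def test_clean_excision_confirmed(self, locus):
        _, _, empty_seq, _, _ = locus
        subject = Genome("t", {"c": empty_seq})
        call, fp = self._putative(locus, subject)
        call = confirm_empty_site(call, fp, subject)
        assert call.status == "confirmed"
        assert call.merged_hit.aln_length >= 9000
        assert call.merged_hit.pct_identity >= 99.0

    def test_second_paralogous_locus_blocks_confirmation(self, rng, locus):
        _, _, empty_seq, _, _ = locus
        # a second, slightly diverged copy of the whole empty locus elsewhere
        paralog = mutate(rng, empty_seq, 30)
        subject = Genome("t", {"c": empty_seq, "c2": paralog})
        call, fp = self._putative(locus, subject)
        call = confirm_empty_site(call, fp, subject)
        assert call.status == "putative"
        assert "single-hit rule" in call.rejection_reason

    def test_low_identity_blocks_confirmation(self, rng, locus):
        _, _, empty_seq, _, _ = locus
        diverged = mutate(rng, empty_seq, 210)  # ~1.5% divergence: below 99%
        subject = Genome("t", {"c": diverged})
        call, fp = self._putative(locus, subject)
        call = confirm_empty_site(call, fp, subject)
        assert call.status == "putative"


class TestDetectTsd:
    def test_planted_8_bp_tsd_recovered(self, rng):
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        d = "GATTCCAA"
        te = "T" + random_dna(rng, 500) + "G"
        filled = a + d + te + d + b
        empty = a + d + b
        res = detect_tsd(filled, empty)
        assert res is not None
        assert res[0] == d

    def test_no_tsd_returns_none(self, rng):
        a, b = random_dna(rng, 200), random_dna(rng, 200)
        te = random_dna(rng, 300)
        # ensure no chance 1-bp duplication at the junction
        filled = a + "A" + te + "C" + b
        empty = a + "A" + "C" + b
        res = detect_tsd(filled, empty)
        assert res is None or len(res[0]) <= 2

    def test_homopolymer_junction_flagged_ambiguous(self):
        # the A-run before the TSD makes the insertion placement non-unique
        a = "GATC" * 49 + "AAAA"
        d = "AAAA"
        te = "G" + "TC" * 150 + "G"
        b = "CTGA" * 50
        filled = a + d + te + d + b
        empty = a + d + b
        res = detect_tsd(filled, empty)
        assert res is not None
        tsd, ambiguous = res
        assert tsd == d
        assert ambiguous

    def test_equal_lengths_mean_no_insertion(self, rng):
        s = random_dna(rng, 100)
        assert detect_tsd(s, s) is None


class TestClustering:
    def test_same_excision_in_two_targets_forms_one_cluster(self, locus):
        donor, annot, empty_seq, _, _ = locus
        (fp,) = extract_flanks(donor, [annot])
        calls = []
        for target_id in ("t1", "t2"):
            subject = Genome(target_id, {"c": empty_seq})
            call = call_putative_empty_site(fp, subject)
            calls.append(confirm_empty_site(call, fp, subject))
        clusters = cluster_homologous_loci(
            calls, {("donor", "famX.c1"): fp})
        assert len(clusters) == 1
        assert len(clusters[0].members) == 2

    def test_single_call_is_a_singleton_cluster(self, locus):
        donor, annot, empty_seq, _, _ = locus
        (fp,) = extract_flanks(donor, [annot])
        subject = Genome("t1", {"c": empty_seq})
        call = call_putative_empty_site(fp, subject)
        clusters = cluster_homologous_loci([call], {("donor", "famX.c1"): fp})
        assert len(clusters) == 1 and len(clusters[0].members) == 1

    def test_loci_farther_than_70_kb_are_split(self, locus, rng):
        donor, annot, empty_seq, _, _ = locus
        (fp,) = extract_flanks(donor, [annot])
        subject = Genome("t1", {"c": empty_seq})
        a = call_putative_empty_site(fp, subject)
        b = call_putative_empty_site(fp, subject)
        b.junction_position = a.junction_position + 75_000
        clusters = cluster_homologous_loci([a, b], {("donor", "famX.c1"): fp})
        assert len(clusters) == 2

    def test_implied_insertion_cap_is_61_kb(self):
        assert implied_max_insertion_size() == 61_000
        assert implied_max_insertion_size(70_000, 9_000) == 61_000


class TestPipelineOnSimulation:
    def test_direction_consistency(self, default_bundle):
        """A TE present in the ancestor and excised in a derived sample is
        found querying ancestor vs derived, never the reverse."""
        from karyoscan.search import KmerIndex
        b = default_bundle
        anc = b.ancestral
        d = b.samples["protoclone_1"]
        exc = b.truth[(b.truth.sample_id == "protoclone_1")
                      & (b.truth.event_type == "excision")]
        forward = scan_empty_sites(anc.genome, anc.annotations, d.genome,
                                   index=KmerIndex(d.genome))
        confirmed = [c for c in forward if c.status == "confirmed"]
        assert len(confirmed) == len(exc)
        # reverse direction: the excised copies are gone from the derived
        # annotations, so their loci cannot be queried at all
        reverse = scan_empty_sites(d.genome, d.annotations, anc.genome,
                                   index=KmerIndex(anc.genome))
        rev_conf = {c.te_copy_id for c in reverse if c.status == "confirmed"}
        assert not (rev_conf & set(exc.copy_id))
        # and the reverse scan reports exactly the planted insertions
        ins = b.truth[(b.truth.sample_id == "protoclone_1")
                      & (b.truth.event_type == "insertion")]
        assert rev_conf == set(ins.copy_id)
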