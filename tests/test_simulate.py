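"""Determinism and self-consistency of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from karyoscan.search import self_inverted_repeat
from karyoscan.simulate import (
    EventPlan,
    SimulationError,
    default_config,
    derive_sample,
    run_default_simulation,
    simulate_ancestral,
    simulate_depth_profiles,
    simulate_read_support,
)


class TestAncestral:
    def test_copies_are_extractable_and_counts_match(self, default_bundle):
        anc = default_bundle.ancestral
        counts = {}
        for a in anc.annotations:
            counts[a.family_id] = counts.get(a.family_id, 0) + 1
            assert 0 <= a.start < a.end <= anc.genome.contig_length(a.contig)
        assert counts == anc.config.ancestral_copies

    def test_same_seed_reproduces_identical_genomes(self):
        a = simulate_ancestral(default_config(9))
        b = simulate_ancestral(default_config(9))
        assert a.genome.contigs == b.genome.contigs
        assert a.annotations == b.annotations
        assert a.consensus == b.consensus

    def test_dna_consensus_has_the_configured_tir(self, default_bundle):
        anc = default_bundle.ancestral
        for fam in anc.config.te_library:
            if fam.te_class != "DNA_TIR":
                continue
            res = self_inverted_repeat(anc.consensus[fam.family_id],
                                       min_tir_len=10, min_tir_identity=95)
            assert res is not None
            assert res[0] == fam.tir_len
            assert res[1] == 100.0

    def test_tir_shared_within_superfamily_group(self, default_bundle):
        anc = default_bundle.ancestral
        assert anc.consensus["hAT_auto"][:28] == anc.consensus["hAT_na"][:28]

    def test_ltr_consensus_carries_identical_ltrs(self, default_bundle):
        anc = default_bundle.ancestral
        seq = anc.consensus["Gypsy_ltr"]
        assert seq[:300] == seq[-300:]

    def test_planted_copy_flanked_by_its_tsd(self, default_bundle):
        anc = default_bundle.ancestral
        for a in anc.annotations[:5]:
            k = anc.families[a.family_id].tsd_len
            seq = anc.genome.contigs[a.contig]
            assert seq[a.start - k:a.start] == seq[a.end:a.end + k]

    def test_infeasible_copy_load_rejected(self):
        cfg = default_config(0)
        cfg.ancestral_copies = {"hAT_auto": 60}
        with pytest.raises(SimulationError):
            simulate_ancestral(cfg)


class TestDeriveSample:
    def test_empty_plan_reproduces_the_ancestor(self, default_bundle):
        anc = default_bundle.ancestral
        d = derive_sample(anc, EventPlan("null_sample"), seed=0)
        assert d.genome.contigs == anc.genome.contigs
        assert len(d.truth) == 0

    def test_excisions_shorten_the_genome_by_copy_lengths(self, default_bundle):
        anc = default_bundle.ancestral
        d = derive_sample(anc, EventPlan("exc_only", n_excisions=4), seed=1)
        removed = d.truth.length.sum()
        assert sum(map(len, d.genome.contigs.values())) == \
            sum(map(len, anc.genome.contigs.values())) - removed

    def test_truth_coordinates_slice_back_to_the_event_sequences(
            self, default_bundle):
        anc = default_bundle.ancestral
        b = default_bundle
        for sid, d in b.samples.items():
            for row in d.truth.itertuples():
                if row.event_type == "insertion":
                    planted = d.genome.slice(row.contig, row.derived_start,
                                             row.derived_end)
                    src = next(a for a in anc.annotations
                               if a.copy_id == row.source_copy_id)
                    assert planted == anc.genome.slice(
                        src.contig, src.start, src.end)
                    # TSD duplicated on both sides of the planted copy
                    k = len(row.tsd) if row.tsd != "." else 0
                    if k:
                        ds, de = row.derived_start, row.derived_end
                        seq = d.genome.contigs[row.contig]
                        assert seq[ds - k:ds] == row.tsd
                        assert seq[de:de + k] == row.tsd
                elif row.event_type == "excision":
                    copy = anc.genome.slice(row.contig, row.anc_start,
                                            row.anc_end)
                    assert len(copy) == row.length
                    # the TSD footprint remains doubled at the junction
                    fam = next(a for a in anc.annotations
                               if a.copy_id == row.copy_id)
                    k = anc.families[fam.family_id].tsd_len
                    j = row.derived_start
                    seq = d.genome.contigs[row.contig]
                    assert seq[j - k:j] == seq[j:j + k]

    def test_solo_ltr_event_leaves_one_ltr(self, default_bundle):
        b = default_bundle
        d = b.samples["protoclone_3"]
        row = d.truth[d.truth.event_type == "solo_ltr"].iloc[0]
        solo = [a for a in d.annotations if a.copy_id.endswith("_solo")]
        assert len(solo) == 1
        ltr_len = b.ancestral.families[row.family_id].ltr_len
        assert solo[0].length == ltr_len
        ltr_seq = d.genome.slice(solo[0].contig, solo[0].start, solo[0].end)
        cons = b.ancestral.consensus[row.family_id]
        assert ltr_seq in (cons[:ltr_len], cons[-ltr_len:]) or \
            len(ltr_seq) == ltr_len

    def test_inversion_reverse_complements_in_place(self, default_bundle):
        from karyoscan.genome import revcomp
        b = default_bundle
        d = b.samples["protoclone_3"]
        row = d.truth[d.truth.event_type == "inversion"].iloc[0]
        original = b.ancestral.genome.slice(row.contig, row.anc_start,
                                            row.anc_end)
        inverted = d.genome.slice(row.contig, row.derived_start,
                                  row.derived_end)
        assert inverted == revcomp(original)

    def test_nahr_deletion_spans_copy_plus_intervening(self, default_bundle):
        b = default_bundle
        d = b.samples["protoclone_3"]
        row = d.truth[d.truth.event_type == "nahr_deletion"].iloc[0]
        assert row.length == row.anc_end - row.anc_start
        id_a, id_b = row.copy_id.split(",")
        a = next(x for x in b.ancestral.annotations if x.copy_id == id_a)
        bb = next(x for x in b.ancestral.annotations if x.copy_id == id_b)
        assert a.family_id == bb.family_id
        assert (row.anc_start, row.anc_end) == (a.start, bb.start)

    def test_infeasible_plan_raises_naming_the_event(self, default_bundle):
        anc = default_bundle.ancestral
        with pytest.raises(SimulationError, match="excision"):
            derive_sample(anc, EventPlan("bad", n_excisions=50), seed=0)


class TestReadSupport:
    def _truth(self, fraction, n=200):
        return pd.DataFrame({
            "sample_id": "s1", "event_type": "insertion", "family_id": "f",
            "copy_id": [f"c{i}" for i in range(n)], "source_copy_id": ".",
            "contig": "c1", "anc_start": 0, "anc_end": 0,
            "derived_start": np.arange(n) * 10_000,
            "derived_end": np.arange(n) * 10_000,
            "length": 100, "tsd": ".", "mosaic_fraction": fraction,
        })

    def test_fully_fixed_events_have_zero_reference_reads(self):
        calls = simulate_read_support(self._truth(1.0, n=50), 40, seed=0)
        assert all(c.ref_support == 0 for c in calls)

    def test_binomial_mean_recovered(self):
        calls = simulate_read_support(self._truth(0.5, n=1000), 40, seed=1)
        mean_alt = np.mean([c.alt_support for c in calls])
        se = np.sqrt(40 * 0.25) / np.sqrt(1000)   # SD of one draw / sqrt(reps)
        assert abs(mean_alt - 20) <= 3 * se

    def test_same_seed_identical_counts(self):
        a = simulate_read_support(self._truth(0.3), 40, seed=4)
        b = simulate_read_support(self._truth(0.3), 40, seed=4)
        assert a == b

    def test_caller_sets_non_empty(self):
        calls = simulate_read_support(self._truth(0.1, n=100), 40, seed=2)
        assert all(len(c.caller_ids) >= 1 for c in calls)


class TestDepthProfiles:
    def test_zero_copy_family_is_absent_downstream(self):
        from karyoscan.te_load import family_presence_median
        profiles = simulate_depth_profiles(
            {"s1": {"fam": 0}}, {"fam": 2000}, seed=1)
        (p,) = profiles
        assert family_presence_median(p.normalized("fam")) == 0.0

    def test_median_scales_with_copy_number(self):
        profiles = simulate_depth_profiles(
            {"s1": {"one": 1, "five": 5}}, {"one": 3000, "five": 3000},
            seed=2)
        (p,) = profiles
        ratio = np.median(p.family_depths["five"]) / \
            np.median(p.family_depths["one"])
        assert ratio == pytest.approx(5.0, rel=0.15)

    def test_large_dispersion_limit_is_poisson(self):
        profiles = simulate_depth_profiles(
            {"s1": {"fam": 2}}, {"fam": 20_000}, seed=3,
            dispersion=1e6)
        vec = profiles[0].family_depths["fam"]
        assert vec.var() / vec.mean() == pytest.approx(1.0, abs=0.1)

    def test_small_dispersion_is_overdispersed(self):
        profiles = simulate_depth_profiles(
            {"s1": {"fam": 2}}, {"fam": 20_000}, seed=3, dispersion=3.0)
        vec = profiles[0].family_depths["fam"]
        assert vec.var() / vec.mean() > 5


class TestBundleDeterminism:
    def test_full_bundle_is_a_pure_function_of_the_seed(self):
        a = run_default_simulation(5)
        b = run_default_simulation(5)
        assert a.ancestral.genome.contigs == b.ancestral.genome.contigs
        for sid in a.samples:
            assert a.samples[sid].genome.contigs == b.samples[sid].genome.contigs
            assert a.samples[sid].annotations == b.samples[sid].annotations
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.support_calls == b.support_calls

    def test_different_seeds_differ(self):
        a = run_default_simulation(5)
        b = run_default_simulation(6)
        assert a.ancestral.genome.contigs != b.ancestral.genome.contigs

    def test_emitted_files_round_trip(self, tmp_path, default_bundle):
        from karyoscan.genome import read_annotations, read_fasta
        from karyoscan.simulate import write_simulation
        write_simulation(default_bundle, tmp_path)
        anc = read_fasta(tmp_path / "ancestral.fasta")
        assert anc.contigs == default_bundle.ancestral.genome.contigs
        bed = read_annotations(tmp_path / "ancestral.bed", "bed")
        assert [(r.contig, r.start, r.end, r.strand) for r in bed] == \
            [(r.contig, r.start, r.end, r.strand)
             for r in default_bundle.ancestral.annotations]
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(truth) == len(default_bundle.truth)
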