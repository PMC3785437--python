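from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preydiet._iupac import reverse_complement
from preydiet.readprep import (
    AmpliconRecord,
    PrimerSet,
    QCConfig,
    TaggedRead,
    demultiplex,
    dereplicate,
    match_iupac,
    qc_filter,
)
from preydiet.synthetic import SimulationConfig, simulate_library, simulate_reads

from .conftest import make_read
from .oracles import iupac_scan

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestMatchIupac:
    def test_degenerate_primer_matches_concrete_site(self):
        assert match_iupac("AATTMGGTTGGGGCGACSHW", "AATTAGGTTGGGGCGACCAT") == [1]

    def test_no_match(self):
        assert match_iupac("ACGT", "TTTT", 0) == []

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            match_iupac("", "ACGT")

    @given(
        pattern=st.text(alphabet="ACGTRYSWKMN", min_size=1, max_size=8),
        text=st.text(alphabet="ACGT", min_size=1, max_size=30),
        max_mm=st.integers(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_position_by_position_scan(self, pattern, text, max_mm):
        assert match_iupac(pattern, text, max_mm) == iupac_scan(pattern, text, max_mm)


class TestDemultiplex:
    MIDS = [("s1", "ACGTACGTAC"), ("s2", "TTGGCCAATT")]

    def test_constructed_read_assigned_to_its_sample(self):
        primers = PrimerSet(mids=self.MIDS)
        insert = "AATTAGGTTGGGGCGACCAT" + "A" * 40
        read = make_read("r1", insert, mid="ACGTACGTAC")
        (out,) = demultiplex([read], primers)
        assert out.sample_id == "s1"

    def test_reverse_strand_read_assigned(self):
        primers = PrimerSet(mids=self.MIDS)
        insert = "AATTAGGTTGGGGCGACCAT" + "A" * 40
        read = make_read("r1", insert, mid="TTGGCCAATT")
        flipped = TaggedRead("r1", reverse_complement(read.sequence),
                             read.qualities[::-1])
        (out,) = demultiplex([flipped], primers)
        assert out.sample_id == "s2"

    def test_read_without_mid_left_unassigned(self):
        primers = PrimerSet(mids=self.MIDS)
        read = TaggedRead("r1", "AATTAGGTTGGGGCGACCAT" + "A" * 40,
                          np.full(60, 35))
        (out,) = demultiplex([read], primers)
        assert out.sample_id is None and not out.ambiguous

    def test_two_matching_mids_flagged_ambiguous(self):
        primers = PrimerSet(mids=self.MIDS)
        fwd_site = "AATTAGGTTGGGGCGACCAT"
        # MID of s1 before a forward-primer site and MID of s2 before another
        seq = "ACGTACGTAC" + fwd_site + "TT" + "TTGGCCAATT" + fwd_site + "AA"
        read = TaggedRead("r1", seq, np.full(len(seq), 35))
        (out,) = demultiplex([read], primers)
        assert out.sample_id is None and out.ambiguous

    def test_simulated_zero_error_reads_fully_assigned(self):
        cfg = SimulationConfig(
            n_species=4, seqs_per_species=2, n_samples=10, reads_per_sample=100,
            per_base_error_rate=0.0, chimera_rate=0.0, truncation_rate=0.0,
            low_quality_rate=0.0, negative_rate=0.0, seed=2,
        )
        lib = simulate_library(cfg)
        reads, truth, primers = simulate_reads(lib, cfg)
        demuxed = demultiplex(reads, primers)
        assert len(demuxed) == len(truth) == 1000
        truth_map = dict(zip(truth.read_id, truth.sample_id))
        assert all(r.sample_id == truth_map[r.read_id] for r in demuxed)

    def test_conservation_assigned_plus_unassigned(self, qc_ten_reads):
        primers = PrimerSet(mids=[("s1", "ACGTACGTAC")])
        demuxed = demultiplex(qc_ten_reads, primers)
        assert len(demuxed) == len(qc_ten_reads)
        n_assigned = sum(r.sample_id is not None for r in demuxed)
        n_unassigned = sum(r.sample_id is None for r in demuxed)
        assert n_assigned + n_unassigned == len(qc_ten_reads)


class TestQCFilter:
    def test_constructed_audit_set(self, qc_ten_reads):
        kept, rejections = qc_filter(qc_ten_reads, QCConfig())
        assert len(kept) == 4
        assert rejections == {"primer": 2, "length": 3, "quality": 1}

    def test_conservation(self, qc_ten_reads):
        kept, rejections = qc_filter(qc_ten_reads, QCConfig())
        assert len(kept) + sum(rejections.values()) == len(qc_ten_reads)

    def test_idempotence(self, qc_ten_reads):
        kept, _ = qc_filter(qc_ten_reads, QCConfig())
        again, rejections = qc_filter(kept, QCConfig())
        assert [r.read_id for r in again] == [r.read_id for r in kept]
        assert [r.insert for r in again] == [r.insert for r in kept]
        assert sum(rejections.values()) == 0

    def test_length_bounds_inclusive(self):
        fwd_site = "AATTAGGTTGGGGCGACCAT"
        rev_site = reverse_complement("AACATCGAGGTGCCAATCCC")
        amplicon_120 = fwd_site + "A" * 80 + rev_site
        assert len(amplicon_120) == 120
        kept, rejections = qc_filter([make_read("r", amplicon_120)], QCConfig())
        assert len(kept) == 1 and kept[0].insert == amplicon_120

    def test_mean_quality_exactly_30_rejected(self):
        fwd_site = "AATTAGGTTGGGGCGACCAT"
        rev_site = reverse_complement("AACATCGAGGTGCCAATCCC")
        amplicon = fwd_site + "A" * 94 + rev_site
        read = make_read("r", amplicon, mean_q=30.0)
        kept, rejections = qc_filter([read], QCConfig())
        assert kept == [] and rejections["quality"] == 1

    def test_reverse_primer_only_read_kept_and_normalised(self):
        rev_site = reverse_complement("AACATCGAGGTGCCAATCCC")
        insert = "A" * 110 + rev_site  # 130 bp, forward primer missing
        read = make_read("r", insert)
        flipped = TaggedRead("r", reverse_complement(read.sequence),
                             read.qualities[::-1])
        kept, _ = qc_filter([flipped], QCConfig())
        assert len(kept) == 1
        assert kept[0].primer_found == "reverse"
        assert kept[0].insert.endswith(rev_site)


class TestDereplicate:
    @staticmethod
    def reads_with_inserts(inserts: list[str], sample: str = "s1"):
        reads = []
        for i, ins in enumerate(inserts):
            r = TaggedRead(f"r{i}", ins, np.full(len(ins), 35), sample_id=sample)
            r.insert = ins
            reads.append(r)
        return reads

    def test_abundance_threshold(self):
        reads = self.reads_with_inserts(["ACGT" * 30] * 5 + ["TGCA" * 30] * 4)
        records = dereplicate(reads, QCConfig())
        assert len(records) == 1
        assert records[0].total_count == 5 and records[0].sequence == "ACGT" * 30

    def test_all_unique_reads_filtered_out(self):
        rng = np.random.default_rng(1)
        inserts = ["".join("ACGT"[i] for i in rng.integers(0, 4, 50)) for _ in range(20)]
        assert dereplicate(self.reads_with_inserts(inserts), QCConfig()) == []

    def test_per_sample_counts_conserved_before_threshold(self):
        cfg = SimulationConfig(
            n_species=3, seqs_per_species=1, n_samples=4, reads_per_sample=50,
            per_base_error_rate=0.0, chimera_rate=0.0, truncation_rate=0.0,
            low_quality_rate=0.0, negative_rate=0.0, seed=4,
        )
        lib = simulate_library(cfg)
        reads, truth, primers = simulate_reads(lib, cfg)
        kept, _ = qc_filter(demultiplex(reads, primers), QCConfig())
        records = dereplicate(kept, QCConfig(c_min=1))
        assert sum(r.total_count for r in records) == len(kept)
        for rec in records:
            assert rec.total_count == sum(rec.per_sample_counts.values())

    def test_zero_error_round_trip_recovers_templates_exactly(self):
        cfg = SimulationConfig(
            n_species=5, seqs_per_species=1, n_samples=6, reads_per_sample=80,
            per_base_error_rate=0.0, chimera_rate=0.0, truncation_rate=0.0,
            low_quality_rate=0.0, negative_rate=0.0, seed=8,
        )
        lib = simulate_library(cfg)
        reads, truth, primers = simulate_reads(lib, cfg)
        kept, rejections = qc_filter(demultiplex(reads, primers), QCConfig())
        assert sum(rejections.values()) == 0 and len(kept) == len(reads)
        records = dereplicate(kept, QCConfig())
        templates = {s.sequence for s in lib.sequences}
        realised = {r.sequence for r in records}
        drawn = {  # species drawn at least c_min times exist in the output
            seq for seq in templates
            if sum(1 for r in kept if r.insert == seq) >= 5
        }
        assert realised == drawn
        counts = truth[~truth.chimera].species.value_counts()
        by_template = {lib.get(f"{sp}_m1").sequence: int(c) for sp, c in counts.items()}
        for rec in records:
            assert rec.total_count == by_template[rec.sequence]


class TestAmpliconRecord:
    def test_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            AmpliconRecord("ACGT", 3, {"s1": 1, "s2": 1})
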