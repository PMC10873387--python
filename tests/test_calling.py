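"""Per-read calls, MM/ML tags, pileups, aggregation, phasing, merge."""

import array

import numpy as np
import pysam
import pytest

from squigmeth import calling, signal_io, simulator
from squigmeth.calling import (AggregatedSite, PerReadCall, SiteCounts,
                               aggregate_strands, encode_mm_ml, merge,
                               phase_split, pileup, read_per_read_tsv,
                               tag_bam, write_per_read_tsv)


def make_call(read_id="r", prob=0.9, ref_pos=100, strand="+", read_pos=5,
              phase=0, ref_cpg=True, is_c=True):
    return PerReadCall(read_id=read_id, read_pos=read_pos, probability=prob,
                       read_length=1000, mean_qscore=20.0, phase=phase,
                       ref_name="ref" if ref_pos is not None else None,
                       ref_pos=ref_pos, ref_strand=strand if ref_pos is not None
                       else None, ref_cpg=ref_cpg, read_base_is_c=is_c)


class TestThreshold:
    @pytest.mark.parametrize("prob,label", [
        (0.73, "methylated"),
        (0.50, "methylated"),   # ties count as methylated
        (0.49999, "unmethylated"),
    ])
    def test_tie_rule(self, prob, label):
        assert make_call(prob=prob).label(0.5) == label


class TestMMEncoding:
    def test_spec_example(self):
        # read "ACGTCG": C's at 1 and 4, both called
        calls = [make_call(prob=0.9, read_pos=1), make_call(prob=0.1, read_pos=4)]
        mm, ml = encode_mm_ml("ACGTCG", calls)
        assert mm == "C+m?,0,0;"
        assert ml == [230, 25]

    def test_skipped_cytosines_counted(self):
        # C's at 0, 2, 5; calls only at 0 and 5 -> second delta skips one C
        calls = [make_call(prob=1.0, read_pos=0), make_call(prob=0.5, read_pos=5)]
        mm, ml = encode_mm_ml("CACATCG", calls)
        assert mm == "C+m?,0,1;"
        assert ml == [255, 128]  # probability 1.0 clips to 255

    def test_non_c_calls_not_taggable(self):
        calls = [make_call(prob=0.9, read_pos=2, is_c=False)]
        assert encode_mm_ml("AATGT", calls) is None


HEADER = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 10000}]}


def _write_bam(path, records):
    with pysam.AlignmentFile(path, "wb", header=HEADER) as bam:
        for rec in records:
            bam.write(rec)


def _record(name, stored_seq, start=100, reverse=False, secondary=False):
    rec = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(HEADER))
    rec.query_name = name
    rec.query_sequence = stored_seq
    rec.query_qualities = array.array("B", [20] * len(stored_seq))
    rec.reference_id = 0
    rec.reference_start = start
    rec.cigartuples = [(0, len(stored_seq))]
    rec.is_reverse = reverse
    rec.is_secondary = secondary
    rec.mapping_quality = 60
    return rec


class TestTagBam:
    def test_round_trip_through_pysam(self, tmp_path):
        # forward read basecall "AACGT" (C at 2); reverse read basecall
        # "ACGTT" stored as "AACGT"
        bam_in = tmp_path / "in.bam"
        _write_bam(bam_in, [_record("fwd", "AACGT"),
                            _record("rev", "AACGT", reverse=True)])
        calls = {
            "fwd": [make_call("fwd", prob=0.8, read_pos=2, ref_pos=102)],
            "rev": [make_call("rev", prob=0.2, read_pos=1, ref_pos=103,
                              strand="-")],
        }
        bam_out = tmp_path / "out.bam"
        tag_bam(bam_in, bam_out, calls)
        seen = {}
        with pysam.AlignmentFile(bam_out, check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                seen[rec.query_name] = rec.modified_bases
        # pysam reports stored-sequence coordinates
        assert seen["fwd"] == {("C", 0, "m"): [(2, int(0.8 * 256))]}
        assert seen["rev"] == {("C", 1, "m"): [(3, int(0.2 * 256))]}

    def test_quantization_bound(self, tmp_path):
        probs = [0.001, 0.26, 0.5, 0.77, 0.999]
        bam_in = tmp_path / "in.bam"
        _write_bam(bam_in, [_record("r", "CCCCC")])
        calls = {"r": [make_call("r", prob=p, read_pos=i, is_c=True)
                       for i, p in enumerate(probs)]}
        bam_out = tmp_path / "out.bam"
        tag_bam(bam_in, bam_out, calls)
        with pysam.AlignmentFile(bam_out, check_sq=False) as bam:
            rec = next(bam.fetch(until_eof=True))
        decoded = [ml / 256.0 for _, ml in rec.modified_bases[("C", 0, "m")]]
        for p, d in zip(probs, decoded):
            assert 0 <= p - d < 1 / 256

    def test_secondary_never_tagged(self, tmp_path):
        bam_in = tmp_path / "in.bam"
        _write_bam(bam_in, [_record("r", "AACGT"),
                            _record("r", "AACGT", start=500, secondary=True)])
        calls = {"r": [make_call("r", prob=0.8, read_pos=2)]}
        bam_out = tmp_path / "out.bam"
        tag_bam(bam_in, bam_out, calls)
        with pysam.AlignmentFile(bam_out, check_sq=False) as bam:
            recs = list(bam.fetch(until_eof=True))
        assert recs[0].has_tag("MM")
        assert not recs[1].has_tag("MM")


class TestPileup:
    def test_basic_frequency(self):
        calls = [make_call(f"r{i}", prob=0.9 if i < 7 else 0.1) for i in range(10)]
        (site,) = pileup(calls)
        assert (site.total, site.meth) == (10, 7)
        assert site.frequency == pytest.approx(0.7)

    def test_deletion_excluded_snv_included(self):
        # 7 methylated, 2 unmethylated C reads, 1 read with a T substitution
        # (anchored via the reference, counted unmethylated), 1 read whose
        # deletion produced no call at all
        calls = [make_call(f"m{i}", prob=0.9) for i in range(7)]
        calls += [make_call(f"u{i}", prob=0.1) for i in range(2)]
        calls += [make_call("snv", prob=0.1, is_c=False)]
        (site,) = pileup(calls)
        assert (site.total, site.meth) == (10, 7)

    def test_non_cpg_ref_flag(self):
        calls = [make_call("a", ref_pos=100, ref_cpg=True),
                 make_call("b", ref_pos=200, ref_cpg=False)]
        assert len(pileup(calls)) == 1
        assert len(pileup(calls, include_non_cpg_ref=True)) == 2

    def test_unanchored_calls_never_piled(self):
        calls = [make_call("a", ref_pos=None)]
        assert pileup(calls, include_non_cpg_ref=True) == []


class TestAggregate:
    def test_both_strands(self):
        stranded = [SiteCounts("ref", 100, "+", total=8, meth=5),
                    SiteCounts("ref", 101, "-", total=6, meth=4)]
        (agg,) = aggregate_strands(stranded)
        assert (agg.cpg_pos, agg.total, agg.meth) == (100, 14, 9)

    def test_single_strand_coverage(self):
        (agg,) = aggregate_strands([SiteCounts("ref", 101, "-", total=6, meth=4)])
        assert (agg.cpg_pos, agg.total, agg.meth) == (100, 6, 4)

    def test_conservation(self, small_calls):
        stranded = pileup(small_calls[0])
        agg = aggregate_strands(stranded)
        assert sum(a.total for a in agg) == sum(s.total for s in stranded)
        assert sum(a.meth for a in agg) == sum(s.meth for s in stranded)


class TestPhaseSplit:
    def test_imprinting_toy(self):
        calls = [make_call(f"h1_{i}", prob=0.9 if i < 5 else 0.1, phase=1)
                 for i in range(6)]
        calls += [make_call(f"h2_{i}", prob=0.1, phase=2) for i in range(4)]
        (site,) = pileup(calls)
        assert (site.total, site.meth) == (10, 5)
        assert (site.phase1_total, site.phase1_meth) == (6, 5)
        assert (site.phase2_total, site.phase2_meth) == (4, 0)

    def test_all_unphased(self):
        calls = [make_call(f"r{i}") for i in range(5)]
        (site,) = pileup(calls)
        assert site.phase1_total == site.phase2_total == 0
        assert site.total == 5

    def test_phase_totals_bounded(self, small_calls):
        for site in pileup(small_calls[0]):
            assert site.phase1_total + site.phase2_total <= site.total
            assert site.phase1_meth <= site.phase1_total
            assert site.phase2_meth <= site.phase2_total


class TestMerge:
    def _tsv(self, tmp_path, calls, name):
        path = tmp_path / name
        write_per_read_tsv(calls, path)
        return path

    def test_single_run_idempotence(self, tmp_path, small_calls):
        calls = small_calls[0]
        path = self._tsv(tmp_path, calls, "run.tsv")
        stranded, _ = merge([path])
        direct = pileup(calls, include_non_cpg_ref=True)
        assert [(s.ref_name, s.pos, s.strand, s.total, s.meth) for s in stranded] \
            == [(s.ref_name, s.pos, s.strand, s.total, s.meth) for s in direct]

    def test_threshold_monotonicity(self, tmp_path, small_calls):
        path = self._tsv(tmp_path, small_calls[0], "run.tsv")
        lo, _ = merge([path], threshold=0.4)
        hi, _ = merge([path], threshold=0.9)
        hi_by_key = {(s.ref_name, s.pos, s.strand): s.meth for s in hi}
        for s in lo:
            assert hi_by_key[(s.ref_name, s.pos, s.strand)] <= s.meth

    def test_two_halves_equal_whole(self, tmp_path, small_calls):
        calls = small_calls[0]
        read_ids = sorted({c.read_id for c in calls})
        half = set(read_ids[:len(read_ids) // 2])
        p1 = self._tsv(tmp_path, [c for c in calls if c.read_id in half], "a.tsv")
        p2 = self._tsv(tmp_path, [c for c in calls if c.read_id not in half], "b.tsv")
        whole = self._tsv(tmp_path, calls, "w.tsv")
        merged, _ = merge([p1, p2])
        full, _ = merge([whole])
        key = lambda sites: [(s.ref_name, s.pos, s.strand, s.total, s.meth)
                             for s in sites]
        assert key(merged) == key(full)

    def test_duplicate_rows_rejected(self, tmp_path, small_calls):
        path = self._tsv(tmp_path, small_calls[0], "run.tsv")
        with pytest.raises(ValueError, match="duplicate"):
            merge([path, path])

    def test_tsv_round_trip(self, tmp_path, small_calls):
        calls = small_calls[0][:50]
        path = self._tsv(tmp_path, calls, "rt.tsv")
        loaded = read_per_read_tsv(path)
        assert len(loaded) == len(calls)
        for a, b in zip(calls, loaded):
            assert a.read_id == b.read_id and a.read_pos == b.read_pos
            assert a.probability == pytest.approx(b.probability, abs=1e-6)
            assert (a.ref_pos, a.ref_strand, a.phase) == \
                (b.ref_pos, b.ref_strand, b.phase)


class TestUnmappedReads:
    def test_calls_without_reference_fields(self, tmp_path, untrained_model):
        cfg = simulator.SimConfig(seed=21, ref_length=4000, n_cpg=40, n_reads=8,
                                  read_length_mean=1000, read_length_sd=100,
                                  fraction_unmapped=1.0)
        ds = simulator.generate_dataset(cfg, tmp_path)
        signals = signal_io.load_signal_index([ds.signal_container])
        moves = signal_io.container_move_tables(ds.signal_container)
        bundles = calling.iter_read_bundles(ds.bam, signals, ref_fasta=None,
                                            container_moves=moves)
        n = 0
        for read_calls in calling.call_reads(bundles, untrained_model):
            for c in read_calls:
                assert c.ref_pos is None and c.ref_name is None
                assert 0.0 <= c.probability <= 1.0
                n += 1
        assert n > 0

    def test_missing_signal_read_warns_and_skips(self, small_dataset, caplog):
        signals = signal_io.load_signal_index([small_dataset.signal_container])
        victim = sorted(signals)[0]
        del signals[victim]
        import logging
        with caplog.at_level(logging.WARNING, logger="squigmeth.calling"):
            bundles = list(calling.iter_read_bundles(small_dataset.bam, signals))
        assert all(b.read_id != victim for b in bundles)
        assert any(victim in rec.message for rec in caplog.records)
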