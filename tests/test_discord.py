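"""Mapping filter, library statistics, classification and extraction."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from tetrace.discord import (
    CoverageMask,
    ExtractionCounters,
    build_coverage_mask,
    classify_pair_mapping,
    estimate_library_stats,
    extract_discordant_pairs,
    filter_read_mappings,
    load_fragments,
)
from tetrace.model import (
    LibraryStats,
    MATE_PAIR_ORIENT,
    Orient,
    PairMapping,
    ReadMapping,
    Signature,
)


def rm(chrom="chr1", orient="-", pos=100, nm=0):
    return ReadMapping(chrom, Orient(orient), pos, nm)


STATS = LibraryStats(M=5000.0, MAD=100.0)  # d_inf=4700, d_sup=5300


# ---------------------------------------------------------------------------
# mismatch filter


class TestMappingFilter:
    def test_perfect_read_retained(self):
        assert filter_read_mappings([rm(nm=0)], max_mismatch=1) == [rm(nm=0)]

    def test_best_mapping_beyond_threshold_drops_read(self):
        assert filter_read_mappings([rm(nm=2), rm(pos=500, nm=3)], max_mismatch=1) == []

    def test_individual_mappings_beyond_threshold_dropped(self):
        kept = filter_read_mappings([rm(nm=1), rm(pos=500, nm=3)], max_mismatch=1)
        assert kept == [rm(nm=1)]

    def test_missing_edit_distance_fails_filter_with_warning(self):
        with pytest.warns(UserWarning):
            assert filter_read_mappings([rm(nm=-1)], max_mismatch=1) == []


# ---------------------------------------------------------------------------
# library statistics


def _median_mad_oracle(values):
    """Brute-force sorted-median / MAD reference."""
    s = sorted(values)
    n = len(s)
    med = (s[(n - 1) // 2] + s[n // 2]) / 2
    dev = sorted(abs(v - med) for v in s)
    mad = (dev[(n - 1) // 2] + dev[n // 2]) / 2
    return med, mad


class TestLibraryStats:
    def test_five_insert_example(self):
        stats = estimate_library_stats([4800, 4900, 5000, 5100, 5300])
        assert (stats.M, stats.MAD) == (5000, 100)
        assert (stats.d_inf, stats.d_sup) == (4700, 5300)

    def test_constant_inserts_flag_degenerate(self):
        with pytest.warns(UserWarning):
            stats = estimate_library_stats([5000] * 5)
        assert stats.MAD == 0 and stats.degenerate

    def test_outlier_resistant_example(self):
        stats = estimate_library_stats([1, 2, 3, 4, 100])
        assert (stats.M, stats.MAD, stats.d_inf, stats.d_sup) == (3, 1, 0, 6)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_library_stats([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=200), st.randoms())
    def test_permutation_invariant_and_matches_oracle(self, inserts, rnd):
        med, mad = _median_mad_oracle(inserts)
        stats = estimate_library_stats(inserts)
        shuffled = list(inserts)
        rnd.shuffle(shuffled)
        stats2 = estimate_library_stats(shuffled)
        assert (stats.M, stats.MAD) == (med, mad) == (stats2.M, stats2.MAD)


# ---------------------------------------------------------------------------
# classification


class TestClassification:
    def test_proper_pair_is_concordant(self):
        p = PairMapping.make(rm("chr1", "-", 100), rm("chr1", "+", 5200))
        assert classify_pair_mapping(p, STATS) is Signature.CONC

    def test_large_insert_is_deletion_signature(self):
        p = PairMapping.make(rm("chr1", "-", 100), rm("chr1", "+", 20100))
        assert classify_pair_mapping(p, STATS) is Signature.DEL

    def test_equal_strands_and_interchromosomal(self):
        inv = PairMapping.make(rm("chr1", "+", 100), rm("chr1", "+", 2000))
        trans = PairMapping.make(rm("chr1", "-", 100), rm("chr2", "+", 500))
        assert classify_pair_mapping(inv, STATS) is Signature.INV
        assert classify_pair_mapping(trans, STATS) is Signature.TRANS

    def test_small_insert_is_insertion_signature(self):
        p = PairMapping.make(rm("chr1", "-", 100), rm("chr1", "+", 1100))
        assert classify_pair_mapping(p, STATS) is Signature.INS

    def test_reversed_orientation_is_duplication(self):
        p = PairMapping.make(rm("chr1", "+", 100), rm("chr1", "-", 5100))
        assert classify_pair_mapping(p, STATS) is Signature.DUP

    def test_exhaustive_truth_table(self):
        """Every orientation x insert regime x chromosome case maps to
        exactly one signature, matching the classification rules."""
        inserts = {
            "below": 4699,
            "at_inf": 4700,
            "inside": 5000,
            "at_sup": 5300,
            "above": 5301,
        }
        for o_a in "+-":
            for o_b in "+-":
                for regime, d in inserts.items():
                    for same_chrom in (True, False):
                        a = rm("chr1", o_a, 10_000)
                        b = rm("chr1" if same_chrom else "chr2", o_b, 10_000 + d)
                        sig = classify_pair_mapping(PairMapping(a, b), STATS)
                        if not same_chrom:
                            expected = Signature.TRANS
                        elif o_a == o_b:
                            expected = Signature.INV
                        elif (o_a, o_b) == ("+", "-"):
                            expected = Signature.DUP
                        elif regime == "above":
                            expected = Signature.DEL
                        elif regime == "below":
                            expected = Signature.INS
                        else:
                            expected = Signature.CONC
                        assert sig is expected, (o_a, o_b, regime, same_chrom)


# ---------------------------------------------------------------------------
# coverage mask


class TestCoverageMask:
    def test_uniform_depth_gives_empty_mask(self):
        mask = build_coverage_mask({"chr1": np.full(100, 20.0)})
        assert mask.total_bp == 0

    def test_extreme_region_masked(self):
        depths = np.full(1000, 20.0)
        depths[100:110] = 1500.0
        depths[::7] += 3.0  # give the background a nonzero MAD
        mask = build_coverage_mask({"chr1": depths})
        assert mask.contains("chr1", 10_500)
        assert not mask.contains("chr1", 50_000)

    def test_single_window_spike_masked_without_floor(self):
        depths = np.full(200, 20.0)
        depths[::2] += 2.0  # median 21, MAD 1 -> c_sup 24
        depths[50] = 25.0  # c_sup + 1
        mask = build_coverage_mask({"chr1": depths}, floor=0.0)
        assert mask.intervals["chr1"] == [(5000, 5100)]

    def test_raising_threshold_never_grows_mask(self):
        rng = np.random.default_rng(0)
        depths = {"chr1": rng.poisson(20, 500).astype(float) * 60}
        sizes = []
        for n_mad in (2.0, 3.0, 5.0, 8.0):
            sizes.append(build_coverage_mask(depths, floor=0.0, n_mad=n_mad).total_bp)
        assert sizes == sorted(sizes, reverse=True)

    def test_zero_coverage_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            mask = build_coverage_mask({"chr1": np.zeros(10)})
        assert mask.total_bp == 0


# ---------------------------------------------------------------------------
# extraction


def _write_sam(path, records, lengths={"chr1": 100_000, "chr2": 100_000}):
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in lengths.items()],
        }
    )
    names = list(lengths)
    records = sorted(records, key=lambda r: (names.index(r[1]), r[2]))
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for qname, chrom, pos, rev, mate_i, secondary, nm in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = (
                0x1
                | (0x10 if rev else 0)
                | (0x40 if mate_i == 0 else 0x80)
                | (0x100 if secondary else 0)
            )
            a.reference_id = names.index(chrom)
            a.reference_start = pos
            a.mapping_quality = 30
            a.cigarstring = "100M"
            a.query_sequence = "A" * 100 if not secondary else None
            a.set_tag("NM", nm)
            fh.write(a)
    return path


class TestExtraction:
    def extract(self, tmp_path, records, stats=STATS, mask=None, **kw):
        sam = _write_sam(str(tmp_path / "in.sam"), records)
        fragments, _ = load_fragments(sam)
        return list(extract_discordant_pairs(fragments, stats, mask, **kw))

    def test_fragment_with_concordant_combination_is_silent(self, tmp_path):
        # primary combination concordant, secondary mapping makes a Del combo
        recs = [
            ("f1", "chr1", 1000, True, 0, False, 0),
            ("f1", "chr1", 6000, False, 1, False, 0),
            ("f1", "chr1", 40_000, False, 1, True, 0),
        ]
        assert self.extract(tmp_path, recs) == []

    def test_all_discordant_combinations_all_recorded(self, tmp_path):
        recs = [
            ("f1", "chr1", 1000, True, 0, False, 0),
            ("f1", "chr1", 40_000, False, 1, False, 0),  # Del
            ("f1", "chr2", 500, False, 1, True, 0),  # Trans
        ]
        out = self.extract(tmp_path, recs)
        assert sorted(r.signature for r in out) == [Signature.DEL, Signature.TRANS]
        assert {r.pair_id for r in out} == {"f1"}

    def test_pair_inside_high_coverage_mask_discarded(self, tmp_path):
        recs = [
            ("f1", "chr1", 1000, True, 0, False, 0),
            ("f1", "chr1", 40_000, False, 1, False, 0),
        ]
        mask = CoverageMask(
            c_inf=0, c_sup=1000, intervals={"chr1": [(0, 50_000)]}
        )
        assert self.extract(tmp_path, recs, mask=mask) == []

    def test_orphan_reads_counted_and_skipped(self, tmp_path):
        sam = _write_sam(str(tmp_path / "in.sam"), [("f1", "chr1", 1000, True, 0, False, 0)])
        fragments, _ = load_fragments(sam)
        counters = ExtractionCounters()
        out = list(extract_discordant_pairs(fragments, STATS, counters=counters))
        assert out == [] and counters.orphans == 1

    def test_unsorted_input_is_an_error(self, tmp_path):
        path = str(tmp_path / "u.sam")
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": [{"SN": "chr1", "LN": 1000}]}
        )
        with pysam.AlignmentFile(path, "w", header=header):
            pass
        with pytest.raises(ValueError, match="coordinate-sorted"):
            load_fragments(path)

    def test_insert_tail_pair_vetoed_but_true_del_kept(self, tmp_path):
        # insert 5400 is discordant by classification (d_sup=5300) but within
        # the 6-MAD near-concordance band (5600); insert 40k is far outside
        tail = [
            ("t1", "chr1", 1000, True, 0, False, 0),
            ("t1", "chr1", 6400, False, 1, False, 0),
        ]
        far = [
            ("t2", "chr1", 1000, True, 0, False, 0),
            ("t2", "chr1", 41_000, False, 1, False, 0),
        ]
        out = self.extract(tmp_path, tail + far)
        assert [r.pair_id for r in out] == ["t2"]
        assert out[0].signature is Signature.DEL
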