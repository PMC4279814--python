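"""Synthetic genomes, injection, mate-pair simulation and evaluation."""

from __future__ import annotations

import numpy as np
import pytest

from tetrace.model import EventCall, EventType, Interval
from tetrace.sim import (
    evaluate_calls,
    inject_transposition_events,
    learn_sim_profile,
    make_synthetic_genome,
    plan_events,
    simulate_exact_placement_sam,
    simulate_mate_pairs,
    synthetic_profile,
)
from tetrace.sim.genome import PlannedEvent, revcomp
from tetrace.sim.placement import simulate_fragment_mappings


SMALL = dict(chrom_lengths={"chr1": 250_000}, n_singletons=3, n_composite_blocks=1)


@pytest.fixture(scope="module")
def small_genome():
    return make_synthetic_genome(seed=5, **SMALL)


def _one_event(donor, pos, inverted=False, tsd=5, cls="normal"):
    return PlannedEvent(
        event_class=cls,
        donor=donor,
        acceptor_chrom="chr1",
        acceptor_pos=pos,
        inverted=inverted,
        tsd_len=tsd,
    )


class TestInjection:
    def test_length_bookkeeping(self, small_genome):
        ref = small_genome.seqs
        donor = small_genome.annotation[0][0]
        truth = inject_transposition_events(ref, [_one_event(donor, 200_000, tsd=5)])
        assert len(truth.modified["chr1"]) == len(ref["chr1"]) + donor.length + 5

    def test_inserted_block_and_tsd_round_trip(self, small_genome):
        ref = small_genome.seqs
        donor = small_genome.annotation[0][0]
        p, t = 200_000, 5
        truth = inject_transposition_events(ref, [_one_event(donor, p, tsd=t)])
        mod = truth.modified["chr1"]
        block_start = truth.events[0].acceptor_pos_mod
        block = mod[block_start : block_start + donor.length]
        assert block == ref[donor.chrom][donor.start : donor.end]
        # target-site duplication flanks the block on both sides
        assert mod[block_start - t : block_start] == ref["chr1"][p : p + t]
        assert (
            mod[block_start + donor.length : block_start + donor.length + t]
            == ref["chr1"][p : p + t]
        )

    def test_inverted_event_inserts_reverse_complement(self, small_genome):
        ref = small_genome.seqs
        donor = small_genome.annotation[0][0]
        truth = inject_transposition_events(
            ref, [_one_event(donor, 200_000, inverted=True)]
        )
        block_start = truth.events[0].acceptor_pos_mod
        block = truth.modified["chr1"][block_start : block_start + donor.length]
        assert block == revcomp(ref[donor.chrom][donor.start : donor.end])

    def test_composite_plan_spans_two_contiguous_elements(self, small_genome):
        events = plan_events(small_genome, n_per_class=1, seed=6, acceptor_margin=6000)
        (comp,) = [e for e in events if e.event_class == "composite"]
        iv1, iv2 = small_genome.composite_blocks[0]
        assert comp.donor.start == iv1.start and comp.donor.end == iv2.end

    def test_overlapping_acceptors_rejected_in_strict_mode(self, small_genome):
        donor = small_genome.annotation[0][0]
        events = [_one_event(donor, 200_000), _one_event(donor, 200_002)]
        with pytest.raises(ValueError, match="inside another insertion"):
            inject_transposition_events(small_genome.seqs, events)

    def test_segment_map_round_trips_reference_coordinates(self, small_genome):
        ref = small_genome.seqs
        donor = small_genome.annotation[0][0]
        truth = inject_transposition_events(
            ref, [_one_event(donor, 200_000, inverted=True)]
        )
        mod = truth.modified["chr1"]
        for seg in truth.segments["chr1"]:
            a = seg.mod_start
            b = min(seg.mod_end, a + 80)
            chrom, s, e, flip = seg.map_interval(a, b)
            src = ref[chrom][s:e]
            assert mod[a:b] == (revcomp(src) if flip else src)


class TestExactPlacement:
    def test_event_free_library_yields_no_discordant_records(self, small_genome):
        """A concordant library never produces a discordant record."""
        from tetrace import discord
        from tetrace.sim.genome import TruthTable, Segment

        ref = small_genome.seqs
        truth = inject_transposition_events(ref, [])
        frags, counters = simulate_fragment_mappings(
            truth, small_genome.groups, coverage=5, seed=9
        )
        stats = discord.estimate_library_stats(
            discord.sample_inserts(frags.values())
        )
        assert list(discord.extract_discordant_pairs(frags, stats)) == []
        assert counters.junction_pairs == 0

    def test_sam_output_is_deterministic(self, small_genome, tmp_path):
        events = plan_events(small_genome, n_per_class=1, seed=6, acceptor_margin=6000)
        truth = inject_transposition_events(small_genome.seqs, events)
        paths = []
        for tag in ("a", "b"):
            p = str(tmp_path / f"{tag}.sam")
            simulate_exact_placement_sam(
                truth, small_genome.seqs, p, small_genome.groups, coverage=3, seed=4
            )
            paths.append(p)
        assert open(paths[0]).read() == open(paths[1]).read()


class TestProfileLearning:
    def _write_library_sam(self, path, n_pairs=400, qual=30, modes=((300, 0.2), (5000, 0.8))):
        import pysam

        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": "chr1", "LN": 200_000}],
            }
        )
        rng = np.random.default_rng(1)
        recs = []
        for i in range(n_pairs):
            size = int(rng.choice([m for m, _ in modes], p=[p for _, p in modes]))
            size += int(rng.integers(-40, 41))
            start = int(rng.integers(0, 150_000))
            recs.append((start, f"p{i}", 0x1 | 0x40 | 0x10, qual))
            recs.append((start + size - 50, f"p{i}", 0x1 | 0x80, qual))
        recs.sort()
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for pos, name, flag, q in recs:
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.flag = flag
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = 37
                a.cigarstring = "50M"
                a.query_sequence = "A" * 50
                a.query_qualities = pysam.qualitystring_to_array(chr(q + 33) * 50)
                fh.write(a)
        return path

    def test_constant_quality_gives_point_mass_histograms(self, tmp_path):
        sam = self._write_library_sam(str(tmp_path / "lib.sam"), qual=30)
        profile = learn_sim_profile(sam)
        assert profile.read_len == 50
        for row in profile.quality_hists:
            assert row[profile.qual_values == 30] == pytest.approx(1.0)

    def test_bimodal_mixture_split_between_modes(self, tmp_path):
        sam = self._write_library_sam(str(tmp_path / "lib.sam"))
        profile = learn_sim_profile(sam)
        assert 400 < profile.split_point < 5000
        assert profile.contamination_odds > 0

    def test_unimodal_mixture_warns_and_zero_odds(self, tmp_path):
        sam = self._write_library_sam(
            str(tmp_path / "lib.sam"), modes=((5000, 1.0),)
        )
        with pytest.warns(UserWarning, match="unimodal"):
            profile = learn_sim_profile(sam)
        assert profile.contamination_odds == 0.0


class TestMatePairSimulation:
    def test_identical_seed_gives_byte_identical_fastq(self, small_genome, tmp_path):
        profile = synthetic_profile(long_mean=3000, long_sd=200)
        outs = []
        for tag in ("a", "b"):
            f1, f2 = str(tmp_path / f"{tag}1.fq"), str(tmp_path / f"{tag}2.fq")
            simulate_mate_pairs(small_genome.seqs, profile, 1.0, 77, f1, f2)
            outs.append(open(f1).read() + open(f2).read())
        assert outs[0] == outs[1]

    def test_noise_free_settings_reproduce_the_fragment(self, small_genome, tmp_path):
        # quality 40 -> 1e-4 error/base; splice centred on the junction
        profile = synthetic_profile(
            long_mean=3000, long_sd=200, qual_start=40, qual_end=40, qual_sd=1e-9
        )
        f1, f2 = str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq")
        pairs = simulate_mate_pairs(
            small_genome.seqs,
            profile,
            0.5,
            3,
            f1,
            f2,
            with_contamination=False,
            with_chimera=False,
        )
        assert not any(p.is_contaminant or p.chimeric1 or p.chimeric2 for p in pairs)
        reads1 = [l.rstrip("\n") for l in open(f1)][1::4]
        genome = small_genome.seqs["chr1"]
        mismatches = bases = 0
        for p, r1 in zip(pairs, reads1):
            # read1 starts at splice offset 0 = junction offset j before frag end
            tpl_start = p.frag_start + p.frag_size - p.junction_offset
            template = (genome + genome)[tpl_start : tpl_start + len(r1)]
            assert len(template) == len(r1)
            mismatches += sum(a != b for a, b in zip(r1, template))
            bases += len(r1)
        assert mismatches / bases == pytest.approx(1e-4, abs=3e-4)

    def test_declared_error_rate_is_respected(self, small_genome, tmp_path):
        # quality 20 -> 1% substitution rate, binomial check at ~2e5 bases
        profile = synthetic_profile(
            long_mean=3000, long_sd=200, qual_start=20, qual_end=20, qual_sd=1e-9
        )
        f1, f2 = str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq")
        pairs = simulate_mate_pairs(
            small_genome.seqs,
            profile,
            2.0,
            3,
            f1,
            f2,
            with_contamination=False,
            with_chimera=False,
        )
        reads1 = [l.rstrip("\n") for l in open(f1)][1::4]
        genome = small_genome.seqs["chr1"]
        mm = bases = 0
        for p, r1 in zip(pairs, reads1):
            tpl_start = p.frag_start + p.frag_size - p.junction_offset
            template = (genome + genome)[tpl_start : tpl_start + len(r1)]
            mm += sum(a != b for a, b in zip(r1, template))
            bases += len(r1)
        rate = mm / bases
        assert rate == pytest.approx(0.01, rel=0.25)

    def test_forced_adjacent_splice_yields_junction_chimeras(self, small_genome, tmp_path):
        profile = synthetic_profile(long_mean=3000, long_sd=200)
        f1, f2 = str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq")
        pairs = simulate_mate_pairs(
            small_genome.seqs, profile, 2.0, 11, f1, f2, with_contamination=False
        )
        chimeric = [p for p in pairs if p.chimeric1]
        assert chimeric, "geometry should produce junction chimeras"
        reads1 = [l.rstrip("\n") for l in open(f1)][1::4]
        genome = small_genome.seqs["chr1"]
        for p, r1 in zip(pairs, reads1):
            if not p.chimeric1:
                continue
            # the two halves flank the junction: prefix from the fragment
            # end, suffix from the fragment start
            j = p.junction_offset
            prefix = genome[p.frag_start + p.frag_size - j : p.frag_start + p.frag_size]
            suffix = genome[p.frag_start : p.frag_start + len(r1) - j]
            expected = prefix + suffix
            diff = sum(a != b for a, b in zip(r1, expected))
            assert diff <= 5  # sequencing errors only
            break


class TestEvaluation:
    def _truth(self, n=1, cls="normal"):
        return [
            PlannedEvent(
                event_class=cls,
                donor=Interval("chr2", 20_000 + 10_000 * i, 24_000 + 10_000 * i),
                acceptor_chrom="chr1",
                acceptor_pos=50_000 + 30_000 * i,
                tsd_len=5,
            )
            for i in range(n)
        ]

    def _line(self, acc_id, acc_start, acc_end, donor=(20_000, 24_000)):
        return EventCall(
            acceptor_id=acc_id,
            event_type=EventType.INSERTION_SENSE,
            acceptor=Interval("chr1", acc_start, acc_end),
            donor=Interval("chr2", *donor),
            overlap=100,
            support=12,
            inverted=False,
        )

    def test_acceptor_within_tolerance_counts_found(self):
        truth = self._truth()
        events = [self._line("A0001", 49_550, 49_750)]  # 250 bp from the point
        report = evaluate_calls(events, truth, tol=300)
        assert report.found == 1 and report.found_with_donor == 1

    def test_acceptor_beyond_tolerance_not_found(self):
        report = evaluate_calls([self._line("A0001", 49_000, 49_400)], self._truth(), tol=300)
        assert report.found == 0

    def test_zero_predictions_gives_undefined_ppv(self):
        report = evaluate_calls([], self._truth(), tol=300)
        assert report.ppv is None and report.sensitivity == 0.0

    def test_duplicate_lines_and_order_do_not_change_counts(self):
        truth = self._truth(2)
        lines = [
            self._line("A0001", 49_900, 50_100),
            self._line("A0001", 49_950, 50_050),  # duplicate candidate line
            self._line("A0002", 79_900, 80_100, donor=(30_000, 34_000)),
        ]
        fwd = evaluate_calls(lines, truth, tol=300)
        rev = evaluate_calls(list(reversed(lines)), list(reversed(truth)), tol=300)
        assert fwd.to_dict() == rev.to_dict()
        assert fwd.n_predictions == 2 and fwd.found_with_donor == 2

    def test_ppv_formula_on_benchmark_scale_counts(self):
        # 300 injected, 351 predicted acceptor sites of which 244 are true
        truth = self._truth(300)
        lines = []
        for i, t in enumerate(truth[:244]):
            lines.append(
                EventCall(
                    acceptor_id=f"T{i:04d}",
                    event_type=EventType.INSERTION_SENSE,
                    acceptor=Interval("chr1", t.acceptor_pos - 50, t.acceptor_pos + 50),
                    donor=t.donor,
                    overlap=10,
                    support=11,
                    inverted=False,
                )
            )
        for i in range(351 - 244):
            lines.append(self._line(f"F{i:04d}", 10_000_000 + i * 5000, 10_000_100 + i * 5000))
        report = evaluate_calls(lines, truth, tol=300)
        assert report.n_predictions == 351
        assert report.true_positive_predictions == 244
        assert round(100 * report.ppv, 1) == 69.5
        assert round(100 * report.sensitivity, 1) == 81.3

    def test_empty_truth_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_calls([], [], tol=300)
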