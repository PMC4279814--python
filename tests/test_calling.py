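"""Event assembly from signature clusters, grid scan and pooling."""

from __future__ import annotations

import pytest

from tetrace.calling import (
    call_events,
    max_detectable_length,
    merge_grid_results,
    run_grid,
)
from tetrace.clustering import partition_points
from tetrace.model import (
    Cluster,
    DiscordantRecord,
    EventCall,
    EventType,
    GridSpec,
    Interval,
    LibraryStats,
    Orient,
    ReadMapping,
    Signature,
)

STATS = LibraryStats(M=4900.0, MAD=100.0)  # d_inf=4600, d_sup=5200


def mk(sig, ia, ib, n, orient=("-", "+"), ca="chr1", cb="chr1"):
    return Cluster(
        signature=sig,
        orient_pair=(Orient(orient[0]), Orient(orient[1])),
        chrom_a=ca,
        chrom_b=cb,
        interval_a=ia,
        interval_b=ib,
        members={f"{sig.value}{ia[0]}_{i}" for i in range(n)},
    )


def call(clusters, **kw):
    kw.setdefault("read_len", 0)
    return call_events(clusters, STATS, **kw)


class TestDetectabilityBounds:
    def test_te_bound_is_twice_the_fragment_length(self):
        assert max_detectable_length(5000, 4900, 100)[0] == 10_000

    def test_translocation_bound_formula(self):
        assert max_detectable_length(5000, 4900, 100)[1] == 10_400

    def test_short_fragment_library_scale(self):
        assert max_detectable_length(150, 140, 10)[0] == 300


class TestCalling:
    def test_sense_insertion_from_del_dup_overlap(self):
        cdel = mk(Signature.DEL, (5000, 5400), (20_000, 24_000), 15)
        cdup = mk(Signature.DUP, (5450, 5800), (22_000, 26_000), 12, orient=("+", "-"))
        events = call([cdel, cdup])
        assert len(events) == 1
        (ev,) = events
        assert ev.event_type is EventType.INSERTION_SENSE
        assert (ev.donor.start, ev.donor.end) == (20_000, 26_000)
        assert ev.overlap == 2000
        assert ev.acceptor == Interval("chr1", 5400, 5450)
        assert ev.support == 27 and not ev.inverted

    def test_lone_del_cluster_with_large_gap_supports_deletion(self):
        cdel = mk(Signature.DEL, (1000, 2000), (10_000, 10_800), 15)
        events = call([cdel])
        assert [e.event_type for e in events] == [EventType.DELETION]
        assert events[0].acceptor.length > STATS.d_inf

    def test_lone_del_cluster_with_small_gap_is_silent(self):
        cdel = mk(Signature.DEL, (1000, 4000), (8_000, 10_800), 15)
        assert call([cdel]) == []

    def test_opposite_inversion_clusters_give_antisense_insertion(self):
        c1 = mk(Signature.INV, (5000, 5400), (20_000, 23_500), 14, orient=("-", "-"))
        c2 = mk(Signature.INV, (5450, 5800), (22_000, 26_000), 11, orient=("+", "+"))
        events = call([c1, c2])
        assert [e.event_type for e in events] == [EventType.INSERTION_ANTISENSE]
        assert events[0].inverted and events[0].overlap == 1500

    def test_same_orientation_inversion_clusters_never_pair(self):
        c1 = mk(Signature.INV, (5000, 5400), (20_000, 23_500), 14, orient=("-", "-"))
        c2 = mk(Signature.INV, (5450, 5800), (22_000, 26_000), 11, orient=("-", "-"))
        assert call([c1, c2]) == []

    def test_interchromosomal_insertion_needs_two_orientations(self):
        c1 = mk(Signature.TRANS, (5000, 5400), (20_000, 24_000), 14, orient=("-", "+"), cb="chr2")
        c2 = mk(Signature.TRANS, (5450, 5800), (22_000, 26_000), 11, orient=("+", "-"), cb="chr2")
        events = call([c1, c2])
        assert [e.event_type for e in events] == [EventType.INSERTION_INTERCHROM]
        assert events[0].donor.chrom == "chr2" and events[0].acceptor.chrom == "chr1"
        assert call([c1]) == []  # a single cluster never yields an insertion

    def test_acceptor_gap_plus_donor_span_bounded_by_translocation_limit(self):
        # donor hull 4 kb, acceptor gap 5.5 kb: 9.5 kb < 2M+6MAD -> called
        cdel = mk(Signature.DEL, (0, 2000), (20_000, 22_000), 15)
        cdup = mk(Signature.DUP, (7500, 9000), (21_000, 24_000), 12, orient=("+", "-"))
        assert len(call([cdel, cdup])) == 1
        # donor hull 4 kb, gap 7 kb: 11 kb > 10.4 kb -> rejected
        cdup2 = mk(Signature.DUP, (9000, 10_500), (21_000, 24_000), 12, orient=("+", "-"))
        assert call([cdel, cdup2]) == []

    def test_candidate_donor_lines_share_acceptor_id(self):
        cdel = mk(Signature.DEL, (5000, 5400), (20_000, 24_000), 15)
        dup_a = mk(Signature.DUP, (5450, 5800), (22_000, 26_000), 12, orient=("+", "-"))
        cdel2 = mk(Signature.DEL, (5000, 5400), (80_000, 84_000), 15)
        dup_b = mk(Signature.DUP, (5450, 5800), (82_000, 86_000), 12, orient=("+", "-"))
        events = call([cdel, dup_a, cdel2, dup_b])
        assert len(events) == 2
        assert len({e.acceptor_id for e in events}) == 1
        assert {e.donor.start for e in events} == {20_000, 80_000}

    def test_companion_del_cluster_flags_cut_and_paste(self):
        cdel = mk(Signature.DEL, (5000, 5400), (20_000, 24_000), 15)
        cdup = mk(Signature.DUP, (5450, 5800), (22_000, 26_000), 12, orient=("+", "-"))
        companion = mk(Signature.DEL, (19_000, 19_500), (27_000, 27_400), 12)
        (ev,) = call([cdel, cdup, companion])[:1]
        assert ev.event_type is EventType.INSERTION_SENSE
        assert ev.companion_del


def _records_for_two_events():
    """Two Del/Dup cluster pairs worth of synthetic discordant records."""
    records = []
    for k, (acc, don) in enumerate([(5000, 20_000), (50_000, 70_000)]):
        for i in range(12):
            records.append(
                DiscordantRecord(
                    f"d{k}_{i}",
                    ReadMapping("chr1", Orient.REV, acc + 30 * i),
                    ReadMapping("chr1", Orient.FWD, don + 30 * i),
                    Signature.DEL,
                )
            )
            records.append(
                DiscordantRecord(
                    f"u{k}_{i}",
                    ReadMapping("chr1", Orient.FWD, acc + 600 + 30 * i),
                    ReadMapping("chr1", Orient.REV, don + 2000 + 30 * i),
                    Signature.DUP,
                )
            )
    return records


class TestGrid:
    def test_default_grid_has_1000_points(self):
        grid = GridSpec()
        assert grid.n_points == 1000
        assert len(grid.points()) == 1000

    def test_singleton_and_small_grids(self):
        assert GridSpec((100,), (500,)).n_points == 1
        assert GridSpec((100, 200), (500, 600)).n_points == 4

    def test_run_grid_keys_every_point(self):
        parts = partition_points(_records_for_two_events())
        grid = GridSpec((100, 200), (500, 1000))
        results = run_grid(parts, grid, STATS, min_support=5, read_len=0)
        assert set(results) == {(100, 500), (100, 1000), (200, 500), (200, 1000)}
        assert all(len(v) == 2 for v in results.values())


def _ev(acc, don, support, etype=EventType.INSERTION_SENSE, acc_id="A0001"):
    return EventCall(
        acceptor_id=acc_id,
        event_type=etype,
        acceptor=Interval("chr1", *acc),
        donor=Interval("chr1", *don),
        overlap=100,
        support=support,
        inverted=False,
    )


class TestGridPooling:
    def test_recurring_event_keeps_highest_support(self):
        per_point = {
            (100, 500): [_ev((5000, 5100), (20_000, 24_000), 12)],
            (200, 1000): [_ev((5020, 5120), (20_100, 24_100), 15)],
        }
        pooled = merge_grid_results(per_point)
        assert len(pooled) == 1 and pooled[0].support == 15

    def test_non_overlapping_event_appended(self):
        per_point = {
            (100, 500): [_ev((5000, 5100), (20_000, 24_000), 12)],
            (200, 1000): [_ev((60_000, 60_100), (80_000, 84_000), 9)],
        }
        pooled = merge_grid_results(per_point)
        assert len(pooled) == 2

    def test_single_contributing_point_passes_through(self):
        events = [_ev((5000, 5100), (20_000, 24_000), 12)]
        per_point = {(100, 500): events, (200, 1000): []}
        pooled = merge_grid_results(per_point)
        assert len(pooled) == 1 and pooled[0].support == 12

    def test_half_overlapping_event_is_not_added(self):
        # same donor, distant acceptor: overlaps the registry on one side
        # only, so it is neither merged nor appended
        per_point = {
            (100, 500): [_ev((5000, 5100), (20_000, 24_000), 12)],
            (200, 1000): [_ev((90_000, 90_100), (20_000, 24_000), 9)],
        }
        pooled = merge_grid_results(per_point)
        assert len(pooled) == 1 and pooled[0].support == 12

    def test_pool_size_at_least_best_single_point(self, e2e):
        best = max(len(v) for v in e2e.per_point.values())
        assert len(e2e.pooled) >= best
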