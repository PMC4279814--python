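"""Assembling signature clusters into transposition events (*Leto* calling).

The geometry behind the calls: when a mobile element shorter than twice the
fragment length inserts somewhere, the read pairs spanning its two
breakpoints form two clusters.  On the donor side (the element's locus of
origin in the reference) the two clusters reach into the element from both
ends and therefore *overlap* over its middle; on the acceptor side they end
close to the insertion point but never overlap, because reads crossing the
exact insertion site stay unmapped.  Demanding this overlap/adjacency
configuration between clusters of compatible signatures is what separates
bona fide transposition events from stray cluster proximity:

* sense intra-chromosomal insertion  = Del cluster x Dup cluster;
* antisense (inverted) insertion     = Inv(-,-) cluster x Inv(+,+) cluster;
* inter-chromosomal insertion        = two Trans clusters of different
  orientation overlapping at the donor;
* plain deletion                     = Del cluster overlapping no Dup
  cluster, with an unsequenced gap larger than d_inf.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Optional, Sequence

from .clustering import ClusterPoint, PartitionKey, cluster_partitions, filter_clusters
from .model import (
    Cluster,
    EventCall,
    EventType,
    GridSpec,
    INSERTION_TYPES,
    Interval,
    LibraryStats,
    LinkThresholds,
    Orient,
    Signature,
)

logger = logging.getLogger(__name__)


def max_detectable_length(L: float, M: float, MAD: float) -> tuple[float, float]:
    """Upper bounds on detectable element and translocation lengths.

    Donor-side clusters can reach at most one fragment length into the
    element from each end, so they stop overlapping for elements longer
    than 2*L (L = mean fragment size).  In insert-size terms the callable
    translocation length is 2*M + 6*MAD.
    """
    if L <= 0 or M <= 0 or MAD < 0:
        raise ValueError("fragment statistics must be positive")
    return 2.0 * L, 2.0 * M + 6.0 * MAD


def _acceptor_hull(sa: Interval, sb: Interval) -> Interval:
    """Hull of the two inner cluster ends: the unsequenced breakpoint gap.

    Widened to one base when the two ends touch, so that candidate-donor
    lines of the same insertion always share an overlappable acceptor.
    """
    if sa.start <= sb.start:
        lo, hi = sa.end, sb.start
    else:
        lo, hi = sb.end, sa.start
    return Interval(sa.chrom, lo, max(hi, lo + 1))


def _pair_geometry(
    c1: Cluster,
    c2: Cluster,
    read_len: int,
    max_span: float,
    acceptor_max_gap: Optional[float] = None,
) -> Optional[tuple[Interval, Interval, int]]:
    """Donor/acceptor geometry of a candidate cluster couple.

    Returns (donor, acceptor, overlap_bp) when the insertion configuration
    holds: one pair of same-letter sides overlaps (donor), the other is
    disjoint with a bounded gap (acceptor).  The gap bound follows from
    fragment geometry: the two acceptor-side inner ends sit one insert
    away from the breakpoint minus how far the donor-side mate reaches
    into the element, so gap + donor span <= 2*d_sup (= the 2M + 6MAD
    callable-translocation bound, ``max_span``).  An explicit
    ``acceptor_max_gap`` further caps the gap when configured.
    """
    a1, b1 = c1.side_a(read_len), c1.side_b(read_len)
    a2, b2 = c2.side_a(read_len), c2.side_b(read_len)

    def check(d1: Interval, d2: Interval, s1: Interval, s2: Interval):
        if not d1.overlaps(d2) or s1.overlaps(s2):
            return None
        donor = d1.hull(d2)
        gap = s1.gap_to(s2)
        limit = max_span - donor.length
        if acceptor_max_gap is not None:
            limit = min(limit, acceptor_max_gap)
        if gap is None or gap > limit:
            return None
        return donor, _acceptor_hull(s1, s2), d1.overlap_bp(d2)

    candidates = [
        g
        for g in (check(a1, a2, b1, b2), check(b1, b2, a1, a2))
        if g is not None
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda t: t[2])


def call_events(
    clusters: Sequence[Cluster],
    stats: LibraryStats,
    acceptor_max_gap: Optional[float] = None,
    read_len: int = 100,
) -> list[EventCall]:
    """Assemble filtered clusters into transposition/deletion calls.

    The acceptor-side gap is bounded by fragment geometry (gap + donor
    span <= 2M + 6MAD); pass ``acceptor_max_gap`` to cap it further.
    """
    _, trans_bound = max_detectable_length(max(stats.M, 1.0), stats.M, stats.MAD)

    dels = [c for c in clusters if c.signature is Signature.DEL]
    dups = [c for c in clusters if c.signature is Signature.DUP]
    invs = [c for c in clusters if c.signature is Signature.INV]
    trans = [c for c in clusters if c.signature is Signature.TRANS]

    events: list[EventCall] = []
    paired_dels: set[int] = set()

    def emit(c1, c2, etype, inverted):
        geom = _pair_geometry(c1, c2, read_len, trans_bound, acceptor_max_gap)
        if geom is None:
            return False
        donor, acceptor, overlap = geom
        if donor.length > trans_bound:
            return False
        events.append(
            EventCall(
                acceptor_id="",
                event_type=etype,
                acceptor=acceptor,
                donor=donor,
                overlap=overlap,
                support=c1.support + c2.support,
                inverted=inverted,
            )
        )
        return True

    # (i) sense intra-chromosomal insertions: Del x Dup
    for i, cdel in enumerate(dels):
        for cdup in dups:
            if cdel.chrom_a != cdup.chrom_a:
                continue
            if emit(cdel, cdup, EventType.INSERTION_SENSE, inverted=False):
                paired_dels.add(i)

    # (ii) antisense: two Inv clusters of opposite orientation
    minus = [c for c in invs if c.orient_pair == (Orient.REV, Orient.REV)]
    plus = [c for c in invs if c.orient_pair == (Orient.FWD, Orient.FWD)]
    for c1, c2 in itertools.product(minus, plus):
        if c1.chrom_a != c2.chrom_a:
            continue
        emit(c1, c2, EventType.INSERTION_ANTISENSE, inverted=True)

    # (iii) inter-chromosomal: two Trans clusters of different orientation
    for c1, c2 in itertools.combinations(trans, 2):
        if (c1.chrom_a, c1.chrom_b) != (c2.chrom_a, c2.chrom_b):
            continue
        if c1.orient_pair == c2.orient_pair:
            continue
        inverted = c1.orient_pair[0] == c1.orient_pair[1]
        emit(c1, c2, EventType.INSERTION_INTERCHROM, inverted=inverted)

    # companion Del cluster around a donor: cut-and-paste advisory
    for ev in events:
        for i, cdel in enumerate(dels):
            if i in paired_dels:
                continue
            hull = Interval(cdel.chrom_a, cdel.interval_a[0], cdel.interval_b[1] + read_len)
            if hull.chrom == ev.donor.chrom and hull.overlaps(ev.donor):
                ev.companion_del = True
                break

    # (iv) deletions: Del cluster overlapping no Dup cluster
    for i, cdel in enumerate(dels):
        if i in paired_dels:
            continue
        sa, sb = cdel.side_a(read_len), cdel.side_b(read_len)
        touches_dup = any(
            cdup.chrom_a == cdel.chrom_a
            and (
                sa.overlaps(cdup.side_a(read_len))
                or sa.overlaps(cdup.side_b(read_len))
                or sb.overlaps(cdup.side_a(read_len))
                or sb.overlaps(cdup.side_b(read_len))
            )
            for cdup in dups
        )
        if touches_dup:
            continue
        gap = Interval(cdel.chrom_a, sa.end, max(sb.start, sa.end))
        if gap.length > stats.d_inf:
            events.append(
                EventCall(
                    acceptor_id="",
                    event_type=EventType.DELETION,
                    acceptor=gap,
                    donor=gap,
                    overlap=0,
                    support=cdel.support,
                    inverted=False,
                )
            )

    assign_acceptor_ids(events)
    return events


def assign_acceptor_ids(events: list[EventCall]) -> None:
    """Group calls whose acceptor intervals overlap under one acceptor id.

    Lines referring to different donor candidates of the same insertion
    share the id; ids are deterministic (sorted by acceptor coordinate).
    """
    order = sorted(
        range(len(events)),
        key=lambda i: (
            events[i].acceptor.chrom,
            events[i].acceptor.start,
            events[i].acceptor.end,
            events[i].donor.chrom,
            events[i].donor.start,
        ),
    )
    current = 0
    last: Optional[Interval] = None
    for i in order:
        acc = events[i].acceptor
        if last is None or not (
            acc.chrom == last.chrom and acc.start < last.end and last.start < acc.end
        ):
            current += 1
            last = acc
        else:
            last = Interval(last.chrom, min(last.start, acc.start), max(last.end, acc.end))
        events[i].acceptor_id = f"A{current:04d}"


def run_grid(
    partitions: Mapping[PartitionKey, list[ClusterPoint]],
    grid: GridSpec,
    stats: LibraryStats,
    min_support: int = 10,
    acceptor_max_gap: Optional[float] = None,
    merge_gap: Optional[int] = None,
    read_len: int = 100,
) -> dict[tuple[int, int], list[EventCall]]:
    """One complete cluster+call pass per grid point.

    Grid points are independent; sequential execution keeps results
    deterministic.
    """
    results: dict[tuple[int, int], list[EventCall]] = {}
    for t in grid.points():
        clusters = cluster_partitions(partitions, t, merge_gap, max_span=stats.d_sup)
        kept = filter_clusters(clusters, stats, min_support)
        results[(t.x, t.y)] = call_events(kept, stats, acceptor_max_gap, read_len)
    return results


def _n_insertions(events: Sequence[EventCall]) -> int:
    return len(
        {e.acceptor_id for e in events if e.event_type in INSERTION_TYPES}
    )


def merge_grid_results(
    per_point: Mapping[tuple[int, int], Sequence[EventCall]]
) -> list[EventCall]:
    """Pool the events found across the (X, Y) grid.

    A registry is seeded from the grid point with the largest number of
    insertions (distinct acceptor sites; ties broken by total support,
    then by (X, Y) order).  Every other point's events join the registry
    only when they overlap no registry event on either donor or acceptor
    side; a recurrence of the same event (overlap on both sides) keeps the
    instance with the most supporting reads, so each insertion is reported
    under its optimal clustering parameters.
    """
    if not per_point:
        raise ValueError("no grid results to merge")
    keys = sorted(per_point)
    seed = max(
        keys,
        key=lambda k: (
            _n_insertions(per_point[k]),
            sum(e.support for e in per_point[k]),
            (-k[0], -k[1]),
        ),
    )
    registry = [
        EventCall(**{**e.__dict__}) for e in per_point[seed]
    ]
    for k in keys:
        if k == seed:
            continue
        for ev in per_point[k]:
            both, either = None, False
            for i, reg in enumerate(registry):
                d = ev.donor.overlaps(reg.donor)
                a = ev.acceptor.overlaps(reg.acceptor)
                if d and a and ev.event_type == reg.event_type:
                    both = i
                    break
                if d or a:
                    either = True
            if both is not None:
                if ev.support > registry[both].support:
                    registry[both] = EventCall(**{**ev.__dict__})
            elif not either:
                registry.append(EventCall(**{**ev.__dict__}))
    assign_acceptor_ids(registry)
    registry.sort(
        key=lambda e: (e.acceptor.chrom, e.acceptor.start, e.donor.chrom, e.donor.start)
    )
    return registry
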