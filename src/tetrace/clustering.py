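"""Single-linkage clustering of discordant pair mappings (the *Leto* core).

Discordant records are partitioned by orientation couple, chromosome pair
and signature, then clustered in the two-coordinate mate-position space
(la = sorted-mate coordinate, lb = unsorted-mate coordinate).  Two points
link when they are within X on the la axis AND within Y on the lb axis;
clusters are the connected components of that proximity graph.  Because the
points arrive sorted by la, a seeded linear scan with a sliding la-window
recovers the exact components without holding the full graph in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import (
    Cluster,
    DiscordantRecord,
    LibraryStats,
    LinkThresholds,
    Orient,
    Signature,
)


@dataclass(frozen=True)
class ClusterPoint:
    """One discordant pair mapping as a point in mate-position space."""

    la: int
    lb: int
    pair_id: str


PartitionKey = tuple[Signature, str, str, Orient, Orient]


def partition_points(
    records: Iterable[DiscordantRecord],
) -> dict[PartitionKey, list[ClusterPoint]]:
    """Subdivide records into independent clustering chunks.

    The key is (signature, chromosome couple, orientation couple): only
    same-signature points on the same chromosome pair mapped in the same
    orientation can ever support one event, so each chunk is clustered
    independently (and performance scales with per-chromosome, not whole
    genome, read counts).  With k chromosomes and four orientation couples
    this yields at most 4 * C(k+1, 2) chunks plus a same-orientation split
    of the proper-orientation chunk into Del and Ins.
    """
    parts: dict[PartitionKey, list[ClusterPoint]] = {}
    for rec in records:
        key = (rec.signature, rec.a.chrom, rec.b.chrom, rec.a.orient, rec.b.orient)
        parts.setdefault(key, []).append(ClusterPoint(rec.a.pos, rec.b.pos, rec.pair_id))
    for pts in parts.values():
        pts.sort(key=lambda p: (p.la, p.lb, p.pair_id))
    return parts


def _clusters_from_components(
    points: Sequence[ClusterPoint],
    labels: Sequence[int],
    key: PartitionKey,
) -> list[Cluster]:
    sig, ca, cb, oa, ob = key
    groups: dict[int, list[ClusterPoint]] = {}
    for pt, lab in zip(points, labels):
        groups.setdefault(lab, []).append(pt)
    out = []
    for pts in groups.values():
        out.append(
            Cluster(
                signature=sig,
                orient_pair=(oa, ob),
                chrom_a=ca,
                chrom_b=cb,
                interval_a=(min(p.la for p in pts), max(p.la for p in pts)),
                interval_b=(min(p.lb for p in pts), max(p.lb for p in pts)),
                members={p.pair_id for p in pts},
            )
        )
    out.sort(key=lambda c: (c.interval_a, c.interval_b))
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def single_linkage_cluster(
    points: Sequence[ClusterPoint],
    thresholds: LinkThresholds,
    key: PartitionKey = (Signature.DEL, ".", ".", Orient.REV, Orient.FWD),
) -> list[Cluster]:
    """Exact single-linkage components of one partition.

    Points must be sorted by la.  The scan keeps a window of points within
    X on the la axis (the seed trail): each new point is linked against the
    window only, which is sufficient because la-distances beyond X can
    never link, making the windowed scan equivalent to the brute-force
    transitive closure over all pairs.
    """
    pts = list(points)
    if not pts:
        return []
    if any(pts[i].la > pts[i + 1].la for i in range(len(pts) - 1)):
        pts.sort(key=lambda p: (p.la, p.lb, p.pair_id))
    uf = _UnionFind(len(pts))
    window_start = 0
    for i in range(1, len(pts)):
        while pts[i].la - pts[window_start].la > thresholds.x:
            window_start += 1
        for j in range(window_start, i):
            if abs(pts[i].lb - pts[j].lb) <= thresholds.y:
                uf.union(i, j)
    labels = [uf.find(i) for i in range(len(pts))]
    return _clusters_from_components(pts, labels, key)


def merge_clusters(
    clusters: Sequence[Cluster], gap: int, max_span: float | None = None
) -> list[Cluster]:
    """Merge nearby same-signature clusters (transitively, idempotently).

    Two clusters merge when the gaps between their interval hulls are at
    most ``gap`` on both axes; this repairs clusters split by local drops
    in coverage.  Signatures (and orientation couples / chromosome pairs)
    must be identical, so the caller may pass one partition's clusters or a
    mixed set.  When ``max_span`` is given, a merge whose result would
    exceed it on either axis is abandoned and the components kept apart:
    merging repairs coverage splits, it must never turn valid clusters
    into one that the d_sup size filter would then reject.
    """
    cl = list(clusters)
    if not cl:
        return []
    uf = _UnionFind(len(cl))
    for i in range(len(cl)):
        for j in range(i + 1, len(cl)):
            a, b = cl[i], cl[j]
            if (
                a.signature != b.signature
                or a.orient_pair != b.orient_pair
                or a.chrom_a != b.chrom_a
                or a.chrom_b != b.chrom_b
            ):
                continue
            gap_a = max(
                0,
                max(a.interval_a[0], b.interval_a[0])
                - min(a.interval_a[1], b.interval_a[1]),
            )
            gap_b = max(
                0,
                max(a.interval_b[0], b.interval_b[0])
                - min(a.interval_b[1], b.interval_b[1]),
            )
            if gap_a <= gap and gap_b <= gap:
                uf.union(i, j)
    groups: dict[int, list[Cluster]] = {}
    for i, c in enumerate(cl):
        groups.setdefault(uf.find(i), []).append(c)
    out = []
    for grp in groups.values():
        ia = (min(c.interval_a[0] for c in grp), max(c.interval_a[1] for c in grp))
        ib = (min(c.interval_b[0] for c in grp), max(c.interval_b[1] for c in grp))
        if (
            max_span is not None
            and len(grp) > 1
            and (ia[1] - ia[0] > max_span or ib[1] - ib[0] > max_span)
        ):
            out.extend(grp)
            continue
        base = grp[0]
        members: set[str] = set()
        for c in grp:
            members |= c.members
        out.append(
            Cluster(
                signature=base.signature,
                orient_pair=base.orient_pair,
                chrom_a=base.chrom_a,
                chrom_b=base.chrom_b,
                interval_a=ia,
                interval_b=ib,
                members=members,
            )
        )
    out.sort(key=lambda c: (c.chrom_a, c.chrom_b, c.interval_a, c.signature.value))
    return out


def filter_clusters(
    clusters: Iterable[Cluster],
    stats: LibraryStats,
    min_support: int = 10,
) -> list[Cluster]:
    """Reject clusters larger than d_sup on either axis or weakly supported.

    Reads around one breakpoint can only be dispersed by as much as the
    insert-size distribution allows, so a span beyond d_sup on the sorted-
    or unsorted-mate side cannot come from a single event.
    """
    out = [
        c
        for c in clusters
        if c.span_a <= stats.d_sup and c.span_b <= stats.d_sup and c.support >= min_support
    ]
    out.sort(key=lambda c: (c.chrom_a, c.chrom_b, c.interval_a, c.signature.value))
    return out


def cluster_partitions(
    partitions: dict[PartitionKey, list[ClusterPoint]],
    thresholds: LinkThresholds,
    merge_gap: int | None = None,
    max_span: float | None = None,
) -> list[Cluster]:
    """Cluster every partition, then merge neighbours within each.

    ``merge_gap`` defaults to the current Y threshold: the same insert-size
    dispersion that motivates Y bounds how far a coverage drop can split a
    cluster.  ``max_span`` (normally d_sup) guards the merge against
    producing clusters the size filter would reject.
    """
    gap = thresholds.y if merge_gap is None else merge_gap
    out: list[Cluster] = []
    for key in sorted(partitions, key=lambda k: (k[0].value, k[1], k[2], k[3].value, k[4].value)):
        clusters = single_linkage_cluster(partitions[key], thresholds, key)
        out.extend(merge_clusters(clusters, gap, max_span))
    return out
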