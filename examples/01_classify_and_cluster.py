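"""Classify discordant pair mappings and cluster them in mate space.

Builds a handful of pair mappings against a mate-pair library with median
insert M = 5000 and MAD = 100, classifies each against the discordance
rules, then single-linkage-clusters a small set of breakpoint points.
"""

from tetrace import (
    LibraryStats,
    LinkThresholds,
    Orient,
    PairMapping,
    ReadMapping,
    classify_pair_mapping,
    single_linkage_cluster,
)
from tetrace.clustering import ClusterPoint

stats = LibraryStats(M=5000, MAD=100)
print(f"concordance window: ({stats.d_inf:.0f}, {stats.d_sup:.0f})")

cases = {
    "proper pair": (("chr1", "-", 1000), ("chr1", "+", 6100)),
    "insert too large": (("chr1", "-", 1000), ("chr1", "+", 21000)),
    "insert too small": (("chr1", "-", 1000), ("chr1", "+", 2100)),
    "reversed orientation": (("chr1", "+", 1000), ("chr1", "-", 6100)),
    "equal strands": (("chr1", "+", 1000), ("chr1", "+", 6100)),
    "two chromosomes": (("chr1", "-", 1000), ("chr2", "+", 6100)),
}
for label, (a, b) in cases.items():
    p = PairMapping.make(
        ReadMapping(a[0], Orient(a[1]), a[2]), ReadMapping(b[0], Orient(b[1]), b[2])
    )
    sig = classify_pair_mapping(p, stats)
    print(f"{label:22s} -> {sig.value}")

# three points chain into one cluster through the middle point; a fourth
# is too far on the unsorted-mate axis and stays alone
points = [
    ClusterPoint(1000, 9000, "p1"),
    ClusterPoint(1050, 9200, "p2"),
    ClusterPoint(1120, 9600, "p3"),
    ClusterPoint(1130, 12_000, "p4"),
]
clusters = single_linkage_cluster(points, LinkThresholds(x=100, y=500))
print(f"\n{len(clusters)} clusters from {len(points)} points (X=100, Y=500):")
for c in clusters:
    print(f"  members={sorted(c.members)} la={c.interval_a} lb={c.interval_b}")
# The Del/Ins/Dup/Inv/Trans signature tells which rearrangement a pair
# supports; clusters of same-signature pairs are the unit evidence the
# caller assembles into transposition events.
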