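"""Exact-placement alignments for simulated mate-pair libraries.

Sequencing fragments are sampled from the *modified* genome; every read is
then placed on the *reference* by construction, using the injector's
piecewise coordinate map instead of an aligner: a read falling inside one
map segment gets the corresponding reference locus (strand composed with
the segment's), a read straddling a segment junction -- i.e. an insertion
breakpoint -- stays unmapped, exactly as breakpoint-crossing reads do in
practice.  Reads landing inside a repeat-family copy additionally receive
one mapping per family member, with the edit distance implied by the
substitutions the read covers.  The result is a deterministic,
coordinate-sorted SAM with NM tags and secondary records, suitable as a
noiseless stand-in for a real alignment.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from ..model import Interval
from .genome import HomologyGroup, Segment, TruthTable, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Placement:
    chrom: str
    pos: int
    reverse: bool
    nm: int


def _locate_segment(segs: Sequence[Segment], start: int, end: int) -> Optional[Segment]:
    i = bisect_right([s.mod_start for s in segs], start) - 1
    if i < 0:
        return None
    s = segs[i]
    if start >= s.mod_start and end <= s.mod_end:
        return s
    return None


class TruthPlacer:
    """Maps modified-genome read intervals to reference placements."""

    def __init__(self, truth: TruthTable, groups: Sequence[HomologyGroup] = ()):
        self.truth = truth
        self.groups = list(groups)
        self._member_index: list[tuple[str, int, int, int, int]] = []
        for gi, g in enumerate(self.groups):
            for mi, m in enumerate(g.members):
                self._member_index.append((m.chrom, m.start, m.end, gi, mi))

    def place_read(
        self, mod_chrom: str, start: int, end: int, reverse: bool
    ) -> list[Placement]:
        """All placements of the read at modified [start, end); [] = unmapped."""
        seg = _locate_segment(self.truth.segments[mod_chrom], start, end)
        if seg is None:
            return []
        chrom, s, e, flip = seg.map_interval(start, end)
        rev = reverse != flip
        placements = [Placement(chrom, s, rev, 0)]
        # homology expansion: read fully inside a family member
        for mc, ms, me, gi, mi in self._member_index:
            if chrom == mc and ms <= s and e <= me:
                g = self.groups[gi]
                off0, off1 = s - ms, e - ms
                for mj, other in enumerate(g.members):
                    if mj == mi:
                        continue
                    nm = g.pairwise_mismatches(mi, mj, off0, off1)
                    placements.append(
                        Placement(other.chrom, other.start + off0, rev, nm)
                    )
                break
        return placements


@dataclass
class PlacementCounters:
    pairs: int = 0
    written_pairs: int = 0
    junction_pairs: int = 0


def _generate_placed_pairs(
    truth: TruthTable,
    placer: TruthPlacer,
    coverage: float,
    mean_frag: int,
    sd_frag: float,
    read_len: int,
    seed: int,
    counters: PlacementCounters,
):
    """Yield (qname, mate1 placements, mate2 placements) for sampled pairs.

    Fragments are uniform on the modified genome with truncated-normal
    sizes; the left mate is on the reverse strand (large-insert
    convention).  Pairs with a junction-crossing mate are counted and
    skipped.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(truth.modified)
    lengths = np.array([len(truth.modified[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    n_frags = int(round(total * coverage / (2 * read_len)))
    chrom_draw = rng.choice(len(chroms), size=n_frags, p=lengths / total)
    sizes = np.clip(
        np.round(rng.normal(mean_frag, sd_frag, size=n_frags)), 2 * read_len + 50, None
    ).astype(int)
    u = rng.random(n_frags)
    for i in range(n_frags):
        counters.pairs += 1
        c = chroms[chrom_draw[i]]
        clen = len(truth.modified[c])
        size = min(int(sizes[i]), clen)
        f0 = int(u[i] * (clen - size + 1))
        mates = (
            (f0, f0 + read_len, True),
            (f0 + size - read_len, f0 + size, False),
        )
        placed = [placer.place_read(c, s, e, rev) for s, e, rev in mates]
        if not placed[0] or not placed[1]:
            counters.junction_pairs += 1
            continue
        counters.written_pairs += 1
        yield f"sim{i:07d}", placed[0], placed[1]


def simulate_fragment_mappings(
    truth: TruthTable,
    groups: Sequence[HomologyGroup] = (),
    coverage: float = 20.0,
    mean_frag: int = 3000,
    sd_frag: float = 222.0,
    read_len: int = 100,
    seed: int = 0,
):
    """In-memory equivalent of the SAM path: per-fragment mapping sets.

    Returns ``(fragments, counters)`` where fragments maps pair id to a
    :class:`tetrace.discord.FragmentMappings`, ready for discordant
    extraction without the SAM round trip.
    """
    from ..discord import FragmentMappings
    from ..model import Orient, ReadMapping

    placer = TruthPlacer(truth, groups)
    counters = PlacementCounters()
    fragments = {}
    for qname, p1, p2 in _generate_placed_pairs(
        truth, placer, coverage, mean_frag, sd_frag, read_len, seed, counters
    ):
        def conv(plist):
            return [
                ReadMapping(
                    chrom=p.chrom,
                    orient=Orient.REV if p.reverse else Orient.FWD,
                    pos=p.pos,
                    mismatches=p.nm,
                )
                for p in plist
            ]

        fragments[qname] = FragmentMappings(qname, conv(p1), conv(p2))
    return fragments, counters


def simulate_exact_placement_sam(
    truth: TruthTable,
    reference: dict[str, str],
    out_sam: str,
    groups: Sequence[HomologyGroup] = (),
    coverage: float = 20.0,
    mean_frag: int = 3000,
    sd_frag: float = 222.0,
    read_len: int = 100,
    seed: int = 0,
    max_mappings: int = 50,
) -> PlacementCounters:
    """Sample fragments from the modified genome and write placed reads.

    Fragments are uniform on the modified genome with normal sizes
    (sd 222 bp gives an insert-size MAD of about 150 bp); mates are taken
    from the two fragment ends in the large-insert convention, i.e. the
    left mate on the reverse strand.  ``coverage`` is read-depth coverage
    (2 * read_len bases per fragment).  Pairs with a junction-crossing
    (unmappable) mate are dropped with a counter, mirroring what an
    aligner reports as single reads.
    """
    placer = TruthPlacer(truth, groups)
    counters = PlacementCounters()

    ref_names = sorted(reference)
    ref_idx = {c: i for i, c in enumerate(ref_names)}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(reference[c])} for c in ref_names],
        }
    )

    # (chrom_idx, pos, qname, flag, nm, seq) per record; sorted before writing
    records: list[tuple[int, int, str, int, int, str, int, int]] = []

    for qname, p1, p2 in _generate_placed_pairs(
        truth, placer, coverage, mean_frag, sd_frag, read_len, seed, counters
    ):
        placed = (p1, p2)
        for mate_i, plist in enumerate(placed):
            plist = plist[:max_mappings]
            primary = plist[0]
            mate_primary = placed[1 - mate_i][0]
            for k, p in enumerate(plist):
                flag = 0x1  # paired
                flag |= 0x40 if mate_i == 0 else 0x80
                if p.reverse:
                    flag |= 0x10
                if mate_primary.reverse:
                    flag |= 0x20
                if k > 0:
                    flag |= 0x100
                # SEQ is stored on the forward reference strand; error-free
                # reads match the reference exactly at their primary locus
                seq = reference[p.chrom][p.pos : p.pos + read_len] if k == 0 else ""
                records.append(
                    (
                        ref_idx[p.chrom],
                        p.pos,
                        qname,
                        flag,
                        p.nm,
                        seq,
                        ref_idx[mate_primary.chrom],
                        mate_primary.pos,
                    )
                )

    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        for tid, pos, qname, flag, nm, seq, mtid, mpos in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = 37 if not (flag & 0x100) else 0
            a.cigarstring = f"{read_len}M"
            a.next_reference_id = mtid
            a.next_reference_start = mpos
            a.template_length = 0
            if seq:
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("NM", nm)
            out.write(a)
    logger.info(
        "placed %d/%d pairs (%d junction-crossing dropped)",
        counters.written_pairs,
        counters.pairs,
        counters.junction_pairs,
    )
    return counters
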