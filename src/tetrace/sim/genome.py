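"""Synthetic genomes and the transposition-event injector.

The generator emulates a small plant-like situation: a multi-chromosome
genome carrying annotated transposable elements, among them one family of
three near-identical members (two byte-identical copies and one diverged
by a handful of substitutions) -- the configuration that makes donor
attribution hard -- plus blocks of contiguous elements that can mobilise
as one composite unit.

The injector copy-and-pastes donor spans into acceptor positions
(reverse-complementing inverted events and duplicating a short target-site
sequence on both sides of the insertion) and records a truth table plus a
piecewise coordinate map from the modified genome back to the reference,
which downstream code uses for exact-placement alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..model import Interval

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

EVENT_CLASSES = ("normal", "composite", "long", "short")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# homology bookkeeping


@dataclass(frozen=True)
class HomologyMember:
    """One copy of a repeat family: interval plus its private substitutions
    (offset -> base, relative to the family consensus)."""

    chrom: str
    start: int
    end: int
    diffs: tuple[tuple[int, str], ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HomologyGroup:
    """A family of same-length, near-identical repeat copies."""

    name: str
    members: list[HomologyMember]

    def pairwise_mismatches(self, i: int, j: int, off0: int, off1: int) -> int:
        """Mismatches between copies i and j over offsets [off0, off1)."""
        di = dict(self.members[i].diffs)
        dj = dict(self.members[j].diffs)
        n = 0
        for off in set(di) | set(dj):
            if off0 <= off < off1 and di.get(off) != dj.get(off):
                n += 1
        return n


# ---------------------------------------------------------------------------
# planned events and truth table


@dataclass
class PlannedEvent:
    """Ground truth for one injected transposition event.

    ``donor`` and ``acceptor_pos`` are reference coordinates; after
    injection ``acceptor_pos_mod`` holds the start of the inserted block in
    the modified genome.
    """

    event_class: str
    donor: Interval
    acceptor_chrom: str
    acceptor_pos: int
    inverted: bool = False
    tsd_len: int = 5
    acceptor_pos_mod: int = -1

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")


@dataclass(frozen=True)
class Segment:
    """Piece of a modified chromosome mapped back to reference coordinates.

    Covers modified [mod_start, mod_end); the source is reference
    [src_start, src_start + length) on ``src_chrom``, reverse-complemented
    when strand is '-'.
    """

    mod_start: int
    mod_end: int
    src_chrom: str
    src_start: int
    strand: str = "+"

    def map_interval(self, start: int, end: int) -> tuple[str, int, int, bool]:
        """Map modified [start, end) (inside this segment) to the reference.

        Returns (chrom, src_start, src_end, flip_strand).
        """
        if not (self.mod_start <= start and end <= self.mod_end):
            raise ValueError("interval not contained in segment")
        if self.strand == "+":
            off = start - self.mod_start
            return (self.src_chrom, self.src_start + off, self.src_start + (end - self.mod_start), False)
        off = self.mod_end - end
        return (self.src_chrom, self.src_start + off, self.src_start + off + (end - start), True)


@dataclass
class TruthTable:
    """Injected events, the modified genome, and its coordinate map."""

    events: list[PlannedEvent]
    modified: dict[str, str]
    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "event_class\tdonor_chrom\tdonor_start\tdonor_end\t"
                "acceptor_chrom\tacceptor_pos\tinverted\ttsd_len\n"
            )
            for e in self.events:
                fh.write(
                    f"{e.event_class}\t{e.donor.chrom}\t{e.donor.start + 1}\t{e.donor.end}\t"
                    f"{e.acceptor_chrom}\t{e.acceptor_pos + 1}\t{int(e.inverted)}\t{e.tsd_len}\n"
                )


def read_truth_tsv(path: str) -> list[PlannedEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cls, dc, ds, de, ac, ap, inv, tsd = line.rstrip("\n").split("\t")
            events.append(
                PlannedEvent(
                    event_class=cls,
                    donor=Interval(dc, int(ds) - 1, int(de)),
                    acceptor_chrom=ac,
                    acceptor_pos=int(ap) - 1,
                    inverted=bool(int(inv)),
                    tsd_len=int(tsd),
                )
            )
    return events


# ---------------------------------------------------------------------------
# synthetic genome


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@dataclass
class SyntheticGenome:
    seqs: dict[str, str]
    annotation: list[tuple[Interval, str]]
    groups: list[HomologyGroup]
    composite_blocks: list[tuple[Interval, ...]]  # contiguous TE runs


def make_synthetic_genome(
    seed: int = 0,
    chrom_lengths: Optional[dict[str, int]] = None,
    family_copy_len: int = 3000,
    family_substitutions: int = 5,
    n_singletons: int = 6,
    n_composite_blocks: int = 3,
) -> SyntheticGenome:
    """Build a genome with planted TE annotation.

    Plants one family of three ``family_copy_len`` copies (two identical,
    one carrying ``family_substitutions`` private substitutions), a few
    singleton elements of 1.5-2.5 kb and ``n_composite_blocks`` runs of
    two contiguous elements (the donors of composite events).  Elements
    are spaced far enough apart that their flanks map uniquely.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 1_000_000, "chr2": 1_000_000}
    rng = np.random.default_rng(seed)
    seqs = {c: np.array(list(_random_seq(rng, n))) for c, n in chrom_lengths.items()}
    chroms = sorted(chrom_lengths)
    annotation: list[tuple[Interval, str]] = []
    composite_blocks: list[tuple[Interval, ...]] = []

    # evenly spread planting slots, sized to fit every planted element
    n_needed = 3 + n_singletons + n_composite_blocks
    margin = min(40_000, min(chrom_lengths.values()) // 10)
    usable = sum(max(0, l - 2 * margin - 10_000) for l in chrom_lengths.values())
    spacing = max(family_copy_len + 8_000, usable // (n_needed + 1))
    slots: list[tuple[str, int]] = []
    for c in chroms:
        pos = margin
        while pos + 10_000 < chrom_lengths[c] - margin:
            slots.append((c, pos))
            pos += spacing
    if len(slots) < n_needed:
        raise ValueError(
            f"genome too small to plant {n_needed} elements "
            f"({len(slots)} slots of {spacing} bp)"
        )
    rng.shuffle(slots)
    slot_iter = iter(slots)

    def plant(seq_str: str) -> tuple[str, int]:
        c, pos = next(slot_iter)
        arr = seqs[c]
        arr[pos : pos + len(seq_str)] = list(seq_str)
        return c, pos

    # the near-identical family
    fam_seq = _random_seq(rng, family_copy_len)
    members = []
    sub_offsets = np.sort(
        rng.choice(
            np.arange(200, family_copy_len - 200), size=family_substitutions, replace=False
        )
    )
    for i in range(3):
        if i < 2:
            copy_seq, diffs = fam_seq, ()
        else:
            arr = np.array(list(fam_seq))
            d = []
            for off in sub_offsets:
                old = arr[off]
                new = rng.choice([b for b in "ACGT" if b != old])
                arr[off] = new
                d.append((int(off), str(new)))
            copy_seq, diffs = "".join(arr), tuple(d)
        c, pos = plant(copy_seq)
        members.append(HomologyMember(c, pos, pos + family_copy_len, diffs))
        annotation.append((Interval(c, pos, pos + family_copy_len), f"FAM_{i + 1}"))
    groups = [HomologyGroup("FAM", members)]

    # singleton elements
    for i in range(n_singletons):
        te_len = int(rng.integers(1500, 2500))
        c, pos = plant(_random_seq(rng, te_len))
        annotation.append((Interval(c, pos, pos + te_len), f"TE_{i + 1}"))

    # contiguous blocks of two elements (composite donors)
    for i in range(n_composite_blocks):
        l1 = int(rng.integers(900, 1200))
        l2 = int(rng.integers(900, 1200))
        gap = int(rng.integers(0, 60))
        c, pos = plant(_random_seq(rng, l1 + gap + l2))
        iv1 = Interval(c, pos, pos + l1)
        iv2 = Interval(c, pos + l1 + gap, pos + l1 + gap + l2)
        annotation.append((iv1, f"BLK{i + 1}_A"))
        annotation.append((iv2, f"BLK{i + 1}_B"))
        composite_blocks.append((iv1, iv2))

    annotation.sort(key=lambda t: (t[0].chrom, t[0].start))
    return SyntheticGenome(
        seqs={c: "".join(a) for c, a in seqs.items()},
        annotation=annotation,
        groups=groups,
        composite_blocks=composite_blocks,
    )


# ---------------------------------------------------------------------------
# event planning


def plan_events(
    genome: SyntheticGenome,
    n_per_class: int = 5,
    seed: int = 0,
    tsd_len: int = 5,
    inverted_fraction: float = 0.4,
    max_donor_len: Optional[int] = None,
    long_flank_range: tuple[int, int] = (100, 1000),
    short_fraction_range: tuple[float, float] = (0.3, 0.7),
    acceptor_margin: int = 8_000,
) -> list[PlannedEvent]:
    """Draw a seeded plan of injections, ``n_per_class`` for each class.

    normal: the exact span of an annotated element; composite: the hull of
    a contiguous two-element block; long: an element plus a uniform
    100-1000 bp flank on each side; short: a uniform 30-70% interior
    sub-span.  Acceptor positions keep ``acceptor_margin`` away from every
    annotated element, donor span and other acceptor.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.seqs)
    lengths = {c: len(s) for c, s in genome.seqs.items()}
    singles = [
        (iv, name)
        for iv, name in genome.annotation
        if not name.startswith(("BLK",))
    ]

    donors: list[tuple[str, Interval]] = []
    fam_ivs = [Interval(m.chrom, m.start, m.end) for m in genome.groups[0].members]
    for k in range(n_per_class):
        # normal: cycle family copies first so donor scoring has work to do
        if k < len(fam_ivs):
            donors.append(("normal", fam_ivs[k]))
        else:
            iv, _ = singles[int(rng.integers(0, len(singles)))]
            donors.append(("normal", iv))
    for k in range(n_per_class):
        iv1, iv2 = genome.composite_blocks[k % len(genome.composite_blocks)]
        donors.append(("composite", iv1.hull(iv2)))
    for k in range(n_per_class):
        iv, _ = singles[int(rng.integers(0, len(singles)))]
        lf = int(rng.integers(*long_flank_range))
        rf = int(rng.integers(*long_flank_range))
        donors.append(
            ("long", Interval(iv.chrom, max(0, iv.start - lf), min(lengths[iv.chrom], iv.end + rf)))
        )
    for k in range(n_per_class):
        iv, _ = singles[int(rng.integers(0, len(singles)))]
        frac = rng.uniform(*short_fraction_range)
        sub_len = max(400, int(iv.length * frac))
        off = int(rng.integers(0, iv.length - sub_len))
        donors.append(("short", Interval(iv.chrom, iv.start + off, iv.start + off + sub_len)))

    if max_donor_len is not None:
        for cls, iv in donors:
            if iv.length > max_donor_len:
                raise ValueError(f"{cls} donor of {iv.length} bp exceeds {max_donor_len}")

    # acceptors: rejection-sample positions clear of annotation and donors
    forbidden: list[tuple[str, int, int]] = [
        (iv.chrom, iv.start - acceptor_margin, iv.end + acceptor_margin)
        for iv, _ in genome.annotation
    ]
    events: list[PlannedEvent] = []
    for cls, donor in donors:
        for _ in range(10_000):
            c = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(acceptor_margin, lengths[c] - acceptor_margin))
            if any(f[0] == c and f[1] <= pos < f[2] for f in forbidden):
                continue
            break
        else:  # pragma: no cover - generator is sized to never get here
            raise RuntimeError("could not place acceptor position")
        forbidden.append((c, pos - acceptor_margin, pos + acceptor_margin))
        forbidden.append((donor.chrom, donor.start - acceptor_margin, donor.end + acceptor_margin))
        events.append(
            PlannedEvent(
                event_class=cls,
                donor=donor,
                acceptor_chrom=c,
                acceptor_pos=pos,
                inverted=bool(rng.random() < inverted_fraction),
                tsd_len=tsd_len,
            )
        )
    return events


# ---------------------------------------------------------------------------
# injection


def inject_transposition_events(
    reference: dict[str, str],
    events: Sequence[PlannedEvent],
    strict: bool = True,
) -> TruthTable:
    """Copy each donor span into its acceptor position.

    Insertion at position p with target-site length t produces
    ``ref[:p+t] + block + ref[p:]``: the t bases at the target are
    duplicated on both sides of the block, and the block is the donor
    sequence (reverse-complemented for inverted events).  Events are
    applied per chromosome in coordinate order; in strict mode an acceptor
    falling inside another planned insertion is an error.
    """
    by_chrom: dict[str, list[PlannedEvent]] = {}
    for e in events:
        if e.acceptor_chrom not in reference:
            raise ValueError(f"unknown acceptor chromosome {e.acceptor_chrom}")
        by_chrom.setdefault(e.acceptor_chrom, []).append(e)
    for chrom, evs in by_chrom.items():
        evs.sort(key=lambda e: e.acceptor_pos)
        for e1, e2 in zip(evs, evs[1:]):
            if e2.acceptor_pos < e1.acceptor_pos + e1.tsd_len:
                if strict:
                    raise ValueError(
                        f"acceptor at {chrom}:{e2.acceptor_pos} inside another insertion"
                    )

    modified: dict[str, str] = {}
    segments: dict[str, list[Segment]] = {}
    for chrom, ref_seq in reference.items():
        evs = by_chrom.get(chrom, [])
        pieces: list[str] = []
        segs: list[Segment] = []
        cur = 0
        mod_off = 0
        for e in evs:
            p, t = e.acceptor_pos, e.tsd_len
            if p + t > len(ref_seq):
                raise ValueError("acceptor too close to chromosome end")
            left = ref_seq[cur : p + t]
            pieces.append(left)
            segs.append(Segment(mod_off, mod_off + len(left), chrom, cur, "+"))
            mod_off += len(left)
            block = reference[e.donor.chrom][e.donor.start : e.donor.end]
            strand = "+"
            if e.inverted:
                block = revcomp(block)
                strand = "-"
            pieces.append(block)
            segs.append(
                Segment(mod_off, mod_off + len(block), e.donor.chrom, e.donor.start, strand)
            )
            e.acceptor_pos_mod = mod_off
            mod_off += len(block)
            cur = p  # re-emit the target site: TSD on the right of the block
        tail = ref_seq[cur:]
        pieces.append(tail)
        segs.append(Segment(mod_off, mod_off + len(tail), chrom, cur, "+"))
        modified[chrom] = "".join(pieces)
        segments[chrom] = segs
    return TruthTable(events=list(events), modified=modified, segments=segments)
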