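"""Core domain types shared by every stage of the pipeline.

Coordinates are 0-based half-open internally; text outputs are 1-based
inclusive (SAM/GFF convention).  A read-pair mapping always stores its two
mates relabelled so that the lower-coordinate mate comes first; the insert
size ``d`` is the distance between the two leftmost mapping coordinates,
defined only for same-chromosome mappings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


class Orient(str, enum.Enum):
    """Mapping strand of a single read."""

    FWD = "+"
    REV = "-"

    def flipped(self) -> "Orient":
        return Orient.FWD if self is Orient.REV else Orient.REV

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Expected mate orientation of a concordant pair in a large-insert
#: (mate-pair) library, after relabelling so the left mate comes first.
MATE_PAIR_ORIENT = (Orient.REV, Orient.FWD)
#: Paired-end (FR / "innie") preset.
PAIRED_END_ORIENT = (Orient.FWD, Orient.REV)


class Signature(str, enum.Enum):
    """Discordance signature of a read-pair mapping.

    ``DEL``/``INS`` are proper-orientation pairs whose insert is too large /
    too small; ``DUP`` has the proper orientation reversed; ``INV`` has both
    mates on the same strand; ``TRANS`` spans two chromosomes.  ``CONC``
    marks a concordant (non-discordant) mapping.
    """

    CONC = "Conc"
    DEL = "Del"
    INS = "Ins"
    DUP = "Dup"
    INV = "Inv"
    TRANS = "Trans"


@dataclass(frozen=True)
class ReadMapping:
    """One mapping of a single read."""

    chrom: str
    orient: Orient
    pos: int  # leftmost mapping coordinate, 0-based
    mismatches: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative mapping position {self.pos}")


@dataclass(frozen=True)
class PairMapping:
    """A doublet of mate mappings, relabelled so ``a.pos <= b.pos``.

    Use :meth:`make` to get the relabelling for free.
    """

    a: ReadMapping
    b: ReadMapping

    @classmethod
    def make(cls, r1: ReadMapping, r2: ReadMapping) -> "PairMapping":
        if (r2.chrom, r2.pos) < (r1.chrom, r1.pos):
            r1, r2 = r2, r1
        return cls(r1, r2)

    @property
    def insert(self) -> Optional[int]:
        """Insert size d = b.pos - a.pos; None across chromosomes."""
        if self.a.chrom != self.b.chrom:
            return None
        return self.b.pos - self.a.pos

    @property
    def orient_pair(self) -> tuple[Orient, Orient]:
        return (self.a.orient, self.b.orient)


@dataclass
class MultiMapPairRecord:
    """All recorded pair mappings of one sequenced fragment (the set P_i)."""

    pair_id: str
    mappings: list[PairMapping]
    discordant: bool = False


@dataclass(frozen=True)
class LibraryStats:
    """Robust insert-size statistics of the sequencing library.

    ``M`` is the median insert, ``MAD`` the raw (unscaled) median absolute
    deviation, and the concordance window is (d_inf, d_sup) =
    (M - 3*MAD, M + 3*MAD).
    """

    M: float
    MAD: float
    proper_orient: tuple[Orient, Orient] = MATE_PAIR_ORIENT
    degenerate: bool = False

    @property
    def d_inf(self) -> float:
        return self.M - 3.0 * self.MAD

    @property
    def d_sup(self) -> float:
        return self.M + 3.0 * self.MAD


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"inverted interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "Interval") -> Optional[int]:
        """Distance between closest ends; 0 when touching/overlapping."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def hull(self, other: "Interval") -> "Interval":
        if self.chrom != other.chrom:
            raise ValueError("hull across chromosomes")
        return Interval(self.chrom, min(self.start, other.start), max(self.end, other.end))


@dataclass(frozen=True)
class DiscordantRecord:
    """One discordant pair mapping, the unit consumed by clustering.

    A multi-mapping fragment emits several records sharing ``pair_id``, each
    treated downstream as if it were a unique mapping of a separate pair.
    """

    pair_id: str
    a: ReadMapping
    b: ReadMapping
    signature: Signature

    @property
    def pair(self) -> PairMapping:
        return PairMapping(self.a, self.b)


@dataclass(frozen=True)
class LinkThresholds:
    """Linkage distances of the single-linkage clustering.

    ``x`` bounds the distance on the sorted-mate axis (set by coverage
    fluctuation), ``y`` on the unsorted-mate axis (set by insert-size
    dispersion); x is intended smaller than y.
    """

    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x <= 0 or self.y <= 0:
            raise ValueError("link thresholds must be positive")


@dataclass
class Cluster:
    """A set of same-signature discordant pair mappings."""

    signature: Signature
    orient_pair: tuple[Orient, Orient]
    chrom_a: str
    chrom_b: str
    interval_a: tuple[int, int]  # [min, max] of left-mate coordinates
    interval_b: tuple[int, int]  # [min, max] of right-mate coordinates
    members: set[str] = field(default_factory=set)

    @property
    def support(self) -> int:
        return len(self.members)

    @property
    def span_a(self) -> int:
        return self.interval_a[1] - self.interval_a[0]

    @property
    def span_b(self) -> int:
        return self.interval_b[1] - self.interval_b[0]

    def side_a(self, read_len: int = 0) -> Interval:
        return Interval(self.chrom_a, self.interval_a[0], self.interval_a[1] + read_len)

    def side_b(self, read_len: int = 0) -> Interval:
        return Interval(self.chrom_b, self.interval_b[0], self.interval_b[1] + read_len)


class EventType(str, enum.Enum):
    INSERTION_SENSE = "insertion_sense"
    INSERTION_ANTISENSE = "insertion_antisense"
    INSERTION_INTERCHROM = "insertion_interchrom"
    DELETION = "deletion"


INSERTION_TYPES = frozenset(
    {
        EventType.INSERTION_SENSE,
        EventType.INSERTION_ANTISENSE,
        EventType.INSERTION_INTERCHROM,
    }
)


@dataclass
class EventCall:
    """A called transposition (or deletion) event.

    One insertion with several candidate donors yields several calls sharing
    ``acceptor_id``; ``overlap`` is the donor-side cluster overlap in bp and
    ``inverted`` flags a mobile element reversed during transposition.
    """

    acceptor_id: str
    event_type: EventType
    acceptor: Interval
    donor: Interval
    overlap: int
    support: int
    inverted: bool
    companion_del: bool = False
    donor_annotation: Optional[str] = None
    acceptor_annotation: Optional[str] = None
    donor_score: Optional[int] = None

    @property
    def acceptor_size(self) -> int:
        return self.acceptor.length

    @property
    def donor_size(self) -> int:
        return self.donor.length


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of (X, Y) linkage thresholds scanned by the caller."""

    x_values: tuple[int, ...] = tuple(range(50, 1001, 50))
    y_values: tuple[int, ...] = tuple(range(100, 5001, 100))

    def __post_init__(self) -> None:
        for vals in (self.x_values, self.y_values):
            if not vals or list(vals) != sorted(set(vals)):
                raise ValueError("grid axes must be strictly increasing and non-empty")

    def points(self) -> list[LinkThresholds]:
        return [LinkThresholds(x, y) for x in self.x_values for y in self.y_values]

    @property
    def n_points(self) -> int:
        return len(self.x_values) * len(self.y_values)


def parse_orient_pair(text: str) -> tuple[Orient, Orient]:
    """Parse e.g. '-+' or '-/+' into an orientation couple."""
    chars = [c for c in text if c in "+-"]
    if len(chars) != 2:
        raise ValueError(f"cannot parse orientation couple {text!r}")
    return (Orient(chars[0]), Orient(chars[1]))
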