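"""Discordant read-pair extraction (the *Eris* stage).

Reads a coordinate-sorted SAM/BAM in which multiple mappings are retained
(secondary records and/or XA-style alternative-hit tags), filters mappings
by edit distance, learns the insert-size distribution of the library and
emits every mapping combination of every fully-discordant fragment as an
independent discordant record.

A fragment is discordant only when *none* of the combinations of its mate
mappings is concordant; in that case every combination is recorded as if it
were a unique mapping of a separate pair, so a multi-mapping fragment
amplifies its signal by its number of mappings.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

from .model import (
    DiscordantRecord,
    LibraryStats,
    MATE_PAIR_ORIENT,
    Orient,
    PairMapping,
    ReadMapping,
    Signature,
)

logger = logging.getLogger(__name__)

#: Default cap on enumerated mapping combinations per fragment, mirroring
#: the reporting cap commonly given to the aligner for repetitive genomes.
MAX_COMBINATIONS = 10_000

_XA_RE = re.compile(r"([^,;]+),([+-])(\d+),([0-9MIDNSHPX=]+),(\d+)")


# ---------------------------------------------------------------------------
# mapping-level filtering


def filter_read_mappings(
    mappings: Sequence[ReadMapping],
    max_mismatch: int = 1,
    missing_nm_fails: bool = True,
) -> list[ReadMapping]:
    """Apply the best-match mismatch filter to one read's mapping set.

    The read is dropped entirely (empty list) when its best mapping carries
    more than ``max_mismatch`` mismatches; otherwise only the individual
    mappings within the threshold are retained.  Mappings with an unknown
    edit distance (``mismatches < 0``) fail the filter by default.
    """
    known = [m for m in mappings if m.mismatches >= 0]
    if len(known) < len(mappings):
        if not missing_nm_fails:
            known = list(mappings)
        else:
            warnings.warn("mappings without an edit-distance attribute were dropped")
    if not known:
        return []
    if min(m.mismatches for m in known) > max_mismatch:
        return []
    return [m for m in known if m.mismatches <= max_mismatch]


# ---------------------------------------------------------------------------
# library statistics


def estimate_library_stats(
    inserts: Iterable[int],
    proper_orient: tuple[Orient, Orient] = MATE_PAIR_ORIENT,
) -> LibraryStats:
    """Median / MAD insert-size statistics from a sample of inserts.

    MAD is the raw median absolute deviation (no normal-consistency
    scaling): the concordance window is (M - 3*MAD, M + 3*MAD).  A zero MAD
    flags a degenerate library in which every non-median insert would be
    classified discordant.
    """
    arr = np.asarray(list(inserts), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate library statistics from an empty sample")
    m = float(np.median(arr))
    mad = float(np.median(np.abs(arr - m)))
    degenerate = mad == 0.0
    if degenerate:
        warnings.warn(
            "insert-size MAD is zero: every non-median insert will be discordant"
        )
    return LibraryStats(M=m, MAD=mad, proper_orient=proper_orient, degenerate=degenerate)


# ---------------------------------------------------------------------------
# classification


def classify_pair_mapping(p: PairMapping, stats: LibraryStats) -> Signature:
    """Classify one pair mapping against the library expectations.

    Exactly one signature holds for every mapping: concordant pairs match
    the proper orientation on one chromosome with an insert inside
    [d_inf, d_sup]; otherwise Del (too large), Ins (too small), Dup
    (reversed proper orientation), Inv (equal strands) or Trans (two
    chromosomes).  Boundary inserts (d == d_inf or d == d_sup) count as
    concordant so that the classification is total.
    """
    if p.a.chrom != p.b.chrom:
        return Signature.TRANS
    o = p.orient_pair
    if o[0] == o[1]:
        return Signature.INV
    proper = stats.proper_orient
    if o == (proper[1], proper[0]):
        return Signature.DUP
    # proper orientation from here on
    d = p.insert
    if d > stats.d_sup:
        return Signature.DEL
    if d < stats.d_inf:
        return Signature.INS
    return Signature.CONC


# ---------------------------------------------------------------------------
# coverage mask


@dataclass
class CoverageMask:
    """Per-chromosome high-depth intervals (pairs inside are discarded)."""

    c_inf: float
    c_sup: float
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            self.intervals[chrom] = sorted(ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    @property
    def total_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def build_coverage_mask(
    window_depths: dict[str, np.ndarray],
    window: int = 100,
    floor: float = 1000.0,
    n_mad: float = 3.0,
) -> CoverageMask:
    """Mask maximal runs of windows whose depth exceeds the upper limit.

    The limits are c_sup = depth_median + n_mad * depth_MAD and c_inf =
    depth_median - n_mad * depth_MAD over all windows (MAD unscaled).  A
    window is maskable only above ``max(c_sup, floor)``; the default floor
    of 1000x restricts masking to the extreme repeat-driven pileups the
    mask exists for (set floor=0 to threshold at c_sup alone).
    """
    all_depths = (
        np.concatenate([np.asarray(d, dtype=float) for d in window_depths.values()])
        if window_depths
        else np.array([])
    )
    if all_depths.size == 0 or not np.any(all_depths > 0):
        warnings.warn("zero-coverage input: empty coverage mask")
        return CoverageMask(c_inf=0.0, c_sup=0.0)
    med = float(np.median(all_depths))
    mad = float(np.median(np.abs(all_depths - med)))
    c_sup = med + n_mad * mad
    c_inf = med - n_mad * mad
    threshold = max(c_sup, floor)
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom, depths in window_depths.items():
        depths = np.asarray(depths, dtype=float)
        above = depths > threshold
        if not above.any():
            continue
        ivs = []
        idx = np.flatnonzero(above)
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                ivs.append((int(start) * window, (int(prev) + 1) * window))
                start = i
            prev = i
        ivs.append((int(start) * window, (int(prev) + 1) * window))
        intervals[chrom] = ivs
    return CoverageMask(c_inf=c_inf, c_sup=c_sup, intervals=intervals)


# ---------------------------------------------------------------------------
# SAM/BAM ingestion


@dataclass
class FragmentMappings:
    """Filtered mapping sets of the two mates of one fragment."""

    pair_id: str
    mate1: list[ReadMapping]
    mate2: list[ReadMapping]


@dataclass
class ExtractionCounters:
    fragments: int = 0
    orphans: int = 0
    filtered_out: int = 0
    concordant: int = 0
    discordant: int = 0
    masked: int = 0
    records: int = 0


def _mappings_from_alignment(aln: pysam.AlignedSegment) -> list[ReadMapping]:
    """Expand one alignment record into mappings (itself plus XA hits)."""
    nm = aln.get_tag("NM") if aln.has_tag("NM") else -1
    score = float(aln.mapping_quality)
    out = [
        ReadMapping(
            chrom=aln.reference_name,
            orient=Orient.REV if aln.is_reverse else Orient.FWD,
            pos=int(aln.reference_start),
            mismatches=int(nm),
            score=score,
        )
    ]
    if aln.has_tag("XA"):
        for m in _XA_RE.finditer(str(aln.get_tag("XA"))):
            chrom, strand, pos, _cigar, xnm = m.groups()
            out.append(
                ReadMapping(
                    chrom=chrom,
                    orient=Orient(strand),
                    pos=int(pos) - 1,  # XA positions are 1-based
                    mismatches=int(xnm),
                    score=score,
                )
            )
    return out


def load_fragments(
    path: str,
    max_mismatch: int = 1,
    require_sorted: bool = True,
) -> tuple[dict[str, FragmentMappings], dict[str, int]]:
    """Collect per-fragment mapping sets from a coordinate-sorted SAM/BAM.

    Secondary records and XA alternative hits both contribute mappings;
    duplicates (same chromosome/position/orientation) are collapsed.
    Returns the fragments together with reference sequence lengths.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    frags: dict[str, tuple[dict, dict]] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        so = (fh.header.to_dict().get("HD") or {}).get("SO", "unknown")
        if require_sorted and so != "coordinate":
            raise ValueError(f"input must be coordinate-sorted (header SO={so!r})")
        ref_lengths = dict(zip(fh.references, fh.lengths))
        for aln in fh:
            if aln.is_unmapped or aln.is_supplementary:
                continue
            key = aln.query_name
            slot = 1 if aln.is_read2 else 0
            if key not in frags:
                frags[key] = ({}, {})
            bucket = frags[key][slot]
            for m in _mappings_from_alignment(aln):
                bucket[(m.chrom, m.pos, m.orient)] = m
    out: dict[str, FragmentMappings] = {}
    for pair_id, (b1, b2) in frags.items():
        m1 = filter_read_mappings(list(b1.values()), max_mismatch)
        m2 = filter_read_mappings(list(b2.values()), max_mismatch)
        out[pair_id] = FragmentMappings(pair_id, m1, m2)
    return out, ref_lengths


def sample_inserts(
    fragments: Iterable[FragmentMappings],
    proper_orient: tuple[Orient, Orient] = MATE_PAIR_ORIENT,
    sample_size: int = 1_000_000,
) -> list[int]:
    """Inserts of uniquely-mapped, proper-orientation pairs (first N)."""
    inserts: list[int] = []
    for frag in fragments:
        if len(frag.mate1) != 1 or len(frag.mate2) != 1:
            continue
        p = PairMapping.make(frag.mate1[0], frag.mate2[0])
        if p.a.chrom != p.b.chrom or p.orient_pair != proper_orient:
            continue
        inserts.append(p.insert)
        if len(inserts) >= sample_size:
            break
    return inserts


def enumerate_pair_mappings(
    frag: FragmentMappings, cap: int = MAX_COMBINATIONS
) -> list[PairMapping]:
    """All combinations of mate mappings of one fragment, deduplicated."""
    combos: dict[tuple, PairMapping] = {}
    n = 0
    for r1, r2 in itertools.product(frag.mate1, frag.mate2):
        if n >= cap:
            logger.warning("combination cap reached for fragment %s", frag.pair_id)
            break
        n += 1
        p = PairMapping.make(r1, r2)
        key = (p.a.chrom, p.a.pos, p.a.orient, p.b.chrom, p.b.pos, p.b.orient)
        combos.setdefault(key, p)
    return list(combos.values())


def _near_concordant(p: PairMapping, stats: LibraryStats, n_mads: float) -> bool:
    """Proper orientation on one chromosome with insert within n_mads MADs."""
    if p.a.chrom != p.b.chrom or p.orient_pair != stats.proper_orient:
        return False
    return abs(p.insert - stats.M) <= n_mads * stats.MAD


def extract_discordant_pairs(
    fragments: dict[str, FragmentMappings],
    stats: LibraryStats,
    mask: Optional[CoverageMask] = None,
    counters: Optional[ExtractionCounters] = None,
    near_concordant_mads: float = 6.0,
) -> Iterator[DiscordantRecord]:
    """Yield one record per discordant mapping of every discordant fragment.

    A fragment contributes records only when none of its pair mappings is
    concordant.  The veto uses a wider band than the classification
    (``near_concordant_mads`` MADs around M, default twice the 3-MAD
    concordance window): fragments whose only discordance is an insert in
    the tail of the size distribution carry no structural signal, yet
    their multi-mappings around near-identical repeat copies would
    otherwise pile up into coherent spurious clusters.  Events callable
    downstream are unaffected, since every calling rule requires distances
    far beyond this band.  Pairs with both mates inside high-coverage mask
    intervals are discarded.
    """
    c = counters if counters is not None else ExtractionCounters()
    n_mads = max(near_concordant_mads, 3.0)
    for pair_id in sorted(fragments):
        frag = fragments[pair_id]
        c.fragments += 1
        if not frag.mate1 and not frag.mate2:
            c.filtered_out += 1
            continue
        if not frag.mate1 or not frag.mate2:
            c.orphans += 1
            continue
        combos = enumerate_pair_mappings(frag)
        sigs = [classify_pair_mapping(p, stats) for p in combos]
        if any(s is Signature.CONC for s in sigs) or any(
            _near_concordant(p, stats, n_mads) for p in combos
        ):
            c.concordant += 1
            continue
        c.discordant += 1
        for p, s in zip(combos, sigs):
            if (
                mask is not None
                and mask.contains(p.a.chrom, p.a.pos)
                and mask.contains(p.b.chrom, p.b.pos)
            ):
                c.masked += 1
                continue
            c.records += 1
            yield DiscordantRecord(pair_id=pair_id, a=p.a, b=p.b, signature=s)


def window_depths_from_fragments(
    fragments: Iterable[FragmentMappings],
    ref_lengths: dict[str, int],
    window: int = 100,
    read_len: int = 100,
) -> dict[str, np.ndarray]:
    """Approximate per-window read depth from primary-equivalent mappings.

    Each retained mapping adds ``read_len`` bases of coverage spread over
    the windows it touches; multi-mapped reads contribute their best
    mapping only, so repeats pile up exactly as the aligner's primary
    placement does.
    """
    cov = {c: np.zeros(int(np.ceil(l / window)), dtype=float) for c, l in ref_lengths.items()}
    for frag in fragments:
        for side in (frag.mate1, frag.mate2):
            if not side:
                continue
            m = min(side, key=lambda r: (r.mismatches, r.chrom, r.pos))
            arr = cov.get(m.chrom)
            if arr is None:
                continue
            w0 = m.pos // window
            w1 = (m.pos + read_len - 1) // window
            for w in range(w0, min(w1, arr.size - 1) + 1):
                lo = max(m.pos, w * window)
                hi = min(m.pos + read_len, (w + 1) * window)
                arr[w] += (hi - lo) / window
    return cov
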