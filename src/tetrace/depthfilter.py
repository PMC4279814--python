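"""Post-hoc exclusion of acceptor sites in anomalously deep regions.

Centromeric repeat units, rDNA arrays and low-complexity sequence attract
extreme read pileups in which insertion breakpoints cannot be mapped with
any confidence.  Read depth is computed on consecutive non-overlapping
100 bp windows, corrected for GC-content bias by median-ratio
normalisation, and windows more than three (unscaled) MADs above the
median depth are merged -- tolerating a single-window gap -- into
segments; acceptor sites overlapping a segment longer than 500 bp are
dropped from the event list.  The threshold is one-sided high: only
excess coverage creates the spurious-cluster problem this filter targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from .model import EventCall, Interval

logger = logging.getLogger(__name__)

WINDOW = 100


@dataclass(frozen=True)
class HighDepthSegment:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# window depth and GC


def window_depth_from_alignment(
    path: str, window: int = WINDOW
) -> dict[str, np.ndarray]:
    """Mean per-base depth on fixed windows, from primary mappings."""
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        depths = {
            c: np.zeros(max(1, -(-l // window)), dtype=float)
            for c, l in zip(fh.references, fh.lengths)
        }
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            arr = depths.get(aln.reference_name)
            if arr is None:
                continue
            s, e = aln.reference_start, aln.reference_end or aln.reference_start
            for w in range(s // window, min(e - 1, len(arr) * window - 1) // window + 1):
                lo, hi = max(s, w * window), min(e, (w + 1) * window)
                arr[w] += (hi - lo) / window
    return depths


def window_gc(fasta_path: str, window: int = WINDOW) -> dict[str, np.ndarray]:
    """GC fraction of each window (ambiguous bases ignored)."""
    out: dict[str, np.ndarray] = {}
    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    for name in fa.keys():
        seq = str(fa[name][:])
        if len(seq) < window:
            warnings.warn(f"chromosome {name} shorter than one window: skipped")
            continue
        n_win = -(-len(seq) // window)
        gc = np.zeros(n_win)
        for w in range(n_win):
            chunk = seq[w * window : (w + 1) * window]
            acgt = sum(chunk.count(b) for b in "ACGT")
            gc[w] = (chunk.count("G") + chunk.count("C")) / acgt if acgt else 0.0
        out[name] = gc
    return out


def gc_correct_depth(
    raw: dict[str, np.ndarray],
    gc: dict[str, np.ndarray],
    min_bin_windows: int = 20,
) -> dict[str, np.ndarray]:
    """Median-ratio GC normalisation on 1% GC bins.

    corrected = raw * (global median depth / median depth of the window's
    GC bin); bins with fewer than ``min_bin_windows`` windows fall back to
    the global median (ratio 1).  On a GC-uniform genome every window
    shares one bin and the correction is the identity.
    """
    chroms = [c for c in raw if c in gc]
    all_depth = np.concatenate([raw[c][: len(gc[c])] for c in chroms])
    all_gc = np.concatenate([gc[c][: len(raw[c])] for c in chroms])
    if all_depth.size == 0:
        return {c: np.asarray(raw[c], dtype=float).copy() for c in raw}
    global_med = float(np.median(all_depth))
    bins = np.clip((all_gc * 100).astype(int), 0, 100)
    ratio = np.ones(101)
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() >= min_bin_windows:
            bin_med = float(np.median(all_depth[sel]))
            if bin_med > 0:
                ratio[b] = global_med / bin_med
    out = {}
    for c in chroms:
        n = min(len(raw[c]), len(gc[c]))
        b = np.clip((gc[c][:n] * 100).astype(int), 0, 100)
        corr = np.asarray(raw[c][:n], dtype=float) * ratio[b]
        out[c] = corr
    return out


# ---------------------------------------------------------------------------
# segmentation


def segment_high_depth(
    depths: dict[str, np.ndarray],
    window: int = WINDOW,
    n_mad: float = 3.0,
    max_gap_windows: int = 1,
) -> list[HighDepthSegment]:
    """Merge outlier windows (depth > median + n_mad*MAD) into segments.

    Runs of outlier windows separated by at most ``max_gap_windows``
    non-outlier windows merge into one segment.
    """
    all_d = np.concatenate([np.asarray(d, dtype=float) for d in depths.values()])
    if all_d.size == 0:
        return []
    med = float(np.median(all_d))
    mad = float(np.median(np.abs(all_d - med)))
    thr = med + n_mad * mad
    segments: list[HighDepthSegment] = []
    for chrom in sorted(depths):
        idx = np.flatnonzero(np.asarray(depths[chrom], dtype=float) > thr)
        if idx.size == 0:
            continue
        start = prev = idx[0]
        for i in idx[1:]:
            if i - prev > max_gap_windows + 1:
                segments.append(
                    HighDepthSegment(chrom, int(start) * window, (int(prev) + 1) * window)
                )
                start = i
            prev = i
        segments.append(
            HighDepthSegment(chrom, int(start) * window, (int(prev) + 1) * window)
        )
    return segments


def compute_depth_segments(
    alignment_path: str,
    fasta_path: str,
    window: int = WINDOW,
    n_mad: float = 3.0,
) -> list[HighDepthSegment]:
    """Full pipeline: window depth -> GC correction -> segmentation."""
    raw = window_depth_from_alignment(alignment_path, window)
    gc = window_gc(fasta_path, window)
    corrected = gc_correct_depth(raw, gc)
    return segment_high_depth(corrected, window, n_mad)


# ---------------------------------------------------------------------------
# event filtering


def filter_acceptor_sites(
    events: Sequence[EventCall],
    segments: Iterable[HighDepthSegment],
    min_len: int = 500,
) -> tuple[list[EventCall], list[tuple[EventCall, HighDepthSegment]]]:
    """Drop events whose acceptor overlaps a segment longer than min_len.

    Returns (kept events, removal log of (event, offending segment)).
    """
    long_segs = [s for s in segments if s.length > min_len]
    kept: list[EventCall] = []
    removed: list[tuple[EventCall, HighDepthSegment]] = []
    for e in events:
        hit = next(
            (s for s in long_segs if e.acceptor.overlaps(s.interval)), None
        )
        if hit is None:
            kept.append(e)
        else:
            logger.info(
                "acceptor %s removed: overlaps %s:%d-%d (%d bp)",
                e.acceptor_id, hit.chrom, hit.start, hit.end, hit.length,
            )
            removed.append((e, hit))
    return kept, removed


def write_segments_bed(segments: Sequence[HighDepthSegment], path: str) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\thigh_depth\n")
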