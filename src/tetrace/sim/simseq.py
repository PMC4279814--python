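"""Two-phase simulation of long-fragment (mate-pair) sequencing libraries.

Mate-pair protocols circularise multi-kilobase fragments and sequence a
short splice taken around the circularisation junction.  Three artefacts
follow and are reproduced here: position-dependent sequencing error rates,
contamination by parasitic short fragments, and junction-chimeric reads
(reads extending across the circularisation point).

Phase one (:func:`learn_sim_profile`) draws a sample from an existing
alignment and derives per-cycle quality histograms and the empirical
fragment-size distribution, which for a contaminated library is bimodal: a
short (parasitic) mode and the long mode of interest.  The minimum between
the two modes becomes the split point, and the ratio of the mode heights
gives the odds of drawing a short fragment.

Phase two (:func:`simulate_mate_pairs`) mirrors the wet protocol: sample a
fragment size and a uniform location, circularise, draw a splice length
from the short-fragment distribution and a splice start around the
junction, read both splice ends, draw a quality per cycle from the learned
histograms and inject a substitution error with the probability the
quality encodes.  Chimeric reads emerge from the splice geometry rather
than from a forced rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam
from scipy import signal as _signal
from scipy import stats as _stats

from .genome import revcomp

logger = logging.getLogger(__name__)

_ALT = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
_DEFAULT_SPLICE = (300, 700)  # fallback splice-length range, bp


@dataclass
class SimProfile:
    """Learned (or declared) model of one mate-pair sequencing run."""

    read_len: int
    qual_values: np.ndarray  # possible quality values, ascending
    quality_hists: np.ndarray  # (read_len, len(qual_values)), rows sum to 1
    frag_sizes: np.ndarray  # support of the fragment-size distribution
    frag_probs: np.ndarray
    split_point: int  # minimum separating the two modes (0 = unimodal)
    contamination_odds: float  # odds short:long
    quality_encoding: str = "phred-33"

    def __post_init__(self) -> None:
        if not np.allclose(self.quality_hists.sum(axis=1), 1.0):
            raise ValueError("per-position quality histograms must sum to 1")
        if not (0.0 <= self.p_short <= 1.0):
            raise ValueError("contamination odds out of range")

    @property
    def p_short(self) -> float:
        return self.contamination_odds / (1.0 + self.contamination_odds)

    def _component(self, short: bool) -> tuple[np.ndarray, np.ndarray]:
        sel = (
            self.frag_sizes < self.split_point
            if short
            else self.frag_sizes >= self.split_point
        )
        sizes, probs = self.frag_sizes[sel], self.frag_probs[sel]
        if probs.sum() == 0:
            return np.array([]), np.array([])
        return sizes, probs / probs.sum()

    @property
    def short_component(self) -> tuple[np.ndarray, np.ndarray]:
        return self._component(short=True)

    @property
    def long_component(self) -> tuple[np.ndarray, np.ndarray]:
        return self._component(short=False)

    def splice_component(self) -> tuple[np.ndarray, np.ndarray]:
        """Splice lengths are re-fragmentation products: the short mode."""
        sizes, probs = self.short_component
        if sizes.size == 0:
            sizes = np.arange(*_DEFAULT_SPLICE)
            probs = np.full(sizes.size, 1.0 / sizes.size)
        return sizes, probs

    def mixture_cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF of the fragment-size mixture the simulator draws from."""
        x = np.asarray(x)
        ss, sp = self.short_component
        ls, lp = self.long_component
        p = self.p_short if ss.size else 0.0

        def comp_cdf(sizes: np.ndarray, probs: np.ndarray) -> np.ndarray:
            if sizes.size == 0:
                return np.zeros(x.shape)
            cum = np.cumsum(probs)
            idx = np.searchsorted(sizes, x, side="right")
            return np.where(idx > 0, cum[np.clip(idx - 1, 0, cum.size - 1)], 0.0)

        return p * comp_cdf(ss, sp) + (1 - p) * comp_cdf(ls, lp)


def synthetic_profile(
    read_len: int = 100,
    long_mean: int = 5000,
    long_sd: float = 300.0,
    short_mean: int = 300,
    short_sd: float = 60.0,
    contamination_odds: float = 0.10,
    qual_start: float = 38.0,
    qual_end: float = 30.0,
    qual_sd: float = 2.0,
) -> SimProfile:
    """A declared profile with the features real libraries show.

    Fragment sizes follow a discretised normal mixture; per-cycle quality
    declines linearly from ``qual_start`` to ``qual_end`` with normal
    spread, as later sequencing cycles accumulate phasing noise.
    """
    sizes = np.arange(max(2 * read_len, short_mean - 4 * int(short_sd)), long_mean + 4 * int(long_sd))
    short_pdf = _stats.norm.pdf(sizes, short_mean, short_sd)
    long_pdf = _stats.norm.pdf(sizes, long_mean, long_sd)
    odds = contamination_odds
    mix = odds / (1 + odds) * short_pdf / short_pdf.sum() + 1 / (1 + odds) * long_pdf / long_pdf.sum()
    keep = mix > 1e-12
    sizes, mix = sizes[keep], mix[keep]
    mix = mix / mix.sum()
    split = int((short_mean + long_mean) / 2)

    quals = np.arange(2, 42)
    hists = np.zeros((read_len, quals.size))
    means = np.linspace(qual_start, qual_end, read_len)
    for i, mu in enumerate(means):
        w = _stats.norm.pdf(quals, mu, qual_sd)
        hists[i] = w / w.sum()
    return SimProfile(
        read_len=read_len,
        qual_values=quals,
        quality_hists=hists,
        frag_sizes=sizes,
        frag_probs=mix,
        split_point=split,
        contamination_odds=contamination_odds,
    )


# ---------------------------------------------------------------------------
# phase one: learning


def learn_sim_profile(
    alignment_path: str,
    sample_size: int = 100_000,
    read_len: Optional[int] = None,
    bin_width: int = 50,
) -> SimProfile:
    """Learn a :class:`SimProfile` from a sample of an alignment file.

    Per-cycle quality histograms come from the first ``sample_size``
    primary records (qualities restored to machine-cycle order for
    reverse-strand alignments); fragment sizes from the leftmost-mapping
    distance of unambiguously mapped pairs.  The two modes of the size
    distribution are located on a smoothed histogram; a unimodal
    distribution yields zero contamination odds with a warning.
    """
    mode = "rb" if alignment_path.endswith(".bam") else "r"
    qual_counts: dict[int, np.ndarray] = {}
    positions: dict[str, list[int]] = {}
    ambiguous: set[str] = set()
    n_sampled = 0
    rl = read_len or 0
    with pysam.AlignmentFile(alignment_path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.is_secondary or aln.is_supplementary or aln.has_tag("XA"):
                ambiguous.add(aln.query_name)
            if aln.is_secondary or aln.is_supplementary:
                continue
            q = aln.query_qualities
            if q is not None and n_sampled < sample_size:
                n_sampled += 1
                arr = np.array(q, dtype=int)
                if aln.is_reverse:
                    arr = arr[::-1]
                rl = max(rl, arr.size)
                for i, v in enumerate(arr):
                    qual_counts.setdefault(i, np.zeros(94))[v] += 1
            positions.setdefault(aln.query_name, []).append(aln.reference_start)
    if n_sampled == 0:
        raise ValueError("no mapped reads with qualities in the sample")

    inserts = np.array(
        [
            max(p) - min(p) + rl
            for name, p in positions.items()
            if len(p) == 2 and name not in ambiguous
        ]
    )
    if inserts.size < 2:
        raise ValueError("not enough unambiguously mapped pairs to learn fragment sizes")

    qual_values = np.arange(94)
    hists = np.zeros((rl, 94))
    for i in range(rl):
        c = qual_counts.get(i, np.zeros(94))
        hists[i] = c / c.sum() if c.sum() else np.eye(94)[30]
    used = hists.sum(axis=0) > 0
    qual_values, hists = qual_values[used], hists[:, used]

    lo, hi = int(inserts.min()), int(inserts.max())
    edges = np.arange(lo, hi + 2 * bin_width, bin_width)
    hist, _ = np.histogram(inserts, bins=edges)
    smooth = np.convolve(hist, np.ones(5) / 5, mode="same")
    # zero-pad so modes at the histogram edges are still detected
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = _signal.find_peaks(padded, prominence=max(smooth.max() * 0.05, 1.0))
    peaks = peaks - 1
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        p_lo, p_hi = int(min(top2)), int(max(top2))
        valley = p_lo + int(np.argmin(smooth[p_lo : p_hi + 1]))
        split = int(edges[valley])
        odds = float(smooth[p_lo] / smooth[p_hi]) if edges[p_lo] < split else 0.0
    else:
        warnings.warn("unimodal fragment-size distribution: contamination odds set to 0")
        split, odds = 0, 0.0

    sizes, counts = np.unique(inserts, return_counts=True)
    return SimProfile(
        read_len=rl,
        qual_values=qual_values,
        quality_hists=hists,
        frag_sizes=sizes.astype(int),
        frag_probs=counts / counts.sum(),
        split_point=split,
        contamination_odds=odds,
    )


# ---------------------------------------------------------------------------
# phase two: simulation


@dataclass
class SimulatedPair:
    """Truth sidecar for one simulated pair.

    ``junction_offset`` is the position of the circularisation junction
    within the splice (-1 for contaminant pairs, which have no junction).
    """

    name: str
    chrom: str
    frag_start: int
    frag_size: int
    is_contaminant: bool
    chimeric1: bool
    chimeric2: bool
    splice_size: int = -1
    junction_offset: int = -1


def expected_chimera_fraction(profile: SimProfile) -> float:
    """Geometric expectation of the junction-chimeric read fraction.

    With the splice start uniform on the ``s + 1`` positions that keep the
    junction inside the splice, a read of length ``rl`` contains the
    junction strictly inside itself for ``rl - 1`` of those positions, so
    each read is chimeric with probability ``(rl - 1) / (s + 1)``;
    averaging over the splice-length distribution (long, non-contaminant
    pairs only) gives the expected chimeric fraction.
    """
    sizes, probs = profile.splice_component()
    rl = profile.read_len
    per_read = np.minimum((rl - 1) / (sizes + 1.0), 1.0)
    return float((1 - profile.p_short) * np.sum(probs * per_read))


def _sample(rng: np.random.Generator, sizes: np.ndarray, probs: np.ndarray) -> int:
    return int(rng.choice(sizes, p=probs))


def _sequence_read(
    rng: np.random.Generator,
    template: str,
    profile: SimProfile,
    cum_hists: np.ndarray,
) -> tuple[str, str]:
    """Draw per-cycle qualities and inject errors accordingly.

    ``cum_hists`` is the row-wise cumulative sum of the per-position
    quality histograms (precomputed once per library).
    """
    rl = len(template)
    rows = np.minimum(np.arange(rl), cum_hists.shape[0] - 1)
    u = rng.random(rl)
    idx = (cum_hists[rows] < u[:, None]).sum(axis=1)
    quals = profile.qual_values[np.minimum(idx, profile.qual_values.size - 1)]
    err = rng.random(rl) < 10.0 ** (-quals / 10.0)
    out = list(template)
    for i in np.flatnonzero(err):
        if out[i] in _ALT:
            out[i] = _ALT[out[i]][rng.integers(0, 3)]
    qstr = "".join(chr(int(q) + 33) for q in quals)
    return "".join(out), qstr


def simulate_mate_pairs(
    genome: dict[str, str],
    profile: SimProfile,
    coverage: float,
    seed: int,
    fastq1: str,
    fastq2: str,
    with_contamination: bool = True,
    with_chimera: bool = True,
    max_retries: int = 100,
) -> list[SimulatedPair]:
    """Write a simulated paired FASTQ library; returns the truth sidecar.

    Each non-contaminant pair circularises a long fragment, splices around
    the junction and reads both splice ends inward; a read whose span
    crosses the junction is a chimera joining the two fragment ends.
    Contaminant pairs (probability ``p_short``) are plain short fragments
    read from both ends.  Identical inputs and seed give byte-identical
    output.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    rl = profile.read_len
    n_pairs = int(round(total * coverage / (2 * rl)))
    s_sizes, s_probs = profile.splice_component()
    l_sizes, l_probs = profile.long_component
    if l_sizes.size == 0:
        raise ValueError("profile has no long-fragment component")
    cum_hists = np.cumsum(profile.quality_hists, axis=1)
    truth: list[SimulatedPair] = []
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for i in range(n_pairs):
            name = f"mp{i:07d}"
            contaminant = bool(
                with_contamination and rng.random() < profile.p_short and s_sizes.size
            )
            sizes, probs = (s_sizes, s_probs) if contaminant else (l_sizes, l_probs)
            for _ in range(max_retries):
                size = max(_sample(rng, sizes, probs), 2 * rl)
                ci = int(rng.choice(len(chroms), p=lengths / total))
                chrom = chroms[ci]
                if size <= len(genome[chrom]):
                    break
            else:
                raise RuntimeError("fragment larger than every chromosome")
            start = int(rng.integers(0, len(genome[chrom]) - size + 1))
            frag = genome[chrom][start : start + size]
            chim1 = chim2 = False
            s, j = -1, -1
            if contaminant:
                splice = frag
            else:
                s = min(max(_sample(rng, s_sizes, s_probs), 2 * rl), size)
                # splice start uniform over the s+1 offsets keeping the
                # circularisation junction inside the splice
                j = int(rng.integers(0, s + 1))  # junction offset within splice
                if not with_chimera:
                    j = s // 2  # junction mid-splice: neither read crosses it
                circ = frag + frag  # circularised fragment, junction at `size`
                splice = circ[size - j : size - j + s]
                chim1 = 0 < j < rl
                chim2 = s - rl < j < s
            read1 = splice[:rl]
            read2 = revcomp(splice[-rl:])
            seq1, q1 = _sequence_read(rng, read1, profile, cum_hists)
            seq2, q2 = _sequence_read(rng, read2, profile, cum_hists)
            f1.write(f"@{name}/1\n{seq1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{seq2}\n+\n{q2}\n")
            truth.append(
                SimulatedPair(name, chrom, start, size, contaminant, chim1, chim2, s, j)
            )
    return truth


def write_pair_truth_tsv(pairs: Sequence[SimulatedPair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tfrag_start\tfrag_size\tcontaminant\tchimeric1\tchimeric2\n")
        for p in pairs:
            fh.write(
                f"{p.name}\t{p.chrom}\t{p.frag_start + 1}\t{p.frag_size}\t"
                f"{int(p.is_contaminant)}\t{int(p.chimeric1)}\t{int(p.chimeric2)}\n"
            )
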