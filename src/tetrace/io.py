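"""Readers and writers for the pipeline's text formats.

Internal coordinates are 0-based half-open; every file written here uses
1-based inclusive coordinates (SAM/GFF convention).  The discordant-record
table is the contract between the extraction and clustering stages, the
event table between calling and annotation.
"""

from __future__ import annotations

import csv
import logging
import warnings
from typing import Iterable, Optional, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Cluster,
    DiscordantRecord,
    EventCall,
    EventType,
    Interval,
    Orient,
    ReadMapping,
    Signature,
)

logger = logging.getLogger(__name__)

STAR = "*"

RECORD_COLUMNS = [
    "pair_id",
    "chromA",
    "posA",
    "orientA",
    "nmA",
    "chromB",
    "posB",
    "orientB",
    "nmB",
    "signature",
]

EVENT_COLUMNS = [
    "acceptor_id",
    "event_type",
    "acceptor_chrom",
    "acceptor_start",
    "acceptor_end",
    "acceptor_size",
    "donor_chrom",
    "donor_start",
    "donor_end",
    "donor_size",
    "overlap_bp",
    "support",
    "inverted",
    "companion_del",
]

METIS_COLUMNS = ["donor_annotation", "acceptor_annotation", "donor_score"]

CLUSTER_COLUMNS = [
    "signature",
    "orientA",
    "orientB",
    "chromA",
    "startA",
    "endA",
    "chromB",
    "startB",
    "endB",
    "support",
]


# ---------------------------------------------------------------------------
# discordant records


def write_records_tsv(records: Iterable[DiscordantRecord], path: str) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RECORD_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.pair_id,
                    r.a.chrom,
                    r.a.pos + 1,
                    r.a.orient.value,
                    r.a.mismatches,
                    r.b.chrom,
                    r.b.pos + 1,
                    r.b.orient.value,
                    r.b.mismatches,
                    r.signature.value,
                ]
            )
            n += 1
    return n


def read_records_tsv(path: str) -> list[DiscordantRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                DiscordantRecord(
                    pair_id=row["pair_id"],
                    a=ReadMapping(
                        row["chromA"],
                        Orient(row["orientA"]),
                        int(row["posA"]) - 1,
                        int(row["nmA"]),
                    ),
                    b=ReadMapping(
                        row["chromB"],
                        Orient(row["orientB"]),
                        int(row["posB"]) - 1,
                        int(row["nmB"]),
                    ),
                    signature=Signature(row["signature"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# clusters


def write_clusters_tsv(clusters: Iterable[Cluster], path: str) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLUSTER_COLUMNS)
        for c in clusters:
            w.writerow(
                [
                    c.signature.value,
                    c.orient_pair[0].value,
                    c.orient_pair[1].value,
                    c.chrom_a,
                    c.interval_a[0] + 1,
                    c.interval_a[1] + 1,
                    c.chrom_b,
                    c.interval_b[0] + 1,
                    c.interval_b[1] + 1,
                    c.support,
                ]
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# events


def write_events_tsv(
    events: Sequence[EventCall], path: str, annotated: bool = False
) -> int:
    cols = EVENT_COLUMNS + (METIS_COLUMNS if annotated else [])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for e in events:
            row = [
                e.acceptor_id,
                e.event_type.value,
                e.acceptor.chrom,
                e.acceptor.start + 1,
                e.acceptor.end,
                e.acceptor_size,
                e.donor.chrom,
                e.donor.start + 1,
                e.donor.end,
                e.donor_size,
                e.overlap,
                e.support,
                int(e.inverted),
                int(e.companion_del),
            ]
            if annotated:
                row += [
                    e.donor_annotation or STAR,
                    e.acceptor_annotation or STAR,
                    STAR if e.donor_score is None else e.donor_score,
                ]
            w.writerow(row)
    return len(events)


def read_events_tsv(path: str) -> list[EventCall]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            score = row.get("donor_score")
            out.append(
                EventCall(
                    acceptor_id=row["acceptor_id"],
                    event_type=EventType(row["event_type"]),
                    acceptor=Interval(
                        row["acceptor_chrom"],
                        int(row["acceptor_start"]) - 1,
                        int(row["acceptor_end"]),
                    ),
                    donor=Interval(
                        row["donor_chrom"],
                        int(row["donor_start"]) - 1,
                        int(row["donor_end"]),
                    ),
                    overlap=int(row["overlap_bp"]),
                    support=int(row["support"]),
                    inverted=bool(int(row["inverted"])),
                    companion_del=bool(int(row.get("companion_del", 0))),
                    donor_annotation=(row.get("donor_annotation") or None)
                    if row.get("donor_annotation") != STAR
                    else None,
                    acceptor_annotation=(row.get("acceptor_annotation") or None)
                    if row.get("acceptor_annotation") != STAR
                    else None,
                    donor_score=None
                    if score in (None, "", STAR)
                    else int(score),
                )
            )
    return out


# ---------------------------------------------------------------------------
# annotation features (BED / GFF3)


def read_features(path: str) -> list[tuple[Interval, str]]:
    """Named intervals from a BED or GFF3 file (picked by extension).

    Malformed lines are skipped with a warning carrying the line number.
    """
    if path.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: str) -> list[tuple[Interval, str]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                iv = Interval(parts[0], int(parts[1]), int(parts[2]))
                name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            except (IndexError, ValueError) as exc:
                warnings.warn(f"{path}:{ln}: skipping malformed BED line ({exc})")
                continue
            out.append((iv, name))
    return out


def _read_gff3(path: str) -> list[tuple[Interval, str]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                warnings.warn(f"{path}:{ln}: skipping malformed GFF3 line")
                continue
            try:
                iv = Interval(parts[0], int(parts[3]) - 1, int(parts[4]))
            except ValueError as exc:
                warnings.warn(f"{path}:{ln}: skipping malformed GFF3 line ({exc})")
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or parts[2]
            out.append((iv, name))
    return out


def write_gff3(features: Sequence[tuple[Interval, str]], path: str, source: str = "tetrace") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, name in features:
            fh.write(
                f"{iv.chrom}\t{source}\ttransposable_element\t{iv.start + 1}\t{iv.end}"
                f"\t.\t+\t.\tID={name};Name={name}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
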