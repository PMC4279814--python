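"""End-to-end orchestration: extraction -> clustering/calling grid ->
depth filter -> annotation and donor scoring.

One flat key=value configuration file (JSON also accepted) carries every
path and threshold; command-line overrides take precedence.  All stage
outputs land under an output prefix and a JSON run report records the
library statistics and per-stage counters, so each stage can be re-run
from its predecessor's files with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from . import annotate as _annotate
from . import depthfilter as _depth
from . import discord as _discord
from . import io as _io
from .calling import merge_grid_results, run_grid
from .clustering import partition_points
from .model import GridSpec, MATE_PAIR_ORIENT, PAIRED_END_ORIENT, EventCall

logger = logging.getLogger(__name__)

_REQUIRED = ("bam",)
_NUMERIC_POSITIVE = (
    "min_support",
    "acceptor_max_gap",
    "merge_gap",
    "min_seg_len",
    "min_score_delta",
    "tol",
    "sample_size",
    "read_len",
)


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    bam: str = ""
    fasta: Optional[str] = None
    annotation: Optional[str] = None
    out_prefix: str = "tetrace_out"
    library: str = "mp"  # mp (large-insert) or pe preset
    max_mismatch: int = 1
    sample_size: int = 1_000_000
    min_support: int = 10
    acceptor_max_gap: Optional[float] = None  # None: d_sup
    merge_gap: Optional[int] = None  # None: current Y
    min_seg_len: int = 500
    min_score_delta: int = 1
    tol: int = 300
    read_len: int = 100
    grid_x: tuple[int, ...] = tuple(range(50, 1001, 50))
    grid_y: tuple[int, ...] = tuple(range(100, 5001, 100))
    mask_floor: float = 1000.0
    seed: int = 0
    run_depth_filter: bool = True
    run_annotation: bool = True
    run_scoring: bool = True

    @property
    def proper_orient(self):
        if self.library == "mp":
            return MATE_PAIR_ORIENT
        if self.library == "pe":
            return PAIRED_END_ORIENT
        raise ValueError(f"unknown library preset {self.library!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.grid_x), tuple(self.grid_y))

    def validate(self) -> "PipelineConfig":
        for key in _NUMERIC_POSITIVE:
            v = getattr(self, key)
            if v is not None and v <= 0:
                raise ValueError(f"configuration value {key} must be positive (got {v})")
        if self.max_mismatch < 0:
            raise ValueError("configuration value max_mismatch must be >= 0")
        _ = self.proper_orient
        _ = self.grid
        if not self.bam:
            raise ValueError("configuration value bam (input alignment) is required")
        return self


def _parse_grid_range(text: str) -> tuple[int, ...]:
    """Parse '50:1000:50' or a comma list '100,200' into grid values."""
    if ":" in text:
        start, stop, step = (int(x) for x in text.split(":"))
        return tuple(range(start, stop + 1, step))
    return tuple(int(x) for x in text.split(","))


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def _coerce(key: str, value):
    if key not in _FIELDS:
        raise ValueError(f"unknown configuration key {key!r}")
    if not isinstance(value, str):
        return value
    if key in ("grid_x", "grid_y"):
        return _parse_grid_range(value)
    if value.lower() in ("none", ""):
        return None
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def load_config(
    path: Optional[str] = None, overrides: Optional[dict] = None
) -> PipelineConfig:
    """Read a flat key=value (or JSON) file, apply overrides, validate."""
    values: dict = {}
    if path:
        with open(path) as fh:
            text = fh.read()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            values.update(json.loads(text))
        else:
            for ln, line in enumerate(text.splitlines(), 1):
                line = line.strip()
                if not line or line.startswith(("#", ";")):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                k, v = (s.strip() for s in line.split("=", 1))
                values[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            values[k] = v
    kwargs = {k: _coerce(k, v) for k, v in values.items()}
    cfg = PipelineConfig(**kwargs)
    logger.info("effective configuration: %s", cfg)
    return cfg.validate()


@dataclass
class RunReport:
    library_stats: dict = field(default_factory=dict)
    grid_points: int = 0
    counters: dict = field(default_factory=dict)
    clusters_per_stage: dict = field(default_factory=dict)
    events_called: int = 0
    events_after_depth_filter: int = 0
    excluded_acceptors: int = 0
    outputs: dict = field(default_factory=dict)

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> tuple[list[EventCall], RunReport]:
    """Run every enabled stage; returns final events and the run report."""
    cfg.validate()
    report = RunReport()
    prefix = cfg.out_prefix

    # --- extraction (Eris)
    fragments, ref_lengths = _discord.load_fragments(cfg.bam, cfg.max_mismatch)
    inserts = _discord.sample_inserts(
        fragments.values(), cfg.proper_orient, cfg.sample_size
    )
    if not inserts:
        logger.warning("empty input: writing empty outputs")
        _io.write_events_tsv([], f"{prefix}.events.tsv", annotated=True)
        report.outputs["events"] = f"{prefix}.events.tsv"
        report.write_json(f"{prefix}.report.json")
        return [], report
    stats = _discord.estimate_library_stats(inserts, cfg.proper_orient)
    depths = _discord.window_depths_from_fragments(
        fragments.values(), ref_lengths, read_len=cfg.read_len
    )
    mask = _discord.build_coverage_mask(depths, floor=cfg.mask_floor)
    counters = _discord.ExtractionCounters()
    records = list(
        _discord.extract_discordant_pairs(fragments, stats, mask, counters)
    )
    _io.write_records_tsv(records, f"{prefix}.discordant.tsv")
    report.library_stats = {
        "M": stats.M,
        "MAD": stats.MAD,
        "d_inf": stats.d_inf,
        "d_sup": stats.d_sup,
        "n_sampled": len(inserts),
    }
    report.counters["extraction"] = dataclasses.asdict(counters)
    report.outputs["discordant"] = f"{prefix}.discordant.tsv"

    # --- clustering and calling over the (X, Y) grid (Leto)
    partitions = partition_points(records)
    grid = cfg.grid
    report.grid_points = grid.n_points
    per_point = run_grid(
        partitions,
        grid,
        stats,
        min_support=cfg.min_support,
        acceptor_max_gap=cfg.acceptor_max_gap,
        merge_gap=cfg.merge_gap,
        read_len=cfg.read_len,
    )
    events = merge_grid_results(per_point)
    report.events_called = len(events)
    report.clusters_per_stage["events_per_grid_point"] = {
        f"{x},{y}": len(v) for (x, y), v in sorted(per_point.items())
    }

    # --- depth filter
    if cfg.run_depth_filter and cfg.fasta:
        segments = _depth.compute_depth_segments(cfg.bam, cfg.fasta)
        _depth.write_segments_bed(segments, f"{prefix}.highdepth.bed")
        events, removed = _depth.filter_acceptor_sites(events, segments, cfg.min_seg_len)
        report.excluded_acceptors = len(removed)
        report.outputs["highdepth_bed"] = f"{prefix}.highdepth.bed"
    report.events_after_depth_filter = len(events)

    # --- annotation and donor scoring (Metis)
    if cfg.run_annotation and cfg.annotation:
        features = _io.read_features(cfg.annotation)
        _annotate.annotate_events(events, features)
    if cfg.run_scoring:
        _annotate.score_all_donors(events, records, stats, cfg.min_score_delta)

    _io.write_events_tsv(events, f"{prefix}.events.tsv", annotated=True)
    report.outputs["events"] = f"{prefix}.events.tsv"
    report.write_json(f"{prefix}.report.json")
    return events, report
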