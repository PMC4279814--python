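"""Shared fixtures: small synthetic genomes and one full-scale run.

The full-scale fixture (two 1-Mb chromosomes, a three-copy TE family, 20
injected events, exact-placement alignments at 20x) is session-scoped: it
backs the end-to-end recovery checks and the pipeline tests.
"""

from __future__ import annotations

import dataclasses
import os

import pytest

from tetrace import discord
from tetrace.io import write_fasta, write_gff3
from tetrace.model import GridSpec
from tetrace.calling import merge_grid_results, run_grid
from tetrace.clustering import partition_points
from tetrace.sim import (
    inject_transposition_events,
    make_synthetic_genome,
    plan_events,
)
from tetrace.sim.placement import simulate_exact_placement_sam

E2E_SEED = 20_260_929
MEAN_FRAG = 3000  # L: mean fragment size of the simulated mate-pair library
SD_FRAG = 222.0  # gives an insert-size MAD of ~150 bp


@dataclasses.dataclass
class EndToEndFixture:
    genome: object
    truth: object
    sam_path: str
    fasta_path: str
    gff_path: str
    truth_path: str
    stats: object
    records: list
    pooled: list
    per_point: dict
    workdir: str


@pytest.fixture(scope="session")
def e2e(tmp_path_factory) -> EndToEndFixture:
    """Noiseless 20-event benchmark: genome, truth, SAM, called events."""
    workdir = tmp_path_factory.mktemp("e2e")
    genome = make_synthetic_genome(seed=E2E_SEED)
    events = plan_events(
        genome, n_per_class=5, seed=E2E_SEED + 1, tsd_len=5, max_donor_len=2 * MEAN_FRAG - 1
    )
    truth = inject_transposition_events(genome.seqs, events)

    sam = str(workdir / "placed.sam")
    simulate_exact_placement_sam(
        truth,
        genome.seqs,
        sam,
        groups=genome.groups,
        coverage=20.0,
        mean_frag=MEAN_FRAG,
        sd_frag=SD_FRAG,
        seed=E2E_SEED + 2,
    )
    fasta = str(workdir / "reference.fasta")
    gff = str(workdir / "te.gff3")
    truth_tsv = str(workdir / "truth.tsv")
    write_fasta(genome.seqs, fasta)
    write_gff3(genome.annotation, gff)
    truth.write_tsv(truth_tsv)

    fragments, _ = discord.load_fragments(sam)
    stats = discord.estimate_library_stats(discord.sample_inserts(fragments.values()))
    records = list(discord.extract_discordant_pairs(fragments, stats))
    per_point = run_grid(
        partition_points(records),
        GridSpec((100, 250), (300, 600, 1500)),
        stats,
        min_support=10,
    )
    pooled = merge_grid_results(per_point)
    return EndToEndFixture(
        genome=genome,
        truth=truth,
        sam_path=sam,
        fasta_path=fasta,
        gff_path=gff,
        truth_path=truth_tsv,
        stats=stats,
        records=records,
        pooled=pooled,
        per_point=per_point,
        workdir=str(workdir),
    )
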