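"""Shared fixtures: simulated crosses at the default study scale and toy
transcript/genome builders for annotation tests."""

from __future__ import annotations

import dataclasses

import pytest

from vdmap import (
    CrossSimConfig,
    MappingSignal,
    build_tracks,
    call_peak_interval,
    partition,
    rank_chromosomes,
    read_vcf,
    simulate_pool,
)

N_RECOVERY_SEEDS = 20


@dataclasses.dataclass
class MappedSim:
    """One simulated cross run through classify -> map."""

    config: CrossSimConfig
    sim: object  # SimOutput
    ranks: list
    peak_call: object  # PeakCall
    top_peak_bp: float


def map_simulation(config: CrossSimConfig, outdir, write_genome: bool = False) -> MappedSim:
    sim = simulate_pool(config, outdir, write_genome=write_genome)
    part = partition(read_vcf(sim.vcf))
    tracks = build_tracks(part, config.chrom_lengths)
    signals = [MappingSignal.from_track(t) for t in tracks]
    ranks = rank_chromosomes(signals)
    top_signal = next(s for s in signals if s.chrom == ranks[0].chrom)
    peak_call = call_peak_interval(top_signal)
    return MappedSim(config, sim, ranks, peak_call, ranks[0].peak)


@pytest.fixture(scope="session")
def default_mapped_sims(tmp_path_factory) -> list[MappedSim]:
    """The default cross (5 x 50 Mb, causal at 20 Mb on chr3, 50 mutants,
    30x, markers every 50 kb) simulated and mapped for 20 seeds."""
    root = tmp_path_factory.mktemp("default_sims")
    out = []
    for seed in range(1, N_RECOVERY_SEEDS + 1):
        config = CrossSimConfig(seed=seed)
        out.append(map_simulation(config, root / f"seed{seed}"))
    return out


# ---------------------------------------------------------------------------
# Toy annotation fixtures


def make_genome(seqs: dict[str, str]) -> dict[str, str]:
    return {k: v.upper() for k, v in seqs.items()}


@pytest.fixture
def single_exon_plus():
    """Plus-strand transcript, CDS = genomic 101..109 ('ATG CTG TAA')."""
    from vdmap import TranscriptModel

    genome = make_genome({"toy": "A" * 100 + "ATGCTGTAA" + "A" * 100})
    tx = TranscriptModel(id="t1", chrom="toy", strand="+", exons=[(101, 109)],
                         cds_start=101, cds_end=109, gene="g1")
    return genome, tx
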