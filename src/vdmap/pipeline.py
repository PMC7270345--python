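"""End-to-end pipeline: classify -> map -> subtract -> annotate -> triage.

Each stage writes a machine-readable report; a single summary JSON records
the top chromosome, the called interval, the ranked candidates and the
count reconciliation across stages.  All stages downstream of simulation
are pure functions of their inputs, so a rerun with identical inputs gives
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import background as bg_mod
from . import effects as fx
from . import mapping as mp
from . import triage as tr
from .variants import (
    GenomicInterval,
    VdmapError,
    read_bed,
    read_chrom_lengths,
    read_vcf,
    write_bed,
    write_vcf,
)
from .zygosity import ClassifierConfig, Zygosity, partition

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run.

    ``chrom_lengths`` may be a dict or a path to a 2-column TSV / .fai.
    GFF3+FASTA, background files, prior interval BED and flags TSV are all
    optional; stages that lack their inputs are skipped and logged.
    """

    vcf: str
    chrom_lengths: dict[str, int] | str
    outdir: str
    sample: str | None = None
    background: list[str] = field(default_factory=list)
    gff3: str | None = None
    fasta: str | None = None
    prior_bed: str | None = None
    flags_tsv: str | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    bandwidth_bp: float = mp.DEFAULT_BANDWIDTH_BP
    grid_step_bp: float = mp.DEFAULT_GRID_STEP_BP
    peak_fraction_of_max: float = mp.DEFAULT_PEAK_FRACTION
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cls_cfg = ClassifierConfig(**raw.pop("classifier", {}))
        return cls(classifier=cls_cfg, **raw)

    def resolved_chrom_lengths(self) -> dict[str, int]:
        if isinstance(self.chrom_lengths, dict):
            return dict(self.chrom_lengths)
        return read_chrom_lengths(self.chrom_lengths)


@dataclass
class PipelineResult:
    summary: dict
    outdir: str

    @property
    def summary_path(self) -> str:
        return os.path.join(self.outdir, "summary.json")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write the report bundle.

    Raises VdmapError (with the failing stage in the message) on any fatal
    stage error; the summary is only written on full success.
    """
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    chrom_lengths = config.resolved_chrom_lengths()
    summary: dict = {"parameters": {
        "bandwidth_bp": config.bandwidth_bp,
        "grid_step_bp": config.grid_step_bp,
        "peak_fraction_of_max": config.peak_fraction_of_max,
        "min_depth": config.classifier.min_depth,
        "hom_alt_min_fraction": config.classifier.hom_alt_min_fraction,
        "het_band": [config.classifier.het_low, config.classifier.het_high],
    }}

    # --- stage 1: read + classify -----------------------------------------
    stage = "classify"
    try:
        variants = read_vcf(config.vcf, sample=config.sample)
        part = partition(variants, config.classifier)
    except VdmapError as exc:
        raise VdmapError(f"stage {stage}: {exc}") from exc
    with open(out("classification.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tad_ref\tad_alt\talt_fraction\tzygosity\n")
        for call in part.calls:
            v = call.variant
            frac = "NA" if call.alt_fraction is None else f"{call.alt_fraction:.6f}"
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.ad_ref}\t{v.ad_alt}\t"
                     f"{frac}\t{call.zclass.value}\n")
    summary["classification"] = {"n_input": len(variants), **part.counts}
    logger.info("classify: %s", summary["classification"])

    # --- stage 2: density mapping -----------------------------------------
    stage = "map"
    try:
        tracks = mp.build_tracks(part, chrom_lengths, config.bandwidth_bp, config.grid_step_bp)
    except VdmapError as exc:
        raise VdmapError(f"stage {stage}: {exc}") from exc
    signals = [mp.MappingSignal.from_track(t) for t in tracks]
    mp.write_density_tsv(tracks, signals, out("density.tsv"))
    if config.make_plots and tracks:
        mp.plot_tracks(tracks, signals, out("density.png"))

    called_interval: GenomicInterval | None = None
    if signals:
        ranks = mp.rank_chromosomes(signals)
        top = ranks[0]
        top_signal = next(s for s in signals if s.chrom == top.chrom)
        peak_call = mp.call_peak_interval(top_signal, config.peak_fraction_of_max)
        called_interval = peak_call.interval
        summary["mapping"] = {
            "top_chromosome": top.chrom,
            "peak_bp": top.peak,
            "max_score": top.max_score,
            "interval_status": peak_call.status,
            "ranking": [{"chrom": r.chrom, "max_score": r.max_score, "peak_bp": r.peak}
                        for r in ranks],
        }
        if called_interval is not None:
            write_bed([called_interval], out("interval.bed"))
            summary["mapping"]["interval"] = {
                "chrom": called_interval.chrom,
                "start": called_interval.start,
                "end": called_interval.end,
            }
    else:
        summary["mapping"] = {"top_chromosome": None, "interval_status": "no-snps"}
    logger.info("map: top=%s", summary["mapping"].get("top_chromosome"))

    # --- stage 3: background subtraction (on the hom-alt candidate stream) -
    stage = "subtract"
    candidates = [c.variant for c in part.hom_alt]
    if config.background:
        try:
            from .variants import load_background

            bg = load_background(config.background)
        except VdmapError as exc:
            raise VdmapError(f"stage {stage}: {exc}") from exc
    else:
        from .variants import BackgroundSet

        bg = BackgroundSet()
    sub = bg_mod.subtract(candidates, bg)
    write_vcf(sub.kept, out("survivors.vcf"), chrom_lengths)
    write_vcf(sub.removed, out("removed.vcf"), chrom_lengths)
    summary["subtraction"] = {
        "n_input": sub.n_input,
        "n_kept": len(sub.kept),
        "n_removed": len(sub.removed),
        "removed_by_source": dict(sorted(sub.removed_by_source.items())),
        "n_background_keys": len(bg),
    }
    logger.info("subtract: %s", summary["subtraction"])

    # --- stage 4: effect annotation ---------------------------------------
    stage = "annotate"
    effects: list[fx.EffectCall] | None = None
    if config.gff3 and config.fasta:
        try:
            import pyfaidx

            transcripts = fx.load_transcripts(config.gff3)
            genome = pyfaidx.Fasta(config.fasta)
            all_calls = fx.annotate_all(sub.kept, transcripts, genome)
        except VdmapError as exc:
            raise VdmapError(f"stage {stage}: {exc}") from exc
        fx.write_effects_tsv(all_calls, out("effects.tsv"))
        effects = fx.most_severe_per_variant(all_calls)
        counts: dict[str, int] = {}
        for e in effects:
            counts[e.consequence] = counts.get(e.consequence, 0) + 1
        summary["annotation"] = {"n_variants": len(effects),
                                 "consequences": dict(sorted(counts.items()))}
        logger.info("annotate: %s", summary["annotation"])
    else:
        summary["annotation"] = {"skipped": "no GFF3/FASTA supplied"}

    # --- stage 5: triage ---------------------------------------------------
    stage = "triage"
    if effects is not None:
        intervals: list[GenomicInterval] = []
        if called_interval is not None:
            intervals.append(called_interval)
        if config.prior_bed:
            intervals.extend(read_bed(config.prior_bed))
        flags = tr.load_flags(config.flags_tsv) if config.flags_tsv else None
        result = tr.run_triage(effects, intervals, flags)
        tr.write_triage_tsv(result, out("triage_report.tsv"), out("triage_audit.tsv"))
        if not result.reconciles:  # pragma: no cover - internal consistency
            raise VdmapError("stage triage: audit counts do not reconcile")
        summary["triage"] = {
            "n_input": result.stages[0].n_in if result.stages else 0,
            "n_candidates": len(result.survivors),
            "stages": [{"name": s.name, "n_in": s.n_in, "n_kept": s.n_kept,
                        "n_removed": s.n_removed} for s in result.stages],
            "top_candidates": [
                {"chrom": c.effect.variant.chrom, "pos": c.effect.variant.pos,
                 "gene": c.effect.gene, "consequence": c.effect.consequence,
                 "cdna": c.effect.cdna_notation, "protein": c.effect.protein_notation}
                for c in result.survivors[:10]
            ],
        }
        logger.info("triage: %d candidates", len(result.survivors))
    else:
        summary["triage"] = {"skipped": "no annotation available"}

    # --- count reconciliation ---------------------------------------------
    cls = summary["classification"]
    recon = {
        "classification_balances": cls["n_input"] == sum(
            cls[z.value] for z in Zygosity
        ),
        "subtraction_balances": summary["subtraction"]["n_input"]
        == summary["subtraction"]["n_kept"] + summary["subtraction"]["n_removed"],
    }
    if effects is not None and "stages" in summary["triage"]:
        recon["triage_balances"] = (
            summary["triage"]["n_input"]
            == summary["triage"]["n_candidates"]
            + sum(s["n_removed"] for s in summary["triage"]["stages"])
        )
    recon["all_balance"] = all(recon.values())
    summary["reconciliation"] = recon
    if not recon["all_balance"]:  # pragma: no cover - internal consistency
        raise VdmapError("pipeline count reconciliation failed")

    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(summary, config.outdir)
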