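"""Candidate triage: interval intersection, protein-changing filter, ranking.

The final narrowing steps of the mapping pipeline: restrict annotated
variants to the mapped (or prior genetic) interval, keep those that change
the protein, then eliminate candidates whose gene is flagged as not
expressed during early development or whose site is flagged as not in a
conserved region.  Flags are curated knowledge supplied as a TSV; an
*unknown* flag never eliminates a candidate, it only ranks it lower.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .effects import EffectCall, SEVERITY
from .variants import GenomicInterval, VdmapError

PROTEIN_CHANGING = frozenset(
    {"missense", "nonsense", "stop_loss", "frameshift", "inframe_indel", "splice_site"}
)

_TRI = {"true": True, "false": False, "unknown": None, "": None, "na": None}


@dataclass
class GeneAnnotationFlags:
    """Expression / conservation flags; tri-state (True / False / None=unknown).

    Conservation may be given per gene or per variant site; a per-variant
    entry overrides the gene-level one.
    """

    gene_flags: dict[str, tuple[bool | None, bool | None]] = field(default_factory=dict)
    variant_conserved: dict[tuple[str, int], bool | None] = field(default_factory=dict)

    def expressed_early(self, gene: str) -> bool | None:
        return self.gene_flags.get(gene, (None, None))[0]

    def conserved(self, gene: str, chrom: str, pos: int) -> bool | None:
        if (chrom, pos) in self.variant_conserved:
            return self.variant_conserved[(chrom, pos)]
        return self.gene_flags.get(gene, (None, None))[1]


def load_flags(path: str | os.PathLike) -> GeneAnnotationFlags:
    """Read a flags TSV: gene, expressed_early, conserved [, chrom, pos].

    Values are true/false/unknown (case-insensitive); rows with chrom+pos
    attach the conservation flag to that site instead of the gene.
    """
    flags = GeneAnnotationFlags()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0].lower() == "gene":
                continue
            if len(parts) < 3:
                raise VdmapError(f"{path}:{ln}: expected >= 3 columns (gene, expressed_early, conserved)")
            gene = parts[0]
            try:
                expressed = _TRI[parts[1].strip().lower()]
                conserved = _TRI[parts[2].strip().lower()]
            except KeyError as exc:
                raise VdmapError(f"{path}:{ln}: flag values must be true/false/unknown") from exc
            if len(parts) >= 5 and parts[3] and parts[4]:
                flags.variant_conserved[(parts[3], int(parts[4]))] = conserved
                if gene and gene not in flags.gene_flags:
                    flags.gene_flags[gene] = (expressed, None)
            else:
                flags.gene_flags[gene] = (expressed, conserved)
    return flags


def intersect_interval(effects: list[EffectCall], interval: GenomicInterval) -> list[EffectCall]:
    """Effects whose variant position falls inside the half-open interval."""
    return [e for e in effects if interval.contains(e.variant.chrom, e.variant.pos)]


def filter_protein_changing(effects: list[EffectCall]) -> list[EffectCall]:
    """Keep consequences that alter the protein (incl. splice_site); order preserved."""
    return [e for e in effects if e.consequence in PROTEIN_CHANGING]


@dataclass
class RankedCandidate:
    effect: EffectCall
    expressed_early: bool | None
    conserved: bool | None

    @property
    def n_unknown(self) -> int:
        return (self.expressed_early is None) + (self.conserved is None)


@dataclass
class TriageStage:
    name: str
    n_in: int
    n_kept: int
    removed: list[EffectCall] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept


@dataclass
class TriageResult:
    survivors: list[RankedCandidate]
    stages: list[TriageStage]

    @property
    def reconciles(self) -> bool:
        """input of stage 1 == survivors + removals across all stages."""
        if not self.stages:
            return len(self.survivors) == 0
        total_removed = sum(s.n_removed for s in self.stages)
        return self.stages[0].n_in == len(self.survivors) + total_removed


def rank_candidates(effects: list[EffectCall], flags: GeneAnnotationFlags) -> TriageResult:
    """Eliminate flagged-out candidates, rank the rest.

    A candidate is eliminated when its gene is flagged not expressed early
    or its site flagged not conserved (False); unknown flags never
    eliminate.  Survivors are ranked by consequence severity, then by the
    number of unknown flags ascending, then genomic position.
    """
    kept: list[RankedCandidate] = []
    removed: list[EffectCall] = []
    for e in effects:
        v = e.variant
        expressed = flags.expressed_early(e.gene)
        conserved = flags.conserved(e.gene, v.chrom, v.pos)
        if expressed is False or conserved is False:
            removed.append(e)
        else:
            kept.append(RankedCandidate(e, expressed, conserved))
    kept.sort(key=lambda c: (c.effect.severity, c.n_unknown, c.effect.variant.chrom, c.effect.variant.pos))
    stage = TriageStage("annotation_flags", len(effects), len(kept), removed)
    return TriageResult(kept, [stage])


def run_triage(
    effects: list[EffectCall],
    intervals: list[GenomicInterval],
    flags: GeneAnnotationFlags | None = None,
) -> TriageResult:
    """Full triage: interval intersection(s) -> protein-changing -> flags.

    Each interval (e.g. the called mapping interval and an optional prior
    genetic interval) is applied as its own audited stage; the audit trail
    reconciles exactly (input = survivors + per-stage removals).
    """
    stages: list[TriageStage] = []
    current = list(effects)
    for i, interval in enumerate(intervals):
        kept = intersect_interval(current, interval)
        removed = [e for e in current if e not in kept]
        stages.append(TriageStage(f"interval_{i}_{interval.chrom}:{interval.start}-{interval.end}",
                                  len(current), len(kept), removed))
        current = kept
    kept = filter_protein_changing(current)
    removed = [e for e in current if e.consequence not in PROTEIN_CHANGING]
    stages.append(TriageStage("protein_changing", len(current), len(kept), removed))
    current = kept
    result = rank_candidates(current, flags if flags is not None else GeneAnnotationFlags())
    stages.extend(result.stages)
    return TriageResult(result.survivors, stages)


def write_triage_tsv(result: TriageResult, report_path, audit_path) -> None:
    with open(report_path, "w") as fh:
        fh.write("rank\tchrom\tpos\tref\talt\tgene\ttranscript\tconsequence\tcdna\tprotein\t"
                 "expressed_early\tconserved\n")
        for rank, c in enumerate(result.survivors, 1):
            e, v = c.effect, c.effect.variant
            fmt = lambda x: "unknown" if x is None else str(x).lower()
            fh.write(f"{rank}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{e.gene}\t{e.transcript_id}\t"
                     f"{e.consequence}\t{e.cdna_notation}\t{e.protein_notation}\t"
                     f"{fmt(c.expressed_early)}\t{fmt(c.conserved)}\n")
    with open(audit_path, "w") as fh:
        fh.write("stage\tn_in\tn_kept\tn_removed\n")
        for s in result.stages:
            fh.write(f"{s.name}\t{s.n_in}\t{s.n_kept}\t{s.n_removed}\n")
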