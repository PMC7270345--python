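"""Transcript-level consequence annotation with c. / p. notation.

Annotates variants against transcript models (GFF3 + genome FASTA),
producing a consequence class and the coding-DNA (c.) and protein (p.)
notation for the changes the pipeline cares about: c.NX>Y substitutions,
c.N_MdelXY deletions, c.N_MinsXY insertions, p.XNY missense and p.XNfs
frameshifts.  c. numbering starts at the A of the start codon and counts
spliced coding bases only; minus-strand transcripts count along the
reverse complement.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from functools import cached_property

from Bio.Seq import Seq

from .variants import Variant, VdmapError

logger = logging.getLogger(__name__)

SPLICE_WINDOW_BP = 2  # canonical donor/acceptor dinucleotides

CONSEQUENCES = (
    "frameshift",
    "nonsense",
    "stop_loss",
    "missense",
    "splice_site",
    "inframe_indel",
    "synonymous",
    "noncoding",
    "intergenic",
)
# lower rank = more severe; frameshift and nonsense share the top rank
SEVERITY: dict[str, int] = {
    "frameshift": 0,
    "nonsense": 0,
    "stop_loss": 1,
    "missense": 2,
    "splice_site": 3,
    "inframe_indel": 4,
    "synonymous": 5,
    "noncoding": 6,
    "intergenic": 7,
}


class TranscriptError(VdmapError):
    pass


class ReferenceMismatchError(VdmapError):
    """Genome base(s) at a variant site disagree with the variant's ref allele."""


def fetch_seq(genome, chrom: str, start1: int, end1: int) -> str:
    """Reference bases [start1, end1] (1-based inclusive) as uppercase string.

    ``genome`` may be a plain mapping of chrom -> sequence string or a
    pyfaidx.Fasta object; both support the same slicing.
    """
    return str(genome[chrom][start1 - 1 : end1]).upper()


@dataclass(eq=False)
class TranscriptModel:
    """One transcript: ordered exons, genomic CDS bounds, strand and gene.

    Exons and CDS bounds are 1-based inclusive genomic coordinates.  Models
    whose spliced CDS is shorter than one codon or not a whole number of
    codons are rejected at construction.
    """

    id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # sorted, disjoint, 1-based inclusive
    cds_start: int
    cds_end: int
    gene: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptError(f"{self.id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise TranscriptError(f"{self.id}: no exons")
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end or e < s:
                raise TranscriptError(f"{self.id}: exons overlap or are malformed")
            prev_end = e
        if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
            raise TranscriptError(f"{self.id}: CDS bounds outside exon span")
        n = len(self.cds_positions)
        if n < 3 or n % 3 != 0:
            raise TranscriptError(
                f"{self.id}: spliced CDS length {n} is not a positive multiple of 3"
            )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @cached_property
    def cds_positions(self) -> list[int]:
        """Ascending genomic positions of spliced coding bases."""
        out: list[int] = []
        for s, e in self.exons:
            lo = max(s, self.cds_start)
            hi = min(e, self.cds_end)
            out.extend(range(lo, hi + 1))
        return out

    @cached_property
    def _cds_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self.cds_positions)}

    @cached_property
    def splice_positions(self) -> frozenset[int]:
        """Intronic positions within SPLICE_WINDOW_BP of an exon boundary."""
        out: set[int] = set()
        for i in range(len(self.exons) - 1):
            donor_end = self.exons[i][1]
            acceptor_start = self.exons[i + 1][0]
            for k in range(1, SPLICE_WINDOW_BP + 1):
                out.add(donor_end + k)
                out.add(acceptor_start - k)
        return frozenset(out)

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end

    def in_cds(self, pos: int) -> bool:
        return pos in self._cds_index

    def cds_seq(self, genome) -> str:
        """Spliced CDS in coding orientation (starts with the start codon)."""
        plus = "".join(fetch_seq(genome, self.chrom, s, e)
                       for s, e in self._cds_exon_blocks())
        return str(Seq(plus).reverse_complement()) if self.strand == "-" else plus

    def _cds_exon_blocks(self) -> list[tuple[int, int]]:
        blocks = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                blocks.append((lo, hi))
        return blocks


def cdna_coordinate(variant: Variant, transcript: TranscriptModel) -> int:
    """c. position of a variant (1 = A of ATG), counting spliced coding bases.

    Raises TranscriptError when the position is not inside the spliced CDS;
    intronic / UTR positions are routed elsewhere by the annotator.
    """
    return _cdna_of_position(variant.pos, transcript)


def _cdna_of_position(pos: int, transcript: TranscriptModel) -> int:
    idx = transcript._cds_index.get(pos)
    if idx is None:
        raise TranscriptError(
            f"position {transcript.chrom}:{pos} is not in the spliced CDS of {transcript.id}"
        )
    n = len(transcript.cds_positions)
    return idx + 1 if transcript.strand == "+" else n - idx


@dataclass(frozen=True)
class EffectCall:
    variant: Variant
    transcript_id: str
    gene: str
    consequence: str
    cdna_notation: str = ""
    protein_notation: str = ""

    @property
    def severity(self) -> int:
        return SEVERITY[self.consequence]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_effect(
    variant: Variant,
    transcript: TranscriptModel,
    genome,
    _cds_seq: str | None = None,
) -> EffectCall:
    """Consequence of one variant on one transcript.

    The genome's reference bases at the site must equal the variant's ref
    allele (fatal otherwise — this catches coordinate bugs early).  SNVs in
    the CDS are translated per codon; CDS indels are frameshift when their
    length is not a multiple of 3; variants whose affected bases touch the
    two intronic bases flanking an exon are splice_site; everything else in
    the transcript span is noncoding and outside it intergenic.
    """
    ref_obs = fetch_seq(genome, variant.chrom, variant.pos, variant.pos + len(variant.ref) - 1)
    if ref_obs != variant.ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {ref_obs!r}, variant claims {variant.ref!r}"
        )

    def call(consequence: str, cdna: str = "", prot: str = "") -> EffectCall:
        return EffectCall(variant, transcript.id, transcript.gene, consequence, cdna, prot)

    if variant.is_snv:
        if transcript.in_cds(variant.pos):
            cds_seq = _cds_seq if _cds_seq is not None else transcript.cds_seq(genome)
            return _annotate_cds_snv(variant, transcript, cds_seq, call)
        if variant.pos in transcript.splice_positions:
            return call("splice_site")
        return call("noncoding") if transcript.contains(variant.pos) else call("intergenic")

    # indel (VCF left-anchored): the affected bases exclude the anchor
    if len(variant.ref) > len(variant.alt):  # deletion
        affected = list(range(variant.pos + 1, variant.pos + len(variant.ref)))
    elif len(variant.alt) > len(variant.ref):  # insertion between pos and pos+1
        affected = [variant.pos, variant.pos + 1]
    else:  # equal-length multi-base substitution
        affected = list(range(variant.pos, variant.pos + len(variant.ref)))

    if any(p in transcript.splice_positions for p in affected):
        return call("splice_site")
    if all(transcript.in_cds(p) for p in affected):
        cds_seq = _cds_seq if _cds_seq is not None else transcript.cds_seq(genome)
        return _annotate_cds_indel(variant, transcript, cds_seq, call)
    if any(transcript.contains(p) for p in affected):
        return call("noncoding")
    return call("intergenic")


def _annotate_cds_snv(variant, transcript, cds_seq, call) -> EffectCall:
    c = _cdna_of_position(variant.pos, transcript)
    if transcript.strand == "+":
        ref_c, alt_c = variant.ref, variant.alt
    else:
        ref_c, alt_c = _revcomp(variant.ref), _revcomp(variant.alt)
    codon_idx = (c - 1) // 3
    phase = (c - 1) % 3
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    if ref_codon[phase] != ref_c:
        raise TranscriptError(
            f"{transcript.id}: CDS sequence disagrees with genome at c.{c} "
            f"({ref_codon[phase]} vs {ref_c})"
        )
    alt_codon = ref_codon[:phase] + alt_c + ref_codon[phase + 1 :]
    aa_ref = _translate_codon(ref_codon)
    aa_alt = _translate_codon(alt_codon)
    cdna = f"c.{c}{ref_c}>{alt_c}"
    aa_pos = codon_idx + 1
    if aa_ref == aa_alt:
        return call("synonymous", cdna, f"p.{aa_ref}{aa_pos}=")
    if aa_alt == "*":
        return call("nonsense", cdna, f"p.{aa_ref}{aa_pos}*")
    if aa_ref == "*":
        return call("stop_loss", cdna, f"p.*{aa_pos}{aa_alt}")
    return call("missense", cdna, f"p.{aa_ref}{aa_pos}{aa_alt}")


def _annotate_cds_indel(variant, transcript, cds_seq, call) -> EffectCall:
    ref, alt = variant.ref, variant.alt
    if len(ref) > len(alt):  # deletion of ref[1:] (anchor shared)
        deleted = list(range(variant.pos + 1, variant.pos + len(ref)))
        cs = sorted(_cdna_of_position(p, transcript) for p in deleted)
        cstart, cend = cs[0], cs[-1]
        del_seq = cds_seq[cstart - 1 : cend]
        cdna = f"c.{cstart}del{del_seq}" if cstart == cend else f"c.{cstart}_{cend}del{del_seq}"
        indel_len = len(ref) - len(alt)
        first_changed_c = cstart
    elif len(alt) > len(ref):  # insertion of alt[1:] between pos and pos+1
        flanks = sorted(
            _cdna_of_position(p, transcript) for p in (variant.pos, variant.pos + 1)
        )
        a, b = flanks
        ins_seq = alt[1:] if transcript.strand == "+" else _revcomp(alt[1:])
        cdna = f"c.{a}_{b}ins{ins_seq}"
        indel_len = len(alt) - len(ref)
        first_changed_c = b
    else:
        # equal-length substitution: frame preserved, treated as in-frame edit
        cs = sorted(_cdna_of_position(p, transcript) for p in range(variant.pos, variant.pos + len(ref)))
        sub = alt if transcript.strand == "+" else _revcomp(alt)
        cdna = f"c.{cs[0]}_{cs[-1]}delins{sub}"
        return call("inframe_indel", cdna)

    if indel_len % 3 != 0:
        aa_pos = (first_changed_c - 1) // 3 + 1
        ref_codon = cds_seq[(aa_pos - 1) * 3 : (aa_pos - 1) * 3 + 3]
        return call("frameshift", cdna, f"p.{_translate_codon(ref_codon)}{aa_pos}fs")
    return call("inframe_indel", cdna)


def annotate_all(
    variants: list[Variant],
    transcripts: list[TranscriptModel],
    genome,
) -> list[EffectCall]:
    """Every variant against every overlapping transcript.

    A variant overlapping no transcript gets a single intergenic call.  One
    EffectCall is emitted per (variant, overlapping transcript); downstream
    summaries keep the most severe per variant.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    cds_cache: dict[str, str] = {}
    calls: list[EffectCall] = []
    for variant in variants:
        span_lo = variant.pos
        span_hi = variant.pos + max(len(variant.ref), 2) - 1
        hits = [
            t for t in by_chrom.get(variant.chrom, [])
            if span_lo <= t.tx_end and span_hi >= t.tx_start
        ]
        if not hits:
            calls.append(EffectCall(variant, "", "", "intergenic"))
            continue
        for t in hits:
            if t.id not in cds_cache:
                cds_cache[t.id] = t.cds_seq(genome)
            calls.append(annotate_effect(variant, t, genome, _cds_seq=cds_cache[t.id]))
    return calls


def most_severe_per_variant(calls: list[EffectCall]) -> list[EffectCall]:
    """One call per variant: lowest severity rank, tie-broken by transcript id."""
    best: dict[tuple, EffectCall] = {}
    order: list[tuple] = []
    for c in calls:
        k = c.variant.key
        if k not in best:
            best[k] = c
            order.append(k)
        elif (c.severity, c.transcript_id) < (best[k].severity, best[k].transcript_id):
            best[k] = c
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# GFF3 loading


def load_transcripts(gff3_path: str | os.PathLike) -> list[TranscriptModel]:
    """Build transcript models from a GFF3 (gene/mRNA/exon/CDS features).

    Models whose spliced CDS fails validation are skipped with a warning;
    loading fails only if no valid model remains.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    n_rejected = 0
    for mrna in list(db.features_of_type("mRNA")) + list(db.features_of_type("transcript")):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon", order_by="start")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS", order_by="start")]
        if not cds:
            n_rejected += 1
            continue
        if not exons:
            exons = cds
        gene = ""
        for parent in db.parents(mrna, featuretype="gene"):
            gene = parent.attributes.get("Name", [parent.id])[0]
        if not gene:
            gene = mrna.attributes.get("gene", [mrna.id])[0]
        try:
            models.append(
                TranscriptModel(
                    id=mrna.id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds_start=min(s for s, _ in cds),
                    cds_end=max(e for _, e in cds),
                    gene=gene,
                )
            )
        except TranscriptError as exc:
            logger.warning("rejecting transcript model: %s", exc)
            n_rejected += 1
    if not models:
        raise TranscriptError(f"no valid transcript model in {gff3_path}")
    logger.info("load_transcripts: %d models (%d rejected)", len(models), n_rejected)
    return models


def write_effects_tsv(calls: list[EffectCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\ttranscript\tconsequence\tcdna\tprotein\n")
        for c in calls:
            v = c.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{c.gene}\t{c.transcript_id}\t"
                f"{c.consequence}\t{c.cdna_notation}\t{c.protein_notation}\n"
            )
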