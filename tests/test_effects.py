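"""Consequence annotation: c./p. arithmetic, codon calls vs a whole-protein
translation oracle, splice routing, and strand-flip symmetry."""

import random

import pytest
from Bio.Seq import Seq

from vdmap import TranscriptModel, Variant, annotate_all, annotate_effect, cdna_coordinate
from vdmap.effects import ReferenceMismatchError, TranscriptError, load_transcripts


def rc(s):
    return str(Seq(s).reverse_complement())


def tx(exons, strand="+", chrom="toy", cds=None, tid="t", gene="g"):
    cds_start = cds[0] if cds else exons[0][0]
    cds_end = cds[1] if cds else exons[-1][1]
    return TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=list(exons),
                           cds_start=cds_start, cds_end=cds_end, gene=gene)


class TestCdnaCoordinate:
    def test_plus_strand_single_exon(self):
        t = tx([(101, 109)])
        assert cdna_coordinate(Variant("toy", 105, "A", "G"), t) == 5

    def test_minus_strand_counts_along_reverse_complement(self):
        t = tx([(101, 109)], strand="-")
        assert cdna_coordinate(Variant("toy", 105, "A", "G"), t) == 5
        assert cdna_coordinate(Variant("toy", 109, "A", "G"), t) == 1
        assert cdna_coordinate(Variant("toy", 101, "A", "G"), t) == 9

    def test_two_exon_junction(self):
        t = tx([(101, 106), (201, 203)])
        assert cdna_coordinate(Variant("toy", 201, "A", "G"), t) == 7

    def test_intronic_position_is_rejected(self):
        t = tx([(101, 106), (201, 203)])
        with pytest.raises(TranscriptError):
            cdna_coordinate(Variant("toy", 150, "A", "G"), t)


class TestAnnotateSnv:
    def test_missense_leu_to_pro(self, single_exon_plus):
        genome, t = single_exon_plus  # CDS "ATG CTG TAA"
        call = annotate_effect(Variant("toy", 105, "T", "C"), t, genome)
        assert call.consequence == "missense"
        assert call.cdna_notation == "c.5T>C"
        assert call.protein_notation == "p.L2P"

    def test_synonymous_leu(self, single_exon_plus):
        genome, t = single_exon_plus
        call = annotate_effect(Variant("toy", 106, "G", "A"), t, genome)  # CTG->CTA
        assert call.consequence == "synonymous"
        assert call.cdna_notation == "c.6G>A"

    def test_nonsense(self, single_exon_plus):
        genome, t = single_exon_plus
        call = annotate_effect(Variant("toy", 104, "C", "T"), t, genome)  # CTG->TTG? no
        # c.4 C>T: codon2 CTG -> TTG = Leu (synonymous); use c.5 T>A: CAG=Gln
        assert call.consequence == "synonymous"
        call = annotate_effect(Variant("toy", 105, "T", "A"), t, genome)  # CAG Gln
        assert call.consequence == "missense"
        # build a real stop: c.4_6 codon CTG; T>G at c.5 -> CGG; instead mutate
        # codon2 first base C->T with second base A would need MNV. Use stop_loss:
        call = annotate_effect(Variant("toy", 107, "T", "C"), t, genome)  # TAA->CAA
        assert call.consequence == "stop_loss" and call.protein_notation == "p.*3Q"

    def test_nonsense_on_dedicated_cds(self):
        genome = {"toy": "A" * 100 + "ATGTACTAA" + "A" * 100}  # Met Tyr Stop
        t = tx([(101, 109)])
        call = annotate_effect(Variant("toy", 106, "C", "A"), t, genome)  # TAC->TAA
        assert call.consequence == "nonsense" and call.protein_notation == "p.Y2*"

    def test_reference_mismatch_is_fatal(self, single_exon_plus):
        genome, t = single_exon_plus
        with pytest.raises(ReferenceMismatchError):
            annotate_effect(Variant("toy", 105, "G", "C"), t, genome)

    def test_minus_strand_missense(self):
        # coding sequence ATG CTG TAA on the minus strand of the genome
        cds = "ATGCTGTAA"
        genome = {"toy": "G" * 100 + rc(cds) + "G" * 100}
        t = tx([(101, 109)], strand="-")
        # c.5 is genomic position 105 on minus: genomic base = complement of T = A
        call = annotate_effect(Variant("toy", 105, "A", "G"), t, genome)
        assert call.cdna_notation == "c.5T>C"
        assert call.consequence == "missense" and call.protein_notation == "p.L2P"


class TestAnnotateIndel:
    def test_frameshift_deletion_notation(self):
        genome = {"toy": "A" * 100 + "ATGCTGAAATAA" + "A" * 100}  # ATG CTG AAA TAA
        t = tx([(101, 112)])
        # delete c.4_5 ("CT"): VCF anchor at genomic 103, ref GCT alt G
        call = annotate_effect(Variant("toy", 103, "GCT", "G"), t, genome)
        assert call.consequence == "frameshift"
        assert call.cdna_notation == "c.4_5delCT"
        assert call.protein_notation == "p.L2fs"

    def test_inframe_deletion(self):
        genome = {"toy": "A" * 100 + "ATGCTGAAATAA" + "A" * 100}
        t = tx([(101, 112)])
        call = annotate_effect(Variant("toy", 103, "GCTG", "G"), t, genome)
        assert call.consequence == "inframe_indel"
        assert call.cdna_notation == "c.4_6delCTG"

    def test_frameshift_insertion(self):
        genome = {"toy": "A" * 100 + "ATGCTGTAA" + "A" * 100}
        t = tx([(101, 109)])
        call = annotate_effect(Variant("toy", 104, "C", "CA"), t, genome)
        assert call.consequence == "frameshift"
        assert call.cdna_notation == "c.4_5insA"

    @pytest.mark.parametrize("del_len", range(1, 10))
    @pytest.mark.parametrize("phase", range(3))
    def test_frameshift_iff_length_not_multiple_of_three(self, del_len, phase):
        cds = "ATG" + "CTGAAAGGGTTTCCC" + "TAA"  # 21 bp
        genome = {"toy": "A" * 100 + cds + "A" * 100}
        t = tx([(101, 100 + len(cds))])
        anchor = 103 + phase  # anchor inside CDS; deletion of next del_len bases
        ref = genome["toy"][anchor - 1 : anchor + del_len]
        call = annotate_effect(Variant("toy", anchor, ref, ref[0]), t, genome)
        expected = "frameshift" if del_len % 3 else "inframe_indel"
        assert call.consequence == expected


class TestRouting:
    def test_splice_site_within_two_bp_of_junction(self):
        genome = {"toy": "A" * 300}
        t = None
        exons = [(101, 106), (201, 203)]
        cds = "ATGCTGTAA"
        g = "A" * 100 + cds[:6] + "G" * 94 + cds[6:] + "A" * 100
        genome = {"toy": g}
        t = tx(exons)
        for pos in (107, 108, 199, 200):
            v = Variant("toy", pos, genome["toy"][pos - 1], "T" if genome["toy"][pos - 1] != "T" else "C")
            assert annotate_effect(v, t, genome).consequence == "splice_site"
        deep = Variant("toy", 150, "G", "T")
        assert annotate_effect(deep, t, genome).consequence == "noncoding"

    def test_intergenic_and_noncoding(self, single_exon_plus):
        genome, t = single_exon_plus
        away = Variant("toy", 50, "A", "G")
        assert annotate_effect(away, t, genome).consequence == "intergenic"
        calls = annotate_all([away], [t], genome)
        assert calls[0].consequence == "intergenic" and calls[0].transcript_id == ""

    def test_most_severe_across_transcripts(self, single_exon_plus):
        from vdmap import most_severe_per_variant

        genome, t1 = single_exon_plus
        t2 = tx([(95, 112)], cds=(101, 109), tid="t2")  # same CDS, UTR flanks
        v = Variant("toy", 105, "T", "C")
        calls = annotate_all([v], [t1, t2], genome)
        assert len(calls) == 2
        assert {c.consequence for c in calls} == {"missense"}
        assert len(most_severe_per_variant(calls)) == 1


# ---------------------------------------------------------------------------
# Whole-protein oracle and random fixtures


def random_transcript(rng, chrom_len=4000, chrom="toy"):
    """Random 1-3 exon transcript; exon blocks are all coding, length % 3 == 0."""
    n_exons = rng.randint(1, 3)
    exons = []
    pos = rng.randint(200, 400)
    for _ in range(n_exons):
        length = rng.randint(30, 200)
        exons.append([pos, pos + length - 1])
        pos += length + rng.randint(20, 120)
    total = sum(e - s + 1 for s, e in exons)
    exons[-1][1] -= total % 3
    strand = rng.choice("+-")
    return tx([tuple(e) for e in exons], strand=strand, chrom=chrom)


def oracle_consequence(variant, t, genome):
    """Independent classification by full translation of both alleles."""
    cds_pos = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        cds_pos.extend(range(lo, hi + 1))
    cds_set = set(cds_pos)
    splice = set()
    for i in range(len(t.exons) - 1):
        splice |= {t.exons[i][1] + 1, t.exons[i][1] + 2,
                   t.exons[i + 1][0] - 2, t.exons[i + 1][0] - 1}
    seq = genome[t.chrom]
    plus_cds = "".join(seq[p - 1] for p in cds_pos)
    ref_cds = rc(plus_cds) if t.strand == "-" else plus_cds

    def c_of(p):
        i = cds_pos.index(p)
        return i + 1 if t.strand == "+" else len(cds_pos) - i

    if len(variant.ref) == 1 == len(variant.alt):
        if variant.pos in cds_set:
            c = c_of(variant.pos)
            alt_b = variant.alt if t.strand == "+" else rc(variant.alt)
            alt_cds = ref_cds[: c - 1] + alt_b + ref_cds[c:]
            p_ref = str(Seq(ref_cds).translate())
            p_alt = str(Seq(alt_cds).translate())
            if p_ref == p_alt:
                return "synonymous", None
            i = next(k for k in range(len(p_ref)) if p_ref[k] != p_alt[k])
            if p_alt[i] == "*":
                return "nonsense", f"p.{p_ref[i]}{i+1}*"
            if p_ref[i] == "*":
                return "stop_loss", f"p.*{i+1}{p_alt[i]}"
            return "missense", f"p.{p_ref[i]}{i+1}{p_alt[i]}"
        if variant.pos in splice:
            return "splice_site", None
        return ("noncoding" if t.tx_start <= variant.pos <= t.tx_end else "intergenic"), None

    if len(variant.ref) > len(variant.alt):
        affected = list(range(variant.pos + 1, variant.pos + len(variant.ref)))
    else:
        affected = [variant.pos, variant.pos + 1]
    if any(p in splice for p in affected):
        return "splice_site", None
    if all(p in cds_set for p in affected):
        diff = abs(len(variant.ref) - len(variant.alt))
        return ("frameshift" if diff % 3 else "inframe_indel"), None
    if any(t.tx_start <= p <= t.tx_end for p in affected):
        return "noncoding", None
    return "intergenic", None


def random_variant(rng, t, genome):
    seq = genome[t.chrom]
    pos = rng.randint(max(1, t.tx_start - 50), min(len(seq) - 5, t.tx_end + 50))
    kind = rng.random()
    ref1 = seq[pos - 1]
    if kind < 0.6:  # SNV
        alt = rng.choice([b for b in "ACGT" if b != ref1])
        return Variant(t.chrom, pos, ref1, alt)
    if kind < 0.85:  # deletion of 1-4 bases
        k = rng.randint(1, 4)
        return Variant(t.chrom, pos, seq[pos - 1 : pos + k], ref1)
    ins = "".join(rng.choices("ACGT", k=rng.randint(1, 4)))
    return Variant(t.chrom, pos, ref1, ref1 + ins)


def test_random_snvs_and_indels_match_whole_protein_oracle():
    rng = random.Random(2024)
    n_checked = 0
    while n_checked < 500:
        seq = "".join(rng.choices("ACGT", k=4000))
        genome = {"toy": seq}
        t = random_transcript(rng)
        for _ in range(10):
            v = random_variant(rng, t, genome)
            call = annotate_effect(v, t, genome)
            expected, expected_p = oracle_consequence(v, t, genome)
            assert call.consequence == expected, (v, t.strand, t.exons)
            if expected_p is not None:
                assert call.protein_notation == expected_p
            n_checked += 1


# ---------------------------------------------------------------------------
# Strand-flip symmetry


def flip_variant(v, genome_len, flipped_seq):
    if len(v.ref) == 1 == len(v.alt):
        pos = genome_len - v.pos + 1
        return Variant(v.chrom, pos, rc(v.ref), rc(v.alt))
    if len(v.ref) > len(v.alt):  # deletion of span [pos+1, pos+len-1]
        lo, hi = v.pos + 1, v.pos + len(v.ref) - 1
        flo = genome_len - hi + 1
        anchor = flo - 1
        ref = flipped_seq[anchor - 1 : anchor - 1 + (hi - lo + 2)]
        return Variant(v.chrom, anchor, ref, ref[0])
    anchor = genome_len - v.pos  # insertion between pos and pos+1
    return Variant(v.chrom, anchor, flipped_seq[anchor - 1],
                   flipped_seq[anchor - 1] + rc(v.alt[1:]))


def flip_transcript(t, genome_len):
    exons = sorted((genome_len - e + 1, genome_len - s + 1) for s, e in t.exons)
    return TranscriptModel(id=t.id, chrom=t.chrom,
                           strand="-" if t.strand == "+" else "+",
                           exons=exons,
                           cds_start=genome_len - t.cds_end + 1,
                           cds_end=genome_len - t.cds_start + 1, gene=t.gene)


def test_strand_flip_symmetry():
    """Reverse-complementing the genome and flipping all coordinates and
    strands leaves every consequence class and p. notation unchanged."""
    rng = random.Random(77)
    n = 4000
    for _ in range(25):
        seq = "".join(rng.choices("ACGT", k=n))
        genome = {"toy": seq}
        flipped = {"toy": rc(seq)}
        t = random_transcript(rng)
        t_f = flip_transcript(t, n)
        for _ in range(8):
            v = random_variant(rng, t, genome)
            if v.pos + len(v.ref) > n:  # keep the flip inside the genome
                continue
            v_f = flip_variant(v, n, flipped["toy"])
            a = annotate_effect(v, t, genome)
            b = annotate_effect(v_f, t_f, flipped)
            assert a.consequence == b.consequence, (v, v_f, t.exons, t.strand)
            assert a.protein_notation == b.protein_notation


# ---------------------------------------------------------------------------
# GFF3 loading


GFF = """##gff-version 3
toy\tsrc\tgene\t101\t109\t.\t+\t.\tID=gene:g1;Name=g1
toy\tsrc\tmRNA\t101\t109\t.\t+\t.\tID=t1;Parent=gene:g1
toy\tsrc\texon\t101\t109\t.\t+\t.\tID=t1.e1;Parent=t1
toy\tsrc\tCDS\t101\t109\t.\t+\t0\tID=t1.c1;Parent=t1
toy\tsrc\tgene\t201\t208\t.\t+\t.\tID=gene:bad;Name=bad
toy\tsrc\tmRNA\t201\t208\t.\t+\t.\tID=tbad;Parent=gene:bad
toy\tsrc\texon\t201\t208\t.\t+\t.\tID=tbad.e1;Parent=tbad
toy\tsrc\tCDS\t201\t208\t.\t+\t0\tID=tbad.c1;Parent=tbad
"""


def test_load_transcripts_rejects_bad_cds_length(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(GFF)
    models = load_transcripts(path)
    assert [m.id for m in models] == ["t1"]  # 8 bp CDS model rejected
    assert models[0].gene == "g1" and models[0].cds_positions == list(range(101, 110))
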