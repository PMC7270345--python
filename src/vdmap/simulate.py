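"""Synthetic pooled F2-incross generator.

Emulates the statistical structure of a mapping-by-sequencing experiment: a
recessive mutation induced on one strain, carriers outcrossed to a
polymorphic mapping strain, phenotypic F2 mutants pooled and sequenced.
Every pooled chromosome descends from a gamete selected to carry the
mutation at the causal locus, so it carries the mutagenized-strain allele
at a nearby marker unless recombination separated them: under the Haldane
map function (no interference) that happens with probability

    r(d) = (1 - e^(-2d)) / 2,      d in Morgans,

so the expected mutagenized-allele fraction at genetic distance d is
1 - r(d), decaying from 1 at the locus to 0.5 when unlinked.  Read counts
are Poisson coverage with binomial allele sampling plus a per-read error
rate.  Output is a single-sample VCF (AD field), a ground-truth TSV, a
background catalogue TSV, and a toy genome FASTA + GFF3 (three genes
around the causal site, one harboring it) so annotation runs end to end.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .variants import VdmapError

BASES = "ACGT"

# toy gene cassette geometry, relative to the causal position P (see _gene_cassette)
_CASSETTE_CDS_LEN = 999  # 333 codons
_CAUSAL_OFFSET_IN_CDS = 499  # 0-based; codon 167, phase 1


class SimulationError(VdmapError):
    pass


def haldane_r(d) -> float:
    """Haldane map function: recombination fraction r = (1 - e^(-2d))/2.

    d is genetic distance in Morgans; r rises from 0 (complete linkage) and
    saturates below 0.5 (free recombination).
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise SimulationError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d_arr))
    # keep the bound strict (r < 0.5) even where exp(-2d) underflows at double
    r = np.minimum(r, np.nextafter(0.5, 0.0))
    return float(r) if np.isscalar(d) or d_arr.ndim == 0 else r


def expected_alt_fraction(d) -> float:
    """Expected mutagenized-strain allele fraction in the pool: 1 - r(d)."""
    r = haldane_r(d)
    return 1.0 - r


@dataclass
class CrossSimConfig:
    """Parameters of the simulated cross and sequencing.

    Defaults describe a genre-typical experiment: 5 chromosomes of 50 Mb,
    a pool of 50 homozygous F2 embryos at 30x coverage, strain markers
    every ~50 kb, a uniform 1.25 cM/Mb map rate, and 70% of markers present
    in the background catalogue.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 50_000_000 for i in range(1, 6)}
    )
    causal_chrom: str = "chr3"
    causal_pos: int = 20_000_000
    n_mutants: int = 50
    mean_coverage: float = 30.0
    error_rate: float = 0.005
    marker_spacing: float = 50_000.0
    cm_per_mb: float = 1.25
    background_fraction: float = 0.7
    seed: int = 1

    def __post_init__(self) -> None:
        if self.causal_chrom not in self.chrom_lengths:
            raise SimulationError(f"causal_chrom {self.causal_chrom!r} not in chrom_lengths")
        if not (1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]):
            raise SimulationError("causal_pos outside its chromosome")
        if self.n_mutants < 1:
            raise SimulationError("n_mutants must be >= 1")
        if not (0 <= self.error_rate < 0.5):
            raise SimulationError("error_rate must be in [0, 0.5)")
        if not (0 <= self.background_fraction <= 1):
            raise SimulationError("background_fraction must be in [0, 1]")
        if self.mean_coverage <= 0 or self.marker_spacing <= 0 or self.cm_per_mb <= 0:
            raise SimulationError("coverage, marker spacing and cM/Mb must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise SimulationError(f"chromosome {chrom} has non-positive length")

    def genetic_distance(self, chrom: str, pos: int) -> float | None:
        """Distance to the causal site in Morgans, or None off the causal chromosome."""
        if chrom != self.causal_chrom:
            return None
        return abs(pos - self.causal_pos) * self.cm_per_mb / 1e6 / 100.0


@dataclass(frozen=True)
class MarkerTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    is_causal: bool
    d_morgans: float | None  # None off the causal chromosome
    expected_alt_fraction: float
    hap_count: int  # realized mutagenized-haplotype chromosomes (of 2*n_mutants)
    in_background: bool


@dataclass
class SimTruth:
    config: CrossSimConfig
    causal: MarkerTruth
    markers: list[MarkerTruth]
    causal_gene: str  # gene symbol of the toy gene harboring the causal variant


@dataclass
class SimOutput:
    vcf: str
    truth_tsv: str
    background_tsv: str
    fasta: str | None
    gff3: str | None
    truth: SimTruth


def _gene_cassette(config: CrossSimConfig):
    """Three toy genes around the causal site; geneB (plus strand) harbors it.

    Returns (list of gene dicts, causal ref base, causal alt base).  Each
    CDS is a single exon; geneC is on the minus strand so strand handling
    is exercised end to end.  The causal base sits at phase 1 of a CTG
    codon; the T>C change makes a Leu->Pro missense.
    """
    P = config.causal_pos
    n_codons = _CASSETTE_CDS_LEN // 3
    cds_b = "ATG" + "CTG" * (n_codons - 2) + "TAA"
    assert cds_b[_CAUSAL_OFFSET_IN_CDS] == "T"
    cds_a = "ATG" + "GCT" * 98 + "TAA"  # 300 bp
    cds_c = "ATG" + "AAA" * 98 + "TAA"  # 300 bp, written revcomp on the genome

    start_b = P - _CAUSAL_OFFSET_IN_CDS
    genes = [
        {"gene": "simA", "tx": "simA.t1", "strand": "+", "start": P - 60_000, "cds": cds_a,
         "genome_seq": cds_a},
        {"gene": "simB", "tx": "simB.t1", "strand": "+", "start": start_b, "cds": cds_b,
         "genome_seq": cds_b},
        {"gene": "simC", "tx": "simC.t1", "strand": "-", "start": P + 40_000, "cds": cds_c,
         "genome_seq": _revcomp(cds_c)},
    ]
    for g in genes:
        g["end"] = g["start"] + len(g["genome_seq"]) - 1
        if g["start"] < 1 or g["end"] > config.chrom_lengths[config.causal_chrom]:
            raise SimulationError(
                "causal_pos too close to a chromosome end for the toy gene cassette"
            )
    return genes, "T", "C"


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _chrom_sequence(config: CrossSimConfig, chrom: str, genes) -> np.ndarray:
    """Deterministic per-chromosome reference sequence as a byte array.

    Uses an independent child RNG stream (seed, chrom index, 0) so the
    sequence can be regenerated without consuming the marker stream.
    """
    chroms = sorted(config.chrom_lengths)
    ci = chroms.index(chrom)
    rng = np.random.default_rng([config.seed % (2**31), ci, 0])
    codes = rng.integers(0, 4, size=config.chrom_lengths[chrom], dtype=np.uint8)
    seq = np.frombuffer(bytes(BASES, "ascii"), dtype=np.uint8)[codes]
    if chrom == config.causal_chrom:
        for g in genes:
            block = np.frombuffer(g["genome_seq"].encode(), dtype=np.uint8)
            seq[g["start"] - 1 : g["end"]] = block
    return seq


def simulate_pool(
    config: CrossSimConfig,
    outdir: str | os.PathLike,
    write_genome: bool = True,
) -> SimOutput:
    """Simulate the pooled-mutant sequencing experiment and write its files.

    Draw order is fixed and documented: chromosomes are processed in name
    order; each has independent child RNG streams for reference sequence
    and for markers; within the marker stream all inter-marker spacings are
    drawn first, then per site in coordinate order the haplotype count,
    depth, alt reads and background flag.  Identical config (including
    seed) therefore gives byte-identical outputs; ``write_genome=False``
    skips the FASTA/GFF3 without perturbing any other output.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    genes, causal_ref, causal_alt = _gene_cassette(config)
    chroms = sorted(config.chrom_lengths)
    two_n = 2 * config.n_mutants
    err = config.error_rate

    vcf_path = os.path.join(outdir, "pool.vcf")
    truth_path = os.path.join(outdir, "truth.tsv")
    bg_path = os.path.join(outdir, "background.tsv")
    fasta_path = os.path.join(outdir, "genome.fa") if write_genome else None
    gff3_path = os.path.join(outdir, "annotation.gff3") if write_genome else None

    all_truth: list[MarkerTruth] = []
    causal_truth: MarkerTruth | None = None
    vcf_lines = ["##fileformat=VCFv4.2"]
    for chrom in chroms:
        vcf_lines.append(f"##contig=<ID={chrom},length={config.chrom_lengths[chrom]}>")
    vcf_lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    vcf_lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool")

    fasta_fh = open(fasta_path, "w") if fasta_path else None
    try:
        for ci, chrom in enumerate(chroms):
            length = config.chrom_lengths[chrom]
            seq = _chrom_sequence(config, chrom, genes)
            if fasta_fh is not None:
                fasta_fh.write(f">{chrom}\n")
                raw = seq.tobytes().decode("ascii")
                for i in range(0, length, 60):
                    fasta_fh.write(raw[i : i + 60])
                    fasta_fh.write("\n")

            rng = np.random.default_rng([config.seed % (2**31), ci, 1])
            # marker positions: Poisson process along the chromosome
            n_exp = int(length / config.marker_spacing * 2) + 16
            positions: list[int] = []
            pos = 0.0
            spacings = rng.exponential(config.marker_spacing, size=n_exp)
            si = 0
            while True:
                if si >= len(spacings):
                    spacings = rng.exponential(config.marker_spacing, size=n_exp)
                    si = 0
                pos += max(1.0, spacings[si])
                si += 1
                ipos = int(round(pos))
                if ipos > length:
                    break
                if chrom == config.causal_chrom and ipos == config.causal_pos:
                    continue
                if positions and ipos <= positions[-1]:
                    ipos = positions[-1] + 1
                    if chrom == config.causal_chrom and ipos == config.causal_pos:
                        ipos += 1
                    if ipos > length:
                        break
                positions.append(ipos)

            sites: list[tuple[int, bool]] = [(p, False) for p in positions]
            if chrom == config.causal_chrom:
                sites.append((config.causal_pos, True))
                sites.sort()

            for p, is_causal in sites:
                ref = chr(seq[p - 1])
                if is_causal:
                    assert ref == causal_ref
                    alt = causal_alt
                    d = 0.0
                    exp_frac = 1.0
                    hap = two_n
                    q = 1.0
                    in_bg = False
                    depth = int(rng.poisson(config.mean_coverage))
                    n_alt = int(rng.binomial(depth, 1.0 - err)) if depth > 0 else 0
                else:
                    others = [b for b in BASES if b != ref]
                    alt = others[int(rng.integers(0, 3))]
                    d = config.genetic_distance(chrom, p)
                    if d is None:
                        p_link, exp_frac = 0.5, 0.5
                    else:
                        p_link = expected_alt_fraction(d)
                        exp_frac = p_link
                    hap = int(rng.binomial(two_n, p_link))
                    q = hap / two_n
                    depth = int(rng.poisson(config.mean_coverage))
                    p_read = q * (1.0 - err) + (1.0 - q) * err
                    n_alt = int(rng.binomial(depth, p_read)) if depth > 0 else 0
                    in_bg = bool(rng.random() < config.background_fraction)
                ad_ref = depth - n_alt
                vcf_lines.append(f"{chrom}\t{p}\t.\t{ref}\t{alt}\t.\tPASS\t.\tAD\t{ad_ref},{n_alt}")
                truth = MarkerTruth(chrom, p, ref, alt, is_causal, d, exp_frac, hap, in_bg)
                all_truth.append(truth)
                if is_causal:
                    causal_truth = truth
    finally:
        if fasta_fh is not None:
            fasta_fh.close()

    assert causal_truth is not None
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(vcf_lines) + "\n")
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tis_causal\td_morgans\texpected_alt_fraction\t"
                 "hap_count\tin_background\n")
        for t in all_truth:
            d_str = "NA" if t.d_morgans is None else f"{t.d_morgans:.8f}"
            fh.write(f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{int(t.is_causal)}\t{d_str}\t"
                     f"{t.expected_alt_fraction:.8f}\t{t.hap_count}\t{int(t.in_background)}\n")
    with open(bg_path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for t in all_truth:
            if t.in_background and not t.is_causal:
                fh.write(f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\n")

    if gff3_path is not None:
        _write_gff3(gff3_path, config, genes)

    truth = SimTruth(config=config, causal=causal_truth, markers=all_truth, causal_gene="simB")
    return SimOutput(vcf_path, truth_path, bg_path, fasta_path, gff3_path, truth)


def _write_gff3(path: str, config: CrossSimConfig, genes) -> None:
    chrom = config.causal_chrom
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {config.chrom_lengths[chrom]}\n")
        for g in genes:
            s, e, st = g["start"], g["end"], g["strand"]
            fh.write(f"{chrom}\tsim\tgene\t{s}\t{e}\t.\t{st}\t.\t"
                     f"ID=gene:{g['gene']};Name={g['gene']}\n")
            fh.write(f"{chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{st}\t.\t"
                     f"ID={g['tx']};Parent=gene:{g['gene']}\n")
            fh.write(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{st}\t.\t"
                     f"ID={g['tx']}.exon1;Parent={g['tx']}\n")
            fh.write(f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{st}\t0\t"
                     f"ID={g['tx']}.cds;Parent={g['tx']}\n")
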