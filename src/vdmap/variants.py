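"""Core domain types and readers/writers for the formats the pipeline touches.

The atom of the pipeline is a :class:`Variant`: one called site with its
allele depths from the pooled-mutant sequencing.  Coordinates follow each
format's native convention — variants are 1-based (VCF), intervals are
0-based half-open (BED) — and conversion happens only at the boundary.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class VdmapError(Exception):
    """Base class for fatal pipeline errors."""


class VcfError(VdmapError):
    pass


class BackgroundError(VdmapError):
    pass


@dataclass(frozen=True, order=True)
class Variant:
    """One called site: chrom, 1-based position, ref/alt and allele depths.

    ``ad_ref``/``ad_alt`` are the reference- and alternate-supporting read
    counts for the pooled sample; their sum is the only depth the pipeline
    trusts (no separate DP field is consulted).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ad_ref: int = 0
    ad_alt: int = 0
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{name} allele {allele!r} does not match [ACGTN]+")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def depth(self) -> int:
        return self.ad_ref + self.ad_alt

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def contains(self, chrom: str, pos1: int) -> bool:
        """Whether a variant at 1-based position ``pos1`` falls inside.

        The position is compared against [start, end) so the end coordinate
        is exclusive: a variant exactly at ``end`` is outside.
        """
        return chrom == self.chrom and self.start <= pos1 < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


class BackgroundSet:
    """Exact-match catalogue of (chrom, pos, ref, alt) background keys.

    Membership is exact tuple equality — a variant is only considered
    background if chrom, position and both alleles match, so a causal allele
    that happens to sit on a known polymorphic position is never deleted.
    """

    def __init__(self) -> None:
        self._sources: dict[tuple[str, int, str, str], set[str]] = {}

    def add(self, key: tuple[str, int, str, str], source: str) -> None:
        self._sources.setdefault(key, set()).add(source)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._sources

    def __len__(self) -> int:
        return len(self._sources)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return set(self._sources)

    def sources_of(self, key: tuple[str, int, str, str]) -> tuple[str, ...]:
        return tuple(sorted(self._sources.get(key, ())))


# ---------------------------------------------------------------------------
# VCF reading


def read_vcf(path: str | os.PathLike, sample: str | None = None) -> list[Variant]:
    """Read AD-bearing VCF records into per-alt :class:`Variant` objects.

    Multi-allelic records are split into one Variant per alternate allele,
    each keeping the shared reference depth.  Records without parseable
    allele depths (or with symbolic alleles) are skipped and counted in the
    log.  Raises :class:`VcfError` on a missing file, on a VCF with zero
    usable records, or when no record carries an AD field at all.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VcfError(f"VCF not found: {path}")
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if sample is None:
        if len(samples) == 1:
            sample = samples[0]
        elif len(samples) > 1:
            raise VcfError(
                f"VCF {path} has {len(samples)} samples; pass the sample name explicitly"
            )
    elif sample not in samples:
        raise VcfError(f"sample {sample!r} not in VCF {path} (has {samples})")

    variants: list[Variant] = []
    n_records = 0
    n_skipped = 0
    saw_ad = False
    first_bad: str | None = None
    for rec in vcf:
        n_records += 1
        ad = None
        if sample is not None and sample in rec.samples:
            ad = rec.samples[sample].get("AD")
        if ad is None or any(a is None for a in ad):
            n_skipped += 1
            if first_bad is None:
                first_bad = f"{rec.chrom}:{rec.pos}"
            continue
        alts = rec.alts or ()
        if len(ad) != 1 + len(alts):
            n_skipped += 1
            if first_bad is None:
                first_bad = f"{rec.chrom}:{rec.pos}"
            continue
        saw_ad = True
        for alt, ad_alt in zip(alts, ad[1:]):
            alt = (alt or "").upper()
            ref = rec.ref.upper()
            if not _ALLELE_RE.match(alt) or not _ALLELE_RE.match(ref) or alt == ref:
                n_skipped += 1
                continue
            variants.append(
                Variant(rec.chrom, rec.pos, ref, alt, int(ad[0]), int(ad_alt), source=path)
            )
    vcf.close()

    if n_records == 0:
        raise VcfError(f"VCF {path} contains no records (header only)")
    if not saw_ad:
        raise VcfError(
            f"no record in {path} carries a parseable AD (allele depth) field for "
            f"sample {sample!r}; re-call variants with per-allele depths enabled"
        )
    if not variants:
        raise VcfError(
            f"VCF {path} has zero usable records; first unusable record at {first_bad}"
        )
    logger.info("read_vcf: %s -> %d variants (%d records, %d skipped)",
                path, len(variants), n_records, n_skipped)
    return variants


def write_vcf(
    variants: list[Variant],
    path: str | os.PathLike,
    chrom_lengths: dict[str, int] | None = None,
    sample: str = "pool",
) -> None:
    """Write variants as a minimal single-sample VCF 4.2 with AD genotypes.

    Output is byte-deterministic for a given input (sorted records, fixed
    header, no timestamps).
    """
    lines = ["##fileformat=VCFv4.2"]
    if chrom_lengths:
        for chrom in sorted(chrom_lengths):
            lines.append(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tAD\t{v.ad_ref},{v.ad_alt}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike) -> None:
    """Write BED3(+score), sorted by chrom then start; half-open 0-based."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
            if iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VdmapError(f"{path}:{ln}: not a BED line: {line!r}")
            score = float(parts[3]) if len(parts) > 3 else None
            intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), score))
    return intervals


# ---------------------------------------------------------------------------
# Background catalogues


def _looks_like_vcf(path: str) -> bool:
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return True
    opener = open
    try:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            import gzip
            opener = gzip.open  # type: ignore[assignment]
        with opener(path, "rt") as fh:  # type: ignore[call-overload]
            first = fh.readline()
        return first.startswith("##fileformat=VCF")
    except OSError:
        return False


def load_background(paths: list[str | os.PathLike]) -> BackgroundSet:
    """Union background catalogues (VCF or 4-column TSV) into one exact-key set.

    Duplicate keys across files collapse; each key remembers every source
    file that contributed it, so subtraction can report per-source counts.
    """
    bg = BackgroundSet()
    for path in paths:
        path = os.fspath(path)
        label = os.path.basename(path)
        n_before = len(bg)
        n_keys = 0
        if _looks_like_vcf(path):
            try:
                vcf = pysam.VariantFile(path)
            except (OSError, ValueError) as exc:
                raise BackgroundError(f"cannot parse background VCF {path}: {exc}") from exc
            for rec in vcf:
                for alt in rec.alts or ():
                    alt = (alt or "").upper()
                    ref = rec.ref.upper()
                    if _ALLELE_RE.match(alt) and _ALLELE_RE.match(ref) and alt != ref:
                        bg.add((rec.chrom, rec.pos, ref, alt), label)
                        n_keys += 1
            vcf.close()
        else:
            with open(path) as fh:
                for ln, line in enumerate(fh, 1):
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    parts = line.split("\t")
                    if len(parts) < 4:
                        raise BackgroundError(
                            f"{path}:{ln}: expected 4 tab-separated columns "
                            f"(chrom, pos, ref, alt), got {len(parts)}"
                        )
                    try:
                        pos = int(parts[1])
                    except ValueError:
                        if ln == 1:  # optional header line
                            continue
                        raise BackgroundError(
                            f"{path}:{ln}: position {parts[1]!r} is not an integer"
                        ) from None
                    ref, alt = parts[2].upper(), parts[3].upper()
                    if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
                        raise BackgroundError(f"{path}:{ln}: bad alleles {parts[2]!r}/{parts[3]!r}")
                    bg.add((parts[0], pos, ref, alt), label)
                    n_keys += 1
        logger.info("load_background: %s contributed %d keys (%d new)",
                    label, n_keys, len(bg) - n_before)
    return bg


# ---------------------------------------------------------------------------
# Chromosome lengths


def read_chrom_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Read chrom lengths from a 2+-column TSV (chrom, length) or a .fai index."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise VdmapError(f"{path}:{ln}: expected at least 2 columns")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                if ln == 1:
                    continue
                raise VdmapError(f"{path}:{ln}: length {parts[1]!r} is not an integer") from None
    if not lengths:
        raise VdmapError(f"no chromosome lengths found in {path}")
    return lengths
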