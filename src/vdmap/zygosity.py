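"""Zygosity classification of pooled variants from allele depths.

In a pool of homozygous mutants, a site that is homozygous in every pooled
individual shows an alternate-allele read fraction near 1, while a strain
polymorphism still segregating in the pool sits near 0.5.  The classifier
turns each variant's allele depths into one of four classes — hom_alt, het,
hom_ref or ambiguous — which is the partition the density mapping consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .variants import Variant, VdmapError


class Zygosity(str, enum.Enum):
    HOM_ALT = "hom_alt"
    HET = "het"
    HOM_REF = "hom_ref"
    AMBIGUOUS = "ambiguous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifierConfig:
    """Depth and allele-fraction thresholds for pooled zygosity calls.

    Defaults (depth >= 10, hom at fraction >= 0.9, het in [0.2, 0.8]) follow
    common mapping-by-sequencing practice; fractions falling in the gaps are
    called ambiguous rather than forced into a class.
    """

    min_depth: int = 10
    hom_alt_min_fraction: float = 0.9
    het_low: float = 0.2
    het_high: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.het_low < self.het_high < self.hom_alt_min_fraction <= 1):
            raise ValueError(
                "require 0 < het_low < het_high < hom_alt_min_fraction <= 1, got "
                f"{self.het_low}/{self.het_high}/{self.hom_alt_min_fraction}"
            )
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")


@dataclass(frozen=True)
class ZygosityCall:
    variant: Variant
    zclass: Zygosity
    alt_fraction: float | None  # None when total depth is zero


class ZeroDepthError(VdmapError):
    """Raised when an alt fraction is requested at zero total depth."""


def alt_fraction(variant: Variant) -> float:
    """ad_alt / (ad_ref + ad_alt); zero total depth is an error, not 0.0."""
    depth = variant.depth
    if depth == 0:
        raise ZeroDepthError(f"zero total depth at {variant.chrom}:{variant.pos}")
    return variant.ad_alt / depth


def classify_zygosity(variant: Variant, config: ClassifierConfig = ClassifierConfig()) -> ZygosityCall:
    """Classify one variant; band edges are inclusive as documented.

    depth < min_depth -> ambiguous; fraction >= hom_alt_min_fraction ->
    hom_alt; fraction in [het_low, het_high] -> het; fraction <=
    1 - hom_alt_min_fraction -> hom_ref; anything else -> ambiguous.
    """
    if variant.depth == 0:
        return ZygosityCall(variant, Zygosity.AMBIGUOUS, None)
    frac = alt_fraction(variant)
    if variant.depth < config.min_depth:
        return ZygosityCall(variant, Zygosity.AMBIGUOUS, frac)
    if frac >= config.hom_alt_min_fraction:
        return ZygosityCall(variant, Zygosity.HOM_ALT, frac)
    if config.het_low <= frac <= config.het_high:
        return ZygosityCall(variant, Zygosity.HET, frac)
    # test the ref fraction directly so the band is exactly symmetric in floats
    if variant.ad_ref / variant.depth >= config.hom_alt_min_fraction:
        return ZygosityCall(variant, Zygosity.HOM_REF, frac)
    return ZygosityCall(variant, Zygosity.AMBIGUOUS, frac)


@dataclass
class PartitionResult:
    """Stable-order partition of calls plus bookkeeping counts.

    Only hom_alt and het calls feed the density mapping; hom_ref and
    ambiguous calls are retained in the counts report.
    """

    hom_alt: list[ZygosityCall] = field(default_factory=list)
    het: list[ZygosityCall] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    calls: list[ZygosityCall] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def partition(variants: list[Variant], config: ClassifierConfig = ClassifierConfig()) -> PartitionResult:
    """Classify every variant and split out the hom_alt / het lists."""
    result = PartitionResult(counts={z.value: 0 for z in Zygosity})
    for variant in variants:
        call = classify_zygosity(variant, config)
        result.calls.append(call)
        result.counts[call.zclass.value] += 1
        if call.zclass is Zygosity.HOM_ALT:
            result.hom_alt.append(call)
        elif call.zclass is Zygosity.HET:
            result.het.append(call)
    return result
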