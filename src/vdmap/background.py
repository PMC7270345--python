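"""Background-strain SNP subtraction.

Removes variants whose exact (chrom, pos, ref, alt) key appears in a
background catalogue — the polymorphisms of the mapping strain and any
previously published SNP lists — leaving only candidate mutations.
Matching is allele-exact: a different alternate allele at a catalogued
position is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .variants import BackgroundSet, Variant

logger = logging.getLogger(__name__)


@dataclass
class SubtractionResult:
    kept: list[Variant]
    removed: list[Variant]
    removed_by_source: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)


def subtract(variants: list[Variant], background: BackgroundSet) -> SubtractionResult:
    """Partition variants into (kept, removed) by exact background membership.

    Order is preserved in both output lists; kept + removed always
    reconstitutes the input.  Removal counts are attributed to every source
    file that catalogued the key.
    """
    kept: list[Variant] = []
    removed: list[Variant] = []
    by_source: dict[str, int] = {}
    for variant in variants:
        if variant.key in background:
            removed.append(variant)
            for src in background.sources_of(variant.key):
                by_source[src] = by_source.get(src, 0) + 1
        else:
            kept.append(variant)
    logger.info("subtract: %d in -> %d kept, %d removed (%s)",
                len(variants), len(kept), len(removed),
                ", ".join(f"{k}:{v}" for k, v in sorted(by_source.items())) or "no sources")
    return SubtractionResult(kept, removed, by_source)
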