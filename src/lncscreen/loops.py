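"""Chromatin-loop support: is a candidate element looped to a gene's promoter?

A Hi-C loop supports an element/promoter pair when one anchor overlaps
the element and the other overlaps the promoter (either anchor order,
1-bp overlap threshold — resolution-aware padding, if wanted, belongs on
the anchors before they reach this module).  Peak support (CTCF,
H3K27ac) is recorded per anchor of each supporting loop, mirroring the
enrichment expected at loop contact points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations_io import (
    GenomicInterval,
    GeneRecord,
    LoopSet,
    PeakSet,
    intervals_overlap,
)

DEFAULT_PROMOTER_UPSTREAM_BP = 2_000
DEFAULT_PROMOTER_DOWNSTREAM_BP = 500


@dataclass(frozen=True)
class LoopSupport:
    """Loop evidence connecting one candidate element to one promoter.

    ``anchor_peak_support`` maps mark -> list (parallel to
    ``supporting_loops``) of (element-side, promoter-side) booleans: does a
    peak of that mark overlap each anchor of the supporting loop?
    """

    candidate_element: GenomicInterval
    promoter: GenomicInterval
    supporting_loops: tuple[int, ...]
    anchor_peak_support: dict[str, tuple[tuple[bool, bool], ...]] = field(default_factory=dict)

    @property
    def supported(self) -> bool:
        return len(self.supporting_loops) > 0


def promoter_region(
    gene: GeneRecord,
    upstream_bp: int = DEFAULT_PROMOTER_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_PROMOTER_DOWNSTREAM_BP,
) -> GenomicInterval:
    """Strand-aware proximal-promoter window around the TSS, clipped at 0.

    For a + gene the window is [tss - upstream, tss + downstream); for a -
    gene it is mirrored about the TSS base, [tss - downstream,
    tss + upstream + 1) — the minus-strand window carries the TSS base on
    its upstream edge (a declared convention; see docs/methods.md).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("promoter window sizes must be >= 0")
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream_bp, tss + downstream_bp
    else:
        start, end = tss - downstream_bp, tss + upstream_bp + 1
    return GenomicInterval(gene.body.chrom, max(0, start), end, gene.strand)


def find_supporting_loops(
    element: GenomicInterval,
    promoter: GenomicInterval,
    loops: LoopSet,
    peaks: list[PeakSet] | None = None,
) -> LoopSupport:
    """Find loops whose anchors connect ``element`` to ``promoter``.

    Anchor order within each loop is irrelevant.  For each supporting
    loop and each provided mark track, records whether a peak overlaps
    the element-side and promoter-side anchors.
    """
    peaks = peaks or []
    supporting: list[int] = []
    # (element-side anchor, promoter-side anchor) per supporting loop
    oriented_anchors: list[tuple[GenomicInterval, GenomicInterval]] = []
    for i, loop in enumerate(loops):
        if intervals_overlap(loop.anchor_a, element) and intervals_overlap(loop.anchor_b, promoter):
            supporting.append(i)
            oriented_anchors.append((loop.anchor_a, loop.anchor_b))
        elif intervals_overlap(loop.anchor_b, element) and intervals_overlap(loop.anchor_a, promoter):
            supporting.append(i)
            oriented_anchors.append((loop.anchor_b, loop.anchor_a))

    anchor_support = {
        ps.mark: tuple(
            (ps.overlaps(elem_anchor), ps.overlaps(prom_anchor))
            for elem_anchor, prom_anchor in oriented_anchors
        )
        for ps in peaks
    }
    return LoopSupport(
        candidate_element=element,
        promoter=promoter,
        supporting_loops=tuple(supporting),
        anchor_peak_support=anchor_support,
    )
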