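"""Proximity screen: find lncRNAs near genes of interest, excluding antisense overlaps.

Implements the first two gates of the candidate funnel: a lncRNA must lie
within a window (default 1 Mbp) upstream or downstream of a GOI, and must
not overlap the GOI on the opposite strand.  Distances are body-to-body
gaps — the most permissive reading of browser-level proximity — and the
window comparison is inclusive (distance == window passes).
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotations_io import (
    INF_DISTANCE,
    GeneRecord,
    interval_overlap_bp,
)

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class ProximalPair:
    """One (lncRNA, GOI) pair surviving the proximity gate.

    ``orientation`` is relative to the GOI's strand: *downstream* means the
    lncRNA lies on the GOI's 3' side.  ``antisense_overlap`` records
    criterion (b): body overlap on opposite strands.
    """

    lnc_id: str
    goi_id: str
    distance_bp: int
    orientation: str  # upstream | downstream | overlapping
    same_strand: bool
    antisense_overlap: bool

    def __post_init__(self) -> None:
        if (self.distance_bp == 0) != (self.orientation == "overlapping"):
            raise ValueError("distance_bp == 0 iff orientation == overlapping")


def gene_distance(a: GeneRecord, b: GeneRecord) -> float:
    """Gap in bp between two gene bodies; 0 if they overlap or abut.

    Returns ``INF_DISTANCE`` (float inf) for genes on different
    chromosomes, so any finite window excludes trans pairs.
    """
    ia, ib = a.body, b.body
    if ia.chrom != ib.chrom:
        return INF_DISTANCE
    if interval_overlap_bp(ia, ib) > 0:
        return 0
    # gap between nearest boundaries; abutting bodies have gap 0
    return max(ia.start, ib.start) - min(ia.end, ib.end)


def has_antisense_overlap(lnc: GeneRecord, goi: GeneRecord, exon_level: bool = False) -> bool:
    """Criterion (b): do the two genes overlap on opposite strands?

    Same-strand overlap is *not* antisense and is not excluded by the
    screen.  By default overlap is judged on gene bodies; ``exon_level``
    restricts the test to annotated exons (falling back to bodies for
    genes without exon annotation).
    """
    if lnc.strand == goi.strand:
        return False
    if not exon_level:
        return interval_overlap_bp(lnc.body, goi.body) > 0
    lnc_ivs = lnc.exons or (lnc.body,)
    goi_ivs = goi.exons or (goi.body,)
    return any(
        interval_overlap_bp(le, ge) > 0 for le in lnc_ivs for ge in goi_ivs
    )


def _orientation(lnc: GeneRecord, goi: GeneRecord, distance_bp: float) -> str:
    """upstream/downstream/overlapping of lnc relative to the GOI's strand.

    Abutting bodies (gap exactly 0) are labelled overlapping so that
    distance 0 and the overlapping label coincide.
    """
    if distance_bp == 0:
        return "overlapping"
    right_of_goi = lnc.body.start >= goi.body.end
    if goi.strand == "+":
        return "downstream" if right_of_goi else "upstream"
    return "upstream" if right_of_goi else "downstream"


def find_proximal_lncrnas(
    gois: list[GeneRecord],
    lncs: list[GeneRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[ProximalPair]:
    """Criterion (a): emit every (lncRNA, GOI) pair with body gap <= window.

    One lncRNA may pair with several GOIs.  Pairs are ordered by
    (goi_id, lnc_id) so output is deterministic.  An empty GOI panel is an
    error (the screen is seeded by the panel); an empty lncRNA set simply
    yields no pairs.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    if not gois:
        raise ValueError("empty GOI panel")
    goi_ids = {g.gene_id for g in gois}
    overlap_ids = goi_ids & {l.gene_id for l in lncs}
    if overlap_ids:
        raise ValueError(f"GOI and lncRNA ID spaces overlap: {sorted(overlap_ids)[:5]}")

    by_chrom: dict[str, list[GeneRecord]] = {}
    for lnc in lncs:
        by_chrom.setdefault(lnc.body.chrom, []).append(lnc)
    for chrom_lncs in by_chrom.values():
        chrom_lncs.sort(key=lambda g: (g.body.start, g.gene_id))

    pairs: list[ProximalPair] = []
    for goi in sorted(gois, key=lambda g: g.gene_id):
        for lnc in by_chrom.get(goi.body.chrom, []):
            if lnc.body.start > goi.body.end + window_bp:
                break  # sorted by start: everything further is out of window
            d = gene_distance(lnc, goi)
            if d <= window_bp:
                pairs.append(
                    ProximalPair(
                        lnc_id=lnc.gene_id,
                        goi_id=goi.gene_id,
                        distance_bp=int(d),
                        orientation=_orientation(lnc, goi, d),
                        same_strand=lnc.strand == goi.strand,
                        antisense_overlap=has_antisense_overlap(lnc, goi),
                    )
                )
    pairs.sort(key=lambda p: (p.goi_id, p.lnc_id))
    return pairs
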