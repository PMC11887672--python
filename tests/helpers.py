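"""Shared builders and independent brute-force oracles for the test suite.

The oracles here deliberately re-derive distances and overlaps from first
principles (pure-Python pairwise scans) so they share no code with the
implementation they check.
"""

from __future__ import annotations

import numpy as np

from lncscreen import GeneRecord, GenomicInterval


def gene(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    biotype: str = "lncRNA",
    exons: tuple = (),
) -> GeneRecord:
    return GeneRecord(
        gene_id, gene_id, GenomicInterval(chrom, start, end, strand), biotype, tuple(exons)
    )


def random_genes(
    rng: np.random.Generator,
    n: int,
    prefix: str,
    n_chroms: int = 5,
    chrom_len: int = 5_000_000,
    biotype: str = "lncRNA",
) -> list[GeneRecord]:
    out = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        length = int(rng.integers(1_000, 50_000))
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.integers(0, 2) else "-"
        out.append(gene(f"{prefix}{i}", chrom, start, start + length, strand, biotype))
    return out


def oracle_pair_set(
    gois: list[GeneRecord], lncs: list[GeneRecord], window_bp: int
) -> set[tuple[str, str, int]]:
    """All-pairs proximity scan, re-deriving the body gap from scratch."""
    out = set()
    for g in gois:
        for l in lncs:
            if g.body.chrom != l.body.chrom:
                continue
            if l.body.start < g.body.end and g.body.start < l.body.end:
                d = 0
            elif l.body.start >= g.body.end:
                d = l.body.start - g.body.end
            else:
                d = g.body.start - l.body.end
            if d <= window_bp:
                out.add((l.gene_id, g.gene_id, d))
    return out


def oracle_overlap_count(
    query: GenomicInterval, peaks: list[GenomicInterval], min_overlap_bp: int = 1
) -> int:
    """Pairwise overlap-count scan."""
    n = 0
    for p in peaks:
        if p.chrom != query.chrom:
            continue
        ov = min(p.end, query.end) - max(p.start, query.start)
        if ov >= min_overlap_bp:
            n += 1
    return n
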