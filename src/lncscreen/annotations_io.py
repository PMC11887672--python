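"""Domain types and readers/writers for the genomic formats the screen touches.

Every coordinate inside the package is 0-based, half-open (`[start, end)`),
the BED convention.  GTF/GFF3 files, which are 1-based inclusive, are
converted on read and converted back on write, so round-trips are identity
on well-formed input.  Chromosome names are taken verbatim: no ``chr``
prefix normalisation is attempted, and a complete mismatch between two
inputs surfaces as zero overlaps plus a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import Feature, feature_from_line

logger = logging.getLogger(__name__)

STRANDS = frozenset({"+", "-", "."})

#: Sentinel distance for loci on different chromosomes.
INF_DISTANCE = float("inf")


class AnnotationError(ValueError):
    """Raised for malformed annotation input (bad coordinates, duplicate IDs...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span: chrom, 0-based half-open [start, end), strand.

    The atom of all screening logic — gene bodies, peaks, regulatory
    elements and loop anchors are all built on it.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset_bp: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset_bp, self.end + offset_bp, self.strand)

    def pad(self, flank_bp: int) -> "GenomicInterval":
        """Extend by ``flank_bp`` on each side, clipped at zero."""
        return GenomicInterval(
            self.chrom, max(0, self.start - flank_bp), self.end + flank_bp, self.strand
        )


def interval_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 on different chromosomes.

    Strand-agnostic.  Half-open abutment ([100,200) vs [200,300)) is 0.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return interval_overlap_bp(a, b) > 0


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene: GOI or lncRNA candidate.

    The body spans the gene's full annotated extent (min start .. max end);
    exon structure, when present in the source GTF, is retained but the
    screen itself operates on gene bodies.  The TSS is the strand-dependent
    5' end of the body.
    """

    gene_id: str
    name: str
    body: GenomicInterval
    biotype: str = "other"
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: genes must be stranded (+ or -)")

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1


@dataclass
class PeakSet:
    """A named mark (H3K27ac, DNase, a TF...) with its peak intervals.

    Overlap queries run against per-chromosome start/end arrays built on
    first query; treat the interval list as immutable after construction.
    """

    mark: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.mark:
            raise AnnotationError("PeakSet mark must be non-empty")
        if self.scores is not None and len(self.scores) != len(self.intervals):
            raise AnnotationError(
                f"{self.mark}: scores length {len(self.scores)} != "
                f"{len(self.intervals)} intervals"
            )
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            chrom: (
                np.asarray([s for s, _ in spans], dtype=np.int64),
                np.asarray([e for _, e in spans], dtype=np.int64),
            )
            for chrom, spans in by_chrom.items()
        }

    def overlap_count(self, query: GenomicInterval, min_overlap_bp: int = 1) -> int:
        """Number of peaks overlapping ``query`` by at least ``min_overlap_bp``."""
        if self._index is None:
            self._index = self._build_index()
        hit = self._index.get(query.chrom)
        if hit is None:
            return 0
        starts, ends = hit
        ov = np.minimum(ends, query.end) - np.maximum(starts, query.start)
        return int(np.count_nonzero(ov >= min_overlap_bp))

    def overlaps(self, query: GenomicInterval, min_overlap_bp: int = 1) -> bool:
        return self.overlap_count(query, min_overlap_bp) > 0


@dataclass
class ExpressionTable:
    """Per-cell-line expression keyed by gene_id; values >= 0 (TPM or 0/1 flags)."""

    data: pd.DataFrame
    units: str = "TPM"

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise AnnotationError("expression table: duplicate cell-line columns")
        if (self.data.to_numpy() < 0).any():
            raise AnnotationError("expression table: negative values")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.columns)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index


@dataclass(frozen=True)
class Loop:
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: float | None = None


@dataclass
class LoopSet:
    """Chromatin loops (paired anchors), typically Hi-C loop calls."""

    loops: list[Loop] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = ("gene_biotype", "gene_type", "biotype")
_NAME_KEYS = ("gene_name", "Name", "gene_id", "ID")


def _attr(feature: Feature, keys: Sequence[str], default: str = "") -> str:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return default


def read_gene_annotation(
    path: str | Path,
    format: str = "GTF",
    biotype_filter: set[str] | None = None,
) -> list[GeneRecord]:
    """Read gene-level records from a GTF or GFF3 file.

    1-based inclusive coordinates are converted to 0-based half-open.
    ``biotype_filter``, when given, keeps only genes whose biotype attribute
    (gene_biotype / gene_type) is in the set.  Exon features belonging to a
    retained gene are attached to its record.
    """
    fmt = format.upper()
    if fmt not in ("GTF", "GFF3"):
        raise ValueError(f"format must be GTF or GFF3, got {format!r}")

    genes: dict[str, GeneRecord] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) < 8:
                raise AnnotationError(f"{path}: malformed {fmt} line {lineno}: too few columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions on bad lines
                raise AnnotationError(f"{path}: malformed {fmt} line {lineno}: {exc}") from exc
            ftype = feat.featuretype.lower()
            if ftype == "gene":
                gene_id = _attr(feat, ("gene_id", "ID"))
                if not gene_id:
                    raise AnnotationError(f"{path}: line {lineno}: gene without gene_id")
                if gene_id in genes:
                    raise AnnotationError(f"{path}: duplicate gene_id {gene_id!r} (line {lineno})")
                try:
                    body = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                    record = GeneRecord(
                        gene_id=gene_id,
                        name=_attr(feat, _NAME_KEYS, gene_id),
                        body=body,
                        biotype=_attr(feat, _BIOTYPE_KEYS, "other"),
                    )
                except AnnotationError as exc:
                    raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
                genes[gene_id] = record
            elif ftype == "exon":
                gene_id = _attr(feat, ("gene_id", "Parent"))
                if gene_id:
                    exons.setdefault(gene_id, []).append(
                        GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                    )

    out: list[GeneRecord] = []
    for gene_id, rec in genes.items():
        if biotype_filter is not None and rec.biotype not in biotype_filter:
            continue
        gene_exons = tuple(sorted(exons.get(gene_id, []), key=lambda iv: iv.start))
        if gene_exons:
            rec = GeneRecord(rec.gene_id, rec.name, rec.body, rec.biotype, gene_exons)
        out.append(rec)
    return out


def write_gene_annotation(
    genes: Iterable[GeneRecord], path: str | Path, source: str = "lncscreen"
) -> None:
    """Write gene (and exon, when present) features as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.body.chrom, g.body.start, g.gene_id)):
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.name}"; gene_biotype "{g.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        g.body.chrom,
                        source,
                        "gene",
                        str(g.body.start + 1),
                        str(g.body.end),
                        ".",
                        g.body.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for ex in g.exons:
                fh.write(
                    "\t".join(
                        [
                            ex.chrom,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            ex.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED / BEDPE / expression TSV
# ---------------------------------------------------------------------------


def read_peaks(path: str | Path, mark: str) -> PeakSet:
    """Read a BED3+ peak track; column 5 is used as score when present."""
    intervals: list[GenomicInterval] = []
    scores: list[float] = []
    have_scores = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise AnnotationError(f"{path}: BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}: BED line {lineno}: non-integer coordinates") from exc
            strand = cols[5] if len(cols) > 5 and cols[5] in STRANDS else "."
            try:
                intervals.append(GenomicInterval(cols[0], start, end, strand))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: BED line {lineno}: {exc}") from exc
            if len(cols) > 4 and cols[4] not in (".", ""):
                scores.append(float(cols[4]))
                have_scores = True
            else:
                scores.append(0.0)
    return PeakSet(mark=mark, intervals=intervals, scores=scores if have_scores else None)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED (BED5/BED6 when scores/strands are present)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            score = peaks.scores[i] if peaks.scores is not None else 0.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.mark}_{i}\t{score:g}\t{iv.strand}\n"
            )


def read_loops(path: str | Path) -> LoopSet:
    """Read chromatin loops from BEDPE (6+ columns; column 8 is the score)."""
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise AnnotationError(f"{path}: BEDPE line {lineno}: fewer than 6 columns")
            try:
                a = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
                b = GenomicInterval(cols[3], int(cols[4]), int(cols[5]))
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}: BEDPE line {lineno}: {exc}") from exc
            score = None
            if len(cols) > 7 and cols[7] not in (".", ""):
                score = float(cols[7])
            loops.append(Loop(a, b, score))
    return LoopSet(loops)


def write_loops(loops: LoopSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            score = "." if lp.score is None else f"{lp.score:g}"
            fh.write(
                f"{lp.anchor_a.chrom}\t{lp.anchor_a.start}\t{lp.anchor_a.end}\t"
                f"{lp.anchor_b.chrom}\t{lp.anchor_b.start}\t{lp.anchor_b.end}\t"
                f"loop_{i}\t{score}\n"
            )


def read_expression(path: str | Path, units: str = "TPM") -> ExpressionTable:
    """Read a TSV expression matrix: first column gene_id, one column per cell line."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df, units=units)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.4f")


def warn_on_chrom_mismatch(name_a: str, chroms_a: set[str], name_b: str, chroms_b: set[str]) -> bool:
    """Log a warning when two inputs share no chromosome names; returns True if disjoint."""
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        logger.warning(
            "no shared chromosome names between %s (%s) and %s (%s); "
            "all overlaps will be zero",
            name_a, sorted(chroms_a), name_b, sorted(chroms_b),
        )
        return True
    return False
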