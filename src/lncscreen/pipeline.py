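"""End-to-end screen: criteria (a)-(d) plus super-enhancer and loop annotation.

The funnel applies four gates to every (lncRNA, GOI) pair found within
the proximity window:

(a) body gap <= window (default 1 Mbp) — emitted pairs only;
(b) no antisense overlap with the paired GOI;
(c) expression >= threshold in at least one screened cell line
    (default H1ESC);
(d) locus chromatin marked: active (H3K36me3/H3K27ac) or repressed
    (H3K9me3/H3K27me3) — the disjunction admits repressed loci.

Funnel counts are per unique lncRNA (a lncRNA paired with several GOIs
is counted once); the pair table keeps every pair.  Final candidates are
further annotated with the super-enhancer at their locus and with
chromatin-loop support between the hub element and the GOI proximal
promoter.  ``evidence_score`` (0-6: four criteria + SE overlap + loop
support) is an additive convenience ranking invented by this package —
it is not part of the published screen, which picked its lead candidate
from the final list by expert inspection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotations_io import (
    GeneRecord,
    GenomicInterval,
    LoopSet,
    PeakSet,
    interval_overlap_bp,
    read_expression,
    read_gene_annotation,
    read_loops,
    read_peaks,
    warn_on_chrom_mismatch,
)
from .chromatin import (
    DEFAULT_H3K4ME1_FLANK_BP,
    DEFAULT_LOCUS_FLANK_BP,
    DEFAULT_MIN_OVERLAP_BP,
    classify_element,
    classify_locus,
    is_expressed,
)
from .loops import (
    DEFAULT_PROMOTER_DOWNSTREAM_BP,
    DEFAULT_PROMOTER_UPSTREAM_BP,
    find_supporting_loops,
    promoter_region,
)
from .proximity import DEFAULT_WINDOW_BP, find_proximal_lncrnas
from .superenhancer import (
    DEFAULT_MIN_CONSTITUENTS,
    DEFAULT_STITCH_BP,
    assign_se_to_candidate,
    call_super_enhancers,
    stitch_enhancers,
)

logger = logging.getLogger(__name__)

#: Marks criterion (d) is defined on; their tracks are mandatory.
REQUIRED_LOCUS_MARKS = ("H3K27ac", "H3K36me3", "H3K9me3", "H3K27me3")
#: Tracks whose merged peak union seeds candidate regulatory elements.
ELEMENT_SEED_MARKS = ("H3K27ac", "DNase")


@dataclass
class ScreenConfig:
    """All inputs and parameters of one screen run."""

    goi_list: Path
    genes_gtf: Path
    expression_tsv: Path
    marks: dict[str, Path]
    lncrnas_gtf: Path | None = None
    loops_bedpe: Path | None = None
    window_bp: int = DEFAULT_WINDOW_BP
    locus_flank_bp: int = DEFAULT_LOCUS_FLANK_BP
    h3k4me1_flank_bp: int = DEFAULT_H3K4ME1_FLANK_BP
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP
    stitch_bp: int = DEFAULT_STITCH_BP
    min_constituents: int = DEFAULT_MIN_CONSTITUENTS
    promoter_upstream_bp: int = DEFAULT_PROMOTER_UPSTREAM_BP
    promoter_downstream_bp: int = DEFAULT_PROMOTER_DOWNSTREAM_BP
    expression_threshold: float = 1.0
    cell_lines: tuple[str, ...] = ("H1ESC",)
    annotate_all: bool = False
    exon_level_antisense: bool = False

    def __post_init__(self) -> None:
        self.goi_list = Path(self.goi_list)
        self.genes_gtf = Path(self.genes_gtf)
        self.expression_tsv = Path(self.expression_tsv)
        self.marks = {m: Path(p) for m, p in self.marks.items()}
        self.lncrnas_gtf = Path(self.lncrnas_gtf) if self.lncrnas_gtf else None
        self.loops_bedpe = Path(self.loops_bedpe) if self.loops_bedpe else None
        self.cell_lines = tuple(self.cell_lines)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        """Load a config from YAML; relative paths resolve against the file."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        for key in ("goi_list", "genes_gtf", "expression_tsv", "lncrnas_gtf", "loops_bedpe"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        if "marks" in raw:
            raw["marks"] = {m: resolve(p) for m, p in raw["marks"].items()}
        return cls(**raw)

    @classmethod
    def from_bundle_dir(cls, bundle_dir: str | Path, **overrides) -> "ScreenConfig":
        """Config pointing at a synthetic bundle written by ``simulate_dataset``."""
        d = Path(bundle_dir)
        marks = {p.stem: p for p in sorted((d / "marks").glob("*.bed"))}
        kwargs: dict = dict(
            goi_list=d / "goi.txt",
            genes_gtf=d / "genes.gtf",
            lncrnas_gtf=d / "lncrnas.gtf",
            expression_tsv=d / "expression.tsv",
            marks=marks,
            loops_bedpe=d / "loops.bedpe",
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("goi_list", "genes_gtf", "expression_tsv", "lncrnas_gtf", "loops_bedpe"):
            out[key] = str(out[key]) if out[key] else None
        out["marks"] = {m: str(p) for m, p in out["marks"].items()}
        out["cell_lines"] = list(self.cell_lines)
        return out


@dataclass(frozen=True)
class CandidateRecord:
    """One (lncRNA, GOI) pair with per-criterion flags and locus annotation."""

    lnc_id: str
    goi_id: str
    distance_bp: int
    orientation: str
    same_strand: bool
    pass_proximity: bool
    pass_antisense: bool
    pass_expression: bool
    pass_chromatin: bool
    chromatin_state: str
    se_overlap: str | None = None  # SE id when an SE overlaps the lnc body
    hub_within_body: bool = False
    loop_supported: bool = False

    @property
    def final_candidate(self) -> bool:
        return (
            self.pass_proximity
            and self.pass_antisense
            and self.pass_expression
            and self.pass_chromatin
        )

    @property
    def evidence_score(self) -> int:
        """0-6: four criteria + SE overlap + loop support (artifact ranking)."""
        return (
            int(self.pass_proximity)
            + int(self.pass_antisense)
            + int(self.pass_expression)
            + int(self.pass_chromatin)
            + int(self.se_overlap is not None)
            + int(self.loop_supported)
        )


@dataclass(frozen=True)
class FunnelCounts:
    """Per-unique-lncRNA attrition through the four criteria."""

    n_goi: int
    n_lnc_total: int
    n_proximal: int
    n_after_antisense: int
    n_after_expression: int
    n_after_chromatin: int

    @property
    def n_final(self) -> int:
        return self.n_after_chromatin

    def __post_init__(self) -> None:
        seq = (self.n_proximal, self.n_after_antisense,
               self.n_after_expression, self.n_after_chromatin)
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"funnel counts must be non-increasing: {seq}")


def read_goi_list(path: str | Path) -> list[str]:
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def _check_inputs(config: ScreenConfig) -> None:
    missing = [
        str(p)
        for p in (config.goi_list, config.genes_gtf, config.expression_tsv,
                  config.lncrnas_gtf, config.loops_bedpe)
        if p is not None and not Path(p).exists()
    ]
    missing += [str(p) for p in config.marks.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    absent_marks = [m for m in REQUIRED_LOCUS_MARKS if m not in config.marks]
    if absent_marks:
        raise ValueError(
            f"criterion (d) needs mark tracks {absent_marks}; "
            "pass them via the marks mapping"
        )


def _candidate_elements(
    peaksets: dict[str, PeakSet],
) -> list[GenomicInterval]:
    """Candidate regulatory elements: merged union of H3K27ac and DNase peaks."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for mark in ELEMENT_SEED_MARKS:
        ps = peaksets.get(mark)
        if ps is None:
            continue
        for iv in ps.intervals:
            spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(spans):
        cur_s = cur_e = None
        for s, e in sorted(spans[chrom]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict: abutting peaks stay separate elements
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def run_screen(config: ScreenConfig) -> tuple[list[CandidateRecord], FunnelCounts]:
    """Run the full screen; deterministic given identical inputs and config."""
    _check_inputs(config)

    genes = read_gene_annotation(config.genes_gtf)
    genes_by_id = {g.gene_id: g for g in genes}
    goi_ids = read_goi_list(config.goi_list)
    unknown = [g for g in goi_ids if g not in genes_by_id]
    if unknown:
        raise ValueError(f"GOI ids not found in gene annotation: {unknown}")
    gois = [genes_by_id[g] for g in goi_ids]

    if config.lncrnas_gtf is not None:
        lncs = read_gene_annotation(config.lncrnas_gtf, biotype_filter={"lncRNA"})
        if not lncs:  # plain GTF without biotype attributes: take everything
            lncs = read_gene_annotation(config.lncrnas_gtf)
    else:
        lncs = [g for g in genes if g.biotype == "lncRNA"]
    lnc_by_id = {l.gene_id: l for l in lncs}

    peaksets = {mark: read_peaks(path, mark) for mark, path in config.marks.items()}
    peak_list = [peaksets[m] for m in sorted(peaksets)]
    expr = read_expression(config.expression_tsv)
    loops = read_loops(config.loops_bedpe) if config.loops_bedpe else LoopSet([])

    gene_chroms = {g.body.chrom for g in genes} | {l.body.chrom for l in lncs}
    peak_chroms = {iv.chrom for ps in peaksets.values() for iv in ps.intervals}
    warn_on_chrom_mismatch("gene annotation", gene_chroms, "peak tracks", peak_chroms)

    # criterion (a)
    pairs = find_proximal_lncrnas(gois, lncs, config.window_bp)
    proximal_lncs = sorted({p.lnc_id for p in pairs})
    logger.info("criterion (a): %d pairs, %d unique lncRNAs within %d bp",
                len(pairs), len(proximal_lncs), config.window_bp)

    # criteria (c) and (d) are per-lncRNA; cache them
    expr_pass: dict[str, bool] = {}
    chrom_call: dict[str, str] = {}
    for lnc_id in proximal_lncs:
        lnc = lnc_by_id[lnc_id]
        expr_pass[lnc_id] = is_expressed(
            lnc_id, expr, list(config.cell_lines), config.expression_threshold
        )
        call = classify_locus(
            lnc.body, peak_list, config.locus_flank_bp, config.min_overlap_bp
        )
        chrom_call[lnc_id] = call.state

    records: list[CandidateRecord] = []
    for pair in pairs:
        records.append(
            CandidateRecord(
                lnc_id=pair.lnc_id,
                goi_id=pair.goi_id,
                distance_bp=pair.distance_bp,
                orientation=pair.orientation,
                same_strand=pair.same_strand,
                pass_proximity=True,
                pass_antisense=not pair.antisense_overlap,
                pass_expression=expr_pass[pair.lnc_id],
                pass_chromatin=chrom_call[pair.lnc_id] != "none",
                chromatin_state=chrom_call[pair.lnc_id],
            )
        )

    # funnel over unique lncRNAs, criteria applied in order (a)->(b)->(c)->(d)
    def survivors(*flags) -> set[str]:
        out = set()
        for r in records:
            if all(getattr(r, f) for f in flags):
                out.add(r.lnc_id)
        return out

    after_b = survivors("pass_antisense")
    after_c = survivors("pass_antisense", "pass_expression")
    after_d = survivors("pass_antisense", "pass_expression", "pass_chromatin")
    funnel = FunnelCounts(
        n_goi=len(gois),
        n_lnc_total=len(lncs),
        n_proximal=len(proximal_lncs),
        n_after_antisense=len(after_b),
        n_after_expression=len(after_c),
        n_after_chromatin=len(after_d),
    )
    logger.info("funnel: proximal=%d antisense=%d expression=%d chromatin=%d",
                funnel.n_proximal, funnel.n_after_antisense,
                funnel.n_after_expression, funnel.n_after_chromatin)

    # SE + loop annotation (final candidates only, unless annotate_all)
    element_ivs = _candidate_elements(peaksets)
    elements = [
        classify_element(iv, peak_list, config.h3k4me1_flank_bp, config.min_overlap_bp)
        for iv in element_ivs
    ]
    ses = call_super_enhancers(
        stitch_enhancers(elements, config.stitch_bp), config.min_constituents
    )
    se_ids = {
        id(se): f"SE_{se.region.chrom}_{se.region.start}_{se.region.end}" for se in ses
    }

    annotated: list[CandidateRecord] = []
    for rec in records:
        if not (rec.final_candidate or config.annotate_all):
            annotated.append(rec)
            continue
        lnc = lnc_by_id[rec.lnc_id]
        goi = genes_by_id[rec.goi_id]
        assignment = assign_se_to_candidate(lnc, ses, config.window_bp)
        se_id = (
            se_ids[id(assignment.se)]
            if assignment.se is not None and assignment.se_overlaps_body
            else None
        )
        # loop support is probed from the hub element when one sits in the
        # body, else from the SE region, else from the gene body itself
        if assignment.se is not None and assignment.hub_within_body:
            probe = next(
                h.interval
                for h in assignment.se.hub_elements
                if interval_overlap_bp(h.interval, lnc.body) > 0
            )
        elif assignment.se is not None and assignment.se_overlaps_body:
            probe = assignment.se.region
        else:
            probe = lnc.body
        promoter = promoter_region(
            goi, config.promoter_upstream_bp, config.promoter_downstream_bp
        )
        support = find_supporting_loops(probe, promoter, loops, peak_list)
        annotated.append(
            dataclasses.replace(
                rec,
                se_overlap=se_id,
                hub_within_body=assignment.hub_within_body,
                loop_supported=support.supported,
            )
        )
    return annotated, funnel


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "lnc_id", "goi_id", "distance_bp", "orientation", "same_strand",
    "pass_proximity", "pass_antisense", "pass_expression", "pass_chromatin",
    "final_candidate", "chromatin_state", "se_overlap", "hub_within_body",
    "loop_supported", "evidence_score",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(
    records: list[CandidateRecord],
    funnel: FunnelCounts,
    out_dir: str | Path,
    config: ScreenConfig | None = None,
    lnc_bodies: dict[str, GenomicInterval] | None = None,
) -> dict[str, Path]:
    """Write candidates.tsv, candidates.bed, funnel.tsv and run_config.json.

    ``lnc_bodies`` (lnc_id -> body interval) enables BED output of the
    final candidates; without it the BED file is omitted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tsv = out_dir / "candidates.tsv"
    with open(tsv, "w") as fh:
        fh.write("# evidence_score: additive 0-6 convenience ranking "
                 "(four criteria + SE overlap + loop support); "
                 "not part of the published screen criteria\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            row = [
                r.lnc_id, r.goi_id, str(r.distance_bp), r.orientation,
                str(r.same_strand), str(r.pass_proximity), str(r.pass_antisense),
                str(r.pass_expression), str(r.pass_chromatin),
                str(r.final_candidate), r.chromatin_state,
                r.se_overlap or ".", str(r.hub_within_body),
                str(r.loop_supported), str(r.evidence_score),
            ]
            fh.write("\t".join(row) + "\n")
    paths["candidates_tsv"] = tsv

    if lnc_bodies is not None:
        bed = out_dir / "candidates.bed"
        final: dict[str, int] = {}
        for r in records:
            if r.final_candidate:
                final[r.lnc_id] = max(final.get(r.lnc_id, 0), r.evidence_score)
        with open(bed, "w") as fh:
            rows = sorted(
                (lnc_bodies[lnc_id], lnc_id, score) for lnc_id, score in final.items()
                if lnc_id in lnc_bodies
            )
            for body, lnc_id, score in rows:
                fh.write(
                    f"{body.chrom}\t{body.start}\t{body.end}\t{lnc_id}\t"
                    f"{score}\t{body.strand}\n"
                )
        paths["candidates_bed"] = bed

    funnel_tsv = out_dir / "funnel.tsv"
    with open(funnel_tsv, "w") as fh:
        fh.write("stage\tn\n")
        for name in ("n_goi", "n_lnc_total", "n_proximal", "n_after_antisense",
                     "n_after_expression", "n_after_chromatin"):
            fh.write(f"{name}\t{getattr(funnel, name)}\n")
    paths["funnel_tsv"] = funnel_tsv

    if config is not None:
        echo = config.to_dict()
        checksums = {}
        for p in [config.goi_list, config.genes_gtf, config.expression_tsv,
                  config.lncrnas_gtf, config.loops_bedpe, *config.marks.values()]:
            if p is not None and Path(p).exists():
                checksums[str(p)] = _sha256(Path(p))
        cfg_json = out_dir / "run_config.json"
        with open(cfg_json, "w") as fh:
            json.dump({"config": echo, "input_sha256": checksums}, fh, indent=1, sort_keys=True)
        paths["run_config_json"] = cfg_json
    return paths
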