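"""Seeded generator for a complete synthetic screen input bundle.

Emulates the statistical structure of the real screen inputs — a panel of
16 stemness transcription factors, lncRNAs planted around them, histone
and TF peak tracks, a per-cell-line expression table and Hi-C-style
loops — together with a truth manifest so that every pipeline stage is
verifiable at desk scale.

The planted world
-----------------
* One GOI per synthetic chromosome (default 16 chromosomes of 6 Mbp),
  placed near the centre so a full 1-Mbp window fits on either side.
* **True candidates** sit within the window (gap <= window - margin) on a
  random strand without touching the GOI, are expressed in the H1ESC
  column, and carry an embedded super-enhancer inside the gene body: one
  hub element (H3K4me3 + H3K27ac + DNase, H3K4me1 flanks), four non-hub
  enhancers (H3K27ac + overlapping H3K4me1) and one open-chromatin site
  (DNase only), plus a chromatin loop joining the hub element to the GOI
  proximal promoter with CTCF/H3K27ac peaks at both anchors and
  stem-cell TF occupancy (NANOG, POU5F1, YY1, RAD21, TCF12) at the hub.
* **Decoy classes** each break exactly one criterion: ``decoy_far``
  (gap > window + margin), ``decoy_antisense`` (overlaps its GOI on the
  opposite strand), ``decoy_unexpressed`` (H1ESC expression below
  threshold), ``decoy_unmarked`` (no peaks anywhere near the locus).
* Noise peaks and noise loops are scattered uniformly but kept a guard
  band away from every planted feature, so the default screen separates
  classes deterministically: precision = recall = 1 is the constructed
  truth, and any deviation is a pipeline bug.

Determinism: a single ``numpy.random.Generator`` seeded from the config
drives every draw, consumed in a fixed order (GOIs, then lncRNAs in
class order true/antisense/unexpressed/unmarked/far, then noise peaks
mark by mark, then noise loops, then expression values).  All
coordinates are integers, so bundles are byte-identical across runs and
platforms for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .annotations_io import (
    GeneRecord,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    ExpressionTable,
    write_expression,
    write_gene_annotation,
    write_loops,
    write_peaks,
)
from .loops import promoter_region

if TYPE_CHECKING:  # avoid a runtime cycle; records are duck-typed
    from .pipeline import CandidateRecord

import pandas as pd

#: The stemness / reprogramming TF panel seeding the screen.
DEFAULT_GOI_NAMES = (
    "POU5F1", "SOX2", "CTNNB1", "MYC", "NANOG", "KLF4", "ZFX", "SMAD2",
    "TCF3", "STAT3", "FBXO15", "GDF3", "UTF1", "ZFP42", "SALL2", "OLIG1",
)

HISTONE_MARKS = ("H3K27ac", "H3K36me3", "H3K9me3", "H3K27me3", "H3K4me1", "H3K4me3")
OPEN_TRACKS = ("DNase", "CTCF")
TF_TRACKS = ("NANOG", "POU5F1", "YY1", "RAD21", "TCF12")
CELL_LINES = ("H1ESC", "iPSC", "HUVEC", "HFNS", "GSC")

LNC_CLASSES = (
    "true_candidate",
    "decoy_antisense",
    "decoy_unexpressed",
    "decoy_unmarked",
    "decoy_far",
)


class PlacementError(RuntimeError):
    """Planted features did not fit after bounded retries."""


@dataclass
class SimulationConfig:
    """Parameters of the planted world.

    Defaults reproduce the published funnel shape: 16 GOIs, 112 lncRNAs
    within the 1-Mbp window (20 true candidates + 32 antisense + 30
    unexpressed + 30 unmarked decoys) and 40 far decoys beyond it.
    """

    seed: int = 1
    n_chroms: int = 16
    chrom_length_bp: int = 6_000_000
    n_goi: int = 16
    n_true_candidates: int = 20
    n_decoy_far: int = 40
    n_decoy_antisense: int = 32
    n_decoy_unexpressed: int = 30
    n_decoy_unmarked: int = 30
    window_bp: int = 1_000_000
    margin_bp: int = 50_000
    guard_bp: int = 20_000
    min_gap_bp: int = 10_000  # planted lnc never closer than this to its GOI
    expression_threshold: float = 1.0
    noise_peaks_per_mb: float = 1.0
    n_noise_loops: int = 30
    hub_flank_bp: int = 5_000
    loop_anchor_width_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.n_goi < 1:
            raise ValueError("n_goi must be >= 1")
        for name in ("n_true_candidates", "n_decoy_far", "n_decoy_antisense",
                     "n_decoy_unexpressed", "n_decoy_unmarked"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        half = self.chrom_length_bp // 2
        if half < self.window_bp + 2 * self.margin_bp + 200_000:
            raise PlacementError(
                "chrom_length_bp too short for the window plus margins; "
                "use longer chromosomes"
            )

    @property
    def n_in_window(self) -> int:
        return (
            self.n_true_candidates
            + self.n_decoy_antisense
            + self.n_decoy_unexpressed
            + self.n_decoy_unmarked
        )


@dataclass
class PlantedLnc:
    lnc_id: str
    lnc_class: str
    goi_id: str
    body: GenomicInterval
    se_region: GenomicInterval | None = None
    hub_element: GenomicInterval | None = None
    loop_index: int | None = None


@dataclass
class TruthManifest:
    """Ground truth of a simulated bundle: what was planted where."""

    config: SimulationConfig
    gois: list[GeneRecord]
    lncs: list[PlantedLnc]

    def by_class(self, lnc_class: str) -> list[PlantedLnc]:
        return [l for l in self.lncs if l.lnc_class == lnc_class]

    @property
    def true_candidate_ids(self) -> set[str]:
        return {l.lnc_id for l in self.lncs if l.lnc_class == "true_candidate"}

    def lnc_class_of(self, lnc_id: str) -> str:
        for l in self.lncs:
            if l.lnc_id == lnc_id:
                return l.lnc_class
        raise KeyError(f"unknown lnc_id {lnc_id!r}")

    def to_json(self, path: str | Path) -> None:
        def iv(x: GenomicInterval | None):
            return None if x is None else [x.chrom, x.start, x.end, x.strand]

        payload = {
            "config": asdict(self.config),
            "gois": [
                {"gene_id": g.gene_id, "name": g.name, "interval": iv(g.body)}
                for g in self.gois
            ],
            "lncrnas": [
                {
                    "lnc_id": l.lnc_id,
                    "class": l.lnc_class,
                    "goi_id": l.goi_id,
                    "interval": iv(l.body),
                    "se_region": iv(l.se_region),
                    "hub_element": iv(l.hub_element),
                    "loop_index": l.loop_index,
                }
                for l in self.lncs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)

        def iv(x):
            return None if x is None else GenomicInterval(x[0], x[1], x[2], x[3])

        config = SimulationConfig(**payload["config"])
        gois = [
            GeneRecord(g["gene_id"], g["name"], iv(g["interval"]), "protein_coding")
            for g in payload["gois"]
        ]
        lncs = [
            PlantedLnc(
                l["lnc_id"], l["class"], l["goi_id"], iv(l["interval"]),
                iv(l["se_region"]), iv(l["hub_element"]), l["loop_index"],
            )
            for l in payload["lncrnas"]
        ]
        return cls(config, gois, lncs)


@dataclass
class SimulatedBundle:
    """Paths of a written bundle plus its truth manifest."""

    out_dir: Path
    genes_gtf: Path
    lncrnas_gtf: Path
    goi_list: Path
    mark_beds: dict[str, Path]
    expression_tsv: Path
    loops_bedpe: Path
    truth_json: Path
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

_SEP_BP = 5_000  # minimum separation between planted gene bodies
_MAX_TRIES = 300


class _Occupancy:
    """Per-chromosome planted spans, for non-overlap checks with a buffer."""

    def __init__(self) -> None:
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int, buffer_bp: int = _SEP_BP) -> bool:
        return any(
            start - buffer_bp < e and s < end + buffer_bp
            for s, e in self.spans.get(chrom, [])
        )

    def add(self, chrom: str, start: int, end: int) -> None:
        self.spans.setdefault(chrom, []).append((start, end))

    def remove(self, chrom: str, start: int, end: int) -> None:
        self.spans[chrom].remove((start, end))


def _span_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Body gap on one chromosome; 0 when overlapping or abutting."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _place_near_goi(
    rng: np.random.Generator,
    goi: GeneRecord,
    length: int,
    gap_lo: int,
    gap_hi: int,
    chrom_length: int,
    occ_lnc: _Occupancy,
    occ_goi: _Occupancy,
) -> GenomicInterval:
    """Place a body at a gap drawn from [gap_lo, gap_hi] on a random side of the GOI."""
    chrom = goi.body.chrom
    if gap_hi < gap_lo:
        raise PlacementError(
            f"no room for a {length}-bp locus near {goi.gene_id} "
            f"(gap range [{gap_lo}, {gap_hi}]); try longer chromosomes"
        )
    for _ in range(_MAX_TRIES):
        side = int(rng.integers(0, 2))  # 0 = left, 1 = right
        gap = int(rng.integers(gap_lo, gap_hi + 1))
        if side:
            start = goi.body.end + gap
        else:
            start = goi.body.start - gap - length
        end = start + length
        if start < 0 or end > chrom_length:
            continue
        if occ_lnc.conflicts(chrom, start, end) or occ_goi.conflicts(chrom, start, end):
            continue
        strand = "+" if rng.integers(0, 2) else "-"
        occ_lnc.add(chrom, start, end)
        return GenomicInterval(chrom, start, end, strand)
    raise PlacementError(
        f"could not place a {length}-bp locus near {goi.gene_id} after "
        f"{_MAX_TRIES} tries; try longer chromosomes"
    )


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate_dataset(
    config: SimulationConfig | None = None,
    out_dir: str | Path = "synthetic_bundle",
) -> SimulatedBundle:
    """Generate and write a complete synthetic input bundle (see module docs).

    Returns the file paths plus the :class:`TruthManifest`.  Fully
    reproducible: the same config (seed included) yields byte-identical
    files.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    (out_dir / "marks").mkdir(parents=True, exist_ok=True)

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    L = cfg.chrom_length_bp
    occ_lnc = _Occupancy()
    occ_goi = _Occupancy()
    peaks: dict[str, list[GenomicInterval]] = {
        m: [] for m in HISTONE_MARKS + OPEN_TRACKS + TF_TRACKS
    }
    loop_list: list[Loop] = []

    # --- GOIs, one per chromosome (round-robin if n_goi > n_chroms) ---------
    gois: list[GeneRecord] = []
    for i in range(cfg.n_goi):
        chrom = chroms[i % cfg.n_chroms]
        length = int(rng.integers(10_000, 30_001))
        jitter = int(rng.integers(-20_000, 20_001))
        start = L // 2 - length // 2 + jitter
        strand = "+" if rng.integers(0, 2) else "-"
        name = DEFAULT_GOI_NAMES[i] if i < len(DEFAULT_GOI_NAMES) else f"GOI{i + 1}"
        body = GenomicInterval(chrom, start, start + length, strand)
        if occ_goi.conflicts(chrom, start, start + length):
            raise PlacementError("GOI placement collision; use more chromosomes")
        occ_goi.add(chrom, start, start + length)
        gois.append(GeneRecord(f"GOI_{name}", name, body, "protein_coding"))

    # --- planted lncRNAs ----------------------------------------------------
    planted: list[PlantedLnc] = []
    lnc_records: list[GeneRecord] = []
    counter = 0  # global round-robin over GOIs
    antisense_side: dict[str, int] = {}

    def next_goi() -> GeneRecord:
        nonlocal counter
        g = gois[counter % cfg.n_goi]
        counter += 1
        return g

    def add_lnc(body: GenomicInterval, lnc_class: str, goi: GeneRecord, **kw) -> PlantedLnc:
        lnc_id = f"LNC{len(planted) + 1:04d}"
        rec = GeneRecord(lnc_id, lnc_id, body, "lncRNA")
        lnc_records.append(rec)
        p = PlantedLnc(lnc_id, lnc_class, goi.gene_id, body, **kw)
        planted.append(p)
        return p

    gap_hi_in = cfg.window_bp - cfg.margin_bp

    # true candidates: embedded SE (1 hub + 4 enhancers + 1 open site) + loop
    for _ in range(cfg.n_true_candidates):
        goi = next_goi()
        length = int(rng.integers(45_000, 70_001))
        body = _place_near_goi(
            rng, goi, length, cfg.min_gap_bp, gap_hi_in - length, L, occ_lnc, occ_goi
        )
        elem_len = 1_500
        gaps = [int(rng.integers(2_000, 5_001)) for _ in range(5)]
        span = 6 * elem_len + sum(gaps)
        offset = int(rng.integers(3_000, body.end - body.start - span - 3_000 + 1))
        starts = []
        pos = body.start + offset
        for k in range(6):
            starts.append(pos)
            pos += elem_len + (gaps[k] if k < 5 else 0)
        hub_idx, oc_idx = (int(x) for x in rng.choice(6, size=2, replace=False))
        hub_iv: GenomicInterval | None = None
        for k, s in enumerate(starts):
            iv = GenomicInterval(body.chrom, s, s + elem_len)
            if k == hub_idx:
                hub_iv = iv
                peaks["H3K27ac"].append(iv)
                peaks["H3K4me3"].append(iv)
                peaks["DNase"].append(iv)
                peaks["H3K4me1"].append(GenomicInterval(iv.chrom, iv.start - 3_000, iv.start - 2_000))
                peaks["H3K4me1"].append(GenomicInterval(iv.chrom, iv.end + 2_000, iv.end + 3_000))
                for tf in TF_TRACKS:
                    peaks[tf].append(iv)
            elif k == oc_idx:
                peaks["DNase"].append(iv)
            else:
                peaks["H3K27ac"].append(iv)
                peaks["H3K4me1"].append(GenomicInterval(iv.chrom, iv.start - 500, iv.end + 500))
        assert hub_iv is not None
        se_region = GenomicInterval(body.chrom, starts[0], starts[-1] + elem_len)

        prom = promoter_region(goi)
        w = cfg.loop_anchor_width_bp
        hub_mid = (hub_iv.start + hub_iv.end) // 2
        prom_mid = (prom.start + prom.end) // 2
        anchor_a = GenomicInterval(body.chrom, hub_mid - w // 2, hub_mid + w // 2)
        anchor_b = GenomicInterval(body.chrom, max(0, prom_mid - w // 2), prom_mid + w // 2)
        loop_index = len(loop_list)
        loop_list.append(Loop(anchor_a, anchor_b, score=10.0))
        # contact-point enrichment at both anchors
        peaks["CTCF"].append(GenomicInterval(body.chrom, hub_mid - 250, hub_mid + 250))
        peaks["CTCF"].append(GenomicInterval(body.chrom, prom_mid - 250, prom_mid + 250))
        peaks["H3K27ac"].append(GenomicInterval(prom.chrom, prom.start, prom.end))

        add_lnc(body, "true_candidate", goi,
                se_region=se_region, hub_element=hub_iv, loop_index=loop_index)

    # antisense decoys: straddle a GOI edge on the opposite strand
    for _ in range(cfg.n_decoy_antisense):
        goi = next_goi()
        length = int(rng.integers(5_000, 20_001))
        side = antisense_side.get(goi.gene_id, 0)
        antisense_side[goi.gene_id] = side + 1
        goi_len = len(goi.body)
        overlap = int(rng.integers(1_000, min(length, goi_len) // 2 + 1_001))
        overlap = min(overlap, length - 1, goi_len - 1)
        chrom = goi.body.chrom
        other_gois = _Occupancy()
        other_gois.spans[chrom] = [
            (g.body.start, g.body.end)
            for g in gois
            if g.body.chrom == chrom and g.gene_id != goi.gene_id
        ]
        for attempt in range(_MAX_TRIES):
            if (side + attempt) % 2:
                start = goi.body.end - overlap
            else:
                start = goi.body.start + overlap - length
            end = start + length
            # strict non-overlap only: antisense decoys legitimately crowd
            # the GOI and may sit close to each other
            if (
                start < 0
                or end > L
                or occ_lnc.conflicts(chrom, start, end, buffer_bp=0)
                or other_gois.conflicts(chrom, start, end, buffer_bp=0)
            ):
                overlap = int(rng.integers(1_000, min(length, goi_len) // 2 + 1_001))
                overlap = min(overlap, length - 1, goi_len - 1)
                continue
            break
        else:
            raise PlacementError("could not place antisense decoy; try longer chromosomes")
        strand = "-" if goi.strand == "+" else "+"
        body = GenomicInterval(chrom, start, end, strand)
        occ_lnc.add(chrom, start, end)
        # expressed and marked: criterion (b) is the only failing gate
        mid = (start + end) // 2
        peaks["H3K27ac"].append(GenomicInterval(body.chrom, mid - 500, mid + 500))
        add_lnc(body, "decoy_antisense", goi)

    # unexpressed decoys: marked but silent in H1ESC
    for _ in range(cfg.n_decoy_unexpressed):
        goi = next_goi()
        length = int(rng.integers(5_000, 20_001))
        body = _place_near_goi(
            rng, goi, length, cfg.min_gap_bp, gap_hi_in - length, L, occ_lnc, occ_goi
        )
        mid = (body.start + body.end) // 2
        peaks["H3K27ac"].append(GenomicInterval(body.chrom, mid - 500, mid + 500))
        add_lnc(body, "decoy_unexpressed", goi)

    # unmarked decoys: expressed but bare chromatin
    for _ in range(cfg.n_decoy_unmarked):
        goi = next_goi()
        length = int(rng.integers(5_000, 20_001))
        body = _place_near_goi(
            rng, goi, length, cfg.min_gap_bp, gap_hi_in - length, L, occ_lnc, occ_goi
        )
        add_lnc(body, "decoy_unmarked", goi)

    # far decoys: beyond the window (checked against every GOI on the chromosome)
    gap_lo_far = cfg.window_bp + cfg.margin_bp
    for _ in range(cfg.n_decoy_far):
        goi = next_goi()
        length = int(rng.integers(5_000, 20_001))
        chrom_gois = [
            g for g in gois
            if g.body.chrom == goi.body.chrom and g.gene_id != goi.gene_id
        ]
        for attempt in range(_MAX_TRIES):
            body = _place_near_goi(
                rng, goi, length, gap_lo_far, L // 2 - cfg.margin_bp, L, occ_lnc, occ_goi
            )
            far_from_all = all(
                _span_gap(body, g.body) > cfg.window_bp + cfg.margin_bp // 2
                for g in chrom_gois
            )
            if far_from_all:
                break
            occ_lnc.remove(body.chrom, body.start, body.end)
        else:
            raise PlacementError("could not place far decoy; try longer chromosomes")
        mid = (body.start + body.end) // 2
        peaks["H3K27ac"].append(GenomicInterval(body.chrom, mid - 500, mid + 500))
        add_lnc(body, "decoy_far", goi)

    # --- noise peaks, kept a guard band away from planted loci --------------
    keepout: dict[str, list[tuple[int, int]]] = {}
    for g in gois:
        keepout.setdefault(g.body.chrom, []).append(
            (g.body.start - cfg.guard_bp, g.body.end + cfg.guard_bp)
        )
    for p in planted:
        keepout.setdefault(p.body.chrom, []).append(
            (p.body.start - cfg.guard_bp, p.body.end + cfg.guard_bp)
        )

    def in_keepout(chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in keepout.get(chrom, []))

    total_mb = cfg.n_chroms * L / 1e6
    n_noise = int(round(cfg.noise_peaks_per_mb * total_mb))
    for mark in HISTONE_MARKS + OPEN_TRACKS + TF_TRACKS:
        placed = 0
        for _ in range(n_noise * 50):
            if placed >= n_noise:
                break
            chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
            length = int(rng.integers(200, 2_001))
            start = int(rng.integers(0, L - length))
            if in_keepout(chrom, start, start + length):
                continue
            peaks[mark].append(GenomicInterval(chrom, start, start + length))
            placed += 1

    # --- noise loops ---------------------------------------------------------
    w = cfg.loop_anchor_width_bp
    placed = 0
    for _ in range(cfg.n_noise_loops * 50):
        if placed >= cfg.n_noise_loops:
            break
        chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
        a_start = int(rng.integers(0, L - w))
        span = int(rng.integers(100_000, 2_000_001))
        b_start = a_start + span
        if b_start + w > L:
            continue
        if in_keepout(chrom, a_start, a_start + w) or in_keepout(chrom, b_start, b_start + w):
            continue
        loop_list.append(
            Loop(GenomicInterval(chrom, a_start, a_start + w),
                 GenomicInterval(chrom, b_start, b_start + w), score=1.0)
        )
        placed += 1

    # --- expression table ----------------------------------------------------
    thr = cfg.expression_threshold

    def expressed_value() -> float:
        return float(thr + rng.lognormal(mean=0.5, sigma=0.8))

    def silent_value() -> float:
        if rng.random() < 0.7:
            return 0.0
        return float(rng.uniform(0, 0.5 * thr))

    rows: dict[str, dict[str, float]] = {}
    for g in gois:
        rows[g.gene_id] = {c: expressed_value() for c in CELL_LINES}
    for p in planted:
        row: dict[str, float] = {}
        for c in CELL_LINES:
            if c == "H1ESC":
                if p.lnc_class == "decoy_unexpressed":
                    row[c] = silent_value()
                else:
                    row[c] = expressed_value()
            elif c == "GSC" and p.lnc_class == "true_candidate":
                row[c] = expressed_value()  # stem-cell-context enrichment
            else:
                row[c] = silent_value()
        rows[p.lnc_id] = row
    expr = ExpressionTable(
        pd.DataFrame.from_dict(rows, orient="index")[list(CELL_LINES)]
    )

    # --- write the bundle ----------------------------------------------------
    genes_gtf = out_dir / "genes.gtf"
    lncrnas_gtf = out_dir / "lncrnas.gtf"
    goi_list = out_dir / "goi.txt"
    expression_tsv = out_dir / "expression.tsv"
    loops_bedpe = out_dir / "loops.bedpe"
    truth_json = out_dir / "truth.json"

    write_gene_annotation(gois, genes_gtf)
    write_gene_annotation(lnc_records, lncrnas_gtf)
    goi_list.write_text("".join(g.gene_id + "\n" for g in gois))
    mark_beds: dict[str, Path] = {}
    for mark, ivs in peaks.items():
        path = out_dir / "marks" / f"{mark}.bed"
        write_peaks(PeakSet(mark, sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))), path)
        mark_beds[mark] = path
    write_expression(expr, expression_tsv)
    write_loops(LoopSet(loop_list), loops_bedpe)

    manifest = TruthManifest(cfg, gois, planted)
    manifest.to_json(truth_json)

    return SimulatedBundle(
        out_dir=out_dir,
        genes_gtf=genes_gtf,
        lncrnas_gtf=lncrnas_gtf,
        goi_list=goi_list,
        mark_beds=mark_beds,
        expression_tsv=expression_tsv,
        loops_bedpe=loops_bedpe,
        truth_json=truth_json,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Precision/recall of the screen against the planted truth."""

    precision: float | None  # None when no candidates were called
    recall: float
    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)


def evaluate_recovery(
    candidates: Iterable["CandidateRecord"],
    truth: TruthManifest,
) -> RecoveryReport:
    """Score final screen candidates against the truth manifest.

    Precision and recall compare the set of lncRNAs flagged
    ``final_candidate`` with the planted ``true_candidate`` class; the
    confusion table counts, per planted class, how many were called.
    An empty candidate set has undefined precision, reported as None.
    """
    known = {l.lnc_id for l in truth.lncs}
    called: set[str] = set()
    for rec in candidates:
        if rec.lnc_id not in known:
            raise KeyError(f"candidate {rec.lnc_id!r} not in truth manifest")
        if rec.final_candidate:
            called.add(rec.lnc_id)

    positives = truth.true_candidate_ids
    tp = len(called & positives)
    fp = len(called - positives)
    fn = len(positives - called)
    confusion = {
        cls: {
            "planted": len(truth.by_class(cls)),
            "called": sum(1 for l in truth.by_class(cls) if l.lnc_id in called),
        }
        for cls in LNC_CLASSES
    }
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return RecoveryReport(
        precision=precision,
        recall=recall,
        n_true_positive=tp,
        n_false_positive=fp,
        n_false_negative=fn,
        confusion=confusion,
    )
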