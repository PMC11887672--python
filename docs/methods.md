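# Methods

## Scope and model

`lncscreen` implements a proximity-and-chromatin screen for
enhancer-associated lncRNA candidates around a panel of stemness
transcription factors (GOIs), plus the element-level machinery needed to
describe a candidate locus: chromatin-state classification, super-enhancer
(SE) stitching with hub/non-hub tallies, and Hi-C loop support between a
candidate element and the GOI proximal promoter. It does not process
sequencing reads, call peaks or loops, or quantify expression — those are
upstream tools' jobs; the screen consumes their standard text outputs
(GTF/GFF3, BED, BEDPE, TSV).

All internal coordinates are 0-based half-open (BED convention); GTF/GFF3
input is converted on read and back on write. Chromosome names are used
verbatim; a complete mismatch between inputs is logged as a warning and
surfaces as zero overlaps rather than an exception.

## Screen criteria and their reading

The four gates are deliberately simple binary predicates, emulating
browser-level inspection rather than signal modelling:

1. **Proximity** is the *body-to-body* gap, not TSS distance — the most
   permissive reading of "within 1 Mbp upstream or downstream", and the
   one that matches genome-browser judgment. The window comparison is
   inclusive (gap = W passes). Genes on different chromosomes are
   infinitely far. A gap of exactly 0 (abutting or overlapping bodies) is
   labelled `overlapping`, so the invariant *distance = 0 ⟺ overlapping*
   holds.
2. **Antisense overlap** is evaluated at gene-body level (≥ 1 bp overlap,
   opposite strands). Same-strand overlap is retained and only flagged.
   An exon-level variant is available (`exon_level=True`) for annotations
   that carry exon features.
3. **Expression** passes when any screened cell-line column is ≥ the
   threshold (default 1 TPM; binary tables use threshold 1). A gene
   absent from the table counts as not transcribed (warning logged), not
   as an error.
4. **Chromatin state** is evaluated on the lncRNA body ± 2 kb (capturing
   promoter marks at the TSS edge). Active marks are H3K36me3/H3K27ac,
   repressive H3K9me3/H3K27me3; *any* non-empty state (active, repressed
   or both) passes, honouring the explicit "or repressed activity"
   disjunction.

Funnel counts are per unique lncRNA (a lncRNA near two GOIs is one
candidate); the pair table keeps every (lncRNA, GOI) pair. Because the
four criteria are independent predicates computed per pair, applying
(b)–(d) in any order yields the same final set; the funnel output exposes
each stage so either reading of the published attrition can be checked.

## Element classification

Candidate elements are classified from binary peak overlap with
`min_overlap_bp = 1` — visual track inspection has no fractional-overlap
rule, so any overlap counts. Precedence, first match wins:

1. H3K4me3 ∧ H3K27ac ∧ H3K4me1 within `h3k4me1_flank_bp` of **both**
   sides → `hub_enhancer`;
2. H3K27ac ∧ H3K4me1 (overlapping the element or flanking **either**
   side) → `enhancer`;
3. DNase without H3K27ac/H3K4me3 → `open_chromatin`;
4. repressive marks without any of H3K27ac/H3K4me3/H3K4me1 → `repressed`;
5. otherwise `none`.

The flank distance defaults to 5 kb: "flanked by H3K4me1" comes with no
stated distance, and 5 kb is within typical enhancer-mark spacing. It is
a declared convention, not an inference of anyone's intent, and is
overridable everywhere. The precedence order (hub > enhancer >
open-chromatin > repressed) is stated explicitly because mixed evidence
is otherwise unadjudicated; it guarantees that adding peaks can never
demote a hub call.

Any peak track whose mark is not a recognised histone/DNase name is
treated as a TF track and reported as element occupancy (e.g. NANOG,
POU5F1, YY1, RAD21, TCF12 at hub elements).

In the end-to-end pipeline, candidate element intervals are seeded from
the merged union of H3K27ac and DNase peaks (strictly overlapping peaks
merge; abutting ones stay separate). The standalone classifier CLI takes
any element BED instead, so externally defined elements (e.g. a
regulatory build) can be classified unchanged.

## Super-enhancer calling

Stitching is single-linkage per chromosome: elements of class
hub/enhancer/open-chromatin join one region when the gap between them is
≤ `stitch_bp` (default 12,500 bp, the field-standard stitching distance;
overlapping elements always join). Regions with ≥ `min_constituents`
(default 2) become SE calls. Calling is count-based, not
H3K27ac-signal-ranked: the screen identifies SEs by element adjacency,
and signal ranking is out of scope. Open-chromatin constituents ride
along in the region and the constituent list but are tallied as neither
hub nor non-hub, matching the convention of listing "active chromatin
sites" separately from enhancers.

SE-to-candidate assignment prefers an SE overlapping the gene body (ties:
one with a hub element inside the body, then largest overlap); otherwise
the nearest SE within the proximity window is reported with
`se_in_neighborhood` only.

## Promoter and loop support

The proximal promoter is a strand-aware window around the TSS, default
−2,000/+500 bp. For a + gene this is `[tss − up, tss + down)`; for a −
gene, `[tss − down, tss + up + 1)` — the mirrored window carries the TSS
base on its upstream edge and is therefore one base longer. This is a
declared coordinate convention (the original promoter coordinates exist
only graphically); at 2.5 kb scale the 1-bp asymmetry is immaterial.

A loop supports an (element, promoter) pair iff one anchor overlaps the
element and the other the promoter, in either anchor order, at a 1-bp
threshold. Resolution-aware padding (e.g. 5-kb Hi-C bins) should be
applied to the anchors before this module, not inside it. CTCF/H3K27ac
peak presence is recorded per anchor of each supporting loop, oriented
(element-side, promoter-side).

## The synthetic world

The generator writes a complete input bundle plus a truth manifest. Its
defaults *are* the stated world of the screen and were fixed before any
test was run:

| parameter | default | why |
|---|---|---|
| GOIs | 16, one per 6-Mbp chromosome | the published TF panel size; one per chromosome removes cross-GOI ambiguity |
| window | 1 Mbp | criterion (a) |
| true candidates | 20 | the published final-list size |
| decoys in window | 32 antisense + 30 unexpressed + 30 unmarked | sums with the positives to the published 112 proximal lncRNAs; the per-class split is not published and was chosen once, roughly evenly |
| far decoys | 40 | out-of-window controls |
| margins | in-window ≤ W − 50 kb; far > W + 50 kb; lncRNA–GOI gap ≥ 10 kb | keeps every planted call away from boundary ambiguity (boundaries are tested separately with hand-built fixtures) |
| guard band | 20 kb | noise peaks/loops never fall within it of a planted locus |
| expression | threshold + lognormal(0.5, 0.8) if expressed; zero-inflated below threshold otherwise | threshold 1 TPM |
| embedded SE | 1 hub + 4 non-hub enhancers + 1 open-chromatin site, 1.5-kb elements, 2–5-kb gaps | the composition described for the exemplar candidate locus |
| loops | one per true candidate, hub ↔ GOI promoter, 5-kb anchors, CTCF/H3K27ac at both anchors | the loop-support finding |

Each decoy class breaks exactly one criterion (antisense decoys are
expressed and marked; unexpressed decoys are marked; unmarked decoys are
expressed), so the funnel attrition is fully determined:
112 → 80 → 50 → 20. By construction — separation margins plus guard
bands — the default pipeline must achieve precision = recall = 1 on every
seed; any deviation is a pipeline bug, not sampling noise.

What the generator does **not** emulate: real peak-signal distributions
and widths, replicate variability, overlapping/nested gene architecture,
multi-GOI chromosomes (supported but not default), trans-chromosomal
loops, and annotation errors. A green end-to-end test therefore
establishes the correctness of the screen's logic on separable input, not
its robustness to noisy real tracks.

Determinism: one `numpy.random.Generator` seeded from the config drives
every draw in documented order (GOIs → lncRNA classes in order
true/antisense/unexpressed/unmarked/far → noise peaks per mark → noise
loops → expression values). Coordinates are integers and floats are
written with fixed formatting, so bundles and reports are byte-identical
across runs and platforms.

## Numerical and degenerate-input choices

- Intervals must satisfy 0 ≤ start < end; zero-length records are input
  errors, not silently dropped.
- Overlap of half-open intervals: abutment is 0 bp, never counted.
- `classify_locus(flank=0)` with a peak ending exactly at the locus start
  reports the mark absent (half-open semantics).
- Stitching with `stitch_bp = 0` merges only overlapping/abutting
  elements (join condition gap ≤ stitch).
- Empty GOI panel is an error (the screen is seeded by it); an empty
  lncRNA set yields an empty, well-formed result.
- Recovery precision with zero called candidates is undefined and
  reported as `None`/NA rather than 0.
- Pair output is sorted (goi_id, lnc_id); all report writers are
  deterministic.

## Known limitations

- Criterion (d) and element calls are binary peak logic; no signal-level
  thresholding, and no HMM-style segmentation.
- SE calling ignores H3K27ac signal rank; loci with many weak elements
  are called the same as strong ones.
- Loop support trusts the provided loop calls; no contact-matrix
  statistics.
- The screen is annotation-agnostic: results depend on the GTF supplied,
  and annotation releases differ materially in lncRNA content. The
  published absolute funnel counts are tied to a specific (unstated)
  annotation release and browser-level calls, and are reproduced here
  only through the synthetic world's construction, not from public data.
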