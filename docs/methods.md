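# Methods

This note documents the models, conventions, and deliberate design
choices behind `leukosv`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

Internal coordinates are 0-based, half-open (BED arithmetic). Clinical
and array reports print 1-based inclusive spans; readers convert on
input and writers convert back, so a printed span (s, e) has internal
length e − s + 1 and write-then-read round-trips are exact. Printed SV
sizes in source material sometimes disagree with their own printed
coordinates; the readers treat coordinates as authoritative and
recompute deletion/duplication sizes, never trusting a size column.

## The matching predicate

No vendor documents how "the same SV" is decided across pipelines or
platforms, so the predicate is this package's own contract, exposed in
`MatchParams`:

* type classes are pooled — deletion with array loss and whole-chromosome
  loss; duplication with gain; insertions, inversions, and the two
  translocation classes each separate;
* interval calls match when reciprocal overlap ≥ 0.5 **or** both span
  endpoints lie within the breakend tolerance (20 kb OGM–OGM, 50 kb
  OGM–array);
* translocations match when both breakends are within tolerance on
  matching chromosomes (either breakend order);
* karyotype events are compared at cytoband resolution: band labels are
  expanded hierarchically (p13.31 → p1, p13, p13.3, p13.31) and agree
  when equal at their shared precision, with ± one sub-band slack below
  the main-band level; FISH fusions match an interchromosomal
  translocation joining the two probe loci within a configurable window
  (default 1 Mb — FISH probes span hundreds of kilobases).

Merging is greedy one-to-one by descending overlap, ties leftmost-first,
after a canonical sort, which makes the output independent of input
order. On instances at realistic call density (calls scattered over tens
of megabases) greedy matching recovers the optimal bipartite pair count
essentially always (the test suite checks ≥ 99% agreement against an
exhaustive assignment oracle); in pathologically dense clusters — many
mutually overlapping calls packed into a few megabases — it can
under-match by one pair. DN coordinates win on a DN/RVP merge because
the de novo assembly is treated as the primary callset; provenance
records both callers.

## Filters

All thresholds are inclusive ("at least"): array CNVs need ≥ 20 probes
and ≥ 50,000 bp, CNN-LOH ≥ 5,000,000 bp, OGM interval calls ≥ 500 bp.
Translocations carry no length and bypass size rules but not the
blacklist. The blacklist rule removes a call when a breakpoint falls
inside an IG/TR locus, centromere, or reference gap, when its span is
contained in one, or — for focal calls only — when its span overlaps
one. Large and whole-chromosome calls that merely *span across* a
centromere (whole-arm duplications, aneuploidies) are deliberately kept:
a literal any-overlap rule would delete every aneuploidy call, which is
plainly not how such blacklists are applied in practice.

Size classes: focal < 5 Mb; whole-chromosome when the span covers
≥ 95% of the contig; large otherwise. Whole-chromosome calls feed the
per-chromosome copy-state map (baseline 2, +1 per gain call; array/CN
segments can carry an explicit integer CN where available).

## Minimal altered regions

Pass-filter somatic focal calls with spans (deletions, duplications,
insertions — insertions as ±1 bp point spans) are clustered per
chromosome by single-linkage any-overlap, ignoring SV type. Within a
cluster, every *maximal* subset of calls with a non-empty common
intersection is found by sweeping the atomic segments between span
breakpoints and keeping the set-maximal coverage sets; each such set
with ≥ 3 distinct patients (multiple calls from one patient count once)
yields one MAR whose region is the intersection of its supporting
spans. This is deterministic, invariant to patient order, and equal to
brute-force enumeration over call subsets (tested exhaustively on small
cohorts). Target genes are those whose body or promoter (2 kb upstream
of the strand-aware 5′ end — a conventional window, configurable, since
no standard exists) overlaps the region; intergenic MARs record the
nearest gene within 20 kb with a signed, strand-aware distance
(negative = upstream). A MAR is subtype-specific iff all supporting
patients share one subtype.

## Rule-based classifiers

`evaluate_ikzf1_plus` is a pure boolean of the somatic deletion set:
IKZF1 hit AND (CDKN2A | CDKN2B | PAX5 | PAR1 hit) AND no ERG hit, with
per-criterion call ids in the rationale. PAR1 is a named region record
(chrX:10,001–2,781,479, GRCh38), not a gene. A subclonal flag is set
when the IKZF1 deletion VAF < 0.1; the rule itself ignores clonality —
whether subclonal deletions should count clinically is unresolved, so
the package reports the flag and leaves interpretation to the user.

`classify_hd_risk` (hyperdiploid only): poor iff (CN17 < 3 and CN18 < 3)
or ((CN17 ≥ 3 or CN18 ≥ 3) and (CN5 ≥ 3 or CN20 ≥ 3)). "Either trisomy
17 or 18" is implemented as inclusive-or with an exclusive-or config
switch, and trisomy means CN ≥ 3 (tetrasomy counts — hyperdiploid
genomes are gain-rich and the rule's wording is about the presence of a
gain).

`predict_fusions` pairs genes within 10 kb of each breakend across the
junction. A pair is orientation-compatible when the retained sides and
strands admit a head-to-tail transcript: a gene donates its 5′ portion
when the retained side contains its transcription start (strand +/left
or −/right), its 3′ portion in the mirrored cases. There is no codon
phase check — OGM breakpoints are label-resolution approximations, so
every candidate is labeled putative and in-frame verification is a
declared non-goal.

## Statistics

The Mann–Whitney U test uses midranks for ties. For pooled samples of
≤ 12 observations the two-sided p-value enumerates all C(n+m, n) group
assignments of the observed pooled values (ties handled exactly);
otherwise a tie-corrected normal approximation with continuity
correction is used, cross-checked against an independent implementation
in the tests. Degenerate input (all values identical) returns p = 1.
Concordance percentages round half-up to integers and fold changes to
one decimal, matching clinical reporting style. Burden tables exclude
hallmark-flagged events (the subtype-defining translocation, 3-way
variants, and whole-chromosome gains) and whole-chromosome calls; the
hallmark flag is set by the producer of the calls, never re-detected
heuristically.

## The synthetic cohort

The generator's defaults encode the study conditions the analysis
assumes; they are not free parameters.

* Cohort: 30 ETV6::RUNX1 + 30 hyperdiploid tumor/normal pairs. Tumor
  blast fraction ~ U(0.75, 0.95); clonal VAF = blast/2; 10% of somatic
  events are subclonal with VAF ~ U(0.05, 0.25).
* Hallmarks: t(12;21) in 100% of ETV6::RUNX1 tumors (breakends inside
  the ETV6/RUNX1 fixtures, fusion-compatible orientations), with a
  3-way variant at probability 9/30. Hyperdiploid per-chromosome gains:
  chr21 tetrasomy 29/30 else trisomy; chr14 trisomy 24/30 or tetrasomy
  6/30; the rest of the classic gained set (4, 6, 10, 17, 18, X, plus
  lower rates for 5, 8, 20) uses configured defaults, since
  per-chromosome frequencies beyond 14/21 are not published — they are
  config values, not assertions.
* Focal-deletion burden: 1 + NegBin(r, μ), chosen for the overdispersion
  the reported ranges imply, with (r = 2.8, μ = 13.5) giving median 13
  and ~99.5th percentile ≈ 47 for ETV6::RUNX1, and (r = 1.8, μ = 3.6)
  giving median 4, ≈ 17 for hyperdiploid — matching the target medians
  13.5 and 4 and ranges ≈ 1–46 / 1–14. Background deletion sizes are
  log-uniform on [1 kb, 2.5 Mb] (median ≈ 50 kb, about half below the
  50 kb array limit). A recurrent-gene panel (ETV6 0.27, CDKN2A 0.23,
  PAX5 0.22, …, plus ETV6::RUNX1-only entries such as BTG1 0.33 and
  GPRC5A 0.17) implants gene-directed deletions that always cover the
  gene's middle third, so any three hits intersect.
* Other SV types follow per-subtype Poisson rates fitted to per-case
  averages (insertions ≈ 2.3/0.7, interchromosomal translocations
  ≈ 1.3/0.25, etc.), large 5–30 Mb SVs at 1.5/0.9 per case, occasional
  whole-chromosome or 9p/9q CNN-LOH. SNV counts are min + NegBin with
  subtype-specific gene weights (NRAS, KRAS, CREBBP, FLT3, PTPN11,
  UBA2, …) to produce realistic double hits.
* Germline: Poisson(25) SVs per patient, shared by tumor and normal.
  This is far below a genome's true germline SV load; it is the set
  that survives the vendor's internal population filters and reaches
  the analyst, which is what germline subtraction operates on.
* Caller models: OGM pipelines (DN/RVP) call all SV types ≥ 500 bp with
  3 kb breakpoint jitter and logistic VAF sensitivity (midpoint 0.05/
  0.03); DN additionally applies a hard VAF floor of 0.15 (de novo
  assembly dilutes subclones), so RVP-only provenance marks subclonal
  events. Arrays call del/dup/aneuploidy/CNN-LOH above their limits
  (CytoSNP-12-like 50 kb at ~10 kb probe spacing; CytoScanHD-like 1 kb
  at ~1.1 kb), with an IKZF1-like probe gap where both arrays are
  blind, sensitivity midpoint 0.12 (≈ 20–25% blasts), and probe-gap
  jitter. The CN tool sees only events ≥ 5 Mb. Events with a breakpoint
  inside a blind region (OGM: centromeres) are invisible. OGM models
  add Poisson false calls (0.25–0.35 per genome). Every per-event
  decision is drawn from an RNG keyed by (seed, event id, platform), so
  a germline event is emitted or dropped jointly for tumor and matched
  normal — without this, germline subtraction tests would be flaky by
  construction.
* Conventional reports: per-tumor karyotype strings (hallmark
  translocation at band resolution, ±chromosome aneuploidies) and a
  FISH fusion assay for ETV6::RUNX1 cases.

What the simulation does *not* model: sequence context (no FASTA/reads),
complex rearrangement chains, clonal phylogenies, label-density-dependent
OGM resolution, array wave artifacts, and real germline SV population
structure. Passing recovery tests therefore demonstrates that the
integration logic is correct under the stated noise model, not that the
pipeline performs at these rates on real instruments.

## Fixtures

The bundled cytoband map, gene panel, and blacklist are synthetic
approximations at roughly real GRCh38 positions (files are named
`*_synthetic.*`). Band boundaries for heavily used chromosomes track the
reference atlas closely; other chromosomes carry coarser synthetic
bands. The contig-length table is the standard GRCh38 primary assembly.

## Problem sizes and determinism

The test suite runs the full 30+30 cohort once (session fixture, seed 1)
for parameter-recovery checks and smaller 6+6 / 2+2 cohorts elsewhere;
property tests are derandomized. The acceptance script derives all
randomness from its `--seed`. Simulating and analysing the 30+30 cohort
takes a few seconds on one CPU.

## Known limitations

* Integer copy number is carried only as gain/loss classes plus one call
  per extra copy; a tetrasomy recovered purely from direction-class
  segments appears as CN 3 unless the segment source supplies integer CN.
  The risk rules only require CN ≥ 3, so they are unaffected.
* Greedy matching can under-pair in extremely dense call clusters (see
  above).
* Fusion prediction is orientation-level; reading-frame and expression
  validation require orthogonal data by design.
* The concordance module reports both per-platform and overall rates;
  when one event is reported by several conventional platforms it counts
  once per platform (the deduplicated overall rate is also emitted).
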