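"""Minimal altered regions (MARs) recurrent across the cohort.

A MAR is the genomic intersection of overlapping somatic focal SVs (not
differentiating between SV types) carried by at least
``recurrence_min_cases`` distinct patients.  The region nominates target
genes (gene body or promoter overlap), or, when intergenic, the nearest
gene within a proximity window.

Algorithm: focal span calls are clustered by single-linkage any-overlap;
inside each cluster every maximal set of calls with a non-empty common
intersection is found by sweeping the atomic segments between breakpoints
and keeping the set-maximal coverage sets.  This is deterministic and, on
small cohorts, provably identical to brute-force enumeration over case
subsets (see the test suite's oracle).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .types import (
    GeneModel, GenomicInterval, LeukoSVError, PipelineConfig, SVCall,
    SampleMeta,
)

#: SV types that participate in MAR detection (focal span calls)
MAR_SV_TYPES = frozenset({"deletion", "duplication", "insertion"})


@dataclass
class MAR:
    """A minimal altered region with its supporting evidence."""

    region: GenomicInterval
    supporting_cases: dict[str, str]  # patient_id -> sv_type (one per patient)
    supporting_calls: list[SVCall]
    target_genes: list[str] = field(default_factory=list)
    nearest_gene: Optional[str] = None
    nearest_distance: Optional[int] = None  # signed; negative = upstream of gene
    specificity: str = "common"

    @property
    def n_cases(self) -> int:
        return len(self.supporting_cases)

    @property
    def intergenic(self) -> bool:
        return not self.target_genes


def _mar_span(call: SVCall) -> GenomicInterval:
    """Span used for clustering; insertions become point spans padded +/-1 bp."""
    if call.sv_type == "insertion":
        s = call.span
        return GenomicInterval(s.chrom, max(0, s.start - 1), s.end + 1)
    return call.span


def _single_linkage_clusters(calls: list[SVCall]) -> list[list[SVCall]]:
    """Group calls connected by any-overlap (per chromosome, sorted sweep)."""
    clusters: list[list[SVCall]] = []
    by_chrom: dict[str, list[SVCall]] = {}
    for c in calls:
        by_chrom.setdefault(_mar_span(c).chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom],
                             key=lambda c: (_mar_span(c).start, _mar_span(c).end,
                                            c.sample_id, c.call_id))
        current: list[SVCall] = []
        reach = -1
        for c in chrom_calls:
            s = _mar_span(c)
            if current and s.start >= reach:
                clusters.append(current)
                current = []
            current.append(c)
            reach = max(reach, s.end)
        if current:
            clusters.append(current)
    return clusters


def _maximal_cover_sets(calls: list[SVCall]) -> list[tuple[GenomicInterval, list[SVCall]]]:
    """All set-maximal subsets of calls with non-empty common intersection.

    Sweeps atomic segments between span breakpoints; each segment's covering
    call set has a non-empty intersection, and the set-maximal ones among
    them are exactly the maximal compatible subsets.
    """
    spans = [_mar_span(c) for c in calls]
    points = sorted({p for s in spans for p in (s.start, s.end)})
    covers: dict[frozenset, None] = {}
    for a, b in zip(points, points[1:]):
        cover = frozenset(i for i, s in enumerate(spans)
                          if s.start <= a and s.end >= b)
        if cover:
            covers.setdefault(cover)
    maximal = [c for c in covers
               if not any(c < other for other in covers)]
    out = []
    for cover in maximal:
        members = [calls[i] for i in sorted(cover)]
        region = GenomicInterval(
            spans[0].chrom,
            max(_mar_span(c).start for c in members),
            min(_mar_span(c).end for c in members))
        out.append((region, members))
    out.sort(key=lambda t: (t[0].start, t[0].end))
    return out


def compute_mars(somatic_by_patient: dict[str, list[SVCall]],
                 config: Optional[PipelineConfig] = None) -> list[MAR]:
    """Detect MARs from per-patient pass-filter somatic focal calls.

    Multiple calls from one patient in a cluster count once toward the
    case threshold.  Output order and content are invariant to the input
    patient order.
    """
    config = config or PipelineConfig()
    calls = []
    for patient_id in sorted(somatic_by_patient):
        for c in somatic_by_patient[patient_id]:
            if c.sv_type in MAR_SV_TYPES and c.span is not None \
                    and c.filter_status == "pass":
                if c.sample_id and c.sample_id != patient_id:
                    c = c.with_(sample_id=patient_id)
                calls.append(c if c.sample_id else c.with_(sample_id=patient_id))
    mars: list[MAR] = []
    for cluster in _single_linkage_clusters(calls):
        patients = {c.sample_id for c in cluster}
        if len(patients) < config.recurrence_min_cases:
            continue
        for region, members in _maximal_cover_sets(cluster):
            supporters: dict[str, str] = {}
            for m in sorted(members, key=lambda c: (c.sample_id, c.call_id)):
                supporters.setdefault(m.sample_id, m.sv_type)
            if len(supporters) < config.recurrence_min_cases:
                continue
            for m in members:
                assert _mar_span(m).contains(region), "MAR outside supporting span"
            mars.append(MAR(region=region, supporting_cases=supporters,
                            supporting_calls=members))
    mars.sort(key=lambda m: (m.region.chrom, m.region.start, m.region.end))
    # identical regions from adjacent clusters cannot occur (clusters are
    # disjoint in coverage), so no dedup step is needed
    return mars


def assign_targets(mar: MAR, genes: list[GeneModel],
                   config: Optional[PipelineConfig] = None) -> MAR:
    """Annotate a MAR with overlapping genes, or the nearest gene within 20 kb.

    The signed distance is negative when the MAR lies upstream of the gene
    (relative to its strand), positive when downstream.
    """
    config = config or PipelineConfig()
    hits = [g.symbol for g in genes
            if mar.region.overlaps(g.span) or mar.region.overlaps(g.promoter)]
    mar.target_genes = sorted(set(hits))
    mar.nearest_gene = None
    mar.nearest_distance = None
    if not hits:
        best = None
        for g in genes:
            d = mar.region.distance_to(g.span)
            if d is None or d > config.intergenic_proximity_bp:
                continue
            if best is None or d < best[0]:
                best = (d, g)
        if best is not None:
            d, g = best
            upstream = (mar.region.end <= g.span.start) == (g.strand == "+")
            mar.nearest_gene = g.symbol
            mar.nearest_distance = -d if upstream else d
    return mar


def subtype_specificity(mar: MAR, samples: list[SampleMeta]) -> str:
    """``<subtype>_specific`` when all supporters share one subtype, else common."""
    by_patient = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, s.subtype)
    subtypes = set()
    for patient_id in mar.supporting_cases:
        if patient_id not in by_patient:
            raise LeukoSVError(f"no subtype known for patient {patient_id!r}")
        subtypes.add(by_patient[patient_id])
    label = f"{subtypes.pop()}_specific" if len(subtypes) == 1 else "common"
    mar.specificity = label
    return label


def annotate_mars(mars: list[MAR], genes: list[GeneModel],
                  samples: list[SampleMeta],
                  config: Optional[PipelineConfig] = None) -> list[MAR]:
    """Convenience: target assignment + specificity for a whole MAR list."""
    for m in mars:
        assign_targets(m, genes, config)
        subtype_specificity(m, samples)
    return mars
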