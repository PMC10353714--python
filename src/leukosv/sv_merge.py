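"""Dual-pipeline call merging, germline subtraction, filtering, size classes.

This stage turns raw per-sample call tables into a curated somatic callset:

1. calls made by both OGM SV pipelines (de novo assembly, DN, and the rare
   variant pipeline, RVP) are collapsed into single calls with joint
   provenance; the copy-number algorithm contributes only segments >= 5 Mb;
2. calls also present in the matched non-tumor sample are removed as
   likely germline;
3. array-derived CNVs below the probe/size thresholds, CNN-LOH below 5 Mb,
   OGM calls below 500 bp, and calls touching IG/TR loci, centromeres or
   reference gaps are filtered with machine-readable reasons;
4. surviving calls are classed focal (< 5 Mb), large, or whole-chromosome.

The cross-pipeline matching predicate (reciprocal overlap or breakend
distance, greedy one-to-one) is this package's own contract; vendor tools
do not publish theirs.  All thresholds are inclusive ("at least").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import BlacklistRegion
from .types import (
    CNSegment, GenomicInterval, LeukoSVError, PipelineConfig, SVCall,
)

#: pooled type classes for cross-platform matching
_TYPE_CLASS = {
    "deletion": "DEL", "aneuploidy_loss": "DEL",
    "duplication": "DUP", "aneuploidy_gain": "DUP",
    "insertion": "INS", "inversion": "INV",
    "intra_translocation": "INTRA", "inter_translocation": "TRA",
    "cnn_loh": "LOH",
}

CN_STATE_TO_SV = {"loss": "deletion", "gain": "duplication", "cnn_loh": "cnn_loh"}


@dataclass
class MatchParams:
    """Predicate parameters for deciding that two calls are the same SV."""

    reciprocal_overlap_min: float = 0.5
    breakend_tol_bp: dict = field(default_factory=lambda: {
        ("OGM", "OGM"): 20_000,
        ("OGM", "ARRAY"): 50_000,
        ("OGM", "KARYOTYPE"): None,  # band-level, handled in concordance
    })
    default_tol_bp: int = 20_000

    def __post_init__(self):
        if not (0.0 < self.reciprocal_overlap_min <= 1.0):
            raise LeukoSVError("reciprocal_overlap_min must be in (0, 1]")
        for tol in self.breakend_tol_bp.values():
            if tol is not None and tol <= 0:
                raise LeukoSVError("breakend tolerances must be > 0")

    def tol(self, pair: Optional[tuple[str, str]] = None) -> int:
        if pair is None:
            return self.default_tol_bp
        t = self.breakend_tol_bp.get(pair, self.breakend_tol_bp.get(pair[::-1]))
        return self.default_tol_bp if t is None else t


def type_class(sv_type: str) -> str:
    return _TYPE_CLASS[sv_type]


def match_calls(a: SVCall, b: SVCall, params: MatchParams,
                tol_bp: Optional[int] = None) -> bool:
    """True iff ``a`` and ``b`` plausibly describe the same event.

    Interval calls match when their type classes agree and either the
    reciprocal overlap reaches the threshold or both endpoints lie within
    the breakend tolerance.  Translocations match when both breakends are
    within tolerance on matching chromosomes.  Symmetric in (a, b).
    """
    if type_class(a.sv_type) != type_class(b.sv_type):
        return False
    tol = params.default_tol_bp if tol_bp is None else tol_bp
    if a.sv_type == "inter_translocation":
        (a1, a2), (b1, b2) = a.breakends, b.breakends
        for (x1, x2) in ((b1, b2), (b2, b1)):
            if (a1.chrom == x1.chrom and a2.chrom == x2.chrom
                    and abs(a1.pos - x1.pos) <= tol
                    and abs(a2.pos - x2.pos) <= tol):
                return True
        return False
    if a.span.chrom != b.span.chrom:
        return False
    if a.span.reciprocal_overlap(b.span) >= params.reciprocal_overlap_min:
        return True
    return (abs(a.span.start - b.span.start) <= tol
            and abs(a.span.end - b.span.end) <= tol)


def _overlap_score(a: SVCall, b: SVCall) -> float:
    if a.sv_type == "inter_translocation":
        d = min(abs(a.breakends[0].pos - b.breakends[0].pos)
                + abs(a.breakends[1].pos - b.breakends[1].pos),
                abs(a.breakends[0].pos - b.breakends[1].pos)
                + abs(a.breakends[1].pos - b.breakends[0].pos))
        return 1.0 / (1.0 + d)
    return a.span.reciprocal_overlap(b.span)


def _sort_key(c: SVCall):
    if c.sv_type == "inter_translocation":
        b = min(c.breakends, key=lambda x: (x.chrom, x.pos))
        return (b.chrom, b.pos, 0, c.call_id)
    return (c.span.chrom, c.span.start, c.span.end, c.call_id)


def greedy_match(a_calls: list[SVCall], b_calls: list[SVCall],
                 params: MatchParams, tol_bp: Optional[int] = None
                 ) -> list[tuple[int, int]]:
    """One-to-one greedy matching by descending overlap, ties leftmost-first.

    Returns index pairs into the canonically sorted inputs' original lists.
    """
    a_order = sorted(range(len(a_calls)), key=lambda i: _sort_key(a_calls[i]))
    b_order = sorted(range(len(b_calls)), key=lambda i: _sort_key(b_calls[i]))
    candidates = []
    for rank_a, i in enumerate(a_order):
        for rank_b, j in enumerate(b_order):
            if match_calls(a_calls[i], b_calls[j], params, tol_bp):
                score = _overlap_score(a_calls[i], b_calls[j])
                candidates.append((-score, rank_a, rank_b, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def _check_single_sample(calls: Iterable[SVCall]) -> Optional[str]:
    sample = None
    for c in calls:
        if sample is None:
            sample = c.sample_id
        elif c.sample_id != sample:
            raise LeukoSVError(
                f"mixed samples in one merge: {sample!r} vs {c.sample_id!r}")
    return sample


def cn_segment_to_call(seg: CNSegment, call_id: str) -> SVCall:
    sv_type = CN_STATE_TO_SV.get(seg.state)
    if sv_type is None:
        raise LeukoSVError(f"CN state {seg.state!r} has no SV equivalent")
    return SVCall(call_id=call_id, sample_id=seg.sample_id, sv_type=sv_type,
                  span=seg.span, size_bp=seg.span.length,
                  callers=frozenset({"CN" if seg.platform == "OGM_CN" else "ARRAY"}),
                  n_probes=seg.n_probes or None)


def merge_pipelines(dn: list[SVCall], rvp: list[SVCall],
                    cn: list[CNSegment], params: MatchParams,
                    config: Optional[PipelineConfig] = None) -> list[SVCall]:
    """Merge DN + RVP callsets and append unmatched CN segments >= 5 Mb.

    Matched DN/RVP pairs collapse into one call carrying the DN coordinates
    (the de novo assembly is the primary callset) and joint provenance.
    Output order is canonical and independent of input order.
    """
    config = config or PipelineConfig()
    _check_single_sample(list(dn) + list(rvp))
    pairs = greedy_match(dn, rvp, params)
    matched_dn = {i for i, _ in pairs}
    matched_rvp = {j for _, j in pairs}
    merged: list[SVCall] = []
    for i, j in pairs:
        merged.append(dn[i].with_(
            callers=dn[i].callers | rvp[j].callers,
            vaf=dn[i].vaf if dn[i].vaf is not None else rvp[j].vaf,
            hallmark=dn[i].hallmark or rvp[j].hallmark))
    merged.extend(c for i, c in enumerate(dn) if i not in matched_dn)
    merged.extend(c for j, c in enumerate(rvp) if j not in matched_rvp)

    # CN tool contributes only large segments not already seen by DN/RVP
    for k, seg in enumerate(seg for seg in cn
                            if seg.span.length >= config.focal_large_boundary_bp
                            and seg.state in CN_STATE_TO_SV):
        call = cn_segment_to_call(seg, f"cn_{seg.sample_id}_{k}")
        if not any(match_calls(call, m, params) for m in merged):
            merged.append(call)
    merged.sort(key=_sort_key)
    return merged


def subtract_germline(tumor: list[SVCall], normal: list[SVCall],
                      params: MatchParams, allow_unmatched: bool = False
                      ) -> tuple[list[SVCall], list[SVCall]]:
    """Partition tumor calls into (somatic, germline-removed).

    A tumor call is removed iff it matches any call from the matched
    non-tumor sample.  ``somatic + removed`` is an exact partition of the
    input.
    """
    if not normal and not allow_unmatched:
        if not tumor:
            return [], []
        raise LeukoSVError(
            "no matched-normal calls given; pass allow_unmatched=True to "
            "treat every tumor call as somatic")
    somatic, removed = [], []
    for t in tumor:
        if any(match_calls(t, n, params) for n in normal):
            removed.append(t.with_(filter_status="filtered:germline"))
        else:
            somatic.append(t)
    return somatic, removed


def _hits_blacklist(call: SVCall, blacklist: list[BlacklistRegion],
                    config: PipelineConfig) -> Optional[BlacklistRegion]:
    """Blacklist test: breakpoint in region, span contained in region, or
    (for focal calls) any span overlap.

    Large and whole-chromosome calls legitimately span across centromeres
    and gaps (e.g. whole-arm duplications), so for calls at or above the
    focal/large boundary only containment or a breakpoint inside the
    region counts.
    """
    points: list[GenomicInterval] = []
    if call.breakends is not None:
        for b in call.breakends:
            points.append(GenomicInterval(b.chrom, b.pos, b.pos + 1))
    focal = (call.span is not None
             and call.span.length < config.focal_large_boundary_bp
             and not call.sv_type.startswith("aneuploidy"))
    if call.span is not None and not call.sv_type.startswith("aneuploidy"):
        points.append(GenomicInterval(call.span.chrom, call.span.start,
                                      call.span.start + 1))
        points.append(GenomicInterval(call.span.chrom,
                                      max(0, call.span.end - 1), call.span.end))
    for region in blacklist:
        if any(p.overlaps(region.region) for p in points):
            return region
        if call.span is not None and region.region.contains(call.span):
            return region
        if focal and call.span.overlaps(region.region):
            return region
    return None


def apply_filters(calls: list[SVCall], config: PipelineConfig,
                  blacklist: list[BlacklistRegion]
                  ) -> tuple[list[SVCall], list[SVCall]]:
    """Partition calls into (kept, filtered-with-reason).

    Array del/dup need >= 20 probes and >= 50 kb; CNN-LOH needs >= 5 Mb;
    OGM interval calls need >= 500 bp; translocations are exempt from size
    rules; anything overlapping an IG/TR locus, centromere, or reference
    gap is removed.  Thresholds are inclusive.
    """
    kept, dropped = [], []
    for c in calls:
        reason = None
        hit = _hits_blacklist(c, blacklist, config)
        if hit is not None:
            reason = hit.cls
        elif c.sv_type == "cnn_loh":
            if c.span.length < config.cnnloh_min_bp:
                reason = "min_size"
        elif c.sv_type == "inter_translocation":
            pass  # breakend calls carry no length
        elif "ARRAY" in c.callers and c.sv_type in ("deletion", "duplication"):
            if c.n_probes is not None and c.n_probes < config.array_min_probes:
                reason = "min_probes"
            elif c.size_bp < config.array_min_cnv_bp:
                reason = "min_size"
        elif c.sv_type in ("aneuploidy_gain", "aneuploidy_loss"):
            pass  # whole-chromosome events have no size rule
        else:
            if c.size_bp < config.ogm_min_sv_bp:
                reason = "min_size"
        if reason is None:
            kept.append(c)
        else:
            dropped.append(c.with_(filter_status=f"filtered:{reason}"))
    return kept, dropped


def filter_array_segments(segments: list[CNSegment], config: PipelineConfig
                          ) -> tuple[list[CNSegment], list[tuple[CNSegment, str]]]:
    """Apply the array inclusion rules at segment level.

    Deletions/duplications: >= ``array_min_probes`` probes AND
    >= ``array_min_cnv_bp``; CNN-LOH: >= ``cnnloh_min_bp``.
    """
    kept, dropped = [], []
    for s in segments:
        if s.state == "cnn_loh":
            if s.span.length >= config.cnnloh_min_bp:
                kept.append(s)
            else:
                dropped.append((s, "min_size"))
        elif s.state in ("loss", "gain"):
            if s.platform != "OGM_CN" and s.n_probes < config.array_min_probes:
                dropped.append((s, "min_probes"))
            elif s.span.length < config.array_min_cnv_bp:
                dropped.append((s, "min_size"))
            else:
                kept.append(s)
        else:
            dropped.append((s, "neutral"))
    return kept, dropped


def classify_size(call: SVCall, config: PipelineConfig,
                  contigs: dict[str, int]) -> str:
    """``focal`` (< 5 Mb), ``large``, or ``whole_chromosome`` (>= 95% of contig)."""
    if call.sv_type == "inter_translocation":
        return "focal"
    if call.sv_type in ("aneuploidy_gain", "aneuploidy_loss"):
        return "whole_chromosome"
    length = call.span.length
    if length < config.focal_large_boundary_bp:
        return "focal"
    chrom_len = contigs.get(call.span.chrom)
    if chrom_len is not None and length >= config.whole_chrom_fraction * chrom_len:
        return "whole_chromosome"
    return "large"
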