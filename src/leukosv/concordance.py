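"""Cross-platform verification of conventional-method calls against OGM.

Each SNP-array, karyotype, or FISH call is matched to at most one OGM
call.  Array segments match by interval overlap/breakend distance;
karyotype events match at cytoband resolution (the OGM breakend's band
must equal the reported band or an adjacent sub-band); FISH fusions match
when an OGM interchromosomal translocation joins the two probe loci.
Percentages are rounded half-up to integers, following the reporting
style of clinical concordance tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import CytobandMap
from .sv_merge import MatchParams, match_calls, type_class
from .types import GenomicInterval, LeukoSVError, PipelineConfig, SVCall


@dataclass
class ConcordanceRecord:
    reference: SVCall            # platform in {ARRAY, KARYOTYPE, FISH}
    matched_ogm_id: Optional[str]
    basis: str                   # "overlap", "band", "fusion_loci", or "none"

    @property
    def verified(self) -> bool:
        return self.matched_ogm_id is not None

    @property
    def platform(self) -> str:
        for p in ("ARRAY", "KARYOTYPE", "FISH"):
            if p in self.reference.callers:
                return p
        raise LeukoSVError(f"reference call {self.reference.call_id} has no "
                           "conventional-platform provenance")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _band_levels(band: str) -> list[str]:
    """Hierarchical prefixes of a band label, e.g. p13.31 ->
    [p1, p13, p13.3, p13.31].  A leading chromosome number is stripped."""
    i = 0
    while i < len(band) and band[i] not in "pq":
        i += 1
    band = band[i:]
    arm, digits = band[0], band[1:].replace(".", "")
    return [arm + digits[:k + 1] for k in range(len(digits))]


def _band_close(a: str, b: str) -> bool:
    """Band labels agree at their shared precision, allowing +/- one
    sub-band below the main-band level (karyotype resolution)."""
    la, lb = _band_levels(a), _band_levels(b)
    if not la or not lb or la[0][0] != lb[0][0]:
        return False
    depth = min(len(la), len(lb))
    if la[depth - 1] == lb[depth - 1]:
        return True
    if depth >= 3 and la[depth - 2] == lb[depth - 2]:
        return abs(int(la[depth - 1][-1]) - int(lb[depth - 1][-1])) <= 1
    return False


def _match_karyotype(ref: SVCall, ogm: SVCall, cytobands: CytobandMap) -> bool:
    if type_class(ref.sv_type) != type_class(ogm.sv_type):
        return False
    if ref.sv_type in ("aneuploidy_gain", "aneuploidy_loss"):
        return ogm.span is not None and ogm.span.chrom == ref.span.chrom
    if ref.sv_type == "inter_translocation":
        rb = {b.chrom: cytobands.lookup(b.chrom, b.pos) for b in ref.breakends}
        ob = {}
        for b in ogm.breakends:
            try:
                ob[b.chrom] = cytobands.lookup(b.chrom, b.pos)
            except LeukoSVError:
                return False
        if set(rb) != set(ob):
            return False
        return all(_band_close(rb[c], ob[c]) for c in rb)
    # band-resolution interval events: any overlap with the reported band span
    return ogm.span is not None and ref.span.overlaps(ogm.span)


def _match_fish(ref: SVCall, ogm: SVCall, window: int) -> bool:
    if ogm.sv_type != "inter_translocation" or ref.breakends is None:
        return False
    for (r1, r2) in (ref.breakends, ref.breakends[::-1]):
        o1, o2 = ogm.breakends
        if (r1.chrom == o1.chrom and r2.chrom == o2.chrom
                and abs(r1.pos - o1.pos) <= window
                and abs(r2.pos - o2.pos) <= window):
            return True
    return False


def match_platform(reference: list[SVCall], ogm: list[SVCall],
                   params: Optional[MatchParams] = None,
                   cytobands: Optional[CytobandMap] = None,
                   fish_window_bp: int = 1_000_000) -> list[ConcordanceRecord]:
    """Match each reference call to at most one OGM call.

    Stable under permutation of the input call order (references are
    processed in canonical order and claim OGM calls greedily).
    """
    params = params or MatchParams()
    records = []
    # one OGM call can verify at most one reference per platform, but the
    # same OGM call may independently verify e.g. a karyotype event and the
    # FISH assay that both describe it
    claimed: set[tuple[str, int]] = set()
    order = sorted(range(len(reference)),
                   key=lambda i: reference[i].call_id)
    ogm_order = sorted(range(len(ogm)), key=lambda j: ogm[j].call_id)
    for i in order:
        ref = reference[i]
        rec = ConcordanceRecord(ref, None, "none")
        platform = rec.platform
        for j in ogm_order:
            if (platform, j) in claimed:
                continue
            cand = ogm[j]
            if platform == "ARRAY":
                ok = match_calls(ref, cand, params, params.tol(("OGM", "ARRAY")))
                basis = "overlap"
            elif platform == "KARYOTYPE":
                if cytobands is None:
                    raise LeukoSVError("karyotype matching needs a cytoband map")
                ok = _match_karyotype(ref, cand, cytobands)
                basis = "band"
            else:
                ok = _match_fish(ref, cand, fish_window_bp)
                basis = "fusion_loci"
            if ok:
                claimed.add((platform, j))
                rec = ConcordanceRecord(ref, cand.call_id, basis)
                break
        records.append(rec)
    records.sort(key=lambda r: r.reference.call_id)
    return records


def concordance_rates(records: list[ConcordanceRecord]) -> dict[str, dict]:
    """Per-platform and overall {verified, total, percent} summaries.

    Platforms with zero reference calls are omitted; percent is rounded
    half-up to the nearest integer.
    """
    if not records:
        raise LeukoSVError("no concordance records to summarize")
    out: dict[str, dict] = {}
    for scope in ("ARRAY", "KARYOTYPE", "FISH", "overall"):
        subset = [r for r in records if scope == "overall" or r.platform == scope]
        if not subset:
            continue
        verified = sum(r.verified for r in subset)
        out[scope] = {"verified": verified, "total": len(subset),
                      "percent": round_half_up(100.0 * verified / len(subset))}
    # deduplicated overall: references verified by the same OGM call (an
    # event reported by several conventional assays) count once
    dedup_verified = len({r.matched_ogm_id for r in records if r.verified})
    dedup_total = dedup_verified + sum(not r.verified for r in records)
    out["overall_dedup"] = {
        "verified": dedup_verified, "total": dedup_total,
        "percent": round_half_up(100.0 * dedup_verified / dedup_total)
        if dedup_total else 0}
    return out


def size_histograms(calls_by_platform: dict[str, list[SVCall]],
                    config: Optional[PipelineConfig] = None,
                    n_bins: int = 30) -> dict[str, dict]:
    """Log-spaced size distributions of deletions and duplications.

    For each platform the counts above its own detection limit are
    reported, plus (for OGM) the count of calls falling below the other
    platforms' limits -- the events only OGM can see.
    """
    config = config or PipelineConfig()
    all_sizes = [c.size_bp for calls in calls_by_platform.values()
                 for c in calls if c.size_bp > 0]
    if all_sizes:
        lo = max(1.0, min(all_sizes) * 0.9)
        hi = max(all_sizes) * 1.1
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.geomspace(100, 1e7, n_bins + 1)
    out: dict[str, dict] = {}
    for platform, calls in calls_by_platform.items():
        limit = config.detection_limits.get(platform, 0)
        result = {}
        for sv_type in ("deletion", "duplication"):
            sizes = np.array([c.size_bp for c in calls if c.sv_type == sv_type],
                             dtype=float)
            counts, _ = np.histogram(sizes, bins=edges) if sizes.size else \
                (np.zeros(len(edges) - 1, dtype=int), edges)
            below = {
                other: int((sizes < other_limit).sum())
                for other, other_limit in config.detection_limits.items()
                if other != platform
            }
            result[sv_type] = {
                "bin_edges_bp": edges.tolist(),
                "counts": counts.tolist(),
                "n_total": int(sizes.size),
                "n_above_own_limit": int((sizes >= limit).sum()),
                "n_below_other_limits": below,
            }
        out[platform] = result
    return out
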