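"""Cohort summaries: SV burden, subtype comparison, provenance, exports.

Burden counts exclude hallmark events (the subtype-defining translocation
and whole-chromosome gains), which are flagged upstream rather than
re-detected here.  The subtype comparison uses the Mann-Whitney U test
with midranks for ties; an exact enumeration over rank assignments is
used for small samples and a tie-corrected normal approximation with
continuity correction otherwise.
"""
from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .recurrence import MAR
from .types import LeukoSVError, PipelineConfig, SVCall, SampleMeta

BURDEN_SV_TYPES = ["deletion", "duplication", "insertion", "inversion",
                   "intra_translocation", "inter_translocation"]

#: switch to exact enumeration when the pooled sample is at most this big
EXACT_ENUMERATION_MAX_N = 12


# -- burden ------------------------------------------------------------------

def burden_per_case(somatic_calls: dict[str, list[SVCall]],
                    samples: list[SampleMeta],
                    config: Optional[PipelineConfig] = None,
                    contigs: Optional[dict[str, int]] = None) -> pd.DataFrame:
    """Per-case SV counts by type and size class, hallmark events excluded.

    Rows are patients (zero rows for empty callsets); columns are per-type
    counts, ``total``, and focal/large splits, plus the subtype label.
    """
    from .sv_merge import classify_size
    config = config or PipelineConfig()
    subtype_by_patient = {s.patient_id: s.subtype for s in samples}
    rows = []
    for patient_id in sorted(somatic_calls):
        counts = {t: 0 for t in BURDEN_SV_TYPES}
        focal = large = 0
        for c in somatic_calls[patient_id]:
            if c.hallmark or c.filter_status != "pass":
                continue
            if c.sv_type not in counts:
                continue  # aneuploidies and CNN-LOH are not secondary-SV burden
            size_class = (classify_size(c, config, contigs)
                          if contigs is not None else
                          ("focal" if c.sv_type == "inter_translocation"
                           or c.size_bp < config.focal_large_boundary_bp
                           else "large"))
            if size_class == "whole_chromosome":
                continue
            counts[c.sv_type] += 1
            if size_class == "focal":
                focal += 1
            else:
                large += 1
        rows.append({"patient_id": patient_id,
                     "subtype": subtype_by_patient.get(patient_id, "NA"),
                     **counts, "total": sum(counts.values()),
                     "focal": focal, "large": large})
    return pd.DataFrame(rows).set_index("patient_id")


# -- Mann-Whitney U ----------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x, computed from midranks of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = ranks[:len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(x: Iterable[float], y: Iterable[float]) -> dict:
    """Two-sided Mann-Whitney U test.

    Midranks handle ties.  For pooled sizes <= 12 the two-sided p-value
    is an exact enumeration over all C(n+m, n) group assignments of the
    observed pooled values (so ties are handled exactly too); otherwise a
    tie-corrected normal approximation with continuity correction is used.
    Degenerate inputs (all values identical) give p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise LeukoSVError("both groups must be non-empty")
    u_x = _u_statistic(x, y)
    mean_u = n * m / 2.0
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return {"U": u_x, "z": 0.0, "p_two_sided": 1.0, "method": "degenerate"}
    if n + m <= EXACT_ENUMERATION_MAX_N:
        dev = abs(u_x - mean_u)
        total = hits = 0
        idx = range(n + m)
        for combo in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mean_u) >= dev - 1e-9:
                hits += 1
        p = hits / total
        z = (u_x - mean_u) / math.sqrt(n * m * (n + m + 1) / 12.0)
        return {"U": u_x, "z": z, "p_two_sided": min(1.0, p), "method": "exact"}
    # tie-corrected normal approximation
    _, counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = ((counts ** 3 - counts).sum()) / (nm * (nm - 1.0))
    var_u = n * m / 12.0 * (nm + 1.0 - tie_term)
    if var_u <= 0:
        return {"U": u_x, "z": 0.0, "p_two_sided": 1.0, "method": "degenerate"}
    cc = 0.5 if u_x != mean_u else 0.0
    z = (u_x - mean_u - math.copysign(cc, u_x - mean_u)) / math.sqrt(var_u)
    p = 2.0 * norm.sf(abs(z))
    return {"U": u_x, "z": z, "p_two_sided": min(1.0, p), "method": "normal"}


# -- provenance / fold change ------------------------------------------------

def provenance_summary(calls: list[SVCall]) -> dict:
    """Fractions of calls per caller combination; fractions sum to 1."""
    if not calls:
        raise LeukoSVError("no calls to summarize")
    counts: dict[str, int] = {}
    for c in calls:
        key = "+".join(sorted(c.callers))
        counts[key] = counts.get(key, 0) + 1
    total = len(calls)
    return {
        "total": total,
        "counts": dict(sorted(counts.items())),
        "fractions": {k: v / total for k, v in sorted(counts.items())},
        "percents": {k: round(100.0 * v / total, 1)
                     for k, v in sorted(counts.items())},
    }


def fold_change(a: float, b: float) -> float:
    """a/b rounded to one decimal, half-up (reporting style '3.4-fold')."""
    if b == 0:
        raise LeukoSVError("fold change with zero denominator")
    return math.floor(a / b * 10 + 0.5) / 10.0


# -- exports -----------------------------------------------------------------

def build_oncoprint(mars: list[MAR],
                    double_hits: list,
                    patients: list[str],
                    snv_genes_by_patient: Optional[dict[str, set]] = None
                    ) -> pd.DataFrame:
    """Cases x MARs alteration matrix with cell codes (DEL, DUP, INS, SNV, ...).

    A cell combines the patient's SV type in the MAR with ``+SNV`` when a
    target gene of that MAR also carries a small variant in that patient.
    """
    snv_genes_by_patient = snv_genes_by_patient or {}
    code = {"deletion": "DEL", "duplication": "DUP", "insertion": "INS",
            "inversion": "INV", "intra_translocation": "TRA",
            "inter_translocation": "TRA"}
    columns = []
    data = {}
    for i, mar in enumerate(mars):
        label = f"{mar.region.chrom}:{mar.region.start + 1}-{mar.region.end}"
        if mar.target_genes:
            label += f" ({'/'.join(mar.target_genes)})"
        columns.append(label)
        col = []
        for p in patients:
            cell = ""
            if p in mar.supporting_cases:
                cell = code.get(mar.supporting_cases[p], "SV")
            snv_genes = snv_genes_by_patient.get(p, set())
            if set(mar.target_genes) & snv_genes:
                cell = f"{cell}+SNV" if cell else "SNV"
            col.append(cell)
        data[label] = col
    return pd.DataFrame(data, index=pd.Index(patients, name="patient_id"),
                        columns=columns)


def circos_links(calls: list[SVCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(segments, links) tables for circos-style plotting.

    Segments: interval calls with type and size class.  Links:
    translocations and inversions as chrom/pos pairs.
    """
    seg_rows, link_rows = [], []
    for c in calls:
        if c.sv_type in ("deletion", "duplication", "insertion"):
            seg_rows.append({"chrom": c.span.chrom, "start": c.span.start,
                             "end": c.span.end, "sv_type": c.sv_type,
                             "sample_id": c.sample_id})
        elif c.breakends is not None:
            b1, b2 = c.breakends
            link_rows.append({"chrom1": b1.chrom, "pos1": b1.pos,
                              "chrom2": b2.chrom, "pos2": b2.pos,
                              "sv_type": c.sv_type, "sample_id": c.sample_id})
    return pd.DataFrame(seg_rows), pd.DataFrame(link_rows)
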