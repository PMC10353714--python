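"""Truth-recovery metrics for simulated cohorts.

Compares the pipeline's somatic output against the simulator's ground
truth: somatic recall and precision, germline leakage into the somatic
set, and recovery of implanted recurrent genes by MAR detection.
"""
from __future__ import annotations

from typing import Optional

from .cohort_sim import Cohort
from .pipeline import PatientResult
from .recurrence import MAR
from .sv_merge import MatchParams, greedy_match
from .types import GeneModel


def somatic_recovery(cohort: Cohort, results: dict[str, PatientResult],
                     params: Optional[MatchParams] = None) -> dict:
    """Per-cohort recall/precision of somatic calls and germline leakage.

    Recall: fraction of somatic truth events matched by a pass-filter
    somatic call.  Precision: fraction of somatic calls matching a somatic
    truth event.  Leakage: fraction of somatic calls matching a germline
    truth event instead.
    """
    params = params or MatchParams()
    tp = n_truth = n_calls = leaked = 0
    for pid, res in results.items():
        truth_som = cohort.truth.somatic.get(pid, [])
        truth_germ = cohort.truth.germline.get(pid, [])
        pairs = greedy_match(truth_som, res.somatic, params)
        tp += len(pairs)
        n_truth += len(truth_som)
        n_calls += len(res.somatic)
        matched_calls = {j for _, j in pairs}
        unmatched = [c for j, c in enumerate(res.somatic)
                     if j not in matched_calls]
        leak_pairs = greedy_match(truth_germ, unmatched, params)
        leaked += len(leak_pairs)
    return {
        "recall": tp / n_truth if n_truth else float("nan"),
        "precision": tp / n_calls if n_calls else float("nan"),
        "germline_leakage": leaked / n_calls if n_calls else 0.0,
        "n_truth_somatic": n_truth,
        "n_somatic_calls": n_calls,
    }


def implanted_gene_recovery(mars: list[MAR], genes: list[GeneModel],
                            symbols: list[str]) -> dict[str, bool]:
    """Which implanted recurrent genes are overlapped by at least one MAR."""
    by_symbol = {g.symbol: g for g in genes}
    out = {}
    for sym in symbols:
        g = by_symbol[sym]
        out[sym] = any(m.region.overlaps(g.span) or m.region.overlaps(g.promoter)
                       for m in mars)
    return out
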