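"""End-to-end per-patient orchestration: merge -> subtract -> filter -> class.

Thin glue over :mod:`sv_merge`; the CLI and the cohort-level summaries
build on these helpers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats
from .io_formats import BlacklistRegion
from .sv_merge import (
    MatchParams, apply_filters, classify_size, filter_array_segments,
    merge_pipelines, subtract_germline,
)
from .types import (
    CNSegment, LeukoSVError, PipelineConfig, SVCall, SampleMeta,
)


@dataclass
class PatientResult:
    patient_id: str
    merged_tumor: list[SVCall]
    somatic: list[SVCall]          # pass-filter somatic calls
    germline_removed: list[SVCall]
    filtered: list[SVCall]
    size_class: dict[str, str] = field(default_factory=dict)  # call_id -> class

    def focal_somatic(self) -> list[SVCall]:
        return [c for c in self.somatic
                if self.size_class.get(c.call_id) == "focal"]


def process_patient(patient_id: str,
                    tumor_calls: dict, normal_calls: dict,
                    params: MatchParams, config: PipelineConfig,
                    blacklist: list[BlacklistRegion],
                    contigs: dict[str, int]) -> PatientResult:
    """Run merge, germline subtraction, filtering and size classification.

    ``tumor_calls``/``normal_calls`` map caller labels (DN, RVP, CN, ARRAY)
    to call lists; CN/ARRAY entries are :class:`CNSegment` lists.
    """
    merged_t = merge_pipelines(tumor_calls.get("DN", []),
                               tumor_calls.get("RVP", []),
                               tumor_calls.get("CN", []), params, config)
    merged_n = merge_pipelines(normal_calls.get("DN", []),
                               normal_calls.get("RVP", []),
                               normal_calls.get("CN", []), params, config)
    # CNN-LOH is visible only to SNP-arrays; incorporate the passing
    # tumor-array segments after subtracting any matched-normal counterpart
    from .sv_merge import cn_segment_to_call
    def _loh_calls(segs, tag):
        kept_segs, _ = filter_array_segments(
            [s for s in segs if s.state == "cnn_loh"], config)
        return [cn_segment_to_call(s, f"loh_{tag}_{i}")
                for i, s in enumerate(kept_segs)]
    loh_t = _loh_calls(tumor_calls.get("ARRAY", []), patient_id)
    loh_n = _loh_calls(normal_calls.get("ARRAY", []), patient_id + "N")
    loh_somatic, loh_removed = subtract_germline(loh_t, loh_n, params,
                                                 allow_unmatched=True)
    somatic, removed = subtract_germline(merged_t, merged_n, params,
                                         allow_unmatched=not normal_calls)
    kept, dropped = apply_filters(somatic + loh_somatic, config, blacklist)
    removed = removed + loh_removed
    size_class = {c.call_id: classify_size(c, config, contigs) for c in kept}
    return PatientResult(patient_id=patient_id, merged_tumor=merged_t,
                         somatic=kept, germline_removed=removed,
                         filtered=dropped, size_class=size_class)


def process_cohort(calls_by_sample: dict[str, dict],
                   samples: list[SampleMeta],
                   params: Optional[MatchParams] = None,
                   config: Optional[PipelineConfig] = None,
                   blacklist: Optional[list[BlacklistRegion]] = None,
                   contigs: Optional[dict[str, int]] = None
                   ) -> dict[str, PatientResult]:
    """Run the somatic pipeline for every tumor/normal pair."""
    params = params or MatchParams()
    config = config or PipelineConfig()
    contigs = contigs or io_formats.load_contigs()
    if blacklist is None:
        blacklist = io_formats.build_blacklist(
            io_formats.read_blacklist(), io_formats.CytobandMap.from_file())
    by_patient: dict[str, dict[str, str]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, {})[s.role] = s.sample_id
    results = {}
    for pid in sorted(by_patient):
        roles = by_patient[pid]
        if "tumor" not in roles:
            continue
        tumor = calls_by_sample.get(roles["tumor"], {})
        normal = calls_by_sample.get(roles.get("normal", ""), {})
        results[pid] = process_patient(pid, tumor, normal, params, config,
                                       blacklist, contigs)
    return results


def read_samples_table(path: str) -> tuple[list[SampleMeta], dict[str, str]]:
    """Read samples.tsv; returns (samples, patient -> array platform)."""
    samples, array_platform = [], {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    idx = {h: i for i, h in enumerate(header)}
    for line in lines[1:]:
        if not line.strip():
            continue
        p = line.split("\t")
        samples.append(SampleMeta(p[idx["sample_id"]], p[idx["patient_id"]],
                                  p[idx["subtype"]], p[idx["role"]],
                                  float(p[idx["blast_fraction"]])))
        if "array_platform" in idx:
            array_platform[p[idx["patient_id"]]] = p[idx["array_platform"]]
    return samples, array_platform


def load_cohort_dir(path: str, contigs: Optional[dict[str, int]] = None
                    ) -> tuple[list[SampleMeta], dict[str, dict]]:
    """Load a cohort directory written by :func:`cohort_sim.write_cohort`."""
    contigs = contigs or io_formats.load_contigs()
    root = Path(path)
    samples, array_platform = read_samples_table(str(root / "samples.tsv"))
    calls: dict[str, dict] = {}
    for s in samples:
        platform = array_platform.get(s.patient_id, "CytoSNP12")
        entry = {}
        for label, suffix in (("DN", "dn.tsv"), ("RVP", "rvp.tsv")):
            f = root / f"{s.sample_id}.{suffix}"
            entry[label] = (io_formats.read_sv_table(str(f), label, contigs)
                            if f.exists() else [])
        for label, suffix, plat in (("CN", "cn.tsv", "OGM_CN"),
                                    ("ARRAY", "array.tsv", platform)):
            f = root / f"{s.sample_id}.{suffix}"
            entry[label] = (io_formats.read_cn_segments(str(f), plat)
                            if f.exists() else [])
        calls[s.sample_id] = entry
    return samples, calls
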