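"""Synthetic tumor/normal cohort generator with per-platform caller emulation.

The generator emulates a 30+30 pediatric BCP-ALL cohort of the
ETV6::RUNX1-translocated and classical hyperdiploid (HD) subtypes:

* every ETV6::RUNX1 tumor carries the t(12;21) hallmark translocation
  (a 3-way variant with probability 9/30); HD tumors draw per-chromosome
  whole-chromosome gains (tetrasomy 21 in 29/30, trisomy 14 in 24/30,
  tetrasomy 14 in 6/30, plus the classic gained set at configured rates);
* the somatic focal-deletion burden is 1 + negative binomial, fitted so
  the median matches the reported 13.5 (ETV6::RUNX1) and 4 (HD) with
  ranges of roughly 1-46 and 1-14; a configurable recurrent-gene panel
  implants gene-directed deletions at per-gene probabilities;
* SNV/indel counts are overdispersed with subtype-specific gene weights
  (NRAS, KRAS, CREBBP, FLT3, PTPN11, UBA2, ...);
* germline SVs are shared between tumor and matched normal.

Caller emulation reproduces the platform differences that drive the
analysis: detection size limits (OGM 500 bp, CytoScanHD ~1 kb,
CytoSNP-12 ~50 kb), breakpoint jitter, VAF-dependent sensitivity, a hard
VAF floor for the de novo assembly pipeline (the rare variant pipeline
retains subclonal events), centromere blindness for OGM, and an
IKZF1-like probe gap for arrays.  Per-event random draws are keyed by
(event id, platform) so tumor and matched normal emit or drop a germline
event jointly, keeping somatic subtraction well-posed.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io_formats
from .io_formats import BlacklistRegion, CytobandMap
from .types import (
    Breakend, CNSegment, GeneModel, GenomicInterval, LeukoSVError, SVCall,
    SampleMeta, SmallVariant,
)

# ---------------------------------------------------------------------------
# configuration

@dataclass
class GenePanelEntry:
    symbol: str
    prob: float                      # per-tumor probability of a focal hit
    subtypes: tuple[str, ...] = ("ETV6_RUNX1", "HD")
    sv_type: str = "deletion"


#: recurrent-gene panel with per-tumor hit probabilities (cohort frequencies
#: of the corresponding minimal altered regions)
DEFAULT_GENE_PANEL = [
    GenePanelEntry("ETV6", 0.27),
    GenePanelEntry("CDKN2A", 0.23),
    GenePanelEntry("PAX5", 0.22),
    GenePanelEntry("NSD2", 0.17),
    GenePanelEntry("RAG2", 0.17),
    GenePanelEntry("MKKS", 0.17),
    GenePanelEntry("CD200", 0.15),
    GenePanelEntry("ZCCHC7", 0.13),
    GenePanelEntry("STAG2", 0.12),
    GenePanelEntry("FOCAD", 0.08),
    GenePanelEntry("IKBKB", 0.07),
    GenePanelEntry("MANBA", 0.05),
    GenePanelEntry("MSRA", 0.05),
    GenePanelEntry("SFMBT2", 0.05),
    GenePanelEntry("BTG1", 0.33, ("ETV6_RUNX1",)),
    GenePanelEntry("ATF7IP", 0.30, ("ETV6_RUNX1",)),
    GenePanelEntry("UHRF1", 0.17, ("ETV6_RUNX1",)),
    GenePanelEntry("UBA2", 0.17, ("ETV6_RUNX1",)),
    GenePanelEntry("GPRC5A", 0.17, ("ETV6_RUNX1",)),
    GenePanelEntry("NCOA6", 0.13, ("ETV6_RUNX1",)),
    GenePanelEntry("MED13L", 0.10, ("ETV6_RUNX1",)),
    GenePanelEntry("MIB1", 0.10, ("ETV6_RUNX1",)),
]


@dataclass
class SubtypeProfile:
    """Statistical description of one leukemia subtype's somatic landscape."""

    subtype: str
    # focal-deletion burden: 1 + NegBin(r, mu); fitted to the subtype medians
    del_burden_r: float
    del_burden_mu: float
    # Poisson means for the other focal SV types
    dup_mean: float
    ins_mean: float
    inv_mean: float
    intra_tra_mean: float
    inter_tra_mean: float
    large_sv_mean: float            # deletions/duplications >= 5 Mb
    # SNVs/indels: min + NegBin(r, mu)
    snv_r: float
    snv_mu: float
    snv_min: int
    snv_gene_weights: dict = field(default_factory=dict)
    # hallmark structure
    hallmark_fusion: Optional[tuple[str, str]] = None  # (5' gene, 3' gene)
    p_three_way: float = 0.0
    # chrom -> (p_trisomy, p_tetrasomy); drawn independently per chromosome
    chrom_gain_probs: dict = field(default_factory=dict)
    # secondary aneuploidies (ETV6::RUNX1): chrom -> (p_gain, p_loss)
    secondary_aneuploidy_probs: dict = field(default_factory=dict)
    whole_chrom_cnnloh_prob: float = 0.0
    arm_cnnloh_prob: float = 0.1    # 9p/9q-style arm-level CNN-LOH
    subclonal_fraction: float = 0.10
    gene_panel: list = field(default_factory=lambda: list(DEFAULT_GENE_PANEL))

    def __post_init__(self):
        for e in self.gene_panel:
            if not (0.0 <= e.prob <= 1.0):
                raise LeukoSVError(f"panel probability out of range: {e}")


ETV6_RUNX1_PROFILE = SubtypeProfile(
    subtype="ETV6_RUNX1",
    del_burden_r=2.8, del_burden_mu=13.5,
    dup_mean=0.5, ins_mean=2.3, inv_mean=0.4,
    intra_tra_mean=0.8, inter_tra_mean=1.3, large_sv_mean=1.5,
    snv_r=1.2, snv_mu=17.0, snv_min=2,
    snv_gene_weights={"NRAS": 0.07, "NSD2": 0.10, "ETV6": 0.09, "UBA2": 0.11,
                      "CCDC168": 0.11, "STAG2": 0.05, "BTG1": 0.05,
                      "MANBA": 0.04, "TBL1XR1": 0.05},
    hallmark_fusion=("ETV6", "RUNX1"),
    p_three_way=9 / 30,
    secondary_aneuploidy_probs={"chr21": (7 / 30, 0.0), "chr16": (1 / 30, 0.0),
                                "chrX": (0.0, 1 / 30)},
    whole_chrom_cnnloh_prob=1 / 30,
)

HD_PROFILE = SubtypeProfile(
    subtype="HD",
    del_burden_r=1.8, del_burden_mu=3.6,
    dup_mean=0.4, ins_mean=0.7, inv_mean=0.15,
    intra_tra_mean=0.3, inter_tra_mean=0.25, large_sv_mean=0.9,
    snv_r=4.0, snv_mu=9.0, snv_min=5,
    snv_gene_weights={"NRAS": 0.40, "KRAS": 0.27, "CREBBP": 0.20, "FLT3": 0.17,
                      "PTPN11": 0.10, "NSD2": 0.07, "ETV6": 0.05},
    # chr21/chr14 frequencies are reported; the rest of the classic HD
    # gained set uses configured defaults
    chrom_gain_probs={
        "chr21": (1 / 30, 29 / 30), "chr14": (24 / 30, 6 / 30),
        "chr4": (0.75, 0.05), "chr6": (0.8, 0.05), "chr10": (0.55, 0.0),
        "chr17": (0.6, 0.05), "chr18": (0.5, 0.05), "chrX": (0.6, 0.0),
        "chr5": (0.25, 0.0), "chr8": (0.3, 0.0), "chr20": (0.3, 0.0),
    },
    whole_chrom_cnnloh_prob=4 / 30,
)


@dataclass
class CallerModel:
    """Detection characteristics of one calling pipeline/platform."""

    platform: str                   # DN | RVP | OGM_CN | CytoSNP12 | CytoScanHD
    min_size_bp: int
    breakpoint_sd_bp: float
    sens_mid_vaf: float             # logistic midpoint of VAF sensitivity
    sens_scale: float
    vaf_floor: float = 0.0          # hard floor (DN de novo assembly)
    blind_regions: list = field(default_factory=list)
    false_call_rate: float = 0.0    # expected false calls per genome
    probe_spacing_bp: int = 0       # arrays: for n_probes emulation
    #: SV types the platform can emit
    sv_types: frozenset = frozenset({
        "deletion", "duplication", "insertion", "inversion",
        "intra_translocation", "inter_translocation"})

    def sensitivity(self, vaf: Optional[float], size_bp: int,
                    is_translocation: bool = False) -> float:
        """Detection probability; non-decreasing in VAF and in size."""
        if not is_translocation and size_bp < self.min_size_bp:
            return 0.0
        if vaf is None:
            vaf = 0.5
        if vaf < self.vaf_floor:
            return 0.0
        return 1.0 / (1.0 + np.exp(-(vaf - self.sens_mid_vaf) / self.sens_scale))


def default_caller_models(cytobands: Optional[CytobandMap] = None
                          ) -> dict[str, CallerModel]:
    """DN/RVP/CN/array models with documented default noise levels."""
    centromeres = cytobands.centromere_intervals() if cytobands else []
    ogm_types = frozenset({"deletion", "duplication", "insertion", "inversion",
                           "intra_translocation", "inter_translocation"})
    cn_types = frozenset({"deletion", "duplication",
                          "aneuploidy_gain", "aneuploidy_loss"})
    array_types = cn_types | {"cnn_loh"}
    # an IKZF1-like repetitive region where arrays lack probe coverage
    ikzf1_gap = [GenomicInterval("chr7", 50_290_000, 50_410_000)]
    return {
        "DN": CallerModel("DN", 500, 3_000.0, 0.05, 0.015, vaf_floor=0.15,
                          blind_regions=list(centromeres),
                          false_call_rate=0.25, sv_types=ogm_types),
        "RVP": CallerModel("RVP", 500, 3_000.0, 0.03, 0.010,
                           blind_regions=list(centromeres),
                           false_call_rate=0.35, sv_types=ogm_types),
        "CN": CallerModel("OGM_CN", 5_000_000, 200_000.0, 0.10, 0.03,
                          blind_regions=list(centromeres), sv_types=cn_types),
        "CytoSNP12": CallerModel("CytoSNP12", 50_000, 10_000.0, 0.12, 0.02,
                                 blind_regions=list(ikzf1_gap),
                                 probe_spacing_bp=10_000, sv_types=array_types),
        "CytoScanHD": CallerModel("CytoScanHD", 1_000, 1_000.0, 0.12, 0.02,
                                  blind_regions=list(ikzf1_gap),
                                  probe_spacing_bp=1_100, sv_types=array_types),
    }


@dataclass
class SimConfig:
    n_per_subtype: int = 30
    seed: int = 0
    germline_sv_mean: float = 25.0
    fraction_cytoscan: float = 18 / 60   # CytoScanHD share of array platforms
    profiles: dict = None
    caller_models: dict = None

    def __post_init__(self):
        if self.n_per_subtype < 1:
            raise LeukoSVError("n_per_subtype must be >= 1")


@dataclass
class SimTruth:
    """Ground truth per patient (sample_id on truth calls = patient id)."""

    germline: dict[str, list[SVCall]] = field(default_factory=dict)
    somatic: dict[str, list[SVCall]] = field(default_factory=dict)
    snvs: dict[str, list[SmallVariant]] = field(default_factory=dict)
    copy_states: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class Cohort:
    samples: list[SampleMeta]
    truth: SimTruth
    #: sample_id -> {"DN": [SVCall], "RVP": [SVCall], "CN": [CNSegment],
    #:               "ARRAY": [CNSegment]}
    calls: dict[str, dict]
    karyotype: dict[str, list[str]]          # tumor sample -> event strings
    fish: dict[str, list[str]]
    snv_variants: list[SmallVariant]
    array_platform: dict[str, str]           # patient -> CytoSNP12|CytoScanHD
    #: (sample_id, platform) -> set of emitted truth event ids (the oracle
    #: log for recovery tests)
    emissions: dict[tuple[str, str], set] = field(default_factory=dict)

    def tumor_samples(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.role == "tumor"]


# ---------------------------------------------------------------------------
# helpers

def _event_rng(seed: int, event_id: str, platform: str) -> np.random.Generator:
    key = zlib.crc32(f"{seed}|{event_id}|{platform}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(key)


def _stream_rng(seed: int, label: str) -> np.random.Generator:
    key = zlib.crc32(f"{seed}|{label}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(key)


class _Placer:
    """Uniform genome placement avoiding blacklist regions."""

    def __init__(self, contigs: dict[str, int], blacklist: list[BlacklistRegion]):
        self.contigs = contigs
        self.chroms = list(contigs)
        lengths = np.array([contigs[c] for c in self.chroms], dtype=float)
        self.weights = lengths / lengths.sum()
        self.blacklist = blacklist

    def ok(self, iv: GenomicInterval) -> bool:
        return not any(iv.overlaps(b.region) for b in self.blacklist)

    def place(self, rng: np.random.Generator, size: int,
              chrom: Optional[str] = None) -> GenomicInterval:
        for _ in range(200):
            c = chrom or rng.choice(self.chroms, p=self.weights)
            limit = self.contigs[c] - size - 1
            if limit <= 1:
                continue
            start = int(rng.integers(1, limit))
            iv = GenomicInterval(c, start, start + size)
            if self.ok(iv):
                return iv
        raise LeukoSVError(f"could not place event of size {size}")

    def position(self, rng: np.random.Generator,
                 chrom: Optional[str] = None) -> tuple[str, int]:
        iv = self.place(rng, 1, chrom)
        return iv.chrom, iv.start


def _log_uniform(rng, lo: float, hi: float) -> int:
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


# ---------------------------------------------------------------------------
# truth generation

def _gene_hit_deletion(rng, gene: GeneModel) -> GenomicInterval:
    """A deletion overlapping the gene, always covering its middle third
    so that any three hits share a common intersection."""
    g = gene.span
    third = max(200, g.length // 3)
    start = int(rng.integers(max(1, g.start - 15_000), g.start + third))
    end = int(rng.integers(g.end - third, g.end + 15_000))
    return GenomicInterval(g.chrom, start, max(end, start + 200))


def _draw_vaf(rng, blast: float, subclonal_fraction: float) -> float:
    if rng.uniform() < subclonal_fraction:
        return float(rng.uniform(0.05, 0.25))
    return blast / 2.0


def _simulate_patient(pid: str, profile: SubtypeProfile, cfg: SimConfig,
                      rng: np.random.Generator, placer: _Placer,
                      genes_by_symbol: dict[str, GeneModel],
                      contigs: dict[str, int]) -> dict:
    blast = float(rng.uniform(0.75, 0.95))
    germline: list[SVCall] = []
    somatic: list[SVCall] = []
    copy_states = {c: 2 for c in contigs}

    def sv(call_id, sv_type, span=None, breakends=None, size=None, vaf=None,
           hallmark=False):
        return SVCall(call_id=call_id, sample_id=pid, sv_type=sv_type,
                      span=span, breakends=breakends,
                      size_bp=size if size is not None else
                      (span.length if span is not None else 0),
                      vaf=vaf, callers=frozenset({"DN"}), hallmark=hallmark)

    # germline SVs (shared with the matched normal)
    n_germ = int(rng.poisson(cfg.germline_sv_mean))
    for i in range(n_germ):
        kind = rng.choice(["deletion", "duplication", "insertion"],
                          p=[0.6, 0.2, 0.2])
        size = _log_uniform(rng, 1_000, 500_000)
        if kind == "insertion":
            c, p = placer.position(rng)
            span = GenomicInterval(c, p, p + 1)
            germline.append(sv(f"{pid}_g{i}", kind, span=span, size=size, vaf=0.5))
        else:
            span = placer.place(rng, size)
            germline.append(sv(f"{pid}_g{i}", kind, span=span, vaf=0.5))

    # hallmark translocation (ETV6::RUNX1-like)
    if profile.hallmark_fusion is not None:
        g5 = genes_by_symbol[profile.hallmark_fusion[0]]
        g3 = genes_by_symbol[profile.hallmark_fusion[1]]
        pos5 = int(rng.integers(g5.span.start + 100, g5.span.end - 100))
        pos3 = int(rng.integers(g3.span.start + 100, g3.span.end - 100))
        o5 = "left" if g5.strand == "+" else "right"
        o3 = "left" if g3.strand == "-" else "right"
        somatic.append(sv(f"{pid}_hallmark", "inter_translocation",
                          breakends=(Breakend(g5.span.chrom, pos5, o5),
                                     Breakend(g3.span.chrom, pos3, o3)),
                          vaf=blast / 2.0, hallmark=True))
        if rng.uniform() < profile.p_three_way:
            c, p = placer.position(rng)
            while c == g3.span.chrom:
                c, p = placer.position(rng)
            somatic.append(sv(f"{pid}_threeway", "inter_translocation",
                              breakends=(Breakend(g3.span.chrom,
                                                  min(pos3 + 50_000,
                                                      contigs[g3.span.chrom] - 2)),
                                         Breakend(c, p)),
                              vaf=blast / 2.0, hallmark=True))

    # whole-chromosome gains (HD hallmark pattern)
    for chrom, (p_tri, p_tet) in sorted(profile.chrom_gain_probs.items()):
        u = rng.uniform()
        copies = 2 if u < p_tet else (1 if u < p_tet + p_tri else 0)
        if copies:
            copy_states[chrom] = 2 + copies
            span = GenomicInterval(chrom, 0, contigs[chrom])
            somatic.append(sv(f"{pid}_gain_{chrom}", "aneuploidy_gain",
                              span=span, vaf=blast / 2.0, hallmark=True))

    # secondary aneuploidies (non-defining)
    for chrom, (p_gain, p_loss) in sorted(profile.secondary_aneuploidy_probs.items()):
        u = rng.uniform()
        span = GenomicInterval(chrom, 0, contigs[chrom])
        if u < p_gain:
            copy_states[chrom] = 3
            somatic.append(sv(f"{pid}_sgain_{chrom}", "aneuploidy_gain",
                              span=span, vaf=blast / 2.0))
        elif u < p_gain + p_loss:
            copy_states[chrom] = 1
            somatic.append(sv(f"{pid}_sloss_{chrom}", "aneuploidy_loss",
                              span=span, vaf=blast / 2.0))

    # CNN-LOH (array-only)
    if rng.uniform() < profile.whole_chrom_cnnloh_prob:
        chrom = str(rng.choice(["chr1", "chr2", "chr9", "chrX"]))
        span = GenomicInterval(chrom, 0, contigs[chrom])
        somatic.append(sv(f"{pid}_cnnloh", "cnn_loh", span=span, vaf=blast / 2.0))
    if rng.uniform() < profile.arm_cnnloh_prob:
        arm = GenomicInterval("chr9", 0, 43_000_000) if rng.uniform() < 0.5 \
            else GenomicInterval("chr9", 50_500_000, contigs["chr9"])
        somatic.append(sv(f"{pid}_cnnloh9", "cnn_loh", span=arm, vaf=blast / 2.0))

    # focal deletions: gene-directed panel hits + background
    n_del = 1 + int(rng.negative_binomial(
        profile.del_burden_r,
        profile.del_burden_r / (profile.del_burden_r + profile.del_burden_mu)))
    hit_genes = [e.symbol for e in profile.gene_panel
                 if profile.subtype in e.subtypes and rng.uniform() < e.prob
                 and e.symbol in genes_by_symbol]
    k = 0
    for symbol in hit_genes:
        span = _gene_hit_deletion(rng, genes_by_symbol[symbol])
        somatic.append(sv(f"{pid}_d{k}", "deletion", span=span,
                          vaf=_draw_vaf(rng, blast, profile.subclonal_fraction)))
        k += 1
    for _ in range(max(0, n_del - len(hit_genes))):
        span = placer.place(rng, _log_uniform(rng, 1_000, 2_500_000))
        somatic.append(sv(f"{pid}_d{k}", "deletion", span=span,
                          vaf=_draw_vaf(rng, blast, profile.subclonal_fraction)))
        k += 1

    # other focal SV types
    for sv_type, mean, size_range in (
            ("duplication", profile.dup_mean, (5_000, 2_000_000)),
            ("insertion", profile.ins_mean, (500, 10_000)),
            ("inversion", profile.inv_mean, (5_000, 2_000_000))):
        for i in range(int(rng.poisson(mean))):
            size = _log_uniform(rng, *size_range)
            vaf = _draw_vaf(rng, blast, profile.subclonal_fraction)
            if sv_type == "insertion":
                c, p = placer.position(rng)
                span = GenomicInterval(c, p, p + 1)
                somatic.append(sv(f"{pid}_{sv_type[:3]}{i}", sv_type, span=span,
                                  size=size, vaf=vaf))
            else:
                span = placer.place(rng, size)
                bnds = None
                if sv_type == "inversion":
                    bnds = (Breakend(span.chrom, span.start, "left"),
                            Breakend(span.chrom, span.end - 1, "right"))
                somatic.append(sv(f"{pid}_{sv_type[:3]}{i}", sv_type, span=span,
                                  breakends=bnds, vaf=vaf))
    for i in range(int(rng.poisson(profile.intra_tra_mean))):
        span = placer.place(rng, _log_uniform(rng, 500_000, 20_000_000))
        somatic.append(sv(f"{pid}_itra{i}", "intra_translocation", span=span,
                          breakends=(Breakend(span.chrom, span.start, "left"),
                                     Breakend(span.chrom, span.end - 1, "right")),
                          vaf=_draw_vaf(rng, blast, profile.subclonal_fraction)))
    for i in range(int(rng.poisson(profile.inter_tra_mean))):
        c1, p1 = placer.position(rng)
        c2, p2 = placer.position(rng)
        while c2 == c1:
            c2, p2 = placer.position(rng)
        somatic.append(sv(f"{pid}_tra{i}", "inter_translocation",
                          breakends=(Breakend(c1, p1, str(rng.choice(["left", "right"]))),
                                     Breakend(c2, p2, str(rng.choice(["left", "right"])))),
                          vaf=_draw_vaf(rng, blast, profile.subclonal_fraction)))
    # large (>= 5 Mb, sub-chromosomal) deletions/duplications
    for i in range(int(rng.poisson(profile.large_sv_mean))):
        sv_type = str(rng.choice(["deletion", "duplication"], p=[0.6, 0.4]))
        span = placer.place(rng, _log_uniform(rng, 5_000_000, 30_000_000))
        somatic.append(sv(f"{pid}_L{i}", sv_type, span=span,
                          vaf=_draw_vaf(rng, blast, profile.subclonal_fraction)))

    # SNVs/indels
    snvs: list[SmallVariant] = []
    effects = ["missense", "frameshift", "stopgain", "splice", "inframe_indel"]
    effect_p = [0.6, 0.2, 0.1, 0.05, 0.05]
    bases = np.array(list("ACGT"))
    def one_snv(chrom, pos, gene):
        ref, alt = rng.choice(bases, size=2, replace=False)
        return SmallVariant(sample_id=pid, chrom=chrom, pos=pos, ref=str(ref),
                            alt=str(alt), gene=gene,
                            effect=str(rng.choice(effects, p=effect_p)),
                            vaf=float(np.clip(rng.normal(blast / 2, 0.08),
                                              0.02, 1.0)))
    targeted = [g for g, w in sorted(profile.snv_gene_weights.items())
                if rng.uniform() < w and g in genes_by_symbol]
    for gsym in targeted:
        gene = genes_by_symbol[gsym]
        exon = gene.exons[int(rng.integers(len(gene.exons)))]
        pos = int(rng.integers(exon.start, exon.end))
        snvs.append(one_snv(gene.span.chrom, pos, gsym))
    n_snv = profile.snv_min + int(rng.negative_binomial(
        profile.snv_r, profile.snv_r / (profile.snv_r + profile.snv_mu)))
    for _ in range(max(0, n_snv - len(targeted))):
        c, p = placer.position(rng)
        snvs.append(one_snv(c, p, None))

    return {"germline": germline, "somatic": somatic, "snvs": snvs,
            "copy_states": copy_states, "blast": blast}


# ---------------------------------------------------------------------------
# caller emulation

def emulate_caller(events: list[SVCall], model: CallerModel, seed: int,
                   sample_id: str) -> tuple[list, set]:
    """Emit platform calls for a sample's truth events.

    Returns (calls, emitted_event_ids).  OGM pipelines (DN/RVP) return
    SVCall lists; the CN tool and arrays return CNSegment lists.
    Detection and jitter draws are keyed by (event id, platform) so the
    same germline event behaves identically in tumor and matched normal.
    """
    is_array = model.platform in ("CytoSNP12", "CytoScanHD")
    is_cn = model.platform == "OGM_CN"
    contigs = io_formats.load_contigs()
    out: list = []
    emitted: set = set()
    for ev in events:
        if ev.sv_type not in model.sv_types and not (
                is_array and ev.sv_type == "cnn_loh"):
            continue
        rng = _event_rng(seed, ev.call_id, model.platform)
        # blind regions: an event is invisible when a breakpoint falls inside
        # one, or its whole span is contained in one; merely spanning across
        # (e.g. a whole-chromosome gain over the centromere) is fine
        points = []
        if ev.span is not None and not ev.sv_type.startswith("aneuploidy"):
            points.extend(GenomicInterval(ev.span.chrom, p, p + 1)
                          for p in (ev.span.start, max(0, ev.span.end - 1)))
        if ev.breakends is not None:
            points.extend(GenomicInterval(b.chrom, b.pos, b.pos + 1)
                          for b in ev.breakends)
        blind = any(p.overlaps(r) for p in points for r in model.blind_regions)
        if not blind and ev.span is not None:
            blind = any(r.contains(ev.span) for r in model.blind_regions)
        if blind:
            continue
        is_tra = ev.sv_type == "inter_translocation"
        size = ev.size_bp if not is_tra else 0
        if ev.sv_type == "cnn_loh" and not is_array:
            continue
        threshold = model.sensitivity(ev.vaf, size, is_translocation=is_tra)
        if ev.sv_type in ("aneuploidy_gain", "aneuploidy_loss") and (is_array or is_cn):
            threshold = max(threshold, 0.999)  # whole-chromosome dosage is easy
        if rng.uniform() >= threshold:
            continue
        emitted.add(ev.call_id)
        jit = lambda: int(round(rng.normal(0.0, model.breakpoint_sd_bp)))
        def clip(chrom, pos):
            return max(0, min(pos, contigs.get(chrom, pos)))
        if is_array or is_cn:
            span = ev.span
            start = clip(span.chrom,
                         span.start + (0 if span.start == 0 else jit()))
            end = span.end + (0 if ev.sv_type.startswith("aneuploidy")
                              or span.end == contigs.get(span.chrom) else jit())
            end = max(start + 1, clip(span.chrom, end))
            state = {"deletion": "loss", "duplication": "gain",
                     "aneuploidy_gain": "gain", "aneuploidy_loss": "loss",
                     "cnn_loh": "cnn_loh"}[ev.sv_type]
            n_probes = 0
            if is_array:
                n_probes = max(1, (end - start) // max(1, model.probe_spacing_bp))
            out.append(CNSegment(sample_id=sample_id,
                                 span=GenomicInterval(span.chrom, start, end),
                                 state=state, n_probes=n_probes,
                                 platform=model.platform))
        else:
            new_span, new_bnds = ev.span, ev.breakends
            if ev.breakends is not None:
                new_bnds = tuple(
                    Breakend(b.chrom,
                             min(clip(b.chrom, b.pos + jit()),
                                 contigs.get(b.chrom, b.pos + 1) - 1),
                             b.orientation) for b in ev.breakends)
            if ev.span is not None:
                if ev.sv_type == "insertion":
                    s = min(clip(ev.span.chrom, ev.span.start + jit()),
                            contigs.get(ev.span.chrom, ev.span.start + 2) - 1)
                    new_span = GenomicInterval(ev.span.chrom, s, s + 1)
                else:
                    s = clip(ev.span.chrom, ev.span.start + jit())
                    e = clip(ev.span.chrom, max(s + 50, ev.span.end + jit()))
                    if e <= s:
                        s, e = max(0, e - 50), e if e > 0 else 50
                    new_span = GenomicInterval(ev.span.chrom, s, e)
            size_bp = ev.size_bp
            if ev.sv_type in ("deletion", "duplication") or (
                    ev.span is not None and ev.sv_type != "insertion"):
                size_bp = new_span.length if new_span is not None else 0
            out.append(SVCall(call_id=ev.call_id, sample_id=sample_id,
                              sv_type=ev.sv_type, span=new_span,
                              breakends=new_bnds, size_bp=size_bp, vaf=ev.vaf,
                              callers=frozenset({model.platform}),
                              hallmark=ev.hallmark))
    # false calls (independent per sample and platform)
    if model.false_call_rate > 0:
        rng = _stream_rng(seed, f"{sample_id}|{model.platform}|fp")
        contigs = io_formats.load_contigs()
        chroms = list(contigs)
        for i in range(int(rng.poisson(model.false_call_rate))):
            c = str(rng.choice(chroms))
            size = _log_uniform(rng, max(600, model.min_size_bp), 50_000)
            start = int(rng.integers(1, contigs[c] - size - 1))
            out.append(SVCall(call_id=f"{sample_id}_{model.platform}_fp{i}",
                              sample_id=sample_id, sv_type="deletion",
                              span=GenomicInterval(c, start, start + size),
                              size_bp=size, vaf=float(rng.uniform(0.3, 0.5)),
                              callers=frozenset({model.platform})))
    return out, emitted


# ---------------------------------------------------------------------------
# cohort assembly

def simulate_cohort(config: SimConfig,
                    genes: Optional[list[GeneModel]] = None,
                    contigs: Optional[dict[str, int]] = None,
                    cytobands: Optional[CytobandMap] = None,
                    blacklist: Optional[list[BlacklistRegion]] = None) -> Cohort:
    """Generate the full synthetic cohort; deterministic given the seed."""
    contigs = contigs or io_formats.load_contigs()
    genes = genes or io_formats.read_gene_models()
    cytobands = cytobands or CytobandMap.from_file()
    if blacklist is None:
        blacklist = io_formats.build_blacklist(io_formats.read_blacklist(),
                                               cytobands)
    genes_by_symbol = {g.symbol: g for g in genes}
    profiles = config.profiles or {"ETV6_RUNX1": ETV6_RUNX1_PROFILE,
                                   "HD": HD_PROFILE}
    models = config.caller_models or default_caller_models(cytobands)
    placer = _Placer(contigs, blacklist)

    samples: list[SampleMeta] = []
    truth = SimTruth()
    calls: dict[str, dict] = {}
    karyotype: dict[str, list[str]] = {}
    fish: dict[str, list[str]] = {}
    emissions: dict[tuple[str, str], set] = {}
    array_platform: dict[str, str] = {}
    all_snvs: list[SmallVariant] = []

    idx = 0
    for subtype in ("ETV6_RUNX1", "HD"):
        profile = profiles[subtype]
        for _ in range(config.n_per_subtype):
            idx += 1
            pid = f"ALL{idx}"
            rng = _stream_rng(config.seed, f"patient|{pid}")
            p = _simulate_patient(pid, profile, config, rng, placer,
                                  genes_by_symbol, contigs)
            truth.germline[pid] = p["germline"]
            truth.somatic[pid] = p["somatic"]
            truth.snvs[pid] = p["snvs"]
            truth.copy_states[pid] = p["copy_states"]
            all_snvs.extend(
                v.__class__(**{**v.__dict__, "sample_id": f"{pid}_T"})
                for v in p["snvs"])

            tumor = SampleMeta(f"{pid}_T", pid, subtype, "tumor", p["blast"])
            normal = SampleMeta(f"{pid}_N", pid, subtype, "normal", 0.0)
            samples.extend([tumor, normal])
            array = "CytoScanHD" if rng.uniform() < config.fraction_cytoscan \
                else "CytoSNP12"
            array_platform[pid] = array

            tumor_events = p["germline"] + p["somatic"]
            normal_events = p["germline"]
            for sample, events in ((tumor, tumor_events), (normal, normal_events)):
                per_sample: dict[str, list] = {}
                for label, model_key in (("DN", "DN"), ("RVP", "RVP"),
                                         ("CN", "CN"), ("ARRAY", array)):
                    model = models[model_key]
                    emitted_calls, ids = emulate_caller(
                        events, model, config.seed, sample.sample_id)
                    per_sample[label] = emitted_calls
                    emissions[(sample.sample_id, label)] = ids
                calls[sample.sample_id] = per_sample

            # conventional cytogenetics reports (tumor only, hallmark-level)
            kt = []
            if profile.hallmark_fusion is not None:
                g5 = genes_by_symbol[profile.hallmark_fusion[0]].span
                g3 = genes_by_symbol[profile.hallmark_fusion[1]].span
                b5 = cytobands.lookup(g5.chrom, (g5.start + g5.end) // 2)
                b3 = cytobands.lookup(g3.chrom, (g3.start + g3.end) // 2)
                kt.append(f"t({g5.chrom.removeprefix('chr')};"
                          f"{g3.chrom.removeprefix('chr')})"
                          f"({b5[len(g5.chrom) - 3:]};{b3[len(g3.chrom) - 3:]})")
                fish[tumor.sample_id] = [
                    f"fusion({profile.hallmark_fusion[0]};"
                    f"{profile.hallmark_fusion[1]})"]
            for chrom, cn in sorted(p["copy_states"].items()):
                if cn > 2:
                    kt.append(f"+{chrom.removeprefix('chr')}")
                elif cn < 2:
                    kt.append(f"-{chrom.removeprefix('chr')}")
            karyotype[tumor.sample_id] = kt

    return Cohort(samples=samples, truth=truth, calls=calls,
                  karyotype=karyotype, fish=fish, snv_variants=all_snvs,
                  array_platform=array_platform, emissions=emissions)


# ---------------------------------------------------------------------------
# file emission

def write_cohort(cohort: Cohort, out_dir: str,
                 contigs: Optional[dict[str, int]] = None) -> None:
    """Emit the cohort as the pipeline's input file formats plus truth.json."""
    contigs = contigs or io_formats.load_contigs()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "samples.tsv", "w") as f:
        f.write("sample_id\tpatient_id\tsubtype\trole\tblast_fraction\t"
                "array_platform\n")
        for s in cohort.samples:
            f.write(f"{s.sample_id}\t{s.patient_id}\t{s.subtype}\t{s.role}\t"
                    f"{s.blast_fraction:.3f}\t"
                    f"{cohort.array_platform[s.patient_id]}\n")
    for sample_id, per_caller in cohort.calls.items():
        io_formats.write_sv_table(per_caller["DN"], out / f"{sample_id}.dn.tsv")
        io_formats.write_sv_table(per_caller["RVP"], out / f"{sample_id}.rvp.tsv")
        io_formats.write_cn_segments(per_caller["CN"], out / f"{sample_id}.cn.tsv")
        io_formats.write_cn_segments(per_caller["ARRAY"],
                                     out / f"{sample_id}.array.tsv")
    with open(out / "karyotype.tsv", "w") as f:
        f.write("sample_id\tevent\n")
        for sample_id in sorted(cohort.karyotype):
            for ev in cohort.karyotype[sample_id]:
                f.write(f"{sample_id}\t{ev}\n")
        for sample_id in sorted(cohort.fish):
            for ev in cohort.fish[sample_id]:
                f.write(f"{sample_id}\t{ev}\n")
    io_formats.write_small_variants(
        cohort.snv_variants, [s for s in cohort.samples if s.role == "tumor"],
        str(out / "small_variants.vcf"), contigs)
    truth_json = {
        "copy_states": cohort.truth.copy_states,
        "array_platform": cohort.array_platform,
        "somatic_ids": {p: [c.call_id for c in v]
                        for p, v in cohort.truth.somatic.items()},
        "germline_ids": {p: [c.call_id for c in v]
                         for p, v in cohort.truth.germline.items()},
    }
    with open(out / "truth.json", "w") as f:
        json.dump(truth_json, f, indent=1, sort_keys=True)
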