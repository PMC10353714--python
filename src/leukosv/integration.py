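"""Per-patient joint SV + SNV interpretation.

* double hits: one gene altered by both a somatic SV and a somatic
  SNV/indel in the same patient (tumor-suppressor signature);
* the IKZF1plus poor-prognosis profile: IKZF1 deletion co-occurring with
  a CDKN2A/B, PAX5, or PAR1 deletion in the absence of an ERG deletion;
* the hyperdiploid aneuploidy risk rule: poor risk without trisomy 17
  and 18, or with trisomy 17/18 plus trisomy 5 or 20;
* translocation breakends paired across genes into putative fusions.
  OGM breakpoints are label-resolution approximations, so compatibility
  is judged at orientation level only, never at codon phase.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .types import (
    GeneModel, GenomicInterval, LeukoSVError, PipelineConfig, SVCall,
    SmallVariant,
)

#: pseudoautosomal region 1 (GRCh38 chrX), handled as a named region record
PAR1_REGION = GenomicInterval("chrX", 10_000, 2_781_479)


@dataclass
class PatientProfile:
    """Merged somatic evidence for one patient."""

    patient_id: str
    subtype: str
    sv_calls: list[SVCall] = field(default_factory=list)
    small_variants: list[SmallVariant] = field(default_factory=list)
    copy_states: dict[str, int] = field(default_factory=dict)  # chrom -> CN

    def __post_init__(self):
        if any(cn < 0 for cn in self.copy_states.values()):
            raise LeukoSVError(f"{self.patient_id}: negative copy state")

    def copy_state(self, chrom: str) -> int:
        if not chrom.startswith("chr"):
            chrom = "chr" + chrom
        return self.copy_states.get(chrom, 2)


def build_copy_states(calls: Iterable[SVCall],
                      contigs: dict[str, int],
                      config: Optional[PipelineConfig] = None) -> dict[str, int]:
    """Integer copy number per chromosome from whole-chromosome calls.

    Baseline 2 per chromosome; each whole-chromosome gain adds one copy
    (a tetrasomy is encoded as two stacked gain calls or a single call
    with ``size_bp`` covering the chromosome twice is not supported --
    the simulator emits one call per extra copy).
    """
    config = config or PipelineConfig()
    states = {c: 2 for c in contigs}
    for call in calls:
        if call.sv_type == "aneuploidy_gain":
            states[call.span.chrom] = states.get(call.span.chrom, 2) + 1
        elif call.sv_type == "aneuploidy_loss":
            states[call.span.chrom] = max(0, states.get(call.span.chrom, 2) - 1)
    return states


# -- double hits -------------------------------------------------------------

@dataclass
class DoubleHit:
    patient_id: str
    gene: str
    sv_evidence: list[tuple[str, str]]   # (call_id, sv_type)
    snv_evidence: list[tuple[str, str]]  # (variant locus, effect)

    def __post_init__(self):
        if not self.sv_evidence or not self.snv_evidence:
            raise LeukoSVError("double hit requires both SV and SNV evidence")


def sv_hits_gene(call: SVCall, gene: GeneModel) -> bool:
    """Span overlap with gene body or promoter, or a breakend inside either."""
    foot = gene.footprint()
    if call.span is not None and call.span.overlaps(foot):
        return True
    if call.breakends is not None:
        for b in call.breakends:
            if b.chrom == foot.chrom and foot.start <= b.pos < foot.end:
                return True
    return False


def snv_in_gene(variant: SmallVariant, gene: GeneModel) -> bool:
    if variant.gene is not None:
        return variant.gene == gene.symbol
    return (variant.chrom == gene.span.chrom
            and gene.span.start <= variant.pos < gene.span.end)


def detect_double_hits(profiles: list[PatientProfile],
                       genes: list[GeneModel]) -> list[DoubleHit]:
    """One DoubleHit per (patient, gene) with >= 1 somatic SV and >= 1 SNV."""
    hits = []
    for p in sorted(profiles, key=lambda p: p.patient_id):
        for g in sorted(genes, key=lambda g: g.symbol):
            sv_ev = [(c.call_id, c.sv_type) for c in p.sv_calls
                     if c.filter_status == "pass" and sv_hits_gene(c, g)]
            if not sv_ev:
                continue
            snv_ev = [(f"{v.chrom}:{v.pos + 1}{v.ref}>{v.alt}", v.effect)
                      for v in p.small_variants if snv_in_gene(v, g)]
            if snv_ev:
                hits.append(DoubleHit(p.patient_id, g.symbol, sv_ev, snv_ev))
    return hits


# -- IKZF1plus ---------------------------------------------------------------

IKZF1PLUS_REQUIRED = ("IKZF1", "CDKN2A", "CDKN2B", "PAX5", "ERG")


def evaluate_ikzf1_plus(profile: PatientProfile, genes: list[GeneModel],
                        config: Optional[PipelineConfig] = None,
                        par1: GenomicInterval = PAR1_REGION) -> dict:
    """Evaluate the IKZF1plus profile on one patient.

    status is True iff a somatic deletion overlaps IKZF1, a deletion
    overlaps CDKN2A, CDKN2B, PAX5, or PAR1, and no deletion overlaps ERG.
    The rationale records each criterion's supporting call ids, and a
    ``subclonal`` flag is set when the IKZF1 deletion VAF is below the
    configured subclonality threshold.
    """
    config = config or PipelineConfig()
    by_symbol = {g.symbol: g for g in genes}
    missing = [s for s in IKZF1PLUS_REQUIRED if s not in by_symbol]
    if missing:
        raise LeukoSVError(f"IKZF1plus needs gene models for {missing}")
    deletions = [c for c in profile.sv_calls
                 if c.sv_type == "deletion" and c.filter_status == "pass"]

    def hits(symbol: str) -> list[SVCall]:
        return [c for c in deletions if sv_hits_gene(c, by_symbol[symbol])]

    ikzf1 = hits("IKZF1")
    co = {s: hits(s) for s in ("CDKN2A", "CDKN2B", "PAX5")}
    co["PAR1"] = [c for c in deletions if c.span.overlaps(par1)]
    erg = hits("ERG")
    status = bool(ikzf1) and any(co.values()) and not erg
    subclonal = any(c.vaf is not None and c.vaf < config.subclonal_vaf
                    for c in ikzf1)
    return {
        "status": status,
        "subclonal": subclonal,
        "rationale": {
            "IKZF1": [c.call_id for c in ikzf1],
            **{k: [c.call_id for c in v] for k, v in co.items()},
            "ERG_exclusion": [c.call_id for c in erg],
        },
    }


# -- hyperdiploid aneuploidy risk --------------------------------------------

def classify_hd_risk(profile: PatientProfile,
                     exclusive_or_17_18: bool = False) -> str:
    """Aneuploidy-profile risk for classical hyperdiploid leukemia.

    poor iff (CN17 < 3 and CN18 < 3) or ((CN17 >= 3 or CN18 >= 3) and
    (CN5 >= 3 or CN20 >= 3)).  Trisomy means CN >= 3 (tetrasomy counts:
    the rule is about the presence of a gain).  ``exclusive_or_17_18``
    switches the 17/18 clause to exclusive-or.
    """
    if profile.subtype != "HD":
        return "not_applicable"
    cn5 = profile.copy_state("chr5")
    cn17 = profile.copy_state("chr17")
    cn18 = profile.copy_state("chr18")
    cn20 = profile.copy_state("chr20")
    tri17, tri18 = cn17 >= 3, cn18 >= 3
    has_17_or_18 = (tri17 != tri18) if exclusive_or_17_18 else (tri17 or tri18)
    if not tri17 and not tri18:
        return "poor"
    if has_17_or_18 and (cn5 >= 3 or cn20 >= 3):
        return "poor"
    return "not_poor"


# -- putative fusions --------------------------------------------------------

@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    orientation_compatible: bool
    confidence: str = "putative"


def _genes_near_breakend(chrom: str, pos: int, genes: list[GeneModel],
                         window: int) -> list[GeneModel]:
    probe = GenomicInterval(chrom, max(0, pos - window), pos + window + 1)
    return [g for g in genes if probe.overlaps(g.footprint())]


def _provides_5prime(gene: GeneModel, orientation: str) -> bool:
    """Retained side keeps the gene's 5' end (promoter + early exons)."""
    return ((gene.strand == "+" and orientation == "left")
            or (gene.strand == "-" and orientation == "right"))


def _provides_3prime(gene: GeneModel, orientation: str) -> bool:
    return ((gene.strand == "+" and orientation == "right")
            or (gene.strand == "-" and orientation == "left"))


def predict_fusions(call: SVCall, genes: list[GeneModel],
                    config: Optional[PipelineConfig] = None
                    ) -> list[FusionCandidate]:
    """Pair genes across a translocation's breakends into putative fusions.

    Genes overlapping each breakend (within ``fusion_window_bp``) are
    combined across the junction; a pair is orientation-compatible when
    the retained sides and gene strands admit a head-to-tail transcript
    (5' portion of one gene joined to the 3' portion of the other).
    Breakends with unknown orientation yield candidates flagged
    incompatible-unknown (``orientation_compatible=False``).
    Symmetric under breakend order up to the 5'/3' role swap.
    """
    config = config or PipelineConfig()
    if call.breakends is None:
        raise LeukoSVError(f"call {call.call_id} has no breakends")
    b1, b2 = call.breakends
    near1 = _genes_near_breakend(b1.chrom, b1.pos, genes, config.fusion_window_bp)
    near2 = _genes_near_breakend(b2.chrom, b2.pos, genes, config.fusion_window_bp)
    out: list[FusionCandidate] = []
    seen: set[frozenset] = set()
    for ga, ba, gb, bb in (
            [(x, b1, y, b2) for x in near1 for y in near2]
            + [(x, b2, y, b1) for x in near2 for y in near1]):
        if ga.symbol == gb.symbol:
            continue
        key = frozenset((ga.symbol, gb.symbol))
        if key in seen:
            continue
        seen.add(key)
        known = ba.orientation != "unknown" and bb.orientation != "unknown"
        if known and _provides_5prime(ga, ba.orientation) \
                and _provides_3prime(gb, bb.orientation):
            out.append(FusionCandidate(ga.symbol, gb.symbol, True))
        elif known and _provides_5prime(gb, bb.orientation) \
                and _provides_3prime(ga, ba.orientation):
            out.append(FusionCandidate(gb.symbol, ga.symbol, True))
        else:
            g5, g3 = sorted((ga.symbol, gb.symbol))
            out.append(FusionCandidate(g5, g3, False))
    out.sort(key=lambda f: (not f.orientation_compatible, f.gene5, f.gene3))
    return out
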