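"""Core domain types for the structural-variant integration pipeline.

All genomic coordinates held by these types are 0-based, half-open
(BED convention).  File readers in :mod:`leukosv.io_formats` convert from
the 1-based inclusive coordinates conventionally printed in clinical and
array reports, and writers convert back.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

# -- closed vocabularies -----------------------------------------------------

SV_TYPES = frozenset({
    "deletion", "duplication", "insertion", "inversion",
    "intra_translocation", "inter_translocation",
    "aneuploidy_gain", "aneuploidy_loss", "cnn_loh",
})

#: SV types that carry a genomic span (interval calls).
SPAN_SV_TYPES = frozenset({
    "deletion", "duplication", "insertion", "inversion",
    "intra_translocation", "aneuploidy_gain", "aneuploidy_loss", "cnn_loh",
})

#: SV types that carry a breakend pair.
BREAKEND_SV_TYPES = frozenset({
    "inversion", "intra_translocation", "inter_translocation",
})

CALLERS = frozenset({"DN", "RVP", "CN", "ARRAY", "KARYOTYPE", "FISH"})

CN_STATES = frozenset({"loss", "gain", "neutral", "cnn_loh"})

PLATFORMS = frozenset({"CytoSNP12", "CytoScanHD", "OGM_CN"})

EFFECTS = frozenset({
    "missense", "frameshift", "stopgain", "splice", "inframe_indel", "other",
})

SUBTYPES = frozenset({"ETV6_RUNX1", "HD"})

ROLES = frozenset({"tumor", "normal", "relapse"})

ORIENTATIONS = frozenset({"left", "right", "unknown"})

BLACKLIST_CLASSES = frozenset({"IG_TR", "centromere", "gap"})


class LeukoSVError(Exception):
    """Base error for pipeline-level validation failures."""


# -- intervals and breakends -------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named contig."""

    chrom: str
    start: int
    end: int
    assembly: str = "GRCh38"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise LeukoSVError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(self.chrom, max(self.start, other.start),
                               min(self.end, other.end), self.assembly)

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Overlap length divided by the longer of the two intervals."""
        if not self.overlaps(other):
            return 0.0
        ov = min(self.end, other.end) - max(self.start, other.start)
        return ov / max(self.length, other.length)

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap between intervals (0 if overlapping), None on different chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def __str__(self) -> str:  # printed 1-based inclusive, as in reports
        return f"{self.chrom}:{self.start + 1:,}-{self.end:,}"


@dataclass(frozen=True)
class Breakend:
    """One side of a junction: position plus which side is retained.

    ``orientation == "left"`` means the sequence left of (below) ``pos``
    is retained on the derivative; ``"right"`` means the right side.
    Karyotype-derived events may carry ``"unknown"``.
    """

    chrom: str
    pos: int
    orientation: str = "unknown"

    def __post_init__(self):
        if self.pos < 0:
            raise LeukoSVError(f"breakend position < 0 on {self.chrom}")
        if self.orientation not in ORIENTATIONS:
            raise LeukoSVError(f"bad breakend orientation {self.orientation!r}")


# -- calls and segments ------------------------------------------------------

@dataclass
class SVCall:
    """One structural-variant call (interval or breakend pair)."""

    call_id: str
    sample_id: str
    sv_type: str
    span: Optional[GenomicInterval] = None
    breakends: Optional[tuple[Breakend, Breakend]] = None
    size_bp: int = 0
    vaf: Optional[float] = None
    callers: frozenset = frozenset()
    filter_status: str = "pass"
    hallmark: bool = False
    #: probe support when the call derives from an array segment
    n_probes: Optional[int] = None

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise LeukoSVError(f"unknown sv_type {self.sv_type!r}")
        if not self.callers:
            raise LeukoSVError(f"call {self.call_id}: callers must be non-empty")
        if not set(self.callers) <= CALLERS:
            raise LeukoSVError(f"call {self.call_id}: unknown caller in {set(self.callers)}")
        self.callers = frozenset(self.callers)
        if self.sv_type == "inter_translocation":
            if self.span is not None:
                raise LeukoSVError(f"call {self.call_id}: inter_translocation must not carry a span")
            if self.breakends is None or self.breakends[0].chrom == self.breakends[1].chrom:
                raise LeukoSVError(
                    f"call {self.call_id}: inter_translocation needs breakends on two chromosomes")
        elif self.span is None:
            raise LeukoSVError(f"call {self.call_id}: sv_type {self.sv_type} requires a span")
        if self.sv_type in ("deletion", "duplication") and self.size_bp != self.span.length:
            raise LeukoSVError(
                f"call {self.call_id}: size_bp {self.size_bp} != span length {self.span.length}")
        if self.size_bp < 0:
            raise LeukoSVError(f"call {self.call_id}: negative size_bp")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise LeukoSVError(f"call {self.call_id}: vaf {self.vaf} outside [0,1]")

    def with_(self, **kw) -> "SVCall":
        return replace(self, **kw)


@dataclass
class CNSegment:
    """A copy-number segment from an array or the OGM CN algorithm."""

    sample_id: str
    span: GenomicInterval
    state: str
    n_probes: int = 0
    platform: str = "OGM_CN"

    def __post_init__(self):
        if self.state not in CN_STATES:
            raise LeukoSVError(f"unknown CN state {self.state!r}")
        if self.platform not in PLATFORMS:
            raise LeukoSVError(f"unknown platform {self.platform!r}")
        if self.platform != "OGM_CN" and self.n_probes <= 0:
            raise LeukoSVError(
                f"array segment {self.span} requires n_probes > 0 on {self.platform}")
        if self.n_probes < 0:
            raise LeukoSVError("n_probes < 0")


@dataclass
class SmallVariant:
    """A somatic SNV or small indel from exome sequencing."""

    sample_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    gene: Optional[str] = None
    effect: str = "other"
    vaf: Optional[float] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise LeukoSVError(f"variant at {self.chrom}:{self.pos}: ref == alt")
        if self.effect not in EFFECTS:
            raise LeukoSVError(f"unknown effect {self.effect!r}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise LeukoSVError(f"variant vaf {self.vaf} outside [0,1]")


@dataclass
class GeneModel:
    """A gene with exon structure and a derived strand-aware promoter."""

    symbol: str
    span: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    promoter: GenomicInterval = None  # derived in __post_init__ when absent

    #: promoter window upstream of the 5' end, bp
    PROMOTER_BP = 2_000

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise LeukoSVError(f"{self.symbol}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if not self.span.contains(ex):
                raise LeukoSVError(f"{self.symbol}: exon {ex} outside gene span {self.span}")
            if prev_end is not None and ex.start < prev_end:
                raise LeukoSVError(f"{self.symbol}: exons not sorted/disjoint")
            prev_end = ex.end
        if self.promoter is None:
            if self.strand == "+":
                pstart = max(0, self.span.start - self.PROMOTER_BP)
                pend = self.span.start
                if pend == 0:  # gene at contig start: degenerate 1 bp window
                    pstart, pend = 0, 1
            else:
                pstart, pend = self.span.end, self.span.end + self.PROMOTER_BP
            self.promoter = GenomicInterval(self.span.chrom, pstart, pend,
                                            self.span.assembly)

    def footprint(self) -> GenomicInterval:
        """Gene body plus promoter, as one interval."""
        return GenomicInterval(self.span.chrom,
                               min(self.span.start, self.promoter.start),
                               max(self.span.end, self.promoter.end),
                               self.span.assembly)


@dataclass
class SampleMeta:
    sample_id: str
    patient_id: str
    subtype: str
    role: str
    blast_fraction: float = 1.0

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise LeukoSVError(f"unknown subtype {self.subtype!r}")
        if self.role not in ROLES:
            raise LeukoSVError(f"unknown role {self.role!r}")
        if not (0.0 <= self.blast_fraction <= 1.0):
            raise LeukoSVError("blast_fraction outside [0,1]")


def check_matched_pairs(samples: list[SampleMeta]) -> dict[str, dict[str, str]]:
    """Validate tumor/normal pairing; returns {patient_id: {role: sample_id}}."""
    by_patient: dict[str, dict[str, str]] = {}
    for s in samples:
        roles = by_patient.setdefault(s.patient_id, {})
        if s.role in roles and s.role != "relapse":
            raise LeukoSVError(f"patient {s.patient_id}: duplicate role {s.role}")
        roles[s.role] = s.sample_id
    for pid, roles in by_patient.items():
        if "tumor" in roles and "normal" not in roles:
            raise LeukoSVError(f"patient {pid}: tumor without matched normal")
    return by_patient


# -- pipeline configuration --------------------------------------------------

@dataclass
class PipelineConfig:
    """Numeric thresholds used across the pipeline.

    All size thresholds are inclusive lower bounds ("at least").
    """

    array_min_probes: int = 20
    array_min_cnv_bp: int = 50_000
    cnnloh_min_bp: int = 5_000_000
    ogm_min_sv_bp: int = 500
    focal_large_boundary_bp: int = 5_000_000
    #: fraction of a chromosome that a call must cover to count as whole-chromosome
    whole_chrom_fraction: float = 0.95
    recurrence_min_cases: int = 3
    intergenic_proximity_bp: int = 20_000
    promoter_bp: int = 2_000
    fusion_window_bp: int = 10_000
    #: per-platform detection limits, bp
    detection_limits: dict = field(default_factory=lambda: {
        "CytoSNP12": 50_000, "CytoScanHD": 1_000, "OGM": 500,
    })
    #: VAF below which a call is flagged subclonal in rule rationales
    subclonal_vaf: float = 0.1

    def __post_init__(self):
        for name in ("array_min_probes", "array_min_cnv_bp", "cnnloh_min_bp",
                     "ogm_min_sv_bp", "focal_large_boundary_bp",
                     "recurrence_min_cases", "intergenic_proximity_bp"):
            if getattr(self, name) <= 0:
                raise LeukoSVError(f"config {name} must be > 0")
        if self.focal_large_boundary_bp < self.array_min_cnv_bp:
            raise LeukoSVError("focal/large boundary below array CNV minimum")
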