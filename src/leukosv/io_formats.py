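"""Readers and writers for the pipeline's file formats.

Conventions
-----------
* Internal coordinates are 0-based half-open.  Printed/report coordinates
  (SV tables, CN segment tables) are 1-based inclusive and converted on
  read; writers convert back, so write-then-read round-trips exactly.
* Structural-variant tables are a TSV dialect with header columns
  ``sample_id call_id chrom1 pos1 chrom2 pos2 sv_type size_bp vaf
  orient1 orient2 callers hallmark`` (the last four optional on read).
* Copy-number segments: ``sample_id chrom start end state n_probes``.
* Small variants: VCF 4.2 with ``GENE``/``EFFECT`` INFO fields and a
  per-sample ``GT:AF`` FORMAT.
* Gene models: BED12 (one transcript per gene) or GFF3.
* Cytobands: UCSC cytoBand layout (0-based starts, band name, stain).
"""
from __future__ import annotations

import bisect
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .types import (
    BLACKLIST_CLASSES, CALLERS, EFFECTS, PLATFORMS, SPAN_SV_TYPES, SV_TYPES,
    Breakend, CNSegment, GeneModel, GenomicInterval, LeukoSVError, SVCall,
    SampleMeta, SmallVariant,
)

_DATA = resources.files("leukosv") / "data"

SV_TABLE_COLUMNS = ["sample_id", "call_id", "chrom1", "pos1", "chrom2", "pos2",
                    "sv_type", "size_bp", "vaf", "orient1", "orient2",
                    "callers", "hallmark"]

CN_TABLE_COLUMNS = ["sample_id", "chrom", "start", "end", "state", "n_probes"]


# -- contigs -----------------------------------------------------------------

def load_contigs(path: Optional[str] = None) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table (default: bundled GRCh38)."""
    if path is None:
        text = (_DATA / "contigs_grch38.tsv").read_text()
    else:
        text = Path(path).read_text()
    contigs: dict[str, int] = {}
    for i, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LeukoSVError(f"contig table line {i}: expected 2 columns")
        contigs[parts[0]] = int(parts[1])
    return contigs


# -- cytobands ---------------------------------------------------------------

class CytobandMap:
    """Chromosome band map with position lookup and band-interval expansion."""

    def __init__(self, bands: dict[str, list[tuple[int, int, str, str]]]):
        # bands: chrom -> sorted [(start, end, name, stain)]
        self.bands = bands
        self._starts = {c: [b[0] for b in rows] for c, rows in bands.items()}

    @classmethod
    def from_file(cls, path: Optional[str] = None) -> "CytobandMap":
        if path is None:
            text = (_DATA / "cytobands_synthetic.tsv").read_text()
        else:
            text = Path(path).read_text()
        bands: dict[str, list[tuple[int, int, str, str]]] = {}
        for i, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise LeukoSVError(f"cytoband file line {i}: expected >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            stain = parts[4] if len(parts) > 4 else "gneg"
            bands.setdefault(chrom, []).append((start, end, name, stain))
        for rows in bands.values():
            rows.sort()
        return cls(bands)

    def lookup(self, chrom: str, pos: int) -> str:
        """Band label at a 0-based position, e.g. ``"12p13.1"``."""
        if chrom not in self.bands:
            raise LeukoSVError(f"unknown contig {chrom!r} in cytoband map")
        rows = self.bands[chrom]
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i < 0 or pos >= rows[i][1]:
            raise LeukoSVError(f"position {chrom}:{pos} outside cytoband map")
        return chrom.removeprefix("chr") + rows[i][2]

    def band_interval(self, chrom: str, band: str) -> GenomicInterval:
        """Interval of a band; a prefix like ``p13`` expands to all sub-bands."""
        if not chrom.startswith("chr"):
            chrom = "chr" + chrom
        if chrom not in self.bands:
            raise LeukoSVError(f"unknown contig {chrom!r} in cytoband map")
        hits = [(s, e) for s, e, name, _ in self.bands[chrom]
                if name == band or name.startswith(band + ".")]
        if not hits:
            raise LeukoSVError(f"band {band!r} not found on {chrom}")
        return GenomicInterval(chrom, min(s for s, _ in hits),
                               max(e for _, e in hits))

    def centromere_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom, rows in self.bands.items():
            acen = [(s, e) for s, e, _, stain in rows if stain == "acen"]
            if acen:
                out.append(GenomicInterval(chrom, min(s for s, _ in acen),
                                           max(e for _, e in acen)))
        return out


# -- SV call tables ----------------------------------------------------------

def _parse_vaf(text: str) -> Optional[float]:
    if text in (".", "", "NA"):
        return None
    return float(text)


def read_sv_table(path: str, caller: str, contigs: dict[str, int]) -> list[SVCall]:
    """Read an SV call table; positions converted 1-based inclusive -> 0-based.

    Deletion/duplication sizes are recomputed from the coordinates (the
    coordinates are authoritative when the two disagree).
    """
    if caller not in CALLERS:
        raise LeukoSVError(f"unknown caller label {caller!r}")
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise LeukoSVError(f"{path}: empty file (missing header)")
    header = lines[0].rstrip("\n").split("\t")
    required = {"call_id", "chrom1", "pos1", "chrom2", "pos2", "sv_type",
                "size_bp", "vaf"}
    missing = required - set(header)
    if missing:
        raise LeukoSVError(f"{path}: missing columns {sorted(missing)}")
    idx = {name: i for i, name in enumerate(header)}
    calls: list[SVCall] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise LeukoSVError(f"{path} line {lineno}: expected {len(header)} "
                               f"columns, got {len(parts)}")
        def col(name, default=None):
            return parts[idx[name]] if name in idx else default
        try:
            call_id = col("call_id")
            if call_id in seen:
                raise LeukoSVError(f"duplicate call_id {call_id!r}")
            seen.add(call_id)
            chrom1, chrom2 = col("chrom1"), col("chrom2")
            for c in (chrom1, chrom2):
                if c not in contigs:
                    raise LeukoSVError(f"unknown contig {c!r}")
            pos1, pos2 = int(col("pos1")), int(col("pos2"))
            sv_type = col("sv_type")
            if sv_type not in SV_TYPES:
                raise LeukoSVError(f"unknown sv_type {sv_type!r}")
            vaf = _parse_vaf(col("vaf"))
            size_bp = int(col("size_bp"))
            o1 = col("orient1", "unknown") or "unknown"
            o2 = col("orient2", "unknown") or "unknown"
            callers_txt = col("callers", "") or ""
            callers = frozenset(callers_txt.split(",")) if callers_txt else frozenset({caller})
            hallmark = (col("hallmark", "0") or "0") in ("1", "true", "True")
            sample_id = col("sample_id", "") or ""

            span = None
            breakends = None
            if sv_type == "inter_translocation":
                breakends = (Breakend(chrom1, pos1 - 1, o1),
                             Breakend(chrom2, pos2 - 1, o2))
            else:
                if chrom1 != chrom2:
                    raise LeukoSVError(f"{sv_type} with two contigs")
                if pos2 > contigs[chrom1]:
                    raise LeukoSVError(f"end {pos2} beyond {chrom1} length")
                span = GenomicInterval(chrom1, pos1 - 1, pos2)
                if sv_type in ("inversion", "intra_translocation"):
                    breakends = (Breakend(chrom1, pos1 - 1, o1),
                                 Breakend(chrom1, pos2 - 1, o2))
                if sv_type in ("deletion", "duplication"):
                    size_bp = span.length
                elif sv_type != "insertion":
                    size_bp = span.length
            calls.append(SVCall(call_id=call_id, sample_id=sample_id,
                                sv_type=sv_type, span=span, breakends=breakends,
                                size_bp=size_bp, vaf=vaf, callers=callers,
                                hallmark=hallmark))
        except LeukoSVError as err:
            raise LeukoSVError(f"{path} line {lineno}: {err}") from None
        except ValueError as err:
            raise LeukoSVError(f"{path} line {lineno}: {err}") from None
    return calls


def write_sv_table(calls: Iterable[SVCall], path: str) -> None:
    """Write calls in the SV TSV dialect (1-based inclusive coordinates)."""
    with open(path, "w") as f:
        f.write("\t".join(SV_TABLE_COLUMNS) + "\n")
        for c in calls:
            if c.sv_type == "inter_translocation":
                b1, b2 = c.breakends
                chrom1, pos1, chrom2, pos2 = b1.chrom, b1.pos + 1, b2.chrom, b2.pos + 1
                o1, o2 = b1.orientation, b2.orientation
            else:
                chrom1 = chrom2 = c.span.chrom
                pos1, pos2 = c.span.start + 1, c.span.end
                if c.breakends is not None:
                    o1, o2 = c.breakends[0].orientation, c.breakends[1].orientation
                else:
                    o1 = o2 = "unknown"
            vaf = "." if c.vaf is None else repr(c.vaf)
            f.write("\t".join(map(str, [
                c.sample_id, c.call_id, chrom1, pos1, chrom2, pos2, c.sv_type,
                c.size_bp, vaf, o1, o2, ",".join(sorted(c.callers)),
                int(c.hallmark)])) + "\n")


# -- CN segment tables -------------------------------------------------------

def read_cn_segments(path: str, platform: str) -> list[CNSegment]:
    """Read a SEG-like table (1-based inclusive) and attach the platform."""
    if platform not in PLATFORMS:
        raise LeukoSVError(f"unknown platform {platform!r}")
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise LeukoSVError(f"{path}: empty file (missing header)")
    header = lines[0].rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for name in CN_TABLE_COLUMNS[:5]:
        if name not in idx:
            raise LeukoSVError(f"{path}: missing column {name!r}")
    array = platform != "OGM_CN"
    if array and "n_probes" not in idx:
        raise LeukoSVError(f"{path}: n_probes required for array platform {platform}")
    segments = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            start, end = int(parts[idx["start"]]), int(parts[idx["end"]])
            if end < start:
                raise LeukoSVError("zero- or negative-length segment")
            n_probes_txt = parts[idx["n_probes"]] if "n_probes" in idx else "0"
            if array and n_probes_txt in (".", ""):
                raise LeukoSVError(f"n_probes missing for array platform {platform}")
            segments.append(CNSegment(
                sample_id=parts[idx["sample_id"]],
                span=GenomicInterval(parts[idx["chrom"]], start - 1, end),
                state=parts[idx["state"]],
                n_probes=int(n_probes_txt or 0),
                platform=platform))
        except (LeukoSVError, ValueError) as err:
            raise LeukoSVError(f"{path} line {lineno}: {err}") from None
    return segments


def write_cn_segments(segments: Iterable[CNSegment], path: str) -> None:
    with open(path, "w") as f:
        f.write("\t".join(CN_TABLE_COLUMNS) + "\n")
        for s in segments:
            f.write("\t".join(map(str, [
                s.sample_id, s.span.chrom, s.span.start + 1, s.span.end,
                s.state, s.n_probes])) + "\n")


# -- small variants (VCF) ----------------------------------------------------

_EFFECT_ALIASES = {
    "missense_variant": "missense", "stop_gained": "stopgain",
    "frameshift_variant": "frameshift", "splice_acceptor_variant": "splice",
    "splice_donor_variant": "splice", "inframe_deletion": "inframe_indel",
    "inframe_insertion": "inframe_indel",
}


def _map_effect(raw: Optional[str]) -> str:
    if raw is None:
        return "other"
    if raw in EFFECTS:
        return raw
    if raw in _EFFECT_ALIASES:
        return _EFFECT_ALIASES[raw]
    warnings.warn(f"unknown effect {raw!r} mapped to 'other'", stacklevel=3)
    return "other"


def read_small_variants(path: str, samples: list[SampleMeta]) -> list[SmallVariant]:
    """Read annotated small variants; one record per carrier sample-allele.

    Records with no carrier among the given samples are dropped.  Unknown
    effect strings map to ``other`` with a warning.
    """
    wanted = {s.sample_id for s in samples}
    out: list[SmallVariant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            gene = rec.info.get("GENE")
            effect = _map_effect(rec.info.get("EFFECT"))
            for sample_name, call in rec.samples.items():
                if sample_name not in wanted:
                    continue
                gt = call.get("GT")
                if gt is None or not any(a not in (None, 0) for a in gt):
                    continue
                alt_index = next(a for a in gt if a not in (None, 0))
                af = call.get("AF")
                if isinstance(af, tuple):
                    af = af[0] if af else None
                out.append(SmallVariant(
                    sample_id=sample_name, chrom=rec.chrom, pos=rec.pos - 1,
                    ref=rec.ref, alt=rec.alts[alt_index - 1], gene=gene,
                    effect=effect, vaf=af))
    return out


def write_small_variants(variants: list[SmallVariant], samples: list[SampleMeta],
                         path: str, contigs: dict[str, int]) -> None:
    """Write a minimal VCF 4.2 with GENE/EFFECT INFO and GT:AF genotypes."""
    sample_ids = [s.sample_id for s in samples]
    order = {c: i for i, c in enumerate(contigs)}
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            f.write(f"##contig=<ID={chrom},length={length}>\n")
        f.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        f.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">\n')
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        f.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">\n')
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(sample_ids) + "\n")
        for i, v in enumerate(sorted(variants, key=lambda v: (order.get(v.chrom, 99), v.pos))):
            info = []
            if v.gene:
                info.append(f"GENE={v.gene}")
            info.append(f"EFFECT={v.effect}")
            gts = []
            for sid in sample_ids:
                if sid == v.sample_id:
                    af = "." if v.vaf is None else f"{v.vaf:.4f}"
                    gts.append(f"0/1:{af}")
                else:
                    gts.append("0/0:.")
            f.write("\t".join([v.chrom, str(v.pos + 1), f"snv{i}", v.ref, v.alt,
                               ".", "PASS", ";".join(info), "GT:AF"] + gts) + "\n")


# -- gene models -------------------------------------------------------------

def read_gene_models(path: Optional[str] = None) -> list[GeneModel]:
    """Read gene models from BED12 (default: bundled synthetic panel) or GFF3."""
    if path is None:
        p = _DATA / "genes_synthetic.bed"
        return _read_bed12(p.read_text().splitlines(), str(p))
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(str(p))
    return _read_bed12(p.read_text().splitlines(), str(p))


def _read_bed12(lines: list[str], label: str) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 12:
            raise LeukoSVError(f"{label} line {lineno}: BED12 needs 12 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        symbol, strand = parts[3], parts[5]
        n_blocks = int(parts[9])
        sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        starts = [int(x) for x in parts[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise LeukoSVError(f"{label} line {lineno}: block count mismatch")
        span = GenomicInterval(chrom, start, end)
        try:
            exons = tuple(GenomicInterval(chrom, start + s, start + s + l)
                          for s, l in zip(starts, sizes))
            genes.append(GeneModel(symbol=symbol, span=span, strand=strand,
                                   exons=exons))
        except LeukoSVError as err:
            raise LeukoSVError(f"{label} line {lineno}: {err}") from None
    return genes


def _read_gff3(path: str) -> list[GeneModel]:
    """Minimal GFF3 reader: ``gene`` features with ``exon`` children."""
    genes_raw: dict[str, dict] = {}
    exons_by_parent: dict[str, list[GenomicInterval]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise LeukoSVError(f"{path} line {lineno}: GFF3 needs 9 columns")
        chrom, _, ftype, start, end, _, strand, _, attrs_txt = parts
        attrs = dict(kv.split("=", 1) for kv in attrs_txt.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attrs.get("ID", attrs.get("Name", f"gene{lineno}"))
            genes_raw[gid] = {
                "symbol": attrs.get("Name", gid),
                "span": GenomicInterval(chrom, int(start) - 1, int(end)),
                "strand": strand,
            }
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent:
                exons_by_parent.setdefault(parent.split(",")[0], []).append(
                    GenomicInterval(chrom, int(start) - 1, int(end)))
    genes = []
    for gid, g in genes_raw.items():
        exons = tuple(sorted(exons_by_parent.get(gid, [g["span"]]),
                             key=lambda e: e.start))
        genes.append(GeneModel(symbol=g["symbol"], span=g["span"],
                               strand=g["strand"], exons=exons))
    return genes


# -- blacklist ---------------------------------------------------------------

@dataclass(frozen=True)
class BlacklistRegion:
    region: GenomicInterval
    name: str
    cls: str  # IG_TR | centromere | gap


def read_blacklist(path: Optional[str] = None) -> list[BlacklistRegion]:
    """BED with name (col 4) and class (col 5; default inferred as gap)."""
    if path is None:
        text = (_DATA / "blacklist_synthetic.bed").read_text()
        label = "bundled blacklist"
    else:
        text = Path(path).read_text()
        label = str(path)
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise LeukoSVError(f"{label} line {lineno}: BED needs >= 3 columns")
        name = parts[3] if len(parts) > 3 else f"region{lineno}"
        cls = parts[4] if len(parts) > 4 else "gap"
        if cls not in BLACKLIST_CLASSES:
            raise LeukoSVError(f"{label} line {lineno}: unknown class {cls!r}")
        out.append(BlacklistRegion(
            GenomicInterval(parts[0], int(parts[1]), int(parts[2])), name, cls))
    return out


def build_blacklist(regions: list[BlacklistRegion],
                    cytobands: Optional[CytobandMap] = None) -> list[BlacklistRegion]:
    """Combine explicit blacklist regions with centromeres from the band map."""
    out = list(regions)
    if cytobands is not None:
        for iv in cytobands.centromere_intervals():
            out.append(BlacklistRegion(iv, f"{iv.chrom}_centromere", "centromere"))
    return out


# -- karyotype / FISH event lists -------------------------------------------

_KT_TRANSLOC = re.compile(r"^t\((\w+);(\w+)\)\(([pq][\d.]*);([pq][\d.]*)\)$")
_KT_GAIN = re.compile(r"^\+(\w+)$")
_KT_LOSS = re.compile(r"^-(\w+)$")
_KT_DELDUP = re.compile(r"^(del|dup)\((\w+)\)\(([pq][\d.]*)([pq][\d.]*)?\)$")
_FISH_FUSION = re.compile(r"^fusion\((\w+);(\w+)\)$")


def parse_karyotype_event(sample_id: str, text: str, cytobands: CytobandMap,
                          contigs: dict[str, int], call_id: str,
                          caller: str = "KARYOTYPE") -> SVCall:
    """Parse one karyotype-style event string into a band-resolution call.

    Supported: ``t(12;21)(p13;q22)``, ``+21``, ``-7``, ``del(9)(p21)``,
    ``dup(1)(q21q42)``.
    """
    text = text.strip()
    m = _KT_TRANSLOC.match(text)
    if m:
        c1, c2 = "chr" + m.group(1), "chr" + m.group(2)
        b1 = cytobands.band_interval(c1, m.group(3))
        b2 = cytobands.band_interval(c2, m.group(4))
        mid1, mid2 = (b1.start + b1.end) // 2, (b2.start + b2.end) // 2
        if c1 == c2:
            span = GenomicInterval(c1, min(mid1, mid2), max(mid1, mid2))
            return SVCall(call_id, sample_id, "intra_translocation", span=span,
                          breakends=(Breakend(c1, mid1), Breakend(c2, mid2)),
                          size_bp=span.length, callers=frozenset({caller}))
        return SVCall(call_id, sample_id, "inter_translocation",
                      breakends=(Breakend(c1, mid1), Breakend(c2, mid2)),
                      callers=frozenset({caller}))
    m = _KT_GAIN.match(text) or _KT_LOSS.match(text)
    if m:
        chrom = "chr" + m.group(1)
        if chrom not in contigs:
            raise LeukoSVError(f"unknown contig in karyotype event {text!r}")
        sv_type = "aneuploidy_gain" if text.startswith("+") else "aneuploidy_loss"
        span = GenomicInterval(chrom, 0, contigs[chrom])
        return SVCall(call_id, sample_id, sv_type, span=span,
                      size_bp=span.length, callers=frozenset({caller}))
    m = _KT_DELDUP.match(text)
    if m:
        kind, chrom = m.group(1), "chr" + m.group(2)
        b1 = cytobands.band_interval(chrom, m.group(3))
        b2 = cytobands.band_interval(chrom, m.group(4)) if m.group(4) else b1
        span = GenomicInterval(chrom, min(b1.start, b2.start),
                               max(b1.end, b2.end))
        sv_type = "deletion" if kind == "del" else "duplication"
        return SVCall(call_id, sample_id, sv_type, span=span,
                      size_bp=span.length, callers=frozenset({caller}))
    raise LeukoSVError(f"cannot parse karyotype event {text!r}")


def parse_fish_event(sample_id: str, text: str, genes: list[GeneModel],
                     call_id: str) -> SVCall:
    """Parse ``fusion(GENEA;GENEB)`` into a FISH-provenance translocation."""
    m = _FISH_FUSION.match(text.strip())
    if not m:
        raise LeukoSVError(f"cannot parse FISH event {text!r}")
    by_symbol = {g.symbol: g for g in genes}
    try:
        g1, g2 = by_symbol[m.group(1)], by_symbol[m.group(2)]
    except KeyError as k:
        raise LeukoSVError(f"FISH event {text!r}: unknown gene {k}") from None
    mid1 = (g1.span.start + g1.span.end) // 2
    mid2 = (g2.span.start + g2.span.end) // 2
    return SVCall(call_id, sample_id, "inter_translocation",
                  breakends=(Breakend(g1.span.chrom, mid1),
                             Breakend(g2.span.chrom, mid2)),
                  callers=frozenset({"FISH"}))


def read_event_list(path: str, cytobands: CytobandMap, contigs: dict[str, int],
                    genes: Optional[list[GeneModel]] = None) -> list[SVCall]:
    """Read a karyotype/FISH event TSV: ``sample_id<TAB>event``."""
    calls = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("sample_id\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise LeukoSVError(f"{path} line {lineno}: expected sample_id<TAB>event")
        sample_id, event = parts[0], parts[1]
        cid = f"kt_{sample_id}_{lineno}"
        try:
            if event.startswith("fusion("):
                if genes is None:
                    raise LeukoSVError("FISH fusion event needs gene models")
                calls.append(parse_fish_event(sample_id, event, genes, cid))
            else:
                calls.append(parse_karyotype_event(sample_id, event, cytobands,
                                                   contigs, cid))
        except LeukoSVError as err:
            raise LeukoSVError(f"{path} line {lineno}: {err}") from None
    return calls
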