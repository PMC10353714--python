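"""Double hits, IKZF1plus rule, HD aneuploidy risk, fusion approximation."""
from itertools import product

import pytest

from leukosv.integration import (
    PAR1_REGION, PatientProfile, build_copy_states, classify_hd_risk,
    detect_double_hits, evaluate_ikzf1_plus, predict_fusions, sv_hits_gene,
)
from leukosv.types import (
    Breakend, GenomicInterval, LeukoSVError, SVCall, SmallVariant,
)


def deletion_in(gene, cid="d", vaf=0.4, pad=0):
    span = GenomicInterval(gene.span.chrom, gene.span.start + pad,
                           gene.span.end - pad if gene.span.length > 2 * pad
                           else gene.span.end)
    return SVCall(cid, "P", "deletion", span=span, size_bp=span.length,
                  vaf=vaf, callers=frozenset({"DN"}))


def snv_in(gene, effect="missense"):
    return SmallVariant("P", gene.span.chrom, gene.span.start + 10, "A", "G",
                        gene.symbol, effect, 0.4)


class TestDoubleHits:
    def test_stag2_deletion_plus_missense_is_double_hit(self, genes,
                                                        genes_by_symbol):
        stag2 = genes_by_symbol["STAG2"]
        profile = PatientProfile("P", "ETV6_RUNX1",
                                 sv_calls=[deletion_in(stag2)],
                                 small_variants=[snv_in(stag2)])
        (hit,) = detect_double_hits([profile], genes)
        assert hit.gene == "STAG2"
        assert hit.sv_evidence and hit.snv_evidence

    def test_sv_alone_is_not_a_double_hit(self, genes, genes_by_symbol):
        profile = PatientProfile("P", "ETV6_RUNX1",
                                 sv_calls=[deletion_in(genes_by_symbol["ETV6"])])
        assert detect_double_hits([profile], genes) == []

    def test_evidence_must_share_a_patient(self, genes, genes_by_symbol):
        stag2 = genes_by_symbol["STAG2"]
        p1 = PatientProfile("P1", "HD", sv_calls=[deletion_in(stag2)])
        sv = snv_in(stag2)
        p2 = PatientProfile("P2", "HD",
                            small_variants=[SmallVariant("P2", sv.chrom, sv.pos,
                                                         "A", "G", "STAG2",
                                                         "missense", 0.4)])
        assert detect_double_hits([p1, p2], genes) == []

    def test_translocation_breakend_in_gene_counts_as_sv_hit(
            self, genes, genes_by_symbol):
        med13l = genes_by_symbol["MED13L"]
        tra = SVCall("t", "P", "inter_translocation",
                     breakends=(Breakend(med13l.span.chrom,
                                         med13l.span.start + 1_000, "left"),
                                Breakend("chr6", 55_000_000, "right")),
                     callers=frozenset({"DN"}))
        assert sv_hits_gene(tra, med13l)
        profile = PatientProfile("P", "ETV6_RUNX1", sv_calls=[tra],
                                 small_variants=[snv_in(med13l, "stopgain")])
        (hit,) = detect_double_hits([profile], genes)
        assert hit.gene == "MED13L"

    def test_equals_intersection_of_sv_and_snv_patient_sets(
            self, full_cohort, full_results, genes):
        """Oracle: double hits = per-gene intersection of the SV-hit and
        SNV-hit patient sets, computed independently."""
        snvs_by_patient = {p: v for p, v in full_cohort.truth.snvs.items()}
        profiles = [PatientProfile(p, "HD", sv_calls=r.somatic,
                                   small_variants=snvs_by_patient.get(p, []))
                    for p, r in full_results.items()]
        hits = detect_double_hits(profiles, genes)
        got = {(h.patient_id, h.gene) for h in hits}
        expect = set()
        for g in genes:
            sv_patients = {p.patient_id for p in profiles
                           if any(c.filter_status == "pass"
                                  and sv_hits_gene(c, g) for c in p.sv_calls)}
            snv_patients = {p.patient_id for p in profiles
                            if any(v.gene == g.symbol or (
                                v.gene is None
                                and v.chrom == g.span.chrom
                                and g.span.start <= v.pos < g.span.end)
                                for v in p.small_variants)}
            expect |= {(pid, g.symbol) for pid in sv_patients & snv_patients}
        assert got == expect
        assert len(hits) > 0  # the simulated cohort implants double hits


class TestIKZF1Plus:
    @pytest.mark.parametrize("has_ikzf1,has_co,has_erg", list(product([0, 1],
                                                                      repeat=3)))
    def test_truth_table(self, genes, genes_by_symbol, has_ikzf1, has_co,
                         has_erg):
        calls = []
        if has_ikzf1:
            calls.append(deletion_in(genes_by_symbol["IKZF1"], "ik"))
        if has_co:
            calls.append(deletion_in(genes_by_symbol["PAX5"], "px"))
        if has_erg:
            calls.append(deletion_in(genes_by_symbol["ERG"], "er"))
        profile = PatientProfile("P", "ETV6_RUNX1", sv_calls=calls)
        result = evaluate_ikzf1_plus(profile, genes)
        assert result["status"] == bool(has_ikzf1 and has_co and not has_erg)

    def test_reported_positive_case_exon_level_deletions(self, genes,
                                                         genes_by_symbol):
        # IKZF1 exon 2-3 deletion plus PAX5 exon 8-9 deletion, no ERG deletion
        ikzf1_del = SVCall("d1", "P", "deletion",
                           span=GenomicInterval("chr7", 50306321, 50348483),
                           size_bp=42162, vaf=0.4, callers=frozenset({"DN"}))
        pax5_del = SVCall("d2", "P", "deletion",
                          span=GenomicInterval("chr9", 36841198, 36916988),
                          size_bp=75790, vaf=0.4, callers=frozenset({"DN"}))
        profile = PatientProfile("P", "ETV6_RUNX1",
                                 sv_calls=[ikzf1_del, pax5_del])
        result = evaluate_ikzf1_plus(profile, genes)
        assert result["status"] is True
        assert result["rationale"]["IKZF1"] == ["d1"]
        assert result["rationale"]["PAX5"] == ["d2"]
        assert result["subclonal"] is False

    def test_subclonal_ikzf1_deletion_alone_flagged(self, genes,
                                                    genes_by_symbol):
        # an isolated IKZF1 deletion at VAF ~0.06: rule negative, subclonal
        ikzf1_del = SVCall("d1", "P", "deletion",
                           span=GenomicInterval("chr7", 50306321, 50399656),
                           size_bp=93335, vaf=0.06, callers=frozenset({"RVP"}))
        profile = PatientProfile("P", "HD", sv_calls=[ikzf1_del])
        result = evaluate_ikzf1_plus(profile, genes)
        assert result["status"] is False
        assert result["subclonal"] is True

    def test_par1_deletion_satisfies_co_criterion(self, genes,
                                                  genes_by_symbol):
        par1_del = SVCall("p", "P", "deletion",
                          span=GenomicInterval("chrX", 1_000_000, 1_200_000),
                          size_bp=200_000, vaf=0.4, callers=frozenset({"DN"}))
        assert par1_del.span.overlaps(PAR1_REGION)
        profile = PatientProfile(
            "P", "HD", sv_calls=[deletion_in(genes_by_symbol["IKZF1"], "ik"),
                                 par1_del])
        assert evaluate_ikzf1_plus(profile, genes)["status"] is True

    def test_missing_gene_model_is_an_error(self, genes):
        reduced = [g for g in genes if g.symbol != "ERG"]
        profile = PatientProfile("P", "HD")
        with pytest.raises(LeukoSVError, match="ERG"):
            evaluate_ikzf1_plus(profile, reduced)


class TestHDRisk:
    @staticmethod
    def expected(cn5, cn17, cn18, cn20):
        return ("poor" if (cn17 < 3 and cn18 < 3)
                or ((cn17 >= 3 or cn18 >= 3) and (cn5 >= 3 or cn20 >= 3))
                else "not_poor")

    @pytest.mark.parametrize("cn5,cn17,cn18,cn20",
                             list(product([2, 3, 4], repeat=4)))
    def test_full_copy_number_grid(self, cn5, cn17, cn18, cn20):
        profile = PatientProfile("P", "HD", copy_states={
            "chr5": cn5, "chr17": cn17, "chr18": cn18, "chr20": cn20})
        assert classify_hd_risk(profile) == self.expected(cn5, cn17, cn18, cn20)

    def test_no_trisomy_17_18_is_poor(self):
        profile = PatientProfile("P", "HD",
                                 copy_states={"chr17": 2, "chr18": 2})
        assert classify_hd_risk(profile) == "poor"

    def test_trisomy17_with_trisomy5_is_poor(self):
        profile = PatientProfile("P", "HD",
                                 copy_states={"chr17": 3, "chr5": 3})
        assert classify_hd_risk(profile) == "poor"

    def test_trisomy17_alone_is_not_poor(self):
        profile = PatientProfile("P", "HD", copy_states={
            "chr17": 3, "chr18": 2, "chr5": 2, "chr20": 2})
        assert classify_hd_risk(profile) == "not_poor"

    def test_other_subtypes_not_applicable(self):
        profile = PatientProfile("P", "ETV6_RUNX1", copy_states={"chr17": 2})
        assert classify_hd_risk(profile) == "not_applicable"

    def test_exclusive_or_switch(self):
        profile = PatientProfile("P", "HD", copy_states={
            "chr17": 3, "chr18": 3, "chr5": 3})
        assert classify_hd_risk(profile) == "poor"
        assert classify_hd_risk(profile, exclusive_or_17_18=True) == "not_poor"

    def test_copy_states_built_from_whole_chromosome_calls(self, contigs):
        gain = SVCall("g", "P", "aneuploidy_gain",
                      span=GenomicInterval("chr21", 0, contigs["chr21"]),
                      size_bp=contigs["chr21"], callers=frozenset({"CN"}))
        loss = SVCall("l", "P", "aneuploidy_loss",
                      span=GenomicInterval("chrX", 0, contigs["chrX"]),
                      size_bp=contigs["chrX"], callers=frozenset({"CN"}))
        states = build_copy_states([gain, loss], contigs)
        assert states["chr21"] == 3 and states["chrX"] == 1
        assert states["chr7"] == 2


class TestPredictFusions:
    def test_pds5b_stag2_compatible(self, genes, genes_by_symbol):
        # t(X;13): breakend in PDS5B intron 1 (5' retained, + strand) and
        # upstream of STAG2 exon 3 (3' retained, + strand)
        pds5b, stag2 = genes_by_symbol["PDS5B"], genes_by_symbol["STAG2"]
        tra = SVCall("t", "P", "inter_translocation",
                     breakends=(Breakend("chr13", pds5b.exons[0].end + 500,
                                         "left"),
                                Breakend("chrX", stag2.exons[2].start - 200,
                                         "right")),
                     callers=frozenset({"DN"}))
        candidates = predict_fusions(tra, genes)
        pair = next(c for c in candidates if {c.gene5, c.gene3}
                    == {"PDS5B", "STAG2"})
        assert (pair.gene5, pair.gene3) == ("PDS5B", "STAG2")
        assert pair.orientation_compatible
        assert pair.confidence == "putative"

    def test_sfmbt2_dgkd_compatible(self, genes, genes_by_symbol):
        # SFMBT2 is on the minus strand: its 5' end is the span end
        sfmbt2, dgkd = genes_by_symbol["SFMBT2"], genes_by_symbol["DGKD"]
        tra = SVCall("t", "P", "inter_translocation",
                     breakends=(Breakend("chr10", sfmbt2.span.end - 5_000,
                                         "right"),
                                Breakend("chr2", dgkd.span.start + 30_000,
                                         "right")),
                     callers=frozenset({"DN"}))
        candidates = predict_fusions(tra, genes)
        pair = next(c for c in candidates if {c.gene5, c.gene3}
                    == {"SFMBT2", "DGKD"})
        assert (pair.gene5, pair.gene3) == ("SFMBT2", "DGKD")
        assert pair.orientation_compatible

    def test_gene_desert_breakends_yield_nothing(self, genes):
        tra = SVCall("t", "P", "inter_translocation",
                     breakends=(Breakend("chr4", 30_000_000, "left"),
                                Breakend("chr6", 100_000_000, "right")),
                     callers=frozenset({"DN"}))
        assert predict_fusions(tra, genes) == []

    def test_symmetric_under_breakend_swap(self, genes, genes_by_symbol):
        pds5b, stag2 = genes_by_symbol["PDS5B"], genes_by_symbol["STAG2"]
        b1 = Breakend("chr13", pds5b.exons[0].end + 500, "left")
        b2 = Breakend("chrX", stag2.exons[2].start - 200, "right")
        fwd = SVCall("t1", "P", "inter_translocation", breakends=(b1, b2),
                     callers=frozenset({"DN"}))
        rev = SVCall("t2", "P", "inter_translocation", breakends=(b2, b1),
                     callers=frozenset({"DN"}))
        as_pairs = lambda cs: {(c.gene5, c.gene3, c.orientation_compatible)
                               for c in cs}
        assert as_pairs(predict_fusions(fwd, genes)) \
            == as_pairs(predict_fusions(rev, genes))

    def test_unknown_orientation_never_claims_compatibility(
            self, genes, genes_by_symbol):
        pds5b, stag2 = genes_by_symbol["PDS5B"], genes_by_symbol["STAG2"]
        tra = SVCall("t", "P", "inter_translocation",
                     breakends=(Breakend("chr13", pds5b.span.start + 100),
                                Breakend("chrX", stag2.span.start + 100)),
                     callers=frozenset({"KARYOTYPE"}))
        candidates = predict_fusions(tra, genes)
        assert candidates and all(not c.orientation_compatible
                                  for c in candidates)
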