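"""Merging, germline subtraction, filters, size classes."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from leukosv.io_formats import BlacklistRegion
from leukosv.sv_merge import (
    MatchParams, apply_filters, classify_size, cn_segment_to_call,
    filter_array_segments, greedy_match, match_calls, merge_pipelines,
    subtract_germline,
)
from leukosv.types import (
    Breakend, CNSegment, GenomicInterval, LeukoSVError, PipelineConfig, SVCall,
)


def make_del(call_id, chrom, start, end, sample="S1", vaf=0.4, callers=("DN",),
             sv_type="deletion", n_probes=None):
    return SVCall(call_id, sample, sv_type,
                  span=GenomicInterval(chrom, start, end), size_bp=end - start,
                  vaf=vaf, callers=frozenset(callers), n_probes=n_probes)


def make_tra(call_id, c1, p1, c2, p2, sample="S1", callers=("DN",)):
    return SVCall(call_id, sample, "inter_translocation",
                  breakends=(Breakend(c1, p1, "left"), Breakend(c2, p2, "right")),
                  callers=frozenset(callers))


class TestMatchCalls:
    def test_high_reciprocal_overlap_matches(self, match_params):
        a = make_del("a", "chr7", 100_000, 200_000)
        b = make_del("b", "chr7", 105_000, 195_000, sv_type="deletion")
        assert match_calls(a, b, match_params)

    def test_reflexive(self, match_params):
        a = make_del("a", "chr7", 100_000, 200_000)
        assert match_calls(a, a, match_params)

    def test_distant_small_calls_do_not_match(self, match_params):
        a = make_del("a", "chr7", 1_000_000, 1_001_000)
        b = make_del("b", "chr7", 11_000_000, 11_001_000)
        assert a.span.reciprocal_overlap(b.span) == 0.0
        assert not match_calls(a, b, match_params)

    def test_type_classes_pool_deletion_with_loss(self, match_params):
        a = make_del("a", "chr7", 100_000, 200_000)
        seg = CNSegment("S1", GenomicInterval("chr7", 100_000, 200_000), "loss",
                        50, "CytoSNP12")
        assert match_calls(a, cn_segment_to_call(seg, "c"), match_params)
        dup = make_del("d", "chr7", 100_000, 200_000, sv_type="duplication")
        assert not match_calls(a, dup, match_params)

    def test_translocation_matches_within_tolerance_either_order(
            self, match_params):
        a = make_tra("a", "chr12", 11_700_000, "chr21", 35_000_000)
        b = make_tra("b", "chr21", 35_010_000, "chr12", 11_695_000)
        assert match_calls(a, b, match_params)
        far = make_tra("c", "chr12", 11_700_000, "chr21", 36_000_000)
        assert not match_calls(a, far, match_params)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric(self, data):
        def rand_call(tag):
            start = data.draw(st.integers(0, 10_000_000), label=f"{tag}s")
            size = data.draw(st.integers(1, 5_000_000), label=f"{tag}l")
            t = data.draw(st.sampled_from(["deletion", "duplication"]),
                          label=f"{tag}t")
            return make_del(tag, "chr1", start, start + size, sv_type=t)
        a, b = rand_call("a"), rand_call("b")
        params = MatchParams()
        assert match_calls(a, b, params) == match_calls(b, a, params)

    def test_brute_force_overlap_oracle_agrees_with_intervaltree(self):
        """The O(n^2) overlap predicate equals an interval-tree query."""
        from intervaltree import IntervalTree
        rng = np.random.default_rng(42)
        params = MatchParams()
        calls = [make_del(f"c{i}", "chr2", s, s + l)
                 for i, (s, l) in enumerate(zip(
                     rng.integers(0, 50_000_000, 300),
                     rng.integers(1_000, 3_000_000, 300)))]
        tree = IntervalTree()
        for i, c in enumerate(calls):
            tree.addi(c.span.start, c.span.end, i)
        for i, c in enumerate(calls[:100]):
            brute = {j for j, o in enumerate(calls)
                     if j != i and c.span.overlaps(o.span)}
            via_tree = {iv.data for iv in tree.overlap(c.span.start, c.span.end)
                        if iv.data != i}
            assert brute == via_tree


class TestMergePipelines:
    def test_matched_pair_collapses_with_dn_coordinates(self, match_params):
        dn = [make_del("d1", "chr9", 21_900_000, 22_000_000, callers=("DN",))]
        rvp = [make_del("r1", "chr9", 21_903_000, 21_998_000, callers=("RVP",)),
               make_del("r2", "chr3", 1_000_000, 1_050_000, callers=("RVP",))]
        merged = merge_pipelines(dn, rvp, [], match_params)
        assert len(merged) == 2
        joint = next(c for c in merged if c.callers == {"DN", "RVP"})
        assert joint.span == dn[0].span  # DN assembly coordinates win
        assert next(c for c in merged if c.callers == {"RVP"}).call_id == "r2"

    @pytest.mark.parametrize("size_mb,expected_n", [(6, 1), (2, 0)])
    def test_cn_contributes_only_large_segments(self, match_params, size_mb,
                                                expected_n):
        seg = CNSegment("S1", GenomicInterval("chr4", 10_000_000,
                                              10_000_000 + size_mb * 10**6),
                        "loss", 0, "OGM_CN")
        merged = merge_pipelines([], [], [seg], match_params)
        assert len(merged) == expected_n

    def test_mixed_samples_rejected(self, match_params):
        dn = [make_del("a", "chr1", 0, 1000, sample="S1")]
        rvp = [make_del("b", "chr1", 0, 1000, sample="S2")]
        with pytest.raises(LeukoSVError, match="mixed samples"):
            merge_pipelines(dn, rvp, [], match_params)

    def test_order_invariant_and_bounded(self, match_params):
        rng = np.random.default_rng(3)
        dn = [make_del(f"d{i}", "chr5", s, s + l, callers=("DN",))
              for i, (s, l) in enumerate(zip(rng.integers(0, 100_000_000, 20),
                                             rng.integers(1_000, 500_000, 20)))]
        rvp = [make_del(f"r{i}", "chr5", s, s + l, callers=("RVP",))
               for i, (s, l) in enumerate(zip(rng.integers(0, 100_000_000, 20),
                                              rng.integers(1_000, 500_000, 20)))]
        merged = merge_pipelines(dn, rvp, [], match_params)
        shuffled = merge_pipelines(dn[::-1], rvp[::-1], [], match_params)
        assert merged == shuffled
        assert len(merged) <= len(dn) + len(rvp)

    def test_idempotent_on_remerge(self, match_params):
        dn = [make_del("d1", "chr5", 0, 10_000, callers=("DN",))]
        rvp = [make_del("r1", "chr5", 100, 9_900, callers=("RVP",))]
        merged = merge_pipelines(dn, rvp, [], match_params)
        assert merge_pipelines(merged, [], [], match_params) == merged

    def test_greedy_matching_near_optimal_bipartite(self):
        """Greedy 1-to-1 matching recovers the optimal number of pairs in
        >= 99% of random instances of <= 50 calls at realistic call density
        (calls scattered over tens of megabases, as in real callsets);
        pathologically dense clusters can under-match, which is documented."""
        rng = np.random.default_rng(11)
        params = MatchParams()
        agree = total = 0
        for _ in range(150):
            n, m = rng.integers(2, 26, 2)
            dn = [make_del(f"d{i}", "chr6", s, s + l, callers=("DN",))
                  for i, (s, l) in enumerate(zip(
                      rng.integers(0, 20_000_000, n),
                      rng.integers(1_000, 400_000, n)))]
            rvp = [make_del(f"r{i}", "chr6", s, s + l, callers=("RVP",))
                   for i, (s, l) in enumerate(zip(
                       rng.integers(0, 20_000_000, m),
                       rng.integers(1_000, 400_000, m)))]
            greedy = len(greedy_match(dn, rvp, params))
            # exhaustive optimum via assignment on the match indicator
            cost = np.zeros((len(dn), len(rvp)))
            for i, a in enumerate(dn):
                for j, b in enumerate(rvp):
                    cost[i, j] = -1.0 if match_calls(a, b, params) else 0.0
            rows, cols = linear_sum_assignment(cost)
            optimal = int(-cost[rows, cols].sum())
            total += 1
            agree += (greedy == optimal)
        assert agree / total >= 0.99


class TestSubtractGermline:
    def test_matching_normal_call_removes_tumor_call(self, match_params):
        g = make_del("g1", "chr8", 1_000_000, 1_100_000)
        s = make_del("s1", "chr2", 5_000_000, 5_040_000)
        gn = make_del("g1n", "chr8", 1_002_000, 1_098_000, sample="S1")
        somatic, removed = subtract_germline([g, s], [gn], match_params)
        assert [c.call_id for c in somatic] == ["s1"]
        assert [c.call_id for c in removed] == ["g1"]
        assert removed[0].filter_status == "filtered:germline"

    def test_empty_normal_requires_explicit_flag(self, match_params):
        t = [make_del("s1", "chr2", 0, 1000)]
        with pytest.raises(LeukoSVError, match="allow_unmatched"):
            subtract_germline(t, [], match_params)
        somatic, removed = subtract_germline(t, [], match_params,
                                             allow_unmatched=True)
        assert somatic == t and removed == []

    def test_partition_law(self, match_params):
        rng = np.random.default_rng(5)
        tumor = [make_del(f"t{i}", "chr3", s, s + l)
                 for i, (s, l) in enumerate(zip(rng.integers(0, 50_000_000, 30),
                                                rng.integers(1_000, 1_000_000, 30)))]
        normal = [make_del(f"n{i}", "chr3", s, s + l)
                  for i, (s, l) in enumerate(zip(rng.integers(0, 50_000_000, 15),
                                                 rng.integers(1_000, 1_000_000, 15)))]
        somatic, removed = subtract_germline(tumor, normal, match_params)
        assert len(somatic) + len(removed) == len(tumor)
        assert {c.call_id for c in somatic} | {c.call_id for c in removed} \
            == {c.call_id for c in tumor}


class TestApplyFilters:
    def test_boundaries_are_inclusive(self, config):
        """Calls exactly at 500 bp / 50 kb / 20 probes / 5 Mb are kept; one
        unit below each is filtered with the matching reason."""
        at = [
            make_del("ogm", "chr2", 10_000_000, 10_000_500),              # 500 bp
            make_del("arr", "chr2", 20_000_000, 20_050_000,
                     callers=("ARRAY",), n_probes=20),                    # 50 kb
            make_del("loh", "chr2", 30_000_000, 35_000_000,
                     sv_type="cnn_loh"),                                  # 5 Mb
        ]
        below = [
            make_del("ogm_b", "chr2", 10_000_000, 10_000_499),
            make_del("arr_size_b", "chr2", 20_000_000, 20_049_999,
                     callers=("ARRAY",), n_probes=20),
            make_del("arr_probe_b", "chr2", 20_000_000, 20_050_000,
                     callers=("ARRAY",), n_probes=19),
            make_del("loh_b", "chr2", 30_000_000, 34_999_999,
                     sv_type="cnn_loh"),
        ]
        kept, dropped = apply_filters(at + below, config, [])
        assert {c.call_id for c in kept} == {"ogm", "arr", "loh"}
        reasons = {c.call_id: c.filter_status for c in dropped}
        assert reasons == {"ogm_b": "filtered:min_size",
                           "arr_size_b": "filtered:min_size",
                           "arr_probe_b": "filtered:min_probes",
                           "loh_b": "filtered:min_size"}

    def test_translocations_exempt_from_size_but_not_blacklist(self, config,
                                                               blacklist):
        ok = make_tra("t1", "chr12", 11_700_000, "chr21", 35_000_000)
        igh = make_tra("t2", "chr14", 106_000_000, "chr8", 127_000_000)
        kept, dropped = apply_filters([ok, igh], config, blacklist)
        assert [c.call_id for c in kept] == ["t1"]
        assert dropped[0].filter_status == "filtered:IG_TR"

    def test_focal_deletion_overlapping_igh_removed(self, config, blacklist):
        d = make_del("d", "chr14", 105_600_000, 105_700_000)
        kept, dropped = apply_filters([d], config, blacklist)
        assert kept == [] and dropped[0].filter_status == "filtered:IG_TR"

    def test_whole_chromosome_gain_not_blacklisted_by_centromere(self, config,
                                                                 blacklist,
                                                                 contigs):
        gain = SVCall("a21", "S1", "aneuploidy_gain",
                      span=GenomicInterval("chr21", 0, contigs["chr21"]),
                      size_bp=contigs["chr21"], callers=frozenset({"CN"}))
        kept, dropped = apply_filters([gain], config, blacklist)
        assert kept == [gain]

    def test_filter_partitions_input(self, config, blacklist):
        rng = np.random.default_rng(8)
        calls = [make_del(f"x{i}", "chr2", s, s + l)
                 for i, (s, l) in enumerate(zip(rng.integers(0, 200_000_000, 40),
                                                rng.integers(100, 3_000_000, 40)))]
        kept, dropped = apply_filters(calls, config, blacklist)
        assert len(kept) + len(dropped) == len(calls)

    def test_array_segment_rules(self, config):
        segs = [CNSegment("S", GenomicInterval("chr1", 0, 50_000), "loss", 20,
                          "CytoSNP12"),
                CNSegment("S", GenomicInterval("chr1", 0, 40_000), "loss", 25,
                          "CytoSNP12"),
                CNSegment("S", GenomicInterval("chr1", 0, 5_500_000), "cnn_loh",
                          900, "CytoSNP12")]
        kept, dropped = filter_array_segments(segs, config)
        assert segs[0] in kept and segs[2] in kept
        assert dropped[0][1] == "min_size"


class TestClassifySize:
    @pytest.mark.parametrize("start,end,expected", [
        (10_000_000, 13_600_000, "focal"),        # 3.6 Mb
        (0, 17_000_000, "large"),                 # 17 Mb chr12p-style loss
        (5_000_000, 9_999_999, "focal"),          # just under the boundary
        (5_000_000, 10_000_000, "large"),         # exactly 5 Mb
    ])
    def test_interval_classes(self, config, contigs, start, end, expected):
        c = make_del("c", "chr12", start, end)
        assert classify_size(c, config, contigs) == expected

    def test_full_chromosome_gain_is_whole_chromosome(self, config, contigs):
        span = GenomicInterval("chr21", 0, contigs["chr21"])
        c = SVCall("g", "S1", "duplication", span=span, size_bp=span.length,
                   callers=frozenset({"CN"}))
        assert classify_size(c, config, contigs) == "whole_chromosome"

    def test_translocations_are_focal_by_convention(self, config, contigs):
        assert classify_size(make_tra("t", "chr1", 1000, "chr2", 2000),
                             config, contigs) == "focal"
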