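"""Donut-filter loop calling and regulatory-element integration rules."""

import numpy as np
import pandas as pd
import pytest

from hicscape import (GenomeLayout, LoopCaller, annotate_loops, call_loops,
                      ctcf_loop_fraction, define_elements, extract_ndrs,
                      genes_looped_to_enhancers, ice_normalize,
                      specific_elements)
from hicscape.core import GeneTable, PeakSet
from hicscape.loops import RegulatoryElementSet
from hicscape.matrix import ContactMatrix
import scipy.sparse as sp

from conftest import decay_matrix

RES = 5000


def planted_loop_matrix(n, loops, enrichment=6.0, depth=1e6, seed=0,
                        peak_bins=2, domains=()):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mean = (1.0 + d) ** -1.0
    for a, b in domains:
        mean[a:b, a:b] *= 3.0
    for b1, b2 in loops:
        mean[b1:b1 + peak_bins, b2:b2 + peak_bins] *= enrichment
        mean[b2:b2 + peak_bins, b1:b1 + peak_bins] *= enrichment
    iu, ju = np.triu_indices(n)
    vals = mean[iu, ju] * (depth / mean[iu, ju].sum())
    rng = np.random.default_rng(seed)
    counts = rng.poisson(vals).astype(float)
    keep = counts > 0
    layout = GenomeLayout({"chr1": n * RES})
    return ContactMatrix(layout, RES, {"chr1": sp.coo_matrix(
        (counts[keep], (iu[keep], ju[keep])), shape=(n, n))})


class TestLoopCalling:
    def test_planted_loops_recovered(self):
        loops = [(200, 210), (400, 412), (600, 608), (800, 811),
                 (1000, 1009), (1200, 1212), (1400, 1407), (1600, 1610)]
        m = planted_loop_matrix(2000, loops, seed=4)
        _, bias = ice_normalize(m)
        calls = call_loops(m, bias)
        called = [(r.bin1, r.bin2) for r in calls.itertuples()]
        def hit(t):
            return any(abs(c[0] - t[0]) <= 1 and abs(c[1] - t[1]) <= 1
                       for c in called)
        recall = sum(hit(t) for t in loops) / len(loops)
        precision = sum(
            any(abs(c[0] - t[0]) <= 1 and abs(c[1] - t[1]) <= 1 for t in loops)
            for c in called) / len(called)
        assert recall >= 0.8
        assert precision >= 0.8

    def test_no_calls_on_pure_decay(self):
        for seed in range(5):
            m = decay_matrix(800, 4e5, seed=seed)
            _, bias = ice_normalize(m)
            assert len(call_loops(m, bias, fdr=0.1)) == 0

    def test_domain_corner_not_called_with_lower_left(self):
        # a sharp domain corner has donut enrichment but the lower-left
        # neighborhood sits inside the domain and vetoes it
        m = planted_loop_matrix(800, [], depth=2e6, seed=6,
                                domains=[(300, 380)])
        _, bias = ice_normalize(m)
        calls = call_loops(m, bias)
        for r in calls.itertuples():
            near_corner = abs(r.bin1 - 300) <= 2 and abs(r.bin2 - 379) <= 2
            assert not near_corner

    def test_disabling_a_neighborhood_never_reduces_calls(self):
        m = planted_loop_matrix(1000, [(300, 308), (600, 610)], seed=7)
        _, bias = ice_normalize(m)
        base = len(LoopCaller().fit(m, bias).loops_)
        for nb in ("donut", "lower_left", "horizontal", "vertical"):
            relaxed = len(LoopCaller().fit(
                m, bias, disabled_neighborhoods=(nb,)).loops_)
            assert relaxed >= base

    def test_missing_bias_raises(self):
        m = decay_matrix(100, 1e4, seed=0)
        with pytest.raises(ValueError, match="bias"):
            call_loops(m)

    def test_empty_matrix_gives_empty_list(self):
        layout = GenomeLayout({"chr1": 500_000})
        m = ContactMatrix(layout, RES, {"chr1": sp.coo_matrix((100, 100))})
        calls = call_loops(m, {"chr1": np.ones(100)})
        assert len(calls) == 0


def peaks(mark, rows):
    return PeakSet(mark, pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                     "signal"]))


@pytest.fixture
def element_setting():
    genes = GeneTable(pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr1"],
        "start": [10_000, 200_000],
        "end": [18_000, 190_000][:1] + [210_000],
        "strand": ["+", "+"]}))
    genes.expressed["s"] = pd.Series({"gA": True, "gB": False})
    h3k4me3 = peaks("H3K4me3", [("chr1", 8_500, 9_500, 5.0),
                                ("chr1", 198_000, 199_000, 5.0)])
    # edge gaps to the nearest TSS (10_000 or 200_000): 1_500 and 2_500
    h3k27ac = peaks("H3K27ac", [("chr1", 11_500, 12_500, 8.0),
                                ("chr1", 30_000, 31_000, 9.0)])
    ctcf = peaks("CTCF", [("chr1", 30_500, 31_500, 3.0),
                          ("chr1", 50_000, 51_000, 3.0)])
    return genes, h3k4me3, h3k27ac, ctcf


class TestDefineElements:
    def test_promoter_window_and_expression_rule(self, element_setting):
        genes, h3k4me3, h3k27ac, ctcf = element_setting
        elements = define_elements(h3k4me3, h3k27ac, ctcf, genes, "s")
        # gA expressed, window [8000, 10000) overlaps its H3K4me3 peak;
        # gB has a peak but is not expressed
        assert elements.promoters[["start", "end"]].values.tolist() == [[8000, 10000]]
        assert elements.promoters["gene_id"].tolist() == ["gA"]

    def test_enhancer_distance_rule(self, element_setting):
        genes, h3k4me3, h3k27ac, ctcf = element_setting
        elements = define_elements(h3k4me3, h3k27ac, ctcf, genes, "s")
        # peak at 11.5k is 1.5 kb from gA's TSS -> rejected; peak at 30k is
        # 20 kb from every TSS -> enhancer (expression plays no role here)
        assert elements.enhancers[["start", "end"]].values.tolist() == [[30_000, 31_000]]

    def test_insulator_exclusion(self, element_setting):
        genes, h3k4me3, h3k27ac, ctcf = element_setting
        elements = define_elements(h3k4me3, h3k27ac, ctcf, genes, "s")
        # first CTCF peak overlaps the enhancer -> excluded
        assert elements.insulators["start"].tolist() == [50_000]

    def test_minus_strand_promoter_is_downstream_window(self):
        genes = GeneTable(pd.DataFrame({
            "gene_id": ["gC"], "chrom": ["chr1"], "start": [40_000],
            "end": [50_000], "strand": ["-"]}))
        k4 = peaks("H3K4me3", [("chr1", 50_500, 51_500, 4.0)])
        elements = define_elements(k4, peaks("H3K27ac", []), peaks("CTCF", []),
                                   genes, "s")
        assert elements.promoters[["start", "end"]].values.tolist() == [[50_000, 52_000]]


def loop_frame(rows, sample="s"):
    recs = []
    for chrom, b1, b2 in rows:
        recs.append({"chrom": chrom, "bin1": b1, "bin2": b2,
                     "start1": b1 * RES, "end1": (b1 + 1) * RES,
                     "start2": b2 * RES, "end2": (b2 + 1) * RES,
                     "observed": 10.0, "q": 0.01, "sample": sample})
    return pd.DataFrame(recs)


def element_set(promoters=(), enhancers=(), insulators=()):
    def frame(rows, extra=None):
        df = pd.DataFrame([{"chrom": c, "start": s, "end": e,
                            "element_id": f"{c}:{s}-{e}"} for c, s, e in rows])
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "start", "end", "element_id"])
        return df
    p = frame(promoters)
    if len(p):
        p["gene_id"] = [f"g{k}" for k in range(len(p))]
    else:
        p["gene_id"] = pd.Series(dtype=object)
    return RegulatoryElementSet(p, frame(enhancers), frame(insulators))


class TestAnnotateLoops:
    def test_enhancer_promoter_category(self):
        loops = loop_frame([("chr1", 10, 20)])
        elements = element_set(promoters=[("chr1", 100_000, 102_000)],
                               enhancers=[("chr1", 51_000, 52_000)])
        annotated, table = annotate_loops(loops, elements)
        assert annotated["category"].tolist() == ["P-E"]

    def test_priority_promoter_over_insulator(self):
        loops = loop_frame([("chr1", 10, 20)])
        elements = element_set(promoters=[("chr1", 51_000, 52_000)],
                               insulators=[("chr1", 52_500, 53_500),
                                           ("chr1", 100_000, 101_000)])
        annotated, _ = annotate_loops(loops, elements)
        assert annotated["anchor1_label"].tolist() == ["P"]
        assert annotated["category"].tolist() == ["P-I"]

    def test_category_table_matches_enumeration_and_anchor_order(self):
        loops = loop_frame([("chr1", 10, 20), ("chr1", 30, 40),
                            ("chr1", 20, 51), ("chr1", 60, 70),
                            ("chr1", 51, 80), ("chr1", 90, 95)])
        elements = element_set(promoters=[("chr1", 100_000, 102_000)],
                               enhancers=[("chr1", 256_000, 257_000)])
        annotated, table = annotate_loops(loops, elements)
        counts = dict(zip(table["category"], table["count"]))
        assert counts == {"N-N": 3, "P-N": 1, "P-E": 1, "E-N": 1}
        # anchor order never changes the category
        assert set(annotated.loc[[2, 4], "category"]) == {"P-E", "E-N"}


class TestCtcfLoopFraction:
    @pytest.fixture
    def ctcf(self):
        return peaks("CTCF", [("chr1", 50_000, 51_000, 1.0),
                              ("chr1", 100_000, 101_000, 1.0)])

    def test_both_mode(self, ctcf):
        loops = loop_frame([("chr1", 10, 20)])
        flags, frac = ctcf_loop_fraction(loops, ctcf, mode="both")
        assert frac == 1.0
        one_anchor = loop_frame([("chr1", 10, 40)])
        _, frac_one = ctcf_loop_fraction(one_anchor, ctcf, mode="both")
        assert frac_one == 0.0
        _, frac_either = ctcf_loop_fraction(one_anchor, ctcf, mode="either")
        assert frac_either == 1.0

    def test_counting(self, ctcf):
        loops = loop_frame([("chr1", 10, 20), ("chr1", 10, 40),
                            ("chr1", 300, 400), ("chr1", 310, 420),
                            ("chr1", 320, 440)])
        _, frac = ctcf_loop_fraction(loops, ctcf, mode="either")
        assert frac == pytest.approx(0.4)

    def test_empty_loops_raise(self, ctcf):
        with pytest.raises(ValueError, match="empty"):
            ctcf_loop_fraction(loop_frame([]), ctcf)


class TestSpecificElements:
    def test_identical_sets_all_common(self):
        e = element_set(enhancers=[("chr1", 0, 1000), ("chr1", 5000, 6000)])
        s1, common, s2 = specific_elements(e, e, "enhancer")
        assert len(common) == 2 and len(s1) == len(s2) == 0

    def test_disjoint_sets_all_specific(self):
        e1 = element_set(enhancers=[("chr1", 0, 1000)])
        e2 = element_set(enhancers=[("chr1", 5000, 6000)])
        s1, common, s2 = specific_elements(e1, e2, "enhancer")
        assert len(s1) == len(s2) == 1 and len(common) == 0

    def test_partial_overlap_counts_as_common(self):
        e1 = element_set(enhancers=[("chr1", 0, 1000), ("chr1", 4000, 5000)])
        e2 = element_set(enhancers=[("chr1", 999, 2000)])
        s1, common, s2 = specific_elements(e1, e2, "enhancer")
        assert common["start"].tolist() == [0]
        assert s1["start"].tolist() == [4000]
        assert len(s2) == 0


class TestGenesLoopedToEnhancers:
    def test_single_enhancer_promoter_loop(self):
        loops = loop_frame([("chr1", 10, 20)])
        elements = element_set(promoters=[("chr1", 100_500, 102_000)],
                               enhancers=[("chr1", 51_000, 52_000)])
        out = genes_looped_to_enhancers(loops, elements.enhancers, elements,
                                        GeneTable(pd.DataFrame({
                                            "gene_id": ["g0"], "chrom": ["chr1"],
                                            "start": [102_000], "end": [110_000],
                                            "strand": ["+"]})))
        assert out["gene_id"].tolist() == ["g0"]
        assert out["enhancer_id"].iloc[0].startswith("chr1:51000")

    def test_enhancer_enhancer_loop_contributes_nothing(self):
        loops = loop_frame([("chr1", 10, 20)])
        elements = element_set(enhancers=[("chr1", 51_000, 52_000),
                                          ("chr1", 101_000, 102_000)])
        out = genes_looped_to_enhancers(loops, elements.enhancers, elements,
                                        GeneTable(pd.DataFrame({
                                            "gene_id": ["g0"], "chrom": ["chr1"],
                                            "start": [0], "end": [10],
                                            "strand": ["+"]})))
        assert len(out) == 0

    def test_hand_enumeration(self):
        # five loops, promoters of four genes at bins 40,60,80,99; enhancers
        # at bins 10 and 20
        proms = [("chr1", b * RES + 100, b * RES + 2100) for b in (40, 60, 80, 99)]
        enhs = [("chr1", 10 * RES + 100, 10 * RES + 1100),
                ("chr1", 20 * RES + 100, 20 * RES + 1100)]
        elements = element_set(promoters=proms, enhancers=enhs)
        loops = loop_frame([("chr1", 10, 40),    # E-P g0
                            ("chr1", 20, 60),    # E-P g1
                            ("chr1", 10, 20),    # E-E
                            ("chr1", 80, 99),    # P-P
                            ("chr1", 30, 99)])   # N-P
        out = genes_looped_to_enhancers(loops, elements.enhancers, elements,
                                        GeneTable(pd.DataFrame({
                                            "gene_id": [f"g{k}" for k in range(4)],
                                            "chrom": ["chr1"] * 4,
                                            "start": [b * RES + 2100 for b in (40, 60, 80, 99)],
                                            "end": [b * RES + 9000 for b in (40, 60, 80, 99)],
                                            "strand": ["+"] * 4})))
        assert sorted(out["gene_id"]) == ["g0", "g1"]


class TestExtractNdrs:
    def test_interval_oracle_and_subset(self):
        elements = element_set(enhancers=[("chr1", 100, 200)])
        atac = peaks("ATAC", [("chr1", 150, 300, 1.0)])
        out = extract_ndrs(elements, [], peaks("H3K27ac", []),
                           peaks("H3K4me3", []), atac)
        assert out[["start", "end"]].values.tolist() == [[150, 200]]
        assert out["kind"].tolist() == ["enhancer"]

    def test_no_atac_overlap_no_ndr(self):
        elements = element_set(enhancers=[("chr1", 100, 200)])
        atac = peaks("ATAC", [("chr1", 5000, 6000, 1.0)])
        out = extract_ndrs(elements, [], peaks("H3K27ac", []),
                           peaks("H3K4me3", []), atac)
        assert len(out) == 0

    def test_promoter_ndr_within_source_peak(self):
        elements = element_set(promoters=[("chr1", 8000, 10_000)])
        k4 = peaks("H3K4me3", [("chr1", 8500, 10_500, 2.0)])
        atac = peaks("ATAC", [("chr1", 9000, 11_000, 1.0)])
        out = extract_ndrs(elements, ["g0"], peaks("H3K27ac", []), k4, atac)
        assert out[["start", "end"]].values.tolist() == [[9000, 10_500]]
        # NDR inside its parent H3K4me3 peak
        assert out["start"].iloc[0] >= 8500 and out["end"].iloc[0] <= 10_500
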