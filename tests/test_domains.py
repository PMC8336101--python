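"""Arrowhead transform, domain calling, states, and domain comparisons."""

import numpy as np
import pandas as pd
import pytest

from hicscape import (BoundarySet, ContactDomain, GenomeLayout,
                      arrowhead_transform, boundaries, call_domains,
                      classify_domain_states, common_domains,
                      ctcf_boundary_fraction, domain_size_stats,
                      state_switch_genes)
from hicscape.core import GeneTable, GenomicInterval, PeakSet
from hicscape.matrix import ContactMatrix

from conftest import decay_matrix

RES = 5000


def domain(chrom, start_bin, end_bin, score=1.0, sample=""):
    return ContactDomain(GenomicInterval(chrom, start_bin * RES, end_bin * RES),
                         score, sample)


def planted_matrix(n, domains, enrichment=3.0, depth=5e5, seed=0, alpha=1.0):
    """Poisson matrix with decay plus enriched domain squares; balanced."""
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mean = (1.0 + d) ** (-alpha)
    for a, b in domains:
        mean[a:b, a:b] *= enrichment
    iu, ju = np.triu_indices(n)
    vals = mean[iu, ju] * (depth / mean[iu, ju].sum())
    vals = np.random.default_rng(seed).poisson(vals).astype(float)
    full = np.zeros((n, n))
    full[iu, ju] = vals
    full = full + np.triu(full, 1).T
    layout = GenomeLayout({"chr1": n * RES})
    return ContactMatrix.from_dense(layout, RES, {"chr1": full}, normalized=True)


class TestArrowheadTransform:
    def test_symmetric_rows_give_zero(self):
        n = 20
        dense = np.ones((n, n))
        A = arrowhead_transform(dense)
        defined = ~np.isnan(A)
        assert np.allclose(A[defined], 0.0)

    def test_two_to_one_contrast(self):
        dense = np.ones((7, 7))
        dense[3, 2] = dense[2, 3] = 2.0   # M(3, 3-1)=2, M(3, 3+1)=1
        A = arrowhead_transform(dense)
        assert A[3, 1] == pytest.approx(1.0 / 3.0)

    def test_values_bounded(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(2.0, (30, 30)).astype(float)
        dense = dense + dense.T
        A = arrowhead_transform(dense)
        defined = ~np.isnan(A)
        assert np.all(A[defined] >= -1.0) and np.all(A[defined] <= 1.0)

    def test_zero_denominator_is_nan(self):
        dense = np.zeros((10, 10))
        A = arrowhead_transform(dense)
        assert np.isnan(A[5, 2])


class TestCallDomains:
    def test_uniform_decay_yields_no_domains(self):
        n = 400
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        full = 100.0 / (1.0 + d)
        layout = GenomeLayout({"chr1": n * RES})
        m = ContactMatrix.from_dense(layout, RES, {"chr1": full}, normalized=True)
        assert call_domains(m) == []

    def test_single_planted_domain_within_one_bin(self):
        m = planted_matrix(400, [(20, 60)], depth=3e5, seed=1)
        calls = call_domains(m)
        assert len(calls) == 1
        iv = calls[0].interval
        assert abs(iv.start // RES - 20) <= 1
        assert abs(iv.end // RES - 60) <= 1

    def test_adjacent_domains_share_one_boundary(self):
        m = planted_matrix(400, [(10, 30), (30, 55)], depth=5e5, seed=2)
        calls = call_domains(m)
        assert len(calls) == 2
        edges = sorted([calls[0].interval.start // RES, calls[0].interval.end // RES,
                        calls[1].interval.start // RES, calls[1].interval.end // RES])
        for got, want in zip(edges, [10, 30, 30, 55]):
            assert abs(got - want) <= 1
        b = boundaries(calls)
        # the shared boundary is reported once
        assert b.count == len(set(edges))

    def test_scale_invariance(self):
        m = planted_matrix(300, [(40, 80)], seed=3)
        scaled = ContactMatrix(m.layout, m.resolution,
                               {"chr1": m.data["chr1"] * 7.0}, normalized=True)
        a = [(d.interval.start, d.interval.end) for d in call_domains(m)]
        b = [(d.interval.start, d.interval.end) for d in call_domains(scaled)]
        assert a == b

    def test_requires_balanced_matrix(self):
        m = decay_matrix(50, 1e4, seed=0)
        with pytest.raises(ValueError, match="balanced"):
            call_domains(m)


class TestBoundaries:
    def test_two_disjoint_domains_four_boundaries(self):
        b = boundaries([domain("chr1", 10, 20), domain("chr1", 40, 60)])
        assert b.count == 4
        assert b.flank == 5000

    def test_nested_shared_endpoint_deduplicated(self):
        b = boundaries([domain("chr1", 10, 50), domain("chr1", 10, 25)])
        assert b.count == 3

    def test_windows_use_flank(self):
        b = boundaries([domain("chr1", 2, 4)], flank=1000)
        assert b.windows("chr1").tolist() == [[9000, 11000], [19000, 21000]]


class TestCtcfBoundaryFraction:
    def test_three_of_five(self):
        pts = BoundarySet({"chr1": np.array([10_000, 50_000, 90_000,
                                             130_000, 170_000])}, flank=2000)
        peaks = PeakSet("CTCF", pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [9_500, 49_500, 129_500],
            "end": [10_500, 50_500, 130_500],
            "signal": [1.0] * 3}))
        assert ctcf_boundary_fraction(pts, peaks) == pytest.approx(0.6)

    @pytest.mark.parametrize("present,expect", [(True, 1.0), (False, 0.0)])
    def test_all_or_none(self, present, expect):
        pts = BoundarySet({"chr1": np.array([10_000, 20_000])}, flank=500)
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [9_900, 19_900],
                           "end": [10_100, 20_100], "signal": [1.0] * 2})
        peaks = PeakSet("CTCF", df if present else df.iloc[:0])
        assert ctcf_boundary_fraction(pts, peaks) == expect

    def test_empty_boundary_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ctcf_boundary_fraction(BoundarySet({}), PeakSet("CTCF"))


class TestCommonDomains:
    def test_identical_sets_all_common(self):
        d1 = [domain("chr1", 0, 20), domain("chr1", 40, 80)]
        d2 = [domain("chr1", 0, 20), domain("chr1", 40, 80)]
        pairs, s1, s2 = common_domains(d1, d2)
        assert len(pairs) == 2 and not s1 and not s2

    def test_half_overlap_not_common(self):
        pairs, s1, s2 = common_domains([domain("chr1", 0, 200)],
                                       [domain("chr1", 0, 100)])
        assert not pairs and len(s1) == len(s2) == 1

    def test_symmetry(self):
        d1 = [domain("chr1", 0, 100), domain("chr1", 150, 260)]
        d2 = [domain("chr1", 2, 98), domain("chr1", 160, 250), domain("chr1", 300, 340)]
        p12, _, _ = common_domains(d1, d2)
        p21, _, _ = common_domains(d2, d1)
        assert {(x.interval.start, y.interval.start) for x, y in p12} == \
               {(y.interval.start, x.interval.start) for x, y in p21}


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


class TestClassifyDomainStates:
    def test_top_quantile_selection(self):
        doms = [domain("chr1", 0, 10), domain("chr1", 20, 30),
                domain("chr1", 40, 50), domain("chr1", 60, 70)]
        # four H3K36me3 peaks, one per domain, signals 1..4; top 25% = {4}
        peaks = {"H3K36me3": PeakSet("H3K36me3", peak_frame(
            [("chr1", 5000 + 100_000 * k, 6000 + 100_000 * k, float(k + 1))
             for k in range(4)]))}
        table = classify_domain_states(doms, peaks)
        assert table["H3K36me3"].tolist() == [False, False, False, True]
        assert table["class"].tolist() == ["none", "none", "none", "active"]

    def test_no_peaks_means_none_with_warning(self):
        with pytest.warns(UserWarning, match="no peaks"):
            table = classify_domain_states([domain("chr1", 0, 10)], {})
        assert table["class"].tolist() == ["none"]

    def test_class_precedence(self):
        doms = [domain("chr1", 0, 10)]
        peaks = {m: PeakSet(m, peak_frame([("chr1", 1000, 2000, 5.0)]))
                 for m in ("H3K9me3", "H3K27me3", "H3K36me3")}
        assert classify_domain_states(doms, peaks)["class"].tolist() == ["active"]
        del peaks["H3K36me3"]
        assert classify_domain_states(doms, peaks)["class"].tolist() == \
            ["heterochromatic"]

    def test_raising_quantile_never_removes_flags(self):
        rng = np.random.default_rng(1)
        doms = [domain("chr1", 10 * k, 10 * k + 8) for k in range(6)]
        starts = [int(rng.integers(0, 290_000)) for _ in range(30)]
        peaks = {"H3K36me3": PeakSet("H3K36me3", peak_frame(
            [("chr1", s0, s0 + 500, float(rng.lognormal())) for s0 in starts]))}
        flags_25 = classify_domain_states(doms, peaks, 0.25)["H3K36me3"]
        flags_50 = classify_domain_states(doms, peaks, 0.50)["H3K36me3"]
        assert (flags_50 | flags_25).equals(flags_50)


class TestStateSwitchGenes:
    def test_toy_report(self):
        d1 = [domain("chr1", 0, 20, sample="p"), domain("chr1", 40, 60, sample="p")]
        d2 = [domain("chr1", 0, 20, sample="m"), domain("chr1", 40, 60, sample="m")]
        pairs = list(zip(d1, d2))
        s1 = pd.DataFrame({"chrom": "chr1", "start": [0, 200_000],
                           "end": [100_000, 300_000],
                           "class": ["repressed", "heterochromatic"]})
        s2 = pd.DataFrame({"chrom": "chr1", "start": [0, 200_000],
                           "end": [100_000, 300_000],
                           "class": ["active", "active"]})
        genes = GeneTable(pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(5)],
            "chrom": ["chr1"] * 5,
            "start": [10_000, 50_000, 210_000, 250_000, 280_000],
            "end": [20_000, 60_000, 220_000, 260_000, 290_000],
            "strand": ["+"] * 5}))
        de = pd.DataFrame({
            "log2FoldChange": [2.0, 1.5, 1.2, -0.8, 0.0],
            "padj": [0.001, 0.01, 0.2, 0.04, 0.9]},
            index=[f"g{i}" for i in range(5)])
        report = state_switch_genes(pairs, s1, s2, genes, de)
        assert len(report["switching_pairs"]) == 2
        assert report["n_up"] == 3 and report["n_down"] == 1
        assert report["n_unchanged"] == 1
        assert report["significant_up"] == ["g0", "g1"]

    def test_no_switching_pairs(self):
        report = state_switch_genes(
            [], pd.DataFrame(columns=["chrom", "start", "end", "class"]),
            pd.DataFrame(columns=["chrom", "start", "end", "class"]),
            GeneTable(pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                                    "start": [0], "end": [10], "strand": ["+"]})),
            pd.DataFrame(columns=["log2FoldChange", "padj"]))
        assert report["genes"] == [] and report["n_up"] == 0


class TestDomainSizeStats:
    def test_identical_lists_p_near_one(self):
        d = [domain("chr1", 0, 10), domain("chr1", 20, 40), domain("chr1", 50, 80)]
        stats = domain_size_stats(d, list(d))
        assert stats["p_value"] == pytest.approx(1.0)

    def test_small_sample_exact_enumeration(self):
        d1 = [domain("chr1", 0, k) for k in (20, 40, 60)]        # 100,200,300 kb
        d2 = [domain("chr1", 0, k) for k in (200, 400, 600)]     # 1,2,3 Mb
        stats = domain_size_stats(d1, d2)
        # most extreme arrangement among C(6,3)=20: one-sided 1/20, two-sided 2/20
        assert stats["p_value"] == pytest.approx(0.1)
        assert stats["mean2"] > stats["mean1"]

    def test_shifted_simulation_detects_smaller_domains(self):
        rng = np.random.default_rng(0)
        sizes1 = rng.integers(40, 80, 200)
        sizes2 = rng.integers(20, 40, 200)
        d1 = [domain("chr1", 0, int(s)) for s in sizes1]
        d2 = [domain("chr1", 0, int(s)) for s in sizes2]
        stats = domain_size_stats(d1, d2)
        assert stats["mean2"] < stats["mean1"]
        assert stats["p_value"] < 0.05

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            domain_size_stats([], [domain("chr1", 0, 10)])
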