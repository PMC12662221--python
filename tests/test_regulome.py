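"""Differential accessibility, regulome selection, GRE classification,
binding annotation, and exact enrichment tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, fisher_exact

from tecomp.design import AccessibilityMatrix, ConditionDesign, SampleInfo
from tecomp.intervals import GenomicInterval, RegionSet
from tecomp import regulome as rg
from tecomp.simulate import CLASS_BACKGROUND, simulate_regulome_dataset
from tecomp.stats import bh_adjust, fisher_exact_2x2


def tiny_design():
    return ConditionDesign(
        [
            SampleInfo("b1", "0h", "baseline"),
            SampleInfo("t1", "48h_low", "induced_low", "48h"),
            SampleInfo("h1", "48h_high", "induced_high", "48h"),
            SampleInfo("e1", "ESC", "esc_ref"),
            SampleInfo("s1", "TSC", "tsc_ref"),
        ]
    )


class TestPairwiseDifferential:
    def test_null_all_zero(self):
        design = tiny_design()
        vals = pd.DataFrame(
            {c: [10.0, 50.0, 120.0] for c in ("b1", "t1", "h1", "e1", "s1")},
            index=["r1", "r2", "r3"],
        )
        fc = rg.pairwise_differential(AccessibilityMatrix(vals), design)
        assert (fc.lfc == 0).all().all()
        assert not fc.significant.any().any()

    def test_binomial_example(self):
        # one responsive region among many balanced ones: size factors 1,
        # measured lfc = log2(40.5/10.5), p = two-sided exact binomial
        design = tiny_design()
        n_flat = 30
        rows = {f"f{i}": [100.0, 100.0, 100.0, 50.0, 50.0] for i in range(n_flat)}
        rows["hit"] = [10.0, 40.0, 10.0, 50.0, 50.0]
        vals = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["b1", "t1", "h1", "e1", "s1"])
        fc = rg.pairwise_differential(AccessibilityMatrix(vals), design)
        assert fc.lfc.loc["hit", "48h_low"] == pytest.approx(np.log2(40.5 / 10.5), abs=1e-9)
        # size factors are 1 here (median region is balanced), so the null
        # proportion is 1/2 and the two-sided p equals the symmetric tail sum
        expect = binomtest(40, 50, 0.5).pvalue
        assert fc.p.loc["hit", "48h_low"] == pytest.approx(expect, rel=1e-12)
        from scipy.stats import binom
        assert expect == pytest.approx(2 * binom.sf(39, 50, 0.5), rel=1e-9)

    def test_bh_matches_textbook_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = rng.uniform(size=40)
            q = bh_adjust(p)
            # textbook BH: sort, scale by m/rank, running minimum from the top
            order = np.argsort(p)
            m = len(p)
            scaled = p[order] * m / np.arange(1, m + 1)
            running = np.minimum.accumulate(scaled[::-1])[::-1]
            expect = np.empty(m)
            expect[order] = np.minimum(running, 1.0)
            np.testing.assert_allclose(q, expect, atol=1e-12)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            ConditionDesign(
                [
                    SampleInfo("t1", "48h_low", "induced_low"),
                    SampleInfo("h1", "48h_high", "induced_high"),
                    SampleInfo("e1", "ESC", "esc_ref"),
                    SampleInfo("s1", "TSC", "tsc_ref"),
                ]
            )


class TestSelectRegulome:
    def _fc(self, lfc_rows):
        design = tiny_design()
        idx = [f"r{i}" for i in range(len(lfc_rows))]
        lfc = pd.DataFrame(lfc_rows, index=idx, columns=["48h_low", "48h_high"])
        ones = pd.DataFrame(1.0, index=idx, columns=lfc.columns)
        sig = pd.DataFrame(False, index=idx, columns=lfc.columns)
        return rg.FoldChangeTable(lfc, ones, ones, sig, design), idx

    def test_inclusion_by_any_condition(self):
        fc, idx = self._fc([[0.8, -1.2], [0.3, 0.9], [1.0, 0.0]])
        regions = RegionSet(
            [GenomicInterval("chr1", 100 * i, 100 * i + 50, name=r) for i, r in enumerate(idx)]
        )
        merged, resp = rg.select_regulome(fc, regions)
        assert set(resp.index) == {"r0", "r2"}
        assert resp["r0"] == pytest.approx(-1.2)

    def test_zero_noise_recovery_exact(self, zero_noise_sim):
        s = zero_noise_sim
        fc = rg.pairwise_differential(s.matrix, s.design)
        _, resp = rg.select_regulome(fc, s.regions)
        planted = set(s.truth.index[s.truth.gre_class != CLASS_BACKGROUND])
        assert set(resp.index) == planted

    def test_empty_table_rejected(self):
        design = tiny_design()
        empty = pd.DataFrame()
        fc = rg.FoldChangeTable(empty, empty, empty, empty, design)
        with pytest.raises(ValueError):
            rg.select_regulome(fc, RegionSet([]))


class TestBinarizeOpenness:
    def test_boundary_inclusive_and_scale_equivariant(self):
        design = tiny_design()
        vals = pd.DataFrame(
            {"b1": [1.0, 1.0], "t1": [1.0, 1.0], "h1": [1.0, 1.0],
             "e1": [5.0, 4.999], "s1": [10.0, 2.0]},
            index=["a", "b"],
        )
        open1 = rg.binarize_openness(AccessibilityMatrix(vals), design, tau=5)
        assert bool(open1.loc["a", "esc_ref"]) is True
        assert bool(open1.loc["b", "esc_ref"]) is False
        open2 = rg.binarize_openness(AccessibilityMatrix(vals * 2), design, tau=10)
        pd.testing.assert_frame_equal(open1, open2)

    def test_auto_threshold_splits_bimodal(self):
        design = tiny_design()
        rng = np.random.default_rng(1)
        low = rng.uniform(1.5, 2.5, size=100)
        high = rng.uniform(40, 60, size=100)
        esc = np.concatenate([low, high])
        tsc = np.concatenate([high, low])
        vals = pd.DataFrame(
            {"b1": 10.0, "t1": 10.0, "h1": 10.0, "e1": esc, "s1": tsc},
            index=[f"r{i}" for i in range(200)],
        )
        calls = rg.binarize_openness(AccessibilityMatrix(vals), design, tau="auto")
        assert calls["esc_ref"].to_numpy().tolist() == ([False] * 100 + [True] * 100)
        assert calls["tsc_ref"].to_numpy().tolist() == ([True] * 100 + [False] * 100)
        # Otsu oracle: exhaustive scan over 256 bins of the pooled log1p signal
        pooled = np.log1p(np.concatenate([esc, tsc]))
        hist, edges = np.histogram(pooled, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        w = hist.cumsum()
        best, best_t = -1.0, None
        for t in range(1, 256):
            w0, w1 = w[t - 1], w[-1] - w[t - 1]
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:t] * centers[:t]).sum() / w0
            m1 = (hist[t:] * centers[t:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best:
                best, best_t = v, centers[t - 1]
        assert np.log1p(calls.attrs["tau"]) == pytest.approx(best_t, rel=1e-9)


class TestClassifyRule:
    def _mk(self, lfc_low, lfc_high, esc, tsc):
        design = tiny_design()
        lfc = pd.DataFrame({"48h_low": [lfc_low], "48h_high": [lfc_high]}, index=["r"])
        ones = pd.DataFrame(1.0, index=["r"], columns=lfc.columns)
        sig = lfc.abs() >= 1
        fc = rg.FoldChangeTable(lfc, ones, ones, sig, design)
        openness = pd.DataFrame({"esc_ref": [esc], "tsc_ref": [tsc]}, index=["r"])
        return rg.classify_gre_rule(fc, openness)[0].gre_class

    @pytest.mark.parametrize(
        "lfc_low,lfc_high,esc,tsc,expected",
        [
            (1.2, 1.6, False, True, "TE-GRE"),
            (1.2, 1.2, False, False, "DIND"),
            (-1.4, -1.8, True, False, "ESC-GRE"),
            (-1.4, -1.8, True, True, "SC-GRE"),
            (-1.4, -1.8, False, False, "unclassified"),
            (0.5, 0.4, False, True, "unclassified"),
            (1.2, 0.4, False, False, "unclassified"),  # opens at low dose only
        ],
    )
    def test_rule_table(self, lfc_low, lfc_high, esc, tsc, expected):
        assert self._mk(lfc_low, lfc_high, esc, tsc) == expected

    def test_missing_openness_rejected(self):
        design = tiny_design()
        lfc = pd.DataFrame({"48h_low": [1.0], "48h_high": [1.0]}, index=["r"])
        ones = pd.DataFrame(1.0, index=["r"], columns=lfc.columns)
        fc = rg.FoldChangeTable(lfc, ones, ones, lfc.abs() >= 1, design)
        with pytest.raises(KeyError):
            rg.classify_gre_rule(fc, pd.DataFrame(columns=["esc_ref", "tsc_ref"]))

    def test_classes_partition_regulome(self, regulome_sim):
        s = regulome_sim
        fc = rg.pairwise_differential(s.matrix, s.design)
        _, resp = rg.select_regulome(fc, s.regions)
        sel = list(resp.index)
        openness = rg.binarize_openness(s.matrix, s.design)
        fcs = rg.FoldChangeTable(
            fc.lfc.loc[sel], fc.p.loc[sel], fc.q.loc[sel], fc.significant.loc[sel], s.design
        )
        records = rg.classify_gre_rule(fcs, openness.loc[sel])
        assert len(records) == len(sel)
        classes = pd.Series([r.gre_class for r in records])
        assert classes.value_counts().sum() == len(sel)


class TestClassifyHclust:
    def test_separable_blocks_recovered(self):
        s = simulate_regulome_dataset(
            n_per_class={c: 25 for c in ("TE-GRE", "ESC-GRE", "SC-GRE", "DIND")},
            n_background=0, noise_sd=0.0, seed=8,
        )
        labels, cmap = rg.classify_gre_hclust(s.matrix, s.design)
        assert (labels == s.truth["gre_class"]).all()

    def test_agreement_with_rule_classifier(self, regulome_sim):
        s = regulome_sim
        fc = rg.pairwise_differential(s.matrix, s.design)
        _, resp = rg.select_regulome(fc, s.regions)
        sel = list(resp.index)
        openness = rg.binarize_openness(s.matrix, s.design)
        fcs = rg.FoldChangeTable(
            fc.lfc.loc[sel], fc.p.loc[sel], fc.q.loc[sel], fc.significant.loc[sel], s.design
        )
        rule = pd.Series(
            {r.region_id: r.gre_class for r in rg.classify_gre_rule(fcs, openness.loc[sel])}
        )
        hc, _ = rg.classify_gre_hclust(s.matrix.restrict(sel), s.design)
        assert (hc.loc[sel] == rule.loc[sel]).mean() >= 0.90

    def test_ward_merge_heights_match_lance_williams_oracle(self):
        # naive Ward (D2) agglomeration via the Lance-Williams update
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 5))
        from scipy.spatial.distance import pdist, squareform
        from scipy.cluster.hierarchy import linkage

        d = squareform(pdist(x, metric="correlation"))
        n = len(x)
        sizes = {i: 1 for i in range(n)}
        dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
        active = set(range(n))
        heights = []
        next_id = n
        while len(active) > 1:
            (i, j), h = min(
                ((tuple(sorted(k)), v) for k, v in dist.items()
                 if set(k) <= active), key=lambda t: t[1]
            )
            heights.append(h)
            ni, nj = sizes[i], sizes[j]
            for k in active - {i, j}:
                nk = sizes[k]
                dik, djk = dist[frozenset((i, k))], dist[frozenset((j, k))]
                dij = dist[frozenset((i, j))]
                new = np.sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                    / (ni + nj + nk)
                )
                dist[frozenset((next_id, k))] = new
            sizes[next_id] = ni + nj
            active -= {i, j}
            active.add(next_id)
            next_id += 1
        tree = linkage(pdist(x, metric="correlation"), method="ward")
        np.testing.assert_allclose(tree[:, 2], heights, rtol=1e-9)
        assert (np.diff(tree[:, 2]) >= -1e-12).all()  # Ward monotonicity


class TestAnnotateBinding:
    def test_exact_peak_and_empty_peakset(self):
        regions = RegionSet([GenomicInterval("chr1", 10, 20, name="a")])
        peaks = RegionSet([GenomicInterval("chr1", 10, 20, name="p")])
        assert rg.annotate_cebpa_binding(regions, peaks)["a"]
        assert not rg.annotate_cebpa_binding(regions, RegionSet([]))["a"]

    def test_recovers_planted_bound_fraction(self, regulome_sim):
        s = regulome_sim
        bound = rg.annotate_cebpa_binding(s.regions, s.chip_peaks)
        assert (bound.loc[s.truth.index] == s.truth.cebpa_bound).all()


class TestDifferentialBinding:
    def test_low_mean_sites_never_tested(self):
        h = pd.Series([15.0, 100.0], index=["low", "ok"])
        l = pd.Series([18.0, 10.0], index=["low", "ok"])
        res = rg.differential_binding(h, l)
        assert "low" not in res.index and "ok" in res.index

    def test_equal_counts_not_reported(self):
        h = pd.Series([50.0, 60.0], index=["a", "b"])
        res = rg.differential_binding(h, h.copy())
        assert (res["lfc"] == 0).all() and not res["reported"].any()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_null_simulation_fdr(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(10, 200, size=2000)
        h = pd.Series(rng.poisson(lam).astype(float))
        l = pd.Series(rng.poisson(lam).astype(float))
        res = rg.differential_binding(h, l)
        assert res["reported"].mean() <= 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rg.differential_binding(pd.Series([-1.0]), pd.Series([5.0]))


def rational_fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p in rational arithmetic."""
    n, r, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    p_obs = Fraction(comb(r, a) * comb(n - r, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - (n - r)), min(r, c1) + 1):
        px = Fraction(comb(r, x) * comb(n - r, c1 - x), denom)
        if px <= p_obs:
            total += px
    return float(total)


class TestMotifEnrichment:
    def _sets(self, n_fg, n_bg):
        fg = RegionSet([GenomicInterval("chr1", 100 * i, 100 * i + 50, name=f"f{i}") for i in range(n_fg)])
        bg = RegionSet([GenomicInterval("chr2", 100 * i, 100 * i + 50, name=f"b{i}") for i in range(n_bg)])
        return fg, bg

    def test_equal_rates_degenerate(self):
        fg, bg = self._sets(10, 10)
        hits = pd.DataFrame(
            {"M": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5},
            index=fg.ids + bg.ids,
        )
        res = rg.motif_enrichment(fg, bg, hits)
        assert res.loc["M", "odds_ratio"] == pytest.approx(1.0)
        assert res.loc["M", "p"] == pytest.approx(1.0)

    def test_enumeration_oracle(self):
        fg, bg = self._sets(10, 100)
        hits = pd.DataFrame(
            {"M": [True] * 6 + [False] * 4 + [True] * 10 + [False] * 90},
            index=fg.ids + bg.ids,
        )
        res = rg.motif_enrichment(fg, bg, hits)
        assert res.loc["M", "p"] == pytest.approx(rational_fisher_oracle(6, 4, 10, 90), abs=1e-12)

    def test_fisher_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 12, size=4)
            p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(fisher_exact_2x2(c, d, a, b), abs=1e-12)
            assert p == pytest.approx(fisher_exact_2x2(b, a, d, c), abs=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            ours = fisher_exact_2x2(a, b, c, d)
            theirs = fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_overlapping_sets_rejected_unless_flagged(self):
        fg, _ = self._sets(5, 0)
        hits = pd.DataFrame({"M": [True] * 5}, index=fg.ids)
        with pytest.raises(ValueError):
            rg.motif_enrichment(fg, fg, hits)
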