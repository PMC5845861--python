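"""Tests of bulk selection, the G statistic, G' smoothing and FDR calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import clsqtl
from clsqtl.qtl_bsa import (
    BulkSelection,
    allele_counts,
    g_statistic,
    genes_in_interval,
    gprime_significance,
    select_bulks,
    significant_regions,
    smooth_gprime,
)

from conftest import qtl_phenotype


class TestSelectBulks:
    def test_disjoint_extreme_bulks(self, cross488):
        y = qtl_phenotype(cross488, "VI_m010", 0.3, seed=1)
        b = select_bulks(y, size=50)
        assert b.size == 50
        assert not set(b.high_bulk) & set(b.low_bulk)
        assert min(y[b.high_bulk]) >= max(y[b.low_bulk])

    def test_half_population_partitions(self):
        y = pd.Series(np.arange(100.0), index=[f"s{i:03d}" for i in range(100)])
        b = select_bulks(y, size=50)
        assert set(b.high_bulk) | set(b.low_bulk) == set(y.index)

    def test_all_ties_resolved_by_id_order(self):
        y = pd.Series(1.0, index=[f"s{i:03d}" for i in range(10)])
        b = select_bulks(y, size=3)
        assert b.low_bulk == ["s000", "s001", "s002"]
        assert b.high_bulk == ["s007", "s008", "s009"]

    def test_oversized_bulks_rejected(self):
        y = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError):
            select_bulks(y, size=6)


class TestAlleleCounts:
    def test_monomorphic_marker(self):
        ids = [f"s{i}" for i in range(8)]
        g = pd.DataFrame({"m": np.zeros(8)}, index=ids)
        b = BulkSelection(high_bulk=ids[:4], low_bulk=ids[4:])
        c = allele_counts(g, b)
        assert tuple(c.iloc[0]) == (0, 4, 0, 4)

    def test_missing_alleles_excluded(self):
        ids = [f"s{i}" for i in range(6)]
        g = pd.DataFrame({"m": [1, 1, np.nan, 0, 0, np.nan]}, index=ids)
        b = BulkSelection(high_bulk=ids[:3], low_bulk=ids[3:])
        c = allele_counts(g, b)
        assert tuple(c.iloc[0]) == (2, 0, 0, 2)

    def test_unknown_bulk_member_named(self, cross488):
        b = BulkSelection(high_bulk=["ghost"], low_bulk=["seg0001"])
        with pytest.raises(KeyError, match="ghost"):
            allele_counts(cross488.genotypes, b)

    def test_qtl_marker_enriched_in_high_bulk(self, cross488):
        # allele 1 increases the phenotype, so the high bulk is enriched for it
        y = qtl_phenotype(cross488, "VI_m010", 0.3, seed=2)
        b = select_bulks(y, size=50)
        c = allele_counts(cross488.genotypes, b).loc["VI_m010"]
        assert c["n_high_allele1"] > c["n_low_allele1"]
        # an unlinked marker stays near 50:50 in both bulks
        c0 = allele_counts(cross488.genotypes, b).loc["XII_m010"]
        for n1 in (c0["n_high_allele1"], c0["n_low_allele1"]):
            assert abs(n1 - 25) <= 3 * np.sqrt(50 * 0.25)


class TestGStatistic:
    def test_perfect_independence_is_zero(self):
        assert g_statistic(25, 25, 25, 25) == 0.0

    def test_worked_association_value(self):
        # all expectations 25: G = 4 * (40 ln 1.6 + 10 ln 0.4)
        expected = 2 * (2 * 40 * np.log(40 / 25) + 2 * 10 * np.log(10 / 25))
        assert expected == pytest.approx(38.549, abs=1e-3)
        assert g_statistic(40, 10, 10, 40) == pytest.approx(expected, abs=1e-9)

    def test_complete_separation_closed_form(self):
        assert g_statistic(50, 0, 0, 50) == pytest.approx(200 * np.log(2), abs=1e-9)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            g_statistic(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 80)] * 4))
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy_likelihood_ratio(self, cells):
        """G equals scipy's log-likelihood-ratio contingency statistic."""
        a, b, c, d = cells
        table = np.array([[a, b], [c, d]])
        # scipy needs positive margins; our implementation handles the rest
        if table.sum() == 0:
            return
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            # degenerate margins: expected counts are 0 where observed are 0
            assert g_statistic(a, b, c, d) >= 0
            return
        oracle = stats.chi2_contingency(table, correction=False,
                                        lambda_="log-likelihood")[0]
        assert g_statistic(a, b, c, d) == pytest.approx(oracle, abs=1e-9)

    @given(st.tuples(*[st.integers(0, 80)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_bulk_and_allele_swap(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        assert g_statistic(a, b, c, d) == pytest.approx(
            g_statistic(d, c, b, a), abs=1e-9
        )


class TestSmoothing:
    def test_constant_g_unchanged(self, yeast_map):
        g = pd.Series(3.7, index=pd.Index(yeast_map["marker_id"], name="marker_id"))
        gp = smooth_gprime(g, yeast_map, window_kb=100)
        np.testing.assert_allclose(gp, 3.7)

    def test_isolated_marker_keeps_own_g(self):
        m = pd.DataFrame(
            {"marker_id": ["a", "b"], "chrom": ["I", "II"],
             "pos_bp": [1, 1], "pos_cm": [0.0, 0.0]}
        )
        g = pd.Series([5.0, 1.0], index=pd.Index(["a", "b"], name="marker_id"))
        gp = smooth_gprime(g, m, window_kb=10)
        np.testing.assert_allclose(gp, [5.0, 1.0])

    def test_hand_evaluated_tricube_weights(self):
        # three equidistant markers at half-window spacing, G = (0, 30, 0)
        m = pd.DataFrame(
            {"marker_id": ["a", "b", "c"], "chrom": ["I"] * 3,
             "pos_bp": [1, 5001, 10001], "pos_cm": [0.0, 1.0, 2.0]}
        )
        g = pd.Series([0.0, 30.0, 0.0], index=pd.Index(m["marker_id"], name="marker_id"))
        gp = smooth_gprime(g, m, window_kb=10)
        w0 = (1 - 0.5**3) ** 3
        assert gp["b"] == pytest.approx(30.0 / (2 * w0 + 1), abs=1e-9)
        assert gp["b"] == pytest.approx(12.8214, abs=1e-3)


class TestSignificance:
    def test_iid_lognormal_null_rarely_calls(self):
        """With no QTL, the robust null keeps the false-positive proportion low."""
        rng = np.random.default_rng(0)
        n_calls = 0
        n_markers = 0
        reps_with_calls = 0
        for _ in range(50):
            gp = pd.Series(np.exp(rng.normal(0.0, 0.6, 300)))
            _, q, _ = gprime_significance(gp, fdr_level=0.05)
            n_calls += int((q <= 0.05).sum())
            n_markers += len(q)
            reps_with_calls += int((q <= 0.05).any())
        assert reps_with_calls <= 10  # most replicates call nothing
        assert n_calls / n_markers <= 0.05

    def test_identical_gprime_never_significant(self):
        gp = pd.Series(2.0, index=range(100))
        p, q, thr = gprime_significance(gp, fdr_level=0.5)
        assert p.nunique() == 1
        assert (q > 0.5).all()
        assert np.isnan(thr)

    def test_minimum_q_at_simulated_qtl(self, yeast_map, cross488):
        y = qtl_phenotype(cross488, "X_m010", 0.30, seed=3)
        res = clsqtl.bsa_scan(cross488.genotypes, yeast_map, y)
        pos = yeast_map.set_index("marker_id")
        best = res.scan["q_value"].idxmin()
        assert pos.loc[best, "chrom"] == "X"
        assert abs(pos.loc[best, "pos_bp"] - pos.loc["X_m010", "pos_bp"]) <= 100_000

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            gprime_significance(pd.Series(np.ones(10)))

    def test_peak_localization_rate(self, yeast_map):
        """G' peak lands within one window of the causal marker in >= 90% of
        strong-QTL crosses."""
        rng = np.random.default_rng(5)
        markers = list(yeast_map["marker_id"])
        pos = yeast_map.set_index("marker_id")
        hit = 0
        n_rep = 20
        for rep in range(n_rep):
            cr = clsqtl.simulate_cross(yeast_map, 488, seed=4000 + rep)
            causal = markers[rng.integers(len(markers))]
            y = qtl_phenotype(cr, causal, 0.30, seed=5000 + rep)
            res = clsqtl.bsa_scan(cr.genotypes, yeast_map, y)
            peak = res.scan["g_prime"].idxmax()
            if (pos.loc[peak, "chrom"] == pos.loc[causal, "chrom"]
                    and abs(pos.loc[peak, "pos_bp"] - pos.loc[causal, "pos_bp"]) <= 100_000):
                hit += 1
        assert hit / n_rep >= 0.90


class TestRegionsAndGenes:
    def _scan(self, yeast_map, qvals):
        scan = pd.DataFrame(
            {"q_value": qvals, "g_prime": 1.0 - np.asarray(qvals)},
            index=pd.Index(yeast_map["marker_id"], name="marker_id"),
        )
        return scan

    def test_no_significant_markers(self, yeast_map):
        scan = self._scan(yeast_map, np.ones(len(yeast_map)))
        assert significant_regions(scan, yeast_map).empty

    def test_contiguous_run_merged_and_width(self, yeast_map):
        q = np.ones(len(yeast_map))
        q[2:5] = 0.01  # markers 3..5 of chromosome I
        scan = self._scan(yeast_map, q)
        out = significant_regions(scan, yeast_map)
        assert len(out) == 1
        grp = yeast_map.iloc[2:5]
        assert out.loc[0, "start_bp"] == grp["pos_bp"].iloc[0]
        assert out.loc[0, "end_bp"] == grp["pos_bp"].iloc[-1]
        assert out.loc[0, "width_kb"] == pytest.approx(
            (grp["pos_bp"].iloc[-1] - grp["pos_bp"].iloc[0]) / 1000
        )

    def test_gap_splits_runs(self, yeast_map):
        q = np.ones(len(yeast_map))
        q[2] = q[4] = 0.01  # two significant markers separated by one
        scan = self._scan(yeast_map, q)
        assert len(significant_regions(scan, yeast_map)) == 2

    def test_genes_in_interval_brute_force(self):
        ann = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(7)],
                "chrom": ["VI"] * 6 + ["VII"],
                "start_bp": [100, 2000, 5000, 9000, 13_000, 40_000, 5000],
                "end_bp": [900, 3000, 6000, 12_000, 14_000, 41_000, 6000],
            }
        )
        region = {"chrom": "VI", "start_bp": 2500, "end_bp": 13_000}
        genes, skipped = genes_in_interval(region, ann)
        # brute force: any-overlap, inclusive; the 13 kb start abuts region end
        expect = [
            r["gene"] for _, r in ann.iterrows()
            if r["chrom"] == "VI" and r["start_bp"] <= 13_000 and r["end_bp"] >= 2500
        ]
        assert genes == expect == ["G1", "G2", "G3", "G4"]
        assert skipped == 0

    def test_abutting_gene_included_and_malformed_skipped(self):
        ann = pd.DataFrame(
            {
                "gene": ["A", "B", None],
                "chrom": ["VI", "VI", "VI"],
                "start_bp": [13_000, 14_000, 1],
                "end_bp": [15_000, 16_000, 10],
            }
        )
        genes, skipped = genes_in_interval(
            {"chrom": "VI", "start_bp": 1000, "end_bp": 13_000}, ann
        )
        assert genes == ["A"]
        assert skipped == 1

    def test_empty_annotation(self):
        ann = pd.DataFrame(columns=["gene", "chrom", "start_bp", "end_bp"])
        genes, skipped = genes_in_interval(
            {"chrom": "VI", "start_bp": 1, "end_bp": 10}, ann
        )
        assert genes == [] and skipped == 0


class TestIsaBsaAgreement:
    def test_two_qtl_cross_peaks_colocalize(self, yeast_map):
        """Both mapping strategies place their peaks at the two causal loci."""
        cr = clsqtl.simulate_cross(yeast_map, 488, seed=99)
        rng = np.random.default_rng(100)
        g1 = cr.genotypes["VI_m005"].to_numpy()
        g2 = cr.genotypes["XV_m010"].to_numpy()
        y = pd.Series(2.0 + 0.9 * g1 + 0.9 * g2 + rng.normal(0, 0.6, 488),
                      index=cr.genotypes.index)
        pos = yeast_map.set_index("marker_id")
        isa = clsqtl.isa_scan(cr.genotypes, yeast_map, y, n_perm=200, seed=101)
        bsa = clsqtl.bsa_scan(cr.genotypes, yeast_map, y)
        for causal in ("VI_m005", "XV_m010"):
            chrom = pos.loc[causal, "chrom"]
            bp = pos.loc[causal, "pos_bp"]
            on_chrom = pos[pos["chrom"] == chrom].index
            isa_peak = isa.scan.loc[on_chrom, "lod"].idxmax()
            bsa_peak = bsa.scan.loc[on_chrom, "g_prime"].idxmax()
            assert abs(pos.loc[isa_peak, "pos_bp"] - bp) <= 100_000
            assert abs(pos.loc[bsa_peak, "pos_bp"] - bp) <= 100_000
            # and ISA declares both loci genome-wide significant
            assert isa.scan.loc[causal, "lod"] >= isa.threshold
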