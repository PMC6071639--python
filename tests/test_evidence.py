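"""Tests for the regression scans, cis windowing and evidence construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pgenmi.evidence as evd
from pgenmi.evidence import (
    AssayMatrix,
    CollinearityError,
    DegenerateFitError,
    FeatureTrack,
    GeneAnnotation,
    GenomicInterval,
    build_evidence,
    cis_feature_scan,
    cis_window,
    filter_peaks,
    genotype_pcs,
    partial_regression_pvalue,
    scan_cis_features,
    twas_scan,
)


class TestPartialRegression:
    def test_orthogonal_predictor(self):
        res = partial_regression_pvalue([1, -1, 1, -1], [1, 1, -1, -1])
        assert res.beta_hat == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0, abs=1e-12)

    def test_frisch_waugh_equivalence(self, rng):
        """The partial test equals simple regression on covariate residuals."""
        for _ in range(100):
            n = int(rng.integers(10, 40))
            k = int(rng.integers(0, 4))
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            C = rng.normal(size=(n, k))
            full = partial_regression_pvalue(y, x, C if k else None)
            # residualise both sides against [1, C] and regress without intercept
            Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
            yr = y - Q @ (Q.T @ y)
            xr = x - Q @ (Q.T @ x)
            beta = (xr @ yr) / (xr @ xr)
            resid = yr - beta * xr
            dof = n - (k + 2)
            se = np.sqrt((resid @ resid) / dof / (xr @ xr))
            t = beta / se
            assert full.t_stat == pytest.approx(t, abs=1e-8)
            assert full.beta_hat == pytest.approx(beta, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 60
        y = rng.normal(size=n)
        x = rng.normal(size=n)
        C = rng.normal(size=(n, 3))
        ours = partial_regression_pvalue(y, x, C)
        ref = sm.OLS(y, np.column_stack([np.ones(n), x, C])).fit()
        assert ours.t_stat == pytest.approx(ref.tvalues[1], abs=1e-10)
        assert ours.pvalue == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_degenerate_fit_detected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateFitError):
            partial_regression_pvalue(2 * x + 1, x)

    def test_collinear_column_named(self, rng):
        n = 20
        x = rng.normal(size=n)
        with pytest.raises(CollinearityError, match="covariate"):
            partial_regression_pvalue(rng.normal(size=n), x, np.column_stack([x]))


class TestTwasScan:
    def test_null_pvalues_uniform(self, rng):
        from scipy.stats import kstest

        n, G = 150, 2000
        expr = AssayMatrix(
            pd.DataFrame(
                rng.normal(size=(G, n)),
                index=[f"g{i}" for i in range(G)],
                columns=[f"i{j}" for j in range(n)],
            )
        )
        phenotype = rng.permutation(rng.normal(size=n))
        pvec = twas_scan(expr, phenotype)
        assert kstest(pvec.values, "uniform").pvalue > 0.01

    def test_planted_gene_attains_min_p(self, rng):
        n, G = 100, 50
        E = rng.normal(size=(G, n))
        y = E[7] + rng.normal(scale=0.1, size=n)
        expr = AssayMatrix(
            pd.DataFrame(E, index=[f"g{i}" for i in range(G)],
                         columns=[f"i{j}" for j in range(n)])
        )
        pvec = twas_scan(expr, y)
        assert pvec.gene_ids[np.argmin(pvec.values)] == "g7"

    def test_phenotype_as_covariate_rejected(self, rng):
        n = 30
        y = rng.normal(size=n)
        expr = AssayMatrix(
            pd.DataFrame(rng.normal(size=(5, n)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"i{j}" for j in range(n)])
        )
        with pytest.raises(DegenerateFitError):
            twas_scan(expr, y, covariates=y[:, None])

    def test_matches_per_gene_ols(self, rng):
        n, G = 40, 10
        E = rng.normal(size=(G, n))
        y = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        expr = AssayMatrix(
            pd.DataFrame(E, index=[f"g{i}" for i in range(G)],
                         columns=[f"i{j}" for j in range(n)])
        )
        _, table = twas_scan(expr, y, C, return_table=True)
        for row in table.itertuples(index=False):
            gi = int(row.gene_id[1:])
            ref = partial_regression_pvalue(y, E[gi], C)
            assert row.t == pytest.approx(ref.t_stat, abs=1e-8)
            assert row.pvalue == pytest.approx(ref.pvalue, abs=1e-8)

    def test_individual_order_invariance(self, rng):
        n, G = 50, 8
        E = rng.normal(size=(G, n))
        y = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        ids = [f"i{j}" for j in range(n)]
        expr = AssayMatrix(pd.DataFrame(E, index=[f"g{i}" for i in range(G)], columns=ids))
        perm = rng.permutation(n)
        expr_p = AssayMatrix(
            pd.DataFrame(E[:, perm], index=expr.row_ids, columns=[ids[j] for j in perm])
        )
        a = twas_scan(expr, y, C)
        b = twas_scan(expr_p, y[perm], C[perm])
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestCisWindow:
    @pytest.mark.parametrize(
        "tss, strand, expected",
        [
            (100_000, "+", (50_000, 100_001)),
            (100_000, "-", (100_000, 150_001)),
            (20_000, "+", (0, 20_001)),
        ],
    )
    def test_stated_convention(self, tss, strand, expected):
        win = cis_window(GeneAnnotation("g", "chr1", tss, strand), span=50_000)
        assert (win.start, win.end) == expected

    def test_exclude_tss(self):
        win = cis_window(GeneAnnotation("g", "chr1", 1000, "+"), span=100,
                         include_tss=False)
        assert (win.start, win.end) == (900, 1000)

    @given(st.integers(0, 10**6), st.sampled_from("+-"), st.integers(1, 10**5))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_halfopen_boundaries(self, tss, strand, span):
        """TSS base included; a feature at distance span included; span+1 not."""
        win = cis_window(GeneAnnotation("g", "chr1", tss, strand), span=span)
        assert win.contains(tss)
        edge = tss - span if strand == "+" else tss + span
        beyond = tss - span - 1 if strand == "+" else tss + span + 1
        if edge >= 0:
            assert win.contains(edge)
        if beyond >= 0:
            assert not win.contains(beyond)


class TestFilterPeaks:
    def test_overlap_removed_abutment_kept(self):
        peaks = {"TF1": [GenomicInterval("chr1", 100, 200)]}
        assert filter_peaks(peaks, [GenomicInterval("chr1", 150, 160)])["TF1"] == []
        kept = filter_peaks(peaks, [GenomicInterval("chr1", 200, 300)])["TF1"]
        assert len(kept) == 1

    def test_empty_exclusion_is_identity(self):
        peaks = {"TF1": [GenomicInterval("chr1", 100, 200)],
                 "TF2": [GenomicInterval("chr2", 5, 10)]}
        assert filter_peaks(peaks, []) == {k: list(v) for k, v in peaks.items()}


def _toy_features(rows, values, individuals):
    table = pd.DataFrame(rows, columns=["feature_id", "chrom", "pos", "kind"]
                         ).set_index("feature_id")
    vals = pd.DataFrame(values, index=table.index, columns=individuals)
    return FeatureTrack(table, vals)


class TestCisFeatureScan:
    def test_windowing_and_planted_eqtl(self, rng):
        n = 200
        inds = [f"i{j}" for j in range(n)]
        gene = GeneAnnotation("g1", "chr1", 100_000, "+")
        dosages = rng.binomial(2, 0.3, size=(3, n)).astype(float)
        rows = [
            ("s_in_causal", "chr1", 80_000, "SNP"),
            ("s_in_null", "chr1", 90_000, "SNP"),
            ("s_out", "chr1", 160_000, "SNP"),
        ]
        feats = _toy_features(rows, dosages, inds)
        expr = 0.8 * dosages[0] + rng.normal(scale=0.3, size=n)
        results = cis_feature_scan(gene, feats, expr)
        ids = [r.unit_id for r in results]
        assert "s_out" not in ids
        best = min(results, key=lambda r: r.pvalue)
        assert best.unit_id == "s_in_causal"

    def test_monomorphic_feature_skipped(self, rng):
        n = 30
        inds = [f"i{j}" for j in range(n)]
        gene = GeneAnnotation("g1", "chr1", 1000, "+")
        vals = np.vstack([np.ones(n), rng.binomial(2, 0.4, size=n)]).astype(float)
        feats = _toy_features(
            [("mono", "chr1", 500, "SNP"), ("poly", "chr1", 600, "SNP")], vals, inds
        )
        results = cis_feature_scan(gene, feats, rng.normal(size=n))
        assert [r.unit_id for r in results] == ["poly"]

    def test_vectorised_scan_matches_scalar(self, small_population):
        _, data, _ = small_population
        C = data.covariates.values.T
        genes = data.genes[:10]
        scans = scan_cis_features(genes, data.features, data.expression, C)
        for gene in genes:
            scalar = cis_feature_scan(
                gene, data.features, data.expression.row(gene.gene_id), C
            )
            sub = scans[scans["gene_id"] == gene.gene_id]
            assert set(sub["feature_id"]) == {r.unit_id for r in scalar}
            lookup = {r.unit_id: r for r in scalar}
            for row in sub.itertuples(index=False):
                ref = lookup[row.feature_id]
                assert row.t == pytest.approx(ref.t_stat, abs=1e-8)
                assert row.pvalue == pytest.approx(ref.pvalue, abs=1e-8)


class TestBuildEvidence:
    @staticmethod
    def _scan_df(rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "feature_id", "kind", "chrom", "pos", "pvalue"],
        )

    def _genes(self):
        return [GeneAnnotation("g1", "chr1", 100_000, "+")]

    def test_threshold_rule(self):
        peaks = {"TF1": [GenomicInterval("chr1", 79_000, 81_000)]}
        scans = self._scan_df([("g1", "s1", "SNP", "chr1", 80_000, 0.03)])
        mats, _ = build_evidence(self._genes(), scans, peaks)
        assert mats["TF1"].entries[0, 0] == 1
        scans = self._scan_df([("g1", "s1", "SNP", "chr1", 80_000, 0.06)])
        mats, _ = build_evidence(self._genes(), scans, peaks)
        assert mats["TF1"].entries[0, 0] == 0

    def test_min_rule_over_in_peak_features(self):
        peaks = {"TF1": [GenomicInterval("chr1", 79_000, 81_000)]}
        scans = self._scan_df([
            ("g1", "s1", "SNP", "chr1", 80_000, 0.2),
            ("g1", "s2", "SNP", "chr1", 80_500, 0.01),
            ("g1", "s3", "SNP", "chr1", 95_000, 0.001),  # outside peak
        ])
        mats, details = build_evidence(self._genes(), scans, peaks)
        assert mats["TF1"].entries[0, 0] == 1
        row = details[(details.tf == "TF1") & (details.evidence == "eQTL")].iloc[0]
        assert row.feature_id == "s2"
        assert row.min_pvalue == pytest.approx(0.01)

    def test_gene_without_in_peak_feature_gets_zero(self):
        peaks = {"TF1": [GenomicInterval("chr2", 0, 100)]}
        scans = self._scan_df([("g1", "s1", "SNP", "chr1", 80_000, 0.001)])
        mats, _ = build_evidence(self._genes(), scans, peaks)
        assert mats["TF1"].entries.sum() == 0

    def test_zero_peak_tf_flagged_all_zero(self):
        scans = self._scan_df([("g1", "s1", "SNP", "chr1", 80_000, 0.001)])
        mats, _ = build_evidence(self._genes(), scans, {"TFempty": []})
        assert mats["TFempty"].entries.sum() == 0

    def test_threshold_monotonicity(self, small_population, rng):
        _, data, _ = small_population
        C = data.covariates.values.T
        scans = scan_cis_features(data.genes, data.features, data.expression, C)
        lo, _ = build_evidence(data.genes, scans, data.peaks_by_tf, threshold=0.01)
        hi, _ = build_evidence(data.genes, scans, data.peaks_by_tf, threshold=0.10)
        for tf in lo:
            assert np.all(hi[tf].entries >= lo[tf].entries)

    def test_global_best_variant_mode(self):
        # global best SNP (s3, p=0.001) lies outside the peak -> no evidence,
        # although an in-peak SNP is significant on its own
        peaks = {"TF1": [GenomicInterval("chr1", 79_000, 81_000)]}
        scans = self._scan_df([
            ("g1", "s2", "SNP", "chr1", 80_500, 0.01),
            ("g1", "s3", "SNP", "chr1", 95_000, 0.001),
        ])
        mats, _ = build_evidence(self._genes(), scans, peaks, best_variant="global")
        assert mats["TF1"].entries[0, 0] == 0


class TestGenotypePCs:
    def test_separates_two_subpopulations(self, rng):
        n_per, n_var = 40, 200
        f1 = rng.uniform(0.05, 0.3, size=n_var)
        f2 = np.clip(f1 + rng.uniform(0.2, 0.4, size=n_var), 0, 0.95)
        pop1 = rng.binomial(2, f1[:, None], size=(n_var, n_per))
        pop2 = rng.binomial(2, f2[:, None], size=(n_var, n_per))
        G = np.hstack([pop1, pop2]).astype(float)
        pcs = genotype_pcs(G, 2)
        a, b = pcs[:n_per, 0], pcs[n_per:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max())  # no overlap on PC1

    def test_orthogonal_columns_and_deterministic_sign(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 30)).astype(float)
        pcs = genotype_pcs(G, 3)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-8)
        np.testing.assert_allclose(pcs, genotype_pcs(G.copy(), 3))

    def test_k_zero_and_k_too_large(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 10)).astype(float)
        assert genotype_pcs(G, 0).shape == (10, 0)
        with pytest.raises(ValueError):
            genotype_pcs(G, 10)


class TestEndToEndNullEvidence:
    def test_null_rate_tracks_threshold(self, rng):
        """With no planted effects the r = 1 rate is ~ the evidence threshold."""
        from pgenmi.simulate import PopulationSimConfig, simulate_population

        cfg = PopulationSimConfig(
            n_individuals=100, n_genes=400, n_mediator_genes=1,
            eqtl_beta=0.0, eqtm_beta=0.0, twas_beta=0.0,
            n_decoy_tfs=2, seed=21,
        )
        data, _ = simulate_population(cfg)
        C = data.covariates.values.T
        scans = scan_cis_features(data.genes, data.features, data.expression, C)
        mats, details = build_evidence(data.genes, scans, data.peaks_by_tf)
        rate = details["r"].mean()
        n = len(details)
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < 4 * se
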