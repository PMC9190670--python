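"""Probe filters, gene summarization, batch correction and PCA QC."""

import numpy as np
import pandas as pd
import pytest

import pedmeth.preprocess as pp
from pedmeth.batch import ComBatCorrector, batch_correct
from pedmeth.transforms import beta_to_m, matrix_to_m
from pedmeth.types import FilterReport, MethylationMatrix

from .conftest import make_matrix, make_metadata


def annotation(rows):
    return pd.DataFrame(rows, columns=["probe_id", "gene_symbol", "tss_distance_bp"])


class TestPromoterFilter:
    @pytest.mark.parametrize(
        "distance, kept", [(250, True), (300, True), (301, False), (350, False)]
    )
    def test_window_boundary_inclusive(self, distance, kept):
        ann = annotation([("cg1", "G1", distance)])
        out, report = pp.filter_promoter_probes(ann)
        assert (len(out) == 1) is kept
        assert report.n_features_in == 1

    def test_report_tallies_pairs(self):
        ann = annotation([("cg1", "G1", 10), ("cg1", "G2", 500), ("cg2", "G1", 299)])
        out, report = pp.filter_promoter_probes(ann)
        assert report.n_features_out == 2
        assert report.removed_ids == ["cg1|G2"]


class TestGeneSummarization:
    def test_mean_of_probes(self):
        m = make_matrix([[0.2], [0.4], [0.9]], prefix="cg")
        ann = annotation([("cg0", "G1", 0), ("cg1", "G1", 0), ("cg2", "G2", 0)])
        gene = pp.summarize_gene_level(m, ann)
        assert gene.values.loc["G1"].iloc[0] == pytest.approx(0.3)
        assert gene.values.loc["G2"].iloc[0] == pytest.approx(0.9)

    def test_three_probe_mean(self):
        m = make_matrix([[0.1], [0.2], [0.6]], prefix="cg")
        ann = annotation([(f"cg{i}", "G1", 0) for i in range(3)])
        assert pp.summarize_gene_level(m, ann).values.loc["G1"].iloc[0] == pytest.approx(0.3)

    def test_multi_gene_probe_counts_for_each(self):
        m = make_matrix([[0.2], [0.4]], prefix="cg")
        ann = annotation([("cg0", "G1", 0), ("cg0", "G2", 0), ("cg1", "G2", 0)])
        gene = pp.summarize_gene_level(m, ann)
        assert gene.values.loc["G1"].iloc[0] == pytest.approx(0.2)
        assert gene.values.loc["G2"].iloc[0] == pytest.approx(0.3)

    def test_commutes_with_sample_subsetting(self, small_normals):
        ann, _ = pp.filter_promoter_probes(small_normals.annotation)
        m = list(small_normals.matrices.values())[0]
        subset = m.subset_samples(m.sample_ids[:5])
        a = pp.summarize_gene_level(subset, ann).values
        b = pp.summarize_gene_level(m, ann).values.loc[:, m.sample_ids[:5]]
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestInvariantFilter:
    def test_constant_low_probe_removed_and_straddler_kept(self):
        m1 = make_matrix([[0.05, 0.1, 0.15], [0.1, 0.1, 0.7], [0.19, 0.21, 0.1]], prefix="cg")
        report = pp.filter_invariant_category_probes([m1])
        assert report.removed_ids == ["cg0"]
        assert report.n_features_out == 2

    def test_category_must_match_across_matrices(self):
        low = make_matrix([[0.1, 0.1]], prefix="cg")
        high = make_matrix([[0.9, 0.9]], prefix="cg")
        report = pp.filter_invariant_category_probes([low, high])
        assert report.removed_ids == []


class TestExpressionCorrelationFilter:
    def _setup(self, rng, n_probes=40, n_samples=20):
        meth = make_matrix(rng.normal(0, 1, (n_probes, n_samples)), scale="M", prefix="cg")
        ann = annotation([(f"cg{i}", f"G{i}", 0) for i in range(n_probes)])
        return meth, ann

    def test_perfectly_anticorrelated_probe_retained(self, rng):
        meth, ann = self._setup(rng)
        expr = pd.DataFrame(
            -meth.values.to_numpy(), index=[f"G{i}" for i in range(40)],
            columns=meth.sample_ids,
        )
        report = pp.filter_expression_correlated_probes(meth, expr, ann)
        assert "cg0" not in report.removed_ids

    def test_constant_expression_removed_as_degenerate(self, rng):
        meth, ann = self._setup(rng)
        expr_vals = -meth.values.to_numpy().copy()
        expr_vals[3] = 1.0
        expr = pd.DataFrame(expr_vals, index=[f"G{i}" for i in range(40)],
                            columns=meth.sample_ids)
        report = pp.filter_expression_correlated_probes(meth, expr, ann)
        assert "cg3" in report.removed_ids
        assert report.extra["n_degenerate"] == 1

    def test_missing_expression_counted_separately(self, rng):
        meth, ann = self._setup(rng, n_probes=5)
        expr = pd.DataFrame(
            -meth.values.to_numpy()[:4], index=[f"G{i}" for i in range(4)],
            columns=meth.sample_ids,
        )
        report = pp.filter_expression_correlated_probes(meth, expr, ann)
        assert report.extra["n_no_expression"] == 1

    def test_null_probes_retained_at_about_alpha_without_adjustment(self, rng):
        # with BH at alpha=0.05 over independent nulls, the retained
        # fraction must be well below the unadjusted 5% type-I rate
        meth, ann = self._setup(rng, n_probes=2000)
        expr = pd.DataFrame(
            rng.normal(0, 1, (2000, 20)), index=[f"G{i}" for i in range(2000)],
            columns=meth.sample_ids,
        )
        report = pp.filter_expression_correlated_probes(meth, expr, ann)
        retained = report.n_features_out
        assert retained / 2000 < 0.05


class TestCrossNormalFilter:
    def test_shifted_probe_excluded_identical_kept(self, rng):
        n = 20
        base = rng.normal(0, 0.3, (30, n))
        a = base.copy()
        b = base + rng.normal(0, 0.3, (30, n))
        a[0] += 0.0
        b[0] = a[0] + 4.0  # planted 4 M-unit shift, tiny variance
        b[1] = a[1]  # identical probe
        ma = make_matrix(a, scale="M", prefix="cg", samples=[f"a{i}" for i in range(n)])
        mb = make_matrix(b, scale="M", prefix="cg", samples=[f"b{i}" for i in range(n)])
        meta = pd.concat(
            [
                make_metadata(ma.sample_ids, dataset_ids=["da"] * n),
                make_metadata(mb.sample_ids, dataset_ids=["db"] * n),
            ]
        )
        report = pp.filter_cross_normal_divergent_probes({"da": ma, "db": mb}, meta)
        assert "cg0" in report.removed_ids
        assert "cg1" not in report.removed_ids

    def test_large_shift_with_huge_variance_kept(self, rng):
        # same mean difference but variance so large the test cannot call it
        n = 6
        a = rng.normal(0, 8.0, (40, n))
        b = rng.normal(2.0, 8.0, (40, n))
        ma = make_matrix(a, scale="M", prefix="cg", samples=[f"a{i}" for i in range(n)])
        mb = make_matrix(b, scale="M", prefix="cg", samples=[f"b{i}" for i in range(n)])
        meta = pd.concat(
            [
                make_metadata(ma.sample_ids, dataset_ids=["da"] * n),
                make_metadata(mb.sample_ids, dataset_ids=["db"] * n),
            ]
        )
        report = pp.filter_cross_normal_divergent_probes({"da": ma, "db": mb}, meta)
        assert len(report.removed_ids) == 0


class TestBatchCorrection:
    def _two_batch(self, rng, shift=0.5, n_per_batch=50, n_features=80):
        base = rng.normal(0, 1, (n_features, 2 * n_per_batch))
        base[:, n_per_batch:] += shift
        betas = 1 / (1 + np.exp(-base))
        samples = [f"s{i}" for i in range(2 * n_per_batch)]
        matrix = make_matrix(betas, samples=samples)
        meta = make_metadata(
            samples, dataset_ids=["b1"] * n_per_batch + ["b2"] * n_per_batch
        )
        return matrix, meta

    def test_planted_batch_shift_removed(self, rng):
        matrix, meta = self._two_batch(rng)
        m_in = matrix_to_m(matrix).values
        diff_before = m_in.iloc[:, :50].mean(axis=1) - m_in.iloc[:, 50:].mean(axis=1)
        vals = matrix_to_m(batch_correct(matrix, meta)).values
        diff_after = vals.iloc[:, :50].mean(axis=1) - vals.iloc[:, 50:].mean(axis=1)
        # the systematic 0.5 M-unit shift is gone; only EB-shrinkage noise
        # (order 1/sqrt(n)) remains per feature
        assert abs(diff_before.mean()) > 0.4
        assert abs(diff_after.mean()) < 0.05
        assert diff_after.abs().mean() < 0.5 * abs(diff_before.mean())

    def test_output_betas_stay_in_unit_interval(self, rng):
        matrix, meta = self._two_batch(rng)
        corrected = batch_correct(matrix, meta)
        arr = corrected.values.to_numpy()
        assert (arr > 0).all() and (arr < 1).all()

    def test_disabled_correction_is_identity(self, rng):
        matrix, meta = self._two_batch(rng)
        out = batch_correct(matrix, meta, enabled=False)
        assert out is matrix

    def test_balanced_batches_preserve_grand_mean_on_m_scale(self, rng):
        # shrinkage leaves an O(1/n) remainder, far below the batch shift
        matrix, meta = self._two_batch(rng)
        m_in = matrix_to_m(matrix).values.to_numpy()
        m_out = matrix_to_m(batch_correct(matrix, meta)).values.to_numpy()
        assert np.abs(m_in.mean(axis=1) - m_out.mean(axis=1)).max() < 1e-2

    def test_singleton_batch_is_hard_error(self, rng):
        X = rng.normal(0, 1, (10, 5))
        with pytest.raises(ValueError, match="fewer than 2"):
            ComBatCorrector().fit_transform(X, batch=["a", "a", "a", "a", "b"])


class TestPcaQc:
    def test_batch_clusters_separate_then_collapse(self, rng):
        n = 30
        base = rng.normal(0, 0.2, (100, 2 * n))
        base[:, n:] += 2.0
        betas = 1 / (1 + np.exp(-base))
        samples = [f"s{i}" for i in range(2 * n)]
        matrix = make_matrix(betas, samples=samples)
        meta = make_metadata(samples, dataset_ids=["b1"] * n + ["b2"] * n)
        before = pp.batch_separation_statistic(pp.pca_qc(matrix, meta))
        corrected = batch_correct(matrix, meta)
        after = pp.batch_separation_statistic(pp.pca_qc(corrected, meta))
        assert before > 1.0
        assert after < before

    def test_constant_matrix_gives_zero_pcs(self):
        matrix = make_matrix(np.full((10, 4), 0.5))
        meta = make_metadata(matrix.sample_ids)
        table = pp.pca_qc(matrix, meta)
        assert np.allclose(table[["PC1", "PC2"]].to_numpy(), 0)


class TestFilterReports:
    def test_report_consistency_enforced(self):
        with pytest.raises(ValueError, match="n_out"):
            FilterReport("bad", 10, 8, removed_ids=["a"])

    def test_chain_check(self):
        r1 = FilterReport("s1", 10, 8, removed_ids=["a", "b"])
        r2 = FilterReport("s2", 8, 8, removed_ids=[])
        pp.chain_reports([r1, r2])
        r3 = FilterReport("s3", 7, 7, removed_ids=[])
        with pytest.raises(ValueError, match="chain mismatch"):
            pp.chain_reports([r1, r3])
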