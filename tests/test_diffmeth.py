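"""Differential testing: BH oracle, moderated t behaviour, calibration, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pedmeth.diffmeth as dm

from .conftest import make_matrix, make_metadata


def bh_bruteforce(p):
    """Independent step-up oracle: adj_i = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank_pos in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adj_sorted[rank_pos] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBhAdjust:
    def test_worked_examples(self):
        assert dm.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert dm.bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])
        assert dm.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(dm.bh_adjust(p), bh_bruteforce(p), atol=0, rtol=0)

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(0, 1, 200)
        adj = dm.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestVariancePrior:
    def test_prior_recovers_planted_hyperparameters(self, rng):
        d0_true, s0_true, df = 8.0, 0.25, 18
        n = 20000
        true_var = s0_true * d0_true / stats.chi2.rvs(d0_true, size=n, random_state=1)
        s2 = true_var * stats.chi2.rvs(df, size=n, random_state=2) / df
        d0, s0 = dm.fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.05)

    def test_equal_variances_give_infinite_prior_df(self, rng):
        s2 = np.full(500, 0.3)
        d0, s0 = dm.fit_variance_prior(s2, 10)
        assert np.isinf(d0)
        assert s0 == pytest.approx(0.3, rel=0.2)


class TestModeratedTTest:
    def _fit(self, X, group, **kw):
        est = dm.ModeratedTTestDM(**kw)
        return est.fit(X, group)

    def test_unmoderated_equals_ols_t(self, rng):
        X = rng.normal(0, 1, (50, 16))
        group = np.array([1] * 8 + [0] * 8)
        est = self._fit(X, group, moderated=False)
        for i in range(50):
            t, p = stats.ttest_ind(X[i, :8], X[i, 8:], equal_var=True)
            assert est.results_.loc[i, "t_stat"] == pytest.approx(t, abs=1e-10)
            assert est.results_.loc[i, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_moderation_with_zero_prior_df_matches_ols(self, rng):
        # d0 = 0 limit: squeeze is a no-op
        X = rng.normal(0, 1, (30, 12))
        group = np.array([1] * 6 + [0] * 6)
        s2 = rng.uniform(0.1, 2, 30)
        assert np.allclose(dm.squeeze_variances(s2, 10, 0.0, 1.0), s2)

    def test_null_p_values_uniform(self, rng):
        X = rng.normal(0, 0.5, (5000, 40))
        group = np.array([1] * 20 + [0] * 20)
        est = self._fit(X, group)
        ks = stats.kstest(est.results_["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_shift_detected(self, rng):
        X = rng.normal(0, 0.5, (500, 40))
        X[:50, :20] += 4.0
        group = np.array([1] * 20 + [0] * 20)
        est = self._fit(X, group)
        sig = est.results_["significant"].to_numpy()
        assert sig[:50].mean() >= 0.95
        assert sig[50:].sum() == 0

    def test_zero_residual_variance_handled_by_moderation(self, rng):
        X = rng.normal(0, 0.5, (100, 20))
        X[0] = 1.0  # zero residual variance feature
        group = np.array([1] * 10 + [0] * 10)
        est = self._fit(X, group)
        assert np.isfinite(est.results_["t_stat"]).all()

    def test_group_smaller_than_two_rejected(self, rng):
        X = rng.normal(0, 1, (5, 4))
        with pytest.raises(ValueError, match="fewer than 2"):
            self._fit(X, np.array([1, 0, 0, 0]))


class TestSexCovariate:
    def test_pure_sex_effect_not_attributed_to_group(self, rng):
        # group correlated with (but not identical to) sex; true effect is sex-only
        n = 40
        sex = np.array([1] * 20 + [0] * 20)
        group = sex.copy()
        flip = rng.choice(n, size=8, replace=False)
        group[flip] = 1 - group[flip]
        X = rng.normal(0, 0.5, (300, n)) + 2.0 * sex
        est = dm.ModeratedTTestDM().fit(X, group, sex=sex)
        coefs = est.results_["log2_fc"].to_numpy()
        # no systematic group effect: |mean coefficient| within 3 SEs of zero
        assert np.abs(coefs.mean()) < 3 * coefs.std(ddof=1) / np.sqrt(len(coefs))
        assert est.results_["significant"].sum() == 0

    def test_fully_confounded_design_is_error(self, rng):
        X = rng.normal(0, 1, (10, 8))
        group = np.array([1] * 4 + [0] * 4)
        with pytest.raises(ValueError, match="rank deficient"):
            dm.ModeratedTTestDM().fit(X, group, sex=group)

    def test_unknown_sex_samples_dropped(self, rng):
        samples = [f"s{i}" for i in range(12)]
        meta = make_metadata(
            samples,
            sexes=["male"] * 5 + ["female"] * 5 + ["unknown"] * 2,
        )
        m = make_matrix(rng.normal(0, 1, (20, 12)), scale="M", samples=samples)
        res = dm.fit_linear_dm(m, meta, samples[:6], samples[6:])
        assert len(res.table) == 20


@pytest.fixture(scope="module")
def study():
    rng = np.random.default_rng(11)
    n_types, n_per, n_norm, n_feat = 3, 15, 20, 60
    normal = rng.normal(0, 0.5, (n_feat, n_norm))
    tumors = {}
    truth_type = "typeB"
    for i, t in enumerate(["typeA", "typeB", "typeC"]):
        vals = rng.normal(0, 0.5, (n_feat, n_per))
        if t == truth_type:
            vals[0] += 4.0  # feature f0 shifted only in typeB
        vals[1] += 4.0  # feature f1 shifted in every type
        tumors[t] = make_matrix(
            vals, scale="M", samples=[f"{t}_s{j}" for j in range(n_per)]
        )
    normal_m = make_matrix(normal, scale="M", samples=[f"n{j}" for j in range(n_norm)])
    meta = pd.concat(
        [make_metadata(normal_m.sample_ids, dataset_ids=["norm"] * n_norm)]
        + [
            make_metadata(
                m.sample_ids,
                dataset_ids=[t] * n_per,
                condition="tumor",
                tumor_type="wilms",
            )
            for t, m in tumors.items()
        ]
    )
    return tumors, normal_m, meta


class TestContrastOrchestration:
    def test_type_specific_flagging(self, study):
        tumors, normal_m, meta = study
        results, flags = dm.tumor_vs_normal_dm(tumors, normal_m, meta)
        assert flags["f0"] == 1
        assert results["typeB"].table.set_index("feature_id").loc["f0", "significant"]
        assert not results["typeA"].table.set_index("feature_id").loc["f0", "significant"]
        assert flags["f1"] == 3  # multi-type flag count

    def test_pairwise_contrast_count_and_separating_feature(self, study):
        tumors, _, meta = study
        results, summary = dm.pairwise_tumor_dm(tumors, meta)
        assert len(results) == 3  # C(3,2)
        summ = summary.set_index("feature_id")
        assert bool(summ.loc["f0", "significant_any_pair"])
        # f0 separates typeB from the others -> significant in 2 pairs
        n_sig_pairs = sum(
            res.table.set_index("feature_id").loc["f0", "significant"]
            for res in results.values()
        )
        assert n_sig_pairs == 2

    def test_volcano_transform(self, study):
        tumors, normal_m, meta = study
        results, _ = dm.tumor_vs_normal_dm(tumors, normal_m, meta)
        table = dm.volcano_table(results["typeA"])
        fdr = results["typeA"].table["fdr"].to_numpy()
        assert np.allclose(table["neg_log10_fdr"], -np.log10(fdr))
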