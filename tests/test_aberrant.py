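"""Z-score aberration calling, proportions and class-stratified rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pedmeth.aberrant as ab
from pedmeth.types import CancerGeneEntry, EventMatrix

from .conftest import make_matrix


class TestNormalReference:
    def test_hand_arithmetic(self):
        m = make_matrix(np.array([[0.1, 0.2, 0.3]]), prefix="g")
        ref = ab.build_normal_reference(m)
        assert ref.loc["g0", "mean"] == pytest.approx(0.2)
        assert ref.loc["g0", "sd"] == pytest.approx(0.1)

    def test_constant_gene_flagged_never_called(self):
        m = make_matrix(np.array([[0.5, 0.5, 0.5], [0.1, 0.2, 0.3]]), prefix="g")
        caller = ab.AberrationCaller().fit(m)
        assert not caller.reference_.loc["g0", "callable"]
        tumors = make_matrix(np.array([[0.99], [0.2]]), prefix="g", samples=["t0"])
        states = caller.predict(tumors)
        assert states.loc["g0", "t0"] == "none"

    def test_single_normal_sample_is_error(self):
        m = make_matrix(np.array([[0.5]]), prefix="g")
        with pytest.raises(ValueError, match=">= 2 normal samples"):
            ab.build_normal_reference(m)


class TestCallAberrant:
    @pytest.mark.parametrize(
        "value, expected_z, expected_state",
        [(0.46, 3.2, "hyper"), (0.44, 2.8, "none"), (0.14, -3.2, "hypo")],
    )
    def test_threshold_rule(self, value, expected_z, expected_state):
        res = ab.call_aberrant(value, mean=0.30, sd=0.05)
        assert res["z"] == pytest.approx(expected_z)
        assert res["state"] == expected_state

    def test_exactly_three_sd_is_not_aberrant(self):
        # exact binary floats so z is exactly 3.0 (strict inequality rule)
        assert ab.call_aberrant(1.0, 0.25, 0.25)["state"] == "none"

    def test_hyper_and_hypo_mutually_exclusive(self, rng):
        normal = make_matrix(rng.uniform(0.3, 0.7, (50, 20)), prefix="g")
        tumors = make_matrix(rng.uniform(0, 1, (50, 10)), prefix="g")
        states = ab.AberrationCaller().fit(normal).predict(tumors)
        hyper, hypo = ab.states_to_event_matrices(states)
        assert not (hyper.hits & hypo.hits).any().any()


class TestProportions:
    def test_counting(self):
        states = pd.DataFrame(
            {"t0": ["hypo"] * 40 + ["none"] * 60},
            index=[f"g{i}" for i in range(100)],
        )
        props = ab.tumor_aberration_proportions(states)
        assert props.loc[0, "frac_hypo"] == pytest.approx(0.40)
        assert props.loc[0, "frac_hyper"] == 0.0

    def test_all_flagged(self):
        states = pd.DataFrame({"t0": ["hyper"] * 10}, index=[f"g{i}" for i in range(10)])
        props = ab.tumor_aberration_proportions(states)
        assert props.loc[0, "frac_hyper"] == 1.0

    def test_normal_like_tumor_matches_gaussian_tail(self, rng):
        # tumor drawn from the reference distribution itself: expected
        # hyper fraction ~ P(Z > 3) with sampling error from finite n
        n_genes, n_normal = 20000, 200
        normal = make_matrix(
            np.clip(0.5 + 0.05 * rng.standard_normal((n_genes, n_normal)), 0, 1), prefix="g"
        )
        tumor = make_matrix(
            np.clip(0.5 + 0.05 * rng.standard_normal((n_genes, 1)), 0, 1), prefix="g"
        )
        props = ab.tumor_aberration_proportions(ab.AberrationCaller().fit(normal).predict(tumor))
        tail = float(stats.norm.sf(3))
        assert props.loc[0, "frac_hyper"] == pytest.approx(tail, abs=4 * np.sqrt(tail / n_genes))


class TestClassRates:
    def _classes(self):
        return [
            CancerGeneEntry("g0", "oncogene", 1),
            CancerGeneEntry("g1", "oncogene", 1),
            CancerGeneEntry("g2", "tsg", 1),
        ]

    def test_rate_counting(self):
        states = pd.DataFrame(
            "none",
            index=[f"g{i}" for i in range(4)],
            columns=[f"t{j}" for j in range(5)],
        )
        states.iloc[0, :2] = "hyper"
        states.iloc[1, 0] = "hyper"
        mut = EventMatrix(
            pd.DataFrame(False, index=states.index, columns=states.columns), "mutation"
        )
        table = ab.class_stratified_rates({"wilms": states}, mut, self._classes())
        row = table.set_index(["event_type", "gene_class"])
        assert row.loc[("hyper", "oncogene"), "rate"] == pytest.approx(3 / 10)
        assert row.loc[("hyper", "tsg"), "rate"] == 0.0
        assert row.loc[("mutation", "other"), "rate"] == 0.0

    def test_rates_recompute_from_raw_matrices(self, rng):
        genes = [f"g{i}" for i in range(30)]
        tumors = [f"t{j}" for j in range(12)]
        states = pd.DataFrame(
            rng.choice(["hyper", "hypo", "none"], p=[0.1, 0.2, 0.7], size=(30, 12)),
            index=genes,
            columns=tumors,
        )
        mut = EventMatrix(
            pd.DataFrame(rng.random((30, 12)) < 0.1, index=genes, columns=tumors),
            "mutation",
        )
        classes = [CancerGeneEntry(g, "oncogene", 1) for g in genes[:5]] + [
            CancerGeneEntry(g, "tsg", 1) for g in genes[5:12]
        ]
        table = ab.class_stratified_rates({"x": states}, mut, classes)
        for _, r in table.iterrows():
            cls_genes = {
                "oncogene": genes[:5],
                "tsg": genes[5:12],
                "other": genes[12:],
            }[r["gene_class"]]
            if r["event_type"] == "mutation":
                expected = mut.hits.loc[cls_genes].to_numpy().mean()
            else:
                expected = (states.loc[cls_genes] == r["event_type"]).to_numpy().mean()
            assert r["rate"] == pytest.approx(expected)

    def test_empty_class_reported_missing(self):
        states = pd.DataFrame(
            "none", index=["g0"], columns=["t0", "t1"]
        )
        mut = EventMatrix(pd.DataFrame(False, index=["g0"], columns=["t0", "t1"]), "mutation")
        table = ab.class_stratified_rates({"x": states}, mut, [])
        row = table.set_index(["event_type", "gene_class"])
        assert np.isnan(row.loc[("hyper", "oncogene"), "rate"])

    def test_planted_class_enrichment_recovered(self, rng):
        # oncogenes hypermethylated at twice the background rate
        genes = [f"g{i}" for i in range(200)]
        onc = genes[:40]
        p = np.where(np.isin(genes, onc), 0.2, 0.1)[:, None]
        states = pd.DataFrame(
            np.where(rng.random((200, 50)) < p, "hyper", "none"),
            index=genes,
            columns=[f"t{j}" for j in range(50)],
        )
        mut = EventMatrix(
            pd.DataFrame(False, index=genes, columns=states.columns), "mutation"
        )
        classes = [CancerGeneEntry(g, "oncogene", 1) for g in onc]
        table = ab.class_stratified_rates({"x": states}, mut, classes).set_index(
            ["event_type", "gene_class"]
        )
        ratio = table.loc[("hyper", "oncogene"), "rate"] / table.loc[("hyper", "other"), "rate"]
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestOncVsTsgMeanM:
    def _matrix(self, onc_shift, rng, n_per_class=10, sd=0.5):
        n_genes = 2 * n_per_class + 5
        vals = rng.normal(0, sd, (n_genes, 30))
        vals[:n_per_class] += onc_shift
        m = make_matrix(vals, scale="M", prefix="g")
        classes = [CancerGeneEntry(f"g{i}", "oncogene", 1) for i in range(n_per_class)] + [
            CancerGeneEntry(f"g{i}", "tsg", 1)
            for i in range(n_per_class, 2 * n_per_class)
        ]
        return m, classes

    def test_planted_oncogene_shift_detected(self, rng):
        hits = 0
        for rep in range(20):
            m, classes = self._matrix(2.0, rng)
            res = ab.compare_onc_tsg_mean_m(m, classes)
            hits += res["one_sided_p"] < 0.01
        assert hits >= 19

    def test_null_p_centered(self, rng):
        ps = []
        for rep in range(50):
            m, classes = self._matrix(0.0, rng)
            ps.append(ab.compare_onc_tsg_mean_m(m, classes)["one_sided_p"])
        assert 0.3 < np.mean(ps) < 0.7

    def test_reversed_direction_gives_large_p(self, rng):
        m, classes = self._matrix(-2.0, rng)
        assert ab.compare_onc_tsg_mean_m(m, classes)["one_sided_p"] > 0.5

    def test_requires_two_genes_per_class(self, rng):
        m = make_matrix(rng.normal(0, 1, (3, 5)), scale="M", prefix="g")
        classes = [CancerGeneEntry("g0", "oncogene", 1), CancerGeneEntry("g1", "tsg", 1)]
        with pytest.raises(ValueError, match=">= 2 genes"):
            ab.compare_onc_tsg_mean_m(m, classes)
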