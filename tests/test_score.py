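"""Polygenic score construction, Fisher-Z machinery, score-vs-gene contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from rxsig.io import DrugResponseTable, ExpressionMatrix, SampleAnnotation
from rxsig.score import (
    PolygenicScorer,
    SignatureWeights,
    compare_score_vs_gene,
    compute_score,
    fisher_transform,
    fisher_zscore,
    fit_weights,
)
from rxsig.simulate import PanelConfig, simulate_panel


class TestFisherTransform:
    def test_symmetry_point(self):
        assert fisher_transform(0.0) == 0.0

    def test_half_log_three(self):
        assert fisher_transform(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_odd_function(self):
        assert fisher_transform(-0.5) == pytest.approx(-fisher_transform(0.5), abs=1e-15)

    def test_domain_error(self):
        for r in (1.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                fisher_transform(r)

    @given(st.floats(-3, 3, allow_nan=False))
    def test_inverse_of_tanh(self, z):
        assert fisher_transform(np.tanh(z)) == pytest.approx(z, abs=1e-12)


class TestFisherZscore:
    def test_zero_correlation_gives_zero(self):
        for n in (4, 50, 1000):
            assert fisher_zscore(0.0, n) == 0.0

    def test_printed_scaling(self):
        expected = np.sqrt(100 / 1.06) * 0.5 * np.log(3.0)
        assert fisher_zscore(0.5, 103) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_n(self):
        zs = [fisher_zscore(0.5, n) for n in (10, 50, 200)]
        assert zs[0] < zs[1] < zs[2]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_zscore(0.5, 3)


def _zmatrix(data, genes, samples):
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples),
                            zscored=True)


class TestComputeScore:
    def test_zero_weights_give_zero_scores(self):
        w = SignatureWeights("D", "L", pd.Series({"g1": 0.0, "g2": 0.0}))
        expr = _zmatrix([[1.0, 2.0], [3.0, 4.0]], ["g1", "g2"], ["s1", "s2"])
        sv = compute_score(w, expr)
        assert (sv.scores == 0).all()

    def test_hand_computed_dot_product(self):
        w = SignatureWeights("D", "L", pd.Series({"g1": 0.5, "g2": -0.2}))
        expr = _zmatrix([[2.0], [1.0]], ["g1", "g2"], ["s1"])
        assert compute_score(w, expr).scores["s1"] == pytest.approx(0.8, abs=1e-15)

    def test_missing_gene_dropped_without_renormalization(self):
        w = SignatureWeights("D", "L", pd.Series({"g1": 0.5, "g2": -0.2}))
        expr = _zmatrix([[2.0]], ["g1"], ["s1"])
        sv = compute_score(w, expr)
        assert sv.scores["s1"] == pytest.approx(1.0, abs=1e-15)
        assert sv.genes_missing == ["g2"]
        assert sv.genes_used + len(sv.genes_missing) == w.n_genes

    def test_zero_overlap_is_error(self):
        w = SignatureWeights("D", "L", pd.Series({"g1": 0.5}))
        expr = _zmatrix([[1.0]], ["other"], ["s1"])
        with pytest.raises(ValueError):
            compute_score(w, expr)

    def test_linearity_in_expression_and_weights(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(5)]
        samples = [f"s{i}" for i in range(7)]
        X = rng.normal(size=(5, 7))
        wa = SignatureWeights("D", "L", pd.Series(rng.normal(size=5), index=genes))
        wb = SignatureWeights("D", "L", pd.Series(rng.normal(size=5), index=genes))
        expr = _zmatrix(X, genes, samples)
        expr3 = _zmatrix(3.0 * X, genes, samples)
        sa = compute_score(wa, expr).scores
        np.testing.assert_allclose(compute_score(wa, expr3).scores, 3.0 * sa, atol=1e-12)
        wsum = SignatureWeights("D", "L", wa.weights + wb.weights)
        np.testing.assert_allclose(
            compute_score(wsum, expr).scores,
            sa + compute_score(wb, expr).scores, atol=1e-12)

    def test_minus_one_gene_differs_by_dropped_term(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i:02d}" for i in range(36)]
        samples = [f"s{i}" for i in range(50)]
        X = rng.normal(size=(36, 50))
        w = SignatureWeights("D", "L", pd.Series(rng.uniform(0.1, 0.6, 36), index=genes))
        expr = _zmatrix(X, genes, samples)
        full = compute_score(w, expr).scores
        dropped = "g07"
        part = compute_score(w.drop([dropped]), expr).scores
        term = w.weights[dropped] * expr.data.loc[dropped]
        np.testing.assert_allclose(full - part, term, atol=1e-12)


class TestFitWeights:
    def test_gene_equal_to_response_gets_weight_one(self, tiny_annotation):
        rng = np.random.default_rng(13)
        y = rng.normal(size=6)
        expr = _zmatrix([y, rng.normal(size=6)], ["g1", "g2"], [f"S{i}" for i in range(6)])
        resp = DrugResponseTable(pd.DataFrame(
            {"drug_id": "D", "sample_id": [f"S{i}" for i in range(6)], "value": y}))
        w = fit_weights(expr, resp, ["g1", "g2"], "D", "BREAST", tiny_annotation,
                        min_samples=6)
        assert w.weights["g1"] == pytest.approx(1.0)

    def test_constant_gene_omitted_with_warning(self, tiny_annotation, caplog):
        rng = np.random.default_rng(14)
        y = rng.normal(size=6)
        expr = _zmatrix([[0.0] * 6, rng.normal(size=6)], ["flat", "g2"],
                        [f"S{i}" for i in range(6)])
        resp = DrugResponseTable(pd.DataFrame(
            {"drug_id": "D", "sample_id": [f"S{i}" for i in range(6)], "value": y}))
        with caplog.at_level("WARNING"):
            w = fit_weights(expr, resp, ["flat", "g2"], "D", "BREAST", tiny_annotation,
                            min_samples=6)
        assert "flat" not in w.weights.index
        assert "omitted" in caplog.text

    def test_too_few_lineage_samples_cites_rule(self, tiny_annotation, tiny_expr,
                                                tiny_response):
        with pytest.raises(ValueError, match="at least 9"):
            fit_weights(tiny_expr, tiny_response, ["GA"], "DR1", "BREAST",
                        tiny_annotation, min_samples=9)

    def test_planted_gene_weights_positive_in_small_lineage(self):
        """48-line lineage with positive planted loadings: every fitted
        weight has the planted sign."""
        cfg = PanelConfig(n_genes=60, n_planted_resistance=8, n_planted_sensitivity=0,
                          n_samples=48, n_lineages=1, n_drugs=4, n_drug_classes=1,
                          seed=1)
        expr, resp, annot, truth = simulate_panel(cfg)
        w = fit_weights(expr, resp, truth.resistance_genes, "DRUG000", "LINEAGE0", annot)
        assert (w.weights > 0).all()


class TestPolygenicScorer:
    def test_sklearn_params_and_clone(self):
        est = PolygenicScorer(min_samples=12)
        assert est.get_params() == {"min_samples": 12}
        assert clone(est).min_samples == 12

    def test_fit_transform_shapes_and_weights(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + 0.1 * rng.normal(size=30)
        est = PolygenicScorer().fit(X, y)
        assert set(est.weights_.index) == set("abcd")
        assert est.weights_["a"] > 0.8
        out = est.transform(X)
        assert out.shape == (30, 1)

    def test_transform_before_fit_raises(self):
        with pytest.raises(Exception):
            PolygenicScorer().transform(pd.DataFrame({"a": [1.0]}))


class TestCompareScoreVsGene:
    def test_identity_construction_matches_baseline(self, panel_seed1):
        expr, resp, _, truth = panel_seed1
        gene = truth.resistance_genes[0]
        w = SignatureWeights("DRUG000", "LINEAGE0", pd.Series({gene: 1.0}))
        cmp_ = compare_score_vs_gene(expr, resp, w, gene,
                                     drug_ids=sorted(resp.drug_ids)[:10])
        np.testing.assert_allclose(cmp_.table["rho_score"], cmp_.table["rho_gene"],
                                   atol=1e-12)
        assert cmp_.p_value == pytest.approx(1.0, abs=0.05)

    def test_two_drugs_flagged_low_power(self, panel_seed1):
        expr, resp, _, truth = panel_seed1
        gene = truth.resistance_genes[0]
        w = SignatureWeights("DRUG000", "LINEAGE0", pd.Series({gene: 1.0}))
        cmp_ = compare_score_vs_gene(expr, resp, w, gene,
                                     drug_ids=["DRUG000", "DRUG001"])
        assert cmp_.low_power

    def test_absent_baseline_gene_is_error(self, panel_seed1):
        expr, resp, _, truth = panel_seed1
        w = SignatureWeights("DRUG000", "LINEAGE0",
                             pd.Series({truth.resistance_genes[0]: 1.0}))
        with pytest.raises(ValueError, match="GHOST"):
            compare_score_vs_gene(expr, resp, w, "GHOST")
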