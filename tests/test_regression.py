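"""Design construction, logistic/lasso fits, and penalty selection."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import (
    fit_lasso_oracle,
    fit_logistic_oracle,
    lasso_objective,
    logistic_nll,
)
from targetsafe.reference_data import PUBLISHED_SOC_COUNTS, PUBLISHED_TOTAL_COUNTS
from targetsafe.regression import (
    DesignMatrix,
    build_design,
    build_pooled_design,
    eligible_categories,
    eligible_categories_from_counts,
    fit_lasso,
    fit_logistic,
    lambda_grid,
    select_lambda,
)
from targetsafe.synthetic import SimConfig, fixture_small, generate


class TestEligibility:
    def test_published_counts_give_18_categories(self):
        se_counts = {soc: a + c
                     for soc, (a, b, c, d) in PUBLISHED_SOC_COUNTS.items()}
        eligible = eligible_categories_from_counts(se_counts, min_count=100)
        assert len(eligible) == 18
        assert set(se_counts) - set(eligible) == {"Congenital", "Ear",
                                                  "Pregnancy"}

    def test_min_count_one_keeps_all_represented(self):
        genes, drugs = fixture_small()
        assert eligible_categories(drugs, min_count=1) == sorted(
            {s for d in drugs.values() for s in d.side_effects},
            key=["Blood", "Heart", "Congenital", "Ear", "Endocrine", "Eye",
                 "Gastrointestinal", "Hepatobiliary", "Immune", "Infection",
                 "Metabolism", "Musculoskeletal", "Neoplasm", "Nervous",
                 "Pregnancy", "Mental", "Urologic", "Reproductive",
                 "Respiratory", "Skin", "Vascular"].index)

    def test_empty_catalog(self):
        assert eligible_categories({}, min_count=1) == []


@pytest.fixture(scope="module")
def catalogs():
    return generate(SimConfig(n_drugs=400, n_genes=200, seed=31))


@pytest.fixture(scope="module")
def signal_design():
    genes, drugs = generate(SimConfig(n_drugs=300, n_genes=150,
                                      beta_genetic=math.log(2), seed=17))
    return build_design(drugs, genes, "Heart")


@pytest.fixture(scope="module")
def cv_design():
    genes, drugs = generate(SimConfig(n_drugs=500, n_genes=250,
                                      beta_genetic=math.log(3), seed=23))
    return build_design(drugs, genes, "Heart")


class TestBuildDesign:
    def test_fixture_hand_checked_row(self):
        genes, drugs = fixture_small()
        design = build_design(drugs, genes, "Heart")
        row = design.predictors.loc["d1"]
        assert row["ind_Heart"] == 1 and row["ind_Skin"] == 0
        assert row["modality_biological"] == 0
        assert row["route_enteral"] == 1 and row["route_parenteral"] == 0
        assert row["expr_enriched"] == 1 and row["expr_all"] == 0
        assert row["constrained"] == 1
        assert row["mend_match"] == 1 and row["mend_mismatch"] == 0
        assert row["gwas_match"] == 0 and row["gwas_mismatch"] == 0
        assert design.response[list(design.drug_ids).index("d1")] == 1.0
        # d3: GWAS match via g2, Mendelian blank on both targets
        d3 = design.predictors.loc["d3"]
        assert d3["gwas_match"] == 1 and d3["mend_match"] == 0
        assert d3["mend_mismatch"] == 0

    def test_on_indication_exclusion(self):
        genes, drugs = fixture_small()
        design = build_design(drugs, genes, "Heart", exclude_on_indication=True)
        assert "d1" not in design.predictors.index  # indicated in Heart

    def test_twenty_indication_columns(self, catalogs):
        genes, drugs = catalogs
        design = build_design(drugs, genes, "Heart")
        ind_cols = [c for c in design.predictors if c.startswith("ind_")]
        assert len(ind_cols) == 20 and "ind_Neoplasm" not in ind_cols

    def test_constant_response_is_an_error(self):
        genes, drugs = fixture_small()
        with pytest.raises(ValueError, match="constant response"):
            build_design(drugs, genes, "Ear")  # nobody has an Ear SE


def _design_from_counts(a, b, c, d):
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return DesignMatrix(response=y,
                        predictors=pd.DataFrame({"support": x}))


class TestFitLogistic:
    def test_saturated_two_by_two_closed_form(self):
        # single binary predictor: slope = ln(ad/bc), intercept = ln(c/d)
        a, b, c, d = PUBLISHED_TOTAL_COUNTS
        fit = fit_logistic(_design_from_counts(a, b, c, d))
        assert fit.params.loc["support", "coef"] == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-6)
        assert fit.intercept == pytest.approx(math.log(c / d), abs=1e-6)
        assert fit.params.loc["support", "odds_ratio"] == pytest.approx(
            math.exp(fit.params.loc["support", "coef"]), rel=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(DesignMatrix(
                response=np.ones(5),
                predictors=pd.DataFrame({"x": np.arange(5.0)})))

    def test_matches_convex_optimizer_oracle(self):
        genes, drugs = generate(SimConfig(n_drugs=300, n_genes=150, seed=13))
        design = build_design(drugs, genes, "Heart")
        keep = [c for c in design.predictors
                if design.predictors[c].nunique() > 1]
        design = DesignMatrix(design.response, design.predictors[keep])
        fit = fit_logistic(design)
        X1 = np.hstack([np.ones((len(design.response), 1)),
                        design.predictors.to_numpy(float)])
        beta = np.r_[fit.intercept, fit.params["coef"].to_numpy()]
        _, nll_oracle = fit_logistic_oracle(
            design.predictors.to_numpy(float), design.response)
        assert logistic_nll(beta, X1, design.response) == pytest.approx(
            nll_oracle, abs=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = y.copy()
        design = DesignMatrix(response=y,
                              predictors=pd.DataFrame({"x": x}))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_logistic(design)
        assert not fit.converged
        assert np.isfinite(fit.params.loc["x", "coef"])


class TestFitLasso:
    def test_zero_penalty_equals_ml_fit(self, signal_design):
        keep = [c for c in signal_design.predictors
                if signal_design.predictors[c].nunique() > 1]
        d2 = DesignMatrix(signal_design.response, signal_design.predictors[keep])
        ml = fit_logistic(d2)
        l0 = fit_lasso(d2, 0.0)
        assert np.allclose(l0.params["coef"], ml.params["coef"], atol=1e-4)

    def test_full_shrinkage_limit(self, signal_design):
        fit = fit_lasso(signal_design, 10.0)
        assert (fit.params["coef"] == 0).all()
        assert not fit.params["selected"].any()

    def test_mid_path_matches_proximal_gradient_oracle(self, signal_design):
        lam = float(lambda_grid(signal_design, n_lambda=10)[4])
        fit = fit_lasso(signal_design, lam)
        X = signal_design.predictors.to_numpy(float)
        y = signal_design.response
        beta_oracle = fit_lasso_oracle(X, y, lam)
        beta_fit = np.r_[fit.intercept, fit.params["coef"].to_numpy()]
        assert lasso_objective(beta_fit, X, y, lam) == pytest.approx(
            lasso_objective(beta_oracle, X, y, lam), abs=1e-7)
        assert np.allclose(beta_fit, beta_oracle, atol=1e-4)

    def test_selected_implies_nonzero(self, signal_design):
        fit = fit_lasso(signal_design, 0.01)
        assert (fit.params.loc[fit.params["selected"], "coef"] != 0).all()

    def test_path_monotonicity(self, signal_design):
        grid = lambda_grid(signal_design, n_lambda=10)
        counts = [int(fit_lasso(signal_design, lam).params["selected"].sum())
                  for lam in grid]  # grid is descending in lambda
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))


class TestSelectLambda:
    def test_determinism(self, cv_design):
        a = select_lambda(cv_design, n_repeats=2, n_folds=4, seed=3, n_lambda=12)
        b = select_lambda(cv_design, n_repeats=2, n_folds=4, seed=3, n_lambda=12)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_lambda_star_is_midpoint_of_means(self, cv_design):
        lam_star, runs = select_lambda(cv_design, n_repeats=3, n_folds=4, seed=1,
                                       n_lambda=12)
        assert lam_star == pytest.approx(
            (runs["lambda_min"].mean() + runs["lambda_1se"].mean()) / 2)
        assert (runs["lambda_1se"] >= runs["lambda_min"] - 1e-15).all()

    def test_strong_genetic_signal_is_selected(self):
        hits = 0
        for seed in range(5):
            genes, drugs = generate(SimConfig(
                n_drugs=2000, n_genes=400, beta_genetic=math.log(3),
                frac_no_gwas=1.0, seed=500 + seed))
            cv_design = build_design(drugs, genes, "Heart")
            lam_star, _ = select_lambda(cv_design, n_repeats=2, n_folds=5,
                                        seed=seed, n_lambda=25)
            fit = fit_lasso(cv_design, lam_star, tol=1e-6)
            hits += bool(fit.params.loc["mend_match", "selected"])
        assert hits >= 4


class TestPooledDesign:
    def test_parameter_recovery_single_seed(self):
        genes, drugs = generate(SimConfig(n_drugs=2000, n_genes=600,
                                          beta_genetic=math.log(2),
                                          frac_no_gwas=1.0, seed=207))
        design = build_pooled_design(drugs, genes)
        keep = [c for c in design.predictors
                if design.predictors[c].nunique() > 1]
        design = DesignMatrix(design.response, design.predictors[keep])
        fit = fit_logistic(design)
        assert fit.params.loc["mend_match", "coef"] == pytest.approx(
            math.log(2), abs=0.3)
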