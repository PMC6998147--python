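"""Logistic fitting, stepwise AIC selection and the PRF composition."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from prfpipe import (
    CohortSimConfig,
    ExpressionMatrix,
    IdentifierError,
    LogisticModel,
    MarkerPanel,
    PRFModel,
    PRFRiskModel,
    PrfPipeError,
    covariate_correlation,
    fit_logistic,
    generate_cohort,
    load_model,
    load_paper_model,
    predict_probability,
    prf_index,
    prf_ratio_vs_control,
    save_model,
    score_samples,
    stepwise_select,
)
from prfpipe.risk import SeparationWarning, group_medians


def _expr_matrix(X: np.ndarray, genes=None) -> ExpressionMatrix:
    """X is samples x genes; build the transposed expression matrix."""
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    samples = [f"s{i}" for i in range(X.shape[0])]
    return ExpressionMatrix(genes, samples, X.T)


def _sim_logistic(rng, n, betas, intercept=0.0):
    X = rng.normal(0, 1, size=(n, len(betas)))
    p = expit(intercept + X @ np.asarray(betas))
    y = (rng.uniform(size=n) < p).astype(int)
    return X, y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = [1] * 30 + [0] * 70
        m = _expr_matrix(np.zeros((100, 1)))
        model = fit_logistic(m, y, [])
        assert np.isclose(model.intercept, np.log(30 / 70), atol=1e-6)
        assert model.aic == pytest.approx(2 - 2 * model.log_likelihood)

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(100)
        X, y = _sim_logistic(rng, 5000, [1.5], intercept=0.0)
        model = fit_logistic(_expr_matrix(X), y, ["g0"])
        # observed-information standard errors
        Xd = np.column_stack([np.ones(5000), X])
        eta = Xd @ np.array([model.intercept, model.coefficients["g0"]])
        w = expit(eta) * (1 - expit(eta))
        se = np.sqrt(np.diag(np.linalg.inv(Xd.T @ (Xd * w[:, None]))))
        assert abs(model.intercept - 0.0) < 3 * se[0]
        assert abs(model.coefficients["g0"] - 1.5) < 3 * se[1]
        assert model.converged

    def test_single_class_rejected(self):
        m = _expr_matrix(np.zeros((10, 1)))
        with pytest.raises(PrfPipeError, match="classes"):
            fit_logistic(m, [1] * 10, ["g0"])

    def test_matches_generic_optimizer(self):
        """IRLS maximum matches a quasi-Newton maximization of the same
        likelihood to 1e-6 on random small datasets."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, p = 60, rng.integers(1, 4)
            X, y = _sim_logistic(rng, n, rng.normal(0, 1, p))
            genes = [f"g{i}" for i in range(p)]
            model = fit_logistic(_expr_matrix(X, genes), y, genes)
            Xd = np.column_stack([np.ones(n), X])

            def nll(beta):
                eta = Xd @ beta
                return -(y @ eta - np.logaddexp(0, eta).sum())

            ref = minimize(nll, np.zeros(p + 1), method="BFGS", tol=1e-12)
            ours = np.array([model.intercept] + [model.coefficients[g] for g in genes])
            np.testing.assert_allclose(ours, ref.x, atol=1e-6)

    def test_separation_warns_not_raises(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]] * 5)
        y = (X[:, 0] > 0).astype(int)
        with pytest.warns(SeparationWarning):
            model = fit_logistic(_expr_matrix(X), y, ["g0"])
        assert not model.converged

    def test_singular_design_rejected(self):
        X = np.ones((20, 2))
        y = [0, 1] * 10
        with pytest.raises(PrfPipeError, match="singular|rank"):
            fit_logistic(_expr_matrix(X), y, ["g0", "g1"])


class TestStepwise:
    def test_informative_genes_kept_and_aic_not_worse(self):
        rng = np.random.default_rng(21)
        n, betas = 800, [1.5, 1.5, 0, 0, 0, 0]
        X, y = _sim_logistic(rng, n, betas)
        genes = [f"g{i}" for i in range(6)]
        m = _expr_matrix(X, genes)
        selected = stepwise_select(m, y, genes)
        full = fit_logistic(m, y, genes)
        assert {"g0", "g1"} <= set(selected.coefficients)
        assert selected.aic <= full.aic + 1e-9

    def test_null_candidates_mostly_dropped(self):
        """With no associated genes, AIC retains each noise gene only with
        P(chi2_1 > 2) ~ 0.157, so most are dropped and AIC never exceeds
        the full model's."""
        rng = np.random.default_rng(22)
        X, y = _sim_logistic(rng, 1000, [0.0] * 6)
        genes = [f"g{i}" for i in range(6)]
        m = _expr_matrix(X, genes)
        selected = stepwise_select(m, y, genes)
        full = fit_logistic(m, y, genes)
        assert len(selected.coefficients) <= 2
        assert selected.aic <= full.aic + 1e-9

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(23)
        X, y = _sim_logistic(rng, 300, [1.0, 0, 0])
        genes = ["b", "a", "c"]
        m = _expr_matrix(X, genes)
        first = stepwise_select(m, y, genes)
        second = stepwise_select(m, y, genes)
        assert first.coefficients == second.coefficients

    def test_matches_exhaustive_oracle_on_most_datasets(self):
        """Greedy bidirectional AIC search finds the best of all 2^6
        subsets on >= 9 of 10 simulated datasets."""
        rng = np.random.default_rng(24)
        genes = [f"g{i}" for i in range(6)]
        wins = 0
        for _ in range(10):
            X, y = _sim_logistic(rng, 400, rng.choice([0.0, 1.0], size=6))
            m = _expr_matrix(X, genes)
            selected = stepwise_select(m, y, genes)
            best = min(
                fit_logistic(m, y, [g for g, b in zip(genes, bits) if b]).aic
                for bits in np.ndindex(*(2,) * 6)
            )
            wins += selected.aic <= best + 1e-6
        assert wins >= 9


class TestPrfComposition:
    def test_closed_forms(self):
        assert prf_index(0.0, 0.9) == 0.0
        assert prf_index(np.sqrt(0.5), np.sqrt(0.5)) == pytest.approx(1.0)
        with pytest.raises(PrfPipeError):
            prf_index(1.0, 0.5)
        with pytest.raises(PrfPipeError):
            prf_index(-0.1, 0.5)

    def test_published_intercepts_compose_to_0_3354(self):
        paper = load_paper_model()
        intercept_only = PRFModel(
            model_smk=LogisticModel(paper.model_smk.intercept, {}, "NS_vs_SMK"),
            model_copd=LogisticModel(paper.model_copd.intercept, {}, "SMK_vs_COPD"),
        )
        p_s = predict_probability(intercept_only.model_smk, {})
        p_c = predict_probability(intercept_only.model_copd, {})
        assert p_s == pytest.approx(0.8418, abs=5e-5)
        assert p_c == pytest.approx(0.2983, abs=5e-5)
        # exact composition gives 0.33527; the published 0.3354 carries
        # last-digit rounding error, hence the looser tolerance
        assert prf_index(p_s, p_c) == pytest.approx(0.3354, abs=2e-4)

    def test_strictly_increasing_in_each_argument(self):
        base = prf_index(0.4, 0.5)
        assert prf_index(0.5, 0.5) > base and prf_index(0.4, 0.6) > base

    def test_predict_probability_contracts(self):
        model = LogisticModel(0.0, {"g": 1.0})
        assert predict_probability(model, {"g": 0.0}) == 0.5
        high = predict_probability(model, {"g": 800.0})
        assert 0.999 < high < 1.0  # 1 - eps, no overflow
        with pytest.raises(IdentifierError, match="'g'"):
            predict_probability(model, {})


class TestScoring:
    def _zero_matrix(self, n=5):
        genes = list(load_paper_model().gene_ids)
        return ExpressionMatrix(genes, [f"s{i}" for i in range(n)], np.zeros((len(genes), n)))

    def test_paper_model_at_zero_expression(self):
        scores = score_samples(load_paper_model(), self._zero_matrix())
        assert np.allclose(scores["prf"], 0.3354, atol=2e-4)

    def test_duplicate_sample_scores_identically(self, cohort_default):
        _, matrix, annotations, _ = cohort_default
        results = PRFRiskModel.from_cohort(matrix, annotations, MarkerPanel(
            [("MARKER_UP_1", "up"), ("MARKER_DN_1", "down")]
        )).fit(stepwise=False)
        scores = results.score()
        dup = matrix.subset_samples([matrix.sample_ids[0], matrix.sample_ids[0]][:1])
        s2 = score_samples(results.prf_model, dup)
        assert s2["prf"].iloc[0] == scores["prf"].iloc[0]

    def test_odds_identity_for_all_samples(self, cohort_default):
        _, matrix, annotations, _ = cohort_default
        panel = MarkerPanel([("MARKER_UP_1", "up"), ("MARKER_UP_2", "up")])
        scores = PRFRiskModel.from_cohort(matrix, annotations, panel).fit(False).score()
        lhs = scores["prf"] / (1 + scores["prf"])
        np.testing.assert_allclose(lhs, scores["p_smk"] * scores["p_copd"], atol=1e-12)

    def test_group_medians_strictly_ordered(self, cohort_default):
        _, matrix, annotations, _ = cohort_default
        from prfpipe import default_planted_panel

        results = PRFRiskModel.from_cohort(matrix, annotations, default_planted_panel()).fit()
        med = results.group_medians()
        assert med["NS"] < med["SMK"] < med["COPD"]
        assert "median PRF" in results.summary()

    def test_missing_gene_rejected(self):
        m = ExpressionMatrix(["other"], ["s1"], [[1.0]])
        with pytest.raises(IdentifierError, match="AREG"):
            score_samples(load_paper_model(), m)


class TestRatiosAndCorrelations:
    def _scores(self, prfs):
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(prfs))], "prf": prfs})

    def test_ratio_identities(self):
        control = self._scores([0.2, 0.3, 0.25])
        ratio, sd = prf_ratio_vs_control(control, control)
        assert ratio == pytest.approx(1.0)
        doubled = self._scores([0.4, 0.6, 0.5])
        assert prf_ratio_vs_control(doubled, control)[0] == pytest.approx(2.0)
        with pytest.raises(PrfPipeError):
            prf_ratio_vs_control(doubled, self._scores([0.0, 0.0]))

    def test_correlation_identities(self):
        scores = self._scores([0.1, 0.5, 0.2, 0.9])
        assert covariate_correlation(scores, scores["prf"]) == pytest.approx(1.0)
        assert covariate_correlation(scores, -scores["prf"]) == pytest.approx(-1.0)
        assert np.isnan(covariate_correlation(scores, [1, 1, 1, 1]))

    def test_independent_covariate_rarely_correlates(self):
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(100):
            prfs = rng.uniform(0, 1, 200)
            cov = rng.normal(size=200)
            hits += abs(covariate_correlation(self._scores(prfs), cov)) < 0.2
        assert hits >= 95


class TestModelIO:
    def test_round_trip(self, tmp_path):
        model = PRFModel(
            model_smk=LogisticModel(1.5, {"A": -2.0, "B": 0.25}, "NS_vs_SMK"),
            model_copd=LogisticModel(-0.5, {"C": 1.0}, "SMK_vs_COPD"),
            scaling_note="test",
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.model_smk.to_dict() == model.model_smk.to_dict()
        assert back.model_copd.to_dict() == model.model_copd.to_dict()
        assert back.scaling_note == "test"

    def test_schema_violation_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"model_smk": {"intercept": 1.0}}))
        with pytest.raises(PrfPipeError):
            load_model(path)

    def test_packaged_published_parameters(self):
        paper = load_paper_model()
        assert paper.model_smk.coefficients["HILPDA"] == 3.2193
        assert set(paper.model_copd.coefficients) == {"AREG", "DUSP6", "EFNA1", "TXNIP"}
        assert paper.model_smk.intercept == 1.6715
        assert paper.model_copd.intercept == -0.8555
        assert len(paper.model_smk.coefficients) == 11
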