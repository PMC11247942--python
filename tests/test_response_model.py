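"""Screening, feature construction, model fitting/selection, metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from rectalresponse import response_model as rm
from rectalresponse import synthetic_cohort as syn
from rectalresponse.cohort_io import MutationMatrix
from rectalresponse.statcore import LogisticFit


def matrix_from(incidence, genes):
    inc = np.asarray(incidence, dtype=np.int8)
    samples = [f"S{i + 1:04d}" for i in range(inc.shape[0])]
    return MutationMatrix(samples, genes, inc)


class TestScreenPredictors:
    def test_null_gene_not_retained(self):
        inc = np.zeros((100, 1), dtype=np.int8)
        inc[:20, 0] = 1
        inc[50:70, 0] = 1  # identical frequency in both halves
        m = matrix_from(inc, ["G0"])
        resp = np.array(["CR"] * 50 + ["ICR"] * 50)
        scr = rm.screen_predictors(m, [], resp)
        assert scr.screened_genes == []

    def test_alpha_one_retains_everything(self, rng):
        inc = rng.binomial(1, 0.3, (60, 4)).astype(np.int8)
        m = matrix_from(inc, ["A", "B", "C", "D"])
        resp = np.array(["CR"] * 20 + ["ICR"] * 40)
        scr = rm.screen_predictors(m, [], resp, alpha_screen=1.0)
        assert len(scr.screened_genes) == 4

    def test_planted_enriched_genes_retained(self):
        # 10 genes with OR ~ 3 for CR at n = 330
        rng = np.random.default_rng(8)
        n_cr, n_icr = 100, 230
        resp = np.array(["CR"] * n_cr + ["ICR"] * n_icr)
        hits = []
        for rep in range(20):
            cols = []
            for _ in range(10):
                p_icr = 0.15
                p_cr = p_icr * 3 / (1 - p_icr + 3 * p_icr)  # OR = 3
                cols.append(np.r_[rng.binomial(1, p_cr, n_cr),
                                  rng.binomial(1, p_icr, n_icr)])
            m = matrix_from(np.column_stack(cols), [f"G{j}" for j in range(10)])
            scr = rm.screen_predictors(m, [], resp)
            hits.append(len(scr.screened_genes))
        assert np.mean(hits) >= 6  # decent average power at OR 3


class TestBuildFeatures:
    def _setup(self):
        inc = np.array([[1, 1, 0, 0],
                        [1, 0, 1, 1],
                        [0, 0, 0, 0],
                        [1, 1, 1, 1]], dtype=np.int8)
        m = matrix_from(inc, ["A", "B", "C", "D"])
        clinical = pd.DataFrame({
            "sample_id": m.sample_ids,
            "response": ["CR", "ICR", "ICR", "CR"],
            "tumor_size": [4.0, 5.0, 3.5, 6.0],
            "ajcc_stage": [2, 3, 2, 3],
        })
        scr = rm.ScreeningResult(
            screened_genes=[("A", 0.01)],
            screened_pairs=[(("A", "B"), 0.02), (("C", "D"), 0.03)])
        return clinical, m, scr

    def test_indicator_and_count(self):
        clinical, m, scr = self._setup()
        f = rm.build_features(clinical, m, scr)
        assert f["network_gene_mutated"].tolist() == [1, 1, 0, 1]
        assert f["pair_count"].tolist() == [1, 1, 0, 2]

    @pytest.mark.parametrize("count,cat", [
        (0, "0"), (1, "1-2"), (2, "1-2"), (3, "3 or more"), (5, "3 or more")])
    def test_category_mapping(self, count, cat):
        assert rm.categorize_pair_count(count) == cat

    def test_missing_size_dropped(self):
        clinical, m, scr = self._setup()
        clinical.loc[1, "tumor_size"] = np.nan
        f = rm.build_features(clinical, m, scr)
        assert len(f) == 3


def _features_cohort(seed=0, n=400, effect=True):
    rng = np.random.default_rng(seed)
    size = np.exp(rng.normal(1.5, 0.3, n))
    stage = rng.binomial(1, 0.6, n) + 2
    network = rng.binomial(1, 0.5, n)
    counts = rng.poisson(1.2, n)
    if effect:
        lin = 0.5 - 0.25 * size + 0.9 * network + 2.1 * (counts >= 3)
    else:
        lin = -0.9 * np.ones(n)
    y = rng.binomial(1, 1 / (1 + np.exp(-lin)))
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "tumor_size": size, "ajcc_stage": stage,
        "network_gene_mutated": network, "pair_count": counts,
        "cooccurrence_category": [rm.categorize_pair_count(c) for c in counts],
        "response": y,
    })


class TestFitResponseModel:
    def test_or_ci_identities(self):
        f = _features_cohort()
        model = rm.fit_response_model(f, "categorical")
        beta = model.fit.coefficients
        se = model.fit.standard_errors
        z = 1.959963984540054
        assert model.odds_ratios["OR"].to_numpy() == pytest.approx(np.exp(beta))
        assert model.odds_ratios["ci_low"].to_numpy() == pytest.approx(
            np.exp(beta - z * se))
        assert model.odds_ratios["ci_high"].to_numpy() == pytest.approx(
            np.exp(beta + z * se))

    def test_lrt_identity(self):
        f = _features_cohort()
        model = rm.fit_response_model(f, "categorical")
        stat, p = model.lrt_cooccurrence
        assert stat >= 0
        # direct identity: 2 * delta logL of the nested refit
        full = model.fit.log_likelihood
        reduced = rm.fit_response_model(
            f.assign(pair_count=0, cooccurrence_category="0"),
            "none").fit.log_likelihood
        assert stat == pytest.approx(2 * (full - reduced), abs=1e-6)

    def test_constant_column_rank_error(self):
        f = _features_cohort()
        f["tumor_size"] = 4.2
        with pytest.raises(np.linalg.LinAlgError, match="tumor_size"):
            rm.fit_response_model(f, "categorical")

    def test_null_cohort_low_tjur(self):
        r2s = [rm.fit_response_model(_features_cohort(seed=s, effect=False),
                                     "categorical").tjur_r2 for s in range(10)]
        assert np.mean(r2s) < 0.05

    def test_too_few_observations(self):
        f = _features_cohort().head(10)
        with pytest.raises(ValueError):
            rm.fit_response_model(f, "categorical")


class TestSelectModel:
    def _mk(self, aic, tjur, form="categorical"):
        fit = LogisticFit(np.zeros(2), np.zeros(2), -aic / 2 + 2, aic, 100,
                          True, np.full(100, 0.3))
        return rm.ResponseModelFit(fit=fit, terms=[], odds_ratios=pd.DataFrame(),
                                   tjur_r2=tjur, aic=aic, n_obs=100,
                                   count_form=form,
                                   response=np.r_[np.ones(30), np.zeros(70)])

    def test_single_candidate(self):
        m = self._mk(350, 0.1)
        assert rm.select_model([m]) is m

    def test_lowest_aic_wins(self):
        a, b = self._mk(349, 0.1), self._mk(355, 0.2, "continuous")
        with pytest.warns(UserWarning, match="disagree"):
            assert rm.select_model([a, b]) is a

    def test_aic_tie_breaks_on_tjur(self):
        a, b = self._mk(350.0, 0.14), self._mk(350.0, 0.10, "continuous")
        assert rm.select_model([a, b]) is a

    def test_never_returns_dominated_candidate(self, rng):
        cands = [self._mk(340 + 10 * rng.random(), rng.random())
                 for _ in range(5)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen = rm.select_model(cands)
        assert chosen.aic == min(c.aic for c in cands)


class TestPerformanceMetrics:
    def _model(self, probs, y):
        fit = LogisticFit(np.zeros(1), np.zeros(1), 0.0, 2.0, len(y), True,
                          np.asarray(probs, float))
        return rm.ResponseModelFit(fit=fit, terms=[], odds_ratios=pd.DataFrame(),
                                   tjur_r2=0, aic=2.0, n_obs=len(y),
                                   count_form="none",
                                   response=np.asarray(y, float))

    def test_perfect_classifier(self):
        m = self._model([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        met = rm.performance_metrics(m)
        assert all(met[k] == 1.0 for k in ("sensitivity", "specificity",
                                           "ppv", "npv"))

    def test_all_positive_predictions(self):
        m = self._model([0.9] * 6, [1, 1, 0, 0, 0, 1])
        with pytest.warns(UserWarning):
            met = rm.performance_metrics(m)
        assert met["sensitivity"] == 1.0
        assert met["specificity"] == 0.0

    def test_threshold_extremes(self):
        probs, y = [0.3, 0.6, 0.7, 0.2], [1, 0, 1, 0]
        with pytest.warns(UserWarning):
            lo = rm.performance_metrics(self._model(probs, y), threshold=0.0)
        with pytest.warns(UserWarning):
            hi = rm.performance_metrics(self._model(probs, y), threshold=1.01)
        assert lo["sensitivity"] == 1.0 and lo["specificity"] == 0.0
        assert hi["sensitivity"] == 0.0 and hi["specificity"] == 1.0

    def test_confusion_matrix_consistency(self, rng):
        y = rng.binomial(1, 0.4, 50)
        p = rng.random(50)
        met = rm.performance_metrics(self._model(p, y))
        pos, neg = int(y.sum()), int((1 - y).sum())
        assert met["tp"] + met["fn"] == pos
        assert met["tn"] + met["fp"] == neg
        if not math.isnan(met["sensitivity"]):
            assert met["sensitivity"] * pos == pytest.approx(met["tp"])


class TestPipelineSmoke:
    def test_closed_loop_single_run(self):
        params = syn.preset("closed-loop", seed=42)
        clinical, _, truth = syn.simulate_cohort(params, emit_maf=False)
        matrix = syn.truth_matrix(truth)
        scr, feats, model = rm.run_pipeline(clinical, matrix,
                                            adjust_interactions=True)
        assert model.n_obs == len(clinical)
        assert model.count_form in ("categorical", "continuous")
        assert 0 < model.tjur_r2 < 1
        assert len(scr.screened_pairs) >= 5  # most planted pairs found
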