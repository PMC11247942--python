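"""Logistic prediction of complete response to neoadjuvant chemoradiation.

Bivariate Fisher screening of gene-mutation and co-occurring-pair
indicators against response (p < 0.1), construction of the model
features (tumor size, AJCC stage, a binary any-network-gene-mutated
indicator, and the 0 / 1-2 / 3-or-more co-occurring-mutation count
category), maximum-likelihood fitting, model selection by AIC with
Tjur R-squared tie-break, and training-set classification metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import statcore
from .statcore import ContingencyTable2x2, LogisticFit
from .cohort_io import MutationMatrix
from .mutnet import GenePairInteraction

__all__ = [
    "ScreeningResult",
    "ResponseModelFit",
    "COOCCURRENCE_CATEGORIES",
    "screen_predictors",
    "build_features",
    "fit_response_model",
    "select_model",
    "performance_metrics",
]

logger = logging.getLogger(__name__)

COOCCURRENCE_CATEGORIES = ("0", "1-2", "3 or more")


@dataclass
class ScreeningResult:
    """Genes and pairs that pass the bivariate screen against response."""

    screened_genes: list[tuple[str, float]]
    screened_pairs: list[tuple[tuple[str, str], float]]
    alpha_screen: float = 0.1


@dataclass
class ResponseModelFit:
    """A fitted complete-response model with its reporting summary."""

    fit: LogisticFit
    terms: list[str]
    odds_ratios: pd.DataFrame  # index=term; columns OR, ci_low, ci_high, p_value
    tjur_r2: float
    aic: float
    n_obs: int
    count_form: str  # "categorical" | "continuous" | "none"
    lrt_cooccurrence: tuple[float, float] | None = None  # (statistic, p)
    metrics: dict[str, float] = field(default_factory=dict)
    response: np.ndarray | None = None


def screen_predictors(matrix: MutationMatrix,
                      interactions: list[GenePairInteraction],
                      response, alpha_screen: float = 0.1) -> ScreeningResult:
    """Bivariate Fisher exact screen of mutation indicators vs response.

    Each gene's mutation indicator and each candidate pair's
    joint-mutation indicator (both genes mutated in the sample) is
    tested against the CR/ICR label; factors with p < ``alpha_screen``
    are retained.
    """
    y = np.asarray(response)
    cr = y == "CR" if y.dtype.kind in "UO" else y.astype(bool)
    n_cr, n_icr = int(cr.sum()), int((~cr).sum())
    if n_cr == 0 or n_icr == 0:
        raise ValueError("both response classes must be present for screening")

    def fisher_vs_response(indicator: np.ndarray) -> float:
        t = ContingencyTable2x2(
            int(indicator[cr].sum()), n_cr - int(indicator[cr].sum()),
            int(indicator[~cr].sum()), n_icr - int(indicator[~cr].sum()))
        return statcore.fisher_exact_2x2(t).p_value

    def retain(p: float) -> bool:
        # strict threshold; alpha >= 1 keeps everything (p can equal 1)
        return p < alpha_screen or alpha_screen >= 1.0

    genes = []
    for j, gene in enumerate(matrix.gene_ids):
        col = matrix.incidence[:, j].astype(bool)
        if not col.any():
            continue
        p = fisher_vs_response(col)
        if retain(p):
            genes.append((gene, p))
    pairs = []
    for it in interactions:
        both = (matrix.gene_column(it.gene_a).astype(bool)
                & matrix.gene_column(it.gene_b).astype(bool))
        if not both.any():
            continue
        p = fisher_vs_response(both)
        if retain(p):
            pairs.append(((it.gene_a, it.gene_b), p))
    genes.sort(key=lambda t: (t[1], t[0]))
    pairs.sort(key=lambda t: (t[1], t[0]))
    if not genes and not pairs:
        logger.warning("no gene or pair passed the %.2f screen; downstream model "
                       "will omit the mutation terms", alpha_screen)
    return ScreeningResult(genes, pairs, alpha_screen)


def categorize_pair_count(count: int) -> str:
    if count <= 0:
        return COOCCURRENCE_CATEGORIES[0]
    if count <= 2:
        return COOCCURRENCE_CATEGORIES[1]
    return COOCCURRENCE_CATEGORIES[2]


def build_features(clinical: pd.DataFrame, matrix: MutationMatrix,
                   screening: ScreeningResult) -> pd.DataFrame:
    """Per-sample model features.

    ``network_gene_mutated`` is 1 iff the sample carries a mutation in
    any screened gene; ``pair_count`` counts the screened pairs whose
    both members are mutated; ``cooccurrence_category`` maps the count
    to 0 / 1-2 / 3 or more.  Rows missing tumor size or stage are
    dropped with a logged count.
    """
    clin = clinical.set_index("sample_id").loc[matrix.sample_ids]
    gene_set = [g for g, _ in screening.screened_genes]
    if gene_set:
        cols = np.column_stack([matrix.gene_column(g) for g in gene_set])
        network = cols.any(axis=1).astype(int)
    else:
        network = np.zeros(len(matrix.sample_ids), dtype=int)
    counts = np.zeros(len(matrix.sample_ids), dtype=int)
    for (a, b), _ in screening.screened_pairs:
        counts += (matrix.gene_column(a).astype(bool)
                   & matrix.gene_column(b).astype(bool)).astype(int)
    feats = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "tumor_size": clin["tumor_size"].to_numpy(),
        "ajcc_stage": clin["ajcc_stage"].to_numpy(),
        "network_gene_mutated": network,
        "pair_count": counts,
        "cooccurrence_category": [categorize_pair_count(c) for c in counts],
        "response": (clin["response"] == "CR").astype(int).to_numpy(),
    })
    n_before = len(feats)
    feats = feats.dropna(subset=["tumor_size", "ajcc_stage"]).reset_index(drop=True)
    if n_before - len(feats):
        logger.warning("%d samples dropped for missing tumor size or stage",
                       n_before - len(feats))
    return feats


def _design(features: pd.DataFrame, count_form: str):
    """Design matrix with reference coding: stage 2, category '0',
    indicator 'no mutation' are the reference levels."""
    n = len(features)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append(features["tumor_size"].to_numpy(float)); names.append("tumor_size")
    stage = pd.to_numeric(features["ajcc_stage"], errors="coerce").to_numpy(float)
    cols.append((stage == 3).astype(float)); names.append("ajcc_stage_3")
    cols.append(features["network_gene_mutated"].to_numpy(float))
    names.append("network_gene_mutated")
    if count_form == "categorical":
        cat = features["cooccurrence_category"]
        cols.append((cat == "1-2").to_numpy(float)); names.append("cooccur_1-2")
        cols.append((cat == "3 or more").to_numpy(float)); names.append("cooccur_3plus")
    elif count_form == "continuous":
        cols.append(features["pair_count"].to_numpy(float)); names.append("pair_count")
    elif count_form != "none":
        raise ValueError(f"unknown count_form {count_form!r}")
    return np.column_stack(cols), names


def fit_response_model(features: pd.DataFrame, count_form: str = "categorical",
                       threshold: float = 0.5) -> ResponseModelFit:
    """Fit the complete-response logistic model on the feature table.

    Reports Wald odds-ratio confidence intervals (exp(beta +/- 1.96 SE)),
    Tjur R-squared, AIC, a likelihood-ratio test for the co-occurrence
    term block (nested refit without it), and training-set metrics at
    the classification threshold.
    """
    y = features["response"].to_numpy(float)
    if len(features) < 20 or y.min() == y.max():
        raise ValueError("need >= 20 observations with both response classes")
    X, names = _design(features, count_form)
    # unobserved factor levels / empty mutation indicators cannot be estimated
    droppable = {"network_gene_mutated", "cooccur_1-2", "cooccur_3plus",
                 "pair_count"}
    keep = [j for j, name in enumerate(names)
            if not (name in droppable and np.all(X[:, j] == X[0, j]))]
    if len(keep) < len(names):
        dropped = [names[j] for j in range(len(names)) if j not in keep]
        logger.warning("dropping constant model term(s): %s", dropped)
        X, names = X[:, keep], [names[j] for j in keep]
    fit = statcore.logistic_mle(X, y, column_names=names)
    z = stats.norm.ppf(0.975)
    beta, se = fit.coefficients, fit.standard_errors
    wald_p = 2 * stats.norm.sf(np.abs(beta / np.where(se > 0, se, np.inf)))
    ors = pd.DataFrame({
        "OR": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "p_value": wald_p,
    }, index=names)
    r2 = statcore.tjur_r2(fit, y)
    lrt = None
    count_terms = {"cooccur_1-2", "cooccur_3plus", "pair_count"}
    if count_form != "none" and any(n in count_terms for n in names):
        X0, names0 = _design(features, "none")
        keep0 = [j for j, name in enumerate(names0) if name in names]
        X0, names0 = X0[:, keep0], [names0[j] for j in keep0]
        fit0 = statcore.logistic_mle(X0, y, column_names=names0)
        stat = 2.0 * (fit.log_likelihood - fit0.log_likelihood)
        df = X.shape[1] - X0.shape[1]
        lrt = (float(stat), float(stats.chi2.sf(max(stat, 0.0), df)))
    model = ResponseModelFit(fit=fit, terms=names, odds_ratios=ors, tjur_r2=r2,
                             aic=fit.aic, n_obs=fit.n_obs, count_form=count_form,
                             lrt_cooccurrence=lrt, response=y)
    model.metrics = performance_metrics(model, threshold=threshold)
    return model


def select_model(candidates: list[ResponseModelFit]) -> ResponseModelFit:
    """Lowest AIC wins; near-ties (dAIC < 1e-6) break to highest Tjur R2.

    When the AIC winner is not also the Tjur winner, the AIC winner is
    returned with an explicit conflict warning.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    by_aic = min(candidates, key=lambda m: m.aic)
    tied = [m for m in candidates if abs(m.aic - by_aic.aic) < 1e-6]
    chosen = max(tied, key=lambda m: m.tjur_r2)
    by_tjur = max(candidates, key=lambda m: m.tjur_r2)
    if by_tjur is not chosen and by_tjur.tjur_r2 > chosen.tjur_r2:
        warnings.warn(
            f"model-selection criteria disagree: AIC prefers {chosen.count_form} "
            f"(AIC {chosen.aic:.2f}) but Tjur R2 prefers {by_tjur.count_form} "
            f"({by_tjur.tjur_r2:.3f} vs {chosen.tjur_r2:.3f}); choosing by AIC",
            UserWarning, stacklevel=2)
    return chosen


def performance_metrics(model: ResponseModelFit,
                        threshold: float = 0.5) -> dict[str, float]:
    """Training-set sensitivity/specificity/PPV/NPV at a probability cutoff.

    Predicted CR when the fitted probability is >= threshold.  Ratios
    with zero denominator are reported as NaN with a warning.
    """
    y = model.response
    p = model.fit.fitted_probabilities
    pred = p >= threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", UserWarning,
                          stacklevel=3)
            return float("nan")
        return num / den

    return {
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "ppv": ratio(tp, tp + fp, "PPV"),
        "npv": ratio(tn, tn + fn, "NPV"),
        "threshold": threshold,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def run_model_selection(features: pd.DataFrame,
                        threshold: float = 0.5) -> ResponseModelFit:
    """Fit both count functional forms and select as the study protocol does."""
    forms = ["categorical", "continuous"]
    candidates = [fit_response_model(features, f, threshold) for f in forms]
    return select_model(candidates)


def run_pipeline(clinical: pd.DataFrame, matrix: MutationMatrix,
                 alpha_screen: float = 0.1, min_freq: float = 0.05,
                 top: int = 25, adjust_interactions: bool = False,
                 threshold: float = 0.5):
    """Screen -> features -> fit -> select, end to end.

    Candidate genes for the interaction network are those above
    ``min_freq`` capped at the ``top`` most frequent; pairs labelled
    co-occurring feed the pair screen.  ``adjust_interactions``
    switches the co-occurrence call to BH-adjusted significance.
    Returns ``(screening, features, selected_model)``.
    """
    from . import mutnet as _mutnet  # local import avoids a cycle

    labels = clinical.set_index("sample_id").loc[
        matrix.sample_ids, "response"].to_numpy()
    genes = _mutnet.select_candidate_genes(matrix, min_freq=min_freq, top=top)
    if len(genes) >= 2:
        inter = [it for it in _mutnet.pairwise_interactions(
            matrix, genes, adjust=adjust_interactions)
            if it.label == "co-occurring"]
    else:
        inter = []
    screening = screen_predictors(matrix, inter, labels, alpha_screen)
    features = build_features(clinical, matrix, screening)
    model = run_model_selection(features, threshold=threshold)
    return screening, features, model
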