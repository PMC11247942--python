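"""Matching-weight propensity-score balancing of CR vs ICR cohorts.

The propensity of complete response is fit by logistic regression on
clinical covariates; samples are re-weighted with the matching-weight
scheme w = min(e, 1-e)/e for the treated (CR) group and
min(e, 1-e)/(1-e) for the comparison (ICR) group, which emulates 1:1
pair matching via weighting.  Balance is checked by weighted
standardized differences, and the propensity model is revised
(squared terms, then interactions) until every covariate balances to
within a threshold (default 10%) or the iteration cap is reached.
The balanced weights then feed a weighted t-test of tumor mutation
burden between the groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import statcore
from .statcore import TestResult, WeightedSampleSet

__all__ = [
    "PropensitySpec",
    "BalanceReport",
    "BalancedCohort",
    "DEFAULT_COVARIATES",
    "fit_propensity",
    "matching_weights",
    "balance_report",
    "iterate_balance",
    "compare_tmb_weighted",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "gender", "bmi", "tumor_size", "t_stage", "n_stage"]

#: propensity scores are clipped into this open interval before weighting
SCORE_CLIP = 1e-6


@dataclass
class PropensitySpec:
    """Covariates and model terms for the propensity logistic regression.

    ``model_terms`` are tuples: ``("main", col)``, ``("square", col)``
    or ``("interaction", col1, col2)`` over encoded covariate columns;
    when empty, main effects of every covariate are used.
    """

    covariates: list[str]
    model_terms: list[tuple] = field(default_factory=list)
    treated_label: str = "CR"

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("covariate list must be non-empty")


def encode_covariates(clinical: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric encoding of clinical covariates.

    Continuous columns pass through; two-level categoricals become a
    single 0/1 indicator; multi-level categoricals expand to one
    indicator per non-reference level (reference = first sorted level).
    Rows with any missing covariate are dropped (complete-case).
    """
    missing = [c for c in covariates if c not in clinical.columns]
    if missing:
        raise ValueError(f"covariates absent from clinical table: {missing}")
    sub = clinical[covariates].copy()
    n_before = len(sub)
    keep = sub.notna().all(axis=1)
    sub = sub[keep]
    if (n_before - len(sub)):
        logger.warning("%d rows with missing covariates excluded from balancing",
                       n_before - len(sub))
    out = {}
    for c in covariates:
        col = sub[c]
        if pd.api.types.is_numeric_dtype(col):
            out[c] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                out[c] = pd.Series(0.0, index=col.index)
            elif len(levels) == 2:
                out[c] = (col.astype(str) == levels[1]).astype(float)
            else:
                for lev in levels[1:]:
                    out[f"{c}={lev}"] = (col.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=sub.index)


def _design_from_terms(encoded: pd.DataFrame, terms: list[tuple]):
    """Build the propensity design matrix (continuous columns standardized)."""
    cols, names = [np.ones(len(encoded))], ["intercept"]
    z = {}
    for c in encoded.columns:
        x = encoded[c].to_numpy(dtype=float)
        sd = x.std()
        is_binary = set(np.unique(x)) <= {0.0, 1.0}
        z[c] = x if is_binary or sd == 0 else (x - x.mean()) / sd
    for term in terms:
        kind = term[0]
        if kind == "main":
            col, name = z[term[1]], term[1]
        elif kind == "square":
            col, name = z[term[1]] ** 2, f"{term[1]}^2"
        elif kind == "interaction":
            col, name = z[term[1]] * z[term[2]], f"{term[1]}:{term[2]}"
        else:
            raise ValueError(f"unknown term kind {kind!r}")
        if np.all(col == col[0]):
            logger.info("dropping uninformative constant term %s", name)
            continue
        cols.append(col); names.append(name)
    return np.column_stack(cols), names


def fit_propensity(clinical: pd.DataFrame, spec: PropensitySpec) -> pd.Series:
    """Fitted probability of complete response given covariates.

    Returns scores indexed like the complete-case subset of the
    clinical table; scores are clipped away from 0 and 1.
    """
    encoded = encode_covariates(clinical, spec.covariates)
    terms = spec.model_terms or [("main", c) for c in encoded.columns]
    X, names = _design_from_terms(encoded, terms)
    y = (clinical.loc[encoded.index, "response"] == spec.treated_label).to_numpy(float)
    fit = statcore.logistic_mle(X, y, column_names=names)
    if not fit.converged:
        warnings.warn(
            "propensity model did not converge (possible separation); "
            "consider simplifying the model terms",
            statcore.SeparationWarning, stacklevel=2)
    scores = np.clip(fit.fitted_probabilities, SCORE_CLIP, 1 - SCORE_CLIP)
    return pd.Series(scores, index=encoded.index, name="propensity")


def matching_weights(scores, group, treated_label: str = "CR") -> np.ndarray:
    """Matching weights from CR-propensity scores.

    Treated (CR): ``min(e, 1-e)/e``; comparison (ICR): ``min(e, 1-e)/(1-e)``.
    """
    e = np.asarray(scores, dtype=float)
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("propensity scores must lie strictly inside (0,1)")
    g = np.asarray(group)
    treated = g == treated_label
    m = np.minimum(e, 1 - e)
    return np.where(treated, m / e, m / (1 - e))


@dataclass
class BalanceReport:
    """Standardized differences (%) per encoded covariate, before/after weighting."""

    before: pd.Series
    after: pd.Series
    iterations_used: int
    converged: bool
    final_terms: list[tuple]
    threshold: float = 10.0
    history: list[pd.Series] = field(default_factory=list)

    @property
    def max_after(self) -> float:
        return float(self.after.max())


@dataclass
class BalancedCohort:
    sample_ids: list
    propensity_scores: pd.Series
    matching_weights: pd.Series
    group: pd.Series
    report: BalanceReport


def _smd_table(encoded: pd.DataFrame, treated: np.ndarray,
               weights: np.ndarray) -> pd.Series:
    out = {}
    for c in encoded.columns:
        x = encoded[c].to_numpy(dtype=float)
        g1 = WeightedSampleSet(x[treated], weights[treated])
        g0 = WeightedSampleSet(x[~treated], weights[~treated])
        out[c] = statcore.standardized_difference(g1, g0)
    return pd.Series(out, name="smd_percent")


def balance_report(clinical: pd.DataFrame, weights, spec: PropensitySpec,
                   threshold: float = 10.0) -> BalanceReport:
    """Before/after standardized differences for every encoded covariate."""
    encoded = encode_covariates(clinical, spec.covariates)
    treated = (clinical.loc[encoded.index, "response"] == spec.treated_label).to_numpy()
    w = np.asarray(weights, dtype=float)
    if w.size != len(encoded):
        raise ValueError("weights misaligned with complete-case clinical rows")
    before = _smd_table(encoded, treated, np.ones(len(encoded)))
    after = _smd_table(encoded, treated, w)
    return BalanceReport(before=before, after=after, iterations_used=1,
                         converged=bool((after < threshold).all()),
                         final_terms=list(spec.model_terms), threshold=threshold)


def _augment(terms: list[tuple], after: pd.Series, encoded: pd.DataFrame) -> list[tuple]:
    """Add the square of the worst-balanced continuous covariate, or an
    interaction with the next-worst if that square is already present."""
    continuous = [c for c in encoded.columns
                  if not set(np.unique(encoded[c])) <= {0.0, 1.0}]
    ranked = after.sort_values(ascending=False).index.tolist()
    worst_cont = next((c for c in ranked if c in continuous), None)
    if worst_cont is not None and ("square", worst_cont) not in terms:
        return terms + [("square", worst_cont)]
    anchor = worst_cont if worst_cont is not None else ranked[0]
    for nxt in ranked:
        if nxt == anchor:
            continue
        cand = ("interaction", *sorted((anchor, nxt)))
        if cand not in terms:
            return terms + [cand]
    # everything tried: add squares of remaining continuous covariates
    for c in continuous:
        if ("square", c) not in terms:
            return terms + [("square", c)]
    return terms


def iterate_balance(clinical: pd.DataFrame, spec: PropensitySpec,
                    threshold: float = 10.0, max_iter: int = 10) -> BalancedCohort:
    """Fit propensity, weight, check balance; revise the model until
    every weighted standardized difference drops below ``threshold``.

    Revision is deterministic: each failed check appends the squared
    term of the worst-balanced continuous covariate, falling back to
    pairwise interactions once squares are exhausted.  A cohort that
    never balances is returned with ``converged=False`` and a warning.
    """
    encoded = encode_covariates(clinical, spec.covariates)
    sub = clinical.loc[encoded.index]
    treated = (sub["response"] == spec.treated_label).to_numpy()
    terms = list(spec.model_terms) or [("main", c) for c in encoded.columns]
    before = _smd_table(encoded, treated, np.ones(len(encoded)))
    history: list[pd.Series] = []
    scores = weights = after = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        it_spec = PropensitySpec(spec.covariates, terms, spec.treated_label)
        scores = fit_propensity(sub, it_spec)
        weights = matching_weights(scores.to_numpy(), sub["response"].to_numpy(),
                                   spec.treated_label)
        after = _smd_table(encoded, treated, weights)
        history.append(after)
        if (after < threshold).all():
            break
        if n_iter < max_iter:
            new_terms = _augment(terms, after, encoded)
            if new_terms == terms:
                logger.warning("no further model terms available; stopping early")
                break
            logger.info("balance iteration %d: adding term %s", n_iter, new_terms[-1])
            terms = new_terms
    converged = bool((after < threshold).all())
    if not converged:
        warnings.warn(
            f"covariate balance not achieved after {n_iter} iteration(s); "
            f"worst standardized difference {after.max():.1f}%",
            UserWarning, stacklevel=2)
    report = BalanceReport(before=before, after=after, iterations_used=n_iter,
                           converged=converged, final_terms=terms,
                           threshold=threshold, history=history)
    return BalancedCohort(sample_ids=list(sub["sample_id"]),
                          propensity_scores=scores,
                          matching_weights=pd.Series(weights, index=encoded.index,
                                                     name="matching_weight"),
                          group=sub["response"],
                          report=report)


def compare_tmb_weighted(tmb, group, weights, treated_label: str = "CR") -> TestResult:
    """Weighted t-test of tumor mutation burden, CR minus ICR."""
    tmb = np.asarray(tmb, dtype=float)
    w = np.asarray(weights, dtype=float)
    g = np.asarray(group)
    treated = g == treated_label
    g1 = WeightedSampleSet(tmb[treated], w[treated])
    g0 = WeightedSampleSet(tmb[~treated], w[~treated])
    return statcore.weighted_ttest(g1, g0)
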