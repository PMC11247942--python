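"""Statistical primitives shared by every pipeline stage.

Exact and chi-squared 2x2 tests, Benjamini-Hochberg adjustment, the
weighted two-sample t-test used for balanced tumor-mutation-burden
comparisons, standardized differences for covariate balance checking,
and a maximum-likelihood logistic fitter (IRLS) that backs both the
propensity model and the complete-response prediction model.

Weight conventions: weights are treated as *reliability* weights.  The
weighted variance is ``sum(w*(x-m)^2) * W / (W^2 - sum(w^2))`` with
``W = sum(w)``, and the effective sample size is ``W^2 / sum(w^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "WeightedSampleSet",
    "TestResult",
    "LogisticFit",
    "DegenerateInputError",
    "SeparationWarning",
    "fisher_exact_2x2",
    "chi2_yates",
    "bh_adjust",
    "weighted_ttest",
    "logistic_mle",
    "tjur_r2",
    "standardized_difference",
]

#: relative tolerance for "probability <= observed" ties in the exact test
_FISHER_REL_TOL = 1e-7


class DegenerateInputError(ValueError):
    """Raised when a test is requested on inputs where it is undefined."""


class SeparationWarning(UserWarning):
    """Emitted when a logistic fit shows signs of (quasi-)complete separation."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 cell counts: rows = factor 1 present/absent, cols = factor 2 present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cell counts must be non-negative integers, got {cells}")
        if sum(cells) < 1:
            raise DegenerateInputError("all-zero 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class WeightedSampleSet:
    """A vector of observations with non-negative reliability weights."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if v.shape != w.shape or v.ndim != 1:
            raise ValueError("values and weights must be 1-d arrays of equal length")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")
        if np.count_nonzero(w) < 2:
            raise ValueError("need at least 2 entries with positive weight")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    @classmethod
    def unit(cls, values) -> "WeightedSampleSet":
        v = np.asarray(values, dtype=float)
        return cls(v, np.ones_like(v))

    @property
    def sum_w(self) -> float:
        return float(self.weights.sum())

    @property
    def mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))

    @property
    def variance(self) -> float:
        """Reliability-weight unbiased variance; 0 if the denominator degenerates."""
        w, x = self.weights, self.values
        sw = w.sum()
        sw2 = (w**2).sum()
        denom = sw**2 - sw2
        if denom <= 0:
            return 0.0
        m = self.mean
        return float((w * (x - m) ** 2).sum() * sw / denom)

    @property
    def effective_n(self) -> float:
        w = self.weights
        return float(w.sum() ** 2 / (w**2).sum())


@dataclass(frozen=True)
class TestResult:
    """Uniform container for a two-group or 2x2 test outcome."""

    statistic: float
    p_value: float
    estimate: float
    df: float | None
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")
        if not self.method:
            raise ValueError("method label must be non-empty")


@dataclass
class LogisticFit:
    """Bernoulli MLE summary: coefficients (intercept first), SEs, fit statistics."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    fitted_probabilities: np.ndarray
    column_names: list[str] = field(default_factory=list)


def _hypergeom_support(table: ContingencyTable2x2):
    """Support and pmf of the a-cell under fixed margins."""
    r1 = table.a + table.b
    c1 = table.a + table.c
    n = table.n
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    return support, pmf


def _odds_ratio_estimate(table: ContingencyTable2x2) -> float:
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        # Haldane-Anscombe correction, applied to the estimate only
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p-value sums hypergeometric probabilities (margins
    fixed) of every outcome whose probability is at most that of the
    observed table, with a small relative tolerance guarding floating
    point ties.  The reported estimate is the sample odds ratio
    ``ad/bc`` with a Haldane +0.5 correction to every cell when any
    cell is zero (estimate only; the p-value is always exact).
    """
    support, pmf = _hypergeom_support(table)
    p_obs = float(pmf[support == table.a][0])
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_REL_TOL)].sum())
    p = min(1.0, p)
    or_hat = _odds_ratio_estimate(table)
    return TestResult(statistic=or_hat, p_value=p, estimate=or_hat, df=None,
                      method="fisher_exact_2x2")


def chi2_yates(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-squared test with Yates continuity correction, df=1."""
    obs = table.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateInputError("zero row or column margin in 2x2 table")
    expected = np.outer(rows, cols) / table.n
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic=statistic, p_value=p,
                      estimate=_odds_ratio_estimate(table), df=1.0,
                      method="chi2_yates")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def weighted_ttest(group1: WeightedSampleSet, group0: WeightedSampleSet) -> TestResult:
    """Welch-style two-sample t-test on weighted samples.

    Uses reliability-weight variances and effective sample sizes
    ``(sum w)^2 / sum w^2``; degrees of freedom by Welch-Satterthwaite
    on the effective sizes.  With unit weights this reduces exactly to
    the unweighted Welch t-test.
    """
    for g in (group1, group0):
        if g.sum_w <= 0:
            raise ValueError("zero total weight")
        if g.effective_n <= 1:
            raise ValueError("effective sample size must exceed 1")
    m1, m0 = group1.mean, group0.mean
    v1, v0 = group1.variance, group0.variance
    n1, n0 = group1.effective_n, group0.effective_n
    diff = m1 - m0
    se2 = v1 / n1 + v0 / n0
    if se2 == 0.0:
        # both variances zero: p=1 when the means agree, else certain difference
        p = 1.0 if diff == 0.0 else 0.0
        return TestResult(statistic=0.0 if diff == 0.0 else np.inf * np.sign(diff),
                          p_value=p, estimate=diff, df=n1 + n0 - 2,
                          method="weighted_ttest")
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=p, estimate=float(diff),
                      df=float(df), method="weighted_ttest")


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    # identify offending columns: each that lies in the span of its predecessors
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        beta, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
        resid = X[:, j] - prev @ beta
        scale = max(1.0, float(np.abs(X[:, j]).max()))
        if np.linalg.norm(resid) < 1e-8 * scale * np.sqrt(X.shape[0]):
            bad.append(names[j])
    raise np.linalg.LinAlgError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
        f"collinear columns: {bad or 'undetermined'}"
    )


def logistic_mle(design, response, weights=None, column_names=None,
                 max_iter: int = 100, score_tol: float = 1e-8,
                 coef_tol: float = 1e-10) -> LogisticFit:
    """Fit a Bernoulli GLM with logit link by iteratively reweighted least squares.

    Parameters
    ----------
    design
        n x k predictor matrix; the caller supplies the intercept column.
    response
        binary 0/1 vector of length n.
    weights
        optional non-negative case weights.
    column_names
        labels used in rank-deficiency errors and separation warnings.

    Convergence is declared when the maximum absolute score drops below
    ``score_tol`` or no coefficient moves more than ``coef_tol``.
    Quasi-complete separation is detected heuristically: any coefficient
    exceeding 15 in absolute value on a standardized column flags the
    fit as non-converged with a :class:`SeparationWarning`.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("design must be n x k and response length n")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("response must be binary 0/1")
    n, k = X.shape
    if n < k:
        raise ValueError(f"need at least as many observations ({n}) as columns ({k})")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    names = list(column_names) if column_names is not None else [f"x{j}" for j in range(k)]
    _check_full_rank(X * np.sqrt(w)[:, None], names)

    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        score = X.T @ (w * (y - p))
        if np.abs(score).max() < score_tol:
            converged = True
            break
        irls_w = w * p * (1 - p)
        H = X.T @ (X * irls_w[:, None])
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, score, rcond=None)[0]
        beta = beta + delta
        if np.abs(delta).max() < coef_tol:
            converged = True
            break

    p = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    # separation heuristic on standardized columns
    col_sd = X.std(axis=0)
    col_sd[col_sd == 0] = 1.0
    std_beta = beta * col_sd
    sep = np.abs(std_beta) > 15.0
    if sep.any():
        converged = False
        warnings.warn(
            "possible (quasi-)complete separation; inflated coefficients for: "
            + ", ".join(names[j] for j in np.flatnonzero(sep)),
            SeparationWarning,
            stacklevel=2,
        )
    irls_w = w * p * (1 - p)
    H = X.T @ (X * irls_w[:, None])
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    ll = float((w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum())
    aic = 2.0 * k - 2.0 * ll
    return LogisticFit(coefficients=beta, standard_errors=se, log_likelihood=ll,
                       aic=aic, n_obs=n, converged=converged,
                       fitted_probabilities=expit(X @ beta), column_names=names)


def tjur_r2(fit: LogisticFit, response) -> float:
    """Tjur's discrimination coefficient.

    Mean fitted probability among events minus mean among non-events.
    """
    y = np.asarray(response, dtype=float)
    p = np.asarray(fit.fitted_probabilities, dtype=float)
    if y.size != p.size:
        raise ValueError("response and fitted probabilities are misaligned")
    if np.all(y == 1) or np.all(y == 0):
        raise DegenerateInputError("Tjur R^2 undefined when the response has one class")
    return float(p[y == 1].mean() - p[y == 0].mean())


def standardized_difference(group1: WeightedSampleSet, group0: WeightedSampleSet,
                            binary: bool | None = None) -> float:
    """Absolute standardized mean difference between two weighted samples, percent.

    ``100 * |m1 - m0| / sqrt((v1 + v0)/2)`` with weighted means and
    reliability-weight variances.  Binary covariates (auto-detected from
    a {0,1} support unless overridden) use the Bernoulli variance
    ``p(1-p)``.  Returns ``inf`` if both variances are zero but the
    means differ; 0 if the groups are identical in mean and variance.
    """
    m1, m0 = group1.mean, group0.mean
    if binary is None:
        vals = np.concatenate([group1.values, group0.values])
        binary = bool(np.all(np.isin(vals, (0.0, 1.0))))
    if binary:
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    else:
        v1, v0 = group1.variance, group0.variance
    pooled = (v1 + v0) / 2.0
    if pooled <= 0:
        return 0.0 if m1 == m0 else float("inf")
    return float(100.0 * abs(m1 - m0) / np.sqrt(pooled))
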