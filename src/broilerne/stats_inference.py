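"""Correlation screening, ANOVA with Duncan grouping, stepwise regression.

The prediction-equation workflow mirrors common nutrition practice:
screen pairwise Pearson correlations among candidate predictors, fit a
bidirectional stepwise least-squares model of NE on composition and
metabolizable-energy values while refusing predictor sets that contain a
significantly correlated pair, then validate the fitted equation on
held-out samples by the Pearson correlation of predicted versus measured
values.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "AnovaResult",
    "RegressionEquation",
    "ValidationResult",
    "pearson_matrix",
    "one_way_anova",
    "duncan_groups",
    "stepwise_fit",
    "predict_ne",
    "validate",
]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


@dataclass
class AnovaResult:
    groups: list[str]
    means: dict[str, float]
    f_stat: float
    p_value: float
    pooled_sem: float
    duncan_letters: dict[str, str]
    mse: float
    df_error: int
    degenerate: bool = False


@dataclass
class RegressionEquation:
    """A fitted (or transcribed) linear NE prediction equation."""

    response: str
    terms: list[tuple[str, float]]
    intercept: float
    r2: Optional[float] = None
    n: Optional[int] = None
    selection_trace: list[str] = field(default_factory=list)

    def predictors(self) -> list[str]:
        return [name for name, _ in self.terms]

    def __str__(self) -> str:
        parts = [f"{coef:+.3f}*{name}" for name, coef in self.terms]
        return (f"{self.response} = {' '.join(parts)} {self.intercept:+.3f}"
                + (f"  (R2={self.r2:.3f}, n={self.n})" if self.r2 is not None
                   else ""))


@dataclass
class ValidationResult:
    pairs: list[tuple[float, float]]  # (measured, predicted)
    pearson_r: Optional[float]
    p_value: Optional[float] = None


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    Rows with a missing value in either column of a pair are dropped for
    that pair (pairwise-complete). Zero-variance columns yield NaN
    correlations and a warning.
    """
    table = table.select_dtypes(include=[np.number])
    if table.shape[0] < 3 or table.shape[1] < 2:
        raise ValueError("need >=3 rows and >=2 numeric columns")
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = table[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                logger.warning("zero-variance column in pair (%s, %s)",
                               cols[i], cols[j])
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    to_df = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationMatrix(variables=cols, r=to_df(r), p=to_df(p),
                             n=to_df(n))


@lru_cache(maxsize=4096)
def _q_crit(prob: float, span: int, df: int) -> float:
    # studentized-range quantiles are expensive; cache by arguments
    return float(stats.studentized_range.ppf(prob, span, df))


def duncan_groups(means: Sequence[float], mse: float, df_error: int,
                  n_per_group: Sequence[int] | int,
                  alpha: float = 0.05) -> list[str]:
    """Duncan's multiple-range letters for a set of group means.

    For a span of p ordered means the critical range is
    q*(p, df_error) * sqrt(MSE/n), where q* is the studentized-range
    quantile at the protection level 1 - (1-alpha)^(p-1). Unequal group
    sizes are handled by the harmonic mean (flagged with a warning).
    Letters are returned in the input order of ``means``.
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    means = np.asarray(means, dtype=float)
    k = means.size
    if np.isscalar(n_per_group) or isinstance(n_per_group, int):
        n_h = float(n_per_group)
    else:
        sizes = np.asarray(n_per_group, dtype=float)
        n_h = sizes.size / np.sum(1.0 / sizes)
        if len(set(sizes.tolist())) > 1:
            logger.warning("unequal group sizes; using harmonic mean n=%.2f",
                           n_h)
    order = np.argsort(-means)  # descending
    sorted_means = means[order]
    se = np.sqrt(mse / n_h)

    def crit(span: int) -> float:
        if se == 0:
            return 0.0
        protection = 1.0 - (1.0 - alpha) ** (span - 1)
        return _q_crit(round(1.0 - protection, 12), span, df_error) * se

    # nonsig[i][j]: means i..j (sorted order) not significantly different;
    # a range is protected (non-significant) if its own span test fails to
    # reject or it is contained in a larger non-significant range.
    nonsig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if sorted_means[i] - sorted_means[j] <= crit(span) or (
                    (i > 0 and nonsig[i - 1, j]) or
                    (j < k - 1 and nonsig[i, j + 1])):
                nonsig[i, j] = True
    for i in range(k):
        nonsig[i, i] = True

    # maximal non-significant stretches -> one letter each
    stretches = []
    j_seen = -1
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if j > j_seen:  # not contained in an earlier stretch
            stretches.append((i, j))
            j_seen = j
    letters_sorted = ["" for _ in range(k)]
    alphabet = string.ascii_lowercase
    for s_idx, (i, j) in enumerate(stretches):
        letter = alphabet[s_idx % len(alphabet)]
        for idx in range(i, j + 1):
            letters_sorted[idx] += letter
    out = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        out[orig] = letters_sorted[pos]
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]],
                  alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA with Duncan's multiple-range letters.

    ``pooled_sem`` is sqrt(MSE / harmonic-mean group size), the per-group
    standard error reported alongside treatment means in feeding-trial
    tables.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(data) < 2:
        raise ValueError("need >= 2 groups")
    if min(d.size for d in data) < 2:
        raise ValueError("each group needs >= 2 replicates")
    k = len(data)
    n_total = sum(d.size for d in data)
    grand = np.concatenate(data).mean()
    ss_between = sum(d.size * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    degenerate = mse == 0
    if degenerate:
        logger.warning("zero within-group variance; ANOVA degenerate")
        f = np.inf if ms_between > 0 else np.nan
        p = 0.0 if ms_between > 0 else np.nan
    else:
        f = ms_between / mse
        p = float(stats.f.sf(f, df_b, df_w))
    sizes = [d.size for d in data]
    n_h = k / sum(1.0 / s for s in sizes)
    sem = float(np.sqrt(mse / n_h))
    letters = duncan_groups([d.mean() for d in data], mse, df_w, sizes,
                            alpha=alpha)
    return AnovaResult(groups=names,
                       means={g: float(d.mean()) for g, d in zip(names, data)},
                       f_stat=float(f), p_value=float(p), pooled_sem=sem,
                       duncan_letters=dict(zip(names, letters)),
                       mse=float(mse), df_error=df_w, degenerate=degenerate)


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_fit(y: Sequence[float], candidates: pd.DataFrame,
                 response: str = "NE",
                 alpha_enter: float = 0.05, alpha_remove: float = 0.10,
                 collinearity_alpha: float = 0.05) -> RegressionEquation:
    """Bidirectional stepwise least squares with a collinearity screen.

    At each forward step the candidate with the smallest partial-F
    p-value enters if that p-value is below ``alpha_enter`` and no pair
    of predictors in the resulting set is correlated with
    p < ``collinearity_alpha``; backward steps then remove any included
    term whose p-value exceeds ``alpha_remove``. If nothing can enter,
    an intercept-only equation is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    if candidates.shape[0] != y.size:
        raise ValueError("y and candidates have different lengths")
    if y.size <= 1:
        raise ValueError("need more observations than fitted parameters")
    included: list[str] = []
    trace: list[str] = []

    # pairwise predictor correlation p-values for the screen
    corr_p: dict[frozenset, float] = {}
    cols = list(candidates.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            xa, xb = candidates[a], candidates[b]
            if xa.std() == 0 or xb.std() == 0:
                corr_p[frozenset((a, b))] = 1.0
            else:
                corr_p[frozenset((a, b))] = stats.pearsonr(xa, xb).pvalue

    def blocked(cand: str) -> bool:
        return any(corr_p[frozenset((cand, inc))] < collinearity_alpha
                   for inc in included)

    while True:
        changed = False
        # stop once the fit is (numerically) perfect: partial tests on a
        # zero residual are meaningless
        if included and _ols(y, candidates[included]).rsquared > 1 - 1e-10:
            break
        # forward
        best_p, best_c = None, None
        for cand in cols:
            if cand in included or blocked(cand):
                continue
            if y.size - (len(included) + 2) < 1:
                continue  # no residual df left
            model = _ols(y, candidates[included + [cand]])
            pval = model.pvalues[cand]
            if np.isnan(pval):
                continue
            if best_p is None or pval < best_p:
                best_p, best_c = pval, cand
        if best_c is not None and best_p < alpha_enter:
            included.append(best_c)
            trace.append(f"enter {best_c} (p={best_p:.4g})")
            changed = True
        # backward
        while included:
            model = _ols(y, candidates[included])
            pvals = model.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > alpha_remove:
                included.remove(worst)
                trace.append(f"remove {worst} (p={pvals[worst]:.4g})")
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        logger.warning("no candidate passed entry; intercept-only equation")
        return RegressionEquation(response=response, terms=[],
                                  intercept=float(y.mean()),
                                  r2=0.0, n=int(y.size),
                                  selection_trace=trace)
    model = _ols(y, candidates[included])
    return RegressionEquation(
        response=response,
        terms=[(name, float(model.params[name])) for name in included],
        intercept=float(model.params["const"]),
        r2=float(model.rsquared), n=int(y.size), selection_trace=trace)


def predict_ne(equation: RegressionEquation,
               values: Mapping[str, float]) -> float:
    """Evaluate a prediction equation on one ingredient's predictor values."""
    total = equation.intercept
    for name, coef in equation.terms:
        if name not in values or values[name] is None:
            raise KeyError(f"missing predictor {name!r}")
        total += coef * values[name]
    return total


def validate(equation: RegressionEquation,
             holdout: Sequence[tuple[Mapping[str, float], float]],
             training: Optional[Sequence[tuple[Mapping[str, float], float]]]
             = None) -> ValidationResult:
    """Predicted-versus-measured agreement of an equation.

    ``holdout`` (and optional ``training``, pooled in as in a combined
    scatter of training circles plus validation triangles) are
    ``(predictor values, measured NE)`` pairs; the result carries the
    Pearson r of measured against predicted.
    """
    points = list(training or []) + list(holdout)
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    pairs = [(float(measured), predict_ne(equation, vals))
             for vals, measured in points]
    meas = np.array([m for m, _ in pairs])
    pred = np.array([p for _, p in pairs])
    if np.std(pred) == 0 or np.std(meas) == 0:
        logger.warning("constant predictions or measurements; r undefined")
        return ValidationResult(pairs=pairs, pearson_r=None)
    res = stats.pearsonr(meas, pred)
    return ValidationResult(pairs=pairs, pearson_r=float(res.statistic),
                            p_value=float(res.pvalue))
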