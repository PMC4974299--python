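"""Statistical machinery shared by all pipeline stages.

Ordinary least squares and the two-way ANOVA are thin wrappers around
statsmodels; the slope-equality test (pooled-residual t test between two
simple regressions), the Tukey-Kramer compact letter display and linear
contrasts on group means are implemented here because no installed
package exposes them in the form the pipeline needs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols as sm_ols
from statsmodels.stats.anova import anova_lm

from .types import ValidationError, _require

log = logging.getLogger(__name__)


@dataclass
class FitResult:
    """An OLS fit with everything downstream tests need retained."""

    names: list[str]  # coefficient names, intercept first
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r2: float
    residuals: np.ndarray
    n: int
    df_resid: int
    x: np.ndarray | None = None  # raw predictor (simple regression only)
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        _require(-1e-12 <= self.r2 <= 1 + 1e-12, "R2 must lie in [0, 1]")
        _require(self.df_resid >= 1, "residual degrees of freedom must be >= 1")

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        """Slope of a simple regression (exactly one predictor)."""
        if len(self.coefficients) != 2:
            raise ValidationError("slope is defined for simple regressions only")
        return float(self.coefficients[1])

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals ** 2))


@dataclass
class ContrastResult:
    estimate: float
    std_error: float
    t: float
    p: float
    df: int


@dataclass
class SlopeComparison:
    t: float
    df: int
    p: float


def ols(y, X, names: list[str] | None = None, *,
        add_intercept: bool = True) -> FitResult:
    """Ordinary least squares of ``y`` on columns of ``X``.

    ``X`` may be a 1-D array (simple regression) or 2-D (n, p). An
    intercept column is prepended unless ``add_intercept`` is False.
    Raises on singular designs, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    _require(len(y) == n, "y and X must have the same length")
    if names is None:
        names = [f"x{i+1}" for i in range(p)]
    _require(len(names) == p, "one name per predictor column required")
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    col_names = (["intercept"] if add_intercept else []) + list(names)
    _require(n > design.shape[1], "need n > number of parameters")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a minimal set of dependent columns for the message
        bad = []
        for j in range(design.shape[1]):
            others = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(col_names[j])
        raise ValidationError(f"singular design; collinear columns: {bad}")
    model = sm.OLS(y, design).fit()
    simple = p == 1 and add_intercept
    return FitResult(
        names=col_names,
        coefficients=np.asarray(model.params, dtype=float),
        std_errors=np.asarray(model.bse, dtype=float),
        p_values=np.asarray(model.pvalues, dtype=float),
        r2=float(model.rsquared),
        residuals=np.asarray(model.resid, dtype=float),
        n=n,
        df_resid=int(model.df_resid),
        x=X[:, 0].copy() if simple else None,
        y=y.copy() if simple else None,
    )


def stepwise_max_r2(y, candidates: dict[str, np.ndarray], *,
                    p_enter: float = 0.15) -> tuple[FitResult, list[str]]:
    """Forward selection maximising R2.

    At each step the candidate giving the largest R2 increase enters if
    its coefficient p-value is <= ``p_enter``. Returns the final fit and
    the selection path (order of entry). If no candidate is admissible
    at the first step a ValidationError is raised (there is no fit to
    return).
    """
    _require(len(candidates) >= 1, "at least one candidate predictor required")
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    remaining = dict(candidates)
    best_fit: FitResult | None = None
    current_r2 = 0.0
    while remaining:
        trial = []
        for name, col in remaining.items():
            cols = [np.asarray(candidates[s], dtype=float) for s in selected]
            cols.append(np.asarray(col, dtype=float))
            try:
                fit = ols(y, np.column_stack(cols), names=selected + [name])
            except ValidationError:
                continue  # collinear with already-selected predictors
            trial.append((fit.r2, name, fit))
        if not trial:
            break
        trial.sort(key=lambda t: t[0], reverse=True)
        r2, name, fit = trial[0]
        p_new = fit.p_values[-1]
        if r2 <= current_r2 + 1e-12 or p_new > p_enter:
            break
        selected.append(name)
        remaining.pop(name)
        best_fit, current_r2 = fit, r2
        log.info("stepwise: entered %s (R2=%.4f, p=%.4g)", name, r2, p_new)
    if best_fit is None:
        raise ValidationError(
            f"no candidate admissible at p_enter={p_enter}")
    return best_fit, selected


def compare_slopes(fit_a: FitResult, fit_b: FitResult) -> SlopeComparison:
    """Test equality of two simple-regression slopes.

    Pooled-residual t test: s2 = (SSE_a + SSE_b) / (n_a + n_b - 4),
    t = (b_a - b_b) / sqrt(s2 * (1/Sxx_a + 1/Sxx_b)),
    df = n_a + n_b - 4, two-sided p.
    """
    for f in (fit_a, fit_b):
        if f.x is None or f.n < 3:
            raise ValidationError(
                "compare_slopes needs simple regressions with >= 3 points "
                "and raw data retained")
    sxx_a = float(np.sum((fit_a.x - fit_a.x.mean()) ** 2))
    sxx_b = float(np.sum((fit_b.x - fit_b.x.mean()) ** 2))
    df = fit_a.n + fit_b.n - 4
    s2 = (fit_a.sse + fit_b.sse) / df
    se = np.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
    diff = fit_a.slope - fit_b.slope
    if se == 0:  # two noise-free lines
        t = np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return SlopeComparison(t=float(t), df=df, p=p)


def _clean_anova_table(table: pd.DataFrame, values) -> pd.DataFrame:
    # an effect explaining (numerically) nothing is F=0 / p=1, not the
    # 0/0 = NaN that a literal zero-variance input would produce
    v = np.asarray(values, dtype=float)
    tol = 1e-10 * (len(v) * float(np.mean(v ** 2)) + 1.0)
    zero = (table["sum_sq"] <= tol) & (table.index != "residual")
    table.loc[zero, "F"] = 0.0
    table.loc[zero, "PR(>F)"] = 1.0
    return table


@dataclass
class AnovaResult:
    table: pd.DataFrame  # index: effect, columns incl. F, PR(>F)

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "PR(>F)"])

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


def anova_two_way(values, factor_a, factor_b, *,
                  names: tuple[str, str] = ("genotype", "treatment")) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction, type-II sums of squares.

    Raises if any factor-level combination has no observation (the
    interaction model is then inestimable)."""
    a_name, b_name = names
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       a_name: list(factor_a), b_name: list(factor_b)})
    counts = df.groupby([a_name, b_name], observed=True).size()
    full = pd.MultiIndex.from_product([df[a_name].unique(), df[b_name].unique()])
    empty = [c for c in full if c not in counts.index]
    if empty:
        raise ValidationError(f"empty factor cells: {empty}")
    model = sm_ols(f"value ~ C({a_name}) * C({b_name})", data=df).fit()
    table = anova_lm(model, typ=2)
    table = table.rename(index={
        f"C({a_name})": a_name,
        f"C({b_name})": b_name,
        f"C({a_name}):C({b_name})": f"{a_name}:{b_name}",
        "Residual": "residual",
    })
    return AnovaResult(table=_clean_anova_table(table, values))


def anova_n_way(values, factors: dict[str, list], formula: str | None = None) -> AnovaResult:
    """Fixed-effects factorial ANOVA for an arbitrary factor set."""
    df = pd.DataFrame({k: list(v) for k, v in factors.items()})
    df["value"] = np.asarray(values, dtype=float)
    if formula is None:
        terms = " * ".join(f"C({k})" for k in factors)
        formula = f"value ~ {terms}"
    model = sm_ols(formula, data=df).fit()
    table = anova_lm(model, typ=2)
    clean = {f"C({k})": k for k in factors}
    table = table.rename(index=lambda s: ":".join(
        clean.get(part, part) for part in s.split(":")))
    table = table.rename(index={"Residual": "residual"})
    return AnovaResult(table=_clean_anova_table(table, values))


def tukey_pairwise_p(means: dict[str, float], n: dict[str, int],
                     mse: float, df: int) -> dict[tuple[str, str], float]:
    """Tukey-Kramer pairwise p-values from group summaries."""
    _require(mse > 0, "MSE must be positive")
    _require(len(means) >= 2, "need >= 2 groups")
    k = len(means)
    out = {}
    for g1, g2 in itertools.combinations(means, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / n[g1] + 1.0 / n[g2]))
        q = abs(means[g1] - means[g2]) / se
        out[(g1, g2)] = float(scipy.stats.studentized_range.sf(q, k, df))
    return out


def tukey_letters(means: dict[str, float], mse: float, df: int,
                  n: dict[str, int], *, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from Tukey-Kramer comparisons.

    Groups sharing a letter are not significantly different at
    ``alpha``. Uses the insert-and-absorb algorithm: one candidate
    letter set per group, split whenever a significant pair would share
    a letter, then redundant sets absorbed.
    """
    pairs = tukey_pairwise_p(means, n, mse, df)
    groups = list(means)
    significant = {frozenset(pair) for pair, p in pairs.items() if p < alpha}
    # letter sets as lists of member sets; start with one set of everything
    sets: list[set[str]] = [set(groups)]
    for g1, g2 in (tuple(s) for s in significant):
        new_sets = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.append(s - {g1})
                new_sets.append(s - {g2})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    # order letter sets by their smallest member mean for stable output
    sets.sort(key=lambda s: min(means[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def linear_contrast(means: dict[str, float], n: dict[str, int], mse: float,
                    df: int, weights: dict[str, float]) -> ContrastResult:
    """Linear contrast sum(w_i * mean_i) on group means.

    Weights must sum to zero; SE = sqrt(MSE * sum(w_i^2 / n_i))."""
    if abs(sum(weights.values())) > 1e-9:
        raise ValidationError("contrast weights must sum to 0")
    est = sum(weights[g] * means[g] for g in weights)
    se = float(np.sqrt(mse * sum(w ** 2 / n[g] for g, w in weights.items())))
    if se == 0:
        t = 0.0 if est == 0 else np.copysign(np.inf, est)
        p = 1.0 if est == 0 else 0.0
    else:
        t = est / se
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return ContrastResult(estimate=float(est), std_error=se, t=float(t),
                          p=p, df=df)


def cv(values) -> float:
    """Coefficient of variation in percent: sample SD over mean x 100."""
    v = np.asarray(values, dtype=float)
    _require(len(v) >= 2, "cv needs n >= 2")
    mean = v.mean()
    if mean == 0:
        raise ValidationError("cv undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)
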