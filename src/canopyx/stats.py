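"""Trial-level statistics: ANOVA + Tukey letters, PCA, correlation
network, and stepwise yield-model selection with LMG variance shares.

The yield-model layer follows the Model/Results idiom: build a
:class:`YieldModel` from the per-plot index table, call :meth:`fit`, and
read estimates, r², SEP (residual standard error of prediction) and
per-predictor LMG variance shares off the returned
:class:`YieldModelResults`, or print its ``summary()``.

LMG relative importance decomposes the model R² into non-negative
per-predictor shares by averaging each predictor's incremental R² over
all orderings of the predictor set; the shares sum to the model R²
exactly.  Computation uses the subset-weighted form (2^p subset fits
instead of p! orderings), which is exact and identical to full
enumeration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "anova_tukey",
    "compact_letter_display",
    "pca",
    "PCAResult",
    "correlation_network",
    "CorrelationNetwork",
    "YieldModel",
    "YieldModelResults",
    "stepwise_select",
    "variance_shares",
    "sep",
    "apply_model",
]


# ---------------------------------------------------------------------------
# ANOVA + Tukey compact letter display


def compact_letter_display(levels: list[str], rejected: dict[frozenset, bool]) -> dict[str, str]:
    """Assign letters so two levels share one iff their pair is NOT rejected.

    Insert-and-absorb algorithm: maintain a list of letter-groups (sets of
    levels); for every significantly different pair, split any group
    containing both; finally absorb groups that are subsets of others and
    letter the survivors in order of first appearance.
    """
    groups: list[set[str]] = [set(levels)]
    for pair, rej in rejected.items():
        if not rej:
            continue
        a, b = tuple(pair)
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            g1, g2 = g - {a}, g - {b}
            for new in (g1, g2):
                if new and not any(new <= other for other in groups):
                    groups.append(new)
    # absorb duplicates/subsets
    groups = [g for i, g in enumerate(groups) if not any(g < h or (g == h and j < i) for j, h in enumerate(groups))]
    # order groups by the earliest level they contain (stable letters)
    order = {lv: i for i, lv in enumerate(levels)}
    groups.sort(key=lambda g: min(order[lv] for lv in g))
    letters = {lv: "" for lv in levels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, g in zip(alphabet, groups):
        for lv in sorted(g, key=order.get):
            letters[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


def anova_tukey(
    table: pd.DataFrame,
    trait: str,
    factor: str,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA with Tukey HSD grouping of factor-level means.

    Levels with fewer than two observations are excluded (with a warning).
    Unbalanced designs use the Tukey–Kramer correction (the statsmodels
    default).  If every group has zero within-group variance the groups
    separate exactly and letters are assigned by distinct means.

    Returns a dict with keys ``f``, ``p``, ``means`` (Series by level) and
    ``letters`` (level -> compact letters; sharing a letter means the pair
    is not significant at ``alpha``).
    """
    data = table[[trait, factor]].dropna()
    counts = data.groupby(factor, observed=True)[trait].count()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"excluding {factor} levels with <2 observations: {small}", stacklevel=2)
        data = data[~data[factor].isin(small)]
    levels = list(data[factor].unique())
    if len(levels) < 2:
        raise ValueError("need at least two factor levels with >=2 observations")

    groups = [data.loc[data[factor] == lv, trait].to_numpy() for lv in levels]
    means = data.groupby(factor, observed=True)[trait].mean().reindex(levels)

    if all(np.ptp(g) == 0 for g in groups):
        # exact separation: identical means share a letter, distinct means differ
        uniq = list(dict.fromkeys(means.round(12)))
        letters = {lv: "abcdefghijklmnopqrstuvwxyz"[uniq.index(round(means[lv], 12))] for lv in levels}
        identical = len(uniq) == 1
        return {"f": 0.0 if identical else np.inf, "p": 1.0 if identical else 0.0, "means": means, "letters": letters}

    f_stat, p_val = scipy.stats.f_oneway(*groups)
    tuk = pairwise_tukeyhsd(data[trait], data[factor], alpha=alpha)
    rejected = {}
    res = tuk.summary().data[1:]
    for row in res:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        rejected[frozenset((g1, g2))] = reject
    letters = compact_letter_display(levels, rejected)
    return {
        "f": float(f_stat),
        "p": float(p_val),
        "means": means,
        "letters": letters,
        "tukey": tuk,
    }


# ---------------------------------------------------------------------------
# PCA (correlation-matrix)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame  # traits x components, orthonormal columns
    explained: np.ndarray  # shares summing to 1
    dropped: list[str] = field(default_factory=list)


def pca(table: pd.DataFrame, traits: list[str]) -> PCAResult:
    """Correlation-matrix PCA of the named trait columns.

    Traits are standardised (zero mean, unit variance) before the SVD, so
    every trait enters with equal weight regardless of units.  Constant
    traits are dropped with a warning.  Sign convention: within each
    component the largest-magnitude loading is positive.
    """
    X = table[traits].dropna()
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs >=3 complete rows and >=2 traits")
    sd = X.std(ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        warnings.warn(f"dropping constant traits: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    Z = (X - X.mean()) / X.std(ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # fix signs: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2
    explained = var / var.sum()
    comp_names = [f"PC{i+1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=X.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, explained=explained, dropped=dropped)


# ---------------------------------------------------------------------------
# correlation network


@dataclass
class CorrelationNetwork:
    edges: pd.DataFrame  # columns: trait_a, trait_b, r, p, sign
    r_threshold: float
    p_threshold: float

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for _, e in self.edges.iterrows():
            g.add_edge(e["trait_a"], e["trait_b"], r=e["r"], p=e["p"], sign=e["sign"])
        return g


def correlation_network(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    r_threshold: float = 0.6,
    p_threshold: float = 0.001,
) -> CorrelationNetwork:
    """Pairwise Pearson correlations thresholded into a trait network.

    An edge requires ``|r| > r_threshold`` *and* ``p < p_threshold``
    (two-sided, exact t-transform with n−2 df, pairwise-complete
    observations).  The p-threshold is applied uncorrected.  Pairs with
    fewer than 3 complete observations are skipped.
    """
    if traits is None:
        traits = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for a, b in itertools.combinations(traits, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            continue
        r, p = scipy.stats.pearsonr(sub[a], sub[b])
        if abs(r) > r_threshold and p < p_threshold:
            rows.append({"trait_a": a, "trait_b": b, "r": float(r), "p": float(p), "sign": 1 if r > 0 else -1})
    edges = pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p", "sign"])
    return CorrelationNetwork(edges=edges, r_threshold=r_threshold, p_threshold=p_threshold)


# ---------------------------------------------------------------------------
# OLS helpers


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    return float(_ols(y, X[:, list(cols)]).rsquared)


def variance_shares(
    table: pd.DataFrame, response: str, predictors: list[str], sampling: bool = False, n_samples: int = 2000, seed: int = 0
) -> dict[str, float]:
    """LMG decomposition of the model R² into per-predictor shares.

    Each share is the predictor's incremental R² averaged over all p!
    orderings of the predictor set, computed exactly via the equivalent
    subset-weighted sum.  Shares are non-negative and sum to the full
    model R².  Exact enumeration is refused above 12 predictors (4096+
    subsets are fine, but the caller should opt in to Monte-Carlo ordering
    sampling via ``sampling=True``).
    """
    p = len(predictors)
    if p == 0:
        raise ValueError("need at least one predictor")
    data = table[[response, *predictors]].dropna()
    y = data[response].to_numpy(dtype=float)
    X = data[predictors].to_numpy(dtype=float)

    if p > 12 and not sampling:
        raise ValueError("exact LMG enumeration refused for >12 predictors; pass sampling=True")

    if p > 12:
        rng = np.random.default_rng(seed)
        shares = np.zeros(p)
        cache: dict[tuple[int, ...], float] = {}
        for _ in range(n_samples):
            order = rng.permutation(p)
            prev: tuple[int, ...] = ()
            r2_prev = 0.0
            for j in order:
                cur = tuple(sorted(prev + (j,)))
                if cur not in cache:
                    cache[cur] = _subset_r2(y, X, cur)
                shares[j] += cache[cur] - r2_prev
                r2_prev = cache[cur]
                prev = cur
        shares /= n_samples
    else:
        cache = {(): 0.0}
        idx = tuple(range(p))
        for k in range(1, p + 1):
            for cols in itertools.combinations(idx, k):
                cache[cols] = _subset_r2(y, X, cols)
        shares = np.zeros(p)
        for j in range(p):
            rest = tuple(i for i in idx if i != j)
            for k in range(p):
                w = factorial(k) * factorial(p - 1 - k) / factorial(p)
                for cols in itertools.combinations(rest, k):
                    with_j = tuple(sorted(cols + (j,)))
                    shares[j] += w * (cache[with_j] - cache[cols])
    return dict(zip(predictors, shares))


def sep(residual_ss: float, n: int, n_predictors: int) -> float:
    """Standard error of prediction: ``sqrt(RSS / (n - p - 1))`` — the
    residual standard error of the fitted model.  Undefined for
    ``n <= p + 1``."""
    dof = n - n_predictors - 1
    if dof <= 0:
        raise ValueError(f"SEP undefined: n={n} <= predictors+1={n_predictors + 1}")
    return float(np.sqrt(residual_ss / dof))


def apply_model(coefficients: dict[str, float], intercept: float, row: pd.Series | dict) -> float:
    """Predict the response as ``intercept + sum(coef * row[name])``."""
    total = intercept
    for name, coef in coefficients.items():
        if name not in row:
            raise KeyError(f"predictor {name!r} missing from input row")
        total += coef * float(row[name])
    return float(total)


# ---------------------------------------------------------------------------
# stepwise yield model (Model/Results)


class YieldModel:
    """Stepwise-selected OLS model of a response on candidate predictors.

    Parameters
    ----------
    data : per-plot table with the response and candidate columns.
    response : response column name (grain yield).
    candidates : candidate predictor columns offered to selection.
    """

    def __init__(self, data: pd.DataFrame, response: str, candidates: list[str]):
        cols = [response, *candidates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from table: {missing}")
        self.data = data[cols].dropna().reset_index(drop=True)
        self.response = response
        self.candidates = sorted(candidates)  # lexicographic tie-break order
        if len(self.data) <= len(candidates) + 1:
            raise ValueError("need n > candidates + 1 observations")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, candidates: list[str]) -> "YieldModel":
        return cls(data, response, candidates)

    # -- selection ---------------------------------------------------------

    def _fit_set(self, predictors: list[str]):
        y = self.data[self.response].to_numpy(dtype=float)
        if predictors:
            X = self.data[predictors].to_numpy(dtype=float)
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < len(predictors) + 1:
                return None  # collinear set: caller skips
            return _ols(y, X)
        return sm.OLS(y, np.ones((len(y), 1))).fit()

    def _step(self, direction: str, criterion: str, p_enter: float, p_remove: float) -> list[str]:
        selected = [] if direction == "forward" else list(self.candidates)
        while True:
            base = self._fit_set(selected)
            changed = False
            if direction == "forward":
                best_name, best_score = None, None
                for name in self.candidates:
                    if name in selected:
                        continue
                    trial = self._fit_set(selected + [name])
                    if trial is None:
                        warnings.warn(f"skipping collinear predictor {name}", stacklevel=2)
                        continue
                    if criterion == "aic":
                        score = trial.aic
                        better = score < base.aic - 1e-10 and (best_score is None or score < best_score - 1e-10)
                    else:
                        score = trial.pvalues[-1]
                        better = score < p_enter and (best_score is None or score < best_score - 1e-12)
                    if better:
                        best_name, best_score = name, score
                if best_name is not None:
                    selected = sorted(selected + [best_name])
                    changed = True
            else:  # backward
                worst_name, worst_score = None, None
                if selected:
                    if criterion == "aic":
                        for name in selected:
                            trial = self._fit_set([c for c in selected if c != name])
                            if trial.aic < base.aic - 1e-10 and (worst_score is None or trial.aic < worst_score - 1e-10):
                                worst_name, worst_score = name, trial.aic
                    else:
                        pv = dict(zip(selected, base.pvalues[1:]))
                        name = max(sorted(pv), key=lambda k: pv[k])
                        if pv[name] > p_remove:
                            worst_name = name
                if worst_name is not None:
                    selected = [c for c in selected if c != worst_name]
                    changed = True
            if not changed:
                return selected

    def fit(
        self,
        direction: str = "both",
        criterion: str = "aic",
        p_enter: float = 0.05,
        p_remove: float = 0.10,
    ) -> "YieldModelResults":
        """Run stepwise selection and fit the selected OLS model.

        ``direction`` is "forward", "backward" or "both"; with "both" each
        direction runs independently, the forward result is reported and a
        disagreement between the two selected sets is recorded (never
        silently resolved).  ``criterion`` is "aic" (default) or "p"
        (p-enter / p-remove thresholds).
        """
        if direction not in ("forward", "backward", "both"):
            raise ValueError("direction must be forward, backward or both")
        if criterion not in ("aic", "p"):
            raise ValueError("criterion must be 'aic' or 'p'")
        runs = ("forward", "backward") if direction == "both" else (direction,)
        sets = {d: self._step(d, criterion, p_enter, p_remove) for d in runs}
        selected = sets[runs[0]]
        disagreement = None
        if len(runs) == 2 and sets["forward"] != sets["backward"]:
            disagreement = dict(sets)
        ols = self._fit_set(selected)
        shares = (
            variance_shares(self.data, self.response, selected) if selected else {}
        )
        n = len(self.data)
        return YieldModelResults(
            model=self,
            predictors=selected,
            intercept=float(ols.params[0]),
            coefficients=dict(zip(selected, map(float, ols.params[1:]))),
            r2=float(ols.rsquared),
            sep_=sep(float(ols.ssr), n, len(selected)),
            shares=shares,
            direction=direction,
            criterion=criterion,
            criterion_value=float(ols.aic),
            disagreement=disagreement,
            ols_results=ols,
        )


@dataclass
class YieldModelResults:
    """Fitted stepwise yield model: estimates, fit quality and importances."""

    model: YieldModel
    predictors: list[str]
    intercept: float
    coefficients: dict[str, float]
    r2: float
    sep_: float
    shares: dict[str, float]
    direction: str
    criterion: str
    criterion_value: float
    disagreement: dict | None = None
    ols_results: object = None

    @property
    def sep(self) -> float:
        return self.sep_

    def predict(self, row: pd.Series | dict) -> float:
        return apply_model(self.coefficients, self.intercept, row)

    def as_dict(self) -> dict:
        return {
            "response": self.model.response,
            "predictors": self.predictors,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "r2": self.r2,
            "sep": self.sep_,
            "variance_shares": self.shares,
            "direction": self.direction,
            "criterion": self.criterion,
            "aic": self.criterion_value,
            "direction_disagreement": self.disagreement,
        }

    def summary(self) -> str:
        lines = [
            f"Stepwise OLS: {self.model.response} ~ {' + '.join(self.predictors) or '1'}",
            f"n = {len(self.model.data)}   direction = {self.direction}   criterion = {self.criterion.upper()}",
            f"r2 = {self.r2:.3f}   SEP = {self.sep_:.3f}   AIC = {self.criterion_value:.1f}",
            f"{'predictor':<16}{'coef':>10}{'LMG share':>12}",
            f"{'(intercept)':<16}{self.intercept:>10.3f}{'':>12}",
        ]
        for name in self.predictors:
            lines.append(f"{name:<16}{self.coefficients[name]:>10.3f}{self.shares.get(name, float('nan')):>12.3f}")
        if self.disagreement:
            lines.append(f"note: forward/backward disagree: {self.disagreement}")
        return "\n".join(lines)


def stepwise_select(
    table: pd.DataFrame,
    response: str,
    candidates: list[str],
    direction: str = "both",
    criterion: str = "aic",
    **kwargs,
) -> YieldModelResults:
    """Functional wrapper over :class:`YieldModel` for one-shot selection."""
    return YieldModel(table, response, candidates).fit(direction=direction, criterion=criterion, **kwargs)
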