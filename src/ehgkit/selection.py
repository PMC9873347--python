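"""Feature selection: four ranking algorithms and their combination rule.

For one (channel, band) dataset the training windows feed four selectors —
one-way F-test ranking, chi-square ranking on discretized features,
multivariate OLS p-value screening, and greedy sequential forward selection
wrapped around a linear SVM.  The final set is

    (seqsel  intersect  (ftest U chi2 U regression))
    union (regression  intersect  (ftest U chi2)),

padded with the highest-F unused features when smaller than 7 and truncated
by F rank when larger than 13, so every model uses 7-13 features.  Ties are
broken everywhere by canonical feature-name order, making the whole
procedure deterministic given (X, y, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

TOP_N = 10
MIN_FINAL, MAX_FINAL = 7, 13
REGRESSION_ALPHA = 0.05


@dataclass
class SelectionResult:
    """Per-algorithm rankings plus the combined final feature set."""

    ftest_top: list[str]
    chi2_top: list[str]
    regression_selected: list[str]
    regression_pvalues: dict[str, float]
    seqsel_selected: list[str]
    final_features: list[str]
    provenance: dict[str, list[str]]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _ordered_by_stat(names: list[str], stats: np.ndarray) -> list[str]:
    """Names sorted by decreasing statistic; ties by name (stable)."""
    order = sorted(range(len(names)), key=lambda i: (-stats[i], names[i]))
    return [names[i] for i in order]


def _f_statistics(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """One-way F statistics; zero within-class variance maps to +inf."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stats, _ = f_classif(X.to_numpy(), y)
    f_stats = np.asarray(f_stats, dtype=float)
    # a feature separating the classes with zero within-class variance
    # produces inf or nan-from-inf; rank it first
    within_zero = np.array([
        all(np.var(X.iloc[:, j].to_numpy()[y == cls]) == 0
            for cls in np.unique(y))
        and np.var(X.iloc[:, j]) > 0
        for j in range(X.shape[1])])
    f_stats[within_zero] = np.inf
    f_stats[np.isnan(f_stats)] = 0.0
    return f_stats


def rank_ftest(X: pd.DataFrame, y: np.ndarray, top_n: int = TOP_N
               ) -> list[str]:
    """Top features by decreasing one-way F statistic."""
    stats = _f_statistics(X, y)
    return _ordered_by_stat(list(X.columns), stats)[:min(top_n, X.shape[1])]


def _chi2_statistic(table: np.ndarray) -> float:
    """Pearson chi-square of a contingency table, no continuity correction;
    empty rows/columns are dropped; degenerate tables give 0."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(np.sum((table - expected) ** 2 / expected))


def rank_chi2(X: pd.DataFrame, y: np.ndarray, n_bins: int = 10,
              top_n: int = TOP_N) -> list[str]:
    """Top features by chi-square of the (equal-width bin) x class table."""
    classes = np.unique(y)
    stats = np.empty(X.shape[1])
    for j, name in enumerate(X.columns):
        x = X[name].to_numpy(dtype=float)
        lo, hi = np.min(x), np.max(x)
        if not np.isfinite([lo, hi]).all() or lo == hi:
            stats[j] = 0.0
            continue
        bins = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(int),
                          n_bins - 1)
        table = np.zeros((n_bins, classes.size))
        for ci, cls in enumerate(classes):
            table[:, ci] = np.bincount(bins[y == cls], minlength=n_bins)
        stats[j] = _chi2_statistic(table)
    return _ordered_by_stat(list(X.columns), stats)[:min(top_n, X.shape[1])]


def _drop_collinear(X: np.ndarray, names: list[str]
                    ) -> tuple[np.ndarray, list[str]]:
    """Greedily drop trailing columns that do not increase matrix rank."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear features: {dropped}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def select_regression(X: pd.DataFrame, y: np.ndarray,
                      alpha: float = REGRESSION_ALPHA, top_n: int = TOP_N
                      ) -> tuple[list[str], dict[str, float]]:
    """OLS of the numeric label (P=1, T=0) on all features jointly;
    keep coefficients with p < alpha, ascending, at most ``top_n``.

    Falls back to univariate regressions when n <= p + 1 (under-determined
    multivariate fit).
    """
    y_num = (np.asarray(y) == "P").astype(float) if np.asarray(y).dtype.kind in "OU" \
        else np.asarray(y, dtype=float)
    names = list(X.columns)
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    n = Xs.shape[0]

    pvals: dict[str, float] = {}
    if n > Xs.shape[1] + 1:
        Xk, kept = _drop_collinear(Xs, names)
        model = sm.OLS(y_num, sm.add_constant(Xk)).fit()
        for name, p in zip(kept, model.pvalues[1:]):
            pvals[name] = float(p)
    else:
        warnings.warn("n <= p + 1: falling back to univariate regressions",
                      stacklevel=2)
        for j, name in enumerate(names):
            model = sm.OLS(y_num, sm.add_constant(Xs[:, [j]])).fit()
            pvals[name] = float(model.pvalues[1])

    sig = [(p, name) for name, p in pvals.items() if p < alpha]
    sig.sort()
    return [name for _, name in sig[:top_n]], pvals


def sequential_forward_selection(X: pd.DataFrame, y: np.ndarray,
                                 base_classifier=None,
                                 max_features: int = MAX_FINAL,
                                 seed: int = 0,
                                 min_improvement: float = 1e-4) -> list[str]:
    """Greedy forward selection maximizing stratified 5-fold CV accuracy.

    Stops when no candidate improves mean accuracy by more than
    ``min_improvement`` or ``max_features`` is reached.
    """
    if base_classifier is None:
        base_classifier = SVC(kernel="linear", C=1.0)
    Xa = X.to_numpy(dtype=float)
    names = list(X.columns)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    folds = list(cv.split(Xa, y))

    def cv_accuracy(cols: list[int]) -> float:
        accs = []
        for tr, va in folds:
            pipe = make_pipeline(StandardScaler(),
                                 type(base_classifier)(
                                     **base_classifier.get_params()))
            pipe.fit(Xa[np.ix_(tr, cols)], y[tr])
            accs.append(pipe.score(Xa[np.ix_(va, cols)], y[va]))
        return float(np.mean(accs))

    selected: list[int] = []
    best_acc = 0.0
    while len(selected) < max_features:
        candidates = [j for j in range(len(names)) if j not in selected]
        if not candidates:
            break
        # evaluate each candidate; ties by name order (candidates iterate
        # in column order, strict > keeps the first)
        best_j, best_cand_acc = None, best_acc + min_improvement
        for j in candidates:
            acc = cv_accuracy(selected + [j])
            if acc > best_cand_acc:
                best_j, best_cand_acc = j, acc
        if best_j is None:
            break
        selected.append(best_j)
        best_acc = best_cand_acc
    return [names[j] for j in selected]


def combine_selections(ftest: list[str], chi2: list[str],
                       regression: list[str], seqsel: list[str],
                       f_stats_by_name: dict[str, float] | None = None,
                       all_names: list[str] | None = None
                       ) -> tuple[list[str], dict[str, list[str]]]:
    """Combine the four selections into the final 7-13 feature set.

    Returns the final names plus a provenance map (feature -> which rules
    contributed it: 'seqsel-overlap', 'regression-overlap', 'padding').
    """
    union_others = set(ftest) | set(chi2) | set(regression)
    if not (union_others | set(seqsel)):
        raise ValueError("all four selections are empty")
    part1 = [f for f in seqsel if f in union_others]
    part2 = [f for f in regression if f in set(ftest) | set(chi2)]

    provenance: dict[str, list[str]] = {}
    final: list[str] = []
    for f in part1:
        provenance.setdefault(f, []).append("seqsel-overlap")
        if f not in final:
            final.append(f)
    for f in part2:
        provenance.setdefault(f, []).append("regression-overlap")
        if f not in final:
            final.append(f)

    ranked_by_f: list[str] = []
    if f_stats_by_name:
        ranked_by_f = sorted(f_stats_by_name,
                             key=lambda n: (-f_stats_by_name[n], n))
    elif all_names:
        ranked_by_f = sorted(all_names)

    if len(final) < MIN_FINAL:
        for f in ranked_by_f:
            if f not in final:
                final.append(f)
                provenance.setdefault(f, []).append("padding")
            if len(final) >= MIN_FINAL:
                break
    if len(final) > MAX_FINAL:
        rank = {n: i for i, n in enumerate(ranked_by_f)}
        final = sorted(final, key=lambda n: rank.get(n, len(rank)))[:MAX_FINAL]
        provenance = {k: v for k, v in provenance.items() if k in set(final)}
        final = [f for f in (part1 + part2 + final) if f in set(final)]
        # keep first-occurrence order of the rule output
        seen: set[str] = set()
        final = [f for f in final if not (f in seen or seen.add(f))]
    return final, provenance


def select_features(X: pd.DataFrame, y: np.ndarray, seed: int = 0,
                    base_classifier=None) -> SelectionResult:
    """Run all four selectors on training data and combine them."""
    y = np.asarray(y)
    ftest = rank_ftest(X, y)
    chi2 = rank_chi2(X, y)
    regression, pvals = select_regression(X, y)
    seqsel = sequential_forward_selection(X, y, base_classifier, seed=seed)
    f_stats = dict(zip(X.columns, _f_statistics(X, y)))
    final, provenance = combine_selections(ftest, chi2, regression, seqsel,
                                           f_stats_by_name=f_stats)
    return SelectionResult(
        ftest_top=ftest, chi2_top=chi2, regression_selected=regression,
        regression_pvalues=pvals, seqsel_selected=seqsel,
        final_features=final, provenance=provenance, seed=seed)
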