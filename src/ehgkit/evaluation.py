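"""Classifier training, k-fold cross-validation, metrics, screening, and the
full study driver.

The classifier presets mirror the named MATLAB Classification Learner
models: quadratic / cubic SVM are polynomial kernels of degree 2 / 3 with
box constraint 1; the fine Gaussian SVM is an RBF kernel with kernel scale
sqrt(p)/4; weighted KNN uses k = 10 with squared-inverse-distance weights;
the bagged tree ensemble has 30 learners.  Features are standardized with
training statistics inside each fit.

Cross-validation pools the train + validation windows and splits them into
k = 23 folds; each of the k models is additionally evaluated on the fixed
test set, which consists of windows from records never seen in the pool —
this record-level independence is asserted, and violating it is an error.

The positive class is P (preterm), so sensitivity reads as preterm
detection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .records import BAND_NAMES, CHANNEL_NAMES
from .features import FEATURE_NAMES, extract_feature_table
from .preprocessing import split_records
from .selection import SelectionResult, select_features

POSITIVE_CLASS = "P"

CLASSIFIER_FAMILIES = (
    "svm_quadratic", "svm_cubic", "svm_fine_gaussian", "knn_weighted",
    "bagged_tree", "discriminant_linear", "discriminant_quadratic",
)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                "auc", "f_score", "precision", "recall")


class LeakageError(RuntimeError):
    """Raised when test records intersect the pooled train/validation set."""


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / (dist ** 2)
    # exact-match neighbours get all the weight
    for row in w:
        inf = ~np.isfinite(row)
        if inf.any():
            row[:] = inf.astype(float)
    return w


def build_classifier(spec: ClassifierSpec, n_features: int) -> Pipeline:
    """Instantiate the sklearn pipeline for a classifier family."""
    fam, seed = spec.family, spec.seed
    if fam == "svm_quadratic":
        clf = SVC(kernel="poly", degree=2, coef0=1.0, C=1.0, gamma="scale",
                  random_state=seed)
    elif fam == "svm_cubic":
        clf = SVC(kernel="poly", degree=3, coef0=1.0, C=1.0, gamma="scale",
                  random_state=seed)
    elif fam == "svm_fine_gaussian":
        scale = np.sqrt(n_features) / 4.0  # "fine" kernel scale
        clf = SVC(kernel="rbf", C=1.0, gamma=1.0 / (2.0 * scale ** 2),
                  random_state=seed)
    elif fam == "knn_weighted":
        clf = KNeighborsClassifier(n_neighbors=10, weights=_squared_inverse)
    elif fam == "bagged_tree":
        clf = BaggingClassifier(DecisionTreeClassifier(random_state=seed),
                                n_estimators=30, random_state=seed)
    elif fam == "discriminant_linear":
        clf = LinearDiscriminantAnalysis()
    else:
        # small per-class window counts need a regularized covariance
        clf = QuadraticDiscriminantAnalysis(reg_param=1e-3)
    return make_pipeline(StandardScaler(), clf)


def train_classifier(spec: ClassifierSpec, X_train: np.ndarray,
                     y_train: np.ndarray) -> Pipeline:
    """Fit one classifier; errors on single-class training labels."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    model = build_classifier(spec, X_train.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_train, y_train)
    return model


def positive_scores(model: Pipeline, X: np.ndarray,
                    positive_class: str = POSITIVE_CLASS) -> np.ndarray:
    """Continuous scores monotone in positive-class confidence (for AUC)."""
    clf = model[-1]
    if hasattr(clf, "decision_function"):
        s = model.decision_function(X)
        return s if clf.classes_[1] == positive_class else -s
    proba = model.predict_proba(X)
    col = int(np.where(clf.classes_ == positive_class)[0][0])
    return proba[:, col]


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    f_score: float
    precision: float
    recall: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray | None = None,
                    positive_class: str = POSITIVE_CLASS) -> MetricSet:
    """Binary classification metric suite from labels, predictions, scores."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))

    sens = _safe_ratio(tp, tp + fn, "sensitivity")
    spec = _safe_ratio(tn, tn + fp, "specificity")
    ppv = _safe_ratio(tp, tp + fp, "PPV")
    npv = _safe_ratio(tn, tn + fn, "NPV")
    prec, rec = ppv, sens
    f = _safe_ratio(2 * prec * rec, prec + rec, "F-score") \
        if np.isfinite(prec) and np.isfinite(rec) else float("nan")

    if scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(pos_t.astype(int), scores))
    else:
        auc = float("nan")
    return MetricSet(
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, auc=auc,
        f_score=f, precision=prec, recall=rec)


@dataclass
class CVResult:
    """Per-fold metrics for train/validation/test plus mean +- SD summary."""

    spec: ClassifierSpec
    k: int
    per_fold: dict[str, list[MetricSet]]
    dataset_id: str = ""

    def summary(self) -> pd.DataFrame:
        rows = []
        for split, metric_sets in self.per_fold.items():
            arr = pd.DataFrame([m.as_dict() for m in metric_sets])
            for metric in METRIC_NAMES:
                rows.append({
                    "split": split, "metric": metric,
                    "mean": float(arr[metric].mean()),
                    "sd": float(arr[metric].std(ddof=1))
                    if len(arr) > 1 else 0.0,
                })
        return pd.DataFrame(rows)

    def mean(self, split: str, metric: str) -> float:
        vals = [getattr(m, metric) for m in self.per_fold[split]]
        return float(np.nanmean(vals))


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled partition into k folds; remainder spread over leading folds."""
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds, start = [], 0
    for sz in sizes:
        folds.append(perm[start:start + sz])
        start += sz
    return folds


def kfold_cross_validate(pool: pd.DataFrame, test: pd.DataFrame,
                         feature_names: list[str], spec: ClassifierSpec,
                         k: int = 23, seed: int = 0,
                         positive_class: str = POSITIVE_CLASS) -> CVResult:
    """k-fold CV over the pooled train+validation windows with a fixed,
    record-independent test set evaluated by every fold model."""
    pool_ids = set(pool["record_id"])
    test_ids = set(test["record_id"])
    if pool_ids & test_ids:
        raise LeakageError(
            f"records appear in both pool and test: {sorted(pool_ids & test_ids)}")
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} windows smaller than k={k}")

    Xp = pool[feature_names].to_numpy(dtype=float)
    yp = pool["label"].to_numpy()
    Xt = test[feature_names].to_numpy(dtype=float)
    yt = test["label"].to_numpy()

    rng = np.random.default_rng(seed)
    folds = _fold_indices(len(pool), k, rng)
    per_fold: dict[str, list[MetricSet]] = {
        "train": [], "validation": [], "test": []}
    for i in range(k):
        val_idx = folds[i]
        tr_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        model = train_classifier(spec, Xp[tr_idx], yp[tr_idx])
        for split, (Xe, ye) in (
                ("train", (Xp[tr_idx], yp[tr_idx])),
                ("validation", (Xp[val_idx], yp[val_idx])),
                ("test", (Xt, yt))):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred = model.predict(Xe)
                scores = positive_scores(model, Xe, positive_class)
                per_fold[split].append(
                    compute_metrics(ye, pred, scores, positive_class))
    return CVResult(spec=spec, k=k, per_fold=per_fold)


# ---------------------------------------------------------------------------
# Mann-Whitney screening

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"),
                   (0.05, "*"))


def star_code(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def mann_whitney_screen(feature_table: pd.DataFrame, labels: np.ndarray,
                        feature_names: list[str] | None = None
                        ) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature with significance stars.

    Uses the exact null distribution when the pooled sample is small
    (n <= 20, no ties), otherwise the normal approximation with tie
    correction; a feature constant in both groups gets p = 1.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("screening needs exactly two classes")
    a_mask = labels == classes[0]
    if min(a_mask.sum(), (~a_mask).sum()) < 3:
        raise ValueError("need at least 3 windows per class")
    feature_names = feature_names or [c for c in feature_table.columns
                                      if c in FEATURE_NAMES]
    rows = []
    for name in feature_names:
        x = feature_table[name].to_numpy(dtype=float)
        a, b = x[a_mask], x[~a_mask]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p, u = 1.0, a.size * b.size / 2.0
        else:
            method = ("exact" if a.size + b.size <= 20
                      and np.unique(x).size == x.size else "asymptotic")
            res = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                      method=method)
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({"feature": name, "U": u, "p_value": min(p, 1.0),
                     "stars": star_code(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study driver

@dataclass
class DatasetReport:
    dataset_id: str
    selection: SelectionResult
    family: str
    validation_accuracy: dict[str, float]
    validation_auc: dict[str, float]
    cv_result: CVResult
    screening: pd.DataFrame
    status: str = "ok"


@dataclass
class StudyReport:
    datasets: dict[str, DatasetReport]
    seed: int

    def best_dataset(self, split: str = "test",
                     metric: str = "accuracy") -> DatasetReport:
        ok = [d for d in self.datasets.values() if d.status == "ok"]
        if not ok:
            raise RuntimeError("no dataset completed successfully")
        return max(ok, key=lambda d: d.cv_result.mean(split, metric))

    def summary_table(self) -> pd.DataFrame:
        frames = []
        for ds_id, rep in self.datasets.items():
            if rep.status != "ok":
                continue
            s = rep.cv_result.summary()
            s.insert(0, "dataset", ds_id)
            s.insert(1, "family", rep.family)
            frames.append(s)
        return pd.concat(frames, ignore_index=True)


def _choose_family(train: pd.DataFrame, validation: pd.DataFrame,
                   feature_names: list[str], families: tuple[str, ...],
                   seed: int) -> tuple[str, dict[str, float], dict[str, float]]:
    """Fit each family on train, score on validation; pick by accuracy with
    AUC as the tie-break."""
    Xtr = train[feature_names].to_numpy(dtype=float)
    ytr = train["label"].to_numpy()
    Xva = validation[feature_names].to_numpy(dtype=float)
    yva = validation["label"].to_numpy()
    accs, aucs = {}, {}
    for fam in families:
        try:
            model = train_classifier(ClassifierSpec(fam, seed), Xtr, ytr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred = model.predict(Xva)
                m = compute_metrics(yva, pred, positive_scores(model, Xva))
        except Exception as exc:
            warnings.warn(f"family {fam} failed during selection: {exc}",
                          stacklevel=2)
            continue
        accs[fam] = m.accuracy
        aucs[fam] = m.auc if np.isfinite(m.auc) else 0.0
    if not accs:
        raise RuntimeError("no classifier family could be trained")
    best = max(accs, key=lambda f: (round(accs[f], 12), round(aucs[f], 12), f))
    return best, accs, aucs


def run_full_study(records, config: dict | None = None,
                   out_dir: str | Path | None = None) -> StudyReport:
    """The end-to-end analysis over every requested (channel, band) dataset.

    Steps per dataset: record-level split -> feature extraction ->
    selection on training windows only -> classifier family chosen by
    validation accuracy (+AUC) -> k-fold CV of the pooled train+validation
    windows with the fixed held-out test set -> Mann-Whitney screening.
    Partial failures are kept with a per-dataset status.
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    channels = tuple(config.get("channels", CHANNEL_NAMES))
    band_names = tuple(config.get("bands", BAND_NAMES))
    families = tuple(config.get("families", CLASSIFIER_FAMILIES))
    k = int(config.get("k", 23))
    window_s = float(config.get("window_s", 120.0))
    overlap = float(config.get("overlap", 0.5))

    from .records import DEFAULT_BANDS
    bands = tuple(b for b in DEFAULT_BANDS if b.name in band_names)

    split = split_records(records, seed=seed)
    table = extract_feature_table(
        records, channels=channels, bands=bands, window_s=window_s,
        overlap=overlap, split_assignment=split)

    reports: dict[str, DatasetReport] = {}
    for ch in channels:
        for band in bands:
            ds_id = f"{ch}{band.name}"
            sub = table[(table["channel"] == ch)
                        & (table["band"] == band.name)]
            try:
                reports[ds_id] = _run_dataset(sub, ds_id, families, k, seed)
            except Exception as exc:  # keep partial results
                reports[ds_id] = DatasetReport(
                    dataset_id=ds_id, selection=None, family="",
                    validation_accuracy={}, validation_auc={},
                    cv_result=None, screening=None,
                    status=f"failed: {exc}")
    report = StudyReport(datasets=reports, seed=seed)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _run_dataset(sub: pd.DataFrame, ds_id: str, families: tuple[str, ...],
                 k: int, seed: int) -> DatasetReport:
    train = sub[sub["split"] == "train"]
    validation = sub[sub["split"] == "validation"]
    test = sub[sub["split"] == "test"]
    if train.empty or test.empty:
        raise ValueError(f"dataset {ds_id}: empty train or test split")

    feature_cols = list(FEATURE_NAMES)
    sel = select_features(train[feature_cols],
                          train["label"].to_numpy(), seed=seed)
    feats = sel.final_features

    fam, accs, aucs = _choose_family(train, validation, feats, families, seed)
    pool = pd.concat([train, validation], ignore_index=True)
    cv = kfold_cross_validate(pool, test, feats, ClassifierSpec(fam, seed),
                              k=min(k, len(pool)), seed=seed)
    cv.dataset_id = ds_id
    screening = mann_whitney_screen(sub, sub["label"].to_numpy())
    return DatasetReport(dataset_id=ds_id, selection=sel, family=fam,
                         validation_accuracy=accs, validation_auc=aucs,
                         cv_result=cv, screening=screening)


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the per-dataset metric summary, selected-feature manifest and
    the screening star matrix to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.summary_table().to_csv(out_dir / "metrics_summary.csv", index=False)
    manifest = {"seed": report.seed, "datasets": {}}
    star_rows = []
    for ds_id, rep in report.datasets.items():
        manifest["datasets"][ds_id] = {
            "status": rep.status, "family": rep.family,
            "selected_features": (rep.selection.final_features
                                  if rep.selection else []),
        }
        if rep.status == "ok":
            stars = rep.screening.set_index("feature")["stars"]
            star_rows.append(pd.Series(stars, name=ds_id))
    if star_rows:
        pd.DataFrame(star_rows).T.to_csv(out_dir / "screening_stars.csv")
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
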