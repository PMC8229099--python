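"""Nested cross-validated one-vs-rest subtype classification.

A bank of classifier families is tuned by an inner grid search inside an
outer stratified cross-validation; the best family (mean outer accuracy)
is refit on the full training data as a one-vs-rest ensemble, evaluated
on held-out samples, and validated with a label-permutation test.
Missing beta values are median-imputed with medians fitted on the
training portion of each split only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .types import BetaMatrix

__all__ = [
    "ModelSpec",
    "ModelReport",
    "FittedClassifier",
    "default_model_bank",
    "median_impute",
    "nested_cv_select",
    "compare_models_wilcoxon",
    "fit_final",
    "predict_subtypes",
    "evaluate_predictions",
    "permutation_test",
]

SUSPECT_PROBABILITY = 0.80

_FAMILIES = {
    "nearest centroid",
    "random forest",
    "multilayer perceptron",
    "logistic regression",
    "support vector machine",
    "k-nearest neighbors",
    "decision tree",
    "naive Bayes",
    "gradient boosting",
}


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family: {self.family!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def combinations(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def default_model_bank(small: bool = False) -> list[ModelSpec]:
    """The nine-family default bank.

    ``small=True`` shrinks every grid to one candidate (used for the
    permutation test and quick runs).
    """
    bank = [
        ModelSpec("nearest centroid", {"shrink_threshold": [None]}),
        ModelSpec("random forest", {"n_estimators": [100],
                                    "max_features": ["sqrt", 0.5]}),
        ModelSpec("multilayer perceptron",
                  {"hidden_layer_sizes": [(32,), (64,), (128,)]}),
        ModelSpec("logistic regression", {"C": [0.1, 1.0, 10.0]}),
        ModelSpec("support vector machine", {"C": [1.0, 10.0]}),
        ModelSpec("k-nearest neighbors", {"n_neighbors": [3, 5]}),
        ModelSpec("decision tree", {"max_depth": [None, 5]}),
        ModelSpec("naive Bayes", {"var_smoothing": [1e-9, 1e-6]}),
        ModelSpec("gradient boosting", {"n_estimators": [50, 100]}),
    ]
    if small:
        bank = [ModelSpec(s.family, {k: v[:1] for k, v in s.grid.items()})
                for s in bank]
    return bank


def _make_estimator(family: str, params: dict, seed: int):
    p = dict(params)
    if family == "nearest centroid":
        return NearestCentroid(**p)
    if family == "random forest":
        return RandomForestClassifier(random_state=seed, **p)
    if family == "multilayer perceptron":
        p.setdefault("max_iter", 300)
        return MLPClassifier(random_state=seed, **p)
    if family == "logistic regression":
        p.setdefault("max_iter", 500)
        return LogisticRegression(random_state=seed, **p)
    if family == "support vector machine":
        return SVC(random_state=seed, **p)
    if family == "k-nearest neighbors":
        return KNeighborsClassifier(**p)
    if family == "decision tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if family == "naive Bayes":
        return GaussianNB(**p)
    if family == "gradient boosting":
        return GradientBoostingClassifier(random_state=seed, **p)
    raise ValueError(family)


# ---------------------------------------------------------------------------
# imputation

def median_impute(train: BetaMatrix, apply_to: BetaMatrix,
                  ) -> tuple[BetaMatrix, BetaMatrix]:
    """Fill missing entries using per-CpG medians from ``train`` only."""
    if train.cpg_ids != apply_to.cpg_ids:
        raise ValueError("train and apply_to must share CpG IDs")
    medians = train.data.median(axis=1)
    all_missing = medians.index[medians.isna()]
    if len(all_missing):
        raise ValueError(
            f"CpG(s) entirely missing in train: {list(all_missing)[:5]}")

    def fill(beta: BetaMatrix) -> BetaMatrix:
        return BetaMatrix(beta.data.T.fillna(medians).T)

    return fill(train), fill(apply_to)


def _fit_medians(x: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(x, axis=0)
    if np.isnan(med).any():
        raise ValueError("feature entirely missing in training split")
    return med


def _apply_medians(x: np.ndarray, med: np.ndarray) -> np.ndarray:
    out = x.copy()
    mask = np.isnan(out)
    if mask.any():
        out[mask] = np.take(med, np.where(mask)[1])
    return out


# ---------------------------------------------------------------------------
# one-vs-rest ensemble

class OneVsRestEnsemble:
    """One binary model per class; probabilities normalized across classes.

    Raw per-class scores come from ``predict_proba`` when the family
    supports it (normalized by their sum) and from ``decision_function``
    or centroid-distance margins otherwise (softmax).  Argmax ties break
    toward the class with more training samples, then by name order.
    """

    def __init__(self, spec: ModelSpec, params: dict, seed: int = 0):
        self.spec = spec
        self.params = dict(params)
        self.seed = seed

    def fit(self, x: np.ndarray, y: np.ndarray) -> "OneVsRestEnsemble":
        y = np.asarray(y)
        self.classes_ = np.array(sorted(set(y)))
        if len(self.classes_) < 2:
            raise ValueError("one-vs-rest requires at least 2 classes")
        self.class_counts_ = np.array([(y == c).sum() for c in self.classes_])
        self.models_ = []
        for c in self.classes_:
            target = (y == c).astype(int)
            if target.sum() == 0 or target.sum() == len(target):
                self.models_.append(None)  # degenerate split: no margin
                continue
            est = _make_estimator(self.spec.family, self.params, self.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(x, target)
            self.models_.append(est)
        return self

    def _raw_scores(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        """Per-class raw scores; second element marks probability scale."""
        n = x.shape[0]
        scores = np.full((n, len(self.classes_)), -np.inf)
        is_proba = None
        for k, est in enumerate(self.models_):
            if est is None:
                continue
            if hasattr(est, "predict_proba"):
                proba = est.predict_proba(x)
                pos = list(est.classes_).index(1)
                scores[:, k] = proba[:, pos]
                is_proba = True if is_proba is None else is_proba
            elif hasattr(est, "decision_function"):
                scores[:, k] = est.decision_function(x)
                is_proba = False
            else:  # nearest centroid: margin = d(rest) - d(class)
                cls = list(est.classes_)
                cents = est.centroids_
                d_pos = np.linalg.norm(x - cents[cls.index(1)], axis=1)
                d_neg = np.linalg.norm(x - cents[cls.index(0)], axis=1)
                scores[:, k] = d_neg - d_pos
                is_proba = False
        return scores, bool(is_proba)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        scores, is_proba = self._raw_scores(x)
        if is_proba:
            p = np.where(np.isfinite(scores), scores, 0.0)
            totals = p.sum(axis=1, keepdims=True)
            uniform = np.full_like(p, 1.0 / p.shape[1])
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(totals > 0, p / totals, uniform)
        else:
            shifted = scores - np.nanmax(
                np.where(np.isfinite(scores), scores, np.nan),
                axis=1, keepdims=True)
            e = np.where(np.isfinite(shifted), np.exp(shifted), 0.0)
            p = e / e.sum(axis=1, keepdims=True)
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.predict_proba(x)
        # tie-break: larger training class first, then name order
        order = np.lexsort((self.classes_, -self.class_counts_))
        ordered_p = p[:, order]
        best = order[np.argmax(ordered_p, axis=1)]
        return self.classes_[best]


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass
class FamilyCVResult:
    outer_accuracies: list[float]
    chosen_params: list[dict]
    fold_predictions: list[np.ndarray]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.outer_accuracies))


@dataclass
class ModelReport:
    family_results: dict[str, FamilyCVResult]
    best_family: str
    outer_k: int
    inner_k: int
    confusion: pd.DataFrame | None = None
    per_class: pd.DataFrame | None = None
    accuracy: float | None = None
    permutation_p: float | None = None
    probabilities: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        rows = [{"family": f,
                 "mean_accuracy": r.mean_accuracy,
                 "outer_accuracies": ",".join(
                     f"{a:.4f}" for a in r.outer_accuracies)}
                for f, r in self.family_results.items()]
        return pd.DataFrame(rows).sort_values(
            "mean_accuracy", ascending=False).reset_index(drop=True)


def _check_labels(labels, sample_ids) -> np.ndarray:
    y = np.asarray(pd.Series(labels).to_numpy())
    if len(y) != len(sample_ids):
        raise ValueError("labels length must match number of samples")
    return y.astype(str)


def _filter_small_classes(x, y, min_count: int = 2):
    counts = pd.Series(y).value_counts()
    small = counts[counts < min_count].index.tolist()
    if small:
        warnings.warn(
            f"classes with < {min_count} samples excluded from "
            f"cross-validation: {sorted(small)}", stacklevel=3)
        keep = ~np.isin(y, small)
        return x[keep], y[keep]
    return x, y


def _inner_grid_search(x, y, spec: ModelSpec, inner_k: int, seed: int) -> dict:
    combos = spec.combinations()
    if len(combos) == 1:
        return combos[0]
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    best_params, best_score = combos[0], -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        splits = list(inner.split(x, y))
    for params in combos:
        scores = []
        for tr, va in splits:
            med = _fit_medians(x[tr])
            clf = OneVsRestEnsemble(spec, params, seed)
            clf.fit(_apply_medians(x[tr], med), y[tr])
            pred = clf.predict(_apply_medians(x[va], med))
            scores.append(float(np.mean(pred == y[va])))
        score = float(np.mean(scores))
        if score > best_score:  # ties keep first combo in grid order
            best_score, best_params = score, params
    return best_params


def nested_cv_select(
    beta_fs: BetaMatrix,
    labels,
    model_specs: list[ModelSpec] | None = None,
    outer_k: int = 5,
    inner_k: int = 3,
    seed: int = 0,
) -> ModelReport:
    """Nested CV over a bank of families; best family by mean accuracy.

    Each outer training split runs an inner ``inner_k``-fold grid search
    (accuracy criterion), refits with the winning hyperparameters and
    scores the outer validation part.  Imputation medians are fitted on
    each training split only, so validation labels never influence any
    fitted parameter.  Family ties break toward the smaller grid, then
    name order.
    """
    if model_specs is None:
        model_specs = default_model_bank()
    y_all = _check_labels(labels, beta_fs.sample_ids)
    x_all = beta_fs.values.T
    x, y = _filter_small_classes(x_all, y_all)

    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        splits = list(outer.split(x, y))

    results: dict[str, FamilyCVResult] = {}
    for spec in model_specs:
        accs, params_list, preds_list = [], [], []
        for fold, (tr, va) in enumerate(splits):
            params = _inner_grid_search(x[tr], y[tr], spec, inner_k,
                                        seed + fold)
            med = _fit_medians(x[tr])
            clf = OneVsRestEnsemble(spec, params, seed)
            clf.fit(_apply_medians(x[tr], med), y[tr])
            pred = clf.predict(_apply_medians(x[va], med))
            accs.append(float(np.mean(pred == y[va])))
            params_list.append(params)
            preds_list.append(pred)
        results[spec.family] = FamilyCVResult(accs, params_list, preds_list)

    def rank_key(family: str):
        spec = next(s for s in model_specs if s.family == family)
        return (-results[family].mean_accuracy, len(spec.combinations()),
                family)

    best = min(results, key=rank_key)
    return ModelReport(results, best, outer_k=outer_k, inner_k=inner_k)


def compare_models_wilcoxon(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired fold scores.

    Exact null distribution for n <= 25 non-zero differences;
    zero differences are dropped.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired scores")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox",
                             alternative="two-sided", method=method)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# final fit / prediction / evaluation

@dataclass
class FittedClassifier:
    ensemble: OneVsRestEnsemble
    medians: np.ndarray
    cpg_ids: list[str]
    classes: np.ndarray
    chosen_params: dict


def fit_final(
    beta_fs: BetaMatrix,
    labels,
    best: ModelSpec,
    seed: int = 0,
    params: dict | None = None,
    inner_k: int = 3,
) -> FittedClassifier:
    """Refit the winning family on all provided samples.

    If ``params`` is not given and the grid has several candidates, an
    ``inner_k``-fold grid search on the full data chooses them.
    """
    y = _check_labels(labels, beta_fs.sample_ids)
    if len(set(y)) < 2:
        raise ValueError("cannot fit a classifier on a single class")
    x = beta_fs.values.T
    if params is None:
        params = _inner_grid_search(x, y, best, inner_k, seed)
    med = _fit_medians(x)
    clf = OneVsRestEnsemble(best, params, seed)
    clf.fit(_apply_medians(x, med), y)
    return FittedClassifier(clf, med, list(beta_fs.cpg_ids), clf.classes_,
                            dict(params))


def predict_subtypes(model: FittedClassifier, beta_new: BetaMatrix,
                     ) -> pd.DataFrame:
    """Predict labels and class probabilities for new samples.

    Returns one row per sample with the argmax ``label``, its
    probability, the ``suspected`` flag (probability >= 0.8) and one
    probability column per class.  Input must contain every training CpG.
    """
    missing = [c for c in model.cpg_ids if c not in set(beta_new.cpg_ids)]
    if missing:
        raise ValueError(f"input lacks training CpGs: {missing[:5]}...")
    sub = beta_new.subset_cpgs(model.cpg_ids)
    x = _apply_medians(sub.values.T, model.medians)
    proba = model.ensemble.predict_proba(x)
    labels = model.ensemble.predict(x)
    top = proba.max(axis=1)
    out = pd.DataFrame({"sample_id": sub.sample_ids, "label": labels,
                        "probability": top,
                        "suspected": top >= SUSPECT_PROBABILITY})
    for k, c in enumerate(model.classes):
        out[f"p_{c}"] = proba[:, k]
    return out


@dataclass
class EvalResult:
    confusion: pd.DataFrame  # rows = true, columns = predicted
    per_class: pd.DataFrame  # precision / recall / f1 / support
    accuracy: float


def evaluate_predictions(pred_labels, true_labels, class_order,
                         ) -> EvalResult:
    """Confusion matrix plus per-class precision/recall/F1 and accuracy.

    Undefined ratios (zero denominators) are reported as 0 with a
    warning.
    """
    pred = [str(v) for v in pred_labels]
    true = [str(v) for v in true_labels]
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    classes = [str(c) for c in class_order]
    unknown = set(pred) - set(classes)
    if unknown:
        raise ValueError(f"predicted labels outside class_order: {unknown}")
    unknown_true = set(true) - set(classes)
    if unknown_true:
        raise ValueError(f"true labels outside class_order: {unknown_true}")

    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        cm[idx[t], idx[p]] += 1

    rows = []
    warned = False
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0 or tp + fn == 0:
            warned = True
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        rows.append({"class": c, "precision": precision, "recall": recall,
                     "f1": f1, "support": int(cm[i, :].sum())})
    if warned:
        warnings.warn("some precision/recall ratios undefined; reported as 0",
                      stacklevel=2)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return EvalResult(confusion, pd.DataFrame(rows), accuracy)


# ---------------------------------------------------------------------------
# permutation test

def _cv_accuracy(x, y, spec: ModelSpec, outer_k: int, inner_k: int,
                 seed: int) -> float:
    """Mean stratified outer-CV accuracy for one family (grid inside)."""
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        splits = list(outer.split(x, y))
    accs = []
    for fold, (tr, va) in enumerate(splits):
        params = _inner_grid_search(x[tr], y[tr], spec, inner_k, seed + fold)
        med = _fit_medians(x[tr])
        clf = OneVsRestEnsemble(spec, params, seed)
        clf.fit(_apply_medians(x[tr], med), y[tr])
        pred = clf.predict(_apply_medians(x[va], med))
        accs.append(float(np.mean(pred == y[va])))
    return float(np.mean(accs))


def permutation_test(
    beta_fs: BetaMatrix,
    labels,
    best: ModelSpec,
    n_permutations: int = 1000,
    outer_k: int = 5,
    inner_k: int = 3,
    seed: int = 0,
    return_scores: bool = False,
):
    """Label-permutation validation of the cross-validated accuracy.

    The observed score is the mean outer-CV accuracy with the true
    labels; each permutation shuffles the labels and recomputes the score
    identically.  ``p = (C + 1) / (B + 1)`` with C the number of permuted
    scores >= observed, so p is never zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y_all = _check_labels(labels, beta_fs.sample_ids)
    x_all = beta_fs.values.T
    x, y = _filter_small_classes(x_all, y_all)

    observed = _cv_accuracy(x, y, best, outer_k, inner_k, seed)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        permuted[b] = _cv_accuracy(x, y_perm, best, outer_k, inner_k, seed)
    c = int(np.sum(permuted >= observed))
    p = (c + 1) / (n_permutations + 1)
    if return_scores:
        return p, observed, permuted
    return p
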