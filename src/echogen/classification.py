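"""Benign/malignant lesion classification from QUS feature vectors.

The protocol: z-score features on the training lesions, two-step feature
selection (top-20 mutual information, then elastic-net logistic regression
with l1 ratio 0.7 / SAGA solver, keeping features whose absolute coefficient
exceeds the mean absolute coefficient), an RBF-kernel SVC tuned by grid
search over (C, gamma) with stratified 5-fold cross-validated ROC AUC, and
bootstrap evaluation (1000 resamples at lesion level) on the held-out test
set. Four experiment conditions compare original-RF and synthetic-RF derived
features under different train/test dependency patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureSelectionResult", "ClassifierReport", "ExperimentMatrix",
    "select_mi", "select_elasticnet", "train_svc", "bootstrap_evaluate",
    "run_condition", "run_experiment_matrix",
]

POSITIVE_LABEL = "malignant"  # sensitivity is defined on the malignant class


@dataclass
class FeatureSelectionResult:
    mi_top: list
    retained: list
    coefficients: dict
    threshold: float
    converged: bool = True


@dataclass
class ClassifierReport:
    accuracy: tuple[float, float]      # mean, sd over bootstrap resamples, %
    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    precision: tuple[float, float]
    best_c: float
    best_gamma: float
    cv_auc: float
    selected_features: list
    n_undefined: dict = field(default_factory=dict)


@dataclass
class ExperimentMatrix:
    conditions: dict                    # name -> ClassifierReport
    feature_overlap: dict               # condition -> overlap with condition 1
    test_lesions: list


def _encode(labels) -> np.ndarray:
    return np.asarray([1 if l == POSITIVE_LABEL else 0 for l in labels])


def select_mi(features: pd.DataFrame, labels: Sequence[str], k: int = 20,
              seed: int = 0) -> list:
    """Top-k features by estimated mutual information with the class label
    (nearest-neighbor estimator for continuous features)."""
    y = _encode(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if k > features.shape[1]:
        raise ValueError("k exceeds the number of features")
    mi = mutual_info_classif(features.values, y, random_state=seed,
                             n_neighbors=min(3, len(y) - 1))
    order = np.argsort(mi)[::-1][:k]
    return [features.columns[i] for i in order]


def select_elasticnet(features: pd.DataFrame, labels: Sequence[str],
                      l1_ratio: float = 0.7, c: float = 1.0,
                      max_iter: int = 10000,
                      seed: int = 0) -> FeatureSelectionResult:
    """Elastic-net logistic regression wrapper selection.

    L1/L2 mixing 0.7/0.3, SAGA solver; features with absolute coefficient
    above the mean absolute coefficient are retained.
    """
    y = _encode(labels)
    model = LogisticRegression(penalty="elasticnet", l1_ratio=l1_ratio,
                               C=c, solver="saga", max_iter=max_iter,
                               random_state=seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(features.values, y)
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
    if not converged:
        warnings.warn(f"elastic net did not converge in {max_iter} iterations")
    coefs = np.abs(model.coef_[0])
    thr = float(coefs.mean())
    retained = [features.columns[i] for i in range(len(coefs))
                if coefs[i] > thr]
    if not retained:
        warnings.warn("elastic net eliminated all features")
    return FeatureSelectionResult(
        mi_top=list(features.columns), retained=retained,
        coefficients={features.columns[i]: float(model.coef_[0][i])
                      for i in range(len(coefs))},
        threshold=thr, converged=converged)


def train_svc(features: pd.DataFrame, labels: Sequence[str],
              seed: int = 0, n_folds: int = 5):
    """Grid-searched RBF SVC: C and gamma over six decades each, stratified
    5-fold CV scored by ROC AUC, refit on the full training set."""
    y = _encode(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError("too few lesions per class for stratified CV")
    grid = {"C": np.logspace(-2, 3, 6), "gamma": np.logspace(-4, 1, 6)}
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(SVC(kernel="rbf"), grid, scoring="roc_auc", cv=cv)
    search.fit(features.values, y)
    return (search.best_estimator_, float(search.best_params_["C"]),
            float(search.best_params_["gamma"]), float(search.best_score_))


def bootstrap_evaluate(classifier, features: pd.DataFrame,
                       labels: Sequence[str], n_resamples: int = 1000,
                       seed: int = 0):
    """Bootstrap the test lesions with replacement; report mean +/- SD (%) of
    accuracy, sensitivity, specificity and precision. Metrics undefined on a
    resample (missing class / no positive calls) are skipped and counted."""
    y = _encode(labels)
    if len(y) == 0 or len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes")
    pred = classifier.predict(features.values)
    rng = np.random.default_rng(seed)
    stats = {"accuracy": [], "sensitivity": [], "specificity": [],
             "precision": []}
    undefined = {k: 0 for k in stats}
    n = len(y)
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        yt, yp = y[idx], pred[idx]
        tp = int(np.sum((yt == 1) & (yp == 1)))
        tn = int(np.sum((yt == 0) & (yp == 0)))
        fp = int(np.sum((yt == 0) & (yp == 1)))
        fn = int(np.sum((yt == 1) & (yp == 0)))
        stats["accuracy"].append((tp + tn) / n)
        for name, num, den in (("sensitivity", tp, tp + fn),
                               ("specificity", tn, tn + fp),
                               ("precision", tp, tp + fp)):
            if den == 0:
                undefined[name] += 1
            else:
                stats[name].append(num / den)
    out = {k: ((float(np.mean(v) * 100.0), float(np.std(v) * 100.0))
               if v else (float("nan"), float("nan")))
           for k, v in stats.items()}
    return out, undefined


def run_condition(train_feats: pd.DataFrame, train_labels,
                  test_feats: pd.DataFrame, test_labels,
                  selected: Optional[list] = None, seed: int = 0,
                  n_resamples: int = 1000, mi_k: int = 20) -> ClassifierReport:
    """One experiment condition: (optional) feature selection on the training
    lesions, SVC training, bootstrap evaluation on the test lesions.
    Standardization is fitted on the training lesions only."""
    scaler = StandardScaler().fit(train_feats.values)
    ztr = pd.DataFrame(scaler.transform(train_feats.values),
                       index=train_feats.index, columns=train_feats.columns)
    zte = pd.DataFrame(scaler.transform(test_feats.values),
                       index=test_feats.index, columns=test_feats.columns)
    if selected is None:
        mi_top = select_mi(ztr, train_labels, k=min(mi_k, ztr.shape[1]),
                           seed=seed)
        en = select_elasticnet(ztr[mi_top], train_labels, seed=seed)
        selected = en.retained if en.retained else mi_top[:5]
    clf, best_c, best_g, cv_auc = train_svc(ztr[selected], train_labels,
                                            seed=seed)
    boot, undefined = bootstrap_evaluate(clf, zte[selected], test_labels,
                                         n_resamples=n_resamples, seed=seed)
    return ClassifierReport(
        accuracy=boot["accuracy"], sensitivity=boot["sensitivity"],
        specificity=boot["specificity"], precision=boot["precision"],
        best_c=best_c, best_gamma=best_g, cv_auc=cv_auc,
        selected_features=list(selected), n_undefined=undefined)


def run_experiment_matrix(original: pd.DataFrame, original_labels: dict,
                          synthetic: pd.DataFrame,
                          train_ids: Sequence, test_ids: Sequence,
                          seed: int = 0,
                          n_resamples: int = 1000) -> ExperimentMatrix:
    """The four-condition protocol on one generator variant.

    1. selection + training + testing on original features;
    2. selection + training + testing on synthetic features;
    3. training + testing on synthetic features with condition 1's selection;
    4. selection + training on original, testing on synthetic.
    The lesion-level split, bootstrap seed and test lesions are identical
    across conditions.
    """
    if list(original.index) != list(synthetic.index):
        raise ValueError("original/synthetic lesions must be paired")
    if (set(train_ids) | set(test_ids)) - set(original.index):
        raise ValueError("split references unknown lesions")
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test lesions overlap")
    tr_lab = [original_labels[i] for i in train_ids]
    te_lab = [original_labels[i] for i in test_ids]
    o_tr, o_te = original.loc[list(train_ids)], original.loc[list(test_ids)]
    s_tr, s_te = synthetic.loc[list(train_ids)], synthetic.loc[list(test_ids)]

    c1 = run_condition(o_tr, tr_lab, o_te, te_lab, seed=seed,
                       n_resamples=n_resamples)
    c2 = run_condition(s_tr, tr_lab, s_te, te_lab, seed=seed,
                       n_resamples=n_resamples)
    c3 = run_condition(s_tr, tr_lab, s_te, te_lab,
                       selected=c1.selected_features, seed=seed,
                       n_resamples=n_resamples)
    c4 = run_condition(o_tr, tr_lab, s_te, te_lab,
                       selected=c1.selected_features, seed=seed,
                       n_resamples=n_resamples)
    conditions = {"orig_train_orig_test": c1,
                  "syn_train_syn_test": c2,
                  "syn_train_syn_test_orig_features": c3,
                  "orig_train_syn_test": c4}
    overlap = {name: sorted(set(rep.selected_features)
                            & set(c1.selected_features))
               for name, rep in conditions.items()}
    return ExperimentMatrix(conditions=conditions, feature_overlap=overlap,
                            test_lesions=list(test_ids))
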