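"""Classifier scoring of (optimized) feature matrices and the two-sample
tests used to compare modality fused-probability columns.

welch_t_test follows the unequal-variance formulation with the
Welch–Satterthwaite degrees of freedom; when one sample is constant the df
reduces to n−1 of the varying sample (the formula's limit).  A constant
column's variance is reported as exactly 0 and the variance-ratio F as
+infinity — not as the ~1e−32 floating-point dust a spreadsheet produces.
"""

from __future__ import annotations

import warnings
from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .extractors import TrainConfig, stratified_split

__all__ = ["classify_and_score", "welch_t_test", "f_test_variances",
           "sample_variance", "WelchResult", "FTestResult", "DEFAULT_CLASSIFIERS"]

WelchResult = namedtuple("WelchResult", "t df p_one p_two")
FTestResult = namedtuple("FTestResult", "F p_one")

DEFAULT_CLASSIFIERS = ("KNN", "RF", "MLP", "DTree", "Softmax")


def _make_classifier(name: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.tree import DecisionTreeClassifier

    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "MLP":
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                             random_state=seed)
    if name == "DTree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "Softmax":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; valid: {DEFAULT_CLASSIFIERS}")


def classify_and_score(features, labels, classifiers=DEFAULT_CLASSIFIERS,
                       seed: int = 0, splits=(0.75, 0.15, 0.10)) -> pd.DataFrame:
    """Held-out accuracy and macro one-vs-rest AUC per classifier.

    Rows are classifier names plus an 'Avg' row; the split (train on the
    train fraction, score on the test fraction) is stratified and a pure
    function of the seed.
    """
    from sklearn.metrics import accuracy_score, roc_auc_score

    X = np.asarray(getattr(features, "X", features), dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for a stratified split")
    train_idx, eval_idx, test_idx = stratified_split(y, splits, seed)
    fit_idx = train_idx
    rows = []
    for name in classifiers:
        clf = _make_classifier(name, seed)
        clf.fit(X[fit_idx], y[fit_idx])
        pred = clf.predict(X[test_idx])
        acc = accuracy_score(y[test_idx], pred)
        proba = clf.predict_proba(X[test_idx])
        if len(classes) == 2:
            auc = roc_auc_score(y[test_idx], proba[:, 1])
        else:
            auc = roc_auc_score(y[test_idx], proba, multi_class="ovr", average="macro")
        rows.append({"classifier": name, "accuracy": acc, "auc": auc})
    table = pd.DataFrame(rows).set_index("classifier")
    table.loc["Avg"] = table.mean()
    return table


def sample_variance(x) -> float:
    """Unbiased sample variance; exactly 0 for a constant sample.

    Naive accumulation over a constant column yields ~1e-33 of floating-
    point dust (and from there an astronomical variance ratio); a sample
    whose elements are all identical has variance 0 by definition.
    """
    x = np.asarray(x, dtype=float)
    if np.all(x == x.flat[0]):
        return 0.0
    return float(x.var(ddof=1))


def welch_t_test(a, b) -> WelchResult:
    """Two-sample t test assuming unequal variances.

    Returns (t, df, one-tailed p, two-tailed p).  Zero combined variance
    (both samples constant) gives t = 0 for equal means, ±inf otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = len(a), len(b)
    va, vb = sample_variance(a), sample_variance(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        t = 0.0 if diff == 0.0 else np.copysign(np.inf, diff)
        df = float(na + nb - 2)
    else:
        t = diff / np.sqrt(se2)
        den = 0.0
        if va > 0:
            den += (va / na) ** 2 / (na - 1)
        if vb > 0:
            den += (vb / nb) ** 2 / (nb - 1)
        # den == 0 cannot happen here (se2 > 0 implies some variance)
        df = se2**2 / den
    p_one = float(sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p_one, 2.0 * p_one)


def f_test_variances(a, b) -> FTestResult:
    """Variance-ratio F test, F = var(a)/var(b) on (n_a−1, n_b−1) df.

    A constant second sample yields F = +inf with a warning rather than an
    astronomically large finite ratio.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = sample_variance(a), sample_variance(b)
    if vb == 0.0:
        warnings.warn("var(b) is exactly 0; reporting F = inf", RuntimeWarning,
                      stacklevel=2)
        return FTestResult(float("inf"), 0.0)
    F = va / vb
    p_one = float(sps.f.sf(F, len(a) - 1, len(b) - 1))
    return FTestResult(float(F), p_one)
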