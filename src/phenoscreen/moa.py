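"""Mechanism-of-action classification over well profiles.

The classifier is a random forest in which every tree is grown on a
class-stratified balanced bootstrap: from each class, the same number of
observations — the size of the smallest class — is drawn with replacement.
This mirrors the stratified/sampsize balancing convention of classical
random-forest implementations and keeps the 500-tree vote unbiased by
class frequency.  Out-of-bag (OOB) predictions are tracked per
observation, giving an internal error estimate without a held-out set.

Training observations are well profiles: for each reference compound the
wells from all screened concentrations are pooled under a single class
label, and vehicle (DMSO) wells form their own class.  Class probabilities
are tree-vote fractions.  Leave-one-cell-line-out cross-validation trains
on all but one cancer line and tests on the held-out line to measure how
well phenotypic classes transfer to an unseen genetic background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from phenoscreen.preprocess import feature_columns

__all__ = [
    "MoARandomForest",
    "ConfusionMatrix",
    "build_training_set",
    "confusion_matrix",
    "harmonize_features",
    "loco_cv",
    "predict_moa",
]

DMSO_LABEL = "DMSO"


def build_training_set(
    profiles: pd.DataFrame,
    annotations: pd.DataFrame,
    doses: tuple[float, ...] | None = None,
    include_dmso: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Label well profiles with their compound's class, pooling doses.

    Every treatment well of an annotated compound becomes one observation
    labelled with the compound's class, regardless of concentration (doses
    can be restricted with ``doses``).  DMSO wells are labelled
    ``"DMSO"`` when ``include_dmso``.  An unannotated treatment compound
    is a hard error naming the compound.
    """
    ann = dict(zip(annotations["compound"], annotations["moa_class"]))
    rows = profiles["role"] == "treatment"
    if doses is not None:
        rows &= profiles["concentration"].isin(doses)
    treated = profiles.loc[rows]
    unknown = sorted(set(treated["compound"]) - set(ann))
    if unknown:
        raise ValueError(f"compounds without MoA annotation: {unknown}")
    labels = treated["compound"].map(ann)
    out = treated
    if include_dmso:
        dmso = profiles.loc[profiles["role"] == "vehicle_control"]
        out = pd.concat([treated, dmso], ignore_index=True)
        labels = pd.concat([labels, pd.Series([DMSO_LABEL] * len(dmso))], ignore_index=True)
    labels.name = "moa_class"
    labels.index = out.index
    return out.reset_index(drop=True), labels.reset_index(drop=True)


class MoARandomForest(BaseEstimator, ClassifierMixin):
    """Random forest with class-stratified balanced bootstraps and OOB error.

    Parameters
    ----------
    n_estimators : number of trees (default 500).
    max_features : per-split feature subsampling, as in standard forests.
    random_state : seed controlling bootstraps and tree growth; fixed seed
        gives identical OOB error and predictions.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels.
    oob_error_ : fraction of observations misclassified by the vote of
        trees that did not see them.
    oob_decision_function_ : per-observation OOB vote fractions.
    bootstrap_class_counts_ : draws per class per tree — every entry equals
        the smallest class size.
    """

    def __init__(self, n_estimators: int = 500, max_features: str | int | float = "sqrt", random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = self._as_matrix(X, fit=True)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_enc)
        small = [str(self.classes_[i]) for i, c in enumerate(counts) if c < 2]
        if small:
            raise ValueError(f"classes with fewer than 2 observations: {small}")
        n_min = int(counts.min())
        class_idx = [np.flatnonzero(y_enc == k) for k in range(len(self.classes_))]

        rng = np.random.default_rng(self.random_state)
        n, k = X.shape[0], len(self.classes_)
        oob_votes = np.zeros((n, k))
        self.estimators_ = []
        draws = np.full((self.n_estimators, k), n_min, dtype=int)
        for t in range(self.n_estimators):
            in_bag = np.concatenate([rng.choice(idx, n_min, replace=True) for idx in class_idx])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[in_bag], y_enc[in_bag])
            self.estimators_.append(tree)
            oob = np.ones(n, dtype=bool)
            oob[np.unique(in_bag)] = False
            if oob.any():
                pred = tree.predict(X[oob])
                oob_votes[np.flatnonzero(oob), pred] += 1.0

        self.bootstrap_class_counts_ = draws
        self.min_class_size_ = n_min
        voted = oob_votes.sum(axis=1) > 0
        totals = np.where(voted, oob_votes.sum(axis=1), 1.0)
        self.oob_decision_function_ = oob_votes / totals[:, None]
        oob_pred = oob_votes.argmax(axis=1)
        self.oob_error_ = float(np.mean(oob_pred[voted] != y_enc[voted])) if voted.any() else np.nan
        return self

    def _as_matrix(self, X, fit: bool = False) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            feats = feature_columns(X)
            if fit:
                self.feature_names_in_ = np.asarray(feats, dtype=object)
            elif self.feature_names_in_ is not None:
                missing = [f for f in self.feature_names_in_ if f not in X.columns]
                if missing:
                    raise ValueError(f"profiles lack model features: {missing}")
                feats = list(self.feature_names_in_)
            return X[feats].to_numpy(dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if fit:
            self.feature_names_in_ = None
        elif self.feature_names_in_ is not None and X.shape[1] != len(self.feature_names_in_):
            raise ValueError("feature count mismatch with trained model")
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Vote-share probabilities: the fraction of trees voting each class."""
        check_is_fitted(self, "estimators_")
        X = self._as_matrix(X)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.estimators_:
            votes[np.arange(X.shape[0]), tree.predict(X)] += 1.0
        return votes / len(self.estimators_)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def predict_moa(model: MoARandomForest, profiles: pd.DataFrame) -> pd.DataFrame:
    """Class-probability vectors per observation, as a labelled DataFrame."""
    proba = model.predict_proba(profiles)
    return pd.DataFrame(proba, columns=list(model.classes_), index=profiles.index)


@dataclass
class ConfusionMatrix:
    """Counts indexed (true class, predicted class), plus per-class sensitivity."""

    counts: pd.DataFrame

    @property
    def sensitivities(self) -> pd.Series:
        """Recall per class: diagonal of the row-normalized matrix."""
        row_sums = self.counts.sum(axis=1)
        diag = pd.Series(np.diag(self.counts.to_numpy()), index=self.counts.index, dtype=float)
        return diag / row_sums.replace(0, np.nan)

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        return float(np.trace(self.counts.to_numpy()) / total) if total else np.nan


def confusion_matrix(y_true, y_pred, classes=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    outside = sorted(set(np.concatenate([y_true, y_pred])) - set(classes))
    if outside:
        raise ValueError(f"labels outside class set: {outside}")
    from sklearn.metrics import confusion_matrix as _sk_cm

    counts = _sk_cm(y_true, y_pred, labels=classes)
    return ConfusionMatrix(pd.DataFrame(counts, index=classes, columns=classes))


def harmonize_features(profiles_by_line: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Restrict every line's profiles to the feature intersection.

    Per-line feature selection can retain different feature sets; model
    transfer across lines requires a shared set, so this keeps the
    intersection (metadata columns untouched) in a stable order.
    """
    names = list(profiles_by_line)
    shared = set(feature_columns(profiles_by_line[names[0]]))
    for n in names[1:]:
        shared &= set(feature_columns(profiles_by_line[n]))
    if len(shared) < 2:
        raise ValueError("fewer than 2 features shared across cell lines")
    order = [f for f in feature_columns(profiles_by_line[names[0]]) if f in shared]
    out = {}
    for n, df in profiles_by_line.items():
        meta = [c for c in df.columns if c not in set(feature_columns(df))]
        out[n] = df[meta + order].copy()
    return out


def loco_cv(
    labeled_by_line: dict[str, tuple[pd.DataFrame, pd.Series]],
    n_estimators: int = 500,
    max_features: str | int | float = "sqrt",
    random_state: int | None = None,
) -> dict[str, dict]:
    """Leave-one-cell-line-out cross-validation.

    ``labeled_by_line`` maps each cancer line to its (profiles, labels).
    For every line, a forest is trained on the pooled other lines and
    tested on the held-out line; one fold per line.  All lines must share
    one feature set (use :func:`harmonize_features` first).
    """
    lines = list(labeled_by_line)
    if len(lines) < 3:
        raise ValueError("leave-one-line-out needs at least 3 cell lines")
    ref_feats = feature_columns(labeled_by_line[lines[0]][0])
    for line in lines[1:]:
        if feature_columns(labeled_by_line[line][0]) != ref_feats:
            raise ValueError(f"feature set of line {line} differs; harmonize upstream")

    results: dict[str, dict] = {}
    for i, test_line in enumerate(lines):
        train_X = pd.concat([labeled_by_line[l][0] for l in lines if l != test_line], ignore_index=True)
        train_y = pd.concat([labeled_by_line[l][1] for l in lines if l != test_line], ignore_index=True)
        seed = None if random_state is None else random_state + i
        model = MoARandomForest(n_estimators=n_estimators, max_features=max_features, random_state=seed).fit(
            train_X, train_y
        )
        test_X, test_y = labeled_by_line[test_line]
        pred = model.predict(test_X)
        cm = confusion_matrix(test_y.to_numpy(), pred, classes=model.classes_)
        results[test_line] = {
            "accuracy": float(np.mean(pred == test_y.to_numpy())),
            "confusion": cm,
            "oob_error": model.oob_error_,
            "model": model,
        }
    return results
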