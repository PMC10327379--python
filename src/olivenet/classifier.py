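"""Per-setting logistic models, nested CV, and the consensus ensemble.

Each propagation setting contributes a single feature (the Pearson
correlation between molecule and disease perturbation profiles at that
setting); a univariate logistic regression is fitted per setting with
class-balanced sample weights.  Generalization is estimated by repeated
nested stratified cross-validation (inner folds pick the best setting,
outer folds score it), members whose own cross-validated balanced
accuracy exceeds the nested-CV mean form the ensemble, and the
consensus "correlation probability (%)" of a molecule is the mean of
the member probabilities scaled to percent.

The univariate fits are batched across settings with a Newton/IRLS
solver (equivalent to weakly L2-regularised logistic regression; the
unit tests cross-check its coefficients against scikit-learn).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_X_y, check_array

from .associations import LabeledDrugSet
from .features import FeatureMatrix
from .propagation import PropagationSettings

logger = logging.getLogger(__name__)

#: ridge penalty on the slope, matching scikit-learn's C = 1/L2_PENALTY
L2_PENALTY = 1e-4


def balanced_accuracy(labels: np.ndarray, predictions: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 for binary labels.

    Errors on single-class label vectors, where the statistic is
    undefined.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("balanced accuracy needs both classes in the labels")
    return float(balanced_accuracy_score(labels, predictions))


def balanced_sample_weight(y: np.ndarray) -> np.ndarray:
    """Class-balanced weights: n / (2 * class count), as in scikit-learn."""
    y = np.asarray(y)
    n = len(y)
    w = np.empty(n)
    for cls in np.unique(y):
        mask = y == cls
        w[mask] = n / (2.0 * mask.sum())
    return w


def fit_logistic_batch(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    l2: float = L2_PENALTY,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one univariate logistic model per column of X, all at once.

    Minimises, per column j,

        sum_i w_i [log(1 + exp(eta_ij)) - y_i eta_ij] + l2/2 * slope_j^2

    with eta_ij = intercept_j + slope_j * X_ij, by damped Newton steps
    (step-halving line search).  Returns (intercepts, slopes), each of
    shape (n_columns,).  The intercept is unpenalised, matching
    scikit-learn's convention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    yw = (w * y)[:, None]
    b0 = np.zeros(k)
    b1 = np.zeros(k)

    def loss(b0, b1):
        eta = b0[None, :] + X * b1[None, :]
        return (
            (w[:, None] * np.logaddexp(0.0, eta)).sum(axis=0)
            - (yw * eta).sum(axis=0)
            + 0.5 * l2 * b1 ** 2
        )

    cur = loss(b0, b1)
    for _ in range(max_iter):
        eta = b0[None, :] + X * b1[None, :]
        mu = expit(eta)
        r = w[:, None] * (mu - y[:, None])
        g0 = r.sum(axis=0)
        g1 = (r * X).sum(axis=0) + l2 * b1
        if max(np.abs(g0).max(), np.abs(g1).max()) < tol * max(1.0, w.sum()):
            break
        s = w[:, None] * mu * (1.0 - mu) + 1e-12
        h00 = s.sum(axis=0)
        h01 = (s * X).sum(axis=0)
        h11 = (s * X * X).sum(axis=0) + l2
        det = np.maximum(h00 * h11 - h01 ** 2, 1e-300)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        # step-halving: per-column backtracking until the loss decreases
        alpha = np.ones(k)
        for _ in range(30):
            cand = loss(b0 - alpha * d0, b1 - alpha * d1)
            worse = cand > cur
            if not worse.any():
                break
            alpha[worse] *= 0.5
        b0 = b0 - alpha * d0
        b1 = b1 - alpha * d1
        cur = loss(b0, b1)
    if not (np.isfinite(b0).all() and np.isfinite(b1).all()):
        raise RuntimeError("logistic fit produced non-finite coefficients")
    return b0, b1


@dataclass(frozen=True)
class SettingModel:
    """A fitted univariate logistic model for one propagation setting."""

    setting: PropagationSettings
    intercept: float
    slope: float
    cv_balanced_accuracy: float = float("nan")


@dataclass(frozen=True)
class CvSummary:
    """Nested-CV performance: mean +/- sd over all repeat x fold scores."""

    mean_balanced_accuracy: float
    sd_balanced_accuracy: float
    n_repeats: int
    n_outer_folds: int
    n_inner_folds: int
    rng_seed: int


@dataclass(frozen=True)
class EnsembleModel:
    """The selected set of above-threshold setting models."""

    members: tuple[SettingModel, ...]
    selection_threshold: float
    cv: CvSummary

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {
            "selection_threshold": self.selection_threshold,
            "cv": asdict(self.cv),
            "members": [
                {
                    "threshold": m.setting.threshold,
                    "c_disease": m.setting.c_disease,
                    "c_molecule": m.setting.c_molecule,
                    "intercept": m.intercept,
                    "slope": m.slope,
                    "cv_balanced_accuracy": m.cv_balanced_accuracy,
                }
                for m in self.members
            ],
        }
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        doc = json.loads(Path(path).read_text())
        members = tuple(
            SettingModel(
                setting=PropagationSettings(
                    threshold=int(m["threshold"]),
                    c_disease=m["c_disease"],
                    c_molecule=m["c_molecule"],
                ),
                intercept=m["intercept"],
                slope=m["slope"],
                cv_balanced_accuracy=m["cv_balanced_accuracy"],
            )
            for m in doc["members"]
        )
        return cls(
            members=members,
            selection_threshold=doc["selection_threshold"],
            cv=CvSummary(**doc["cv"]),
        )


class EnsembleCorrelationClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of per-setting univariate logistic models.

    ``fit`` runs the whole training protocol on a (molecules x
    settings) correlation matrix: repeated nested stratified CV for the
    generalization estimate, a single stratified CV per setting for the
    member accuracies, a full-data refit per setting, and selection of
    the settings whose CV balanced accuracy strictly exceeds the
    nested-CV mean (falling back to the single best setting when none
    does).  ``predict_proba`` averages the member probabilities.

    Parameters
    ----------
    n_repeats, n_outer, n_inner : int
        Repeats and fold counts of the nested stratified CV.
    l2 : float
        Ridge penalty on each slope (1 / scikit-learn's C).
    random_state : int or None
        Seeds every fold shuffle; the fit is a pure function of
        (X, y, random_state).

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; ``classes_[1]`` is the positive class.
    intercepts_, slopes_ : ndarray of shape (n_settings,)
        Full-data univariate fits, one per feature column.
    setting_cv_accuracies_ : ndarray of shape (n_settings,)
        Per-setting 5-fold stratified CV balanced accuracy on the full
        labeled set.
    cv_summary_ : CvSummary
        Nested-CV mean +/- sd balanced accuracy.
    member_indices_ : ndarray
        Columns selected into the ensemble.
    """

    def __init__(
        self,
        n_repeats: int = 25,
        n_outer: int = 5,
        n_inner: int = 5,
        l2: float = L2_PENALTY,
        random_state: int | None = None,
    ):
        self.n_repeats = n_repeats
        self.n_outer = n_outer
        self.n_inner = n_inner
        self.l2 = l2
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y) -> "EnsembleCorrelationClassifier":
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly 2 classes, got {len(self.classes_)}"
            )
        counts = np.bincount(y_enc)
        if counts.min() < self.n_outer:
            raise ValueError(
                f"minimum class size for {self.n_outer}-fold stratified CV is "
                f"{self.n_outer}; got class counts {counts.tolist()}"
            )
        rng = check_random_state(self.random_state)
        seed_int = self.random_state if self.random_state is not None else -1

        scores = []
        for _ in range(self.n_repeats):
            outer_seed = rng.randint(2 ** 31)
            outer = StratifiedKFold(
                n_splits=self.n_outer, shuffle=True, random_state=outer_seed
            )
            for train_idx, test_idx in outer.split(X, y_enc):
                inner_seed = rng.randint(2 ** 31)
                best = self._select_setting(
                    X[train_idx], y_enc[train_idx], inner_seed
                )
                b0, b1 = fit_logistic_batch(
                    X[train_idx][:, [best]],
                    y_enc[train_idx],
                    balanced_sample_weight(y_enc[train_idx]),
                    l2=self.l2,
                )
                pred = expit(b0[0] + b1[0] * X[test_idx, best]) >= 0.5
                scores.append(balanced_accuracy_score(y_enc[test_idx], pred))
        scores = np.asarray(scores)
        self.nested_cv_scores_ = scores
        self.cv_summary_ = CvSummary(
            mean_balanced_accuracy=float(scores.mean()),
            sd_balanced_accuracy=float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
            n_repeats=self.n_repeats,
            n_outer_folds=self.n_outer,
            n_inner_folds=self.n_inner,
            rng_seed=seed_int,
        )

        # per-setting member accuracy: one stratified 5-fold CV on all data
        member_seed = rng.randint(2 ** 31)
        self.setting_cv_accuracies_ = self._per_setting_cv(
            X, y_enc, n_folds=5, seed=member_seed
        )

        self.intercepts_, self.slopes_ = fit_logistic_batch(
            X, y_enc, balanced_sample_weight(y_enc), l2=self.l2
        )

        threshold = self.cv_summary_.mean_balanced_accuracy
        members = np.flatnonzero(self.setting_cv_accuracies_ > threshold)
        if members.size == 0:
            best = int(np.argmax(self.setting_cv_accuracies_))
            logger.warning(
                "no setting beats the nested-CV mean %.4f; "
                "falling back to the single best setting (index %d)",
                threshold, best,
            )
            members = np.array([best])
        self.member_indices_ = members
        self.selection_threshold_ = threshold
        self.n_features_in_ = X.shape[1]
        return self

    def _select_setting(self, X: np.ndarray, y: np.ndarray, seed: int) -> int:
        """Best setting by mean inner-CV balanced accuracy (tie: lowest index)."""
        acc = self._per_setting_cv(X, y, n_folds=self.n_inner, seed=seed)
        return int(np.argmax(acc))

    def _per_setting_cv(
        self, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int
    ) -> np.ndarray:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        acc = np.zeros(X.shape[1])
        for train_idx, test_idx in kf.split(X, y):
            b0, b1 = fit_logistic_batch(
                X[train_idx], y[train_idx],
                balanced_sample_weight(y[train_idx]), l2=self.l2,
            )
            prob = expit(b0[None, :] + X[test_idx] * b1[None, :])
            pred = prob >= 0.5
            y_test = y[test_idx]
            pos = y_test == 1
            sens = pred[pos].mean(axis=0)
            spec = 1.0 - pred[~pos].mean(axis=0)
            acc += (sens + spec) / 2.0
        return acc / n_folds

    # -- prediction ------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} settings columns, expected {self.n_features_in_}"
            )
        idx = self.member_indices_
        member_probs = expit(
            self.intercepts_[idx][None, :] + X[:, idx] * self.slopes_[idx][None, :]
        )
        pos = member_probs.mean(axis=1)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def correlation_probability(self, X) -> np.ndarray:
        """Consensus probability of the positive class, in percent."""
        return 100.0 * self.predict_proba(X)[:, 1]


# -- module-level operations over the domain types -----------------------


def _align_labels(features: FeatureMatrix, labels: LabeledDrugSet) -> tuple[np.ndarray, np.ndarray]:
    labeled = [m for m in features.molecules if m in labels.labels]
    missing = [m for m in labels.labels if m not in features.molecules]
    if missing:
        logger.warning("%d labeled molecules missing from the feature matrix", len(missing))
    X = features.subset(labeled).values
    y = np.array([1 if labels.labels[m] == "positive" else 0 for m in labeled])
    return X, y


def fit_setting_model(
    feature: np.ndarray,
    labels: np.ndarray,
    setting: PropagationSettings,
    l2: float = L2_PENALTY,
    cv_balanced_accuracy: float = float("nan"),
) -> SettingModel:
    """Univariate class-weighted logistic fit for one setting."""
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError(f"setting {setting.label()}: need both classes to fit")
    try:
        b0, b1 = fit_logistic_batch(
            np.asarray(feature, float)[:, None], y, balanced_sample_weight(y), l2=l2
        )
    except RuntimeError as exc:
        raise RuntimeError(f"setting {setting.label()}: {exc}") from exc
    return SettingModel(
        setting=setting, intercept=float(b0[0]), slope=float(b1[0]),
        cv_balanced_accuracy=cv_balanced_accuracy,
    )


def nested_cv(
    features: FeatureMatrix,
    labels: LabeledDrugSet,
    n_repeats: int = 25,
    n_outer: int = 5,
    n_inner: int = 5,
    rng_seed: int = 0,
) -> CvSummary:
    """Repeated nested stratified CV balanced accuracy of the protocol."""
    labels.require_both_classes()
    X, y = _align_labels(features, labels)
    clf = EnsembleCorrelationClassifier(
        n_repeats=n_repeats, n_outer=n_outer, n_inner=n_inner, random_state=rng_seed
    ).fit(X, y)
    return clf.cv_summary_


def select_ensemble(
    per_setting_models: Sequence[SettingModel], cv: CvSummary
) -> EnsembleModel:
    """Keep models whose CV balanced accuracy strictly beats the CV mean."""
    if not per_setting_models:
        raise ValueError("no setting models to select from")
    members = tuple(
        m for m in per_setting_models
        if m.cv_balanced_accuracy > cv.mean_balanced_accuracy
    )
    if not members:
        best = max(per_setting_models, key=lambda m: m.cv_balanced_accuracy)
        logger.warning(
            "no setting model beats the CV mean %.4f; falling back to the "
            "single best (%s, %.4f)",
            cv.mean_balanced_accuracy, best.setting.label(), best.cv_balanced_accuracy,
        )
        members = (best,)
    return EnsembleModel(
        members=members, selection_threshold=cv.mean_balanced_accuracy, cv=cv
    )


def train_ensemble(
    features: FeatureMatrix,
    labels: LabeledDrugSet,
    n_repeats: int = 25,
    n_outer: int = 5,
    n_inner: int = 5,
    rng_seed: int = 0,
) -> tuple[EnsembleModel, EnsembleCorrelationClassifier]:
    """Full training protocol on a labeled feature matrix.

    Returns both the serialisable :class:`EnsembleModel` (with settings
    attached to every member) and the fitted estimator.
    """
    labels.require_both_classes()
    X, y = _align_labels(features, labels)
    clf = EnsembleCorrelationClassifier(
        n_repeats=n_repeats, n_outer=n_outer, n_inner=n_inner, random_state=rng_seed
    ).fit(X, y)
    models = [
        SettingModel(
            setting=features.settings[j],
            intercept=float(clf.intercepts_[j]),
            slope=float(clf.slopes_[j]),
            cv_balanced_accuracy=float(clf.setting_cv_accuracies_[j]),
        )
        for j in clf.member_indices_
    ]
    ensemble = EnsembleModel(
        members=tuple(models),
        selection_threshold=clf.selection_threshold_,
        cv=clf.cv_summary_,
    )
    return ensemble, clf


def predict_consensus(
    ensemble: EnsembleModel, features: FeatureMatrix
) -> dict[str, float]:
    """Mean member probability per molecule, in percent (Table-1 scale)."""
    cols = []
    for m in ensemble.members:
        try:
            cols.append(features.settings.index(m.setting))
        except ValueError:
            raise KeyError(
                f"feature matrix lacks the setting column {m.setting.label()}"
            ) from None
    out: dict[str, float] = {}
    for i, mol in enumerate(features.molecules):
        probs = [
            expit(m.intercept + m.slope * features.values[i, j])
            for m, j in zip(ensemble.members, cols)
        ]
        out[mol] = float(100.0 * np.mean(probs))
    return out
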