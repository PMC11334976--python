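"""Supervised colour classification of nanoparticle HSV features.

Two classifiers are supported, mirroring the standard baseline/champion
pairing for this kind of three-class chromatic separation task:

* ``gaussian_nb`` — Gaussian naive Bayes: per-class diagonal-covariance
  Gaussian likelihoods with empirical priors;
* ``svm_rbf`` — a support-vector machine with radial-basis-function kernel
  ``exp(-gamma * ||x - x'||^2)``, one-vs-one multiclass voting.

Models are fitted with scikit-learn but persisted as portable JSON holding
every numeric parameter (support vectors, dual coefficients, intercepts,
class means/variances/priors, the feature normalizer), so a saved model can
be checked, versioned and re-evaluated without language-native pickles.
Prediction from the JSON parameters is implemented here in plain NumPy and
is verified in the test suite to agree with scikit-learn's own prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .errors import InvalidInputError
from .features import (
    FEATURE_COLUMNS,
    NormalizerParams,
    apply_normalizer,
    fit_normalizer,
)

__all__ = [
    "DEFAULT_CLASS_SET",
    "ConfusionMatrix",
    "TrainedClassifier",
    "split_dataset",
    "train_classifier",
    "confusion_matrix",
    "MODEL_SCHEMA_VERSION",
]

DEFAULT_CLASS_SET = ("blue", "green", "yellow")
MODEL_SCHEMA_VERSION = 1


def split_dataset(
    labelled: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation split of a labelled feature table.

    Deterministic for a fixed seed; the two outputs partition the input.
    """
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError("train_fraction must lie in (0, 1)")
    if "label" not in labelled.columns:
        raise InvalidInputError("labelled table must have a 'label' column")
    counts = labelled["label"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise InvalidInputError(
            f"every class needs >= 2 rows; too few for {list(thin.index)}"
        )
    train, val = train_test_split(
        labelled,
        train_size=train_fraction,
        stratify=labelled["label"],
        random_state=seed,
        shuffle=True,
    )
    return train.reset_index(drop=True), val.reset_index(drop=True)


# ---------------------------------------------------------------------------
# portable prediction from JSON-serializable parameters


def _rbf_kernel(x: np.ndarray, sv: np.ndarray, gamma: float) -> np.ndarray:
    d2 = ((x[:, None, :] - sv[None, :, :]) ** 2).sum(-1)
    return np.exp(-gamma * d2)


def _svm_ovo_predict(params: dict, x: np.ndarray) -> np.ndarray:
    """One-vs-one RBF-SVM voting from stored parameters.

    ``dual_coef`` follows the libsvm layout: row ``k`` holds, for every
    support vector, its coefficient in the binary problems that involve its
    own class and class ``k`` (shifted by one). Ties in the vote go to the
    class with the lowest index, matching libsvm. With three or more
    classes a positive pairwise decision favours the first class of the
    pair; scikit-learn stores two-class models with the opposite sign
    (positive favours the second class), which is handled separately.
    """
    sv = np.asarray(params["support_vectors"], dtype=float)
    dual = np.asarray(params["dual_coef"], dtype=float)
    intercept = np.asarray(params["intercept"], dtype=float)
    n_support = np.asarray(params["n_support"], dtype=int)
    gamma = float(params["gamma"])
    n_classes = len(n_support)
    starts = np.concatenate([[0], np.cumsum(n_support)])

    k = _rbf_kernel(x, sv, gamma)
    if n_classes == 2:
        dec = k @ dual[0] + intercept[0]
        return (dec > 0).astype(int)
    votes = np.zeros((len(x), n_classes), dtype=int)
    p = 0
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            sv_i = slice(starts[i], starts[i + 1])
            sv_j = slice(starts[j], starts[j + 1])
            dec = (
                k[:, sv_i] @ dual[j - 1, sv_i]
                + k[:, sv_j] @ dual[i, sv_j]
                + intercept[p]
            )
            votes[:, i] += dec > 0
            votes[:, j] += dec <= 0
            p += 1
    return votes.argmax(axis=1)


def _gnb_predict(params: dict, x: np.ndarray) -> np.ndarray:
    theta = np.asarray(params["theta"], dtype=float)
    var = np.asarray(params["var"], dtype=float)
    prior = np.asarray(params["prior"], dtype=float)
    log_like = -0.5 * (
        np.log(2.0 * np.pi * var)[None, :, :]
        + (x[:, None, :] - theta[None, :, :]) ** 2 / var[None, :, :]
    ).sum(-1)
    return (log_like + np.log(prior)[None, :]).argmax(axis=1)


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion matrix: ``c[i, j]`` is the fraction of
    true-class-``i`` validation particles predicted as class ``j``."""

    c: np.ndarray
    class_set: tuple[str, ...]
    support: np.ndarray  # per-row true counts

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        k = len(self.class_set)
        if self.c.shape != (k, k):
            raise InvalidInputError(
                f"confusion matrix shape {self.c.shape} does not match {k} classes"
            )

    def validate_rows(self, tol: float = 1e-6) -> None:
        sums = self.c.sum(axis=1)
        bad = (self.support > 0) & (np.abs(sums - 1.0) > tol)
        if bad.any():
            raise InvalidInputError(
                f"confusion rows not normalized: {[self.class_set[i] for i in np.nonzero(bad)[0]]}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=list(self.class_set), columns=list(self.class_set))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="true\\predicted")

    def to_dict(self) -> dict:
        return {
            "class_set": list(self.class_set),
            "c": self.c.tolist(),
            "support": self.support.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        return cls(
            c=np.asarray(d["c"], dtype=float),
            class_set=tuple(d["class_set"]),
            support=np.asarray(d["support"], dtype=int),
        )


def confusion_matrix(
    true_labels,
    predicted_labels,
    class_set=DEFAULT_CLASS_SET,
) -> ConfusionMatrix:
    """Confusion matrix row-normalized by the true-class support.

    Rows with zero support are left all-zero. Depends only on the multiset
    of (true, predicted) pairs.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise InvalidInputError("true and predicted label lists differ in length")
    unknown = set(true_labels) | set(predicted_labels)
    unknown -= set(class_set)
    if unknown:
        raise InvalidInputError(f"labels outside the class set: {sorted(unknown)}")
    raw = _sk_confusion(true_labels, predicted_labels, labels=list(class_set))
    support = raw.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(support[:, None] > 0, raw / np.maximum(support[:, None], 1), 0.0)
    return ConfusionMatrix(c=c, class_set=tuple(class_set), support=support)


@dataclass
class TrainedClassifier:
    """A fitted colour classifier bundled with its feature normalizer.

    ``predict`` accepts raw (unnormalized) HSV features and applies the
    bundled normalizer internally, so the training-time scaling can never
    drift from the inference-time scaling.
    """

    kind: str  # 'svm_rbf' | 'gaussian_nb'
    class_set: tuple[str, ...]
    normalizer: NormalizerParams
    params: dict
    metadata: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> list[str]:
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise InvalidInputError(f"feature table lacks column(s) {missing}")
        if len(features) == 0:
            return []
        normalized = apply_normalizer(features, self.normalizer)
        x = normalized[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        if self.kind == "svm_rbf":
            idx = _svm_ovo_predict(self.params, x)
        elif self.kind == "gaussian_nb":
            idx = _gnb_predict(self.params, x)
        else:  # pragma: no cover - guarded at construction
            raise InvalidInputError(f"unknown classifier kind {self.kind!r}")
        return [self.class_set[i] for i in idx]

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": self.kind,
            "class_set": list(self.class_set),
            "normalizer": self.normalizer.to_dict(),
            "params": self.params,
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedClassifier":
        return cls(
            kind=d["kind"],
            class_set=tuple(d["class_set"]),
            normalizer=NormalizerParams.from_dict(d["normalizer"]),
            params=d["params"],
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_classifier(
    train: pd.DataFrame,
    kind: str = "svm_rbf",
    hyper: dict | None = None,
    class_set=None,
    normalizer: NormalizerParams | None = None,
    metadata: dict | None = None,
) -> TrainedClassifier:
    """Fit a classifier on a labelled (raw-feature) training table.

    The feature normalizer is fitted on ``train`` unless one is supplied,
    then the normalized features are passed to scikit-learn. For
    ``svm_rbf`` the default hyperparameters are ``C = 1`` and the scale
    heuristic ``gamma = 1 / (n_features * Var(X))`` evaluated on the
    normalized training features.
    """
    if kind not in ("svm_rbf", "gaussian_nb"):
        raise InvalidInputError(f"unknown classifier kind {kind!r}")
    if "label" not in train.columns:
        raise InvalidInputError("training table must have a 'label' column")
    present = sorted(train["label"].unique())
    if len(present) < 2:
        raise InvalidInputError("training data must contain at least 2 classes")
    if class_set is None:
        class_set = tuple(c for c in DEFAULT_CLASS_SET if c in present)
        if set(present) - set(class_set):
            class_set = tuple(present)
    if set(present) - set(class_set):
        raise InvalidInputError("training labels outside the declared class set")

    if normalizer is None:
        normalizer = fit_normalizer(train)
    normalized = apply_normalizer(train, normalizer)
    x = normalized[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    # integer codes in class_set order so stored parameters follow it
    code = {name: i for i, name in enumerate(class_set)}
    y = train["label"].map(code).to_numpy(dtype=int)

    hyper = dict(hyper or {})
    if kind == "svm_rbf":
        c_val = float(hyper.get("C", 1.0))
        gamma = hyper.get("gamma", "scale")
        est = SVC(kernel="rbf", C=c_val, gamma=gamma, decision_function_shape="ovo")
        est.fit(x, y)
        params = {
            "support_vectors": est.support_vectors_.tolist(),
            "dual_coef": est.dual_coef_.tolist(),
            "intercept": est.intercept_.tolist(),
            "n_support": est.n_support_.tolist(),
            "gamma": float(est._gamma),
            "C": c_val,
            "classes": est.classes_.tolist(),
        }
    else:
        est = GaussianNB()
        est.fit(x, y)
        params = {
            "theta": est.theta_.tolist(),
            "var": est.var_.tolist(),
            "prior": est.class_prior_.tolist(),
            "classes": est.classes_.tolist(),
        }

    # libsvm orders classes by their integer code; re-map class_set if a
    # class is absent from training (guarded above: all must be present)
    classes = [int(c) for c in params["classes"]]
    ordered = tuple(class_set[i] for i in classes)

    meta = {"kind": kind, "n_train": int(len(train)), **(metadata or {})}
    return TrainedClassifier(
        kind=kind,
        class_set=ordered,
        normalizer=normalizer,
        params=params,
        metadata=meta,
    )
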