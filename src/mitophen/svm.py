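"""Linear support-vector classifier over symptom vectors.

The classifier is epsilon-insensitive support-vector *regression* (linear
kernel) trained on +1/-1 group labels, used as a margin classifier: a
positive score indicates the test disease resembles the positive reference
group, a negative score the controls.  Prevalences are fed unscaled
(0-100) by default.

Features can be restricted by *cumulative prevalence*: the sum of a
parameter's prevalences across all reference diseases.  A cumulative
prevalence of 25 % means, e.g., one disease at 25 % or five diseases at
5 % each; raising the threshold keeps only progressively more common
parameters, and the surviving feature sets are nested.

Cross-validation uses stratified folds so both classes appear in every
training split; the report pools the held-out predictions and gives the
mean squared error against the +/-1 labels, their Pearson correlation, and
the *separation* — the percentage of held-out predictions whose sign
matches the label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVR

from .errors import ValidationError
from .phenodb import DiseaseProfile, PhenotypeMatrix

__all__ = [
    "SvmModel",
    "CvReport",
    "cumulative_prevalence",
    "filter_parameters",
    "labels_from_groups",
    "train",
    "svm_score",
    "cross_validate",
]

REFERENCE_GROUPS = ("positive", "negative")


@dataclass
class SvmModel:
    """Linear model: score(x) = dot(weights, x) + bias over ``parameters``."""

    parameters: list[str]
    weights: np.ndarray
    bias: float
    filter_threshold: float | None = None
    epsilon: float = 0.1
    cost: float = 1.0
    scale: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.parameters),):
            raise ValidationError("one weight per parameter required")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "parameters": self.parameters,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "filter_threshold": self.filter_threshold,
            "epsilon": self.epsilon,
            "cost": self.cost,
            "scale": self.scale,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SvmModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            parameters=doc["parameters"],
            weights=np.asarray(doc["weights"], dtype=float),
            bias=float(doc["bias"]),
            filter_threshold=doc.get("filter_threshold"),
            epsilon=float(doc.get("epsilon", 0.1)),
            cost=float(doc.get("cost", 1.0)),
            scale=bool(doc.get("scale", False)),
        )


@dataclass
class CvReport:
    k: int
    fold_assignment: dict[str, int]
    mse: float
    correlation: float
    separation: float
    predictions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "mse": self.mse,
            "correlation": self.correlation,
            "separation": self.separation,
            "fold_assignment": self.fold_assignment,
            "predictions": self.predictions,
        }


def _reference_rows(matrix: PhenotypeMatrix) -> list[int]:
    return [i for i, g in enumerate(matrix.groups) if g in REFERENCE_GROUPS]


def cumulative_prevalence(matrix: PhenotypeMatrix, parameter: str) -> float:
    """Sum of a parameter's prevalences over all reference diseases."""
    if parameter not in matrix.parameters:
        return 0.0
    j = matrix.parameters.index(parameter)
    rows = _reference_rows(matrix)
    return float(matrix.values[rows, j].sum())


def filter_parameters(matrix: PhenotypeMatrix, threshold: float) -> PhenotypeMatrix:
    """Keep parameters whose cumulative prevalence is >= threshold.

    Column order is preserved, so thresholds produce nested feature sets.
    """
    rows = _reference_rows(matrix)
    cum = matrix.values[rows].sum(axis=0)
    keep = [p for j, p in enumerate(matrix.parameters) if cum[j] >= threshold]
    if not keep:
        raise ValidationError(f"empty feature set at cumulative-prevalence threshold {threshold}")
    return matrix.subset_parameters(keep)


def labels_from_groups(matrix: PhenotypeMatrix) -> dict[str, int]:
    """+1 for positive-group diseases, -1 for negative; test diseases omitted."""
    return {
        d: (1 if g == "positive" else -1)
        for d, g in zip(matrix.diseases, matrix.groups)
        if g in REFERENCE_GROUPS
    }


def _design(
    matrix: PhenotypeMatrix, labels: Mapping[str, int] | None, scale: bool
) -> tuple[list[str], np.ndarray, np.ndarray]:
    if labels is None:
        labels = labels_from_groups(matrix)
    names = [d for d in matrix.diseases if d in labels]
    if not names:
        raise ValidationError("no labelled reference diseases")
    y = np.array([labels[d] for d in names], dtype=float)
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValidationError("training requires both +1 and -1 labels")
    x = np.vstack([matrix.row(d) for d in names])
    if scale:
        x = x / 100.0
    return names, x, y


def train(
    matrix: PhenotypeMatrix,
    labels: Mapping[str, int] | None = None,
    *,
    epsilon: float = 0.1,
    cost: float = 1.0,
    filter_threshold: float | None = None,
    scale: bool = False,
) -> SvmModel:
    """Fit the linear eps-regression SVM on the reference diseases.

    ``labels`` defaults to +1/-1 from the group labels.  When
    ``filter_threshold`` is given, the cumulative-prevalence filter is
    applied first and the model's feature set is the filtered one.
    """
    if filter_threshold is not None:
        matrix = filter_parameters(matrix, filter_threshold)
    _names, x, y = _design(matrix, labels, scale)
    svr = SVR(kernel="linear", C=cost, epsilon=epsilon)
    svr.fit(x, y)
    return SvmModel(
        parameters=list(matrix.parameters),
        weights=svr.coef_.ravel(),
        bias=float(svr.intercept_[0]),
        filter_threshold=filter_threshold,
        epsilon=epsilon,
        cost=cost,
        scale=scale,
    )


def svm_score(model: SvmModel, test: DiseaseProfile) -> float:
    """Score a profile; parameters unknown to the model are ignored."""
    x = np.array([test.prevalences.get(p, 0.0) for p in model.parameters])
    if model.scale:
        x = x / 100.0
    return float(np.dot(model.weights, x) + model.bias)


def cross_validate(
    matrix: PhenotypeMatrix,
    labels: Mapping[str, int] | None = None,
    *,
    k: int = 11,
    epsilon: float = 0.1,
    cost: float = 1.0,
    filter_threshold: float | None = None,
    scale: bool = False,
    seed: int = 0,
    max_redraws: int = 5,
) -> CvReport:
    """k-fold cross-validation of the classifier on the reference diseases.

    Folds are stratified by label and shuffled with ``seed``, so the report
    is bit-for-bit reproducible for the same seed.  If a fold assignment
    nevertheless leaves a training split single-class, folds are redrawn
    (up to ``max_redraws``) before giving up.
    """
    if filter_threshold is not None:
        matrix = filter_parameters(matrix, filter_threshold)
    names, x, y = _design(matrix, labels, scale)
    n = len(names)
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, {n}], got {k}")
    # stratification requires k <= minority class size; beyond that
    # (e.g. leave-one-out) fall back to plain shuffled folds
    min_class = int(min(np.sum(y > 0), np.sum(y < 0)))
    fold_cls = StratifiedKFold if k <= min_class else KFold
    last_error: Exception | None = None
    for attempt in range(max_redraws + 1):
        skf = fold_cls(n_splits=k, shuffle=True, random_state=seed + attempt)
        fold_assignment: dict[str, int] = {}
        preds = np.empty(n)
        try:
            for fold, (tr, te) in enumerate(skf.split(x, y)):
                if not (np.any(y[tr] > 0) and np.any(y[tr] < 0)):
                    raise ValidationError(f"fold {fold}: single-class training split")
                svr = SVR(kernel="linear", C=cost, epsilon=epsilon)
                svr.fit(x[tr], y[tr])
                preds[te] = svr.predict(x[te])
                for i in te:
                    fold_assignment[names[i]] = fold
        except ValidationError as exc:
            last_error = exc
            continue
        mse = float(np.mean((preds - y) ** 2))
        correlation = float(pearsonr(preds, y).statistic)
        separation = float(100.0 * np.mean((preds > 0) == (y > 0)))
        return CvReport(
            k=k,
            fold_assignment=fold_assignment,
            mse=mse,
            correlation=correlation,
            separation=separation,
            predictions={names[i]: float(preds[i]) for i in range(n)},
        )
    raise ValidationError(f"could not draw valid folds: {last_error}")
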