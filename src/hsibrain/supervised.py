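"""Supervised SVM classification of labeled spectra and whole cubes.

Training consumes the gold-standard signature dataset; prediction produces
per-pixel class-probability maps (Platt-calibrated, pairwise-coupled —
the LIBSVM convention) that feed the spatial-spectral KNN filter.
Evaluation follows the one-vs-all confusion-matrix convention:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)

measured under stratified 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DimensionError, StratificationError, TrainingError
from .hsdata import CLASS_NAMES, HSCube, ProbabilityMap, SignatureDataset


@dataclass
class ConfusionMatrix:
    """One-vs-all counts for a single positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise DimensionError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class SvmModel:
    kernel: str
    classes_: np.ndarray
    svc: SVC
    n_bands: int
    params: dict = field(default_factory=dict)


def train_svm(dataset: SignatureDataset, kernel: str = "linear", C: float = 1.0,
              seed: int = 0, probability: bool = True, **kernel_params) -> SvmModel:
    """Fit a probability-calibrated SVM on the labeled spectra.

    The linear kernel is the default; RBF, polynomial and sigmoid are
    accepted.  C defaults to 1 with library-default kernel parameters.
    """
    y = dataset.class_ids
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise TrainingError("need at least 2 classes to train")
    if counts.min() < 2:
        raise TrainingError("need at least 2 samples per class")
    kmap = {"linear": "linear", "rbf": "rbf", "polynomial": "poly", "poly": "poly",
            "sigmoid": "sigmoid"}
    if kernel not in kmap:
        raise TrainingError(f"unknown kernel {kernel!r}")
    svc = SVC(kernel=kmap[kernel], C=C, probability=probability,
              random_state=seed, **kernel_params)
    import warnings as _w
    with _w.catch_warnings():
        # scikit-learn deprecates SVC(probability=True) in favour of external
        # calibration; the built-in pairwise-coupled Platt scaling is exactly
        # the LIBSVM behaviour this pipeline wants, so keep it while it exists
        _w.simplefilter("ignore", FutureWarning)
        svc.fit(dataset.spectra, y)
    return SvmModel(kernel=kernel, classes_=svc.classes_, svc=svc,
                    n_bands=dataset.spectra.shape[1],
                    params={"C": C, "seed": seed, **kernel_params})


def predict_proba_cube(model: SvmModel, cube: HSCube,
                       class_order: tuple = (1, 2, 3, 4)) -> ProbabilityMap:
    """Per-pixel class probabilities over the fixed class order.

    Classes absent from training get probability 0 so downstream maps keep
    a consistent C-length vector.
    """
    H, W, B = cube.shape
    if B != model.n_bands:
        raise DimensionError(f"cube has {B} bands, model trained on {model.n_bands}")
    raw = model.svc.predict_proba(cube.pixels())
    probs = np.zeros((H * W, len(class_order)))
    for j, cid in enumerate(model.classes_):
        probs[:, class_order.index(int(cid))] = raw[:, j]
    probs /= probs.sum(axis=1, keepdims=True)
    return ProbabilityMap(probs.reshape(H, W, len(class_order)), class_order=class_order)


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Sensitivity, specificity and accuracy; undefined ratios (zero
    denominator) are flagged as None rather than raising."""
    def ratio(num, den):
        return num / den if den > 0 else None
    return {"sensitivity": ratio(cm.TP, cm.TP + cm.FN),
            "specificity": ratio(cm.TN, cm.TN + cm.FP),
            "accuracy": ratio(cm.TP + cm.TN, cm.total)}


def confusion_one_vs_all(y_true: np.ndarray, y_pred: np.ndarray,
                         positive: int) -> ConfusionMatrix:
    """Collapse a multi-class outcome into one-vs-all counts for *positive*."""
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return ConfusionMatrix(TP=int(np.sum(t & p)), FP=int(np.sum(~t & p)),
                           TN=int(np.sum(~t & ~p)), FN=int(np.sum(t & ~p)))


def cross_validate(dataset: SignatureDataset, kernel: str = "linear",
                   n_folds: int = 10, C: float = 1.0, seed: int = 0) -> dict:
    """Stratified k-fold cross-validation with per-class one-vs-all metrics.

    Returns overall accuracy, a per-class metrics table, the pooled
    multi-class confusion table, and the fold assignment (deterministic
    under *seed*).  Fold scoring uses hard decisions; probability
    calibration is only needed for per-cube maps.
    """
    y = dataset.class_ids
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise StratificationError(
            f"smallest class has {counts.min()} samples < {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.zeros_like(y)
    fold_of = np.zeros(len(y), dtype=np.int32)
    for f, (tr, te) in enumerate(skf.split(dataset.spectra, y)):
        model = train_svm(
            SignatureDataset(dataset.patient_ids[tr], y[tr], dataset.spectra[tr]),
            kernel=kernel, C=C, seed=seed, probability=False)
        y_pred[te] = model.svc.predict(dataset.spectra[te])
        fold_of[te] = f
    overall = float(np.mean(y_pred == y))
    rows = []
    cms = {}
    for cid in classes:
        cm = confusion_one_vs_all(y, y_pred, int(cid))
        cms[int(cid)] = cm
        m = compute_metrics(cm)
        rows.append({"class_id": int(cid),
                     "class": CLASS_NAMES.get(int(cid), str(cid)), **m})
    confusion = pd.crosstab(pd.Series(y, name="true"), pd.Series(y_pred, name="pred"))
    return {"overall_accuracy": overall,
            "per_class": pd.DataFrame(rows),
            "confusion_matrices": cms,
            "confusion_table": confusion,
            "fold_assignment": fold_of,
            "kernel": kernel}


def compare_kernels(dataset: SignatureDataset, kernels=("linear", "rbf", "polynomial",
                                                        "sigmoid"),
                    n_folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Cross-validated overall accuracy per kernel, one row per kernel."""
    rows = [{"kernel": k,
             "overall_accuracy": cross_validate(dataset, kernel=k, n_folds=n_folds,
                                                seed=seed)["overall_accuracy"]}
            for k in kernels]
    return pd.DataFrame(rows)
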