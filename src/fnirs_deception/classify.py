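"""Per-subject multi-class SVM classification of question responses.

The four raw response classes are remapped before classification: the
selection criteria cannot discriminate non-induced truths from non-induced
lies, so the standard problem is tri-class (induced lie IL, induced truth IT,
non-induced NI); a coarser bi-class problem (induced vs non-induced) is also
provided.

Evaluation is per-subject stratified k-fold cross-validation (default 10
folds over 30 questions) with an RBF-kernel SVM.  A (C, gamma) grid search on
the canonical log2 grid is nested inside each training fold, and features are
standardized with training-fold statistics only, so no test information leaks
into model selection.  The report aggregates out-of-fold predictions into a
confusion matrix and one-vs-rest specificity / sensitivity / accuracy per
class:

    specificity = TN / (FP + TN)
    sensitivity = TP / (TP + FN)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .epochs import QuestionFeatures

__all__ = [
    "LabelRemap",
    "ClassificationReport",
    "tri_class",
    "bi_class",
    "build_design",
    "cross_validate_svm",
    "confusion_metrics",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "COARSE_C_GRID",
    "COARSE_GAMMA_GRID",
]

logger = logging.getLogger(__name__)

#: Canonical log2 search grids of the LIBSVM practical guide.
DEFAULT_C_GRID: np.ndarray = 2.0 ** np.arange(-5, 16, 2)
DEFAULT_GAMMA_GRID: np.ndarray = 2.0 ** np.arange(-15, 4, 2)

#: Reduced grids for Monte-Carlo studies where many CV runs are repeated.
COARSE_C_GRID: np.ndarray = 2.0 ** np.array([-1.0, 3.0, 7.0])
COARSE_GAMMA_GRID: np.ndarray = 2.0 ** np.array([-7.0, -3.0, 1.0])


@dataclass(frozen=True)
class LabelRemap:
    """Total, surjective map from raw classes m in {1,2,3,4} to problem classes."""

    mapping: dict[int, str]
    problem: str

    def __post_init__(self) -> None:
        if set(self.mapping) != {1, 2, 3, 4}:
            raise ValueError("mapping must cover raw classes 1..4")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def __call__(self, labels: np.ndarray) -> np.ndarray:
        return np.array([self.mapping[int(m)] for m in labels])


def tri_class() -> LabelRemap:
    """IL / IT / Non-Induced (m=3 and m=4 merged)."""
    return LabelRemap({1: "IL", 2: "IT", 3: "NI", 4: "NI"}, problem="tri")


def bi_class() -> LabelRemap:
    """Induced (m=1,2) vs Non-Induced (m=3,4)."""
    return LabelRemap({1: "IND", 2: "IND", 3: "NI", 4: "NI"}, problem="bi")


@dataclass
class ClassificationReport:
    """Cross-validated per-subject results."""

    subject_id: str
    problem: str
    classes: list[str]
    confusion: np.ndarray  # rows = true, cols = predicted
    per_class: dict[str, dict[str, float | None]]
    overall_accuracy: float
    cv_scheme: str
    feature_set: str

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "problem": self.problem,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "cv_scheme": self.cv_scheme,
            "feature_set": self.feature_set,
        }


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(
    qf: QuestionFeatures,
    mask_flags: np.ndarray,
    remap: LabelRemap,
    include_oxygenation: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (questions x selected voxels) and remapped labels.

    Columns are the blood-volume question means of the selected voxels; the
    oxygenation means can be appended by flag (the default follows the
    finding that only blood volume carries relevant class differences).
    """
    flags = np.asarray(mask_flags, dtype=bool)
    if flags.size != qf.n_voxels:
        raise ValueError("mask length does not match voxel count")
    if not flags.any():
        raise ValueError("empty voxel mask: no features to build")
    X = qf.mean_dB[:, flags]
    if include_oxygenation:
        X = np.hstack([X, qf.mean_dO[:, flags]])
    if not np.isfinite(X).all():
        q = int(np.nonzero(~np.isfinite(X))[0][0])
        raise ValueError(f"question {qf.question_ids[q]} has a missing voxel mean")
    return X, remap(qf.class_labels)


# ---------------------------------------------------------------------------
# cross-validated SVM
# ---------------------------------------------------------------------------

def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: np.ndarray,
    gamma_grid: np.ndarray,
    inner_folds: int,
    seed: int,
) -> tuple[float, float]:
    """Pick (C, gamma) by inner stratified CV accuracy; ties keep grid order."""
    _, counts = np.unique(y, return_counts=True)
    k = int(min(inner_folds, counts.min()))
    if k < 2:
        return float(C_grid[0]), float(gamma_grid[0])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = (-1.0, C_grid[0], gamma_grid[0])
    for C in C_grid:
        for gamma in gamma_grid:
            hits = 0
            for tr, te in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                hits += int((clf.predict(X[te]) == y[te]).sum())
            acc = hits / len(y)
            if acc > best[0]:
                best = (acc, C, gamma)
    return float(best[1]), float(best[2])


def cross_validate_svm(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    C_grid: np.ndarray = DEFAULT_C_GRID,
    gamma_grid: np.ndarray = DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
    subject_id: str = "",
    feature_set: str = "",
    problem: str = "",
    return_fold_details: bool = False,
):
    """Stratified k-fold CV with a nested (C, gamma) search per training fold.

    Every question is predicted exactly once, out of fold; standardization
    statistics come from the training fold only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to classify")
    folds_eff = int(min(folds, counts.min()))
    if folds_eff < folds:
        logger.info(
            "reducing folds from %d to %d (smallest class has %d members)",
            folds, folds_eff, counts.min(),
        )
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=y.dtype)
    seen = np.zeros(y.shape, dtype=bool)
    fold_details = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        Xtr = scaler.transform(X[tr])
        C, gamma = _grid_search(
            Xtr, y[tr], C_grid, gamma_grid, inner_folds, seed + 1 + i
        )
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(Xtr, y[tr])
        pred[te] = clf.predict(scaler.transform(X[te]))
        seen[te] = True
        fold_details.append(
            {
                "train": tr,
                "test": te,
                "scaler_mean": scaler.mean_.copy(),
                "scaler_scale": scaler.scale_.copy(),
                "C": C,
                "gamma": gamma,
            }
        )
    assert seen.all(), "out-of-fold predictions must cover every question once"

    K = classes.size
    lut = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((K, K), dtype=int)
    for t, p in zip(y, pred):
        confusion[lut[t], lut[p]] += 1

    per_class = {
        str(c): confusion_metrics(confusion, i) for i, c in enumerate(classes)
    }
    report = ClassificationReport(
        subject_id=subject_id,
        problem=problem,
        classes=[str(c) for c in classes],
        confusion=confusion,
        per_class=per_class,
        overall_accuracy=float(np.trace(confusion) / confusion.sum()),
        cv_scheme=f"stratified {folds_eff}-fold, seed {seed}, "
        f"nested {inner_folds}-fold (C, gamma) grid search",
        feature_set=feature_set,
    )
    if return_fold_details:
        return report, fold_details
    return report


def confusion_metrics(confusion: np.ndarray, k: int) -> dict[str, float | None]:
    """One-vs-rest specificity / sensitivity / accuracy for class index ``k``.

    Ratios with a zero denominator are reported as ``None`` (absent), not 0.
    """
    confusion = np.asarray(confusion)
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = int(confusion[k, k])
    fn = int(confusion[k].sum() - tp)
    fp = int(confusion[:, k].sum() - tp)
    tn = total - tp - fn - fp

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return {
        "specificity": ratio(tn, fp + tn),
        "sensitivity": ratio(tp, tp + fn),
        "accuracy": ratio(tp + tn, total),
    }
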