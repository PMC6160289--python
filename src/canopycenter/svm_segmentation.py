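"""Local segmentation of the canopy central region with a linear SVM.

After the global HLS mask isolates green vegetation, a soft-margin linear
SVM trained on per-pixel (H, L, S) feature triples separates the canopy
central region (ROI, label +1) from the surrounding vegetation (N-ROI,
label −1).  The decision function is f(x) = Σ aᵢ yᵢ (xᵢ·x) + b, i.e. a
hyperplane w·x + b in the 3-dimensional color space; pixels with f(x) ≥ 0
are assigned to the ROI.

Features are the raw HLS triples, deliberately unscaled: the penalty
C = 0.1 was selected on that scale and rescaling the features would change
its meaning.  A kernel-width parameter ``gamma`` is accepted in the config
for interface completeness but has no effect on a linear kernel.

Model selection utilities mirror the usual workflow: a stratified k-fold
sweep over the penalty grid (``cross_validate_C``), a learning curve over
training-set sizes, and ROC/AUC scoring with vertical mean-ROC averaging
across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .imaging_core import BinaryMask, HlsImage

__all__ = [
    "PixelSample",
    "TrainingSet",
    "LinearSvmModel",
    "SvmConfig",
    "sample_training_pixels",
    "fit_linear_svm",
    "predict_mask",
    "cross_validate_C",
    "learning_curve",
    "roc_auc",
    "mean_roc",
    "save_model",
    "load_model",
]

ROI_LABEL = 1
NROI_LABEL = -1


@dataclass(frozen=True)
class PixelSample:
    """One training pixel: (H, L, S) features plus a ±1 class label."""

    features: np.ndarray  # shape (3,)
    label: int

    def __post_init__(self) -> None:
        if self.label not in (ROI_LABEL, NROI_LABEL):
            raise ValueError("PixelSample: label must be +1 or -1")


@dataclass(frozen=True, eq=False)
class TrainingSet:
    """A labeled pixel sample: features (n, 3), labels (n,) in {+1, −1}."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64)
        if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] != y.shape[0]:
            raise ValueError("TrainingSet: features must be (n, 3) aligned with labels")
        if X.shape[0] < 2:
            raise ValueError("TrainingSet: need at least 2 samples")
        if not np.isin(y, (ROI_LABEL, NROI_LABEL)).all():
            raise ValueError("TrainingSet: labels must be +1 or -1")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def samples(self) -> list:
        return [PixelSample(f, int(l)) for f, l in zip(self.features, self.labels)]


@dataclass
class SvmConfig:
    """Classifier settings.

    C is the soft-margin penalty (default 0.1, the plateau onset of the
    cross-validation score curve); the kernel is fixed linear.  ``gamma``
    is accepted but ignored by the linear kernel.  ``sample_size`` is the
    total training-pixel budget, split evenly between classes.
    """

    C: float = 0.1
    kernel: str = "linear"
    cv_folds: int = 4
    sample_size: int = 100
    gamma: Union[str, float] = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("SvmConfig: C must be positive")
        if self.kernel != "linear":
            raise ValueError("SvmConfig: only the linear kernel is supported")
        if self.cv_folds < 2:
            raise ValueError("SvmConfig: cv_folds must be >= 2")


@dataclass(frozen=True, eq=False)
class LinearSvmModel:
    """A fitted hyperplane w·x + b over (H, L, S) features."""

    w: np.ndarray
    b: float
    C: float
    n_support: int = 0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        """±1 labels; the boundary itself (f = 0) is assigned to the ROI."""
        return np.where(self.decision_function(X) >= 0, ROI_LABEL, NROI_LABEL)


def sample_training_pixels(
    veg: HlsImage,
    roi_truth: BinaryMask,
    nroi_truth: BinaryMask,
    n: int = 100,
    seed: int = 0,
) -> TrainingSet:
    """Draw n/2 ROI and n/2 N-ROI pixels uniformly without replacement.

    The truth masks play the role of the manually selected candidate
    regions used to label training pixels; they must be disjoint.
    """
    if roi_truth.shape != veg.shape[:2] or nroi_truth.shape != veg.shape[:2]:
        raise ValueError("sample_training_pixels: mask shapes must match the image")
    if (roi_truth.pixels & nroi_truth.pixels).any():
        raise ValueError("sample_training_pixels: truth masks overlap")
    k_pos = n // 2
    k_neg = n - k_pos
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for mask, k, lab, name in (
        (roi_truth, k_pos, ROI_LABEL, "ROI"),
        (nroi_truth, k_neg, NROI_LABEL, "N-ROI"),
    ):
        coords = np.argwhere(mask.pixels == 1)
        if len(coords) < k:
            raise ValueError(
                f"sample_training_pixels: {name} region has {len(coords)} pixels, need {k}"
            )
        idx = rng.choice(len(coords), size=k, replace=False)
        ys, xs = coords[idx, 0], coords[idx, 1]
        feats.append(veg.pixels[ys, xs].astype(np.float64))
        labels.append(np.full(k, lab, dtype=np.int64))
    return TrainingSet(np.concatenate(feats), np.concatenate(labels))


def fit_linear_svm(train: TrainingSet, cfg: SvmConfig = SvmConfig()) -> LinearSvmModel:
    """Fit the soft-margin linear SVM (hinge loss, penalty C) in dual form."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("fit_linear_svm: training set contains a single class")
    clf = SVC(kernel="linear", C=cfg.C)
    clf.fit(train.features, train.labels)
    return LinearSvmModel(
        w=clf.coef_[0].astype(np.float64),
        b=float(clf.intercept_[0]),
        C=cfg.C,
        n_support=int(clf.n_support_.sum()),
    )


def predict_mask(model: LinearSvmModel, veg: HlsImage, domain: BinaryMask) -> BinaryMask:
    """Classify every domain pixel; +1 (ROI) → 1, −1 → 0, outside domain → 0."""
    if model is None or model.w is None:
        raise ValueError("predict_mask: model is not trained")
    if domain.shape != veg.shape[:2]:
        raise ValueError("predict_mask: domain shape must match the image")
    out = np.zeros(domain.shape, dtype=np.uint8)
    sel = domain.pixels == 1
    if sel.any():
        X = veg.pixels[sel].astype(np.float64)
        out[sel] = (model.decision_function(X) >= 0).astype(np.uint8)
    return BinaryMask(out)


def _fold_scores(X, y, C: float, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    train_scores, val_scores = [], []
    for tr, va in skf.split(X, y):
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[tr], y[tr])
        train_scores.append(clf.score(X[tr], y[tr]))
        val_scores.append(clf.score(X[va], y[va]))
    return np.array(train_scores), np.array(val_scores)


@dataclass(frozen=True)
class CvPoint:
    C: float
    mean_score: float
    var_score: float


def cross_validate_C(
    train: TrainingSet,
    grid: Sequence[float],
    folds: int = 4,
    seed: int = 0,
) -> tuple:
    """Stratified k-fold accuracy for each penalty on the grid.

    Returns ``(best_C, points)``.  The best penalty is the smallest grid
    value whose mean score is within 1e−6 of the maximum — the onset of
    the score plateau, matching the convention of picking the knee of the
    C curve rather than its (flat) maximum.
    """
    if len(grid) == 0:
        raise ValueError("cross_validate_C: empty grid")
    class_min = min(np.sum(train.labels == ROI_LABEL), np.sum(train.labels == NROI_LABEL))
    if folds > class_min:
        raise ValueError("cross_validate_C: folds exceed the minority-class count")
    points = []
    for C in grid:
        _, val = _fold_scores(train.features, train.labels, C, folds, seed)
        points.append(CvPoint(C=float(C), mean_score=float(val.mean()), var_score=float(val.var())))
    best_mean = max(p.mean_score for p in points)
    best = min((p.C for p in points if p.mean_score >= best_mean - 1e-6))
    return best, points


@dataclass(frozen=True)
class LearningPoint:
    size: int
    train_score: float
    val_score: float
    val_var: float


def learning_curve(
    train_pool: TrainingSet,
    sizes: Sequence[int],
    folds: int = 4,
    cfg: SvmConfig = SvmConfig(),
    seed: int = 0,
) -> list:
    """Cross-validated score trajectory over training-set sizes.

    For each size a stratified subsample of the pool is drawn and k-fold
    cross-validated; validation score should rise and its variance shrink
    as the sample grows.
    """
    rng = np.random.default_rng(seed)
    out = []
    y = train_pool.labels
    for size in sizes:
        if size > train_pool.n:
            raise ValueError(f"learning_curve: size {size} exceeds pool size {train_pool.n}")
        if size == train_pool.n:
            idx = np.arange(train_pool.n)
        else:
            # stratified subsample: proportional share of each class
            idx_parts = []
            for lab in (ROI_LABEL, NROI_LABEL):
                lab_idx = np.flatnonzero(y == lab)
                k = max(folds, int(round(size * len(lab_idx) / train_pool.n)))
                k = min(k, len(lab_idx))
                idx_parts.append(rng.choice(lab_idx, size=k, replace=False))
            idx = np.concatenate(idx_parts)
        X_sub, y_sub = train_pool.features[idx], y[idx]
        tr, va = _fold_scores(X_sub, y_sub, cfg.C, folds, seed)
        out.append(
            LearningPoint(
                size=int(len(idx)),
                train_score=float(tr.mean()),
                val_score=float(va.mean()),
                val_var=float(va.var()),
            )
        )
    return out


@dataclass(frozen=True, eq=False)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve by threshold sweep and AUC by the trapezoidal rule."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc: need both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc)


def mean_roc(
    fold_scores: Sequence[Sequence[float]],
    fold_labels: Sequence[Sequence[int]],
    grid_points: int = 101,
) -> RocResult:
    """Vertical-average ROC across folds on a common FPR grid."""
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = []
    for s, y in zip(fold_scores, fold_labels):
        r = roc_auc(s, y)
        tpr = np.interp(grid, r.fpr, r.tpr)
        tpr[0] = 0.0
        tprs.append(tpr)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return RocResult(fpr=grid, tpr=mean_tpr, auc=float(np.trapezoid(mean_tpr, grid)))


# ---------------------------------------------------------------------------
# Persistence: a small key=value text format
# ---------------------------------------------------------------------------

def save_model(model: LinearSvmModel, path: Union[str, Path]) -> None:
    lines = [
        "format=canopycenter-linear-svm-v1",
        "features=H,L,S",
        "hue_scale=180",
        f"w={','.join(repr(float(v)) for v in model.w)}",
        f"b={model.b!r}",
        f"C={model.C!r}",
        f"n_support={model.n_support}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: Union[str, Path]) -> LinearSvmModel:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    if kv.get("format") != "canopycenter-linear-svm-v1":
        raise ValueError(f"load_model: unrecognized model file {path}")
    w = np.array([float(v) for v in kv["w"].split(",")])
    return LinearSvmModel(w=w, b=float(kv["b"]), C=float(kv["C"]), n_support=int(kv.get("n_support", 0)))
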