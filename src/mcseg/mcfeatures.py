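"""Morphology features of segmented MCs and malignancy classification.

Given a fixed-size 256x256 region of interest (ROI) and its MC segmentation
mask, 31 features are computed: 17 regional features describing all MCs in
the ROI as one region (foreground area, convex-hull area, ellipse major and
minor axis lengths, orientation of the major axis, eccentricity, solidity,
the two eigenvalues of the central second-moment tensor, the seven Hu
invariant moments, and the MC count), plus 14 aggregated per-object
features (mean and standard deviation over 8-connected components of area,
major axis, minor axis, maximum/minimum/mean intensity, and eccentricity).

ROIs with empty segmentations produce all-missing vectors; downstream the
classifier pipeline imputes by training-fold means and standardizes before
gradient tree boosting, evaluated with patient-wise fivefold
cross-validation and reported at an operating threshold chosen for
sensitivity close to 0.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ROI",
    "FEATURE_NAMES",
    "extract_roi",
    "compute_features",
    "crossval_classify",
    "roc_report",
]

ROI_SIZE = 256

_REGIONAL = [
    "area",
    "convex_area",
    "major_axis_length",
    "minor_axis_length",
    "orientation_deg",
    "eccentricity",
    "solidity",
    "inertia_moment_1",
    "inertia_moment_2",
    *[f"hu_moment_{i + 1}" for i in range(7)],
    "mc_count",
]
_PER_OBJECT = ["area", "major_axis_length", "minor_axis_length",
               "max_intensity", "min_intensity", "mean_intensity", "eccentricity"]
FEATURE_NAMES: tuple[str, ...] = tuple(
    _REGIONAL
    + [f"obj_{name}_mean" for name in _PER_OBJECT]
    + [f"obj_{name}_std" for name in _PER_OBJECT]
)
assert len(FEATURE_NAMES) == 31


@dataclass(frozen=True)
class ROI:
    """A fixed-size region of interest with its segmentation crop."""

    image: np.ndarray
    mask: np.ndarray
    center: tuple[int, int]
    label: int | None = None      # 0 benign, 1 malignant
    patient_id: str = ""
    padded: bool = False

    def __post_init__(self) -> None:
        if self.image.shape != (ROI_SIZE, ROI_SIZE) or self.mask.shape != (ROI_SIZE, ROI_SIZE):
            raise ValueError(f"ROI crops must be {ROI_SIZE}x{ROI_SIZE}")


def extract_roi(
    image: np.ndarray,
    mask: np.ndarray,
    bbox: tuple[int, int, int, int],
    size: int = ROI_SIZE,
    label: int | None = None,
    patient_id: str = "",
) -> ROI:
    """Crop a size x size window centered on the bounding box center.

    ``bbox`` is (min_row, min_col, max_row, max_col), exclusive max. A
    window that would cross the image border is shifted minimally to fit;
    images smaller than the window are reflect-padded first (and flagged).
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    padded = False
    pad_r = max(0, size - image.shape[0])
    pad_c = max(0, size - image.shape[1])
    if pad_r or pad_c:
        image = np.pad(image, ((0, pad_r), (0, pad_c)), mode="reflect")
        mask = np.pad(mask, ((0, pad_r), (0, pad_c)), mode="reflect")
        padded = True
    cr = (bbox[0] + bbox[2]) // 2
    cc = (bbox[1] + bbox[3]) // 2
    r0 = min(max(cr - size // 2, 0), image.shape[0] - size)
    c0 = min(max(cc - size // 2, 0), image.shape[1] - size)
    return ROI(
        image=image[r0 : r0 + size, c0 : c0 + size].copy(),
        mask=mask[r0 : r0 + size, c0 : c0 + size].copy(),
        center=(cr, cc),
        label=label,
        patient_id=patient_id,
        padded=padded,
    )


def compute_features(roi: ROI) -> pd.Series:
    """The 31-dimensional feature vector of one ROI.

    Regional shape descriptors are measured on the union mask treated as a
    single (possibly disconnected) region; per-object statistics aggregate
    over 8-connected components with the std of a single object defined as
    0. An empty mask yields a vector of NaNs for downstream imputation.
    """
    mask = roi.mask
    values = pd.Series(np.nan, index=list(FEATURE_NAMES), dtype=float)
    if not mask.any():
        return values

    union = measure.regionprops(mask.astype(np.uint8))[0]
    hull_area = union.area_convex
    inertia = union.inertia_tensor_eigvals
    values["area"] = float(union.area)
    values["convex_area"] = float(hull_area)
    values["major_axis_length"] = float(union.axis_major_length)
    values["minor_axis_length"] = float(union.axis_minor_length)
    # skimage orientation: angle from the row axis, in (-pi/2, pi/2]
    values["orientation_deg"] = math.degrees(float(union.orientation))
    values["eccentricity"] = float(union.eccentricity)
    values["solidity"] = float(union.solidity)
    values["inertia_moment_1"] = float(inertia[0])
    values["inertia_moment_2"] = float(inertia[1])
    for i, hu in enumerate(union.moments_hu):
        values[f"hu_moment_{i + 1}"] = float(hu)

    labels, n_obj = ndi.label(mask, structure=np.ones((3, 3), bool))
    values["mc_count"] = float(n_obj)
    props = measure.regionprops(labels, intensity_image=roi.image)
    per_obj = {
        "area": [float(p.area) for p in props],
        "major_axis_length": [float(p.axis_major_length) for p in props],
        "minor_axis_length": [float(p.axis_minor_length) for p in props],
        "max_intensity": [float(p.intensity_max) for p in props],
        "min_intensity": [float(p.intensity_min) for p in props],
        "mean_intensity": [float(p.intensity_mean) for p in props],
        "eccentricity": [float(p.eccentricity) for p in props],
    }
    for name, vals in per_obj.items():
        values[f"obj_{name}_mean"] = float(np.mean(vals))
        values[f"obj_{name}_std"] = float(np.std(vals))  # single object -> 0
    return values


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    scores: np.ndarray
    labels: np.ndarray


def crossval_classify(
    features: pd.DataFrame,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 3,
    learning_rate: float = 0.1,
) -> list[FoldResult]:
    """Patient-wise cross-validated gradient tree boosting.

    Folds are patient-disjoint. Within each fold, mean imputation and
    standardization are fit on the training rows only and applied to both
    subsets before fitting the booster; test-fold scores and labels are
    returned for ROC analysis.
    """
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float) \
        if all(c in features.columns for c in FEATURE_NAMES) else features.to_numpy(dtype=float)
    results: list[FoldResult] = []
    splitter = GroupKFold(n_splits=folds)
    for train_idx, test_idx in splitter.split(X, labels, groups=patient_ids):
        y_train, y_test = labels[train_idx], labels[test_idx]
        if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
            raise ValueError(
                "a cross-validation fold contains a single class; "
                "use more patients or fewer folds"
            )
        imputer = SimpleImputer(strategy="mean")
        scaler = StandardScaler()
        X_train = scaler.fit_transform(imputer.fit_transform(X[train_idx]))
        X_test = scaler.transform(imputer.transform(X[test_idx]))
        clf = GradientBoostingClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
            random_state=seed,
        )
        clf.fit(X_train, y_train)
        scores = clf.predict_proba(X_test)[:, 1]
        results.append(FoldResult(scores=scores, labels=y_test))
    return results


def _metrics_at_threshold(scores, labels, thr):
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(labels)
    ppv = tp / (tp + fp) if tp + fp else 0.0
    return acc, sens, spec, ppv


def roc_report(fold_results: list[FoldResult], sensitivity_target: float = 0.9) -> pd.DataFrame:
    """Per-fold ROC metrics at a high-sensitivity operating threshold.

    For each fold the threshold is the observed score whose sensitivity is
    closest to the target (ties toward the higher threshold); the table
    reports mean and standard deviation across folds of ROC AUC, accuracy,
    sensitivity, specificity, and PPV.
    """
    rows = {m: [] for m in ("roc_auc", "accuracy", "sensitivity", "specificity", "ppv")}
    for fold in fold_results:
        scores, labels = fold.scores, np.asarray(fold.labels)
        if len(np.unique(scores)) == 1:
            auc = 0.5  # constant scores rank nothing: tie convention
        else:
            auc = float(roc_auc_score(labels, scores))
        cand = np.unique(scores)[::-1]
        sens = np.array([_metrics_at_threshold(scores, labels, t)[1] for t in cand])
        best = np.flatnonzero(np.abs(sens - sensitivity_target)
                              == np.abs(sens - sensitivity_target).min())
        thr = float(cand[best.min()])  # cand is descending: min index = highest thr
        acc, sen, spe, ppv = _metrics_at_threshold(scores, labels, thr)
        rows["roc_auc"].append(auc)
        rows["accuracy"].append(acc)
        rows["sensitivity"].append(sen)
        rows["specificity"].append(spe)
        rows["ppv"].append(ppv)
    return pd.DataFrame(
        {
            "mean": {m: float(np.mean(v)) for m, v in rows.items()},
            "std": {m: float(np.std(v)) for m, v in rows.items()},
        }
    )
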