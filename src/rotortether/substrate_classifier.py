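"""Substrate classification: does the local tissue support rotor tethering?

Per-node features (CV_max, APD_max, optionally the case's atrial surface
area) are labelled by the tethering mask and fed to a support vector
machine.  Tethering tissue is rare (well under a percent of nodes at
clinical scale), so the pipeline standardizes on the training split only,
weights classes inversely to frequency, and reports balanced accuracy next
to plain accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, GroupShuffleSplit, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FEATURES_2 = ["cv_max", "apd_max"]
FEATURES_3 = ["cv_max", "apd_max", "surface_cm2"]


def build_feature_table(cases, masks=None, include_surface: bool = False) -> pd.DataFrame:
    """One row per (case, node) with features and the tethering label.

    ``cases`` is a list of CohortCase (or (domain, fields, record, mask)
    tuples); ``masks`` optionally overrides the per-case label arrays, e.g.
    with masks derived from simulated PS density maps.
    """
    rows = []
    for k, case in enumerate(cases):
        domain, fields, record = case.domain, case.fields, case.record
        mask = masks[k] if masks is not None else case.true_mask
        if mask is None:
            raise ValueError(
                f"case {record.case_id} has no tethering mask")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != domain.n_nodes:
            raise ValueError(
                f"case {record.case_id}: mask and domain disagree on node count")
        df = pd.DataFrame({
            "case_id": record.case_id,
            "node_id": np.arange(domain.n_nodes),
            "cv_max": fields.cv_max,
            "apd_max": fields.apd_max,
            "label": np.where(mask, "tethering", "normal"),
        })
        if include_surface:
            df["surface_cm2"] = record.surface_cm2
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


@dataclass
class ClassifierReport:
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: tuple            # (tn, fp, fn, tp)
    features: list
    split: str
    seed: int
    n_train: int = 0
    n_test: int = 0
    noise_fraction: float = 0.0

    def __post_init__(self):
        for name in ("accuracy", "balanced_accuracy", "sensitivity",
                     "specificity", "f1"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} = {val} outside [0, 1]")

    def as_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self).items()}


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int) -> dict:
    total = tn + fp + fn + tp
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": (tp + tn) / total if total else 0.0,
        "balanced_accuracy": 0.5 * (sens + spec),
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
    }


@dataclass
class FittedClassifier:
    pipeline: Pipeline
    features: list
    train_mean: np.ndarray
    train_sd: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    report: ClassifierReport


def _evaluate(pipeline, X_test, y_test, features, split, seed, n_train,
              noise_fraction=0.0) -> ClassifierReport:
    pred = pipeline.predict(X_test)
    tn, fp, fn, tp = confusion_matrix(y_test, pred, labels=[0, 1]).ravel()
    m = metrics_from_confusion(tn, fp, fn, tp)
    return ClassifierReport(
        **m, confusion=(int(tn), int(fp), int(fn), int(tp)),
        features=list(features), split=split, seed=seed,
        n_train=n_train, n_test=len(y_test), noise_fraction=noise_fraction)


def train_svm(
    table: pd.DataFrame,
    include_surface: bool | None = None,
    C: float = 10.0,
    gamma="scale",
    kernel: str = "rbf",
    grid: dict | None = None,
    split: str = "stratified",
    test_size: float = 0.3,
    subsample_negatives: float | None = 20.0,
    max_rows: int | None = 40000,
    seed: int = 0,
) -> FittedClassifier:
    """Train and evaluate the tethering SVM.

    Features are standardized on the training split only; classes are
    weighted inversely to their frequency (the tethering class is rare).
    ``split`` is "stratified" (point-wise 70/30) or "grouped"
    (leave-cases-out by case_id).  Negative-class subsampling (default cap
    at 20 negatives per positive) and a total row cap keep the kernel SVM
    tractable; an optional (C, gamma) grid is searched by 3-fold
    cross-validation on the training split.
    """
    if include_surface is None:
        include_surface = "surface_cm2" in table.columns
    feats = FEATURES_3 if include_surface else FEATURES_2
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = table[feats].to_numpy(dtype=float)
    y = (table["label"] == "tethering").to_numpy(dtype=int)
    rng = np.random.default_rng(seed)

    if split == "grouped":
        gss = GroupShuffleSplit(n_splits=1, test_size=test_size,
                                random_state=int(rng.integers(2**31)))
        tr, te = next(gss.split(X, y, groups=table["case_id"].to_numpy()))
    elif split == "stratified":
        tr, te = train_test_split(
            np.arange(len(y)), test_size=test_size, stratify=y,
            random_state=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown split scheme {split!r}")

    for cls, name in ((1, "tethering"), (0, "normal")):
        if not np.any(y[tr] == cls):
            raise ValueError(f"training split contains no '{name}' examples")

    # tractability: cap the negative:positive ratio, then the total rows
    pos = tr[y[tr] == 1]
    neg = tr[y[tr] == 0]
    if subsample_negatives is not None and len(neg) > subsample_negatives * len(pos):
        neg = rng.choice(neg, size=int(subsample_negatives * len(pos)),
                         replace=False)
    tr_used = np.concatenate([pos, neg])
    if max_rows is not None and len(tr_used) > max_rows:
        keep_pos = pos if len(pos) <= max_rows // 2 else rng.choice(
            pos, size=max_rows // 2, replace=False)
        keep_neg = rng.choice(neg, size=max_rows - len(keep_pos), replace=False)
        tr_used = np.concatenate([keep_pos, keep_neg])
    tr_used = np.sort(tr_used)

    base = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=kernel, C=C, gamma=gamma, class_weight="balanced",
                    random_state=int(rng.integers(2**31)))),
    ])
    if grid:
        search = GridSearchCV(base, {f"svm__{k}": v for k, v in grid.items()},
                              cv=3, scoring="balanced_accuracy", n_jobs=1)
        search.fit(X[tr_used], y[tr_used])
        pipeline = search.best_estimator_
    else:
        pipeline = base
        pipeline.fit(X[tr_used], y[tr_used])

    scaler: StandardScaler = pipeline.named_steps["scale"]
    report = _evaluate(pipeline, X[te], y[te], feats, split, seed, len(tr_used))
    return FittedClassifier(
        pipeline=pipeline, features=feats,
        train_mean=scaler.mean_.copy(), train_sd=scaler.scale_.copy(),
        X_test=X[te], y_test=y[te], report=report)


def noise_robustness(fitted: FittedClassifier, noise_fraction: float,
                     seed: int = 0) -> ClassifierReport:
    """Re-evaluate on the held-out split after adding zero-mean Gaussian
    noise with SD = ``noise_fraction`` x the per-feature training SD.

    The clean report is untouched; fraction 0 reproduces it exactly.
    """
    if noise_fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    rng = np.random.default_rng(seed)
    X = fitted.X_test.copy()
    if noise_fraction > 0:
        X = X + rng.normal(0.0, noise_fraction * fitted.train_sd,
                           size=X.shape)
    rep = _evaluate(fitted.pipeline, X, fitted.y_test, fitted.features,
                    fitted.report.split, seed, fitted.report.n_train,
                    noise_fraction=noise_fraction)
    return rep


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------

def group_parameter_stats(table: pd.DataFrame, group_col: str = "label",
                          parameters=("cv_max", "apd_max")) -> pd.DataFrame:
    """Box-plot style summaries (median, quartiles, 1.5*IQR fences) per
    parameter per group.  Empty groups are marked, not fatal."""
    rows = []
    for grp, g in table.groupby(group_col):
        for par in parameters:
            vals = g[par].to_numpy(dtype=float)
            if vals.size == 0:
                rows.append({"group": grp, "parameter": par, "empty": True})
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            rows.append({
                "group": grp, "parameter": par, "empty": False,
                "median": med, "q1": q1, "q3": q3,
                "fence_low": q1 - 1.5 * iqr, "fence_high": q3 + 1.5 * iqr,
                "n": vals.size,
            })
    return pd.DataFrame(rows)


def kde_distribution(values, grid=None, min_bandwidth: float = 1e-3):
    """Gaussian kernel density with bandwidth equal to the sample SD.

    Returns (grid, density); the density integrates to one.  A zero-SD
    sample falls back to ``min_bandwidth`` with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a KDE")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance sample: falling back to the minimum "
                      "KDE bandwidth", stacklevel=2)
        bw = min_bandwidth
        if grid is None:
            grid = np.linspace(values[0] - 5 * bw, values[0] + 5 * bw, 512)
        dens = np.exp(-0.5 * ((grid - values.mean()) / bw) ** 2)
        dens /= np.trapezoid(dens, grid)
        return grid, dens
    # gaussian_kde's factor multiplies the data SD; factor 1 => bandwidth = SD
    kde = gaussian_kde(values, bw_method=1.0)
    if grid is None:
        lo = values.min() - 4 * sd
        hi = values.max() + 4 * sd
        grid = np.linspace(lo, hi, 512)
    return grid, kde(grid)
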