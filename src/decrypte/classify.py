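"""Curve-shape classification and regulation calling.

A random forest (1,200 trees, 15 candidate features per split, minimum
node size 3, Gini impurity) labels each fitted dose-response curve as
up-, down- or not-regulated from a fixed 20-feature vector: the nine
descriptive curve parameters, the relative intensity and unique-peptide
count at each of the five doses, and the protein's abundance percentile
among the screen's vehicle controls.  Classifier calls are then filtered
by effect size: up-regulation requires an end-of-curve fold change
>= 1.5, down-regulation <= 0.7; everything else reverts to "not".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_score, roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from .curves import CurveMetrics, FitResult

__all__ = [
    "CLASS_ORDER",
    "FEATURE_NAMES",
    "ValidationReport",
    "abundance_percentiles",
    "build_features",
    "build_feature_matrix",
    "train_classifier",
    "classify_curves",
    "apply_regulation_filters",
    "transcript_filter",
    "UP_FOLD_CHANGE",
    "DOWN_FOLD_CHANGE",
]

CLASS_ORDER = ("down", "not", "up")  # lexicographic, matches sklearn classes_

UP_FOLD_CHANGE = 1.5
DOWN_FOLD_CHANGE = 0.7

FEATURE_NAMES = (
    "slope", "top", "bottom", "x0", "auc", "r2", "mad",
    "curve_fold_change", "linear_slope",
    "rel_int_1", "rel_int_2", "rel_int_3", "rel_int_4", "rel_int_5",
    "n_pep_1", "n_pep_2", "n_pep_3", "n_pep_4", "n_pep_5",
    "abundance_percentile",
)

# hyperparameters of the final tuned forest
N_TREES = 1200
MAX_FEATURES = 15
MIN_NODE_SIZE = 3


def abundance_percentiles(mean_vehicle_intensity: pd.Series) -> pd.Series:
    """Percentile (0-100) of each protein among vehicle-control abundances.

    Defined as 100 x (fraction of proteins with strictly lower mean
    vehicle intensity), so the most abundant of P proteins scores
    100 (P-1)/P.  NaN abundances get percentile 0.
    """
    v = mean_vehicle_intensity.to_numpy(dtype=float)
    finite = np.isfinite(v)
    sorted_vals = np.sort(v[finite])
    below = np.searchsorted(sorted_vals, v, side="left")
    pct = 100.0 * below / max(len(v), 1)
    pct[~finite] = 0.0
    return pd.Series(pct, index=mean_vehicle_intensity.index,
                     name="abundance_percentile")


def _impute(fit_fields: np.ndarray, rel: np.ndarray, npep: np.ndarray,
            pct: float) -> np.ndarray:
    rel = np.where(np.isfinite(rel), rel, 1.0)       # neutral ratio
    npep = np.where(np.isfinite(npep), npep, 0.0)    # not observed
    fit_fields = np.where(np.isfinite(fit_fields), fit_fields, 0.0)
    if not np.isfinite(pct):
        pct = 0.0
    return np.concatenate([fit_fields, rel, npep, [pct]])


def build_features(fit: FitResult, metrics: CurveMetrics,
                   rel_intensities: Sequence[float],
                   peptide_counts: Sequence[float],
                   abundance_percentile: float) -> tuple[np.ndarray, bool]:
    """One curve's fixed-order feature vector plus its fittable flag.

    Unfittable curves yield a sentinel (zero-filled fit block) and
    ``fittable=False``; the classifier never sees them — they are routed
    straight to "not".
    """
    rel = np.asarray(rel_intensities, dtype=float)
    npep = np.asarray(peptide_counts, dtype=float)
    if rel.size != 5 or npep.size != 5:
        raise ValueError("expected 5 dose intensities and 5 peptide counts")
    fit_fields = np.array([fit.s, fit.t, fit.b, fit.x0, metrics.auc,
                           metrics.r2, metrics.mad,
                           metrics.curve_fold_change, metrics.linear_slope])
    vec = _impute(fit_fields, rel, npep, float(abundance_percentile))
    return vec, bool(fit.fittable)


def build_feature_matrix(curve_table: pd.DataFrame,
                         percentiles: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized feature construction from a fitted curve table.

    ``curve_table`` must carry the fit/metric columns plus ``rel_int_*``
    and ``n_pep_*``; returns (X of shape n x 20, fittable flags).
    """
    fit_cols = ["s", "t", "b", "x0", "auc", "r2", "mad",
                "curve_fold_change", "linear_slope"]
    rel_cols = [f"rel_int_{i}" for i in range(1, 6)]
    pep_cols = [f"n_pep_{i}" for i in range(1, 6)]
    fit_block = curve_table[fit_cols].to_numpy(dtype=float)
    rel = curve_table[rel_cols].to_numpy(dtype=float)
    npep = curve_table[pep_cols].to_numpy(dtype=float)
    pct = percentiles.reindex(curve_table["protein_id"]).to_numpy(dtype=float)

    fittable = np.isfinite(fit_block[:, 1])  # t is NaN for sentinel fits
    X = np.concatenate([
        np.where(np.isfinite(fit_block), fit_block, 0.0),
        np.where(np.isfinite(rel), rel, 1.0),
        np.where(np.isfinite(npep), npep, 0.0),
        np.where(np.isfinite(pct), pct, 0.0)[:, None],
    ], axis=1)
    return X, fittable


@dataclass
class ValidationReport:
    """Held-out performance of the trained forest."""

    precision: dict[str, float]
    confusion: pd.DataFrame          # rows true, columns predicted
    roc: dict[str, tuple[np.ndarray, np.ndarray, float]]  # one-vs-rest
    macro_auc: float
    n_train: int
    n_validation: int


def train_classifier(X: np.ndarray, labels: Sequence[str],
                     split_frac: float = 0.8, seed: int = 0,
                     n_trees: int = N_TREES,
                     ) -> tuple[RandomForestClassifier, ValidationReport]:
    """Train the up/down/not forest with an 80:20 stratified split.

    Raises if any of the three classes is absent from the training data;
    a forest cannot call a class it never saw.
    """
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("features and labels differ in length")
    present = set(np.unique(y))
    missing = set(CLASS_ORDER) - present
    if missing:
        raise ValueError(f"class(es) absent from training data: {sorted(missing)}")

    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, train_size=split_frac, random_state=seed, stratify=y)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(MAX_FEATURES, X.shape[1]),
        min_samples_split=MIN_NODE_SIZE,
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X_tr, y_tr)

    y_hat = model.predict(X_va)
    prob = model.predict_proba(X_va)
    classes = list(model.classes_)
    precision = {c: float(p) for c, p in zip(
        classes, precision_score(y_va, y_hat, labels=classes,
                                 average=None, zero_division=0.0))}
    conf = pd.DataFrame(
        confusion_matrix(y_va, y_hat, labels=classes),
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"))
    roc = {}
    aucs = []
    for i, c in enumerate(classes):
        bin_true = (y_va == c).astype(int)
        fpr, tpr, _ = roc_curve(bin_true, prob[:, i])
        auc = float(roc_auc_score(bin_true, prob[:, i]))
        roc[c] = (fpr, tpr, auc)
        aucs.append(auc)
    report = ValidationReport(precision=precision, confusion=conf, roc=roc,
                              macro_auc=float(np.mean(aucs)),
                              n_train=len(y_tr), n_validation=len(y_va))
    return model, report


def classify_curves(model: RandomForestClassifier, X: np.ndarray,
                    fittable: Optional[np.ndarray] = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class probabilities, in ``CLASS_ORDER`` columns.

    Unfittable curves bypass the forest and are called "not" with
    probability 1.
    """
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature length {X.shape[1]} != model's {model.n_features_in_}")
    labels = model.predict(X).astype(object)
    prob_model = model.predict_proba(X)
    # re-order model columns into canonical CLASS_ORDER
    col = {c: i for i, c in enumerate(model.classes_)}
    prob = np.column_stack([prob_model[:, col[c]] for c in CLASS_ORDER])
    if fittable is not None:
        fittable = np.asarray(fittable, dtype=bool)
        labels[~fittable] = "not"
        sentinel = np.zeros(len(CLASS_ORDER))
        sentinel[CLASS_ORDER.index("not")] = 1.0
        prob[~fittable] = sentinel
    return labels.astype(str), prob


def apply_regulation_filters(labels: Sequence[str],
                             curve_fold_change: Sequence[float],
                             up_threshold: float = UP_FOLD_CHANGE,
                             down_threshold: float = DOWN_FOLD_CHANGE,
                             ) -> np.ndarray:
    """Effect-size filter on classifier calls.

    Up-calls survive only with end-of-curve fold change >= 1.5, down-calls
    only with <= 0.7; filtered calls become "not".
    """
    labels = np.asarray(labels, dtype=object)
    cfc = np.asarray(curve_fold_change, dtype=float)
    out = np.full(labels.shape, "not", dtype=object)
    up = (labels == "up") & (cfc >= up_threshold)
    down = (labels == "down") & (cfc <= down_threshold)
    out[up] = "up"
    out[down] = "down"
    return out.astype(str)


def save_model(model: RandomForestClassifier, path) -> None:
    """Serialize a trained forest with its feature-layout manifest."""
    import joblib

    joblib.dump({"model": model, "feature_names": list(FEATURE_NAMES),
                 "class_order": list(CLASS_ORDER)}, path)


def load_model(path) -> RandomForestClassifier:
    import joblib

    payload = joblib.load(path)
    if payload.get("feature_names") != list(FEATURE_NAMES):
        raise ValueError("model was trained with a different feature layout")
    return payload["model"]


def transcript_filter(counts: Sequence[float]) -> bool:
    """Keep a transcript curve only if every per-dose read count is > 50."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        return False
    return bool(np.all(np.isfinite(counts)) and np.all(counts > 50))
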