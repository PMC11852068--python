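"""Decoding the detection state from network features.

Per subject, each trial contributes two rows — the 7 pre-event and the 7
post-event window values of a feature — giving a 120 x 7 matrix per feature
(60 trials x 2 conditions) or 120 x 14 for the column-wise combination
(degree block then modularity block); subjects stack row-wise.  Three
decoder families are evaluated under stratified ten-fold cross-validation:
a linear max-margin classifier, a recurrent sequence classifier consuming
the 7-step window sequence, and an axis-aligned decision tree.  Features are
standardized per column with statistics fit on the training folds only.
Held-out continuous scores are pooled across folds into one ROC curve and
trapezoidal AUC per (feature set, decoder).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._rnn import RecurrentClassifier
from .errors import DataError, ParameterError
from .preprocess import BandSpec

__all__ = [
    "FeatureMatrix",
    "DecodeResult",
    "FEATURE_SETS",
    "DECODERS",
    "assemble_features",
    "ten_fold_cv",
    "roc_curve",
    "run_decoding_suite",
]

FEATURE_SETS = ("degree", "modularity", "combined")
DECODERS = ("margin", "recurrent", "tree")

_FEATURE_COLUMN = {"degree": "k_bar", "modularity": "Q"}


@dataclass
class FeatureMatrix:
    """Rows = (trial, condition) samples; columns = per-window feature values."""

    X: np.ndarray
    y: np.ndarray  # 1 = post (target detected), 0 = pre
    row_meta: pd.DataFrame  # subject_id, trial, condition
    feature_set: str
    n_windows: int

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class DecodeResult:
    """Cross-validated performance of one (feature set, decoder) combination."""

    feature_set: str
    decoder: str
    fold_accuracies: np.ndarray
    roc: np.ndarray  # (n_points, 2): false-positive rate, true-positive rate
    auc: float

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


def _pivot_feature(cell: pd.DataFrame, column: str) -> np.ndarray:
    """7 window values in temporal order for one (trial, condition) cell."""
    ordered = cell.sort_values("window")
    return ordered[column].to_numpy()


def assemble_features(
    features: pd.DataFrame, band: BandSpec | str, feature_set: str
) -> FeatureMatrix:
    """Build the decoding matrix for one band and feature set.

    Each row is one (subject, trial, condition); its columns are that
    condition's per-window values in window order — degree and modularity
    blocks are concatenated column-wise for the combined set.
    """
    if feature_set not in FEATURE_SETS:
        raise ParameterError(
            f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}"
        )
    band_name = band.name if isinstance(band, BandSpec) else band
    df = features[features["band"] == band_name]
    if df.empty:
        raise DataError(f"feature table contains no rows for band {band_name!r}")
    columns = (
        [_FEATURE_COLUMN[feature_set]]
        if feature_set != "combined"
        else [_FEATURE_COLUMN["degree"], _FEATURE_COLUMN["modularity"]]
    )
    rows, labels, meta = [], [], []
    window_counts = set()
    for (subject, trial), trial_df in df.groupby(["subject_id", "trial"], sort=True):
        for condition in ("pre", "post"):
            cell = trial_df[trial_df["condition"] == condition]
            window_counts.add(len(cell))
            blocks = [_pivot_feature(cell, col) for col in columns]
            rows.append(np.concatenate(blocks))
            labels.append(1 if condition == "post" else 0)
            meta.append({"subject_id": subject, "trial": trial, "condition": condition})
    if len(window_counts) != 1:
        raise DataError(
            f"unequal window counts across trials/conditions: {sorted(window_counts)}"
        )
    n_windows = window_counts.pop()
    if n_windows == 0:
        raise DataError("no windows per condition")
    try:
        x = np.vstack(rows)
    except ValueError as exc:  # ragged rows
        raise DataError("ragged feature rows") from exc
    return FeatureMatrix(
        X=x,
        y=np.asarray(labels),
        row_meta=pd.DataFrame(meta),
        feature_set=feature_set,
        n_windows=n_windows,
    )


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from pooled continuous scores.

    All score thresholds are swept from high to low; tied scores move
    diagonally, so ties contribute half, making the AUC equal to the
    probability that a random positive outscores a random negative plus half
    the tie probability.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _to_sequences(x: np.ndarray, feature_set: str, n_windows: int) -> np.ndarray:
    """Reshape flat rows into (n, n_windows, n_channels) step sequences.

    For the combined set the degree and modularity values of each window
    form a 2-vector per step, preserving temporal order.
    """
    if feature_set == "combined":
        n = x.shape[0]
        return np.stack(
            [x[:, :n_windows], x[:, n_windows:]], axis=-1
        ).reshape(n, n_windows, 2)
    return x[:, :, None]


def _make_decoder(name: str, seed: int):
    if name == "margin":
        return SVC(kernel="linear", C=1.0)
    if name == "tree":
        return DecisionTreeClassifier(max_depth=5, min_samples_leaf=5, random_state=seed)
    if name == "recurrent":
        return RecurrentClassifier(random_state=seed)
    raise ParameterError(f"unknown decoder {name!r}; registered decoders: {DECODERS}")


def ten_fold_cv(
    matrix: FeatureMatrix, decoder_name: str, seed: int = 0, n_folds: int = 10
) -> DecodeResult:
    """Stratified ten-fold cross-validation of one decoder on one feature matrix.

    Rows are shuffled by ``seed`` and split into label-stratified folds; per
    fold the decoder is fit on the other nine (with per-column
    standardization fit on those nine only) and scored on the held-out fold.
    Held-out continuous scores — decision-function values for the margin
    decoder, positive-class probabilities otherwise — are pooled into one
    ROC/AUC.
    """
    _make_decoder(decoder_name, seed)  # validate the name early
    x, y = matrix.X, matrix.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < n_folds:
        raise ParameterError(f"need >= {n_folds} rows per class for {n_folds}-fold CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accuracies = np.empty(n_folds)
    pooled_scores = np.empty_like(y, dtype=float)
    for fold, (train, test) in enumerate(skf.split(x, y)):
        scaler = StandardScaler().fit(x[train])
        x_train = scaler.transform(x[train])
        x_test = scaler.transform(x[test])
        decoder = _make_decoder(decoder_name, seed)
        if decoder_name == "recurrent":
            x_train = _to_sequences(x_train, matrix.feature_set, matrix.n_windows)
            x_test = _to_sequences(x_test, matrix.feature_set, matrix.n_windows)
        decoder.fit(x_train, y[train])
        pred = decoder.predict(x_test)
        accuracies[fold] = float((pred == y[test]).mean())
        if decoder_name == "margin":
            pooled_scores[test] = decoder.decision_function(x_test)
        else:
            pooled_scores[test] = decoder.predict_proba(x_test)[:, 1]
    roc, auc = roc_curve(pooled_scores, y)
    return DecodeResult(
        feature_set=matrix.feature_set,
        decoder=decoder_name,
        fold_accuracies=accuracies,
        roc=roc,
        auc=auc,
    )


def run_decoding_suite(
    features: pd.DataFrame, band: BandSpec | str = "beta", seed: int = 0
) -> list[DecodeResult]:
    """All nine (feature set x decoder) cross-validated results for one band."""
    results = []
    for feature_set in FEATURE_SETS:
        matrix = assemble_features(features, band, feature_set)
        for decoder in DECODERS:
            results.append(ten_fold_cv(matrix, decoder, seed=seed))
    return results
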