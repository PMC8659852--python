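"""Exhaustive feature-combination screening with LOOCV scoring.

Single, coupled and tripled feature combinations are scored against a bank
of nine simple, interpretable classifiers — k-nearest-neighbour (k = 1, 3,
5), linear soft-margin SVMs (C = 0.1, 1, 10) and L2 logistic regressions
(C = 0.1, 1, 10) — by leave-one-out cross-validated mean accuracy: each
sample is predicted by a model trained on all the others, and the score is
the fraction predicted correctly.

Inside every training fold, features are z-scored and missing values
replaced by the fold's feature means; the held-out sample is transformed
with the training fold's statistics only, so no information leaks from the
held-out sample into standardization or imputation.  A feature that is
constant within a training fold standardizes to zero everywhere and can
never influence a prediction.

Everything is deterministic: the solvers have unique optima or fixed
tie-break rules, and ranking ties are broken by (fewer features,
lexicographic feature names, bank order).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import loocv_bank
from .features import FeatureTable

__all__ = [
    "ClassifierSpec",
    "ScreenResult",
    "default_bank",
    "loocv_accuracy",
    "screen_combinations",
    "summarize_screen",
]

logger = logging.getLogger(__name__)

_FAMILIES = ("nearest_neighbour", "linear_max_margin", "logistic")


@dataclass(frozen=True)
class ClassifierSpec:
    """One bank member: a family plus its single hyperparameter
    (k for nearest-neighbour, C for the margin/logistic families)."""

    family: str
    hyperparameter: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"family must be one of {_FAMILIES}, got {self.family!r}"
            )
        if self.family == "nearest_neighbour":
            k = self.hyperparameter
            if int(k) != k or int(k) < 1:
                raise ValueError("k must be a positive integer")
        elif not self.hyperparameter > 0:
            raise ValueError("C must be positive")

    def __str__(self) -> str:
        name = {"nearest_neighbour": "kNN", "linear_max_margin": "SVM",
                "logistic": "LogReg"}[self.family]
        param = "k" if self.family == "nearest_neighbour" else "C"
        return f"{name}({param}={self.hyperparameter:g})"


def default_bank() -> list[ClassifierSpec]:
    """The nine-member default bank: kNN(1,3,5), SVM and logistic at
    C = 0.1, 1, 10."""
    bank = [ClassifierSpec("nearest_neighbour", k) for k in (1, 3, 5)]
    bank += [ClassifierSpec("linear_max_margin", c) for c in (0.1, 1.0, 10.0)]
    bank += [ClassifierSpec("logistic", c) for c in (0.1, 1.0, 10.0)]
    return bank


@dataclass
class ScreenResult:
    """LOOCV outcome of one (feature subset, classifier) evaluation."""

    feature_names: tuple
    classifier: ClassifierSpec
    loocv_accuracy: float
    per_fold_predictions: list | None = None


def _bank_arrays(bank: Sequence[ClassifierSpec]):
    """Split a bank into kernel parameter arrays plus the index mapping
    from kernel output order (kNN, SVM, logistic) back to bank order."""
    ks, svm_cs, lr_cs = [], [], []
    order: list[int] = []
    for fam, store in (("nearest_neighbour", ks),
                       ("linear_max_margin", svm_cs),
                       ("logistic", lr_cs)):
        for idx, spec in enumerate(bank):
            if spec.family == fam:
                store.append(spec.hyperparameter)
                order.append(idx)
    kernel_to_bank = np.argsort(np.array(order, dtype=np.int64))
    return (np.array(ks, dtype=np.int64),
            np.array(svm_cs, dtype=np.float64),
            np.array(lr_cs, dtype=np.float64),
            np.array(order, dtype=np.int64),
            kernel_to_bank)


def _fold_standardized(X: np.ndarray) -> np.ndarray:
    """Per-fold standardized data cube Z (n_folds, n_samples, n_features).

    ``Z[i]`` is the whole matrix z-scored with the statistics of the
    training fold that excludes sample i (NaN-aware), with missing entries
    imputed by the training-fold mean (standardized value 0).  Features
    constant — or entirely missing — within a training fold get unit scale,
    hence standardize to exactly zero.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    notnan = np.isfinite(X)
    Xz = np.where(notnan, X, 0.0)
    cnt = notnan.sum(axis=0)                    # (p,)
    s1 = Xz.sum(axis=0)
    s2 = (Xz * Xz).sum(axis=0)
    # leave-one-out training statistics per fold
    cnt_i = cnt[None, :] - notnan               # (n, p)
    s1_i = s1[None, :] - Xz
    s2_i = s2[None, :] - Xz * Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt_i > 0, s1_i / np.maximum(cnt_i, 1), 0.0)
        var = np.where(cnt_i > 0,
                       s2_i / np.maximum(cnt_i, 1) - mean**2, 0.0)
    std = np.sqrt(np.clip(var, 0.0, np.inf))
    std = np.where(std > 1e-12, std, 1.0)
    Z = (X[None, :, :] - mean[:, None, :]) / std[:, None, :]
    return np.where(np.isfinite(Z), Z, 0.0)


def _check_table(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    y = table.y
    if len(y) != len(set(table.data.index)):
        raise ValueError("duplicate sample ids in table")
    n1 = int(y.sum())
    if n1 < 2 or len(y) - n1 < 2:
        raise ValueError(
            "need at least 2 samples per class for LOOCV screening"
        )
    return table.X, y


def loocv_accuracy(table: FeatureTable, feature_subset: Sequence[str],
                   classifier: ClassifierSpec) -> ScreenResult:
    """Leave-one-out accuracy of one classifier on one feature subset.

    Standardization and imputation statistics come from each training fold
    alone.  Returns the exact fraction of correctly predicted held-out
    samples along with the per-fold predicted labels.
    """
    X, y = _check_table(table)
    names = list(table.feature_names)
    try:
        cols = [names.index(f) for f in feature_subset]
    except ValueError as err:
        raise KeyError(f"unknown feature in subset: {err}") from err
    Z = _fold_standardized(X)[:, :, cols]
    ks, svm_cs, lr_cs, _, _ = _bank_arrays([classifier])
    acc, preds = loocv_bank(np.ascontiguousarray(Z), y, ks, svm_cs, lr_cs)
    labels = ["LC" if p == 1 else "H" for p in preds[0]]
    return ScreenResult(feature_names=tuple(feature_subset),
                        classifier=classifier,
                        loocv_accuracy=float(acc[0]),
                        per_fold_predictions=labels)


def screen_combinations(table: FeatureTable, subset_size: int,
                        bank: Sequence[ClassifierSpec] | None = None,
                        features: Sequence[str] | None = None,
                        max_combinations: int | None = None,
                        rng_seed: int = 0) -> pd.DataFrame:
    """Score every feature combination of the given size against the bank.

    Returns one row per (combination, bank member), ranked by LOOCV
    accuracy descending with deterministic tie-breaks (fewer features,
    lexicographic feature names, bank order).  ``max_combinations`` switches
    to a seeded random subsample of the enumeration for very large feature
    registries; the default is exhaustive.
    """
    if bank is None:
        bank = default_bank()
    if len(bank) == 0:
        raise ValueError("classifier bank must not be empty")
    X, y = _check_table(table)
    names = list(table.feature_names) if features is None else list(features)
    if features is not None:
        all_names = list(table.feature_names)
        cols_base = [all_names.index(f) for f in names]
    else:
        cols_base = list(range(len(names)))
    if subset_size < 1 or subset_size > len(names):
        raise ValueError(
            f"subset_size {subset_size} out of range for {len(names)} features"
        )

    ks, svm_cs, lr_cs, order, _ = _bank_arrays(bank)
    Z = _fold_standardized(X)

    combos = list(itertools.combinations(range(len(names)), subset_size))
    if max_combinations is not None and len(combos) > max_combinations:
        rng = np.random.default_rng(rng_seed)
        pick = rng.choice(len(combos), size=max_combinations, replace=False)
        combos = [combos[i] for i in np.sort(pick)]
        logger.info("sampled %d of %d combinations", len(combos),
                    int(len(pick)))

    n_bank = len(bank)
    accs = np.empty((len(combos), n_bank))
    for ci, combo in enumerate(combos):
        cols = [cols_base[j] for j in combo]
        acc, _ = loocv_bank(np.ascontiguousarray(Z[:, :, cols]), y,
                            ks, svm_cs, lr_cs)
        accs[ci] = acc

    rows = []
    for ci, combo in enumerate(combos):
        feats = tuple(names[j] for j in combo)
        for pos, bank_idx in enumerate(order):
            spec = bank[bank_idx]
            rows.append((feats, spec.family, spec.hyperparameter,
                         accs[ci, pos], bank_idx))
    df = pd.DataFrame(rows, columns=["features", "family", "hyperparameter",
                                     "accuracy", "_bank_order"])
    df["n_features"] = df["features"].map(len)
    df = df.sort_values(
        by=["accuracy", "n_features", "features", "_bank_order"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).drop(columns=["_bank_order"]).reset_index(drop=True)
    return df


def summarize_screen(results: pd.DataFrame, top_n: int = 10) -> dict:
    """Condense a screen into a report.

    Contains the maximum accuracy, the ``top_n`` distinct combinations with
    their best bank member, and per-feature appearance counts within the top
    decile of all scored rows.
    """
    if len(results) == 0:
        raise ValueError("empty screen results")
    best_per_combo = (
        results.groupby("features", sort=False)
        .first()  # results are ranked, so first row is the combo's best
        .reset_index()
        .head(top_n)
    )
    top = [
        {
            "features": list(row.features),
            "family": row.family,
            "hyperparameter": float(row.hyperparameter),
            "accuracy": float(row.accuracy),
        }
        for row in best_per_combo.itertuples()
    ]
    decile = results.head(max(len(results) // 10, 1))
    counts: dict[str, int] = {}
    for feats in decile["features"]:
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
    return {
        "max_accuracy": float(results["accuracy"].max()),
        "n_results": int(len(results)),
        "top_combinations": top,
        "top_decile_feature_counts": dict(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
    }
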