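"""Change-feature computation and labelled feature-matrix assembly.

Every scalar feature P extracted from a sensor's response is measured twice:
``P0`` before contact with the plasma sample and ``Ppl`` after incubation.
Two change-features are derived per base feature:

    Dlt[P]  = P0 - Ppl
    Incr[P] = (P0 - Ppl) / P0 * 100        (percent)

The assembled matrix has one row per sample and, for each base feature P,
three columns: the before-state value ``P``, ``Dlt[P]`` and ``Incr[P]``,
grouped base-first, then all Dlt, then all Incr, plus a class-label column
(``LC``/``H``).  Two base-feature registries are supported:

``paper12``
    8 CV quantities (Ea, Ec, dE, Ia, Ic, Sa, Sc, R_S) + 4 EIS quantities
    (C_dl, omega_min, C_min, omega_max) — 12 base and 24 change columns.
``full``
    all 18 extracted CV quantities + the 4 EIS quantities — 22 base and 44
    change columns.  This is the default for combination screening.

Missing sub-features (e.g. an absent Cole–Cole extremum) propagate as NaN;
rows are never dropped.  Imputation is a training-fold concern and happens
downstream in the screening stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .impedance import (EISFeatures, cole_cole_transform,
                        extract_eis_features)
from .voltammetry import CVFeatures, CV_FEATURE_NAMES, extract_cv_features

__all__ = [
    "SampleRecord",
    "FeatureTable",
    "BASE_SETS",
    "EIS_FEATURE_NAMES",
    "dlt",
    "incr",
    "build_feature_table",
    "extract_sample_record",
]

logger = logging.getLogger(__name__)

EIS_FEATURE_NAMES = ("C_dl", "omega_min", "C_min", "omega_max")

#: named base-feature registries
BASE_SETS: dict[str, tuple[str, ...]] = {
    "paper12": ("Ea", "Ec", "dE", "Ia", "Ic", "Sa", "Sc", "R_S")
    + EIS_FEATURE_NAMES,
    "full": CV_FEATURE_NAMES + EIS_FEATURE_NAMES,
}


@dataclass
class SampleRecord:
    """Per-sample before/after extracted features with a class label."""

    sample_id: str
    label: str  # "LC" | "H"
    before: tuple  # (CVFeatures, EISFeatures)
    after: tuple   # (CVFeatures, EISFeatures)

    def __post_init__(self) -> None:
        if self.label not in ("LC", "H"):
            raise ValueError(f"label must be 'LC' or 'H', got {self.label!r}")

    def state_values(self, state: str) -> dict[str, float]:
        """Flat feature-name → value mapping for one measurement state."""
        cv, eis = self.before if state == "before" else self.after
        values: dict[str, float] = {}
        if isinstance(cv, CVFeatures):
            values.update(cv.as_dict())
        elif cv is not None:
            values.update(dict(cv))
        if isinstance(eis, EISFeatures):
            values.update(eis.as_dict())
        elif eis is not None:
            values.update(dict(eis))
        return values


def dlt(p0: float, ppl: float) -> float:
    """Before-minus-after difference of a feature: ``Dlt = P0 - Ppl``."""
    return p0 - ppl


def incr(p0: float, ppl: float) -> float:
    """Relative change of a feature in percent: ``Incr = Dlt/P0 * 100``.

    Undefined at ``P0 = 0``; returns NaN with a logged warning rather than
    raising, so a single degenerate feature never aborts table assembly.
    """
    if p0 == 0:
        logger.warning("Incr undefined for P0 = 0; propagating NaN")
        return float("nan")
    return (p0 - ppl) / p0 * 100.0


@dataclass
class FeatureTable:
    """Assembled base+change feature matrix with labels.

    ``data`` holds one row per sample indexed by sample id; feature columns
    come first (registry order: base, Dlt, Incr) and the class label last.
    """

    data: pd.DataFrame
    base_set: str

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "label"]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    @property
    def X(self) -> np.ndarray:
        """Feature matrix (n_samples, n_features), NaN for missing."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary class vector: 1 for LC, 0 for H."""
        return (self.data["label"] == "LC").to_numpy().astype(np.int64)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.reset_index().rename(columns={"index": "sample_id"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, base_set: str = "full") -> "FeatureTable":
        df = pd.read_csv(path).set_index("sample_id")
        df.index.name = None
        return cls(data=df, base_set=base_set)


def extract_sample_record(sample_id: str, label: str, *,
                          cv_before, eis_before, cv_after, eis_after,
                          baseline_fraction: float = 0.2,
                          onset_fraction: float = 0.05) -> SampleRecord:
    """Run CV and Cole–Cole feature extraction on one sample's paired
    before/after measurements and wrap the result as a SampleRecord."""
    def _state(cv, eis):
        cvf = extract_cv_features(cv, baseline_fraction=baseline_fraction,
                                  onset_fraction=onset_fraction)
        eisf = extract_eis_features(cole_cole_transform(eis))
        return (cvf, eisf)

    return SampleRecord(
        sample_id=sample_id,
        label=label,
        before=_state(cv_before, eis_before),
        after=_state(cv_after, eis_after),
    )


def build_feature_table(records: Sequence[SampleRecord],
                        base_set: str = "full") -> FeatureTable:
    """Assemble the labelled base+change matrix from per-sample records.

    For each base feature P the row carries the before-state value ``P``,
    ``Dlt[P]`` and ``Incr[P]``.  Missing sub-features propagate as NaN (the
    row is kept).  Column order is deterministic; duplicate sample ids are
    rejected.
    """
    if base_set not in BASE_SETS:
        raise ValueError(
            f"unknown base set {base_set!r}; choose from {sorted(BASE_SETS)}"
        )
    names = BASE_SETS[base_set]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated sample_id(s): {dupes}")

    rows = []
    for rec in records:
        before = rec.state_values("before")
        after = rec.state_values("after")
        row: dict[str, float | str] = {}
        for name in names:
            p0 = before.get(name, float("nan"))
            ppl = after.get(name, float("nan"))
            row[name] = p0
            if math.isnan(p0) or math.isnan(ppl):
                row[f"Dlt[{name}]"] = float("nan")
                row[f"Incr[{name}]"] = float("nan")
            else:
                row[f"Dlt[{name}]"] = dlt(p0, ppl)
                row[f"Incr[{name}]"] = incr(p0, ppl)
        row["label"] = rec.label
        rows.append(row)

    columns = (
        list(names)
        + [f"Dlt[{n}]" for n in names]
        + [f"Incr[{n}]" for n in names]
        + ["label"]
    )
    df = pd.DataFrame(rows, index=ids)[columns]
    return FeatureTable(data=df, base_set=base_set)
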