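"""Vertex/antivertex discretization of the raw cohort.

Every retained clinical variable is projected onto a pair of boolean
descriptors forming the augmented vertex set: ``var[1]`` is true when the
observed value lies in the risk range, its antivertex ``var[0]`` when it
lies in the non-risk range, and a missing observation leaves both false
(the <0,0> encoding).  "Observed as not a risk sign" is therefore distinct
from "not observed", and no imputation is ever performed.  Values the range
map covers by neither descriptor (e.g. a heart rate below 50) carry no
usable risk information and are encoded <0,0> as well, with a warning.

The 19 retained variables yield 38 descriptor columns; the final-diagnosis
pair (two further columns) can be appended for the Q-analysis view of the
patient-descriptor relation, but is never part of a classifier feature
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .schema import (
    ALL_COLUMNS,
    LABEL_COLUMN,
    RETAINED_VARIABLES,
    descriptor_pair,
)
from .thresholds import Interval, ThresholdMap, load_threshold_map

__all__ = [
    "DescriptorPair",
    "AugmentedIncidence",
    "select_variables",
    "discretize",
    "build_incidence",
    "AugmentedVertexEncoder",
]


class DescriptorPair(NamedTuple):
    """One variable's augmented-vertex encoding for one observation."""

    variable: str
    anti: bool  # the `[0]` antivertex descriptor
    pos: bool  # the `[1]` vertex descriptor


def select_variables(cohort: pd.DataFrame, allow_unknown: bool = False) -> list[str]:
    """Pick the analysis variables from a raw cohort table.

    Drops the identifier, the redundant/near-empty indicators, the clinical
    prediction rules, and the final-diagnosis label; on the full 28-column
    schema exactly 19 variables remain.  Columns outside the canonical
    vocabulary are dropped with a warning unless *allow_unknown* is set, in
    which case they pass through untouched.
    """
    present = list(cohort.columns)
    retained = [v for v in RETAINED_VARIABLES if v in present]
    absent = [v for v in RETAINED_VARIABLES if v not in present]
    if absent:
        warnings.warn(f"expected analysis variables absent from cohort: {absent}")
    unknown = [c for c in present if c not in ALL_COLUMNS]
    if unknown:
        if allow_unknown:
            retained.extend(unknown)
        else:
            warnings.warn(f"unknown columns ignored: {unknown}")
    return retained


def _classify(values: np.ndarray, anti: Interval, pos: Interval) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized range membership; returns (anti_flags, pos_flags, gap_flags)."""
    observed = ~pd.isna(values)
    vals = np.where(observed, values, 0.0).astype(float)
    # risk range takes precedence where the printed ranges touch (WBC at 10000)
    in_pos = observed & np.array([pos.contains(v) for v in vals])
    in_anti = observed & ~in_pos & np.array([anti.contains(v) for v in vals])
    gap = observed & ~in_pos & ~in_anti
    return in_anti, in_pos, gap


def discretize(
    value: float | bool | None,
    variable: str,
    threshold_map: ThresholdMap | None = None,
) -> DescriptorPair:
    """Encode a single observation as its vertex/antivertex pair.

    A missing observation (None/NaN) and a value in the uncovered gap
    between the two ranges both yield ``(anti=False, pos=False)``; the gap
    case is flagged with a warning since it indicates a value outside the
    map's clinical vocabulary.
    """
    tmap = threshold_map if threshold_map is not None else load_threshold_map()
    if variable not in tmap:
        raise KeyError(f"no threshold mapping for variable {variable!r}")
    anti_iv, pos_iv = tmap[variable]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return DescriptorPair(variable, False, False)
    v = float(value)
    if pos_iv.contains(v):
        return DescriptorPair(variable, False, True)
    if anti_iv.contains(v):
        return DescriptorPair(variable, True, False)
    warnings.warn(
        f"value {v!r} of {variable!r} falls in the gap between the [0] and [1] "
        f"ranges; encoded as <0,0>"
    )
    return DescriptorPair(variable, False, False)


@dataclass
class AugmentedIncidence:
    """Boolean patient x descriptor incidence matrix with aligned labels.

    ``labels`` is aligned to ``patients`` and holds NaN where the final
    diagnosis itself was missing; such patients stay in the matrix (they
    still carry structure for Q-analysis) but are excluded from supervised
    fitting via :attr:`labeled_mask`.
    """

    patients: list[str]
    descriptors: list[str]
    matrix: np.ndarray  # bool, shape (n_patients, n_descriptors)
    labels: np.ndarray  # float, NaN = missing diagnosis

    @property
    def labeled_mask(self) -> np.ndarray:
        return ~np.isnan(self.labels)

    @property
    def y(self) -> np.ndarray:
        """Integer labels of the patients whose diagnosis is observed."""
        return self.labels[self.labeled_mask].astype(int)

    def feature_view(self) -> "AugmentedIncidence":
        """Drop the final-diagnosis descriptor columns, if present."""
        keep = [
            i
            for i, d in enumerate(self.descriptors)
            if not d.startswith(LABEL_COLUMN + "[")
        ]
        return AugmentedIncidence(
            patients=self.patients,
            descriptors=[self.descriptors[i] for i in keep],
            matrix=self.matrix[:, keep],
            labels=self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.astype(int), index=self.patients, columns=self.descriptors
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="patient")

    @classmethod
    def from_csv(cls, path: str | Path, labels: np.ndarray | None = None) -> "AugmentedIncidence":
        df = pd.read_csv(path, index_col="patient")
        n = len(df)
        return cls(
            patients=[str(p) for p in df.index],
            descriptors=list(df.columns),
            matrix=df.to_numpy().astype(bool),
            labels=np.full(n, np.nan) if labels is None else np.asarray(labels, dtype=float),
        )


def build_incidence(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    threshold_map: ThresholdMap | None = None,
    include_diagnosis: bool = False,
    invert_po2: bool = False,
) -> AugmentedIncidence:
    """Discretize a cohort into the augmented incidence matrix.

    Columns follow the range-map listing order: ``var[0], var[1]`` for each
    retained variable, with the final-diagnosis pair appended last when
    *include_diagnosis* is set.  *invert_po2* swaps the printed PO2 ranges
    so that low oxygen tension becomes the risk descriptor.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if variables is None:
        variables = select_variables(cohort)
    missing_cols = [v for v in variables if v not in cohort.columns]
    if missing_cols:
        raise ValueError(f"variables not in cohort: {missing_cols}")
    tmap = dict(threshold_map if threshold_map is not None else load_threshold_map())
    if invert_po2 and "PO2" in tmap:
        tmap["PO2"] = (tmap["PO2"][1], tmap["PO2"][0])

    encode_vars = list(variables) + ([LABEL_COLUMN] if include_diagnosis else [])
    names: list[str] = []
    columns: list[np.ndarray] = []
    for variable in encode_vars:
        if variable not in tmap:
            raise KeyError(f"no threshold mapping for variable {variable!r}")
        anti_iv, pos_iv = tmap[variable]
        values = cohort[variable].to_numpy()
        anti, pos, gap = _classify(values, anti_iv, pos_iv)
        if gap.any():
            warnings.warn(
                f"{int(gap.sum())} value(s) of {variable!r} fall in the gap "
                f"between the [0] and [1] ranges; encoded as <0,0>"
            )
        d0, d1 = descriptor_pair(variable)
        names.extend([d0, d1])
        columns.extend([anti, pos])

    if "ID" in cohort.columns:
        patients = [str(p) for p in cohort["ID"]]
    else:
        patients = [str(i) for i in cohort.index]
    if LABEL_COLUMN in cohort.columns:
        labels = cohort[LABEL_COLUMN].to_numpy(dtype=float)
    else:
        labels = np.full(len(cohort), np.nan)
    return AugmentedIncidence(
        patients=patients,
        descriptors=names,
        matrix=np.column_stack(columns),
        labels=labels,
    )


class AugmentedVertexEncoder(TransformerMixin, BaseEstimator):
    """Sklearn transformer wrapping the vertex/antivertex discretization.

    ``fit`` selects the analysis variables present in the cohort frame and
    loads the range map; ``transform`` returns the 0/1 descriptor frame
    (feature descriptors only — the diagnosis pair is never emitted here).

    Parameters
    ----------
    threshold_path : str or None
        YAML range map to use instead of the packaged clinical defaults.
    invert_po2 : bool
        Swap the printed PO2 ranges (low oxygen tension as the risk sign).
    allow_unknown : bool
        Pass through columns outside the canonical vocabulary.
    """

    def __init__(
        self,
        threshold_path: str | None = None,
        invert_po2: bool = False,
        allow_unknown: bool = False,
    ):
        self.threshold_path = threshold_path
        self.invert_po2 = invert_po2
        self.allow_unknown = allow_unknown

    def fit(self, X: pd.DataFrame, y=None) -> "AugmentedVertexEncoder":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("AugmentedVertexEncoder expects a cohort DataFrame")
        self.threshold_map_ = load_threshold_map(self.threshold_path)
        self.variables_ = select_variables(X, allow_unknown=self.allow_unknown)
        unmapped = [v for v in self.variables_ if v not in self.threshold_map_]
        if unmapped:
            raise KeyError(f"no threshold mapping for variable(s) {unmapped}")
        self.descriptors_ = [d for v in self.variables_ for d in descriptor_pair(v)]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "descriptors_")
        inc = build_incidence(
            X,
            variables=self.variables_,
            threshold_map=self.threshold_map_,
            include_diagnosis=False,
            invert_po2=self.invert_po2,
        )
        return inc.to_frame()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "descriptors_")
        return np.asarray(self.descriptors_, dtype=object)
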