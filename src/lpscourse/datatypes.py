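"""In-memory containers passed between pipeline stages.

Tabular data lives in pandas objects with documented shapes; the thin
dataclasses below exist where a bare DataFrame would lose a contract the
pipeline relies on (expression units, the replicate axis of a time-course
tensor, cluster ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

#: controlled vocabulary for condition groups in a sample design
CONDITION_GROUPS = (
    "unstimulated_monocyte",
    "unstimulated_MDM",
    "IFN_monocyte",
    "inflammatory_monocyte",
    "LPS_MDM_t",
)


@dataclass
class ExpressionTable:
    """Feature-by-sample expression matrix.

    Parameters
    ----------
    data : DataFrame, shape (n_features, n_samples)
        Non-negative finite values; index is feature ids, columns sample ids.
    unit : {"tags", "tpm"}
        Whether values are raw tag counts or tags-per-million.
    """

    data: pd.DataFrame
    unit: str = "tpm"

    def __post_init__(self) -> None:
        if self.unit not in ("tags", "tpm"):
            raise SchemaError(f"unknown expression unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dupes[:5]}")
        values = self.data.to_numpy()
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise SchemaError("expression values must be non-negative and finite")

    @property
    def feature_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    def copy(self) -> "ExpressionTable":
        return ExpressionTable(self.data.copy(), self.unit)


@dataclass
class TimeCourseTensor:
    """Per-replicate expression over a shared time grid.

    ``values[f, t, d]`` is the expression (TPM) of feature ``f`` at timepoint
    ``t`` in donor ``d``. Timepoints are minutes from stimulation and must be
    strictly increasing.
    """

    feature_ids: list
    timepoints_minutes: np.ndarray
    donors: list
    values: np.ndarray  # (n_features, n_timepoints, n_donors)

    def __post_init__(self) -> None:
        self.timepoints_minutes = np.asarray(self.timepoints_minutes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (
            len(self.feature_ids),
            len(self.timepoints_minutes),
            len(self.donors),
        ):
            raise SchemaError(
                f"tensor shape {self.values.shape} inconsistent with axis labels"
            )
        if np.any(np.diff(self.timepoints_minutes) <= 0):
            raise SchemaError("timepoints must be strictly increasing")
        if self.values.size and (
            not np.isfinite(self.values).all() or (self.values < 0).any()
        ):
            raise SchemaError("tensor values must be non-negative and finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_sample_table(self, unit: str = "tpm") -> ExpressionTable:
        """Flatten to a feature x sample table with one column per
        (timepoint, donor) pair, samples named ``<donor>_t<minutes>``."""
        cols, mats = [], []
        for d, donor in enumerate(self.donors):
            for t, minutes in enumerate(self.timepoints_minutes):
                cols.append(f"{donor}_t{int(minutes)}")
                mats.append(self.values[:, t, d])
        frame = pd.DataFrame(
            np.column_stack(mats), index=self.feature_ids, columns=cols
        )
        return ExpressionTable(frame, unit)


@dataclass
class FilterReport:
    """Casualty report of the expression-level / variability filter."""

    n_input: int
    n_pass_tpm: int
    n_pass_cv: int
    removed_ids: list
    thresholds: dict = field(default_factory=lambda: {"min_tpm": 10.0, "min_cv": 0.5})

    def __post_init__(self) -> None:
        if not (self.n_pass_cv <= self.n_pass_tpm <= self.n_input):
            raise SchemaError("filter counts must be nested: cv <= tpm <= input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass_tpm": self.n_pass_tpm,
            "n_pass_cv": self.n_pass_cv,
            "n_removed": len(self.removed_ids),
            "thresholds": dict(self.thresholds),
        }


def validate_design(design: pd.DataFrame, table: ExpressionTable | None = None) -> pd.DataFrame:
    """Check a sample design table (sample_id, donor, timepoint_minutes,
    condition_group) and, if given, its coverage of an expression table."""
    required = {"sample_id"}
    missing = required - set(design.columns)
    if missing:
        raise SchemaError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        raise SchemaError("design table has duplicate sample_id rows")
    if table is not None:
        missing_samples = set(table.sample_ids) - set(design["sample_id"])
        if missing_samples:
            raise SchemaError(
                f"samples without a design row: {sorted(missing_samples)[:5]}"
            )
    return design
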