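"""Expression cohort container: a feature x sample matrix with sample annotations.

All statistics in the pipeline run on :class:`ExpressionCohort`.  Before
preprocessing the matrix holds raw counts; afterwards it holds log2
normalized expression.  Sample annotations carry the tumor/normal group
label, an integer batch, and optionally sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PreprocessingError

GROUP_COL = "group"
BATCH_COL = "batch"
TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionCohort:
    """Feature x sample expression matrix plus per-sample annotations.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    annotations
        DataFrame indexed by sample id with at least a ``group`` column
        (values ``tumor``/``normal``); a ``batch`` integer column is added
        (all 1) when absent.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    is_log: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.values.shape[1] == 0 or self.values.shape[0] == 0:
            raise PreprocessingError("empty expression matrix")
        if list(self.values.columns) != list(self.annotations.index):
            # tolerate same set, different order
            if set(self.values.columns) != set(self.annotations.index):
                raise PreprocessingError(
                    "matrix columns and annotation rows do not match"
                )
            self.annotations = self.annotations.loc[list(self.values.columns)]
        if GROUP_COL not in self.annotations.columns:
            raise PreprocessingError("annotations lack a 'group' column")
        if BATCH_COL not in self.annotations.columns:
            self.annotations = self.annotations.assign(**{BATCH_COL: 1})
        if self.values.isna().any().any():
            raise PreprocessingError("expression matrix contains missing values")

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group(self) -> pd.Series:
        return self.annotations[GROUP_COL]

    @property
    def batch(self) -> pd.Series:
        return self.annotations[BATCH_COL]

    def samples_in_group(self, label: str) -> list[str]:
        return list(self.annotations.index[self.group == label])

    def feature_vector(self, feature_id: str) -> pd.Series:
        if feature_id not in self.values.index:
            raise KeyError(f"feature '{feature_id}' not in cohort")
        return self.values.loc[feature_id]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionCohort":
        return ExpressionCohort(
            self.values[sample_ids].copy(),
            self.annotations.loc[sample_ids].copy(),
            is_log=self.is_log,
        )

    def copy(self) -> "ExpressionCohort":
        return ExpressionCohort(
            self.values.copy(), self.annotations.copy(), is_log=self.is_log
        )

    # -- IO ----------------------------------------------------------------

    def write(self, matrix_path: str | Path, annot_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally annotations) as TSV.

        Features are rows; the header row holds sample ids.  Counts are
        written as integers when the matrix is integral.
        """
        vals = self.values
        if not self.is_log and np.allclose(vals.to_numpy(), np.round(vals.to_numpy())):
            vals = vals.astype(np.int64)
        vals.to_csv(matrix_path, sep="\t", index_label="feature_id")
        if annot_path is not None:
            self.annotations.to_csv(annot_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(
        cls, matrix_path: str | Path, annot_path: str | Path, is_log: bool = False
    ) -> "ExpressionCohort":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        annotations = pd.read_csv(annot_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        annotations.index = annotations.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, annotations, is_log=is_log)
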