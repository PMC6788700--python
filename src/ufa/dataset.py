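"""Tabular container shared by every stage of the pipeline.

A :class:`Dataset` is a rectangular table of continuous explanatory
variables (``NaN`` marks a missing cell) together with a binary outcome
column. It is a thin, validated wrapper around a pandas ``DataFrame`` /
``Series`` pair so that detection, flagging and evaluation all agree on
what "missing" and "binary target" mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "DataError"]


class DataError(ValueError):
    """Raised when input data violate the tabular contract."""


@dataclass
class Dataset:
    """Observations x variables table with a binary outcome.

    Parameters
    ----------
    X : pandas.DataFrame
        One column per continuous explanatory variable; ``NaN`` encodes a
        missing cell. Columns must be numeric.
    y : pandas.Series
        Outcome, one entry per row of ``X``. Must be 0/1 unless
        ``continuous_target`` is set, in which case any value in [0, 1]
        is accepted and downstream group rates become group means.
    continuous_target : bool
        Opt-in relaxation of the binary contract.
    """

    X: pd.DataFrame
    y: pd.Series
    continuous_target: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise DataError(
                f"X has {len(self.X)} rows but y has {len(self.y)} entries"
            )
        if len(self.X) == 0:
            raise DataError("dataset has zero rows")
        if not self.X.index.equals(self.y.index):
            raise DataError("X and y must share the same index")
        if not self.X.index.is_unique:
            raise DataError("observation ids must be unique")
        for name in self.X.columns:
            if not np.issubdtype(self.X[name].dtype, np.number):
                raise DataError(f"variable {name!r} is not numeric")
        yv = self.y.to_numpy(dtype=float)
        if np.isnan(yv).any():
            raise DataError("target contains missing values")
        if self.continuous_target:
            if ((yv < 0) | (yv > 1)).any():
                raise DataError("continuous target must lie in [0, 1]")
        else:
            bad = set(np.unique(yv)) - {0.0, 1.0}
            if bad:
                raise DataError(
                    f"target must be binary 0/1; found values {sorted(bad)}"
                )
            self.y = self.y.astype(np.int8)

    # -- convenience -----------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.X)

    @property
    def variables(self) -> list[str]:
        return list(self.X.columns)

    @property
    def ids(self) -> pd.Index:
        return self.X.index

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, target: str, continuous_target: bool = False
    ) -> "Dataset":
        """Split a single table into variables and the named target column."""
        if target not in frame.columns:
            raise DataError(f"target column {target!r} not found")
        X = frame.drop(columns=[target])
        return cls(X, frame[target], continuous_target=continuous_target)

    def to_frame(self, target: str = "y") -> pd.DataFrame:
        out = self.X.copy()
        out[target] = self.y
        return out

    def subset(self, index) -> "Dataset":
        """Row subset by positional indices (labels preserved)."""
        return Dataset(
            self.X.iloc[index],
            self.y.iloc[index],
            continuous_target=self.continuous_target,
        )

    def copy(self) -> "Dataset":
        return Dataset(
            self.X.copy(), self.y.copy(), continuous_target=self.continuous_target
        )
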