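"""Symmetric sample-by-sample matrices (distances and pairwise statistics).

A :class:`PairwiseMatrix` is deliberately laxer than a metric distance
matrix: betaNTI and Raup-Crick matrices are symmetric pairwise statistics
whose values may be negative and whose diagonal is undefined (stored as
NaN), which rules out :class:`skbio.DistanceMatrix` as the container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PairwiseMatrix:
    """Symmetric sample x sample matrix with named samples and metric."""

    data: pd.DataFrame
    metric_name: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.data.columns):
            raise ValueError("PairwiseMatrix requires identical row/column ids")
        vals = self.data.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, equal_nan=True):
            raise ValueError(f"{self.metric_name}: matrix is not symmetric")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (excluding the diagonal), row-major."""
        v = self.values
        iu = np.triu_indices(len(v), k=1)
        return v[iu]

    def pair_frame(self) -> pd.DataFrame:
        """Long form: one row per unordered sample pair."""
        ids = self.sample_ids
        iu = np.triu_indices(len(ids), k=1)
        return pd.DataFrame(
            {
                "sample_a": [ids[i] for i in iu[0]],
                "sample_b": [ids[j] for j in iu[1]],
                self.metric_name: self.values[iu],
            }
        )

    def subset(self, ids: list[str]) -> "PairwiseMatrix":
        return PairwiseMatrix(self.data.loc[ids, ids], self.metric_name)

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.10g", index_label="sample_id")

    @classmethod
    def read(cls, path, metric_name: str = "unnamed") -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        return cls(df, metric_name)

    @classmethod
    def from_values(
        cls, values: np.ndarray, sample_ids, metric_name: str = "unnamed"
    ) -> "PairwiseMatrix":
        ids = list(sample_ids)
        df = pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=ids)
        return cls(df, metric_name)
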