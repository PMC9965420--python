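"""Gene-by-sample expression container used by every pipeline stage.

The container is a thin, validated wrapper around a pandas DataFrame with
genes as rows and samples as columns. All values are non-negative on input
(expression units are platform-agnostic: microarray intensities, counts,
or simulated expected counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression matrix.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Values must be finite; negatives are rejected unless
        ``allow_negative`` is set (standardized matrices may contain them).
    allow_negative
        Permit negative entries (e.g. after z-scoring rows).
    """

    data: pd.DataFrame
    allow_negative: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TypeError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains NaN")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if not self.allow_negative and (values < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """G x n array of expression values."""
        return self.data.to_numpy(dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.data.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[genes].copy(), allow_negative=self.allow_negative)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, sep: str = "\t", allow_negative: bool = False) -> "ExpressionMatrix":
        """Read a genes-in-rows table; first column holds gene identifiers."""
        frame = pd.read_csv(path, sep=sep, index_col=0)
        return cls(frame, allow_negative=allow_negative)

    def to_tsv(self, path, float_format: str = "%.10g") -> None:
        self.data.to_csv(path, sep="\t", float_format=float_format)
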