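"""Core containers shared across the pipeline.

The central object is :class:`AbundanceMatrix`, a proteins x samples matrix of
log2 TMT reporter ratios with a per-sample batch (TMT-set) annotation.  It is a
thin, validated wrapper around a pandas DataFrame so that every stage of the
pipeline can rely on unique identifiers and aligned batch labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "InputContractError"]


class InputContractError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance matrix (log2 ratios unless stated).

    Parameters
    ----------
    values
        DataFrame indexed by protein id, columns are sample ids.
    batch_of_sample
        Series mapping sample id -> batch (TMT set) label.  Defaults to a
        single batch ``"B1"`` for every sample.
    """

    values: pd.DataFrame
    batch_of_sample: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise InputContractError(f"duplicate protein ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise InputContractError(f"duplicate sample ids: {dups[:5]}")
        v.index.name = "protein_id"
        v.columns.name = None
        if self.batch_of_sample is None:
            self.batch_of_sample = pd.Series("B1", index=v.columns)
        else:
            missing = v.columns.difference(self.batch_of_sample.index)
            if len(missing):
                raise InputContractError(
                    f"samples without batch annotation: {list(missing)[:5]}"
                )
            self.batch_of_sample = self.batch_of_sample.reindex(v.columns)

    # -- convenience accessors -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_proteins(self, protein_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[protein_ids], self.batch_of_sample)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.loc[:, sample_ids], self.batch_of_sample.loc[sample_ids]
        )
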