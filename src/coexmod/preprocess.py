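"""Quantification normalization and variance-based feature selection.

Normalization follows the TMT ratio-to-pool convention: each sample is scaled
by its median ratio, ratios are log2-transformed, and each protein is mean
centered within each TMT set (batch).  Feature selection keeps the top
fraction of proteins by log2 abundance variance.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, InputContractError

__all__ = ["normalize", "filter_complete", "select_top_variable"]

log = logging.getLogger(__name__)


def normalize(raw_ratios: AbundanceMatrix) -> AbundanceMatrix:
    """Median-scale, log2, and batch-center a matrix of linear pool ratios.

    Steps, in order: (1) divide each sample by its median ratio; (2) log2;
    (3) subtract, per protein, the mean within each batch.  After (3) every
    protein's within-batch mean is 0.
    """
    v = raw_ratios.values
    if (v.to_numpy() <= 0).any():
        bad = v.stack()
        bad = bad[bad <= 0]
        prot, samp = bad.index[0]
        raise InputContractError(
            f"nonpositive ratio at protein {prot!r}, sample {samp!r}: {bad.iloc[0]}"
        )
    scaled = v / v.median(axis=0)
    logged = np.log2(scaled)
    centered = logged.copy()
    for _, cols in raw_ratios.batch_of_sample.groupby(raw_ratios.batch_of_sample).groups.items():
        block = logged.loc[:, cols]
        centered.loc[:, cols] = block.sub(block.mean(axis=1), axis=0)
    return AbundanceMatrix(centered, raw_ratios.batch_of_sample)


def filter_complete(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Keep only proteins quantified in every sample; order preserved."""
    keep = matrix.values.notna().all(axis=1)
    if not keep.any():
        log.warning("filter_complete: no complete rows remain")
    return AbundanceMatrix(matrix.values.loc[keep], matrix.batch_of_sample)


def select_top_variable(matrix: AbundanceMatrix, fraction: float) -> AbundanceMatrix:
    """Retain the ceil(fraction * n_proteins) rows of largest sample variance.

    Ties broken by protein id (lexicographic); the retained rows keep their
    original order.  ``fraction`` must lie in (0, 1].
    """
    if not 0.0 < fraction <= 1.0:
        raise InputContractError(f"fraction must lie in (0, 1], got {fraction}")
    n = matrix.shape[0]
    if n == 0:
        raise InputContractError("select_top_variable: empty matrix")
    n_keep = math.ceil(fraction * n)
    var = matrix.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda p: (-var[p], p))
    chosen = set(order[:n_keep])
    keep = [p for p in matrix.protein_ids if p in chosen]
    return AbundanceMatrix(matrix.values.loc[keep], matrix.batch_of_sample)
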