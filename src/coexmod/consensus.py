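"""Subsampled k-means consensus clustering and module-signature stratification.

Each iteration subsamples 80% of items (samples) and 80% of features without
replacement, runs k-means on the standardized subsample, and records which
co-sampled item pairs landed in the same cluster.  The consensus matrix entry
for a pair is the fraction of co-sampled iterations in which they co-clustered;
final labels come from complete-linkage clustering of 1 - consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from ._rng import stream
from .datatypes import AbundanceMatrix, InputContractError
from .modules import ModuleSet, hub_proteins

__all__ = [
    "ConsensusResult",
    "consensus_matrix",
    "cut_consensus",
    "consensus_cdf_report",
    "stratify_module_signature",
]

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Consensus matrix with its co-sampling counts and run settings."""

    consensus: pd.DataFrame  # samples x samples in [0, 1]
    co_sampled_counts: pd.DataFrame  # iterations in which both were drawn
    k: int
    iterations: int
    item_fraction: float
    feature_fraction: float


def consensus_matrix(
    data: pd.DataFrame,
    k: int,
    iterations: int = 1000,
    item_fraction: float = 0.8,
    feature_fraction: float = 0.8,
    seed: int = 0,
    n_restarts: int = 10,
) -> ConsensusResult:
    """Consensus matrix over repeated subsampled k-means runs.

    ``data`` is items (samples) x features.  Features are standardized within
    each subsample.  k-means uses k-means++ starts with ``n_restarts``
    restarts per iteration and a per-iteration seed stream, so the whole
    procedure is deterministic for a fixed ``seed``.
    """
    if k < 2:
        raise InputContractError("k must be >= 2")
    if iterations < 1:
        raise InputContractError("iterations must be >= 1")
    if not (0.0 < item_fraction <= 1.0 and 0.0 < feature_fraction <= 1.0):
        raise InputContractError("subsampling fractions must lie in (0, 1]")
    n, p = data.shape
    n_items = int(np.floor(item_fraction * n))
    n_feats = max(1, int(np.floor(feature_fraction * p)))
    if n_items < k:
        raise InputContractError(f"subsample of {n_items} items cannot hold k={k} clusters")

    x = data.to_numpy(dtype=float)
    rng = stream(seed, "consensus")
    co_clustered = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(iterations):
        items = np.sort(rng.choice(n, size=n_items, replace=False))
        feats = np.sort(rng.choice(p, size=n_feats, replace=False))
        sub = x[np.ix_(items, feats)]
        sd = sub.std(axis=0)
        sd[sd == 0.0] = 1.0
        sub = (sub - sub.mean(axis=0)) / sd
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            tol=1e-6,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(sub)
        lab = km.labels_
        co_sampled[np.ix_(items, items)] += 1.0
        same = lab[:, None] == lab[None, :]
        co_clustered[np.ix_(items, items)] += same
    never = co_sampled == 0
    if never.any() and n > 1:
        off = never.copy()
        np.fill_diagonal(off, False)
        if off.any():
            log.warning("consensus_matrix: %d pairs never co-sampled (consensus set to 0)",
                        off.sum() // 2)
    cons = np.divide(co_clustered, co_sampled, out=np.zeros((n, n)), where=~never)
    ids = data.index
    return ConsensusResult(
        consensus=pd.DataFrame(cons, index=ids, columns=ids),
        co_sampled_counts=pd.DataFrame(co_sampled, index=ids, columns=ids),
        k=k,
        iterations=iterations,
        item_fraction=item_fraction,
        feature_fraction=feature_fraction,
    )


def cut_consensus(result: ConsensusResult, k: int | None = None) -> pd.Series:
    """Complete-linkage clustering of 1 - consensus cut into k clusters.

    Labels 1..k are ordered by decreasing cluster size.
    """
    if k is None:
        k = result.k
    cons = result.consensus.to_numpy()
    n = cons.shape[0]
    if k > n:
        raise InputContractError(f"k={k} exceeds sample count {n}")
    d = 1.0 - cons
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = linkage(squareform(d, checks=False), method="complete")
    raw = fcluster(z, t=k, criterion="maxclust")
    order = pd.Series(raw).value_counts().index
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return pd.Series([mapping[r] for r in raw], index=result.consensus.index)


def consensus_cdf_report(data: pd.DataFrame, ks=range(2, 7), **kwargs) -> pd.DataFrame:
    """Informational consensus-CDF area and delta-area over a range of k.

    Reported for inspection only; the pipeline never auto-selects k from it.
    """
    rows, prev = [], None
    for k in ks:
        res = consensus_matrix(data, k=k, **kwargs)
        vals = res.consensus.to_numpy()[np.triu_indices(len(data), 1)]
        grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(np.sort(vals), grid, side="right") / max(1, len(vals))
        area = float(np.trapezoid(cdf, grid))
        rows.append({"k": k, "cdf_area": area,
                     "delta_area": area if prev is None else (area - prev) / prev})
        prev = area
    return pd.DataFrame(rows)


def stratify_module_signature(
    matrix: AbundanceMatrix,
    module_set: ModuleSet,
    module: int,
    n_top: int = 50,
    k: int = 2,
    iterations: int = 1000,
    item_fraction: float = 0.8,
    feature_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, list[str], ConsensusResult]:
    """Consensus-cluster samples on a module's top-kME signature.

    Takes the module's ``n_top`` highest-kME members, consensus-clusters the
    samples on those proteins, and names the clusters by mean signature
    abundance: for k=2 the labels are "high"/"low" (ECM-high/ECM-low style
    naming); otherwise "1".."k" in descending mean order.
    Returns (labels, signature protein list, consensus result).
    """
    size = int((module_set.assignments == module).sum())
    if size < n_top:
        log.warning("module %d has %d members < n_top=%d; using all", module, size, n_top)
    sig = hub_proteins(module_set, module, min(n_top, size))
    data = matrix.values.loc[sig].T  # samples x signature proteins
    res = consensus_matrix(
        data, k=k, iterations=iterations, item_fraction=item_fraction,
        feature_fraction=feature_fraction, seed=seed,
    )
    clusters = cut_consensus(res, k)
    mean_sig = data.mean(axis=1)
    cluster_means = mean_sig.groupby(clusters).mean().sort_values(ascending=False)
    if k == 2:
        names = ["high", "low"]
    else:
        names = [str(i + 1) for i in range(k)]
    mapping = {c: names[i] for i, c in enumerate(cluster_means.index)}
    labels = clusters.map(mapping)
    off = res.consensus.to_numpy()[np.triu_indices(len(labels), 1)]
    if len(off) and 0.05 < float(np.mean(off)) < 0.95 and float(np.std(off)) < 0.05:
        log.warning("stratify_module_signature: consensus looks unstable "
                    "(mean off-diagonal %.2f)", float(np.mean(off)))
    return labels, sig, res
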