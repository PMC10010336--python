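"""Two-group, multi-group and gene-set statistics used across the pipeline.

Wilcoxon rank-sum (exact by enumeration for small samples, tie-corrected
normal approximation otherwise), Kruskal-Wallis, Fisher's exact test,
Benjamini-Hochberg adjustment, Welch's t, differential expression tables and
hypergeometric over-representation against GMT gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceMatrix, InputContractError

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "fisher_exact_2x2",
    "welch_t",
    "bh_adjust",
    "differential_expression",
    "GeneSetCollection",
    "enrich_hypergeometric",
]

EXACT_WILCOXON_MAX_N = 12  # combined sample size for exact enumeration


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    extras: dict = field(default_factory=dict)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact by enumerating all C(n_x+n_y, n_x) group assignments when the
    combined size is <= 12 (ties handled by midranks, two-sided p by doubling
    the smaller tail, capped at 1); tie-corrected normal approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputContractError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[: x.size].sum())
    if pooled.size <= EXACT_WILCOXON_MAX_N:
        sums = np.array([ranks[list(c)].sum() for c in combinations(range(pooled.size), x.size)])
        lo = np.mean(sums <= w_obs + 1e-9)
        hi = np.mean(sums >= w_obs - 1e-9)
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(w_obs, float(p), "wilcoxon-exact", {"n_x": x.size, "n_y": y.size})
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(w_obs, float(res.pvalue), "wilcoxon-normal",
                      {"U": float(res.statistic), "n_x": x.size, "n_y": y.size})


def kruskal_wallis(values, groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square null on k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) < 2:
        raise InputContractError("need >= 2 groups")
    samples = [values[groups == g] for g in names]
    if np.ptp(values) == 0.0:
        return TestResult(0.0, 1.0, "kruskal-wallis", {"df": len(names) - 1})
    h, p = sps.kruskal(*samples)
    return TestResult(float(h), float(p), "kruskal-wallis", {"df": len(names) - 1})


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test (two-sided probability-mass rule) with sample OR."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise InputContractError("table must be a 2x2 array of nonnegative integers")
    a, b, c, d = t.ravel()
    _, p = sps.fisher_exact(t, alternative="two-sided")
    extras = {}
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
        extras["degenerate_or"] = True
    else:
        odds = a * d / (b * c)
    return TestResult(float(odds), float(p), "fisher-exact", extras)


def welch_t(x, y) -> TestResult:
    """Two-sample Welch's t test (unequal variances)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch-t",
                      {"df": float(res.df)})


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputContractError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: AbundanceMatrix, group_a, group_b
) -> pd.DataFrame:
    """Per-protein Wilcoxon DE table between two sample groups.

    log2FC is mean(group_a) - mean(group_b) on the (already log2) matrix;
    p-values are BH-adjusted across all tested proteins.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise InputContractError("groups overlap: " + str(sorted(set(group_a) & set(group_b))[:5]))
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputContractError("both groups need >= 2 samples")
    xa = matrix.values[group_a].to_numpy()
    xb = matrix.values[group_b].to_numpy()
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    pvals = np.array([
        wilcoxon_rank_sum(xa[i], xb[i]).p_value for i in range(matrix.shape[0])
    ])
    return pd.DataFrame({
        "protein_id": matrix.protein_ids,
        "log2fc": log2fc,
        "p": pvals,
        "p_adjusted": bh_adjust(pvals),
    }).set_index("protein_id")


@dataclass
class GeneSetCollection:
    """Named gene/protein sets (GMT-style) with an optional description."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputContractError(f"gene set {name!r} is empty")


def enrich_hypergeometric(
    query, universe, collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the query.

    For each set the p-value is the upper tail P(overlap >= k) when drawing
    |query| proteins from the universe containing |set ∩ universe| set
    members; BH adjustment across sets.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise InputContractError(f"query proteins outside universe: {sorted(stray)[:5]}")
    n_u, n_q = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        k = len(query & in_universe)
        p = float(sps.hypergeom.sf(k - 1, n_u, len(in_universe), n_q)) if in_universe else 1.0
        rows.append({"set": name, "set_size": len(in_universe), "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
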