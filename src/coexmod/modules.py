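"""Module characterization: eigenproteins, kME, hubs, trait tests and graphs.

A module eigenprotein (ME) is the first principal component of the module's
standardized protein x sample submatrix — the module's representative profile.
kME (module membership) is the Pearson correlation of an individual protein
with an ME; members with the highest kME are the intramodular hub proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kruskal

from .datatypes import AbundanceMatrix, InputContractError

__all__ = [
    "module_eigenproteins",
    "kme",
    "ModuleSet",
    "build_module_set",
    "hub_proteins",
    "me_trait_association",
    "sample_clusters",
    "module_graph",
]

log = logging.getLogger(__name__)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return (x - mu) / sd


def module_eigenproteins(matrix: AbundanceMatrix, assignments: pd.Series) -> pd.DataFrame:
    """First principal component per module, as a modules x samples matrix.

    Member rows are standardized (zero mean, unit sample variance); the first
    right singular vector is scaled to unit sample variance and sign-flipped
    so its mean correlation with member profiles is >= 0.  Row index is
    "M1".."Mk" in label order.
    """
    labels = assignments.reindex(matrix.protein_ids)
    mods = sorted(set(labels) - {0})
    rows = {}
    for m in mods:
        members = matrix.protein_ids[labels == m]
        x = _standardize_rows(matrix.values.loc[members].to_numpy())
        if x.shape[0] == 1:
            log.warning("module %s has a single protein; ME is its profile", m)
            rows[f"M{m}"] = x[0]
            continue
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        v = vt[0]
        v = v / v.std(ddof=1)
        if np.mean([np.corrcoef(v, row)[0, 1] for row in x]) < 0:
            v = -v
        rows[f"M{m}"] = v
    return pd.DataFrame(rows, index=matrix.sample_ids).T


def kme(matrix: AbundanceMatrix, eigenproteins: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every protein (assigned or not) with every ME."""
    x = matrix.to_numpy()
    me = eigenproteins.to_numpy()
    if x.shape[1] != me.shape[1]:
        raise InputContractError("matrix and eigenproteins have different sample counts")

    def _unit(rows: np.ndarray) -> np.ndarray:
        a = rows - rows.mean(axis=1, keepdims=True)
        n = np.linalg.norm(a, axis=1, keepdims=True)
        bad = n[:, 0] == 0.0
        if bad.any():
            log.warning("kme: %d constant proteins get kME 0", bad.sum())
            n[bad] = 1.0
        return a / n

    vals = np.clip(_unit(x) @ _unit(me).T, -1.0, 1.0)
    return pd.DataFrame(vals, index=matrix.protein_ids, columns=eigenproteins.index)


@dataclass
class ModuleSet:
    """Assignments plus the derived ME and kME matrices and module sizes."""

    assignments: pd.Series  # protein -> int label, 0 = unassigned
    eigenproteins: pd.DataFrame  # modules x samples
    kme: pd.DataFrame  # proteins x modules
    sizes: pd.Series  # "M1".. -> member count

    def members(self, module: int) -> pd.Index:
        return self.assignments.index[self.assignments == module]


def build_module_set(matrix: AbundanceMatrix, assignments: pd.Series) -> ModuleSet:
    me = module_eigenproteins(matrix, assignments)
    k = kme(matrix, me)
    sizes = pd.Series(
        {name: int((assignments == int(name[1:])).sum()) for name in me.index}
    )
    return ModuleSet(assignments=assignments, eigenproteins=me, kme=k, sizes=sizes)


def hub_proteins(module_set: ModuleSet, module: int, n: int) -> list[str]:
    """The n module members of highest kME to their own ME, descending.

    Ties broken by protein id; asking for more than the module holds returns
    all members with a warning.
    """
    if n < 1:
        raise InputContractError("n must be >= 1")
    members = module_set.members(module)
    if len(members) == 0:
        raise InputContractError(f"module {module} has no members")
    if n > len(members):
        log.warning("hub_proteins: n=%d exceeds module size %d", n, len(members))
        n = len(members)
    k = module_set.kme.loc[members, f"M{module}"]
    order = sorted(members, key=lambda p: (-k[p], p))
    return list(order[:n])


def me_trait_association(eigenproteins: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Kruskal-Wallis test of each ME across sample groups.

    Returns a table (module, H, p) using the tie-corrected H statistic with a
    chi-square null on (groups - 1) degrees of freedom.
    """
    groups = groups.reindex(eigenproteins.columns)
    names = groups.dropna().unique()
    if len(names) < 2 or any((groups == g).sum() < 2 for g in names):
        raise InputContractError("need >= 2 groups with >= 2 samples each")
    rows = []
    for mod in eigenproteins.index:
        vals = [eigenproteins.loc[mod, groups == g].to_numpy() for g in names]
        pooled = np.concatenate(vals)
        if np.ptp(pooled) == 0.0:
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*vals)
        rows.append({"module": mod, "H": float(h), "p": float(p)})
    return pd.DataFrame(rows)


def sample_clusters(
    matrix: AbundanceMatrix,
    k: int,
    method: str = "complete",
    distance: str = "pearson",
) -> pd.Series:
    """Hierarchical clustering of samples cut into k groups.

    Distance is 1 - Pearson correlation over proteins ("pearson") or
    euclidean; labels 1..k are ordered by decreasing cluster size.
    """
    if k < 2:
        raise InputContractError("k must be >= 2")
    n = matrix.shape[1]
    if k > n:
        raise InputContractError(f"k={k} exceeds sample count {n}")
    x = matrix.to_numpy().T  # samples x proteins
    if distance == "pearson":
        c = np.corrcoef(x)
        d = 1.0 - np.clip(c, -1.0, 1.0)
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method=method)
    else:
        z = linkage(x, method=method, metric=distance)
    raw = fcluster(z, t=k, criterion="maxclust")
    order = pd.Series(raw).value_counts().index
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return pd.Series([mapping[r] for r in raw], index=matrix.sample_ids)


def module_graph(
    matrix: AbundanceMatrix,
    module_set: ModuleSet,
    module: int,
    kme_min: float = 0.7,
    cor_min: float = 0.3,
    method: str = "pearson",
) -> nx.Graph:
    """Intramodular correlation graph of a module's high-kME proteins.

    Nodes are members with kME strictly above ``kme_min``; edges connect node
    pairs with pairwise correlation strictly above ``cor_min`` (edge weight =
    correlation).  Isolated nodes are retained; node degree is stored as a
    node attribute.
    """
    members = module_set.members(module)
    k = module_set.kme.loc[members, f"M{module}"]
    nodes = [p for p in members if k[p] > kme_min]
    g = nx.Graph(module=f"M{module}", kme_min=kme_min, cor_min=cor_min)
    if not nodes:
        log.warning("module_graph: no members exceed kME %.2f", kme_min)
        return g
    g.add_nodes_from(nodes)
    from .network import correlation_matrix

    c = correlation_matrix(matrix.subset_proteins(pd.Index(nodes)), method=method)
    arr = c.to_numpy()
    for i, pi in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            if arr[i, j] > cor_min:
                g.add_edge(pi, nodes[j], weight=float(arr[i, j]))
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    return g
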