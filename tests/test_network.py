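"""Network construction: bicor, adjacency, scale-free fit, TOM, tree cut."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from coexmod.datatypes import AbundanceMatrix, InputContractError
from coexmod.network import (bicor_pair, build_dendrogram, compute_tom,
                             correlation_matrix, cut_modules, detect_modules,
                             merge_modules, pick_soft_threshold,
                             scale_free_fit, signed_adjacency, trim_membership)
from coexmod.simulate import SimulationConfig, SurvivalConfig, generate_dataset


def _am(arr):
    arr = np.asarray(arr, dtype=float)
    return AbundanceMatrix(pd.DataFrame(
        arr, index=[f"P{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])]))


# ---------------------------------------------------------------------------
# bicor
# ---------------------------------------------------------------------------

def test_bicor_self_and_reflection():
    x = np.array([0.3, -1.2, 2.0, 0.7, -0.4])
    assert bicor_pair(x, x) == pytest.approx(1.0)
    assert bicor_pair(x, -x) == pytest.approx(-1.0)


def test_bicor_outlier_regression_value():
    """Frozen brute-force evaluation of the weight formula on outlier data."""
    x, y = [1, 2, 3, 4, 100], [1, 2, 3, 4, 5]
    b = bicor_pair(x, y)
    assert b == pytest.approx(0.7828107175223247, abs=1e-12)
    # down-weighting moves bicor toward the rank correlation (here 1.0)
    pearson = np.corrcoef(x, y)[0, 1]
    assert abs(b - 1.0) < abs(pearson - 1.0)


def test_bicor_matches_pearson_on_clean_gaussian():
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        assert abs(bicor_pair(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05


@given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
def test_bicor_invariant_under_positive_affine_maps(scale, shift):
    x = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 0.0, 2.2])
    y = np.array([0.7, -1.0, 0.2, 2.5, -2.0, 0.3, 1.8])
    assert bicor_pair(scale * x + shift, y) == pytest.approx(bicor_pair(x, y), abs=1e-9)


def test_bicor_contract_errors():
    with pytest.raises(InputContractError):
        bicor_pair([1, 2], [1, 2])
    with pytest.raises(InputContractError):
        bicor_pair([1, 2, 3], [1, 2])
    assert bicor_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0  # constant -> 0


def test_bicor_mad_zero_falls_back_to_pearson():
    # x has mad 0 but nonzero variance: one outlier off a constant base
    x = np.array([1.0, 1.0, 1.0, 1.0, 9.0])
    y = np.array([0.2, 0.4, 0.1, 0.3, 5.0])
    expect = bicor_pair(y, x)  # symmetric; both use x's Pearson fallback
    assert bicor_pair(x, y) == pytest.approx(expect)


# ---------------------------------------------------------------------------
# correlation matrix / adjacency
# ---------------------------------------------------------------------------

def test_correlation_matrix_identical_rows_and_pearson():
    base = np.random.default_rng(1).normal(size=6)
    m = _am([base, base, -base])
    c = correlation_matrix(m, "bicor")
    assert c.loc["P0", "P1"] == pytest.approx(1.0)
    assert c.loc["P0", "P2"] == pytest.approx(-1.0)
    mp = _am(np.random.default_rng(2).normal(size=(4, 7)))
    assert np.allclose(correlation_matrix(mp, "pearson").to_numpy(),
                       np.corrcoef(mp.to_numpy()), atol=1e-12)


def test_independent_noise_has_small_correlations():
    m = _am(np.random.default_rng(3).normal(size=(10, 1000)))
    c = correlation_matrix(m, "bicor").to_numpy()
    off = c[np.triu_indices(10, 1)]
    assert np.abs(off).max() < 0.15


def test_signed_adjacency_endpoints_and_identity():
    c = pd.DataFrame([[1.0, 0.0, -1.0], [0.0, 1.0, 0.5], [-1.0, 0.5, 1.0]],
                     index=list("abc"), columns=list("abc"))
    a12 = signed_adjacency(c, 12)
    assert a12.loc["a", "c"] == pytest.approx(0.0)
    assert a12.loc["a", "b"] == pytest.approx(0.5 ** 12)
    a1 = signed_adjacency(c, 1)
    assert np.allclose(a1.to_numpy()[np.triu_indices(3, 1)],
                       ((1 + c.to_numpy()) / 2)[np.triu_indices(3, 1)])
    with pytest.raises(InputContractError):
        signed_adjacency(c, 0.5)


# ---------------------------------------------------------------------------
# scale-free fit & soft threshold
# ---------------------------------------------------------------------------

def test_scale_free_fit_on_preferential_attachment():
    g = nx.barabasi_albert_graph(500, 3, seed=0)
    a = nx.to_numpy_array(g)
    ids = [str(i) for i in range(500)]
    r2, slope = scale_free_fit(pd.DataFrame(a, index=ids, columns=ids))
    assert slope < 0
    assert r2 >= 0.8


def test_scale_free_fit_degenerate_and_sign_convention():
    ids = [str(i) for i in range(25)]
    equal = pd.DataFrame(np.full((25, 25), 0.4), index=ids, columns=ids)
    r2, _ = scale_free_fit(equal)
    assert r2 == 0.0
    # frequency increasing with k (few low-, some mid-, many high-degree
    # nodes; rank-one weights give three distinct connectivity levels)
    w = np.concatenate([np.full(5, 0.1), np.full(15, 0.5), np.full(25, 1.0)])
    a = np.outer(w, w)
    np.fill_diagonal(a, 1.0)
    r2_inc, slope_inc = scale_free_fit(pd.DataFrame(a, index=[str(i) for i in range(45)],
                                                    columns=[str(i) for i in range(45)]))
    assert slope_inc > 0
    assert r2_inc <= 0


def test_pick_soft_threshold_rules(planted_dataset):
    _, matrix, _, _ = planted_dataset
    cor = correlation_matrix(matrix, "bicor")
    scan = pick_soft_threshold(cor)
    assert scan.chosen_beta in scan.table.beta.values
    # selection rule cross-check on the scan table itself
    hits = scan.table[scan.table.r_squared >= scan.r2_target]
    expect = int(hits.beta.iloc[0]) if len(hits) else \
        int(scan.table.beta.iloc[int(scan.table.r_squared.idxmax())])
    assert scan.chosen_beta == expect
    # a target below every candidate's index is hit immediately
    assert pick_soft_threshold(cor, r2_target=-1.0).chosen_beta == 1
    # mean connectivity decreases with beta
    mc = scan.table.mean_connectivity.to_numpy()
    assert (np.diff(mc) < 0).all()


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def _tom_bruteforce(a):
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(0)
    for _ in range(5):
        a = rng.uniform(0, 1, size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [str(i) for i in range(20)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        assert np.abs(compute_tom(adj).to_numpy() - _tom_bruteforce(a)).max() < 1e-10


def test_tom_trivial_cases():
    ids = ["a", "b"]
    pair = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=ids, columns=ids)
    assert compute_tom(pair).loc["a", "b"] == pytest.approx(1.0)
    ids4 = list("abcd")
    disc = pd.DataFrame(np.eye(4), index=ids4, columns=ids4)
    t = compute_tom(disc).to_numpy()
    assert np.allclose(t - np.eye(4), 0.0)


@given(arrays(float, (8, 8), elements=st.floats(0.0, 1.0)))
def test_tom_bounded_on_random_signed_adjacencies(raw):
    a = (raw + raw.T) / 2
    np.fill_diagonal(a, 1.0)
    ids = [str(i) for i in range(8)]
    t = compute_tom(pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
    assert (t >= 0.0).all() and (t <= 1.0 + 1e-12).all()
    assert np.allclose(t, t.T)


# ---------------------------------------------------------------------------
# dendrogram & modules
# ---------------------------------------------------------------------------

def test_dendrogram_two_perfect_blocks_and_heights_monotone():
    d = np.ones((6, 6))
    d[:3, :3] = 0.0
    d[3:, 3:] = 0.0
    np.fill_diagonal(d, 0.0)
    ids = [str(i) for i in range(6)]
    tom = pd.DataFrame(1.0 - d, index=ids, columns=ids)
    dend = build_dendrogram(tom)
    # four within-block merges at height 0 first, one final at 1
    assert np.allclose(dend.heights[:4], 0.0)
    assert dend.heights[-1] == pytest.approx(1.0)
    assert (np.diff(dend.heights) >= -1e-12).all()


def test_three_point_hand_linkage():
    d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
    ids = list("abc")
    dend = build_dendrogram(pd.DataFrame(1.0 - d, index=ids, columns=ids))
    assert dend.heights[0] == pytest.approx(0.1)
    assert dend.heights[1] == pytest.approx(0.85)  # average of 0.9 and 0.8
    assert sorted(dend.linkage[0, :2]) == [0, 1]


def test_single_protein_dendrogram_degenerate():
    tom = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
    dend = build_dendrogram(tom)
    assert dend.linkage.shape == (0, 4)
    lab = cut_modules(dend, min_size=1)
    assert list(lab) == [1]


def test_cut_two_planted_blocks_noise_free():
    d = np.ones((200, 200))
    d[:100, :100] = 0.0
    d[100:, 100:] = 0.0
    np.fill_diagonal(d, 0.0)
    ids = [f"P{i}" for i in range(200)]
    dend = build_dendrogram(pd.DataFrame(1.0 - d, index=ids, columns=ids))
    lab = cut_modules(dend, min_size=50)
    assert sorted(lab.value_counts().to_dict().items()) == [(1, 100), (2, 100)]


def test_min_size_larger_than_n_unassigns_everything():
    d = np.ones((4, 4)) - np.eye(4)
    ids = list("abcd")
    dend = build_dendrogram(pd.DataFrame(1.0 - d, index=ids, columns=ids))
    assert (cut_modules(dend, min_size=10) == 0).all()


def test_module_recovery_on_planted_factors(planted_dataset):
    _, matrix, _, truth = planted_dataset
    labels, scan = detect_modules(matrix)
    ari = adjusted_rand_score(truth.module_of_protein.values, labels.values)
    assert ari >= 0.9
    sizes = labels[labels != 0].value_counts()
    assert len(sizes) == 5


def test_pipeline_invariant_to_protein_permutation(planted_dataset):
    _, matrix, _, _ = planted_dataset
    labels, _ = detect_modules(matrix)
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(matrix.protein_ids))
    m2 = matrix.subset_proteins(pd.Index(perm))
    labels2, _ = detect_modules(m2)
    aligned = labels2.reindex(labels.index)
    assert adjusted_rand_score(labels.values, aligned.values) == pytest.approx(1.0)


def _factor_matrix(factors, sizes, noise, rng):
    rows = []
    for f, s in zip(factors, sizes):
        rows.append(f + noise * rng.normal(size=(s, len(f))))
    return _am(np.vstack(rows))


def test_merge_modules_identical_and_orthogonal():
    rng = np.random.default_rng(0)
    f1, f2 = rng.normal(size=(2, 40))
    m = _factor_matrix([f1, f1, f2], [30, 30, 30], 0.3, rng)
    lab = pd.Series([1] * 30 + [2] * 30 + [3] * 30, index=m.protein_ids)
    merged = merge_modules(lab, m)
    assert merged.nunique() == 2  # shared-factor pair merged
    lab_orth = pd.Series([1] * 30 + [2] * 60, index=m.protein_ids)
    assert merge_modules(lab_orth, m).nunique() == 2  # unchanged


def test_merge_modules_correlated_factor_pair():
    rng = np.random.default_rng(1)
    f1 = rng.normal(size=60)
    f2 = 0.95 * f1 + np.sqrt(1 - 0.95**2) * rng.normal(size=60)  # cor ~ 0.95
    f3 = rng.normal(size=60)
    m = _factor_matrix([f1, f2, f3], [30, 30, 30], 0.05, rng)
    lab = pd.Series([1] * 30 + [2] * 30 + [3] * 30, index=m.protein_ids)
    merged = merge_modules(lab, m, merge_height=0.15)
    assert merged.nunique() == 2
    assert merged.iloc[0] == merged.iloc[35]  # modules 1 and 2 joined


def test_trim_membership_drops_background_contamination():
    rng = np.random.default_rng(2)
    f = rng.normal(size=50)
    member_rows = f + 0.4 * rng.normal(size=(60, 50))
    noise_rows = rng.normal(size=(10, 50))
    m = _am(np.vstack([member_rows, noise_rows]))
    lab = pd.Series([1] * 70, index=m.protein_ids)  # noise wrongly assigned
    trimmed = trim_membership(lab, m, min_size=20)
    kept = trimmed[trimmed == 1].index
    members = {f"P{i}" for i in range(60)}
    # at most one noise protein can sneak past the kME floor by chance
    assert len(set(kept) - members) <= 1
    assert len(set(kept) & members) >= 55
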