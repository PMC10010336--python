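"""Eigenproteins, kME, hubs, trait association, sample clustering, graphs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmod.datatypes import AbundanceMatrix, InputContractError
from coexmod.modules import (build_module_set, hub_proteins, kme,
                             me_trait_association, module_eigenproteins,
                             module_graph, sample_clusters)


def _am(arr, prefix="P"):
    arr = np.asarray(arr, dtype=float)
    return AbundanceMatrix(pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])]))


def _assign(sizes, ids):
    lab = []
    for m, s in enumerate(sizes, start=1):
        lab += [m] * s
    return pd.Series(lab, index=ids)


def test_me_of_identical_profiles_is_the_profile():
    rng = np.random.default_rng(0)
    profile = rng.normal(size=20)
    m = _am(np.tile(profile, (5, 1)))
    me = module_eigenproteins(m, _assign([5], m.protein_ids))
    z = (profile - profile.mean()) / profile.std(ddof=1)
    assert np.allclose(me.loc["M1"].to_numpy(), z, atol=1e-8)
    # explained variance fraction is 1 for identical standardized members
    assert np.corrcoef(me.loc["M1"], profile)[0, 1] == pytest.approx(1.0)


def test_me_sign_convention_with_reflected_profiles():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    m = _am([x, x, -x])
    me = module_eigenproteins(m, _assign([3], m.protein_ids))
    v = me.loc["M1"].to_numpy()
    assert abs(np.corrcoef(v, x)[0, 1]) == pytest.approx(1.0)
    member_cors = [np.corrcoef(v, row)[0, 1] for row in m.to_numpy()]
    assert np.mean(member_cors) >= 0


def test_me_recovers_planted_factor(planted_dataset):
    _, matrix, _, truth = planted_dataset
    me = module_eigenproteins(matrix, truth.module_of_protein)
    for mod in range(1, 6):
        f = truth.factor_matrix.iloc[mod - 1].to_numpy()
        r2 = np.corrcoef(me.loc[f"M{mod}"], f)[0, 1] ** 2
        assert r2 >= 0.9


def test_me_unit_variance_rows(planted_dataset):
    _, matrix, _, truth = planted_dataset
    me = module_eigenproteins(matrix, truth.module_of_protein)
    assert np.allclose(me.std(axis=1, ddof=1), 1.0, atol=1e-10)


def test_me_maximal_variance_against_random_directions(planted_dataset):
    """ME explains at least as much member variance as random unit directions."""
    _, matrix, _, truth = planted_dataset
    me = module_eigenproteins(matrix, truth.module_of_protein)
    members = matrix.values[truth.module_of_protein == 1]
    x = members.to_numpy()
    x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)

    def explained(direction):
        d = (direction - direction.mean()) / np.linalg.norm(direction - direction.mean())
        return float(((x @ d) ** 2).sum())

    e_me = explained(me.loc["M1"].to_numpy())
    rng = np.random.default_rng(0)
    for _ in range(100):
        assert e_me >= explained(rng.normal(size=x.shape[1]))


def test_kme_identity_noise_and_specificity(planted_dataset):
    _, matrix, _, truth = planted_dataset
    me = module_eigenproteins(matrix, truth.module_of_protein)
    # protein equal to an ME
    probe = AbundanceMatrix(pd.DataFrame([me.loc["M1"]], index=["probe"]))
    assert kme(probe, me).loc["probe", "M1"] == pytest.approx(1.0)
    # pure-noise protein with many samples stays near zero for all modules
    rng = np.random.default_rng(0)
    me_wide = pd.DataFrame(rng.normal(size=(3, 500)),
                           index=["M1", "M2", "M3"]).rename_axis(None)
    noise = AbundanceMatrix(pd.DataFrame(rng.normal(size=(1, 500)), index=["n"]))
    assert np.abs(kme(noise, me_wide).to_numpy()).max() < 0.15
    # members correlate more with their own module than with others
    k = kme(matrix, me)
    for mod in range(1, 6):
        members = truth.module_of_protein.index[truth.module_of_protein == mod]
        own = k.loc[members, f"M{mod}"]
        others = k.loc[members].drop(columns=f"M{mod}")
        assert (own.to_numpy()[:, None] > others.to_numpy()).mean() > 0.95


def test_kme_equals_direct_pearson_formula(planted_dataset):
    _, matrix, _, truth = planted_dataset
    me = module_eigenproteins(matrix, truth.module_of_protein)
    k = kme(matrix, me)
    rng = np.random.default_rng(1)
    for i in rng.choice(matrix.shape[0], 20, replace=False):
        for m in range(me.shape[0]):
            direct = np.corrcoef(matrix.to_numpy()[i], me.to_numpy()[m])[0, 1]
            assert k.iloc[i, m] == pytest.approx(direct, abs=1e-12)


def test_hub_proteins_ordering_and_bounds(planted_dataset):
    _, matrix, _, truth = planted_dataset
    mset = build_module_set(matrix, truth.module_of_protein)
    top = hub_proteins(mset, 1, 50)
    assert len(top) == 50
    kvals = mset.kme.loc[top, "M1"].to_numpy()
    assert (np.diff(kvals) <= 1e-12).all()  # descending
    size = int(mset.sizes["M1"])
    assert len(hub_proteins(mset, 1, size)) == size
    assert len(hub_proteins(mset, 1, size + 10)) == size  # clipped with warning
    with pytest.raises(InputContractError):
        hub_proteins(mset, 1, 0)


def test_hub_protein_equal_to_factor_ranks_first():
    rng = np.random.default_rng(2)
    f = rng.normal(size=40)
    rows = [f] + [f + 0.8 * rng.normal(size=40) for _ in range(9)]
    m = _am(rows)
    mset = build_module_set(m, _assign([10], m.protein_ids))
    assert hub_proteins(mset, 1, 1) == ["P0"]


def test_me_trait_association_hand_value_and_power():
    # two groups {1,2,3} vs {4,5,6}: H = 3.857 (rank formula, no ties)
    me = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["M1"],
                      columns=[f"S{j}" for j in range(6)]).astype(float)
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=me.columns)
    out = me_trait_association(me, groups)
    assert out.loc[0, "H"] == pytest.approx(3.857142857, abs=1e-6)
    # three clearly shifted groups reach p < 0.001
    rng = np.random.default_rng(3)
    shifted = np.concatenate([rng.normal(2, 1, 15), rng.normal(0, 1, 15),
                              rng.normal(-2, 1, 15)])
    me2 = pd.DataFrame([shifted], index=["M1"],
                       columns=[f"S{j}" for j in range(45)])
    groups2 = pd.Series(["a"] * 15 + ["b"] * 15 + ["c"] * 15, index=me2.columns)
    assert me_trait_association(me2, groups2).loc[0, "p"] < 0.001


def test_me_trait_association_contract():
    me = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["M1"],
                      columns=["S0", "S1", "S2", "S3"])
    groups = pd.Series(["a", "a", "b", "b"], index=me.columns)
    out = me_trait_association(me, groups)  # identical pooled values
    assert out.loc[0, "H"] == 0.0 and out.loc[0, "p"] == 1.0
    with pytest.raises(InputContractError):
        me_trait_association(me, pd.Series(["a"] * 4, index=me.columns))


def test_sample_clusters_separable_and_degenerate():
    rng = np.random.default_rng(4)
    a = rng.normal(size=30)
    b = rng.normal(size=30) + 5
    m = _am(np.column_stack([a, a, a, b, b, b]))
    lab = sample_clusters(m, k=2)
    assert lab.nunique() == 2
    assert lab.iloc[:3].nunique() == 1 and lab.iloc[3:].nunique() == 1
    singletons = sample_clusters(m, k=6)
    assert singletons.nunique() == 6
    with pytest.raises(InputContractError):
        sample_clusters(m, k=7)


def test_sample_clusters_recover_groups():
    """Groups with distinct +/-1.5 module-shift patterns are recovered."""
    from coexmod.simulate import SimulationConfig, generate_dataset

    shifts = [[1.5, 1.5, 1.5, -1.5, -1.5],
              [-1.5, 1.5, -1.5, 1.5, -1.5],
              [-1.5, -1.5, 1.5, 1.5, 1.5]]
    cfg = SimulationConfig(
        n_proteins=600, n_samples=60, module_sizes=[150, 120, 100, 80, 60],
        kme_target=0.8, group_shifts=shifts, seed=1)
    matrix, _, truth = generate_dataset(cfg)
    lab = sample_clusters(matrix, k=3)
    ari = adjusted_rand_score(truth.group_of_sample.values, lab.values)
    assert ari >= 0.9


def test_module_graph_thresholds_and_complete_case():
    rng = np.random.default_rng(5)
    f = rng.normal(size=100)
    rows = [f + 0.2 * rng.normal(size=100) for _ in range(4)]
    rows.append(rng.normal(size=100))  # low-kME member
    m = _am(rows)
    mset = build_module_set(m, _assign([5], m.protein_ids))
    g = module_graph(m, mset, 1, kme_min=0.7, cor_min=0.3)
    assert "P4" not in g  # kME below threshold -> excluded
    assert g.number_of_nodes() == 4
    assert g.number_of_edges() == 6  # complete K4
    assert all(d == 3 for _, d in g.nodes(data="degree"))
    assert all(w > 0.3 for _, _, w in g.edges(data="weight"))
    # strict inequality: nothing at or below the correlation floor
    g_high = module_graph(m, mset, 1, kme_min=0.7, cor_min=0.9999)
    assert g_high.number_of_edges() == 0
    assert g_high.number_of_nodes() == 4  # isolated nodes retained
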