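"""AMOVA, pairwise PhiST, permutation tests, and MDS."""

import numpy as np
import pandas as pd
import pytest

from mitolineage import structure as st
from mitolineage.refio import VariantProfile

from conftest import make_profile, random_canonical_variants


# ---------------------------------------------------------------------------
# distances


def test_identical_profiles_zero_matrix(ref):
    ps = [make_profile(ref, f"s{i}", ["73"]) for i in range(3)]
    dm = st.distance_matrix(ps)
    assert np.all(dm.d == 0)


def test_disjoint_singletons_distance_two(ref):
    dm = st.distance_matrix([make_profile(ref, "a", ["73"]),
                             make_profile(ref, "b", ["263"])])
    assert dm.d[0, 1] == 2


def test_distance_matrix_matches_pair_loop(ref):
    rng = np.random.default_rng(17)
    ps = [VariantProfile(sample_id=f"s{i}", variants=tuple(
        random_canonical_variants(ref, rng, 0, 10, allow_indels=False)))
        for i in range(12)]
    dm = st.distance_matrix(ps)
    for i in range(12):
        for j in range(12):
            di = {v.position: v.derived_state for v in ps[i].variants}
            dj = {v.position: v.derived_state for v in ps[j].variants}
            brute = sum(1 for p in set(di) | set(dj) if di.get(p) != dj.get(p))
            assert dm.d[i, j] == brute


# ---------------------------------------------------------------------------
# AMOVA


def _dm(d, ids=None):
    return st.DistanceMatrix(ids=ids or [f"s{i}" for i in range(len(d))],
                             d=np.asarray(d, dtype=float))


def test_amova_hand_worked_two_by_two():
    """Within A: 2; within B: 4; between: all 10 -> sigma_a=3.5, sigma_c=1.5."""
    d = np.zeros((4, 4))
    d[0, 1] = d[1, 0] = 2
    d[2, 3] = d[3, 2] = 4
    d[np.ix_([0, 1], [2, 3])] = 10
    d[np.ix_([2, 3], [0, 1])] = 10
    res = st.amova(_dm(d), ["A", "A", "B", "B"], n_perm=0)
    assert res.variance_components["among_populations"] == pytest.approx(3.5)
    assert res.variance_components["within_populations"] == pytest.approx(1.5)
    assert res.phi_statistics["Phi_ST"] == pytest.approx(0.7)
    assert sum(res.percent_variation.values()) == pytest.approx(100.0)


def test_fixed_difference_limit(ref):
    ps = ([make_profile(ref, f"a{i}", ["73"]) for i in range(6)]
          + [make_profile(ref, f"b{i}", ["263", "750"]) for i in range(6)])
    dm = st.distance_matrix(ps)
    res = st.amova(dm, ["A"] * 6 + ["B"] * 6, n_perm=99, seed=0)
    assert res.phi_statistics["Phi_ST"] == pytest.approx(1.0)
    assert res.percent_variation["within_populations"] == pytest.approx(0.0)
    assert res.p_values["Phi_ST"] == pytest.approx(1 / 100)


def test_null_case_phi_near_zero(ref):
    rng = np.random.default_rng(23)
    ps = [VariantProfile(sample_id=f"s{i}", variants=tuple(
        random_canonical_variants(ref, rng, 3, 12, allow_indels=False)))
        for i in range(20)]
    dm = st.distance_matrix(ps)
    res = st.amova(dm, ["A"] * 10 + ["B"] * 10, n_perm=200, seed=1)
    assert abs(res.phi_statistics["Phi_ST"]) < 0.15
    assert res.p_values["Phi_ST"] > 0.05


def test_singleton_population_rejected():
    d = np.ones((3, 3)) - np.eye(3)
    with pytest.raises(st.StructureError, match="singleton"):
        st.amova(_dm(d), ["A", "A", "B"], n_perm=0)


def test_two_level_amova_reproduces_pairwise_phist(ref):
    rng = np.random.default_rng(31)
    ps = [VariantProfile(sample_id=f"s{i}", variants=tuple(
        random_canonical_variants(ref, rng, 1, 10, allow_indels=False)))
        for i in range(14)]
    pops = ["A"] * 5 + ["B"] * 5 + ["C"] * 4
    dm = st.distance_matrix(ps)
    phist, _ = st.pairwise_phist(dm, pops, n_perm=0)
    for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
        idx = [i for i, p in enumerate(pops) if p in (a, b)]
        sub = st.DistanceMatrix(ids=[dm.ids[i] for i in idx],
                                d=dm.d[np.ix_(idx, idx)])
        res = st.amova(sub, [pops[i] for i in idx], n_perm=0)
        assert phist.loc[a, b] == pytest.approx(
            res.phi_statistics["Phi_ST"], abs=1e-12)


def test_permutation_pvalues_invariant_to_row_order():
    rng = np.random.default_rng(9)
    n = 12
    base = rng.integers(0, 8, size=(n, n)).astype(float)
    d = np.triu(base, 1)
    d = d + d.T
    ids = [f"s{i}" for i in range(n)]
    pops = ["A"] * 6 + ["B"] * 6
    res1 = st.amova(_dm(d, ids), pops, n_perm=300, seed=4)
    order = rng.permutation(n)
    res2 = st.amova(_dm(d[np.ix_(order, order)],
                        [ids[i] for i in order]),
                    [pops[i] for i in order], n_perm=300, seed=4)
    assert res1.p_values == res2.p_values
    assert res1.phi_statistics["Phi_ST"] == pytest.approx(
        res2.phi_statistics["Phi_ST"])


def test_phi_invariant_to_shared_variants(ref):
    rng = np.random.default_rng(13)
    base = [random_canonical_variants(ref, rng, 1, 6, allow_indels=False)
            for _ in range(8)]
    shared = random_canonical_variants(ref, rng, 3, 3, allow_indels=False)
    used = {v.position for vs in base for v in vs}
    shared = [v for v in shared if v.position not in used]
    ps1 = [VariantProfile(sample_id=f"s{i}", variants=tuple(vs))
           for i, vs in enumerate(base)]
    ps2 = [VariantProfile(sample_id=f"s{i}", variants=tuple(vs) + tuple(shared))
           for i, vs in enumerate(base)]
    pops = ["A"] * 4 + ["B"] * 4
    r1 = st.amova(st.distance_matrix(ps1), pops, n_perm=0)
    r2 = st.amova(st.distance_matrix(ps2), pops, n_perm=0)
    assert r1.phi_statistics["Phi_ST"] == pytest.approx(
        r2.phi_statistics["Phi_ST"], abs=1e-12)


def test_three_level_amova_components_sum():
    rng = np.random.default_rng(77)
    n = 16
    pts = rng.normal(size=(n, 4))
    pts[:8] += 3.0
    d = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
    np.fill_diagonal(d, 0)
    pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4
    groups = ["G1"] * 8 + ["G2"] * 8
    res = st.amova(_dm(d), pops, groups=groups, n_perm=50, seed=2)
    assert set(res.phi_statistics) == {"Phi_CT", "Phi_SC", "Phi_ST"}
    assert sum(res.percent_variation.values()) == pytest.approx(100.0)
    assert res.phi_statistics["Phi_CT"] > 0.2  # groups are truly separated


# ---------------------------------------------------------------------------
# MDS


def test_mds_exact_one_dimensional_configuration():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    D = np.abs(x[:, None] - x[None, :])
    emb = st.mds(D, seed=0)
    assert emb.stress <= 1e-6
    # collinear up to rotation/reflection: smallest singular value ~ 0
    s = np.linalg.svd(emb.coords - emb.coords.mean(0), compute_uv=False)
    assert s[-1] < 1e-4 * max(1.0, s[0])


def test_mds_two_points_zero_stress():
    D = np.array([[0.0, 0.4], [0.4, 0.0]])
    emb = st.mds(D, seed=0)
    assert emb.stress <= 1e-12


def test_mds_close_to_reference_implementation():
    """Best-of-restarts stress within 1e-3 of sklearn's nonmetric MDS."""
    from sklearn.manifold import MDS

    rng = np.random.default_rng(5)
    for _ in range(2):
        P = rng.uniform(size=(6, 3))
        D = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
        D += rng.uniform(0, 0.05, size=D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        emb = st.mds(D, seed=1, restarts=10)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            m = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                    n_init=10, random_state=0, normalized_stress=True,
                    max_iter=500, eps=1e-9)
            m.fit(D)
        assert emb.stress <= m.stress_ + 1e-3


def test_mds_clamps_negative_entries_with_warning():
    D = np.array([[0.0, -0.01, 0.5], [-0.01, 0.0, 0.4], [0.5, 0.4, 0.0]])
    with pytest.warns(UserWarning, match="clamped"):
        emb = st.mds(D, seed=0)
    assert emb.stress >= 0


def test_mds_rejects_asymmetric_input():
    D = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(st.StructureError):
        st.mds(D, seed=0)


def test_mds_coordinates_centered():
    rng = np.random.default_rng(2)
    P = rng.uniform(size=(7, 2))
    D = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
    emb = st.mds(D, seed=0)
    assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)
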