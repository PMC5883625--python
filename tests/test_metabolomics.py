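"""Metabolome statistics: normalization, scaling, PCA, PLS-DA VIP, t/FDR,
fold changes, selection and clustering — each against a hand computation or
an independently coded oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmaflux.metabolomics import (
    IntensityTable,
    bh_fdr,
    fold_change,
    hierarchical_clustering,
    normalize_by_internal_standard,
    pca,
    plsda_vip,
    run_differential_analysis,
    select_differential,
    two_sample_t,
    uv_scale,
)
from pmaflux.synth import MetabolomeSpec, gen_metabolome


def _small_table(values: np.ndarray, standards=()) -> IntensityTable:
    n_met, n_smp = values.shape
    met_ids = [f"M{i}" for i in range(n_met - len(standards))] + list(standards)
    samples = [f"s{i}" for i in range(n_smp)]
    half = n_smp // 2
    design = pd.DataFrame(
        {
            "carbon_source": ["glucose"] * half + ["sucrose"] * (n_smp - half),
            "timepoint_h": [48] * n_smp,
            "replicate": list(range(1, half + 1)) + list(range(1, n_smp - half + 1)),
        },
        index=samples,
    )
    return IntensityTable(
        values=pd.DataFrame(values, index=met_ids, columns=samples),
        design=design,
        internal_standard_ids=tuple(standards),
    )


# ------------------------------------------------------------- normalization


def test_normalization_is_scale_invariant_per_sample():
    base = np.array([[10.0, 10.0], [5.0, 5.0], [2.0, 2.0]])
    table = _small_table(base, standards=("IS1",))
    scaled_col = base.copy()
    scaled_col[:, 1] *= 3.0  # triple one injection, standards included
    table3 = _small_table(scaled_col, standards=("IS1",))
    a = normalize_by_internal_standard(table).values
    b = normalize_by_internal_standard(table3).values
    pd.testing.assert_frame_equal(a, b)


def test_normalization_recovers_planted_injection_factors():
    factors = (1.0, 2.5, 0.4, 1.3, 0.9, 1.8, 1.0, 1.0, 0.7, 1.2, 2.0, 0.5,
               1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    spec = MetabolomeSpec(seed=3, sigma_log=0.0, injection_factors=factors)
    table, _ = gen_metabolome(spec)
    normalized = normalize_by_internal_standard(table)
    # after normalization all replicate columns of a group are identical
    values = normalized.analyte_values()
    g48 = values[[c for c in values.columns if c.startswith("glucose_48")]]
    assert np.allclose(g48.to_numpy(), g48.to_numpy()[:, [0]], rtol=1e-12)


def test_normalization_requires_standards():
    table = _small_table(np.ones((2, 2)) * 3.0)
    with pytest.raises(ValueError, match="internal standards"):
        normalize_by_internal_standard(table)


# ------------------------------------------------------------------- scaling


def test_uv_scale_hand_example_and_unit_variance():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [10.0, 30.0, 20.0]], index=["a", "b"],
        columns=["s1", "s2", "s3"],
    )
    scaled = uv_scale(frame)
    assert np.allclose(scaled.loc["a"], [-1.0, 0.0, 1.0])  # sd(1,2,3) = 1
    assert np.allclose(scaled.var(axis=1, ddof=1), 1.0, atol=1e-12)
    assert np.allclose(scaled.mean(axis=1), 0.0, atol=1e-12)


def test_uv_scale_drops_constant_rows_with_warning():
    frame = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
    with pytest.warns(UserWarning, match="flat"):
        scaled = uv_scale(frame)
    assert list(scaled.index) == ["ok"]
    with pytest.raises(ValueError):
        uv_scale(frame[[0]])


# ----------------------------------------------------------------------- PCA


def test_pca_perfectly_correlated_rows():
    rng = np.random.default_rng(0)
    x = rng.normal(size=8)
    frame = pd.DataFrame([x, 2 * x], index=["a", "b"])
    scaled = uv_scale(frame)
    result = pca(scaled)
    ev = result.explained_variance
    assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-12)


def test_pca_reconstruction_and_orthonormal_loadings():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(rng.normal(size=(6, 10)))
    scaled = uv_scale(frame)
    result = pca(scaled)
    L = result.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
    recon = result.scores.to_numpy() @ L.T  # samples × metabolites
    assert np.allclose(recon, scaled.to_numpy().T, atol=1e-8)
    # explained variances are non-increasing and sum to the total variance
    ev = result.explained_variance
    assert (np.diff(ev) <= 1e-12).all()
    assert ev.sum() == pytest.approx(
        scaled.var(axis=1, ddof=1).sum(), abs=1e-8
    )


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(2)
    frame = pd.DataFrame(rng.normal(size=(5, 9)))
    scaled = uv_scale(frame)
    a, b = pca(scaled), pca(scaled)
    pd.testing.assert_frame_equal(a.loadings, b.loadings)
    for col in a.loadings:
        j = a.loadings[col].abs().idxmax()
        assert a.loadings.loc[j, col] > 0


# ------------------------------------------------------------------- PLS VIP


def test_vip_single_metabolite_is_one():
    frame = pd.DataFrame([[1.0, -1.0, 2.0, -2.0]], index=["only"])
    scaled = uv_scale(frame)
    vip = plsda_vip(scaled, np.array(["A", "A", "B", "B"]), n_components=1)
    assert vip["only"] == pytest.approx(1.0, abs=1e-12)


def test_vip_duplicated_rows_get_equal_scores():
    rng = np.random.default_rng(3)
    x = rng.normal(size=8)
    frame = pd.DataFrame([x, x, rng.normal(size=8)], index=["a", "a2", "c"])
    scaled = uv_scale(frame)
    labels = np.array(["A"] * 4 + ["B"] * 4)
    vip = plsda_vip(scaled, labels)
    assert vip["a"] == pytest.approx(vip["a2"], abs=1e-10)


def test_vip_against_single_component_covariance_oracle():
    """One informative and one pure-noise metabolite: the single-component
    VIP follows directly from the covariance weights w ∝ X'y,
    VIP_j = sqrt(p·w_j²/Σw²) — computed here without the NIPALS code path."""
    rng = np.random.default_rng(4)
    labels = np.array(["A"] * 5 + ["B"] * 5)
    informative = np.where(labels == "B", 1.0, -1.0) + 0.05 * rng.normal(size=10)
    noise = rng.normal(size=10)
    frame = pd.DataFrame([informative, noise], index=["inf", "noise"])
    scaled = uv_scale(frame)
    y = np.where(labels == "B", 1.0, 0.0)
    y = y - y.mean()
    w = scaled.to_numpy() @ y  # oracle: covariance weights
    vip_oracle = np.sqrt(2 * w**2 / (w**2).sum())
    vip = plsda_vip(scaled, labels, n_components=1)
    assert vip["inf"] > 1 > vip["noise"]
    assert np.allclose(vip.to_numpy(), vip_oracle, atol=1e-10)


def test_vip_matches_sklearn_weights_on_first_component():
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(5)
    frame = pd.DataFrame(rng.normal(size=(7, 12)))
    frame.iloc[0] += np.repeat([0.0, 2.0], 6)
    scaled = uv_scale(frame)
    labels = np.repeat(["A", "B"], 6)
    vip = plsda_vip(scaled, labels, n_components=1)
    pls = sklearn.PLSRegression(n_components=1, scale=False)
    X = scaled.to_numpy().T
    y = (labels == "B").astype(float)
    pls.fit(X, y - y.mean())
    w = pls.x_weights_[:, 0]
    vip_ref = np.sqrt(len(w) * w**2 / (w**2).sum())
    assert np.allclose(vip.to_numpy(), vip_ref, atol=1e-8)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_vip_squared_sums_to_p(seed):
    rng = np.random.default_rng(seed)
    p, n = int(rng.integers(2, 30)), 2 * int(rng.integers(2, 7))
    frame = pd.DataFrame(rng.normal(size=(p, n)))
    scaled = uv_scale(frame)
    labels = np.repeat(["A", "B"], n // 2)
    vip = plsda_vip(scaled, labels, n_components=2)
    assert (vip.to_numpy() ** 2).sum() == pytest.approx(len(scaled), rel=1e-6)


def test_vip_input_validation():
    frame = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 6)))
    scaled = uv_scale(frame)
    with pytest.raises(ValueError, match="two groups"):
        plsda_vip(scaled, np.array(["A"] * 6))
    with pytest.raises(ValueError, match="fewer than 2"):
        plsda_vip(scaled, np.array(["A", "B", "B", "B", "B", "B"]))
    with pytest.warns(UserWarning, match="truncated"):
        plsda_vip(scaled, np.repeat(["A", "B"], 3), n_components=10)


# ------------------------------------------------------------------- t tests


def test_t_statistic_textbook_example():
    a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"])
    b = pd.DataFrame([[2.0, 3.0, 4.0]], index=["m"])
    out = two_sample_t(a, b)
    assert out.loc["m", "t_statistic"] == pytest.approx(-1.224745, abs=1e-5)
    assert out.loc["m", "p_value"] == pytest.approx(0.2879, abs=1e-4)
    # swapped order negates t, keeps p
    rev = two_sample_t(b, a)
    assert rev.loc["m", "t_statistic"] == pytest.approx(1.224745, abs=1e-5)
    assert rev.loc["m", "p_value"] == out.loc["m", "p_value"]


def test_t_degenerate_and_identical_groups():
    same = pd.DataFrame([[5.0, 5.0, 5.0]], index=["m"])
    with pytest.warns(UserWarning, match="zero pooled variance"):
        out = two_sample_t(same, same)
    assert out.loc["m", "t_statistic"] == 0.0
    assert out.loc["m", "p_value"] == 1.0
    ident = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"])
    out = two_sample_t(ident, ident.copy())
    assert out.loc["m", "t_statistic"] == pytest.approx(0.0)
    assert out.loc["m", "p_value"] == pytest.approx(1.0)


# -------------------------------------------------------------------- BH FDR


def test_bh_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([0.123]) == pytest.approx([0.123])
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_is_monotone_and_never_below_p(ps):
    p = np.asarray(ps)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


# -------------------------------------------------------------- fold changes


def test_fold_change_basics():
    values = np.array([[2.0, 2.0, 8.0, 8.0], [3.0, 3.0, 3.0, 3.0]])
    table = _small_table(values)
    fc = fold_change(table, "glucose_48", "sucrose_48")
    assert fc["M0"] == pytest.approx(2.0)  # 4-fold -> log2 = 2
    assert fc["M1"] == pytest.approx(0.0)
    with pytest.raises(KeyError):
        fold_change(table, "glucose_48", "mystery_99")


def test_fold_change_recovers_planted_ratio():
    """A 1.84-fold planted increase is recovered as log2(1.84) ≈ 0.88 up to
    replicate sampling noise."""
    effect = float(np.log2(1.84))
    spec = MetabolomeSpec(seed=11, sigma_log=0.1,
                          planted_effects={("M001", "sucrose_48"): effect})
    table, _ = gen_metabolome(spec)
    fc = fold_change(normalize_by_internal_standard(table),
                     "glucose_48", "sucrose_48")
    assert fc["M001"] == pytest.approx(effect, abs=0.25)
    spec0 = MetabolomeSpec(seed=11, sigma_log=0.0, injection_sigma_log=0.0,
                           planted_effects={("M001", "sucrose_48"): 2.0})
    table0, _ = gen_metabolome(spec0)
    fc0 = fold_change(table0, "glucose_48", "sucrose_48")
    assert fc0["M001"] == pytest.approx(2.0, abs=1e-12)


# ----------------------------------------------------------------- selection


def test_selection_rule_combines_three_criteria():
    idx = pd.Index(["a", "b", "c", "d"])
    fc = pd.Series([1.0, 1.0, 1.0, 1.0], index=idx)
    t = pd.DataFrame(
        {"t_statistic": [3.0, 3.0, 1.0, 3.0],
         "p_value": [0.001, 0.04, 0.50, 0.002]},
        index=idx,
    )
    vip = pd.Series([1.2, 0.9, 1.5, 1.8], index=idx)
    means = pd.Series([1.0] * 4, index=idx)
    res = select_differential(fc, t, vip, means, means, "A", "B")
    q = res.table["q_value"]
    assert (q >= res.table["p_value"] - 1e-15).all()
    assert bool(res.table.loc["a", "selected"])  # p, q, VIP all pass
    assert not res.table.loc["b", "selected"]  # VIP fails
    assert not res.table.loc["c", "selected"]  # p fails
    mismatched = vip.rename(index={"a": "z"})
    with pytest.raises(ValueError, match="different metabolite set"):
        select_differential(fc, t, mismatched, means, means, "A", "B")


def test_pipeline_is_equivariant_to_metabolite_rescaling():
    """Multiplying a raw metabolite row by a constant changes nothing
    downstream: UV scaling, VIP, t on logs and the selection flags are all
    scale-free in each row."""
    spec = MetabolomeSpec(seed=21, n_metabolites=30).with_planted(6, 2.0)
    table, _ = gen_metabolome(spec)
    res_a = run_differential_analysis(table, "glucose_48", "sucrose_48")
    values = table.values.copy()
    values.loc["M003"] *= 137.0
    table_b = IntensityTable(values, table.design, table.internal_standard_ids)
    res_b = run_differential_analysis(table_b, "glucose_48", "sucrose_48")
    for col in ("t_statistic", "p_value", "q_value", "vip"):
        assert np.allclose(res_a.table[col], res_b.table[col], atol=1e-8), col
    assert (res_a.table["selected"] == res_b.table["selected"]).all()
    # the fold change of the rescaled metabolite shifts by log2(137)
    assert res_b.table.loc["M003", "fold_change_log2"] == pytest.approx(
        res_a.table.loc["M003", "fold_change_log2"], abs=1e-8
    )


# ---------------------------------------------------------------- clustering


def _naive_ward(points: np.ndarray):
    """O(n³) agglomeration with the Lance–Williams Ward update, ties to the
    lowest-index pair — written independently of scipy."""
    n = len(points)
    active = {i: (1, i) for i in range(n)}  # cluster id -> (size, label)
    # pairwise squared distances seeded from the points
    import itertools

    d = {}
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = float(np.sum((points[i] - points[j]) ** 2))
    merges = []
    next_id = n
    sizes = {i: 1 for i in range(n)}
    while len(active) > 1:
        # Ward merge cost for clusters u, v is sqrt(2·|u||v|/(|u|+|v|)·d²)
        # with d² maintained by Lance–Williams; scipy reports the sqrt form
        best, pair = None, None
        for i, j in itertools.combinations(sorted(active), 2):
            cost = d[(i, j)]
            if best is None or cost < best - 1e-15:
                best, pair = cost, (i, j)
        i, j = pair
        merges.append((i, j, float(np.sqrt(best)), sizes[i] + sizes[j]))
        k = next_id
        next_id += 1
        sizes[k] = sizes[i] + sizes[j]
        for m in list(active):
            if m in (i, j):
                continue
            si, sj, sm = sizes[i], sizes[j], sizes[m]
            dik = d[tuple(sorted((i, m)))]
            djk = d[tuple(sorted((j, m)))]
            dij = d[(i, j)]
            new = ((si + sm) * dik + (sj + sm) * djk - sm * dij) / (si + sj + sm)
            d[tuple(sorted((k, m)))] = new
        del active[i], active[j]
        active[k] = (sizes[k], k)
    return merges


def test_clustering_merges_identical_rows_first():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 0.0]],
        index=["a", "b", "c"],
    )
    merges = hierarchical_clustering(frame)
    assert {merges.loc[0, "left"], merges.loc[0, "right"]} == {0, 1}
    assert merges.loc[0, "height"] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        hierarchical_clustering(frame.iloc[:1])


def test_clustering_matches_naive_oracle_on_five_points():
    rng = np.random.default_rng(8)
    points = rng.normal(size=(5, 4))
    frame = pd.DataFrame(points)
    merges = hierarchical_clustering(frame)
    oracle = _naive_ward(points)
    for row, (i, j, h, size) in zip(merges.itertuples(index=False), oracle):
        assert {row.left, row.right} == {i, j}
        assert row.height == pytest.approx(h, rel=1e-9)
        assert row.size == size
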