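import itertools

import numpy as np
import pandas as pd
import pytest

import microgrove as mg
from microgrove.errors import AliasingError, InvariantError, UntestableError
from microgrove.io import FactorInfo, FactorTable
from microgrove.permanova import gower_center, pairwise_vif

TAXA = ["A", "B", "C", "D"]


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------


def test_unweighted_unifrac_toy_values(toy_tree):
    assert mg.unweighted_unifrac([1, 1, 0, 0], [2, 5, 0, 0], toy_tree, TAXA) == 0.0
    assert mg.unweighted_unifrac([1, 0, 0, 0], [0, 1, 0, 0], toy_tree, TAXA) \
        == pytest.approx(2 / 3)
    assert mg.unweighted_unifrac([1, 1, 0, 0], [0, 0, 1, 1], toy_tree, TAXA) == 1.0


def test_weighted_unifrac_toy_values(toy_tree):
    assert mg.weighted_unifrac([10, 10, 0, 0], [1, 1, 0, 0], toy_tree, TAXA) == 0.0
    assert mg.weighted_unifrac([100, 0, 0, 0], [0, 100, 0, 0], toy_tree, TAXA) \
        == pytest.approx(2.0)
    a, b = [8, 4, 2, 0], [3, 9, 0, 1]
    half = [4, 2, 1, 0]
    assert mg.weighted_unifrac(a, b, toy_tree, TAXA) == pytest.approx(
        mg.weighted_unifrac(half, b, toy_tree, TAXA))


def test_unifrac_metric_axioms(small_cohort):
    otu, tree = small_cohort["otu"], small_cohort["tree"]
    sub = otu.select_samples(otu.sample_ids[:25])
    for metric in ("unweighted_unifrac", "weighted_unifrac"):
        d = mg.unifrac_matrix(sub, tree, metric)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)
        assert (d.values >= 0).all()
        if metric == "unweighted_unifrac":
            assert (d.values <= 1.0).all()


def test_unifrac_matrix_agrees_with_pairwise_functions(small_cohort):
    otu, tree = small_cohort["otu"], small_cohort["tree"]
    sub = otu.select_samples(otu.sample_ids[:6])
    for metric, fn in (("unweighted_unifrac", mg.unweighted_unifrac),
                       ("weighted_unifrac", mg.weighted_unifrac)):
        d = mg.unifrac_matrix(sub, tree, metric)
        for i, j in [(0, 1), (2, 5), (3, 4)]:
            expected = fn(sub.counts[i], sub.counts[j], tree, sub.taxon_ids)
            assert d.values[i, j] == pytest.approx(expected)


def test_unifrac_cross_checked_against_skbio(small_cohort):
    skbio = pytest.importorskip("skbio")
    from io import StringIO
    from skbio import TreeNode
    from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac

    otu, tree = small_cohort["otu"], small_cohort["tree"]
    sknode = TreeNode.read(StringIO(tree.to_newick()))
    i, j = 0, 7
    uw = mg.unweighted_unifrac(otu.counts[i], otu.counts[j], tree, otu.taxon_ids)
    uw_ref = unweighted_unifrac(otu.counts[i], otu.counts[j],
                                taxa=otu.taxon_ids, tree=sknode)
    assert uw == pytest.approx(float(uw_ref), abs=1e-10)
    w = mg.weighted_unifrac(otu.counts[i], otu.counts[j], tree, otu.taxon_ids)
    w_ref = weighted_unifrac(otu.counts[i], otu.counts[j],
                             taxa=otu.taxon_ids, tree=sknode)
    assert w == pytest.approx(float(w_ref), abs=1e-10)


def test_empty_sample_raises(toy_tree):
    with pytest.raises(InvariantError):
        mg.unweighted_unifrac([0, 0, 0, 0], [1, 0, 0, 0], toy_tree, TAXA)


# ---------------------------------------------------------------------------
# PERMANOVA core
# ---------------------------------------------------------------------------


def _dist_from_points(x):
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(x))
    ids = [f"s{i}" for i in range(len(x))]
    return mg.DistanceMatrix(ids, d, "euclidean")


def test_gower_identity_total_ss(small_cohort):
    otu, tree = small_cohort["otu"], small_cohort["tree"]
    sub = otu.select_samples(otu.sample_ids[:20])
    d = mg.unifrac_matrix(sub, tree, "unweighted_unifrac")
    g = gower_center(d.values)
    n = len(d)
    expected = (d.values[np.triu_indices(n, 1)] ** 2).sum() / n
    assert np.trace(g) == pytest.approx(expected)


def test_permanova_enumeration_oracle_n6():
    """Permutation p at n=6 (3 vs 3) equals complete enumeration."""
    rng = np.random.default_rng(12)
    x = rng.normal(0, 1, (6, 3))
    x[3:] += 1.2
    dist = _dist_from_points(x)
    labels = pd.Series(["a", "a", "a", "b", "b", "b"],
                       index=dist.sample_ids, name="g")
    res = mg.permanova_single(dist, labels, "binary", n_perm="all")
    # independent enumeration from the Gower decomposition
    g = gower_center(dist.values)
    tot = np.trace(g)

    def fstat(members_a):
        z = np.zeros((6, 2))
        z[:, 0] = 1
        z[list(members_a), 1] = 1
        q, _ = np.linalg.qr(z)
        h = q @ q.T
        ss = (h * g).sum()
        return (ss / 1) / ((tot - ss) / 4)

    f_obs = fstat([0, 1, 2])
    fs = [fstat(c) for c in itertools.combinations(range(6), 3)]
    p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
    assert res.terms["p"].iloc[0] == pytest.approx(p_exact)
    assert res.terms["F"].iloc[0] == pytest.approx(f_obs)


def test_permanova_extreme_separation():
    rng = np.random.default_rng(1)
    x = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(50, 0.1, (10, 3))])
    dist = _dist_from_points(x)
    labels = pd.Series(["a"] * 10 + ["b"] * 10, index=dist.sample_ids, name="g")
    res = mg.permanova_single(dist, labels, "binary", n_perm=199, seed=0)
    assert res.terms["p"].iloc[0] == pytest.approx(1 / 200)
    assert res.terms["r2"].iloc[0] > 0.5


def test_permanova_p_invariant_to_sample_reordering():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, (14, 3))
    x[7:, 0] += 1.0
    dist = _dist_from_points(x)
    labels = pd.Series(["a"] * 7 + ["b"] * 7, index=dist.sample_ids, name="g")
    res1 = mg.permanova_single(dist, labels, "binary", n_perm=499, seed=5)
    order = list(rng.permutation(dist.sample_ids))
    res2 = mg.permanova_single(dist.select(order), labels.loc[order],
                               "binary", n_perm=499, seed=5)
    assert res1.terms["F"].iloc[0] == pytest.approx(res2.terms["F"].iloc[0])
    assert abs(res1.terms["p"].iloc[0] - res2.terms["p"].iloc[0]) < 0.05


def test_permanova_missing_dropped_and_constant_raises():
    rng = np.random.default_rng(2)
    dist = _dist_from_points(rng.normal(0, 1, (8, 2)))
    f = pd.Series(["a", "b"] * 4, index=dist.sample_ids, name="g")
    f.iloc[0] = np.nan
    res = mg.permanova_single(dist, f, "binary", n_perm=99, seed=0)
    assert res.n == 7
    const = pd.Series(["a"] * 8, index=dist.sample_ids, name="g")
    with pytest.raises(UntestableError):
        mg.permanova_single(dist, const, "binary", n_perm=99, seed=0)


def test_permanova_cross_checked_against_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix as SkDM, permanova

    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, (20, 4))
    x[10:] += 0.8
    dist = _dist_from_points(x)
    labels = pd.Series(["a"] * 10 + ["b"] * 10, index=dist.sample_ids, name="g")
    res = mg.permanova_single(dist, labels, "binary", n_perm=999, seed=1)
    ref = permanova(SkDM(dist.values, ids=dist.sample_ids), labels.to_numpy(),
                    permutations=999)
    assert res.terms["F"].iloc[0] == pytest.approx(ref["test statistic"])
    assert abs(res.terms["p"].iloc[0] - ref["p-value"]) < 0.03


# ---------------------------------------------------------------------------
# marginal tests
# ---------------------------------------------------------------------------


def _binary_ft(**cols):
    n = len(next(iter(cols.values())))
    idx = [f"s{i}" for i in range(n)]
    data = pd.DataFrame({k: v for k, v in cols.items()}, index=idx)
    info = {k: FactorInfo("binary", "NSV", k) for k in cols}
    return FactorTable(data, info)


def test_marginal_single_term_equals_single_factor():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, (16, 3))
    labels = ["a"] * 8 + ["b"] * 8
    x[8:, 0] += 1.0
    dist = _dist_from_points(x)
    ft = _binary_ft(g=labels)
    single = mg.permanova_single(dist, ft.data["g"], "binary", 299, seed=3)
    marginal = mg.permanova_marginal(dist, ft, ["g"], n_perm=299, seed=3)
    assert marginal.terms.loc["g", "ss"] == pytest.approx(
        single.terms.loc["g", "ss"])
    assert marginal.terms.loc["g", "F"] == pytest.approx(
        single.terms.loc["g", "F"])
    assert marginal.total_ss == pytest.approx(single.total_ss)


def test_marginal_orthogonal_factors_recover_sequential_ss():
    """Two orthogonal balanced binary factors: marginal SS == sequential SS."""
    rng = np.random.default_rng(5)
    a = np.tile(["x", "x", "y", "y"], 5)
    b = np.tile(["u", "v"], 10)
    x = rng.normal(0, 1, (20, 3))
    x[a == "y", 0] += 1.0
    x[b == "v", 1] += 0.7
    dist = _dist_from_points(x)
    ft = _binary_ft(a=list(a), b=list(b))
    marg = mg.permanova_marginal(dist, ft, ["a", "b"], n_perm=99, seed=0)
    # sequential SS of the first term = its single-factor SS (orthogonality)
    sing_a = mg.permanova_single(dist, ft.data["a"], "binary", 99, 0)
    sing_b = mg.permanova_single(dist, ft.data["b"], "binary", 99, 0)
    assert marg.terms.loc["a", "ss"] == pytest.approx(
        sing_a.terms.loc["a", "ss"])
    assert marg.terms.loc["b", "ss"] == pytest.approx(
        sing_b.terms.loc["b", "ss"])


def test_marginal_aliased_terms_raise():
    rng = np.random.default_rng(6)
    labels = ["a"] * 6 + ["b"] * 6
    dist = _dist_from_points(rng.normal(0, 1, (12, 2)))
    ft = _binary_ft(g1=labels, g2=list(labels))
    with pytest.raises(AliasingError):
        mg.permanova_marginal(dist, ft, ["g1", "g2"], n_perm=49, seed=0)


def test_adjusted_r2_formula():
    rng = np.random.default_rng(8)
    x = rng.normal(0, 1, (15, 3))
    labels = ["a"] * 7 + ["b"] * 8
    dist = _dist_from_points(x)
    ft = _binary_ft(g=labels)
    res = mg.permanova_marginal(dist, ft, ["g"], n_perm=49, seed=0)
    n, m, r2 = res.n, 1, res.model_r2
    assert res.adj_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - m - 1))


# ---------------------------------------------------------------------------
# imputation and VIF rules
# ---------------------------------------------------------------------------


def _mk_ft(columns):
    n = len(next(iter(columns.values()))[0])
    idx = [f"s{i}" for i in range(n)]
    data = pd.DataFrame({k: v[0] for k, v in columns.items()}, index=idx)
    info = {k: FactorInfo(v[1], v[2], v[3]) for k, v in columns.items()}
    return FactorTable(data, info)


def test_impute_mean_and_missing_category():
    ft = _mk_ft({
        "bmi": ([1.0, 2.0, np.nan], "continuous", "pregnancy", "bmi"),
        "ets": (["yes", np.nan, "no"], "binary", "NSV", "ets"),
        "ok": (["a", "b", "a"], "categorical", "NSV", "ok"),
    })
    out = mg.impute_factors(ft)
    assert out.data.loc["s2", "bmi"] == pytest.approx(1.5)
    assert out.data.loc["s1", "ets"] == "missing"
    assert out.kind("ets") == "categorical"  # binary + missing level
    assert list(out.data["ok"]) == ["a", "b", "a"]  # untouched
    ft_all_missing = _mk_ft({"x": ([np.nan, np.nan], "continuous", "NSV", "x")})
    with pytest.raises(InvariantError):
        mg.impute_factors(ft_all_missing)


def test_pairwise_vif_matches_correlation_formula():
    rng = np.random.default_rng(9)
    n = 4000
    a = rng.normal(0, 1, n)
    for r, expected in ((0.7, 1 / (1 - 0.49)), (0.8, 1 / (1 - 0.64))):
        b = r * a + np.sqrt(1 - r * r) * rng.normal(0, 1, n)
        sa = pd.Series(a)
        sb = pd.Series(b)
        v = pairwise_vif(sa, "continuous", sb, "continuous")
        assert v == pytest.approx(expected, rel=0.08)


def test_vif_rules_two_measurements():
    rng = np.random.default_rng(10)
    n = 300
    a = rng.normal(0, 1, n)
    dup = pd.Series(a)
    ft = _mk_ft({
        "m_preg": (list(a), "continuous", "pregnancy", "grp"),
        "m_nsv": (list(dup), "continuous", "NSV", "grp"),
    })
    kept, log = mg.vif_prefilter(ft, stool_time=1.0)
    assert kept == ["m_nsv"]  # duplicated: keep closest to stool (NSV)
    b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(0, 1, n)  # VIF ~ 1.33
    ft2 = _mk_ft({
        "m_preg": (list(a), "continuous", "pregnancy", "grp"),
        "m_nsv": (list(b), "continuous", "NSV", "grp"),
    })
    kept2, _ = mg.vif_prefilter(ft2, stool_time=1.0)
    assert set(kept2) == {"m_preg", "m_nsv"}


def test_vif_rules_three_measurements():
    rng = np.random.default_rng(11)
    n = 500
    a = rng.normal(0, 1, n)
    near_dup = a + rng.normal(0, 0.05, n)
    indep = rng.normal(0, 1, n)
    ft = _mk_ft({
        "m_preg": (list(a), "continuous", "pregnancy", "grp"),
        "m_del": (list(near_dup), "continuous", "delivery", "grp"),
        "m_isv": (list(indep), "continuous", "ISV", "grp"),
    })
    kept, log = mg.vif_prefilter(ft, stool_time=6.0)
    # furthest apart = pregnancy vs ISV; their VIF is low -> keep that pair
    assert set(kept) == {"m_preg", "m_isv"}

    near_dup2 = a + rng.normal(0, 0.05, n)
    ft2 = _mk_ft({
        "m_preg": (list(a), "continuous", "pregnancy", "grp"),
        "m_del": (list(near_dup), "continuous", "delivery", "grp"),
        "m_isv": (list(near_dup2), "continuous", "ISV", "grp"),
    })
    kept2, _ = mg.vif_prefilter(ft2, stool_time=6.0)
    assert kept2 == ["m_isv"]  # still collinear -> closest to stool only


def test_vif_singleton_groups_pass_through():
    ft = _mk_ft({
        "x": ([1.0, 2.0, 3.0], "continuous", "NSV", "x"),
        "y": (["a", "b", "a"], "binary", "NSV", "y"),
    })
    kept, log = mg.vif_prefilter(ft, stool_time=1.0)
    assert kept == ["x", "y"]
    assert log.empty


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------


def test_backward_elimination_single_significant_candidate():
    rng = np.random.default_rng(13)
    x = rng.normal(0, 1, (24, 3))
    labels = ["a"] * 12 + ["b"] * 12
    x[12:] += 1.5
    dist = _dist_from_points(x)
    ft = _binary_ft(g=labels)
    res, trace = mg.backward_eliminate(dist, ft, ["g"], alpha=0.05,
                                       n_perm=199, seed=0)
    assert trace.retained == ["g"]
    assert trace.steps.empty
    assert res.terms.loc["g", "p"] < 0.05


def test_backward_elimination_drops_noise():
    rng = np.random.default_rng(14)
    n = 40
    x = rng.normal(0, 1, (n, 3))
    signal = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    x[signal == "b"] += 1.5
    cols = {"signal": list(signal)}
    for j in range(3):
        cols[f"noise{j}"] = list(rng.choice(["u", "v"], n))
    dist = _dist_from_points(x)
    ft = _binary_ft(**cols)
    res, trace = mg.backward_eliminate(dist, ft, list(cols), alpha=0.05,
                                       n_perm=199, seed=1)
    assert "signal" in trace.retained
    dropped = set(trace.steps["dropped"])
    assert dropped.issubset({"noise0", "noise1", "noise2"})
    for row in trace.steps.itertuples():
        assert row.p_at_drop >= 0.05
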