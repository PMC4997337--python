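import itertools

import numpy as np
import pandas as pd
import pytest

import microgrove as mg
from microgrove.errors import InvariantError, MicrogroveError
from microgrove.lca import LcaModel


def _two_class_items(n, rng, sep=0.9, pi=0.6, n_items=6):
    """Well-separated 2-class binary items: class 0 has P(level '1') = sep."""
    classes = (rng.random(n) >= pi).astype(int)
    data = {}
    for j in range(n_items):
        p = np.where(classes == 0, sep, 1 - sep)
        data[f"item{j}"] = np.where(rng.random(n) < p, "1", "0")
    return pd.DataFrame(data), classes


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_k1_matches_closed_form():
    rng = np.random.default_rng(0)
    items, _ = _two_class_items(200, rng)
    model = mg.fit_lca(items, K=1, n_starts=3, seed=1)
    ll = 0.0
    for col in items.columns:
        freq = items[col].value_counts(normalize=True)
        counts = items[col].value_counts()
        for lev in freq.index:
            ll += counts[lev] * np.log(freq[lev])
        fitted = dict(zip(model.item_levels[items.columns.get_loc(col)],
                          model.rho[items.columns.get_loc(col)][0]))
        for lev in freq.index:
            assert fitted[lev] == pytest.approx(freq[lev], abs=1e-6)
    assert model.loglik == pytest.approx(ll, abs=1e-8)
    assert model.pi[0] == pytest.approx(1.0)


def test_em_loglik_monotone():
    rng = np.random.default_rng(1)
    items, _ = _two_class_items(300, rng)
    model = mg.fit_lca(items, K=2, n_starts=1, seed=2)
    diffs = np.diff(model.em_trace)
    assert (diffs >= -1e-8).all()


def test_two_class_parameter_recovery():
    rng = np.random.default_rng(2)
    items, classes = _two_class_items(1000, rng, sep=0.9, pi=0.6)
    model = mg.fit_lca(items, K=2, n_starts=10, seed=3)
    # classes canonicalized by descending prevalence: class 0 is the 60% one
    assert model.pi[0] == pytest.approx(0.6, abs=0.05)
    for j in range(6):
        lev1 = model.item_levels[j].index("1")
        # best-permutation alignment: prevalence order fixes it here
        assert model.rho[j][0, lev1] == pytest.approx(0.9, abs=0.05)
        assert model.rho[j][1, lev1] == pytest.approx(0.1, abs=0.05)


def test_posterior_rows_sum_to_one_and_stationarity():
    rng = np.random.default_rng(3)
    items, _ = _two_class_items(400, rng)
    model = mg.fit_lca(items, K=2, n_starts=5, seed=4)
    assert np.allclose(model.posterior.sum(axis=1), 1.0, atol=1e-10)
    # MLE stationarity: fitted marginals match empirical item frequencies
    for j, col in enumerate(items.columns):
        marginal = model.pi @ model.rho[j]
        empirical = items[col].value_counts(normalize=True)
        for li, lev in enumerate(model.item_levels[j]):
            assert marginal[li] == pytest.approx(empirical.get(lev, 0.0),
                                                 abs=1e-5)


def test_k_exceeding_patterns_raises():
    items = pd.DataFrame({"a": ["0", "1", "0", "1"], "b": ["0", "1", "0", "1"]})
    with pytest.raises(MicrogroveError):
        mg.fit_lca(items, K=3, n_starts=1, seed=0)


def test_information_criteria_formulas():
    rng = np.random.default_rng(4)
    items, _ = _two_class_items(150, rng, n_items=3)
    model = mg.fit_lca(items, K=2, n_starts=3, seed=5)
    k = (2 - 1) + 2 * sum(len(l) - 1 for l in model.item_levels)
    assert model.n_params == k
    assert model.bic == pytest.approx(-2 * model.loglik + k * np.log(model.n))
    assert model.abic == pytest.approx(
        -2 * model.loglik + k * np.log((model.n + 2) / 24))
    # the two criteria share structure: equal when penalties coincide
    n_eq = 22  # ln((22+2)/24) = 0 -> aBIC reduces to -2 loglik
    fake = LcaModel(model.K, model.pi, model.rho, model.loglik, n_eq,
                    model.item_names, model.item_levels, model.posterior)
    assert fake.abic == pytest.approx(-2 * model.loglik)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


def test_sklearn_facade_fit_predict():
    rng = np.random.default_rng(5)
    items, classes = _two_class_items(600, rng)
    est = mg.LatentClassAnalysis(n_classes=2, n_starts=5, random_state=6)
    est.fit(items)
    proba = est.predict_proba(items)
    assert proba.shape == (600, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    hard = est.predict(items)
    # accuracy up to label permutation
    acc = max(np.mean(hard == classes), np.mean(hard == 1 - classes))
    assert acc > 0.9
    assert est.get_params()["n_classes"] == 2


# ---------------------------------------------------------------------------
# bootstrap LRT and selection
# ---------------------------------------------------------------------------


def test_bootstrap_lrt_floor_on_separated_classes():
    rng = np.random.default_rng(6)
    items, _ = _two_class_items(400, rng, sep=0.92)
    p, obs = mg.bootstrap_lrt(items, 1, n_starts=4, B=19, seed=7)
    assert p == pytest.approx(1 / 20)  # all bootstrap LRTs below observed
    assert obs > 50


def test_select_k_one_class_generator():
    rng = np.random.default_rng(7)
    items = pd.DataFrame({
        f"item{j}": np.where(rng.random(300) < 0.5, "1", "0")
        for j in range(5)
    })
    k, table = mg.select_k(items, K_max=3, n_starts=4, B=19, seed=8)
    assert k == 1
    assert table.shape[0] == 3


def test_select_k_kmax_one_degenerate():
    rng = np.random.default_rng(8)
    items, _ = _two_class_items(100, rng)
    k, table = mg.select_k(items, K_max=1, n_starts=2, B=19, seed=9)
    assert k == 1
    assert len(table) == 1


# ---------------------------------------------------------------------------
# assignment, invariance, report
# ---------------------------------------------------------------------------


def test_assignment_ties_and_separation():
    rng = np.random.default_rng(9)
    items, classes = _two_class_items(500, rng, sep=0.95)
    model = mg.fit_lca(items, K=2, n_starts=5, seed=10)
    assignments, mean_max = mg.assign_profiles(model, items)
    assert (mean_max >= 0.95).all()
    assert set(assignments.unique()) <= {1, 2}
    # uniform posterior -> lowest class index by tie-break
    flat = LcaModel(2, np.array([0.5, 0.5]),
                    [np.full((2, 2), 0.5) for _ in range(6)],
                    0.0, 4, list(items.columns), [["0", "1"]] * 6,
                    pd.DataFrame())
    a2, m2 = mg.assign_profiles(flat, items.head(4))
    assert (a2 == 1).all()
    assert m2["class_1"] == pytest.approx(0.5)


def test_assignment_unseen_level_raises():
    rng = np.random.default_rng(10)
    items, _ = _two_class_items(100, rng)
    model = mg.fit_lca(items, K=2, n_starts=3, seed=11)
    bad = items.head(3).copy()
    bad.iloc[0, 0] = "never-seen"
    with pytest.raises(MicrogroveError, match="never-seen"):
        mg.assign_profiles(model, bad)


def test_measurement_invariance_single_group_and_null():
    rng = np.random.default_rng(11)
    items, _ = _two_class_items(400, rng)
    single = pd.Series(["g1"] * 400, index=items.index)
    assert mg.measurement_invariance(items, single, K=2) == 1.0
    both = pd.Series(["g1"] * 200 + ["g2"] * 200, index=items.index)
    p = mg.measurement_invariance(items, both, K=2, n_starts=5, seed=12)
    assert 0.0 <= p <= 1.0


def test_measurement_invariance_detects_shifted_response():
    rng = np.random.default_rng(12)
    a, _ = _two_class_items(500, rng, sep=0.9)
    b, _ = _two_class_items(500, rng, sep=0.6)  # same classes, shifted rho
    items = pd.concat([a, b], ignore_index=True)
    grouping = pd.Series(["a"] * 500 + ["b"] * 500)
    p = mg.measurement_invariance(items, grouping, K=2, n_starts=5, seed=13)
    assert p < 0.01


def test_profile_report_column_percentages_and_chi2():
    assignments = pd.Series([1] * 609 + [2] * 474 + [3] * 175)
    married = pd.Series(["Yes"] * 293 + ["No"] * 316 +
                        ["Yes"] * 445 + ["No"] * 29 +
                        ["Yes"] * 35 + ["No"] * 140)
    report = mg.profile_report(assignments, pd.DataFrame({"married": married}))
    tab = report.level_tables["married"]
    assert tab.loc["Yes", ("pct", 1)] == pytest.approx(48.1, abs=0.05)
    assert tab.loc["Yes", ("pct", 2)] == pytest.approx(93.9, abs=0.05)
    assert tab.loc["Yes", ("pct", 3)] == pytest.approx(20.0, abs=0.05)
    assert report.class_shares.loc[3] == pytest.approx(175 / 1258, abs=1e-9)
    assert report.pvalues.loc["married", "overall"] < 1e-10
    # identical compositions -> chi-square p ~ 1
    same = pd.Series(["x"] * 50 + ["y"] * 50 + ["x"] * 50 + ["y"] * 50)
    asg = pd.Series([1] * 100 + [2] * 100)
    rep2 = mg.profile_report(asg, pd.DataFrame({"f": same}))
    assert rep2.pvalues.loc["f", "overall"] == pytest.approx(1.0)


def test_chi2_hand_computed_2x3():
    from scipy.stats import chi2_contingency
    table = np.array([[20, 30, 10], [10, 25, 25]])
    assignments = pd.Series(np.repeat([1, 2], 60))
    levels = (["a"] * 20 + ["b"] * 30 + ["c"] * 10 +
              ["a"] * 10 + ["b"] * 25 + ["c"] * 25)
    rep = mg.profile_report(assignments, pd.DataFrame({"f": levels}))
    expected = chi2_contingency(table, correction=False)[1]
    assert rep.pvalues.loc["f", "overall"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# added variance
# ---------------------------------------------------------------------------


def _dist_from_points(x):
    from scipy.spatial.distance import pdist, squareform
    ids = [f"s{i}" for i in range(len(x))]
    return mg.DistanceMatrix(ids, squareform(pdist(x)), "euclidean")


def test_mmp_added_variance_signal_and_aliasing():
    from microgrove.io import FactorInfo, FactorTable
    rng = np.random.default_rng(13)
    n = 60
    classes = rng.integers(1, 4, n)
    x = rng.normal(0, 1, (n, 3)) + classes[:, None] * 1.5
    dist = _dist_from_points(x)
    other = rng.choice(["u", "v"], n)
    ft = FactorTable(pd.DataFrame({"g": other}, index=dist.sample_ids),
                     {"g": FactorInfo("binary", "NSV", "g")})
    assignments = pd.Series(classes, index=dist.sample_ids)
    delta, p = mg.mmp_added_variance(dist, ft, ["g"], assignments,
                                     n_perm=199, seed=1)
    assert delta > 0.2
    assert p < 0.05
    # assignments equal to an existing factor -> aliasing
    dup = pd.Series(other, index=dist.sample_ids)
    from microgrove.errors import AliasingError
    with pytest.raises(AliasingError):
        mg.mmp_added_variance(dist, ft, ["g"], dup, n_perm=49, seed=2)


def test_mmp_added_variance_missing_assignment_raises():
    from microgrove.io import FactorInfo, FactorTable
    rng = np.random.default_rng(14)
    dist = _dist_from_points(rng.normal(0, 1, (10, 2)))
    ft = FactorTable(pd.DataFrame({"g": ["u", "v"] * 5},
                                  index=dist.sample_ids),
                     {"g": FactorInfo("binary", "NSV", "g")})
    partial = pd.Series([1] * 5, index=dist.sample_ids[:5])
    with pytest.raises(InvariantError):
        mg.mmp_added_variance(dist, ft, ["g"], partial, n_perm=49, seed=0)
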