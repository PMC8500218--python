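import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from motionrca import stats


def brute_force_split_plot(data, groups):
    """Cell-means sums-of-squares oracle for the balanced split-plot design.

    Full enumeration of the classical decomposition: between-subjects SS
    split into group and subjects-within-groups; within-subjects SS split
    into condition, group x condition and condition x subjects-within-
    groups.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    names = list(dict.fromkeys(groups))
    n_g = {g: (groups == g).sum() for g in names}
    n, c = data.shape
    grand = data.mean()
    subj_mean = data.mean(axis=1)
    group_mean = {g: data[groups == g].mean() for g in names}
    cond_mean = data.mean(axis=0)
    cell_mean = {g: data[groups == g].mean(axis=0) for g in names}

    ss_group = sum(n_g[g] * c * (group_mean[g] - grand) ** 2 for g in names)
    ss_subj = c * sum((subj_mean[i] - group_mean[groups[i]]) ** 2 for i in range(n))
    ss_cond = n * sum((cond_mean[j] - grand) ** 2 for j in range(c))
    ss_int = sum(n_g[g] * (cell_mean[g][j] - group_mean[g] - cond_mean[j] + grand) ** 2
                 for g in names for j in range(c))
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_cond - ss_int

    df_g, df_s = len(names) - 1, n - len(names)
    df_c, df_e = c - 1, (c - 1) * (n - len(names))
    return {
        "group": (ss_group / df_g) / (ss_subj / df_s),
        "condition": (ss_cond / df_c) / (ss_err / df_e),
        "interaction": (ss_int / df_g / (c - 1)) / (ss_err / df_e),
    }


def test_split_plot_matches_bruteforce_on_balanced_integer_fixture():
    data = np.array([[3, 5], [4, 6], [2, 5], [7, 6], [8, 9], [6, 8]], dtype=float)
    groups = np.array(["TD"] * 3 + ["dys"] * 3)
    table = stats.split_plot_anova(data, groups).set_index("effect")
    oracle = brute_force_split_plot(data, groups)
    for eff in ("group", "condition", "interaction"):
        assert table.loc[eff, "F"] == pytest.approx(oracle[eff], abs=1e-10)


def test_split_plot_matches_independent_oracles_unbalanced():
    rng = np.random.default_rng(0)
    groups = np.array(["TD"] * 6 + ["aut"] * 3 + ["dys"] * 5)
    data = rng.normal(size=(14, 2)) + np.array([0.3, 0.0])
    table = stats.split_plot_anova(data, groups).set_index("effect")
    m = data.mean(axis=1)
    d = data[:, 1] - data[:, 0]
    f_grp, p_grp = sps.f_oneway(m[:6], m[6:9], m[9:])
    f_int, p_int = sps.f_oneway(d[:6], d[6:9], d[9:])
    assert table.loc["group", "F"] == pytest.approx(f_grp, rel=1e-10)
    assert table.loc["group", "p"] == pytest.approx(p_grp, rel=1e-10)
    assert table.loc["interaction", "F"] == pytest.approx(f_int, rel=1e-10)
    # condition effect: effect-coded OLS intercept test (Type III hypothesis)
    import statsmodels.api as sm
    X = np.zeros((14, 3))
    X[:, 0] = 1.0
    X[:6, 1] = 1.0
    X[6:9, 2] = 1.0
    X[9:, 1:] = -1.0
    fit = sm.OLS(d, X).fit()
    assert table.loc["condition", "F"] == pytest.approx(fit.tvalues[0] ** 2, rel=1e-8)
    assert table.loc["condition", "p"] == pytest.approx(fit.pvalues[0], rel=1e-8)


def test_split_plot_matches_pingouin_balanced():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    groups = np.array(["TD"] * 5 + ["aut"] * 5)
    data = rng.normal(size=(10, 2)) + np.array([0.0, 0.8])
    table = stats.split_plot_anova(data, groups).set_index("effect")
    df = pd.DataFrame({
        "y": data.ravel(), "cond": ["c1", "c2"] * 10,
        "subj": np.repeat(np.arange(10), 2), "grp": np.repeat(groups, 2)})
    ref = pg.mixed_anova(data=df, dv="y", within="cond", subject="subj",
                         between="grp").set_index("Source")
    assert table.loc["group", "F"] == pytest.approx(ref.loc["grp", "F"], rel=1e-8)
    assert table.loc["condition", "F"] == pytest.approx(ref.loc["cond", "F"], rel=1e-8)
    assert table.loc["interaction", "F"] == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-8)
    assert table.loc["group", "eta_p2"] == pytest.approx(ref.loc["grp", "np2"], rel=1e-8)


def test_equal_cell_means_give_zero_f_and_shift_invariance():
    data = np.tile([2.0, 2.0], (8, 1))
    groups = np.array(["TD"] * 4 + ["aut"] * 4)
    table = stats.split_plot_anova(data, groups)
    assert (table["F"] == 0.0).all()
    rng = np.random.default_rng(2)
    data = rng.normal(size=(8, 2))
    t0 = stats.split_plot_anova(data, groups)
    t1 = stats.split_plot_anova(data + 17.3, groups)
    np.testing.assert_allclose(t0["F"], t1["F"], atol=1e-9)


def test_split_plot_requires_two_per_group():
    with pytest.raises(ValueError):
        stats.split_plot_anova(np.zeros((3, 2)),
                               np.array(["TD", "TD", "aut"]))


# ---------------------------------------------------------------- centering

def test_center_by_cell_zeroes_every_cell_and_is_idempotent():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(12, 2, 7)) + 5.0
    groups = np.array(["TD"] * 4 + ["aut"] * 4 + ["dys"] * 4)
    c = stats.center_by_cell(data, groups)
    for g in ("TD", "aut", "dys"):
        np.testing.assert_allclose(c[groups == g].mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(stats.center_by_cell(c, groups), c, atol=1e-12)


def test_centered_null_f_has_mean_near_one():
    # under pure noise the F statistic's expectation is df2/(df2-2)
    rng = np.random.default_rng(4)
    groups = np.array(["TD"] * 10 + ["aut"] * 10 + ["dys"] * 10)
    fs = []
    for _ in range(300):
        data = stats.center_by_cell(rng.normal(size=(30, 2, 1)), groups)
        idx = rng.integers(0, 30, size=30)
        tab = stats.split_plot_anova(data[idx, :, 0], groups)
        fs.append(tab.set_index("effect").loc["group", "F"])
    df2 = 27
    assert np.mean(fs) == pytest.approx(df2 / (df2 - 2), rel=0.25)


# ------------------------------------------------------------ cluster test

def _null_input(rng, n_per=8, t=30):
    groups = np.array(["TD"] * n_per + ["aut"] * n_per + ["dys"] * n_per)
    data = rng.standard_normal((3 * n_per, 2, t))
    return stats.MassUnivariateInput(data=data, groups=groups,
                                     time_ms=np.arange(t) * 2.0)


def test_all_zero_data_yields_no_clusters():
    inp = stats.MassUnivariateInput(
        data=np.zeros((12, 2, 20)),
        groups=np.array(["TD"] * 4 + ["aut"] * 4 + ["dys"] * 4),
        time_ms=np.arange(20) * 2.0)
    res = stats.bootstrap_cluster_test(inp, n_boot=200, seed=0)
    for eff in res.effects.values():
        assert eff.clusters == []


def test_cluster_test_deterministic_under_fixed_seed():
    rng = np.random.default_rng(5)
    inp = _null_input(rng)
    a = stats.bootstrap_cluster_test(inp, n_boot=200, seed=42)
    b = stats.bootstrap_cluster_test(inp, n_boot=200, seed=42)
    for eff in stats.EFFECTS:
        np.testing.assert_array_equal(a.effects[eff].max_sums,
                                      b.effects[eff].max_sums)
        assert a.effects[eff].threshold == b.effects[eff].threshold


def test_injected_condition_effect_detected_and_localized():
    rng = np.random.default_rng(6)
    inp = _null_input(rng, n_per=12, t=50)
    sel = (np.arange(50) * 2.0 >= 40) & (np.arange(50) * 2.0 <= 60)
    inp.data[:, 1, sel] += 1.5
    res = stats.bootstrap_cluster_test(inp, n_boot=500, seed=7)
    sig = [c for c in res.effects["condition"].clusters if c.significant]
    assert sig and any(c.start_ms <= 60 and c.end_ms >= 40 for c in sig)
    assert not [c for c in res.effects["group"].clusters if c.significant]


def test_cluster_invariants():
    rng = np.random.default_rng(8)
    inp = _null_input(rng, n_per=10, t=40)
    inp.data[inp.groups == "aut"] += 1.0
    res = stats.bootstrap_cluster_test(inp, n_boot=300, seed=9)
    for eff in res.effects.values():
        crit = sps.f.isf(0.05, *eff.df)
        for c in eff.clusters:
            sel = (inp.time_ms >= c.start_ms) & (inp.time_ms <= c.end_ms)
            assert (eff.f[sel] > crit).all()
            assert c.cluster_sum == pytest.approx(eff.f[sel].sum())
            assert c.significant == (c.cluster_sum > eff.threshold)
        assert len(eff.max_sums) == 300


def test_bootstrap_small_n_warns():
    rng = np.random.default_rng(10)
    with pytest.warns(UserWarning):
        stats.bootstrap_cluster_test(_null_input(rng), n_boot=50, seed=0)


# --------------------------------------------------------------- follow-up

def test_followup_identical_groups_not_significant():
    rng = np.random.default_rng(11)
    groups = np.array(["TD"] * 8 + ["aut"] * 8)
    base = rng.standard_normal((8, 2, 30))
    data = np.concatenate([base, base])   # identical groups
    inp = stats.MassUnivariateInput(data=data, groups=groups,
                                    time_ms=np.arange(30) * 2.0)
    res = stats.followup_pairwise_cluster(inp, ("TD", "aut"), (10.0, 50.0),
                                          n_boot=200, seed=1)
    assert not [c for c in res.effects["group"].clusters if c.significant]


def test_followup_detects_offset_with_correct_sign():
    rng = np.random.default_rng(12)
    groups = np.array(["TD"] * 10 + ["aut"] * 10 + ["dys"] * 10)
    data = rng.standard_normal((30, 2, 40))
    tms = np.arange(40) * 2.0
    win = (tms >= 20) & (tms <= 50)
    data[np.ix_(groups == "aut", [0, 1], np.flatnonzero(win))] += 2.0
    inp = stats.MassUnivariateInput(data=data, groups=groups, time_ms=tms)
    res = stats.followup_pairwise_cluster(inp, ("TD", "aut"), (20.0, 50.0),
                                          n_boot=300, seed=2)
    sig = [c for c in res.effects["group"].clusters if c.significant]
    assert sig
    for c in sig:
        assert 20.0 <= c.start_ms <= c.end_ms <= 50.0   # never outside window
        assert c.mean_difference_uv > 0                  # autistic above TD


# ---------------------------------------------------- contrasts and extras

def test_contrast_zero_when_means_equal():
    values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 5.0, 6.0])
    groups = np.array(["TD"] * 3 + ["aut"] * 3 + ["dys"] * 2)
    out = stats.planned_simple_contrasts(values, groups)
    assert out["aut"]["t"] == pytest.approx(0.0, abs=1e-12)


def test_two_group_contrast_equals_omnibus_anova():
    rng = np.random.default_rng(13)
    values = rng.normal(size=(10, 2)).mean(axis=1)
    groups = np.array(["TD"] * 5 + ["dys"] * 5)
    contrast = stats.planned_simple_contrasts(values, groups)["dys"]
    f, p = sps.f_oneway(values[:5], values[5:])
    assert contrast["t"] ** 2 == pytest.approx(f, rel=1e-10)
    assert contrast["p"] == pytest.approx(p, rel=1e-10)


def test_contrast_invariant_to_uninvolved_group_relabel():
    rng = np.random.default_rng(14)
    values = rng.normal(size=12)
    g1 = np.array(["TD"] * 4 + ["aut"] * 4 + ["dys"] * 4)
    g2 = np.array(["TD"] * 4 + ["aut"] * 4 + ["other"] * 4)
    a = stats.planned_simple_contrasts(values, g1)["aut"]
    b = stats.planned_simple_contrasts(values, g2)["aut"]
    assert a["estimate"] == b["estimate"] and a["t"] == b["t"]


def test_pearson_correlations_identities():
    x = np.arange(10, dtype=float)
    table = pd.DataFrame({"double": 2 * x, "noise": np.sin(x * 7.7)})
    out = stats.pearson_correlations(x, table).set_index("measure")
    assert out.loc["double", "r"] == pytest.approx(1.0)
    # affine invariance
    out2 = stats.pearson_correlations(3 * x - 5, table).set_index("measure")
    assert out2.loc["noise", "r"] == pytest.approx(out.loc["noise", "r"])
    # missing scores handled pairwise
    table["gappy"] = 2 * x
    table.loc[3, "gappy"] = np.nan
    out3 = stats.pearson_correlations(x, table).set_index("measure")
    assert out3.loc["gappy", "n"] == 9
    with pytest.raises(ValueError):
        stats.pearson_correlations(x, pd.DataFrame({"const": np.ones(10)}))


def test_block_score_formula():
    assert stats.block_score(1.0, 19) == 38
    assert stats.block_score(0.5, 10) == 40
    assert stats.block_score(1.0, 0) == 0
    assert stats.block_score(0.8, 15) == 38   # 37.5 rounds half away from zero
    with pytest.raises(ValueError):
        stats.block_score(0.0, 5)


def test_result_serialization(tmp_path):
    rng = np.random.default_rng(15)
    inp = _null_input(rng)
    res = stats.bootstrap_cluster_test(inp, n_boot=150, seed=3)
    path = tmp_path / "clusters.json"
    res.to_json(path)
    import json
    payload = json.loads(path.read_text())
    assert set(payload["effects"]) == set(stats.EFFECTS)
    assert payload["n_boot"] == 150
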