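import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brachymet import damstats
from brachymet.featuretable import FeatureTable, LINES, ORGANS
from conftest import make_table


def log2_table(values, seed=0):
    t = make_table(values, seed=seed)
    t.transformed = "log2"
    return t


def test_constant_feature_gives_null_result():
    t = log2_table(np.full((1, 48), 7.0))
    r = damstats.anova_two_way_block(t, "F0000")
    assert r.F_organ == r.F_line == r.F_interaction == 0.0
    assert r.p_organ == r.p_line == r.p_interaction == 1.0


def _hand_ss(df):
    """Balanced-design sequential sums of squares by direct group-mean
    arithmetic (independent of the QR implementation)."""
    grand = df["y"].mean()
    n = len(df)
    ss = {}
    ss["block"] = sum(len(g) * (g["y"].mean() - grand) ** 2
                      for _, g in df.groupby("experiment"))
    ss["organ"] = sum(len(g) * (g["y"].mean() - grand) ** 2
                      for _, g in df.groupby("organ"))
    ss["line"] = sum(len(g) * (g["y"].mean() - grand) ** 2
                     for _, g in df.groupby("line"))
    cell = df.groupby(["organ", "line"])["y"].mean()
    om = df.groupby("organ")["y"].mean()
    lm = df.groupby("line")["y"].mean()
    ss["interaction"] = sum(
        (df.groupby(["organ", "line"]).size()[k]
         * (cell[k] - om[k[0]] - lm[k[1]] + grand) ** 2) for k in cell.index)
    total = ((df["y"] - grand) ** 2).sum()
    ss["resid"] = total - sum(v for k, v in ss.items())
    return ss


def test_anova_matches_hand_ss_on_16_value_toy():
    # 2 organs x 2 lines x 2 blocks x 2 replicates, fixed values
    rows = []
    vals = iter([10.0, 11.0, 12.5, 13.1, 9.2, 9.8, 15.0, 14.2,
                 10.5, 11.7, 12.0, 13.9, 9.9, 9.1, 15.8, 14.6])
    for organ in ("leaf", "root"):
        for line in LINES:
            for exp in ("E1", "E2"):
                for rep in (1, 2):
                    rows.append((f"{organ}_{line}_{exp}_r{rep}", organ, line,
                                 exp, rep, next(vals)))
    df = pd.DataFrame(rows, columns=["sample_id", "organ", "line",
                                     "experiment", "replicate", "y"])
    design = df.drop(columns="y")
    features = pd.DataFrame({"feature_id": ["toy"], "mz": [100.0],
                             "rt": [1.0], "polarity": ["negative"]})
    ints = pd.DataFrame([df["y"].to_numpy()], index=["toy"],
                        columns=df["sample_id"])
    table = FeatureTable(features, design, ints, "log2")
    res = damstats.anova_all(table)
    ss = _hand_ss(df)
    dfres = 16 - 1 - 1 - 1 - 1 - 1
    for term in ("organ", "line", "interaction"):
        F_hand = (ss[term] / 1) / (ss["resid"] / dfres)
        assert res[f"F_{term}"].iloc[0] == pytest.approx(F_hand, abs=1e-10)


def test_anova_matches_statsmodels_type1():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    rng = np.random.default_rng(11)
    t = log2_table(rng.normal(10, 1, size=(5, 48)))
    res = damstats.anova_all(t)
    for i, fid in enumerate(t.features["feature_id"]):
        df = t.design.copy()
        df["y"] = t.intensities.iloc[i].to_numpy()
        fit = smf.ols("y ~ C(experiment) + C(organ) + C(line) "
                      "+ C(organ):C(line)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        assert res.loc[fid, "F_organ"] == pytest.approx(tab.loc["C(organ)", "F"], rel=1e-8)
        assert res.loc[fid, "F_line"] == pytest.approx(tab.loc["C(line)", "F"], rel=1e-8)
        assert res.loc[fid, "F_interaction"] == pytest.approx(
            tab.loc["C(organ):C(line)", "F"], rel=1e-8)


def test_type1_equals_type3_on_balanced_design():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    rng = np.random.default_rng(12)
    t = log2_table(rng.normal(10, 1, size=(2, 48)))
    res = damstats.anova_all(t)
    for i, fid in enumerate(t.features["feature_id"]):
        df = t.design.copy()
        df["y"] = t.intensities.iloc[i].to_numpy()
        fit = smf.ols("y ~ C(experiment, Sum) + C(organ, Sum) + C(line, Sum) "
                      "+ C(organ, Sum):C(line, Sum)", data=df).fit()
        tab3 = sm.stats.anova_lm(fit, typ=3)
        assert res.loc[fid, "F_line"] == pytest.approx(
            tab3.loc["C(line, Sum)", "F"], rel=1e-8)
        assert res.loc[fid, "F_interaction"] == pytest.approx(
            tab3.loc["C(organ, Sum):C(line, Sum)", "F"], rel=1e-8)


def test_anova_invariant_under_column_permutation():
    rng = np.random.default_rng(13)
    t = log2_table(rng.normal(10, 1, size=(4, 48)))
    res = damstats.anova_all(t)
    perm = rng.permutation(48)
    t2 = FeatureTable(t.features, t.design.iloc[perm].reset_index(drop=True),
                      t.intensities.iloc[:, perm], "log2")
    res2 = damstats.anova_all(t2)
    assert np.allclose(res[["p_organ", "p_line", "p_interaction"]],
                       res2[["p_organ", "p_line", "p_interaction"]])


def test_fold_change_examples_and_oracle():
    rng = np.random.default_rng(14)
    vals = rng.normal(10, 1, size=(3, 48))
    t = log2_table(vals)
    # plant an exact 4x (log2 FC = 2) line effect on feature 0
    bd31 = (t.design["line"] == LINES[1]).to_numpy()
    vals[0] = 10.0 + 2.0 * bd31
    vals[1] = 5.0
    t = log2_table(vals)
    fcs = damstats.fold_change_per_organ(t)
    assert np.allclose(fcs.loc["F0000"], 2.0)
    assert np.allclose(fcs.loc["F0001"], 0.0)
    # direct arithmetic oracle on the random feature
    for organ in ORGANS:
        hi = (t.design["organ"] == organ) & bd31
        lo = (t.design["organ"] == organ) & ~bd31
        expect = vals[2][hi.to_numpy()].mean() - vals[2][lo.to_numpy()].mean()
        assert fcs.loc["F0002", organ] == pytest.approx(expect, abs=1e-12)
    single = damstats.fold_change_per_organ(t, "F0000")
    assert single == {o: pytest.approx(2.0) for o in ORGANS}


def _dam_frame(p_line, p_int, fc):
    anova = pd.DataFrame({"p_organ": [0.5], "p_line": [p_line],
                          "p_interaction": [p_int]}, index=["f"])
    fcs = pd.DataFrame({o: [fc] for o in ORGANS}, index=["f"])
    return anova, fcs


def test_select_dams_rule():
    anova, fcs = _dam_frame(0.02, 0.5, 5.0)
    out = damstats.select_dams(anova, fcs, p_max=0.01, min_abs_log2_fc=1.0)
    assert not out["passes"].any()          # p too large regardless of FC
    anova, fcs = _dam_frame(0.001, 0.5, 1.5)
    out = damstats.select_dams(anova, fcs, p_max=0.01, min_abs_log2_fc=1.0)
    assert out["passes"].all()


@settings(derandomize=True, max_examples=40)
@given(st.floats(1e-6, 1), st.floats(1e-6, 1), st.floats(-4, 4),
       st.floats(1e-4, 0.2), st.floats(0.1, 2))
def test_select_dams_threshold_monotonicity(p_line, p_int, fc, p_max, min_fc):
    anova, fcs = _dam_frame(p_line, p_int, fc)
    loose = damstats.select_dams(anova, fcs, p_max, min_fc)["passes"].any()
    tight_p = damstats.select_dams(anova, fcs, p_max / 2, min_fc)["passes"].any()
    tight_fc = damstats.select_dams(anova, fcs, p_max, min_fc * 2)["passes"].any()
    assert (not tight_p) or loose
    assert (not tight_fc) or loose


def test_effect_partition_against_enumeration():
    rng = np.random.default_rng(15)
    anova = pd.DataFrame({
        "p_organ": rng.random(200), "p_line": rng.random(200),
        "p_interaction": rng.random(200),
    }, index=[f"f{i}" for i in range(200)])
    part = damstats.effect_partition(anova, p_max=0.3)
    O = set(anova.index[anova.p_organ <= 0.3])
    L = set(anova.index[anova.p_line <= 0.3])
    X = set(anova.index[anova.p_interaction <= 0.3])
    assert part.venn["O"] == len(O - L - X)
    assert part.venn["O&L"] == len((O & L) - X)
    assert part.venn["O&L&OxL"] == len(O & L & X)
    assert sum(part.venn.values()) == len(O | L | X) == part.n_any


def test_effect_partition_degenerate():
    anova = pd.DataFrame({"p_organ": [1.0], "p_line": [1.0],
                          "p_interaction": [1.0]}, index=["f"])
    part = damstats.effect_partition(anova, 0.01)
    assert all(v == 0 for v in part.venn.values())
    anova.iloc[0] = [0.001, 0.001, 0.001]
    part = damstats.effect_partition(anova, 0.01)
    assert part.venn["O&L&OxL"] == 1 and sum(part.venn.values()) == 1


def test_pca_cluster_separation_and_duplicates():
    vals = np.zeros((30, 48))
    vals[:, 24:] = 5.0                      # two exact sample clusters
    rng = np.random.default_rng(16)
    vals += rng.normal(0, 0.01, vals.shape)
    t = log2_table(vals)
    scores, explained = damstats.pca_scores(t, 3)
    pc1 = scores["PC1"].to_numpy()
    assert (pc1[:24].mean() - pc1[24:].mean()) ** 2 > 20
    assert explained[0] > explained[1] and explained[0] > 0.9

    dup = vals.copy()
    dup[:, 1] = dup[:, 0]
    t2 = log2_table(dup)
    s2, _ = damstats.pca_scores(t2, 3)
    assert np.allclose(s2.iloc[0], s2.iloc[1], atol=1e-9)


def test_pca_against_eigendecomposition():
    rng = np.random.default_rng(17)
    t = log2_table(rng.normal(0, 1, size=(50, 48)))
    scores, explained = damstats.pca_scores(t, 3)
    X = t.intensities.to_numpy().T
    X = X - X.mean(axis=0)
    C = X @ X.T                              # sample Gram matrix
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for k in range(3):
        ref = V[:, k] * np.sqrt(w[k])
        got = scores.iloc[:, k].to_numpy()
        assert (np.allclose(got, ref, atol=1e-8)
                or np.allclose(got, -ref, atol=1e-8))
    assert np.allclose(explained, (w / w.sum())[:3], atol=1e-12)


def test_pca_component_limit():
    t = log2_table(np.random.default_rng(0).normal(size=(5, 48)))
    with pytest.raises(ValueError):
        damstats.pca_scores(t, 49)
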