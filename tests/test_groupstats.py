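"""Mixed-ANOVA tests against a naive sums-of-squares oracle and pingouin,
plus contrasts, t tests and per-group correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from alphacoupling import (
    Contrast,
    feature_neuropsych_corr,
    independent_t_d,
    mixed_anova,
    posthoc_pairwise,
)


def random_mixed_design(rng, n_per_group, within_levels):
    """Long-format balanced mixed design with random cell effects."""
    rows = []
    factors = [f"w{i}" for i in range(len(within_levels))]
    for g in ("A", "B"):
        for s in range(n_per_group):
            subj_eff = rng.normal(scale=0.8)
            for combo in itertools.product(
                *[range(L) for L in within_levels]
            ):
                rows.append(
                    {
                        "subject": f"{g}{s}",
                        "group": g,
                        **{f: f"l{c}" for f, c in zip(factors, combo)},
                        "y": rng.normal() + subj_eff + (0.5 if g == "B" else 0),
                    }
                )
    return pd.DataFrame(rows), factors


def oracle_split_plot(df, within):
    """Naive oracle: sums of squares from explicit marginal means.

    Implements the textbook balanced split-plot decomposition with loops
    over cells — a different algorithm from the tensor projections in the
    implementation.
    """
    groups = sorted(df["group"].unique())
    subjects = {g: sorted(df.loc[df["group"] == g, "subject"].unique()) for g in groups}
    n = len(subjects[groups[0]])
    levels = {w: sorted(df[w].unique()) for w in within}
    W = int(np.prod([len(levels[w]) for w in within]))
    grand = df["y"].mean()

    def cell_mean(**conds):
        m = np.ones(len(df), dtype=bool)
        for k, v in conds.items():
            m &= (df[k] == v).to_numpy()
        return df.loc[m, "y"].mean()

    out = {}
    # between group
    out["group"] = (
        n * W * sum((cell_mean(group=g) - grand) ** 2 for g in groups)
    )
    out["_subj"] = W * sum(
        (cell_mean(subject=s) - cell_mean(group=g)) ** 2
        for g in groups
        for s in subjects[g]
    )
    # within effects by inclusion-exclusion over marginal means
    def effect_value(subset, combo, extra=None):
        total = 0.0
        for r in range(len(subset) + 1):
            for sub2 in itertools.combinations(range(len(subset)), r):
                conds = {subset[i]: combo[i] for i in sub2}
                if extra:
                    conds.update(extra)
                total += (-1) ** (len(subset) - r) * cell_mean(**conds)
        return total

    m = len(within)
    for r in range(1, m + 1):
        for fs in itertools.combinations(within, r):
            reps = len(df) / np.prod([len(levels[f]) for f in fs])
            ss = reps * sum(
                effect_value(fs, combo) ** 2
                for combo in itertools.product(*[levels[f] for f in fs])
            )
            name = " * ".join(fs)
            out[name] = ss
            # interaction with group: SS(E×B) = SS(E within groups) − SS(E)
            reps_g = reps / len(groups)
            ss_wg = 0.0
            for g in groups:
                base = {"group": g}
                ss_wg += reps_g * sum(
                    effect_value(fs, combo, extra=base) ** 2
                    for combo in itertools.product(*[levels[f] for f in fs])
                )
            out[f"{name} * group"] = ss_wg - ss
            # error stratum: E × subject within groups
            reps_s = reps / (len(groups) * n)
            ss_ws = 0.0
            for g in groups:
                for s in subjects[g]:
                    base = {"subject": s}
                    ss_ws += reps_s * sum(
                        effect_value(fs, combo, extra=base) ** 2
                        for combo in itertools.product(*[levels[f] for f in fs])
                    )
            out[f"_err_{name}"] = ss_ws - ss - out[f"{name} * group"]
    return out


@pytest.mark.parametrize(
    "within_levels,n_per_group,seed",
    [((2,), 4, 0), ((2, 2), 5, 1), ((2, 2), 3, 2), ((3,), 4, 3), ((2, 3), 4, 4)],
)
def test_anova_matches_ss_oracle(within_levels, n_per_group, seed):
    """F statistics agree with the naive marginal-means oracle to 1e-8
    relative on random balanced designs."""
    rng = np.random.default_rng(seed)
    df, factors = random_mixed_design(rng, n_per_group, within_levels)
    got = mixed_anova(df, "y", "subject", "group", factors).set_index("effect")
    want = oracle_split_plot(df, factors)
    assert got.loc["group", "SS"] == pytest.approx(want["group"], rel=1e-8)
    assert got.loc["group", "SS_error"] == pytest.approx(want["_subj"], rel=1e-8)
    for r in range(1, len(factors) + 1):
        for fs in itertools.combinations(factors, r):
            name = " * ".join(fs)
            for eff in (name, f"{name} * group"):
                assert got.loc[eff, "SS"] == pytest.approx(want[eff], rel=1e-8, abs=1e-12)
            ss_err = want[f"_err_{name}"]
            F_want = (want[name] / got.loc[name, "df_num"]) / (
                ss_err / got.loc[name, "df_den"]
            )
            assert got.loc[name, "F"] == pytest.approx(F_want, rel=1e-8)


def test_anova_constant_data_all_zero_F():
    rows = [
        {"subject": f"{g}{s}", "group": g, "w0": w, "y": 3.0}
        for g in "AB" for s in range(3) for w in ("l0", "l1")
    ]
    out = mixed_anova(pd.DataFrame(rows), "y", "subject", "group", ["w0"])
    assert (out["F"] == 0.0).all()


def test_two_level_within_has_unit_epsilon():
    rng = np.random.default_rng(5)
    df, factors = random_mixed_design(rng, 6, (2, 2))
    out = mixed_anova(df, "y", "subject", "group", factors)
    assert (out["eps"] == 1.0).all()
    np.testing.assert_allclose(out["p_gg"], out["p_unc"])


def test_partial_eta_squared_identity():
    rng = np.random.default_rng(6)
    df, factors = random_mixed_design(rng, 5, (2,))
    out = mixed_anova(df, "y", "subject", "group", factors)
    for _, row in out.iterrows():
        assert row["partial_eta_sq"] == pytest.approx(
            row["SS"] / (row["SS"] + row["SS_error"]), abs=1e-12
        )
        assert 0.0 <= row["partial_eta_sq"] <= 1.0


def test_agrees_with_pingouin_two_way_mixed():
    """Independent cross-check of SS/F/dfs on a 3-level within design."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    df, factors = random_mixed_design(rng, 6, (3,))
    mine = mixed_anova(df, "y", "subject", "group", factors).set_index("effect")
    ref = pg.mixed_anova(
        df, dv="y", within="w0", subject="subject", between="group"
    ).set_index("Source")
    assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
    assert mine.loc["w0", "F"] == pytest.approx(ref.loc["w0", "F"], rel=1e-9)
    assert mine.loc["w0 * group", "F"] == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-9
    )
    assert mine.loc["w0", "df_num"] == ref.loc["w0", "DF1"]
    assert mine.loc["w0", "df_den"] == ref.loc["w0", "DF2"]
    # epsilon below 1 for a 3-level factor, within its theoretical range
    assert 1.0 / 2.0 <= mine.loc["w0", "eps"] <= 1.0


def test_unequal_group_sizes_rejected():
    rows = [
        {"subject": f"{g}{s}", "group": g, "w0": w, "y": float(s)}
        for g, ns in (("A", 3), ("B", 4)) for s in range(ns) for w in ("l0", "l1")
    ]
    with pytest.raises(ValueError, match="equal n"):
        mixed_anova(pd.DataFrame(rows), "y", "subject", "group", ["w0"])


def test_missing_cell_rejected():
    rows = [
        {"subject": f"{g}{s}", "group": g, "w0": w, "y": 1.0}
        for g in "AB" for s in range(2) for w in ("l0", "l1")
    ]
    with pytest.raises(ValueError, match="missing cell"):
        mixed_anova(pd.DataFrame(rows[:-1]), "y", "subject", "group", ["w0"])


class TestContrasts:
    def test_single_contrast_uncorrected(self):
        rng = np.random.default_rng(8)
        c = Contrast("a", rng.normal(size=10), rng.normal(size=10))
        out = posthoc_pairwise([c])
        assert out.loc[0, "p_bonferroni"] == pytest.approx(out.loc[0, "p"])

    def test_family_multiplies_p(self):
        rng = np.random.default_rng(9)
        fam = [
            Contrast(f"c{i}", rng.normal(size=8), rng.normal(size=8))
            for i in range(4)
        ]
        out = posthoc_pairwise(fam)
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, 4 * out["p"])
        )

    def test_empty_family_raises(self):
        with pytest.raises(ValueError):
            posthoc_pairwise([])

    def test_paired_contrast_uses_difference(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = posthoc_pairwise([Contrast("d", x + 0.5, x, paired=True)])
        assert out.loc[0, "df"] == 3
        assert out.loc[0, "estimate"] == pytest.approx(0.5)


class TestIndependentT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 2.0])
        out = independent_t_d(x, x)
        assert out["t"] == 0.0 and out["cohens_d"] == 0.0

    def test_df_for_28_per_group(self):
        rng = np.random.default_rng(10)
        out = independent_t_d(rng.normal(size=28), rng.normal(size=28))
        assert out["df"] == 54

    def test_matches_hand_formulas(self):
        x = np.array([5.0, 7.0, 6.0, 8.0])
        y = np.array([4.0, 5.0, 3.0, 4.0])
        nx = ny = 4
        sp2 = (3 * np.var(x, ddof=1) + 3 * np.var(y, ddof=1)) / 6
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        d_hand = (x.mean() - y.mean()) / np.sqrt(sp2)
        out = independent_t_d(x, y)
        assert out["t"] == pytest.approx(t_hand, abs=1e-12)
        assert out["cohens_d"] == pytest.approx(d_hand, abs=1e-12)
        assert out["df"] == 6

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            independent_t_d(np.ones(4), np.ones(4))


class TestFeatureNeuropsychCorr:
    def make_frames(self, n=5, seed=11):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"S{i}" for i in range(n)], name="subject")
        feats = pd.DataFrame(
            {"group": "HC", "f1": rng.normal(size=n), "f2": rng.normal(size=n)},
            index=idx,
        )
        scores = pd.DataFrame(
            {"group": "HC", "MMSE": rng.normal(28, 1, n), "BNT": feats["f1"]},
            index=idx,
        )
        return feats, scores

    def test_feature_equal_to_score_r_one(self):
        feats, scores = self.make_frames()
        out = feature_neuropsych_corr(feats, scores, "HC")
        row = out[(out.feature == "f1") & (out.test == "BNT")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_matches_direct_covariance(self):
        feats, scores = self.make_frames()
        out = feature_neuropsych_corr(feats, scores, "HC")
        x = feats["f2"].to_numpy()
        y = scores["MMSE"].to_numpy()
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        row = out[(out.feature == "f2") & (out.test == "MMSE")].iloc[0]
        assert row["r"] == pytest.approx(r_hand, abs=1e-12)

    def test_no_cross_group_pooling(self):
        feats, scores = self.make_frames()
        feats2 = feats.copy()
        feats2.loc["S0", "group"] = "MCI"
        scores2 = scores.copy()
        scores2.loc["S0", "group"] = "MCI"
        with pytest.raises(ValueError, match=">= 3"):
            feature_neuropsych_corr(feats2.iloc[:3], scores2.iloc[:3], "MCI")

    def test_null_feature_mean_r_near_zero(self):
        rng = np.random.default_rng(12)
        rs = []
        for seed in range(30):
            feats, scores = self.make_frames(n=20, seed=100 + seed)
            out = feature_neuropsych_corr(feats, scores, "HC")
            rs.append(out[(out.feature == "f2") & (out.test == "MMSE")].iloc[0]["r"])
        assert abs(np.mean(rs)) < 0.1
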