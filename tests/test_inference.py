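"""Linear model, selection, contrasts, GLS, and test statistics against
independent oracles (projection matrices, closed forms, scipy, enumeration)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reinfiso.errors import DomainError, FitError
from reinfiso.inference import (
    SOP_FULL_TERMS,
    backward_select,
    cohens_d,
    fit_gls_heteroskedastic,
    fit_linear_model,
    interaction,
    lsmeans_contrasts,
    main_effect,
    mann_whitney,
    nested,
    one_sample_t,
    wilcoxon_signed_rank,
)


def projection_anova(fit):
    """Independent Type III computation: quadratic forms in projection
    matrices built from the same design columns."""
    X, y = fit.X, fit.y
    n = len(y)
    P_full = X @ np.linalg.pinv(X)
    rss = float(y @ (np.eye(n) - P_full) @ y)
    df_resid = n - np.linalg.matrix_rank(X)
    out = {}
    for name, sl in fit.term_slices.items():
        keep = [i for i in range(X.shape[1]) if not (sl.start <= i < sl.stop)]
        Pr = X[:, keep] @ np.linalg.pinv(X[:, keep])
        ss = float(y @ (P_full - Pr) @ y)
        df_t = sl.stop - sl.start
        out[name] = (df_t, (ss / df_t) / (rss / df_resid))
    return out, df_resid


def random_nested_frame(rng, n_per_cell=3):
    rows = []
    pops = {"P1": "sympatric", "P2": "sympatric", "P3": "allopatric", "P4": "allopatric"}
    for pop, ctx in pops.items():
        for sex in ("female", "male"):
            for _ in range(n_per_cell):
                rows.append(
                    {"population": pop, "context": ctx, "sex": sex,
                     "sop": rng.normal()}
                )
    return pd.DataFrame(rows)


class TestAnova:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_projection_oracle_nested(self, seed):
        rng = np.random.default_rng(seed)
        df = random_nested_frame(rng)
        fit = fit_linear_model(df, SOP_FULL_TERMS)
        oracle, df_resid = projection_anova(fit)
        assert fit.anova.residual_df == df_resid
        for row in fit.anova.rows:
            df_t, f = oracle[row.term]
            assert row.df == df_t
            assert row.f_value == pytest.approx(f, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_projection_oracle_crossed(self, seed):
        rng = np.random.default_rng(100 + seed)
        df = pd.DataFrame(
            {
                "a": rng.choice(["x", "y", "z"], 30),
                "b": rng.choice(["u", "v"], 30),
                "sop": rng.normal(size=30),
            }
        )
        terms = [main_effect("a"), main_effect("b"), interaction("a", "b")]
        fit = fit_linear_model(df, terms, nesting={})
        oracle, _ = projection_anova(fit)
        for row in fit.anova.rows:
            assert row.f_value == pytest.approx(oracle[row.term][1], abs=1e-8)

    def test_two_level_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        df = pd.DataFrame(
            {"g": ["a"] * 12 + ["b"] * 12, "sop": np.concatenate([a, b])}
        )
        fit = fit_linear_model(df, [main_effect("g")], nesting={})
        t, _ = sps.ttest_ind(a, b)
        assert fit.anova.rows[0].f_value == pytest.approx(t**2, rel=1e-10)

    def test_nested_design_df_partition(self, sop_recs):
        fit = fit_linear_model(pd.DataFrame(
            {"population": [r.population for r in sop_recs],
             "context": [r.context.value for r in sop_recs],
             "sex": [r.sex.value for r in sop_recs],
             "sop": [r.sop for r in sop_recs]}), SOP_FULL_TERMS)
        dfs = {r.term: r.df for r in fit.anova.rows}
        assert dfs == {"context": 1, "sex": 1, "population(context)": 2,
                       "population:sex": 3}
        assert fit.anova.residual_df == fit.anova.n_obs - 8

    def test_constant_response_degenerate(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"], "sop": [1.0] * 4})
        fit = fit_linear_model(df, [main_effect("g")], nesting={})
        row = fit.anova.rows[0]
        assert row.degenerate and row.f_value == 0.0 and row.p_value == 1.0

    def test_rank_deficiency_names_term(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"],
             "sop": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(FitError, match="b"):
            fit_linear_model(df, [main_effect("a"), main_effect("b")], nesting={})


class TestBackwardSelect:
    def test_all_significant_keeps_full(self):
        rng = np.random.default_rng(0)
        df = random_nested_frame(rng, n_per_cell=8)
        eff = {"sympatric": 1.0, "allopatric": 0.0}
        df["sop"] += df["context"].map(eff)
        df.loc[df["sex"] == "male", "sop"] += 1.0
        df.loc[df["population"].isin(["P1", "P3"]), "sop"] += 1.0
        # pure population x sex pattern, orthogonal to the main effects
        sign = df["population"].map({"P1": 1, "P2": -1, "P3": 1, "P4": -1})
        df["sop"] += 2.0 * sign * np.where(df["sex"] == "male", 1.0, -1.0)
        final, trace, _ = backward_select(df, SOP_FULL_TERMS)
        assert {t.name for t in final} == {
            "context", "sex", "population(context)", "population:sex"
        }
        assert len(trace) == 1 and trace[-1].dropped is None

    def test_noise_interaction_dropped_before_main_effect(self):
        rng = np.random.default_rng(1)
        df = random_nested_frame(rng, n_per_cell=10)
        df["sop"] += np.where(df["context"] == "sympatric", 1.2, 0.0)
        final, trace, _ = backward_select(df, SOP_FULL_TERMS)
        names = {t.name for t in final}
        assert "context" in names
        dropped = [s.dropped for s in trace if s.dropped]
        assert "population:sex" in dropped
        # interaction must leave before the main effects it contains
        if "sex" in dropped:
            assert dropped.index("population:sex") < dropped.index("sex")

    def test_marginality_protects_main_effects(self):
        rng = np.random.default_rng(2)
        df = random_nested_frame(rng, n_per_cell=10)
        # pure interaction signal: sex effect differs by population only
        mask = (df["population"].isin(["P1", "P3"])) & (df["sex"] == "male")
        df.loc[mask, "sop"] += 2.0
        df.loc[~df["population"].isin(["P1", "P3"]) & (df["sex"] == "male"), "sop"] -= 2.0
        final, _, fit = backward_select(df, SOP_FULL_TERMS)
        names = {t.name for t in final}
        if "population:sex" in names:
            # retained interaction keeps sex and population(context) in place
            assert {"sex", "population(context)", "context"} <= names


class TestLsMeans:
    def test_balanced_lsmeans_equal_raw_means(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 4), "sop": rng.normal(size=12)}
        )
        fit = fit_linear_model(df, [main_effect("g")], nesting={})
        table = lsmeans_contrasts(fit, "g")
        raw = df.groupby("g")["sop"].mean()
        for lev, lsm in table.lsmeans.items():
            assert lsm == pytest.approx(raw[lev], abs=1e-10)

    def test_two_groups_adjusted_equals_raw(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5, "sop": rng.normal(size=10)})
        fit = fit_linear_model(df, [main_effect("g")], nesting={})
        (row,) = lsmeans_contrasts(fit, "g").rows
        assert row.p_adjusted == pytest.approx(row.p_raw)

    def test_contrast_matches_matrix_algebra(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 4), "sop": rng.normal(size=12)}
        )
        fit = fit_linear_model(df, [main_effect("g")], nesting={})
        table = lsmeans_contrasts(fit, "g")
        row = next(r for r in table.rows if r.pair == ("a", "b"))
        diff = df[df.g == "a"]["sop"].mean() - df[df.g == "b"]["sop"].mean()
        se = np.sqrt(fit.sigma2 * (1 / 4 + 1 / 4))
        assert row.estimate == pytest.approx(diff, abs=1e-10)
        assert row.se == pytest.approx(se, abs=1e-10)
        assert row.t_statistic == pytest.approx(diff / se, abs=1e-8)
        assert row.df == fit.residual_df
        assert row.p_adjusted == pytest.approx(min(1, 3 * row.p_raw))

    def test_population_sex_cells_on_nested_model(self, sop_recs):
        fit = fit_linear_model(
            pd.DataFrame(
                {"population": [r.population for r in sop_recs],
                 "context": [r.context.value for r in sop_recs],
                 "sex": [r.sex.value for r in sop_recs],
                 "sop": [r.sop for r in sop_recs]}
            ),
            SOP_FULL_TERMS,
        )
        table = lsmeans_contrasts(fit, ("population", "sex"))
        assert len(table.lsmeans) == 8
        assert table.family_size == 28
        assert all(r.df == fit.residual_df for r in table.rows)


def two_group_frame(rng, na=8, nb=10, mu=0.0, spread_b=3.0):
    y = np.concatenate([rng.normal(0, 1, na), rng.normal(mu, spread_b, nb)])
    return pd.DataFrame(
        {"context": ["allopatric"] * na + ["sympatric"] * nb, "y": y}
    )


class TestGls:
    def test_welch_closed_form(self):
        rng = np.random.default_rng(6)
        df = two_group_frame(rng, mu=1.5)
        fit = fit_gls_heteroskedastic(df, "y", ("context",), "context")
        a = df[df.context == "allopatric"]["y"]
        s = df[df.context == "sympatric"]["y"]
        coef = fit.coefficients["context[sympatric]"]
        assert coef.estimate == pytest.approx(s.mean() - a.mean(), abs=1e-10)
        welch_se = np.sqrt(a.var(ddof=1) / len(a) + s.var(ddof=1) / len(s))
        assert coef.se == pytest.approx(welch_se, abs=1e-8)
        assert fit.variance_groups["allopatric"] == pytest.approx(a.var(ddof=1), abs=1e-8)

    def test_homoskedastic_limit_equals_ols(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "context": rng.choice(["sympatric", "allopatric"], 20),
                "species": rng.choice(["s1", "s2"], 20),
                "y": rng.normal(size=20),
            }
        )
        df["one"] = "all"
        fit = fit_gls_heteroskedastic(df, "y", ("context", "species"), "one")
        X = np.column_stack(
            [
                np.ones(20),
                (df.context == "sympatric").astype(float),
                (df.species == "s2").astype(float),
            ]
        )
        beta_ols, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        est = [fit.coefficients[k].estimate for k in
               ("Intercept", "context[sympatric]", "species[s2]")]
        assert np.allclose(est, beta_ols, atol=1e-8)

    def test_small_variance_group_rejected(self):
        df = pd.DataFrame({"context": ["a", "b", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(FitError, match="fewer than 2"):
            fit_gls_heteroskedastic(df, "y", ("context",), "context")

    def test_replicate_correlation_option_runs(self):
        rng = np.random.default_rng(9)
        df = two_group_frame(rng, mu=1.0)
        df["rep"] = [f"r{i % 3}" for i in range(len(df))]
        fit = fit_gls_heteroskedastic(
            df, "y", ("context",), "context",
            replicate_col="rep", replicate_correlation=0.2,
        )
        assert np.isfinite(fit.coefficients["context[sympatric]"].estimate)
        assert np.isfinite(fit.log_likelihood)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.p_exact == pytest.approx(1 / 3)

    def test_identical_samples_symmetric(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u == pytest.approx(8.0)  # n^2 / 2
        assert abs(res.z) < 1e-12

    def test_shift_monotonicity(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        ps = [
            mann_whitney(a, [x + shift for x in a]).p_value
            for shift in (0.5, 2.0, 10.0)
        ]
        assert ps[0] >= ps[1] >= ps[2]

    def test_degenerate_flagged(self):
        assert mann_whitney([1, 1], [1, 1]).degenerate

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(np.arange(10.0))[:4]
        b = rng.normal(1.0, 1.0, 5)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_exact == pytest.approx(ref.pvalue, abs=1e-9)


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.w == 6.0
        assert res.p_exact == pytest.approx(0.25)

    def test_antisymmetric_pair_z_zero(self):
        res = wilcoxon_signed_rank([-2.0, 2.0])
        assert res.z == 0.0

    def test_paired_identical_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], paired_with=[1.0, 2.0, 3.0])
        assert res.degenerate and res.n_used == 0

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0])
        assert res.n_used == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(50 + seed)
        d = rng.normal(0.5, 1.0, 9)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
        assert ours.p_exact == pytest.approx(ref.pvalue, abs=1e-9)


class TestTAndEffectSize:
    def test_textbook_t(self):
        res = one_sample_t([1, 2, 3])
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2

    def test_mean_at_null(self):
        res = one_sample_t([-1.0, 0.0, 1.0], 0.0)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = [1.0, 2.0, 4.0, 8.0]
        r1, r2 = one_sample_t(a, 2.0), one_sample_t([3 * x for x in a], 6.0)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_zero_variance_degenerate(self):
        assert one_sample_t([2.0, 2.0, 2.0]).degenerate

    def test_cohens_d_hand_value(self):
        assert cohens_d([0, 1], [1, 2]).d == pytest.approx(-np.sqrt(2), abs=1e-10)

    def test_cohens_d_identical_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).d == 0.0

    def test_cohens_d_shift_linearity(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        d0 = cohens_d(a, b).d
        s_pool = (a.mean() - b.mean()) / d0 if d0 != 0 else 1.0
        d1 = cohens_d(a + s_pool, b).d
        assert d1 == pytest.approx(d0 + 1.0, rel=1e-9)

    def test_too_small_samples_rejected(self):
        with pytest.raises(DomainError):
            cohens_d([1.0], [1.0, 2.0])
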