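"""Multi-membership REML model: estimation, inference, contrasts, VIF."""

import numpy as np
import pandas as pd
import pytest

import socmix.mm as mm


def _dyad_frame(rng, n=120, n_birds=12, n_years=3, sd_bird=1.0, sd_year=0.5,
                sd_resid=1.0, beta=(1.0, 0.5, -0.3)):
    """Simulate a dyadic response with known effects and variance components."""
    birds = [f"b{i}" for i in range(n_birds)]
    u = rng.normal(0, sd_bird, n_birds)
    yr = rng.normal(0, sd_year, n_years)
    rows = []
    for _ in range(n):
        a, b = rng.choice(n_birds, 2, replace=False)
        year = int(rng.integers(0, n_years))
        x1, x2 = rng.normal(), rng.normal()
        y = (beta[0] + beta[1] * x1 + beta[2] * x2 + u[a] + u[b] + yr[year]
             + rng.normal(0, sd_resid))
        rows.append({"bird_a": birds[a], "bird_b": birds[b], "year": year,
                     "x1": x1, "x2": x2, "y": y})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    df = _dyad_frame(rng, n=300)
    design = mm.build_design(df, "y", ["x1", "x2"])
    return df, design, mm.fit_reml(design)


class TestBuildDesign:
    def test_multi_membership_rows_sum_to_two(self, fitted):
        _, design, _ = fitted
        Z = next(b.Z for b in design.blocks if b.name == "bird")
        assert np.all(np.asarray(Z.sum(axis=1)).ravel() == 2.0)
        row = Z[0].toarray().ravel()
        assert sorted(row[row > 0]) == [1.0, 1.0]

    def test_status_factor_expands_with_domdom_reference(self):
        rng = np.random.default_rng(1)
        df = _dyad_frame(rng, n=200)
        df["status_pair"] = rng.choice(["DomDom", "DomHelp", "DomSub",
                                        "HelpSub", "SubSub"], len(df))
        design = mm.build_design(df, "y", ["status_pair", "x1"])
        status_cols = [n for n in design.x_names if n.startswith("status_pair[")]
        assert status_cols == ["status_pair[DomHelp]", "status_pair[DomSub]",
                               "status_pair[HelpSub]", "status_pair[SubSub]"]
        assert design.factors["status_pair"][0] == "DomDom"

    def test_duplicated_covariate_raises_rank_error(self):
        rng = np.random.default_rng(2)
        df = _dyad_frame(rng, n=60)
        df["x1_copy"] = df["x1"]
        with pytest.raises(ValueError, match="aliased.*x1"):
            mm.build_design(df, "y", ["x1", "x1_copy"])


class TestFitREML:
    def test_collapses_to_ols_when_variances_fixed_at_zero(self):
        rng = np.random.default_rng(3)
        df = _dyad_frame(rng, n=150, sd_bird=0.0, sd_year=0.0)
        design = mm.build_design(df, "y", ["x1", "x2"])
        fit = mm.fit_reml(design, fix_variance={"bird": 0.0, "year": 0.0})
        X = design.X
        beta_ols, *_ = np.linalg.lstsq(X, design.y, rcond=None)
        assert np.allclose(fit.beta, beta_ols, rtol=1e-6)
        r = design.y - X @ beta_ols
        s2 = r @ r / (len(df) - X.shape[1])
        se_ols = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(fit.se, se_ols, rtol=1e-6)
        assert fit.df == pytest.approx(len(df) - X.shape[1])

    def test_balanced_one_way_anova_closed_form(self):
        # single grouping random effect, balanced: REML = ANOVA estimators
        rng = np.random.default_rng(4)
        g, m = 12, 8  # groups, replicates per group
        u = rng.normal(0, 1.3, g)
        y = np.repeat(u, m) + rng.normal(0, 0.7, g * m)
        df = pd.DataFrame({"y": y, "grp": np.repeat([f"g{i}" for i in range(g)], m)})
        design = mm.build_design(df, "y", [], random_terms=("grp",))
        fit = mm.fit_reml(design)
        ybar = y.reshape(g, m).mean(axis=1)
        msb = m * ((ybar - y.mean()) ** 2).sum() / (g - 1)
        msw = ((y.reshape(g, m) - ybar[:, None]) ** 2).sum() / (g * (m - 1))
        assert fit.varcomp["residual"] == pytest.approx(msw, rel=1e-5)
        assert fit.varcomp["grp"] == pytest.approx((msb - msw) / m, rel=1e-4)

    def test_variance_recovery_on_large_instance(self):
        rng = np.random.default_rng(5)
        df = _dyad_frame(rng, n=2000, n_birds=60, sd_bird=1.0, sd_resid=1.0)
        design = mm.build_design(df, "y", ["x1", "x2"])
        fit = mm.fit_reml(design)
        assert fit.converged
        assert fit.varcomp["bird"] == pytest.approx(1.0, abs=0.35)
        assert fit.varcomp["residual"] == pytest.approx(1.0, abs=0.2)
        assert fit.beta[1] == pytest.approx(0.5, abs=0.1)

    def test_row_order_and_bird_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        df = _dyad_frame(rng, n=150)
        design = mm.build_design(df, "y", ["x1", "x2"])
        fit = mm.fit_reml(design)

        perm = rng.permutation(len(df))
        fit_p = mm.fit_reml(mm.build_design(df.iloc[perm], "y", ["x1", "x2"]))
        assert np.allclose(fit.beta, fit_p.beta, atol=1e-8)
        assert fit.reml_loglik == pytest.approx(fit_p.reml_loglik, abs=1e-7)

        rename = {f"b{i}": f"zz{i:03d}" for i in range(12)}
        df_r = df.assign(bird_a=df.bird_a.map(rename), bird_b=df.bird_b.map(rename))
        fit_r = mm.fit_reml(mm.build_design(df_r, "y", ["x1", "x2"]))
        assert np.allclose(fit.beta, fit_r.beta, atol=1e-8)

    def test_member_swap_symmetry(self):
        rng = np.random.default_rng(7)
        df = _dyad_frame(rng, n=150)
        swapped = df.assign(bird_a=df.bird_b, bird_b=df.bird_a)
        fit = mm.fit_reml(mm.build_design(df, "y", ["x1", "x2"]))
        fit_s = mm.fit_reml(mm.build_design(swapped, "y", ["x1", "x2"]))
        assert np.array_equal(fit.beta, fit_s.beta)
        assert fit.reml_loglik == fit_s.reml_loglik


class TestSatterthwaite:
    def test_df_bounded_by_residual_df(self, fitted):
        _, design, fit = fitted
        assert (fit.df <= fit.n_obs - len(fit.beta) + 1e-9).all()
        assert (fit.df >= 1).all()

    def test_zero_variance_gives_residual_df(self):
        rng = np.random.default_rng(8)
        df = _dyad_frame(rng, n=100, sd_bird=0.0, sd_year=0.0)
        design = mm.build_design(df, "y", ["x1"])
        fit = mm.fit_reml(design, fix_variance={"bird": 0.0, "year": 0.0})
        c = np.zeros(len(fit.beta))
        c[1] = 1.0
        assert mm.satterthwaite_df(fit, c) == pytest.approx(fit.n_obs - 2)

    def test_intercept_df_shrinks_with_random_structure(self, fitted):
        _, _, fit = fitted
        # the intercept is informed by few year/bird levels; covariate slopes
        # by nearly all observations
        assert fit.df[0] < fit.df[1]


class TestWaldTable:
    def test_structure_and_tstat(self, fitted):
        _, _, fit = fitted
        tab = mm.wald_table(fit)
        assert list(tab.columns) == ["term", "beta", "se", "statistic", "df", "p"]
        assert np.allclose(tab["statistic"], tab["beta"] / tab["se"])
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()

    def test_se_scales_with_sqrt_n(self):
        rng = np.random.default_rng(9)
        ses = []
        for n in (200, 800):
            df = _dyad_frame(rng, n=n, sd_bird=0.0, sd_year=0.0)
            fit = mm.fit_reml(mm.build_design(df, "y", ["x1"]),
                              fix_variance={"bird": 0.0, "year": 0.0})
            ses.append(fit.se[1])
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.25)


@pytest.fixture(scope="module")
def status_fit():
    rng = np.random.default_rng(10)
    df = _dyad_frame(rng, n=400, n_birds=20)
    effects = {"DomDom": 0.0, "DomHelp": -0.1, "DomSub": -1.0,
               "HelpSub": -1.0, "SubSub": -1.2}
    df["status_pair"] = rng.choice(list(effects), len(df))
    df["y"] = df["y"] + df["status_pair"].map(effects)
    design = mm.build_design(df, "y", ["status_pair", "x1"])
    return mm.fit_reml(design)


class TestTukey:

    def test_five_levels_give_ten_contrasts(self, status_fit):
        tab = mm.tukey_contrasts(status_fit, "status_pair")
        assert len(tab) == 10
        assert (tab["p_adjusted"] >= tab["p_unadjusted"] - 1e-12).all()

    def test_two_level_factor_adjusted_equals_unadjusted(self):
        rng = np.random.default_rng(11)
        df = _dyad_frame(rng, n=200)
        df["nest_sharing"] = rng.choice(["nest_sharing", "non_nest_sharing"],
                                        len(df))
        fit = mm.fit_reml(mm.build_design(df, "y", ["nest_sharing", "x1"]))
        tab = mm.tukey_contrasts(fit, "nest_sharing")
        assert len(tab) == 1
        assert tab["p_adjusted"].iloc[0] == tab["p_unadjusted"].iloc[0]

    def test_absent_factor_raises(self, status_fit):
        with pytest.raises(KeyError):
            mm.tukey_contrasts(status_fit, "season")

    def test_omnibus_detects_the_simulated_separation(self, status_fit):
        F, df1, df2, p = mm.omnibus_wald(status_fit, "status_pair")
        assert df1 == 4
        assert p < 1e-4


class TestVIF:
    @pytest.mark.parametrize("r", [0.0, 0.5, 0.8])
    def test_two_predictor_closed_form(self, r):
        rng = np.random.default_rng(12)
        n = 500
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z1 -= z1.mean(); z2 -= z2.mean()
        z1 /= np.linalg.norm(z1)
        z2 -= (z2 @ z1) * z1  # exact orthogonalisation
        z2 /= np.linalg.norm(z2)
        x2 = r * z1 + np.sqrt(1 - r ** 2) * z2  # sample corr(x1,x2) == r
        df = pd.DataFrame({"x1": z1, "x2": x2, "y": rng.normal(size=n),
                           "bird_a": "a", "bird_b": "b", "year": 0})
        design = mm.build_design(df, "y", ["x1", "x2"], random_terms=())
        v = mm.vif(design)
        expected = 1.0 if r == 0 else 1.0 / (1.0 - r ** 2)
        assert v["x1"] == pytest.approx(expected, abs=1e-8)
        assert v["x2"] == pytest.approx(expected, abs=1e-8)

    def test_near_duplicates_reported_uncapped(self):
        rng = np.random.default_rng(13)
        n = 300
        x1 = rng.normal(size=n)
        df = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 1e-3, n),
                           "y": rng.normal(size=n),
                           "bird_a": "a", "bird_b": "b", "year": 0})
        v = mm.vif(mm.build_design(df, "y", ["x1", "x2"], random_terms=()))
        assert v["x1"] > 1e3
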