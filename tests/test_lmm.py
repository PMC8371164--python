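"""Design construction, REML estimation and Satterthwaite inference."""

import numpy as np
import pandas as pd
import pytest

from hbfkit.lmm import (
    DesignMatrices,
    GroupSpec,
    ModelSpec,
    build_design,
    fit_reml,
    interaction_profile,
    satterthwaite_test,
)


def two_factor_table(n_per_cell=5, seed=0):
    gen = np.random.default_rng(seed)
    rows = []
    for d1 in (0, 1, 2):
        for d2 in (0, 1, 2):
            for i in range(n_per_cell):
                rows.append(
                    {
                        "y": 20 + 5 * d1 + 3 * d2 + 2 * d1 * d2 + gen.normal(0, 2),
                        "d1": d1, "d2": d2,
                        "donor": f"D{gen.integers(2) + 1}",
                        "guide": f"g{gen.integers(2) + 1}",
                    }
                )
    return pd.DataFrame(rows)


SPEC2 = ModelSpec(
    response="y", fixed_terms=["d1", "d2"], interaction_pairs=[("d1", "d2")],
    random_groups=[GroupSpec("donor"), GroupSpec("guide")],
)


class TestBuildDesign:
    def test_dimension_counting(self):
        """2 donors + 1 condition and 2 mains + 1 interaction: p=4, q=3."""
        t = two_factor_table().assign(guide="g1")
        dm = build_design(t, SPEC2)
        assert dm.p == 4
        assert dm.q == 3
        assert dm.x_names == ["(Intercept)", "d1", "d2", "d1:d2"]

    def test_interaction_column_is_product(self):
        dm = build_design(two_factor_table(), SPEC2)
        np.testing.assert_array_equal(dm.X[:, 3], dm.X[:, 1] * dm.X[:, 2])

    def test_excluded_rows_dropped(self):
        t = two_factor_table()
        t["exclude_flag"] = False
        t.loc[:4, "exclude_flag"] = True
        dm = build_design(t, SPEC2)
        assert dm.n == len(t) - 5
        assert dm.n_dropped == 5

    def test_reference_level_gets_no_indicator(self):
        t = two_factor_table()
        spec = ModelSpec(
            response="y", fixed_terms=["d1", "d2"],
            random_groups=[GroupSpec("guide", reference="g1")],
        )
        dm = build_design(t, spec)
        assert "g1" not in dm.z_levels[0]
        assert dm.z_blocks[0].shape[1] == t["guide"].nunique() - 1
        # reference rows are all-zero in this block
        ref_rows = (t["guide"] == "g1").to_numpy()
        assert not dm.z_blocks[0][ref_rows].any()

    @pytest.mark.parametrize(
        "mutate,match",
        [
            (lambda t: t.drop(columns=["d2"]), "missing"),
            (lambda t: t.assign(d1=1), "constant"),
            (lambda t: t.iloc[:0], "no usable rows"),
        ],
    )
    def test_errors(self, mutate, match):
        with pytest.raises((KeyError, ValueError), match=match):
            build_design(mutate(two_factor_table()), SPEC2)

    def test_interaction_pair_must_be_in_mains(self):
        with pytest.raises(ValueError, match="fixed_terms"):
            ModelSpec(response="y", fixed_terms=["d1"],
                      interaction_pairs=[("d1", "d2")])


class TestREML:
    def test_zero_variance_limit_equals_ols(self, balanced_oneway):
        """With no random components the GLS estimate collapses to OLS."""
        k, m, table = balanced_oneway
        spec = ModelSpec(response="y", fixed_terms=["x"])
        dm = build_design(table, spec)
        fit = fit_reml(dm)
        ols = np.linalg.lstsq(dm.X, dm.y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-8)

    def test_balanced_oneway_matches_anova_closed_form(self, balanced_oneway):
        """REML components equal the ANOVA method-of-moments estimates on
        a balanced one-way design (interior optimum)."""
        k, m, table = balanced_oneway
        spec = ModelSpec(response="y", fixed_terms=["x"],
                         random_groups=[GroupSpec("grp")])
        dm = build_design(table, spec)
        # intercept-only closed form requires dropping the covariate
        dm0 = DesignMatrices(
            y=dm.y, X=dm.X[:, :1], x_names=["(Intercept)"],
            z_blocks=dm.z_blocks, z_names=dm.z_names, z_levels=dm.z_levels,
        )
        fit = fit_reml(dm0)
        y = dm.y.reshape(k, m)
        gm = y.mean(axis=1)
        msb = m * np.sum((gm - y.mean()) ** 2) / (k - 1)
        msw = np.sum((y - gm[:, None]) ** 2) / (k * (m - 1))
        assert fit.sigma2["residual"] == pytest.approx(msw, abs=1e-6)
        assert fit.sigma2["grp"] == pytest.approx((msb - msw) / m, abs=1e-6)
        # GLS at the fitted components equals the grand mean here
        assert fit.beta[0] == pytest.approx(gm.mean(), abs=1e-8)

    def test_matches_statsmodels_mixedlm(self, balanced_oneway):
        """Independent cross-check of the full fit against statsmodels."""
        import statsmodels.formula.api as smf

        _, _, table = balanced_oneway
        spec = ModelSpec(response="y", fixed_terms=["x"],
                         random_groups=[GroupSpec("grp")])
        fit = fit_reml(build_design(table, spec))
        sm_fit = smf.mixedlm("y ~ x", table, groups=table["grp"]).fit(reml=True)
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params.values, atol=1e-5)
        assert fit.sigma2["residual"] == pytest.approx(sm_fit.scale, rel=1e-4)
        assert fit.sigma2["grp"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3
        )

    def test_row_permutation_invariance(self):
        t = two_factor_table(seed=3)
        fit_a = fit_reml(build_design(t, SPEC2))
        fit_b = fit_reml(build_design(t.sample(frac=1.0, random_state=1), SPEC2))
        # row order only changes floating-point summation order
        np.testing.assert_allclose(fit_a.beta, fit_b.beta, rtol=1e-6)
        assert fit_a.reml_loglik == pytest.approx(fit_b.reml_loglik, abs=1e-6)

    def test_recovers_generating_coefficients(self):
        """Mean estimate over replicates within Monte-Carlo error of the
        generating betas."""
        betas = []
        for rep in range(60):
            t = two_factor_table(n_per_cell=8, seed=100 + rep)
            betas.append(fit_reml(build_design(t, SPEC2)).beta)
        betas = np.array(betas)
        truth = np.array([20.0, 5.0, 3.0, 2.0])
        mc_se = betas.std(axis=0, ddof=1) / np.sqrt(len(betas))
        assert np.all(np.abs(betas.mean(axis=0) - truth) < 4 * mc_se)

    def test_boundary_component_flagged(self):
        gen = np.random.default_rng(5)
        t = pd.DataFrame(
            {"y": gen.normal(size=80), "x": gen.normal(size=80),
             "grp": np.repeat([f"g{i}" for i in range(8)], 10)}
        )
        spec = ModelSpec(response="y", fixed_terms=["x"],
                         random_groups=[GroupSpec("grp")])
        fit = fit_reml(build_design(t, spec))
        # no group signal: the component sits at (or near) zero
        assert fit.sigma2["grp"] < 0.05
        if fit.sigma2["grp"] == 0.0:
            assert fit.boundary == ["grp"]


class TestSatterthwaite:
    def test_fixed_effects_only_df_is_n_minus_p(self):
        t = two_factor_table()
        spec = ModelSpec(response="y", fixed_terms=["d1", "d2"],
                         interaction_pairs=[("d1", "d2")])
        dm = build_design(t, spec)
        fit = fit_reml(dm)
        np.testing.assert_allclose(fit.df, dm.n - dm.p, rtol=1e-10)

    def test_balanced_oneway_intercept_df_is_k_minus_1(self, balanced_oneway):
        k, m, table = balanced_oneway
        spec = ModelSpec(response="y", fixed_terms=["x"],
                         random_groups=[GroupSpec("grp")])
        dm = build_design(table, spec)
        dm0 = DesignMatrices(
            y=dm.y, X=dm.X[:, :1], x_names=["(Intercept)"],
            z_blocks=dm.z_blocks, z_names=dm.z_names, z_levels=dm.z_levels,
        )
        fit = fit_reml(dm0)
        df, _ = satterthwaite_test(fit, dm0, np.array([1.0]))
        assert df == pytest.approx(k - 1, rel=1e-6)

    def test_contrast_shape_checked(self, balanced_oneway):
        _, _, table = balanced_oneway
        spec = ModelSpec(response="y", fixed_terms=["x"],
                         random_groups=[GroupSpec("grp")])
        dm = build_design(table, spec)
        fit = fit_reml(dm)
        with pytest.raises(ValueError, match="length"):
            satterthwaite_test(fit, dm, np.array([1.0, 0.0, 0.0]))


class TestInteractionProfile:
    def make_fit(self, interaction=2.0, seed=0):
        gen = np.random.default_rng(seed)
        rows = []
        for d1 in (0, 1, 2):
            for d2 in (0, 1, 2):
                for _ in range(6):
                    rows.append(
                        {"y": 10 + 4 * d1 + 2 * d2 + interaction * d1 * d2
                              + gen.normal(0, 0.01),
                         "d1": d1, "d2": d2}
                    )
        t = pd.DataFrame(rows)
        spec = ModelSpec(response="y", fixed_terms=["d1", "d2"],
                         interaction_pairs=[("d1", "d2")])
        dm = build_design(t, spec)
        return fit_reml(dm), dm

    def test_zero_interaction_gives_parallel_lines(self):
        """A fit whose interaction coefficient is exactly zero yields
        exactly parallel profile lines."""
        fit, dm = self.make_fit(interaction=0.0)
        fit.beta[fit.x_names.index("d1:d2")] = 0.0
        prof = interaction_profile(fit, dm, {"d1": [0, 1, 2], "d2": [0, 2]})
        wide = prof.pivot(index="d1", columns="d2", values="predicted")
        gaps = wide[2] - wide[0]
        np.testing.assert_allclose(gaps, gaps.iloc[0], atol=1e-6)

    def test_prediction_at_zero_dosage_is_intercept(self):
        fit, dm = self.make_fit()
        prof = interaction_profile(fit, dm, {"d1": [0], "d2": [0]})
        assert prof.loc[0, "predicted"] == pytest.approx(fit.beta[0])

    def test_synergy_steepens_slopes(self):
        """A positive interaction makes the d1 slope increase with d2."""
        fit, dm = self.make_fit(interaction=2.0)
        prof = interaction_profile(fit, dm, {"d1": [0, 2], "d2": [0, 1, 2]})
        wide = prof.pivot(index="d2", columns="d1", values="predicted")
        slopes = (wide[2] - wide[0]) / 2.0
        assert slopes.is_monotonic_increasing
        assert slopes.iloc[-1] > slopes.iloc[0] + 1.0

    def test_ci_bands_contain_point_estimates(self):
        fit, dm = self.make_fit()
        prof = interaction_profile(fit, dm, {"d1": [0, 1, 2], "d2": [0, 1, 2]})
        assert ((prof["ci_low"] <= prof["predicted"])
                & (prof["predicted"] <= prof["ci_high"])).all()

    def test_extrapolation_warns(self):
        fit, dm = self.make_fit()
        with pytest.warns(UserWarning, match="beyond"):
            interaction_profile(fit, dm, {"d1": [0, 5], "d2": [0]})
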