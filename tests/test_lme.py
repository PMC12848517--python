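"""REML engine, Satterthwaite df, contrast tests, Welch t-test."""

import numpy as np
import pandas as pd
import pytest

import littervol as lv
from littervol.lme import design_matrix

from oracles import reml_criterion_direct, reml_grid_search


def _random_small_dataset(seed):
    """Small cohort + response with seed-varying litter/residual variance."""
    rng = np.random.default_rng(seed)
    design = lv.generate_cohort(4, max_litter_size=4, seed=seed)
    X, litter, _ = design_matrix(design)
    sd_l = rng.uniform(0.0, 0.2)
    sd_r = rng.uniform(0.05, 0.15)
    b = rng.normal(0, sd_l, litter.max() + 1)
    y = 1.0 + 0.1 * X[:, 2] + b[litter] + rng.normal(0, sd_r, len(X))
    return design, X, litter, y


class TestremlFit:
    @pytest.mark.parametrize("seed", range(20))
    def test_optimum_matches_brute_force_grid(self, seed):
        design, X, litter, y = _random_small_dataset(seed)
        fit = lv.fit_lme(y, design)
        lam_grid, crit_grid, grid = reml_grid_search(y, X, litter, n_grid=10_000)
        crit_fit = reml_criterion_direct(y, X, litter, fit.lam)
        # the fitted optimum is at least as good as any of 10,000 grid points
        assert crit_fit <= crit_grid + 1e-8
        if not fit.boundary and lam_grid > 0:
            log_step = np.log(grid[2] / grid[1])
            assert abs(np.log(fit.lam) - np.log(lam_grid)) <= log_step

    def test_singleton_litters_reduce_to_ols(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "sex": ["F", "M"] * 6,
                "diet": ["CD"] * 6 + ["HFHSS"] * 6,
                "litter_id": [f"L{i}" for i in range(12)],
            }
        )
        design = lv.CohortDesign(df)
        rng = np.random.default_rng(0)
        y = rng.normal(1.0, 0.1, 12)
        fit = lv.fit_lme(y, design)
        assert fit.boundary and fit.sigma2_litter == 0.0
        X, _, _ = design_matrix(design)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-10)

    def test_balanced_design_diet_estimate_equals_ols(self):
        # equal litter sizes, equal litter counts, even sex split: GLS = OLS
        rows = []
        for diet in ("CD", "HFHSS"):
            for i in range(4):
                for j, sex in enumerate(["F", "F", "M", "M"]):
                    rows.append(
                        {
                            "sample_id": f"{diet}{i}{j}",
                            "sex": sex,
                            "diet": diet,
                            "litter_id": f"{diet}_L{i}",
                        }
                    )
        design = lv.CohortDesign(pd.DataFrame(rows))
        X, litter, _ = design_matrix(design)
        rng = np.random.default_rng(3)
        y = 1.0 + 0.05 * X[:, 1] + rng.normal(0, 0.1, litter.max() + 1)[litter] \
            + rng.normal(0, 0.05, len(X))
        fit = lv.fit_lme(y, design)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert not fit.boundary
        assert fit.beta[1] == pytest.approx(beta_ols[1], abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": list("abcdefgh"),
                "sex": ["F"] * 8,  # missing sex level
                "diet": ["CD"] * 4 + ["HFHSS"] * 4,
                "litter_id": ["L1"] * 4 + ["L2"] * 4,
            }
        )
        with pytest.raises(lv.lme.RankDeficientDesignError):
            lv.LmeWorkspace(lv.CohortDesign(df))

    def test_series_response_aligned_by_sample_id(self, study_design):
        params = lv.StructureParams("s", 1.0, 1.0, 0.02, 0.05)
        rel = lv.simulate_relative_volumes(study_design, [params], seed=0)
        shuffled = rel["s"].sample(frac=1.0, random_state=1)
        fit_a = lv.fit_lme(rel["s"], study_design)
        fit_b = lv.fit_lme(shuffled, study_design)
        np.testing.assert_allclose(fit_a.beta, fit_b.beta)


class TestSatterthwaite:
    def test_boundary_gives_residual_df(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "sex": ["F", "M"] * 6,
                "diet": ["CD"] * 6 + ["HFHSS"] * 6,
                "litter_id": [f"L{i}" for i in range(12)],
            }
        )
        design = lv.CohortDesign(df)
        y = np.random.default_rng(1).normal(size=12)
        fit = lv.fit_lme(y, design)
        assert fit.boundary
        assert lv.satterthwaite_df(fit, lv.DIET_CONTRAST) == 12 - 4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_litter_dominated_balanced_case_near_between_litter_df(self, seed):
        # litter variance >> residual: the diet test runs on litter means,
        # so df should approach n_litters - 2 (here 20 - 2 = 18)
        rows = []
        for diet in ("CD", "HFHSS"):
            for i in range(10):
                for j, sex in enumerate(["F", "F", "M", "M"]):
                    rows.append(
                        {
                            "sample_id": f"{diet}{i}{j}",
                            "sex": sex,
                            "diet": diet,
                            "litter_id": f"{diet}_L{i}",
                        }
                    )
        design = lv.CohortDesign(pd.DataFrame(rows))
        sp = lv.StructureParams("s", 1.0, 1.0, 1.0, 0.05)
        rel = lv.simulate_relative_volumes(design, [sp], seed=seed)
        fit = lv.fit_lme(rel["s"], design)
        df = lv.satterthwaite_df(fit, lv.DIET_CONTRAST)
        assert df == pytest.approx(18.0, rel=0.10)

    @pytest.mark.parametrize("seed", range(8))
    def test_df_clamped_to_valid_range(self, seed, study_design):
        sp = lv.StructureParams("s", 1.0, 1.0, 0.03, 0.08)
        rel = lv.simulate_relative_volumes(study_design, [sp], seed=seed)
        fit = lv.fit_lme(rel["s"], study_design)
        for c in (lv.DIET_CONTRAST, lv.SEX_CONTRAST, lv.INTERACTION_CONTRAST):
            df = lv.satterthwaite_df(fit, c)
            assert 0 < df <= fit.n - fit.p


class TestContrastTests:
    def test_pvalues_invariant_to_affine_rescaling(self, study_design):
        sp = lv.StructureParams("s", 1.0, 1.0, 0.03, 0.08)
        rel = lv.simulate_relative_volumes(study_design, [sp], seed=3)
        y = rel["s"].to_numpy()
        ct1 = lv.test_contrast(lv.fit_lme(y, study_design), lv.DIET_CONTRAST)
        ct2 = lv.test_contrast(lv.fit_lme(5.0 + 3.0 * y, study_design), lv.DIET_CONTRAST)
        assert ct1.t == pytest.approx(ct2.t, abs=1e-7)
        assert ct1.df == pytest.approx(ct2.df, rel=1e-6)
        assert ct1.p == pytest.approx(ct2.p, abs=1e-8)

    def test_against_lme4_lmertest_reference(self):
        """Frozen reference values from an independent REML/Satterthwaite
        implementation (lme4 + lmerTest) on this exact generated dataset."""
        design = lv.generate_cohort(8, seed=42)
        sp = lv.StructureParams("ref", 0.9, 0.95, 0.05, 0.10)
        rel = lv.simulate_relative_volumes(design, [sp], seed=7)
        fit = lv.fit_lme(rel["ref"].to_numpy(), design)
        assert fit.sigma2_litter == pytest.approx(0.00175856221501, rel=1e-5)
        assert fit.sigma2_resid == pytest.approx(0.00970358985330, rel=1e-5)
        expected = {
            # contrast: (estimate, se, df, p)
            "intercept": (0.92422567922044, 0.0216502258210, 11.9913746564, 1.80484414117e-14),
            "diet": (0.00916551216602, 0.0310974274564, 12.6398886552, 0.772981000738),
            "sex": (0.06966088932028, 0.0312339386314, 58.1221078218, 0.0296033749317),
            "diet_sex": (-0.03551736491767, 0.0454449890249, 58.4586079422, 0.437635133004),
        }
        contrasts = dict(zip(lv.lme.FIXED_EFFECTS, np.eye(4)))
        for name, (est, se, df, p) in expected.items():
            ct = lv.test_contrast(fit, contrasts[name])
            assert ct.estimate == pytest.approx(est, rel=1e-6)
            assert ct.se == pytest.approx(se, rel=1e-5)
            assert ct.df == pytest.approx(df, rel=1e-3)
            assert ct.p == pytest.approx(p, rel=1e-3, abs=1e-12)

    def test_against_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        design = lv.generate_cohort(8, seed=42)
        sp = lv.StructureParams("ref", 0.9, 0.95, 0.05, 0.10)
        rel = lv.simulate_relative_volumes(design, [sp], seed=7)
        y = rel["ref"].to_numpy()
        fit = lv.fit_lme(y, design)
        X, litter, _ = design_matrix(design)
        sm_fit = sm.MixedLM(y, X, groups=litter).fit(reml=True)
        np.testing.assert_allclose(fit.beta, np.asarray(sm_fit.fe_params), atol=1e-6)
        assert fit.sigma2_litter == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3
        )
        assert fit.sigma2_resid == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_type_one_error_calibrated_while_naive_ols_inflated(self):
        # litter-level exposure with strong litter effects (ICC 0.5): the
        # mixed model should hold its nominal 5% level, naive OLS should not
        design = lv.generate_cohort(
            10, max_litter_size=4, litter_size_weights=[0, 0, 0, 1.0], seed=0
        )
        ws = lv.LmeWorkspace(design)
        X = ws.X
        XtXinv = np.linalg.inv(X.T @ X)
        n, p = X.shape
        from scipy import stats

        sp = lv.StructureParams("s", 1.0, 1.0, 0.1, 0.1)
        n_rep = 1200
        lme_rej = ols_rej = 0
        rng_master = np.random.SeedSequence(99)
        for child in rng_master.spawn(n_rep):
            rng = np.random.default_rng(child)
            y = 1.0 + rng.normal(0, 0.1, ws.n_litters)[ws.litter_index] \
                + rng.normal(0, 0.1, n)
            fit = ws.fit(y)
            lme_rej += lv.test_contrast(fit, lv.DIET_CONTRAST).p < 0.05
            beta = XtXinv @ (X.T @ y)
            resid = y - X @ beta
            se = np.sqrt(resid @ resid / (n - p) * XtXinv[1, 1])
            p_ols = 2 * stats.t.sf(abs(beta[1] / se), n - p)
            ols_rej += p_ols < 0.05
        assert 0.03 <= lme_rej / n_rep <= 0.07  # within 3 MC SE of nominal
        assert ols_rej / n_rep > 0.10  # clearly inflated


class TestWelch:
    def test_hand_computed_example(self):
        ct = lv.welch_t_test([1, 2, 3], [2, 3, 4])
        assert ct.t == pytest.approx(-1.2247, abs=1e-4)
        assert ct.df == pytest.approx(4.0, abs=1e-9)
        assert ct.p == pytest.approx(0.2878, abs=1e-3)

    def test_identical_vectors(self):
        ct = lv.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ct.t == 0.0 and ct.p == 1.0

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(0.5, 2.0, size=14)
        ours = lv.welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_separation_limit(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        ct = lv.welch_t_test(a, a + 1000.0)
        assert ct.p < 1e-6

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            lv.welch_t_test([1.0], [1.0, 2.0])

    def test_constant_unequal_samples_rejected(self):
        with pytest.raises(ValueError):
            lv.welch_t_test([1.0, 1.0], [2.0, 2.0])
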