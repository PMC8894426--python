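"""Linear models, variance moderation, BH, and pairwise tests.

The moderated pipeline is checked three ways: against closed-form /
brute-force oracles, against parameter recovery on simulated variances,
and against frozen reference values computed once with the standard
empirical-Bayes linear-modeling implementation on the same seeded
fixture.
"""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import polygamma

import metabophen as mp
import metabophen.diffabund as da
from metabophen.containers import ValidationError


def _eb_fixture():
    """8 samples x 40 features, heterogeneous variances, 5 true effects."""
    rng = np.random.default_rng(42)
    n, p = 8, 40
    age = rng.uniform(5, 50, n)
    sex = np.array([0, 1] * 4)
    grp = np.array([0] * 4 + [1] * 4)
    sig = np.sqrt(0.5 * 4 / rng.chisquare(4, p))
    y = rng.normal(0, 1, (n, p)) * sig + 0.8 * grp[:, None] * (np.arange(p) < 5)
    frame = pd.DataFrame(
        y, index=[str(i) for i in range(n)], columns=[f"M{j:03d}" for j in range(p)]
    )
    X = np.column_stack([np.ones(n), grp, age, sex])
    design = da.DesignMatrix(
        X, ["intercept", "grp", "age", "sex"], list(frame.index), ["grp"]
    )
    return frame, design


class TestDesign:
    def test_two_group_shape(self, cohort):
        d = mp.build_design(cohort, ("ASD_DD", "CANCER"))
        assert d.X.shape == (20, 4)
        assert d.contrast_cols == ["group_CANCER"]

    def test_three_group_shape(self, cohort):
        d = mp.build_design(cohort, "three_group")
        assert d.X.shape == (30, 5)
        assert len(d.contrast_cols) == 2

    def test_constant_sex_rejected(self):
        meta = mp.generate_cohort(n_per_group=5, n_female_per_group=5, seed=0)
        with pytest.raises(da.DesignError, match="sex"):
            mp.build_design(meta, ("ASD_DD", "CANCER"))


class TestLinearFits:
    def test_matches_normal_equations_oracle(self, rng):
        frame, design = _eb_fixture()
        fits = mp.fit_linear_models(frame, design)
        X = design.X
        for j, feat in enumerate(fits.features[:10]):
            beta = np.linalg.solve(X.T @ X, X.T @ frame[feat].to_numpy())
            assert fits.coef[j, 0] == pytest.approx(beta[1], abs=1e-8)
            resid = frame[feat].to_numpy() - X @ beta
            assert fits.sigma2[j] == pytest.approx(
                resid @ resid / (len(resid) - 4), rel=1e-8
            )

    def test_perfect_fit_zero_residual(self, cohort):
        d = mp.build_design(cohort, ("ASD_DD", "CANCER"))
        y = pd.DataFrame({"f": d.X[:, 1]}, index=d.sample_ids)
        fits = mp.fit_linear_models(y, d)
        assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-18)

    def test_planted_effect_unbiased(self):
        """beta_hat averages to the planted 1.0 log effect across features."""
        rng = np.random.default_rng(1)
        n_per = 10
        grp = np.array([0] * n_per + [1] * n_per)
        X = np.column_stack([np.ones(2 * n_per), grp,
                             rng.uniform(5, 50, 2 * n_per),
                             np.tile([0, 1], n_per)])
        design = da.DesignMatrix(
            X, ["intercept", "grp", "age", "sex"],
            [str(i) for i in range(2 * n_per)], ["grp"],
        )
        y = rng.normal(0, 0.5, (2 * n_per, 500)) + grp[:, None] * 1.0
        frame = pd.DataFrame(y, index=design.sample_ids)
        fits = mp.fit_linear_models(frame, design)
        assert abs(fits.coef[:, 0].mean() - 1.0) < 0.05


class TestVariancePrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = mp.fit_variance_prior(np.full(100, 2.5), 16)
        assert np.isinf(prior.d0)
        # bias-corrected geometric mean, close to (but not exactly) 2.5
        assert prior.s0_sq == pytest.approx(2.5, rel=0.1)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        d0, s0, dg = 4.0, 1.0, 16
        s2 = s0 * d0 / rng.chisquare(d0, 5000) * rng.chisquare(dg, 5000) / dg
        prior = mp.fit_variance_prior(s2, dg)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0, rel=0.10)

    @pytest.mark.parametrize("x", [1e-5, 0.01, 0.5, 2.0, 50.0, 1e6])
    def test_trigamma_inverse_against_bisection(self, x):
        y = da.trigamma_inverse(x)
        lo, hi = 1e-8, 1e9
        for _ in range(200):
            mid = (lo + hi) / 2
            if polygamma(1, mid) > x:
                lo = mid
            else:
                hi = mid
        assert y == pytest.approx((lo + hi) / 2, rel=1e-8)


class TestModeratedTest:
    # frozen reference values computed once with the standard R
    # empirical-Bayes implementation (limma::eBayes) on _eb_fixture()
    LIMMA_D0 = 7.612643288
    LIMMA_S0SQ = 0.6409235841
    LIMMA_ROWS = {
        "M000": (1.27037543212369, 2.2049641478805, 0.048421597348174),
        "M003": (1.61637677375446, 3.2839801575407, 0.006802556306355),
        "M005": (-0.26369112086328, -0.4839409014959, 0.637425403097252),
    }

    def test_matches_frozen_reference(self):
        frame, design = _eb_fixture()
        fits = mp.fit_linear_models(frame, design)
        prior = mp.fit_variance_prior(fits.sigma2, fits.df_residual)
        res = mp.moderated_test(fits, prior)
        assert prior.d0 == pytest.approx(self.LIMMA_D0, rel=1e-8)
        assert prior.s0_sq == pytest.approx(self.LIMMA_S0SQ, rel=1e-8)
        for feat, (coef, t, p) in self.LIMMA_ROWS.items():
            assert res.loc[feat, "coef"] == pytest.approx(coef, rel=1e-9)
            assert res.loc[feat, "t_moderated"] == pytest.approx(t, rel=1e-9)
            assert res.loc[feat, "p_raw"] == pytest.approx(p, rel=1e-8)

    def test_signs_agree_and_shrinkage_direction(self):
        frame, design = _eb_fixture()
        fits = mp.fit_linear_models(frame, design)
        prior = mp.fit_variance_prior(fits.sigma2, fits.df_residual)
        res = mp.moderated_test(fits, prior)
        assert (np.sign(res["t_ordinary"]) == np.sign(res["t_moderated"])).all()
        low_var = fits.sigma2 < prior.s0_sq
        assert (res["t_moderated"].abs() <= res["t_ordinary"].abs() + 1e-12)[low_var].all()
        assert (res["t_moderated"].abs() >= res["t_ordinary"].abs() - 1e-12)[~low_var].all()

    def test_infinite_d0_pools_completely(self):
        frame, design = _eb_fixture()
        fits = mp.fit_linear_models(frame, design)
        prior = da.ModerationPrior(np.inf, 0.5)
        res = mp.moderated_test(fits, prior)
        se = np.sqrt(fits.cov_unscaled[0, 0] * 0.5)
        assert np.allclose(res["t_moderated"], fits.coef[:, 0] / se)

    def test_null_p_values_uniform_single_batch(self):
        from metabophen.synthdata import generate_tables
        cohort = mp.generate_cohort(seed=11, n_batches=1)
        tabs = generate_tables(cohort, n_cell_mets=2000, n_media_mets=10,
                               n_shared=10, n_panel=0, n_panel_cells_only=0,
                               n_panel_media_only=0, seed=7)
        norm = mp.normalize_matrix(tabs.cells)
        res = mp.moderated_test(
            mp.fit_linear_models(norm, mp.build_design(cohort))
        )
        assert stats.kstest(res["p_raw"], "uniform").pvalue > 0.01

    def test_null_discoveries_controlled_with_batches_and_imputation(self, cohort):
        """Batch median scaling and minimum-value imputation perturb the raw
        p-value distribution mildly, but adjusted discoveries on null data
        stay controlled."""
        from metabophen.synthdata import generate_tables
        tabs = generate_tables(cohort, n_cell_mets=2000, n_media_mets=10,
                               n_shared=10, n_panel=0, n_panel_cells_only=0,
                               n_panel_media_only=0, seed=7)
        norm = mp.normalize_matrix(tabs.cells)
        res = mp.moderated_test(
            mp.fit_linear_models(norm, mp.build_design(cohort))
        )
        p = res["p_raw"].to_numpy()
        assert (p < 0.05).mean() < 0.10
        assert int(res["significant"].sum()) == 0

    def test_moderation_beats_ordinary_t_at_small_n(self):
        """3/group with dispersed variances: moderation finds more planted
        effects at the same adjusted-significance cut."""
        rng = np.random.default_rng(21)
        reps, n_true, p = 200, 20, 200
        mod_hits = ord_hits = 0
        grp = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        X = np.column_stack([np.ones(6), grp])
        design = da.DesignMatrix(X, ["intercept", "grp"], list("abcdef"), ["grp"])
        for _ in range(reps):
            sig = np.sqrt(0.25 * 4 / rng.chisquare(4, p))
            y = rng.normal(0, 1, (6, p)) * sig
            y[:, :n_true] += grp[:, None] * 3 * 0.5
            frame = pd.DataFrame(y, index=design.sample_ids)
            fits = mp.fit_linear_models(frame, design)
            res = mp.moderated_test(fits)
            p_ord = 2 * stats.t.sf(np.abs(res["t_ordinary"]), fits.df_residual)
            mod_hits += res["significant"][:n_true].sum()
            ord_hits += (mp.adjust_bh(p_ord) < 0.05)[:n_true].sum()
        assert mod_hits > ord_hits


class TestBH:
    def test_stepup_example(self):
        assert np.allclose(mp.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert mp.adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=200)
        ours = mp.adjust_bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_properties(self, p):
        adj = mp.adjust_bh(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mp.adjust_bh([0.5, 1.5])


class TestPairwise:
    def test_wilcoxon_exact_enumeration_example(self, cohort, rng):
        """[1,2,3] vs [4,5,6]: 2 of 20 rank assignments are as extreme."""
        frame = pd.DataFrame(
            {"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
            index=cohort.frame.index[[0, 1, 2, 10, 11, 12]],
        )
        meta = cohort.subset(frame.index)
        p = da.pairwise_tests(frame, meta, "ASD_DD", "CANCER", "wilcoxon")
        assert p["f"] == pytest.approx(0.1, rel=1e-9)

    def test_identical_groups_p_one(self, cohort):
        frame = pd.DataFrame(
            {"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            index=cohort.frame.index[[0, 1, 2, 10, 11, 12]],
        )
        meta = cohort.subset(frame.index)
        p = da.pairwise_tests(frame, meta, "ASD_DD", "CANCER", "wilcoxon")
        assert p["f"] == pytest.approx(1.0)

    def test_welch_matches_oracle(self, cohort, rng):
        ids = list(cohort.frame.index[:20])
        frame = pd.DataFrame(rng.normal(size=(20, 5)), index=ids)
        meta = cohort.subset(ids)
        p = da.pairwise_tests(frame, meta, "ASD_DD", "CANCER", "student_t")
        a = frame.loc[meta.frame["group"] == "ASD_DD"]
        b = frame.loc[meta.frame["group"] == "CANCER"]
        for j in range(5):
            # Welch statistic and Welch-Satterthwaite df by hand
            va, vb = a[j].var(ddof=1) / 10, b[j].var(ddof=1) / 10
            t = (a[j].mean() - b[j].mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / 9 + vb**2 / 9)
            assert p[j] == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-10)
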