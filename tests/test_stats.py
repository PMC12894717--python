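"""Design assembly, mixed-model fitting, VIF screening and basic tests."""

import numpy as np
import pandas as pd
import pytest

import isletscope as isc
from isletscope.stats import (
    BIOMARKER_EFFECTS,
    ModelSpec,
    aic_select,
    anova_f,
    assemble_design,
    fit_gmlm,
    model_diagnostics,
    t_test,
    vif_screen,
    z_test,
)
from isletscope.synthetic import ValidationError


@pytest.fixture(scope="module")
def study_tables():
    cohort = isc.generate_cohort(100, 35, 9, seed=4)
    bio = isc.simulate_biomarker_table(cohort, isc.EffectConfig(), seed=4)
    return cohort, bio


class TestAssembleDesign:
    def test_status_design_has_600_rows(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.diabetes_status())
        assert d.X.shape[0] == 600
        assert d.group_counts_ok if hasattr(d, "group_counts_ok") else True
        assert len(d.group_levels["staining"]) == 6
        assert len(d.group_levels["cohort"]) == 2

    def test_homa2b_design_drops_missing_to_546(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b())
        assert d.X.shape[0] == 546

    def test_standardization_contract(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.diabetes_status())
        age = d.X[:, d.columns.index("age")]
        assert abs(age.mean()) < 1e-10 and np.isclose(age.std(ddof=1), 1.0)
        sex = d.X[:, d.columns.index("sex")]
        assert set(np.unique(sex)) <= {0.0, 1.0}  # binary left as indicator

    def test_interaction_built_after_standardization(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b())
        a = d.X[:, d.columns.index("adipocyte_cluster_area")]
        b = d.X[:, d.columns.index("bmi")]
        inter = d.X[:, d.columns.index("adipocyte_cluster_area:bmi")]
        np.testing.assert_allclose(inter, a * b)

    def test_orphan_biomarkers_rejected(self, study_tables):
        cohort, bio = study_tables
        bad = bio.copy()
        bad.loc[0, "patient_id"] = "GHOST"
        with pytest.raises(ValidationError, match="GHOST"):
            assemble_design(cohort, bad, ModelSpec.diabetes_status())


class TestGMLM:
    @staticmethod
    def _lme4_fit(design, tmp_path, family=None):
        """Fit the same model with lme4 via Rscript (independent oracle)."""
        import subprocess

        df = pd.DataFrame(
            design.X[:, 1:], columns=[f"x{i}" for i in range(design.X.shape[1] - 1)]
        )
        df["y"] = design.y if family != "binomial" else design.y.astype(int)
        df["staining"] = design.frame["staining"].to_numpy()
        df["cohort"] = design.frame["cohort"].to_numpy()
        csv = tmp_path / "design.csv"
        df.to_csv(csv, index=False)
        fixed = " + ".join(f"x{i}" for i in range(design.X.shape[1] - 1))
        call = (
            f'glmer(y ~ {fixed} + (1|staining) + (1|cohort), data=d, family=binomial, nAGQ=1)'
            if family == "binomial"
            else f"lmer(y ~ {fixed} + (1|staining) + (1|cohort), data=d, REML=FALSE)"
        )
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            f"m <- {call};"
            'cat(logLik(m), "\\n"); cat(fixef(m), "\\n"); cat(sqrt(diag(vcov(m))), "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=240
        )
        assert out.returncode == 0, out.stderr[-500:]
        lines = out.stdout.strip().split("\n")
        return (
            float(lines[0]),
            np.array(lines[1].split(), dtype=float),
            np.array(lines[2].split(), dtype=float),
        )

    def test_gaussian_matches_lme4_oracle(self, study_tables, tmp_path):
        """Laplace-ML fit equals lme4's ML fit (crossed random intercepts)."""
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b())
        fit = fit_gmlm(d)
        ll, coefs, ses = self._lme4_fit(d, tmp_path)
        assert np.isclose(fit.loglik, ll, atol=1e-3)
        np.testing.assert_allclose(fit.params["estimate"].to_numpy(), coefs, atol=1e-4)
        np.testing.assert_allclose(fit.params["se"].to_numpy(), ses, rtol=1e-3)

    def test_binomial_matches_glmer_oracle(self, study_tables, tmp_path):
        """Binomial Laplace-ML fit equals glmer's Laplace fit."""
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.diabetes_status())
        fit = fit_gmlm(d)
        ll, coefs, ses = self._lme4_fit(d, tmp_path, family="binomial")
        assert np.isclose(fit.loglik, ll, atol=1e-3)
        np.testing.assert_allclose(fit.params["estimate"].to_numpy(), coefs, atol=1e-3)
        np.testing.assert_allclose(fit.params["se"].to_numpy(), ses, rtol=1e-3)

    def test_gaussian_loglik_equals_closed_form(self, study_tables):
        from scipy.stats import multivariate_normal

        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b())
        fit = fit_gmlm(d)
        n = d.X.shape[0]
        V = fit.dispersion * np.eye(n)
        for factor, sd in zip(fit.random_effects["factor"], fit.random_effects["sd"]):
            codes = d.groups[factor]
            Z = np.zeros((n, codes.max() + 1))
            Z[np.arange(n), codes] = 1
            V += sd**2 * Z @ Z.T
        ll = multivariate_normal.logpdf(d.y, mean=d.X @ fit.params["estimate"].to_numpy(), cov=V)
        assert np.isclose(ll, fit.loglik, atol=1e-6)

    def test_planted_binomial_recovery(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.diabetes_status())
        fit = fit_gmlm(d)
        assert fit.converged and fit.nobs == 600
        p = fit.params
        assert p.loc["islet_mean_area", "estimate"] < 0
        assert p.loc["adipocyte_cluster_area", "estimate"] > 0
        assert p.loc["islet_adipocyte_distance", "estimate"] < 0
        assert (p.loc[list(BIOMARKER_EFFECTS), "p"] < 0.05).sum() >= 3

    def test_aic_loglik_identity(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b())
        fit = fit_gmlm(d)
        k = len(fit.params) + len(fit.random_effects) + 1  # + dispersion
        assert np.isclose(fit.aic, 2 * k - 2 * fit.loglik)

    def test_identical_cohorts_zero_variance(self):
        """When group structure carries no signal the variance hits the
        zero boundary and is reported as 0, not dropped."""
        rng = np.random.default_rng(0)
        n = 300
        frame = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "staining": "insulin",
                "x": rng.normal(0, 1, n),
            }
        )
        cohort = pd.DataFrame(
            {
                "patient_id": frame["patient_id"],
                "y": 2.0 * frame["x"] + rng.normal(0, 1, n),
                "cohort": np.where(np.arange(n) % 2 == 0, "A", "B"),
            }
        )
        spec = ModelSpec(response="y", family="gaussian", fixed_effects=("x",), zstandardize=False)
        d = assemble_design(cohort, frame, spec)
        fit = fit_gmlm(d)
        assert fit.random_effects.set_index("factor").loc["staining", "sd"] < 1e-3
        assert fit.random_effects.set_index("factor").loc["cohort", "sd"] < 0.2

    def test_diabetes_duration_model(self, study_tables):
        """Duration model controls for status; status dominates duration."""
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.diabetes_duration())
        fit = fit_gmlm(d)
        assert fit.nobs == 600
        assert fit.params.loc["diabetic_status", "estimate"] > 0
        assert fit.params.loc["diabetic_status", "p"] < 0.001

    def test_gamma_family_fits(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b(family="gamma"))
        fit = fit_gmlm(d)
        assert fit.converged
        assert fit.dispersion > 0


class TestAicSelect:
    def test_argmin_and_ties(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b())
        gauss = fit_gmlm(d)
        dg = assemble_design(cohort, bio, ModelSpec.homa2b(family="gamma"))
        gamma = fit_gmlm(dg)
        # differing nobs -> rejected
        if gauss.nobs == gamma.nobs:
            best = aic_select([gauss, gamma])
            assert best.aic == min(gauss.aic, gamma.aic)
        assert aic_select([gauss]) is gauss
        with pytest.warns(UserWarning):
            aic_select([gauss, gauss])

    def test_recomputed_aic_matches(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.diabetes_status())
        fit = fit_gmlm(d)
        k = len(fit.params) + len(fit.random_effects)
        assert np.isclose(fit.aic, 2 * k - 2 * fit.loglik)


class TestVif:
    def test_constructed_collinearity_removed(self, study_tables):
        """benign = 1 - malignant - pancreatitis is perfectly collinear and
        the later-declared effect is dropped."""
        cohort, _ = study_tables
        frame = cohort.copy()
        frame["benign_tumor"] = 1 - frame["malignant_tumor"] - frame["chronic_pancreatitis"]
        retained, table, dropped = vif_screen(
            frame, ["malignant_tumor", "chronic_pancreatitis", "benign_tumor"]
        )
        assert dropped == ["benign_tumor"]
        assert set(retained) == {"malignant_tumor", "chronic_pancreatitis"}

    def test_orthogonal_covariates_vif_near_one(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        retained, table, dropped = vif_screen(frame, ["a", "b", "c"])
        assert dropped == []
        assert (table["vif"] < 1.1).all()

    def test_duplicated_column_detected(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"a": rng.normal(size=100)})
        frame["b"] = frame["a"]
        frame["c"] = rng.normal(size=100)
        retained, _, dropped = vif_screen(frame, ["a", "c", "b"])
        assert dropped == ["b"] and "a" in retained


class TestBasicTests:
    def test_identical_groups(self):
        a = np.arange(10.0)
        res = t_test(a, a.copy())
        assert abs(res.statistic) < 1e-12 and res.pvalue > 0.99

    def test_two_group_anova_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        t = t_test(a, b)
        f = anova_f(a, b)
        assert np.isclose(f.statistic, t.statistic**2)
        assert np.isclose(f.pvalue, t.pvalue)

    def test_z_test_null(self):
        res = z_test(0.0, 1.0)
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert not res.significant
        with pytest.raises(ValidationError):
            z_test(1.0, 0.0)


class TestDiagnostics:
    def test_near_perfect_predictor_confusion(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(0, 1, n)
        y = (x + rng.normal(0, 0.1, n) > 0).astype(float)
        frame = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)], "staining": "s", "x": x})
        cohort = pd.DataFrame({"patient_id": frame["patient_id"], "y": y, "cohort": "A"})
        spec = ModelSpec(response="y", family="binomial", fixed_effects=("x",),
                         random_effects=("cohort",), zstandardize=False)
        d = assemble_design(cohort, frame, spec)
        fit = fit_gmlm(d)
        diag = model_diagnostics(fit, d)
        cm = diag["confusion_matrix"]
        assert cm.sum() == n
        assert diag["accuracy"] > 0.9
        assert cm[0, 0] + cm[1, 1] >= 0.9 * n

    def test_gaussian_residuals_and_qq(self, study_tables):
        cohort, bio = study_tables
        d = assemble_design(cohort, bio, ModelSpec.homa2b())
        fit = fit_gmlm(d)
        diag = model_diagnostics(fit, d)
        assert abs(diag["residuals"].mean()) < 0.05
        qq = diag["qq"]
        r = np.corrcoef(qq["theoretical"], qq["sample"])[0, 1]
        assert r > 0.98
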