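"""Random-intercept effect models: EMMs, ratios, odds ratios, VIF."""

import shutil

import numpy as np
import pandas as pd
import pytest

from enclospace.effects import (
    FittedConditionModel,
    ModelSpec,
    UndefinedRatioError,
    effect_ratio,
    estimated_marginal_means,
    fit_condition_model,
    variance_inflation,
)
from enclospace.synth import generate_binomial_sessions

REFS = {"condition": "Standard", "sex": "female"}


def _balanced_gaussian():
    rows = []
    means = {("Standard", "female"): 10.0, ("Standard", "male"): 12.0,
             ("Complex", "female"): 20.0, ("Complex", "male"): 22.0}
    for i in range(8):
        sex = "male" if i % 2 else "female"
        for cond in ("Standard", "Complex"):
            rows.append({"subject_id": f"S{i}", "sex": sex, "condition": cond,
                         "y": means[(cond, sex)]})
    return pd.DataFrame(rows)


def _manual_fit(beta: dict, family: str = "binomial") -> FittedConditionModel:
    names = list(beta)
    spec = ModelSpec("y", family, weights="n" if family == "binomial" else None,
                     reference_levels=REFS)
    return FittedConditionModel(
        spec=spec,
        params=pd.Series(beta),
        cov=pd.DataFrame(np.eye(len(names)) * 1e-4, index=names, columns=names),
        tau=0.0,
        levels={"condition": ["Standard", "Complex"], "sex": ["female", "male"]},
        converged=True,
        residuals=np.zeros(4),
        residual_skew=0.0,
        backend="manual",
    )


class TestGaussianModel:
    def test_balanced_emms_equal_group_means(self):
        df = _balanced_gaussian()
        fit = fit_condition_model(
            df, ModelSpec("y", "gaussian", reference_levels=REFS)
        )
        emms = estimated_marginal_means(fit).emms.set_index(["factor", "level"])
        # equal-weight average over sex: Standard (10+12)/2, Complex (20+22)/2
        assert emms.loc[("condition", "Standard"), "emm"] == pytest.approx(11.0, abs=1e-6)
        assert emms.loc[("condition", "Complex"), "emm"] == pytest.approx(21.0, abs=1e-6)

    def test_emm_ratio_and_reciprocal(self):
        df = _balanced_gaussian()
        fit = fit_condition_model(
            df, ModelSpec("y", "gaussian", reference_levels=REFS)
        )
        ab = effect_ratio(fit, "condition", "Complex", "Standard")
        ba = effect_ratio(fit, "condition", "Standard", "Complex")
        assert ab["estimate"] == pytest.approx(21.0 / 11.0, abs=1e-6)
        assert ab["estimate"] * ba["estimate"] == pytest.approx(1.0)

    def test_negative_denominator_rejected(self):
        fit = _manual_fit({"Intercept": -5.0, "condition[Complex]": 1.0,
                           "sex[male]": 0.0}, family="gaussian")
        with pytest.raises(UndefinedRatioError):
            effect_ratio(fit, "condition", "Complex", "Standard")


class TestBinomialModel:
    def test_constant_response_or_near_one(self):
        rows = []
        for i in range(6):
            for cond in ("Standard", "Complex"):
                for _ in range(10):
                    rows.append({"subject_id": f"S{i}", "sex": "female",
                                 "condition": cond, "y": 0.3, "n": 20})
        df = pd.DataFrame(rows)
        fit = fit_condition_model(
            df, ModelSpec("y", "binomial", fixed=("condition",), weights="n",
                          reference_levels=REFS)
        )
        out = effect_ratio(fit, "condition", "Complex", "Standard")
        assert out["estimate"] == pytest.approx(1.0, abs=1e-3)

    def test_no_heterogeneity_matches_contingency_or(self):
        # identical subjects: the GLMM collapses to the pooled 2x2 table
        rows = []
        for i in range(8):
            for cond, p in (("Standard", 0.2), ("Complex", 0.4)):
                for _ in range(6):
                    rows.append({"subject_id": f"S{i}", "sex": "female",
                                 "condition": cond, "y": p, "n": 20})
        df = pd.DataFrame(rows)
        fit = fit_condition_model(
            df, ModelSpec("y", "binomial", fixed=("condition",), weights="n",
                          reference_levels=REFS)
        )
        pooled_or = (0.4 / 0.6) / (0.2 / 0.8)
        out = effect_ratio(fit, "condition", "Complex", "Standard")
        assert out["estimate"] == pytest.approx(pooled_or, rel=1e-2)
        assert fit.tau < 0.05

    def test_logit_emm_half_back_transforms_to_half(self):
        fit = _manual_fit({"Intercept": 0.0, "condition[Complex]": 0.0,
                           "sex[male]": 0.0})
        emms = estimated_marginal_means(fit).emms
        assert np.allclose(emms["emm"], 0.5)

    def test_or_forced_by_back_transformation(self):
        fit = _manual_fit({"Intercept": -2.0,
                           "condition[Complex]": np.log(4.96),
                           "sex[male]": 0.3})
        out = effect_ratio(fit, "condition", "Complex", "Standard")
        assert out["estimate"] == pytest.approx(4.96)

    def test_recovers_known_effect_within_ci(self, rng):
        df = generate_binomial_sessions(rng, n_subjects=12)
        fit = fit_condition_model(
            df, ModelSpec("y", "binomial", weights="n", reference_levels=REFS)
        )
        out = effect_ratio(fit, "condition", "Complex", "Standard")
        assert out["ci_low"] <= 2.5 <= out["ci_high"]
        assert fit.converged


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R backend not installed")
class TestGlmmTMBOracle:
    def test_agrees_with_glmmtmb(self, rng):
        """The quadrature fitter matches the reference mixed-model package
        on a small fixture (coefficients and SEs to ~1%)."""
        df = generate_binomial_sessions(rng, n_subjects=8,
                                        sessions_per_condition=24)
        spec = ModelSpec("y", "binomial", fixed=("condition",), weights="n",
                         reference_levels=REFS)
        mine = fit_condition_model(df, spec)
        ref = fit_condition_model(df, spec, backend="glmmtmb")
        b = "condition[Complex]"
        assert mine.params[b] == pytest.approx(ref.params[b], abs=0.01)
        assert np.sqrt(mine.cov.loc[b, b]) == pytest.approx(
            np.sqrt(ref.cov.loc[b, b]), rel=0.05
        )
        assert mine.tau == pytest.approx(ref.tau, abs=0.05)


class TestResidualFallback:
    def test_skew_threshold_flags_descriptive(self):
        fit = _manual_fit({"Intercept": 0.0, "condition[Complex]": 0.0,
                           "sex[male]": 0.0})
        fit.residual_skew = 1.5
        assert fit.descriptive_fallback
        fit.residual_skew = -0.4
        assert not fit.descriptive_fallback


class TestVIF:
    def test_orthogonal_design(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]})
        out = variance_inflation(X)
        assert np.allclose(out["vif"], 1.0)
        assert not out["flagged"].any()

    def test_duplicated_column_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out = variance_inflation(X)
        assert np.isinf(out["vif"]).all()
        assert out["flagged"].all()

    def test_correlation_half_closed_form(self):
        z1 = np.array([1.0, 1, -1, -1])
        z2 = np.array([1.0, -1, 1, -1])
        X = pd.DataFrame({"a": z1, "b": 0.5 * z1 + np.sqrt(0.75) * z2})
        out = variance_inflation(X)
        assert np.allclose(out["vif"], 1 / (1 - 0.25))
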