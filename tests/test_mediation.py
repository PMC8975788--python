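"""Weights, WLS fitting, effect arithmetic, standardization, robust-SE diagnostic."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ipdmed as im
from ipdmed import Arm
from ipdmed.data_model import IPDDataset, ModelSpec
from ipdmed.mediation import WeightVector, design_matrix
from .conftest import make_small_design


def _uniform_weights(n):
    return WeightVector(np.ones(n), "uniform")


class TestWeights:
    def test_single_study_normalizes_to_unity(self, small_design):
        one = make_small_design(studies=[small_design.studies[0]])
        ds, _ = im.generate_multistudy(one, seed=1)
        w = im.compute_weights(ds)
        assert np.allclose(w.w, 1.0)

    def test_inverse_root_size_proportionality(self, complete_data):
        ds, _ = complete_data
        w = im.compute_weights(ds)
        per_study = pd.Series(w.w, index=ds.df["study"].to_numpy())
        sizes = ds.study_sizes
        # weight ratio between studies equals sqrt of inverse size ratio
        w9 = per_study.loc["9"].iloc[0]
        w8b = per_study.loc["8b"].iloc[0]
        assert w9 / w8b == pytest.approx(np.sqrt(sizes["8b"] / sizes["9"]), rel=1e-12)
        assert w.w.sum() == pytest.approx(ds.n, rel=1e-12)
        # raw (unnormalized) weight for a study of n=314 is 1/sqrt(314)
        assert 1.0 / np.sqrt(314) == pytest.approx(0.05643, abs=5e-6)

    def test_two_to_one_ratio_for_quadruple_size(self):
        df = pd.DataFrame({
            "study": ["a"] * 100 + ["b"] * 400,
            "arm": [Arm.CONTROL] * 500,
            **{v: np.zeros(500) for v in ("bl_mediator", "post_mediator", "bl_outcome",
                                          "post_outcome", "male", "firstyr", "nonwhite")},
        })
        w = im.compute_weights(IPDDataset(df))
        assert w.w[0] / w.w[-1] == pytest.approx(2.0, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([1.0, 0.0]), "uniform")


class TestFitEquation:
    def test_noiseless_equations_interpolate_truth(self):
        # a noiseless mediator equation makes the post-baseline mediator an exact
        # linear combination of the outcome equation's other regressors, so each
        # equation must be checked in its own noiseless limit
        design = make_small_design(resid_sd_A=0.0, resid_sd_B=0.5)
        ds, _ = im.generate_multistudy(design, seed=3)
        spec = im.detect_estimable_terms(ds)
        w = im.compute_weights(ds)
        fitA = im.fit_equation(ds, spec, "A", w)
        for t, v in design.eqA_coef.items():
            assert fitA.coefficients[t] == pytest.approx(v, abs=1e-8)
        assert fitA.r_squared == pytest.approx(1.0, abs=1e-10)

        design = make_small_design(resid_sd_A=0.5, resid_sd_B=0.0)
        ds, _ = im.generate_multistudy(design, seed=3)
        fitB = im.fit_equation(ds, im.detect_estimable_terms(ds), "B",
                               im.compute_weights(ds))
        for t, v in design.eqB_coef.items():
            assert fitB.coefficients[t] == pytest.approx(v, abs=1e-8)

    def test_matches_pseudoinverse_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(40, 80))
            ds = _random_dataset(rng, n)
            spec = im.detect_estimable_terms(ds)
            w = _uniform_weights(n)
            fit = im.fit_equation(ds, spec, "A", w)
            X = design_matrix(ds, spec.eqA_terms)
            beta_oracle = np.linalg.pinv(X) @ ds.df["post_mediator"].to_numpy()
            assert np.allclose(list(fit.coefficients.values()), beta_oracle, atol=1e-8)

    def test_weight_scale_invariance(self, small_data):
        ds, _ = small_data
        spec = im.detect_estimable_terms(ds)
        w1 = im.compute_weights(ds)
        w2 = WeightVector(2.0 * w1.w, w1.scheme, normalized=False)
        f1 = im.fit_equation(ds, spec, "B", w1)
        f2 = im.fit_equation(ds, spec, "B", w2)
        for t in spec.eqB_terms:
            assert f1.coefficients[t] == pytest.approx(f2.coefficients[t], rel=1e-10)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-10)

    def test_rank_deficiency_names_collinear_terms(self, small_data):
        ds, _ = small_data
        df = ds.df.copy()
        df["bl_outcome"] = df["bl_mediator"]  # force exact collinearity
        spec = im.detect_estimable_terms(ds)
        with pytest.raises(np.linalg.LinAlgError, match="BL_"):
            im.fit_equation(IPDDataset(df), spec, "A", _uniform_weights(len(df)))

    def test_r_squared_within_unit_interval(self, small_data):
        ds, _ = small_data
        spec = im.detect_estimable_terms(ds)
        fit = im.fit_mediation(ds, spec, im.compute_weights(ds))
        assert 0.0 <= fit.eqA.r_squared <= 1.0
        assert 0.0 <= fit.eqB.r_squared <= 1.0


def _random_dataset(rng, n):
    df = pd.DataFrame({
        "study": rng.choice(["u", "v"], size=n),
        "arm": [Arm(a) for a in rng.choice([a.value for a in Arm], size=n)],
        **{v: rng.standard_normal(n) for v in
           ("bl_mediator", "post_mediator", "bl_outcome", "post_outcome")},
        **{v: rng.integers(0, 2, n).astype(float) for v in ("male", "firstyr", "nonwhite")},
    })
    return IPDDataset(df)


class TestEffects:
    def test_product_of_coefficients_value(self):
        # a one-unit feedback-arm increase of 0.07 and mediator slope of -0.22
        fit = _synthetic_fit(a_pf=0.07, b_med=-0.22)
        eff = im.compute_effects(fit)
        assert eff.indirect[Arm.PF] == pytest.approx(-0.0154, abs=1e-12)

    def test_null_mediator_path_gives_zero_indirect(self):
        fit = _synthetic_fit(a_pf=0.0, b_med=-0.22)
        eff = im.compute_effects(fit)
        assert eff.indirect[Arm.PF] == 0.0
        assert eff.total[Arm.PF] == eff.direct[Arm.PF]

    def test_total_identity_exact_on_random_coefficients(self, rng):
        for _ in range(200):
            fit = _synthetic_fit(a_pf=rng.standard_normal(), b_med=rng.standard_normal(),
                                 direct_pf=rng.standard_normal(),
                                 sd_a=np.exp(rng.standard_normal()),
                                 sd_b=np.exp(rng.standard_normal()))
            eff = im.standardize_effects(fit, im.compute_effects(fit))
            scale = max(1.0, abs(eff.total[Arm.PF]))
            assert abs(eff.total[Arm.PF] - eff.direct[Arm.PF]
                       - eff.indirect[Arm.PF]) <= 1e-12 * scale
            s_scale = max(1.0, abs(eff.std_total[Arm.PF]))
            assert abs(eff.std_total[Arm.PF] - eff.std_direct[Arm.PF]
                       - eff.std_indirect[Arm.PF]) <= 1e-12 * s_scale

    def test_standardization_arithmetic(self):
        fit = _synthetic_fit(direct_pf=0.4, sd_b=2.0)
        eff = im.standardize_effects(fit, im.compute_effects(fit))
        assert eff.std_direct[Arm.PF] == pytest.approx(0.2, rel=1e-12)
        fit1 = _synthetic_fit(direct_pf=0.4, sd_b=1.0)
        eff1 = im.standardize_effects(fit1, im.compute_effects(fit1))
        assert eff1.std_direct[Arm.PF] == eff1.direct[Arm.PF]

    def test_difference_of_coefficients_oracle(self, small_design):
        # classical linear-mediation identity: the TX coefficient from the outcome
        # equation refit without the mediator equals direct + indirect (= total)
        ds, _ = im.generate_multistudy(make_small_design(), seed=21)
        spec = im.detect_estimable_terms(ds)
        w = im.compute_weights(ds)
        fit = im.fit_mediation(ds, spec, w)
        eff = im.compute_effects(fit)
        X = design_matrix(ds, tuple(t for t in spec.eqB_terms if t != "POST_PBS"))
        y = ds.df["post_outcome"].to_numpy()
        sw = np.sqrt(w.w)
        beta_red, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        terms_red = [t for t in spec.eqB_terms if t != "POST_PBS"]
        for arm, t in ((Arm.MIPF, "TX_MIPF"), (Arm.PF, "TX_PF"), (Arm.GMI, "TX_GMI")):
            b_reduced = beta_red[terms_red.index(t)]
            assert b_reduced - fit.eqB.coefficients[t] == pytest.approx(
                eff.indirect[arm], abs=1e-8
            )


def _synthetic_fit(a_pf=0.07, b_med=-0.22, direct_pf=0.01, sd_a=1.0, sd_b=1.0):
    """Hand-assembled MediationFit for effect-arithmetic tests."""
    from ipdmed.mediation import EquationFit, MediationFit

    spec = ModelSpec(("intercept", "TX_PF", "BL_ALCPROB", "BL_PBS"),
                     ("intercept", "TX_PF", "BL_ALCPROB", "BL_PBS", "POST_PBS"))
    eqA = EquationFit("A", {"intercept": 0.0, "TX_PF": a_pf, "BL_ALCPROB": 0.0,
                            "BL_PBS": 0.5}, 0.5, sd_a, 0.4, 100)
    eqB = EquationFit("B", {"intercept": 0.0, "TX_PF": direct_pf, "BL_ALCPROB": 0.5,
                            "BL_PBS": 0.0, "POST_PBS": b_med}, 0.5, sd_b, 0.4, 100)
    return MediationFit(eqA, eqB, spec, WeightVector(np.ones(100), "uniform"))


class TestParameterRecovery:
    def test_bias_shrinks_with_sample_size(self):
        errs = []
        for n_per_arm in (125, 1250, 12500):
            abs_err = []
            for seed in (1, 2, 3):
                big = [im.StudyDesign("S", {Arm.CONTROL: n_per_arm, Arm.PF: n_per_arm},
                                      female_n=n_per_arm, firstyr_n=n_per_arm // 2,
                                      nonwhite_n=n_per_arm // 2, bl_mediator_mean=0.4,
                                      bl_mediator_sd=0.9, bl_outcome_mean=0.1,
                                      bl_outcome_sd=0.9)]
                design = make_small_design(studies=big)
                ds, truth = im.generate_multistudy(design, seed=seed)
                spec = im.detect_estimable_terms(ds)
                fit = im.fit_mediation(ds, spec, im.compute_weights(ds))
                eff = im.compute_effects(fit)
                abs_err.append(abs(eff.a[Arm.PF] - truth.a[Arm.PF])
                               + abs(eff.b_med - truth.b_med))
            errs.append(np.mean(abs_err))
        assert errs[2] < errs[0]
        assert errs[2] < errs[1] * 3  # no blow-up at the largest n

    def test_null_treatment_effects_estimated_near_zero(self):
        coefA = {k: (0.0 if k.startswith("TX") else v)
                 for k, v in make_small_design().eqA_coef.items()}
        design = make_small_design(eqA_coef=coefA, seed=5)
        ds, _ = im.generate_multistudy(design, seed=5)
        spec = im.detect_estimable_terms(ds)
        fit = im.fit_mediation(ds, spec, im.compute_weights(ds))
        # Monte-Carlo SE of a two-arm contrast with n=40/arm, resid sd 0.7
        se = 0.7 * np.sqrt(2 / 40)
        for t in ("TX_MIPF", "TX_PF", "TX_GMI"):
            assert abs(fit.eqA.coefficients[t]) < 3 * se


class TestClusterRobustSE:
    def test_single_cluster_is_an_error(self, small_design):
        one = make_small_design(studies=[small_design.studies[0]])
        ds, _ = im.generate_multistudy(one, seed=1)
        spec = im.detect_estimable_terms(ds)
        fit = im.fit_mediation(ds, spec, im.compute_weights(ds))
        with pytest.raises(ValueError, match="two studies"):
            im.cluster_robust_se(fit, ds)

    def test_independent_data_robust_close_to_classical(self):
        # 60 equal studies of iid data: sandwich and classical SEs should agree
        rng = np.random.default_rng(8)
        studies = [im.StudyDesign(f"s{i}", {Arm.CONTROL: 15, Arm.PF: 15}, female_n=15,
                                  firstyr_n=15, nonwhite_n=10, bl_mediator_mean=0.0,
                                  bl_mediator_sd=1.0, bl_outcome_mean=0.0,
                                  bl_outcome_sd=1.0)
                   for i in range(60)]
        design = make_small_design(studies=studies)
        ds, _ = im.generate_multistudy(design, seed=8)
        spec = im.detect_estimable_terms(ds)
        w = im.compute_weights(ds, "uniform")
        fit = im.fit_mediation(ds, spec, w)
        robust = im.cluster_robust_se(fit, ds)
        X = design_matrix(ds, spec.eqA_terms)
        classical = sm.OLS(ds.df["post_mediator"].to_numpy(), X).fit().bse
        ratio = robust["A"]["TX_PF"] / classical[list(spec.eqA_terms).index("TX_PF")]
        assert 0.8 < ratio < 1.25

    def test_between_study_heterogeneity_inflates_robust_se(self):
        # strong study intercept shifts: robust SE for the intercept (a
        # study-constant predictor) must exceed the classical one
        studies = [im.StudyDesign(f"s{i}", {Arm.CONTROL: 25, Arm.PF: 25}, female_n=25,
                                  firstyr_n=25, nonwhite_n=15, bl_mediator_mean=0.0,
                                  bl_mediator_sd=1.0, bl_outcome_mean=0.0,
                                  bl_outcome_sd=1.0)
                   for i in range(12)]
        design = make_small_design(studies=studies, tau_intercept_A=0.8)
        ds, _ = im.generate_multistudy(design, seed=9)
        spec = im.detect_estimable_terms(ds)
        w = im.compute_weights(ds, "uniform")
        fit = im.fit_mediation(ds, spec, w)
        robust = im.cluster_robust_se(fit, ds)
        X = design_matrix(ds, spec.eqA_terms)
        classical = sm.OLS(ds.df["post_mediator"].to_numpy(), X).fit().bse
        assert robust["A"]["intercept"] > 1.5 * classical[0]
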