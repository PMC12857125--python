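import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from maihda import (
    CohortConfig,
    GeneratingTruth,
    McmcConfig,
    PosteriorDraws,
    backtransform_lognormal,
    compute_pcv,
    compute_vpc,
    decompose_interaction,
    default_design,
    generate_cohort,
    predict_strata,
    run_maihda,
    summarize_variances,
)
from maihda.bayes import LOGISTIC_RESIDUAL_VARIANCE


def _manual_fit(design, beta_by_name, u=None, ndraws=1, family="logistic",
                sigma_e2=None):
    """Hand-built PosteriorDraws for closed-form prediction checks."""
    J = design.n_strata
    names = ["intercept"]
    for axis in design.axes:
        names += [f"{axis.name}:{lv}" for lv in axis.levels
                  if lv != axis.reference_level]
    beta = np.zeros((ndraws, len(names)))
    for k, v in beta_by_name.items():
        beta[:, names.index(k)] = v
    u = np.zeros((ndraws, J)) if u is None else np.atleast_2d(u)
    if sigma_e2 is None:
        sigma_e2 = np.full(ndraws, LOGISTIC_RESIDUAL_VARIANCE)
    return PosteriorDraws(
        family=family, beta=beta, beta_names=names, u=u,
        sigma_u2=np.full(ndraws, 0.05), sigma_e2=np.asarray(sigma_e2, float),
        n_chains=1, n_draws_per_chain=ndraws,
        stratum_counts=np.zeros(J, dtype=int),
    )


class TestVpcPcv:
    @pytest.mark.parametrize(
        "su,se,expected",
        [(0.67, 3.29, 0.169), (0.0, 3.29, 0.0), (0.41, 2.98, 0.121)],
    )
    def test_vpc_arithmetic(self, su, se, expected):
        assert compute_vpc(su, se) == pytest.approx(expected, abs=5e-4)

    def test_vpc_per_draw_vectorised(self):
        su = np.array([0.5, 1.0])
        out = compute_vpc(su, 3.29)
        assert out.shape == (2,)
        assert np.all((out > 0) & (out < 1))

    def test_vpc_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            compute_vpc(0.0, 0.0)

    @pytest.mark.parametrize(
        "null,main,expected",
        [(0.67, 0.05, 0.925), (0.3, 0.3, 0.0), (0.41, 0.04, 0.902)],
    )
    def test_pcv_arithmetic(self, null, main, expected):
        assert compute_pcv(null, main) == pytest.approx(expected, abs=5e-4)

    def test_pcv_rejects_zero_null_variance(self):
        with pytest.raises(ValueError):
            compute_pcv(0.0, 0.1)

    def test_summarize_modes_agree_on_tight_posteriors(self, design):
        rng = np.random.default_rng(0)
        mk = lambda su: PosteriorDraws(
            family="logistic",
            beta=np.zeros((400, 1)), beta_names=["intercept"],
            u=np.zeros((400, 1)),
            sigma_u2=su + 0.001 * rng.standard_normal(400),
            sigma_e2=np.full(400, LOGISTIC_RESIDUAL_VARIANCE),
            n_chains=1, n_draws_per_chain=400,
            stratum_counts=np.zeros(1, dtype=int),
        )
        null, main = mk(0.67), mk(0.05)
        a = summarize_variances(null, main, mode="per-draw")
        b = summarize_variances(null, main, mode="plug-in")
        assert a.vpc_null == pytest.approx(b.vpc_null, abs=1e-3)
        assert a.pcv == pytest.approx(b.pcv, abs=1e-3)
        assert a.mode == "per-draw" and b.mode == "plug-in"


class TestDecomposition:
    def test_identity_holds_per_draw_and_per_summary(self):
        rng = np.random.default_rng(1)
        total = rng.normal(50, 10, size=(500, 108))
        additive = rng.normal(50, 10, size=(500, 108))
        out = decompose_interaction(total, additive)
        np.testing.assert_allclose(
            out["interaction"], out["total"] - out["additive"], atol=1e-10
        )

    def test_equal_series_give_zero_nonsignificant_interaction(self):
        draws = np.random.default_rng(2).normal(size=(200, 5))
        out = decompose_interaction(draws, draws)
        assert np.allclose(out["interaction"], 0)
        assert not out["significant"].any()

    def test_misaligned_draws_rejected(self):
        with pytest.raises(ValueError):
            decompose_interaction(np.zeros((10, 3)), np.zeros((9, 3)))

    @pytest.mark.parametrize(
        "total,additive,interaction",
        [(85.4, 81.5, 3.9), (38.6, 52.9, -14.3), (63.8, 54.6, 9.2),
         (12.6, 8.2, 4.4), (1.7, 2.5, -0.8), (12.5, 15.5, -3.0)],
    )
    def test_published_decomposition_identities(self, total, additive, interaction):
        out = decompose_interaction(np.array([[total]]), np.array([[additive]]))
        assert out["interaction"][0] == pytest.approx(interaction, abs=1e-9)


class TestPredictions:
    def test_hand_inverse_logit_for_reference_women(self, design):
        fit = _manual_fit(design, {"intercept": 1.21, "sex:Women": -0.55})
        pred = predict_strata(fit, design, reference_year=None)
        women_ref = pred[pred["label"] == "F, 21-24, White, low"].iloc[0]
        assert women_ref["total"] == pytest.approx(100 / (1 + np.exp(-0.66)), abs=1e-6)
        assert women_ref["total"] == pytest.approx(65.9, abs=0.05)
        men_ref = pred[pred["label"] == "M, 21-24, White, low"].iloc[0]
        assert men_ref["total"] == pytest.approx(100 * expit(1.21), abs=1e-6)

    def test_total_equals_additive_when_u_is_zero(self, design):
        fit = _manual_fit(design, {"intercept": 0.4}, ndraws=20)
        pred = predict_strata(fit, design, reference_year=None)
        assert np.allclose(pred["total"], pred["additive"])
        assert np.allclose(pred["interaction"], 0)

    def test_binary_predictions_strictly_inside_0_100(self, design):
        rng = np.random.default_rng(3)
        fit = _manual_fit(design, {"intercept": 0.0},
                          u=rng.normal(0, 3, size=(50, 108)), ndraws=50)
        pred = predict_strata(fit, design, reference_year=None)
        for col in ("total", "additive", "total_lo", "total_hi"):
            assert (pred[col] > 0).all() and (pred[col] < 100).all()

    def test_increasing_intercept_raises_every_stratum(self, design):
        lo = predict_strata(_manual_fit(design, {"intercept": 0.2}), design, None)
        hi = predict_strata(_manual_fit(design, {"intercept": 0.8}), design, None)
        assert (hi["total"].to_numpy() > lo["total"].to_numpy()).all()

    def test_unknown_reference_year_is_an_error(self, design):
        fit = _manual_fit(design, {"intercept": 0.0})
        fit.beta_names = fit.beta_names + ["year:2001"]
        fit.beta = np.hstack([fit.beta, np.zeros((1, 1))])
        with pytest.raises(ValueError, match="reference year"):
            predict_strata(fit, design, reference_year=1999)


class TestBacktransform:
    def test_closed_forms(self):
        assert backtransform_lognormal(0.0, 0.0) == pytest.approx(1.0)
        assert backtransform_lognormal(1.0, 2.0) == pytest.approx(np.e**2)

    def test_reduces_to_exp_eta_as_variance_vanishes(self):
        eta = np.linspace(-1, 3, 7)
        np.testing.assert_allclose(
            backtransform_lognormal(eta, 1e-12), np.exp(eta), rtol=1e-6
        )

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(4)
        eta, se2 = 0.8, 1.5
        mc = np.exp(rng.normal(eta, np.sqrt(se2), 1_000_000)).mean()
        assert backtransform_lognormal(eta, se2) == pytest.approx(mc, rel=0.01)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            backtransform_lognormal(0.0, -0.1)


class TestRunMaihda:
    def test_additive_truth_yields_few_significant_interactions(self, design):
        # purely additive generating truth: zero stratum effects and offsets
        from maihda.simulate import STATUS_MAIN_EFFECTS

        additive = GeneratingTruth(dict(STATUS_MAIN_EFFECTS), 0.0, "logistic")
        rec = generate_cohort(
            CohortConfig(n_individuals=108 * 400, design=design,
                         truth_status=additive, year_range=(2009, 2009), seed=10)
        )
        res = run_maihda(
            rec, design, "logistic",
            McmcConfig(chains=1, iterations=900, burn_in=300, seed=1),
            include_year=False,
        )
        assert len(res.predictions) == 108
        # additive generating truth: far fewer flagged than the ~34% of the
        # real data; allow generous slack over the nominal 5% false positives
        assert res.predictions["significant"].mean() < 0.15
        np.testing.assert_allclose(
            res.predictions["interaction"],
            res.predictions["total"] - res.predictions["additive"],
            atol=1e-9,
        )

    def test_known_offsets_are_recovered(self, design):
        rng = np.random.default_rng(5)
        off = rng.normal(0, 0.35, 108)
        truth = GeneratingTruth(
            {"intercept": 0.5}, 0.0, "logistic", interaction_offsets=off
        )
        rec = generate_cohort(
            CohortConfig(n_individuals=108 * 2000, design=design,
                         truth_status=truth, year_range=(2009, 2009), seed=11)
        )
        res = run_maihda(
            rec, design, "logistic",
            McmcConfig(chains=1, iterations=900, burn_in=300, seed=2),
            include_year=False,
        )
        r = np.corrcoef(off, res.predictions["interaction"])[0, 1]
        assert r > 0.8

    def test_vpc_invariant_to_offset_plus_intercept_shift(self, design):
        c = 0.7
        base = CohortConfig(n_individuals=2000, design=design,
                            year_range=(2009, 2009), seed=12)
        shifted = CohortConfig(
            n_individuals=2000, design=design, year_range=(2009, 2009), seed=12,
            truth_status=GeneratingTruth(
                dict(base.truth_status.fixed_effects,
                     intercept=base.truth_status.fixed_effects["intercept"] - c),
                base.truth_status.stratum_sd, "logistic",
                interaction_offsets=np.full(108, c),
            ),
        )
        a, b = generate_cohort(base), generate_cohort(shifted)
        pd.testing.assert_frame_equal(a, b)  # identical data => identical VPC

    def test_single_stratum_input_is_an_error(self, design):
        s = design.strata[0]
        rec = pd.DataFrame(
            [dict(zip(design.axis_names, s.labels), survey_year=2009,
                  drinker=i % 2) for i in range(40)]
        )
        with pytest.raises(ValueError):
            run_maihda(rec, design, "logistic",
                       McmcConfig(chains=1, iterations=100, burn_in=50, seed=0),
                       include_year=False)


def test_null_intercept_is_precision_weighted_grand_mean(design):
    """On balanced linear data the null intercept matches the closed-form
    precision-weighted grand mean of the stratum means."""
    rec = generate_cohort(
        CohortConfig(
            n_individuals=108 * 300, design=design, year_range=(2009, 2009),
            truth_status=GeneratingTruth({"intercept": 6.0}, 0.0, "logistic"),
            truth_gpd=GeneratingTruth({"intercept": 0.57}, np.sqrt(0.41),
                                      "lognormal", residual_sd=np.sqrt(2.98)),
            seed=13,
        )
    )
    from maihda import ModelSpec, assign_strata, fit_model

    rec = rec[(rec["drinker"] == 1) & (rec["gpd"] > 0)]
    fit = fit_model(
        rec, ModelSpec("linear", "null", design, include_year=False),
        McmcConfig(chains=1, iterations=900, burn_in=300, seed=3),
    )
    y = np.log(rec["gpd"].to_numpy())
    j = assign_strata(rec, design).to_numpy()
    su2, se2 = fit.sigma_u2.mean(), fit.sigma_e2.mean()
    n_j = np.bincount(j - 1, minlength=108)
    ybar = np.bincount(j - 1, weights=y, minlength=108) / n_j
    w = 1.0 / (su2 + se2 / n_j)
    mu = (w * ybar).sum() / w.sum()
    b0 = fit.beta[:, 0]
    assert abs(b0.mean() - mu) < 3 * b0.std()
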