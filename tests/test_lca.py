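"""Engine tests: WLS fits against closed forms and independent
optimisers, model enumeration and screening, Akaike weighting, model
averaging, and pseudo-R^2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linecross import (
    InestimableModelError,
    ModelFit,
    collinearity_check,
    count_model_space,
    cox_snell_r2,
    fit_wls,
    model_average,
    model_search,
)
from linecross.cmatrix import CMatrix


def _cohorts(means, ses):
    return pd.DataFrame({"cohort": [f"L{i}" for i in range(len(means))],
                         "mean": means, "se": ses})


def _cmatrix(frame_dict, index):
    return CMatrix(pd.DataFrame(frame_dict, index=index))


class TestFitWLS:
    def test_null_model_equal_weights_is_plain_mean(self):
        cohorts = _cohorts([0.2, 0.6], [0.1, 0.1])
        cm = _cmatrix({"a": [1.0, -1.0]}, ["L0", "L1"])
        mf = fit_wls(cohorts, cm, ())
        assert mf.estimates["mu"] == pytest.approx(0.4)

    def test_null_model_is_inverse_variance_weighted_mean(self):
        # closed form: (0.2/0.01 + 0.6/0.04) / (1/0.01 + 1/0.04) = 0.28
        cohorts = _cohorts([0.2, 0.6], [0.1, 0.2])
        cm = _cmatrix({"a": [1.0, -1.0]}, ["L0", "L1"])
        mf = fit_wls(cohorts, cm, ())
        assert mf.estimates["mu"] == pytest.approx(0.28)

    def test_saturated_model_interpolates(self, toy_cohorts, cmatrix_full):
        subset = ("Aa", "Ad", "Xa", "Ca", "Md", "AaAd", "AaCa")
        mf = fit_wls(toy_cohorts, cmatrix_full, subset)
        X = np.column_stack([np.ones(8), cmatrix_full.aligned(
            list(toy_cohorts["cohort"])).columns(subset)])
        beta = np.array([mf.estimates[t] for t in ("mu",) + subset])
        np.testing.assert_allclose(X @ beta, toy_cohorts["mean"], atol=1e-8)

    def test_rank_deficient_subset_raises(self, toy_cohorts, cmatrix_full):
        # Xd is exactly Ad/2 across pooled cohorts
        with pytest.raises(InestimableModelError):
            fit_wls(toy_cohorts, cmatrix_full, ("Ad", "Xd"))

    def test_parameter_count_includes_mu(self, toy_cohorts, cmatrix_full):
        mf = fit_wls(toy_cohorts, cmatrix_full, ("Aa", "Ad"))
        assert mf.k == 3
        assert set(mf.estimates) == {"mu", "Aa", "Ad"}
        assert mf.aic == pytest.approx(-2 * mf.loglik + 2 * 3)

    def test_wls_equals_ols_under_equal_ses(self, cmatrix_full):
        rng = np.random.default_rng(5)
        for _ in range(10):
            cohorts = pd.DataFrame({
                "cohort": cmatrix_full.cohort_ids,
                "mean": rng.uniform(0.05, 0.9, 8),
                "se": np.full(8, 0.05)})
            subset = tuple(rng.choice(
                ["Aa", "Ad", "Ca", "Ma", "AaAa"], size=2, replace=False))
            mf = fit_wls(cohorts, cmatrix_full, subset)
            X = np.column_stack([np.ones(8), cmatrix_full.columns(subset)])
            beta_ols, *_ = np.linalg.lstsq(X, cohorts["mean"], rcond=None)
            got = [mf.estimates[t] for t in ("mu",) + subset]
            np.testing.assert_allclose(got, beta_ols, atol=1e-10)

    def test_matches_statsmodels_wls(self, toy_cohorts, cmatrix_full):
        sm = pytest.importorskip("statsmodels.api")
        subset = ("Aa", "Ad", "Ca")
        mf = fit_wls(toy_cohorts, cmatrix_full, subset)
        X = np.column_stack([np.ones(8), cmatrix_full.aligned(
            list(toy_cohorts["cohort"])).columns(subset)])
        w = 1 / toy_cohorts["se"].to_numpy() ** 2
        res = sm.WLS(toy_cohorts["mean"].to_numpy(), X, weights=w).fit()
        got = [mf.estimates[t] for t in ("mu",) + subset]
        np.testing.assert_allclose(got, res.params, atol=1e-10)

    def test_brute_force_minimiser_agrees(self, toy_cohorts, cmatrix_full):
        """Nelder-Mead minimisation of the weighted SS lands on the same
        estimates as the linear-algebra solution."""
        from scipy.optimize import minimize
        rng = np.random.default_rng(11)
        y = toy_cohorts["mean"].to_numpy()
        se = toy_cohorts["se"].to_numpy()
        cm = cmatrix_full.aligned(list(toy_cohorts["cohort"]))
        for subset in [("Aa",), ("Aa", "Ad"), ("Aa", "Ca", "AaAa")]:
            mf = fit_wls(toy_cohorts, cmatrix_full, subset)
            X = np.column_stack([np.ones(8), cm.columns(subset)])

            def wss(beta):
                r = y - X @ beta
                return np.sum(r * r / se**2)

            opt = minimize(wss, rng.normal(size=X.shape[1]), method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 20000, "maxfev": 20000})
            got = np.array([mf.estimates[t] for t in ("mu",) + subset])
            np.testing.assert_allclose(got, opt.x, atol=1e-6)

    def test_v_mode_se_changes_weighting(self):
        cohorts = _cohorts([0.2, 0.6], [0.1, 0.2])
        cm = _cmatrix({"a": [1.0, -1.0]}, ["L0", "L1"])
        mf = fit_wls(cohorts, cm, (), v_mode="se")
        # weights 1/0.1 and 1/0.2 -> (2 + 3) / (10 + 5) = 1/3
        assert mf.estimates["mu"] == pytest.approx((0.2 / 0.1 + 0.6 / 0.2) / 15)


class TestModelSpace:
    def test_counts(self):
        assert count_model_space(27, 7) == 1_285_623
        assert count_model_space(3, 3) == 7
        assert count_model_space(27, 1) == 27

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            count_model_space(5, 6)


class TestCollinearity:
    def test_identical_columns_dropped_with_pair(self, cmatrix_full):
        dec = collinearity_check(cmatrix_full, ["Ad", "Xd"])
        assert dec.drop and set(dec.offending_pair) == {"Ad", "Xd"}

    def test_orthogonal_columns_kept(self):
        cm = _cmatrix({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]},
                      ["A", "B", "C", "D"])
        assert not collinearity_check(cm, ["a", "b"]).drop

    def test_threshold_is_respected(self):
        cm = _cmatrix({"a": [1.0, 2, 3, 4], "b": [1.1, 2, 3, 4.2]},
                      ["A", "B", "C", "D"])
        assert collinearity_check(cm, ["a", "b"], threshold=0.9).drop
        assert not collinearity_check(cm, ["a", "b"], threshold=0.9999).drop

    def test_constant_column_confounded_with_mu(self):
        cm = _cmatrix({"a": [2.0, 2, 2, 2], "b": [1, -1, 1, -1]},
                      ["A", "B", "C", "D"])
        dec = collinearity_check(cm, ["a", "b"])
        assert dec.drop and "constant" in dec.reason


@pytest.fixture(scope="module")
def search(toy_cohorts, cmatrix_autocyto):
    return model_search(toy_cohorts, cmatrix_autocyto, max_size=3)


class TestModelSearch:
    def test_enumeration_is_conserved(self, search, cmatrix_autocyto):
        total = count_model_space(len(cmatrix_autocyto.effect_ids), 3)
        assert search.n_models_evaluated + search.n_models_dropped == total

    def test_weights_sum_to_one(self, search):
        assert search.weight.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ranking_is_by_aic(self, search):
        ranked = search.aic[search.order]
        assert np.all(np.diff(ranked) >= -1e-12)

    def test_nesting_never_lowers_loglik(self, toy_cohorts, cmatrix_autocyto):
        base = fit_wls(toy_cohorts, cmatrix_autocyto, ("Aa",))
        for extra in ("Ad", "Ca", "Ma", "AaAa"):
            bigger = fit_wls(toy_cohorts, cmatrix_autocyto, ("Aa", extra))
            assert bigger.loglik >= base.loglik - 1e-9

    def test_deterministic(self, toy_cohorts, cmatrix_autocyto, search):
        again = model_search(toy_cohorts, cmatrix_autocyto, max_size=3)
        np.testing.assert_array_equal(again.order, search.order)
        np.testing.assert_allclose(again.aic, search.aic)

    def test_strong_additive_signal_ranks_aa_first(self, cmatrix_autocyto):
        aa = cmatrix_autocyto.frame["Aa"]
        cohorts = pd.DataFrame({"cohort": cmatrix_autocyto.cohort_ids,
                                "mean": 0.4 + 0.25 * aa.to_numpy(),
                                "se": np.full(8, 0.02)})
        search = model_search(cohorts, cmatrix_autocyto, max_size=3)
        assert "Aa" in search.subset_tokens(search.order[0])

    def test_all_models_dropped_is_explicit(self):
        # constant columns are confounded with mu, so every subset dies
        cm = _cmatrix({"a": [2.0, 2, 2, 2], "b": [3.0, 3, 3, 3]},
                      ["A", "B", "C", "D"])
        cohorts = pd.DataFrame({"cohort": list("ABCD"),
                                "mean": [0.1, 0.2, 0.3, 0.4],
                                "se": [0.05] * 4})
        with pytest.raises(ValueError, match="0.9"):
            model_search(cohorts, cm, max_size=2, threshold=0.9)


class TestModelAverage:
    def _fit(self, subset, aic, est=None):
        est = est or {}
        return ModelFit(effect_subset=subset,
                        estimates={"mu": 0.3, **est},
                        cond_se={"mu": 0.01, **{k: 0.05 for k in est}},
                        loglik=-aic / 2, aic=aic)

    def test_two_model_weights(self):
        fits = [self._fit(("Aa",), 10.0, {"Aa": 0.5}),
                self._fit(("Ad",), 12.0, {"Ad": 0.2})]
        res = model_average(fits, level=0.999)
        w = [f.weight for f in res.confidence_set]
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_single_dominant_model_degenerates(self):
        fits = [self._fit(("Aa",), 0.0, {"Aa": 0.5}),
                self._fit(("Ad",), 60.0, {"Ad": 0.2})]
        res = model_average(fits)
        assert len(res.confidence_set) == 1
        assert res.importance("Aa") == pytest.approx(1.0)
        assert res.estimate("Aa") == pytest.approx(0.5)
        assert res.importance("Ad") == 0.0

    def test_absent_effect_reports_no_estimate(self):
        fits = [self._fit(("Aa",), 0.0, {"Aa": 0.5})]
        res = model_average(fits, effect_tokens=["Aa", "Ca"])
        assert res.importance("Ca") == 0.0
        assert np.isnan(res.estimate("Ca"))

    def test_confidence_set_covers_level(self, toy_cohorts, cmatrix_autocyto):
        search = model_search(toy_cohorts, cmatrix_autocyto, max_size=4)
        res = model_average(search, level=0.95)
        assert res.weight_covered >= 0.95
        # and is minimal: removing the last model goes below the level
        w = np.array([f.weight for f in res.confidence_set])
        assert w[:-1].sum() < 0.95

    def test_unconditional_se_exceeds_spread(self):
        fits = [self._fit(("Aa",), 0.0, {"Aa": 0.5}),
                self._fit(("Aa", "Ad"), 0.5, {"Aa": 0.1, "Ad": 0.2})]
        res = model_average(fits, level=0.9999)
        t = res.effects_table.loc["Aa"]
        assert t["unconditional_se"] > 0.05  # conditional SE alone
        assert t["importance"] == pytest.approx(1.0)


class TestCoxSnell:
    def test_zero_when_likelihoods_match(self, toy_cohorts, cmatrix_full):
        null = fit_wls(toy_cohorts, cmatrix_full, ())
        assert cox_snell_r2(null, null, 8) == 0.0

    def test_monotone_in_loglik(self, toy_cohorts, cmatrix_full):
        null = fit_wls(toy_cohorts, cmatrix_full, ())
        small = fit_wls(toy_cohorts, cmatrix_full, ("Aa",))
        big = fit_wls(toy_cohorts, cmatrix_full, ("Aa", "Ad"))
        assert 0 < cox_snell_r2(small, null) <= cox_snell_r2(big, null) <= 1.0

    def test_non_null_reference_rejected(self, toy_cohorts, cmatrix_full):
        m = fit_wls(toy_cohorts, cmatrix_full, ("Aa",))
        with pytest.raises(ValueError, match="mu-only"):
            cox_snell_r2(m, m, 8)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(0.05, 0.95), min_size=4, max_size=4),
       st.floats(0.01, 0.2))
def test_wls_with_equal_ses_is_ols_property(means, se):
    """Property: with a common SE the weighted fit is the ordinary one."""
    cohorts = pd.DataFrame({"cohort": list("ABCD"), "mean": means,
                            "se": [se] * 4})
    cm = _cmatrix({"a": [-1.0, -0.5, 0.5, 1.0]}, list("ABCD"))
    mf = fit_wls(cohorts, cm, ("a",))
    X = np.column_stack([np.ones(4), cm.values])
    beta, *_ = np.linalg.lstsq(X, np.asarray(means), rcond=None)
    np.testing.assert_allclose([mf.estimates["mu"], mf.estimates["a"]],
                               beta, atol=1e-10)
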