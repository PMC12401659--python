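"""Richness matrices, Poisson mixed models, AIC bookkeeping and CCA."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import gammaln

from xericfish.assemblage import (aic_table, build_matrix, cca,
                                  evidence_ratio, explained_fraction,
                                  fit_poisson_glmm)
from xericfish.synth import AssemblageSimParams, gen_assemblage


def _occ(hexid, years_species):
    rows = [dict(hexid=hexid, year=y, species=s)
            for y, specs in years_species.items() for s in specs]
    return pd.DataFrame(rows)


class TestBuildMatrix:
    def test_short_series_dropped(self):
        occ = _occ("h1", {2000 + i: ["a"] for i in range(9)})
        mats, dropped = build_matrix(occ, min_years=10)
        assert mats == {} and dropped == [("h1", 9)]

    def test_duplicate_detections_collapse(self):
        occ = _occ("h1", {2000 + i: ["a", "a", "b"] for i in range(10)})
        mats, _ = build_matrix(occ)
        m = mats["h1"]
        assert m.presence.shape == (10, 2)
        assert (m.richness == 2).all()

    def test_richness_equals_unique_species_count(self, rng):
        pool = [f"s{i}" for i in range(20)]
        data = {2000 + y: list(rng.choice(pool, size=rng.integers(1, 15),
                                          replace=False))
                for y in range(12)}
        mats, _ = build_matrix(_occ("h1", data))
        m = mats["h1"]
        for i, y in enumerate(m.years):
            assert m.richness[i] == len(set(data[y]))


class TestPoissonGlmm:
    def test_intercept_only_single_group_closed_form(self):
        y = np.array([3, 5, 2, 8, 4, 6])
        df = pd.DataFrame({"richness": y, "hexid": "h"})
        with pytest.warns(UserWarning, match="single group"):
            fit = fit_poisson_glmm(df, [])
        assert fit.beta[0] == pytest.approx(math.log(y.mean()))
        ll = float(np.sum(y * math.log(y.mean()) - y.mean() - gammaln(y + 1)))
        assert fit.loglik == pytest.approx(ll)
        assert fit.aic == pytest.approx(-2 * ll + 2 * fit.n_params)

    def test_vanishing_group_effect_matches_plain_glm(self, rng):
        # two groups simulated WITHOUT a group effect: the mixed fit should
        # approach the ordinary Poisson regression likelihood
        n = 120
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        df = pd.DataFrame({"richness": y, "x": x,
                           "hexid": np.repeat(["a", "b"], n // 2)})
        fit = fit_poisson_glmm(df, ["x"], scale=False)
        X = sm.add_constant(x)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.loglik >= glm.llf - 1e-4  # mixed model nests the GLM
        assert fit.loglik <= glm.llf + 2.0
        assert fit.beta[1] == pytest.approx(glm.params[1], abs=0.05)

    def test_scaling_changes_coefficients_not_likelihood(self):
        occ, truth = gen_assemblage(AssemblageSimParams(n_hexes=8,
                                                        n_years=12, seed=21))
        truth = truth.rename(columns={"year_index": "yr"})
        f1 = fit_poisson_glmm(truth, ["yr"], scale=True)
        f2 = fit_poisson_glmm(truth, ["yr"], scale=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-3)
        m, s = f1.scaler["yr"]
        assert f1.beta[1] / s == pytest.approx(f2.beta[1], abs=1e-3)

    def test_recovers_injected_decline_single_replicate(self):
        occ, truth = gen_assemblage(AssemblageSimParams(seed=3))
        truth = truth.rename(columns={"year_index": "yr"})
        fit = fit_poisson_glmm(truth, ["yr"])
        m, s = fit.scaler["yr"]
        lo, hi = fit.wald_ci("yr")
        assert lo / s < -0.02 < hi / s

    def test_rejects_non_count_response(self):
        df = pd.DataFrame({"richness": [1.5, 2.0], "hexid": ["a", "b"]})
        with pytest.raises(ValueError):
            fit_poisson_glmm(df, [])


class TestAicTable:
    PRINTED = {"year": 1413.8, "full": 1420.0, "null": 1427.2,
               "max_dur": 1429.0, "naa": 1429.2, "zero_days": 1429.2,
               "first_day": 1429.2}

    def test_reported_model_ranking_weights(self):
        tab = aic_table(self.PRINTED)
        assert tab.iloc[0]["model"] == "year"
        assert round(float(tab.iloc[0]["weight"]), 4) == 0.9541
        assert tab.iloc[0]["delta_aic"] == 0.0

    def test_evidence_ratio_year_vs_full(self):
        tab = aic_table(self.PRINTED)
        assert evidence_ratio(tab, "year", "full") == pytest.approx(
            math.exp(6.2 / 2), rel=1e-6)
        assert round(evidence_ratio(tab, "year", "full")) == 22

    def test_equal_aics_split_weight(self):
        tab = aic_table({"a": 100.0, "b": 100.0})
        assert np.allclose(tab["weight"], 0.5)

    def test_weights_sum_to_one_and_shift_invariance(self, rng):
        aics = rng.uniform(500, 540, 6)
        t1 = aic_table(list(aics))
        t2 = aic_table(list(aics + 123.4))
        assert t1["weight"].sum() == pytest.approx(1.0)
        np.testing.assert_allclose(t1["weight"], t2["weight"])

    def test_confidence_set_is_top_model_only(self):
        # top weight 0.9541 >= 0.95: the year model alone is retained
        tab = aic_table(self.PRINTED)
        assert tab["in_confidence_set"].tolist() == [True] + [False] * 6

    def test_seven_point_plausibility_window(self):
        tab = aic_table(self.PRINTED)
        plausible = set(tab.loc[tab["equally_plausible"], "model"])
        assert plausible == {"year", "full"}  # delta 0 and 6.2 only


class TestCca:
    def _data(self, rng, n=25, p=12):
        Y = rng.poisson(2.0, (n, p)).astype(float)
        X = rng.normal(size=(n, 3))
        return Y, X

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.ordination import cca as sk_cca
        Y, X = self._data(rng)
        mine = cca(Y, X, n_perm=19, seed=0)
        ref = sk_cca(pd.DataFrame(Y), pd.DataFrame(X))
        k = len(mine.eigenvalues)
        np.testing.assert_allclose(mine.eigenvalues,
                                   ref.eigvals.values[:k], rtol=1e-8)

    def test_constrained_at_most_total(self, rng):
        for _ in range(5):
            Y, X = self._data(rng)
            res = cca(Y, X, n_perm=9)
            assert 0 <= res.constrained_inertia <= res.total_inertia + 1e-12
            assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_constructed_gradient_is_detected(self, rng):
        n, p = 40, 15
        grad = np.linspace(-1, 1, n)
        lam = np.exp(1.2 + np.outer(grad, np.linspace(-1.2, 1.2, p)))
        Y = rng.poisson(lam).astype(float)
        X = np.column_stack([grad, rng.normal(size=n)])
        res = cca(Y, X, n_perm=199, seed=1)
        assert res.axis_p[0] <= 0.05
        assert res.eigenvalues[0] > res.eigenvalues[1:].sum()

    def test_random_constraints_explain_little(self, rng):
        hits = 0
        for i in range(20):
            Y = rng.poisson(2.0, (30, 10)).astype(float)
            X = rng.normal(size=(30, 1))
            res = cca(Y, X, n_perm=99, seed=i)
            hits += res.axis_p[0] <= 0.05
        assert hits <= 4  # ~5% nominal

    def test_rejects_negative_response(self):
        with pytest.raises(ValueError):
            cca(np.array([[1.0, -1.0]]), np.array([[1.0]]))


class TestExplainedFraction:
    def test_reported_inertia_ratio(self):
        assert explained_fraction(0.50, 11.14) == 4.5

    def test_extremes(self):
        assert explained_fraction(3.0, 3.0) == 100.0
        assert explained_fraction(0.0, 3.0) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            explained_fraction(0.0, 0.0)
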