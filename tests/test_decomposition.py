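"""Concentration-index decomposition: elasticities, contributions, closure."""

import numpy as np
import pandas as pd
import pytest

from parityineq import decomposition as dec
from parityineq import multilevel as ml
from parityineq.concentration import (concentration_index,
                                      weighted_fractional_rank,
                                      weighted_mean)
from conftest import brute_force_ci


def make_fit(spec, fixed, data, u0=None, u1=None):
    """Hand-assembled MixedFit for toy decomposition arithmetic."""
    areas = pd.Index(sorted(data["area_id"].unique()), name="area_id")
    u0 = pd.Series(u0 if u0 is not None else 0.0, index=areas, dtype=float)
    u1 = pd.Series(u1 if u1 is not None else 0.0, index=areas, dtype=float)
    fixed = pd.Series(fixed)
    lp = np.full(len(data), fixed["intercept"])
    for name, beta in fixed.items():
        if name != "intercept":
            lp += beta * data[name].to_numpy(float)
    aid = data["area_id"].to_numpy()
    rnd = u0.reindex(aid).to_numpy()
    if spec.random_slope is not None:
        rnd = rnd + u1.reindex(aid).to_numpy() * \
            data[spec.random_slope].to_numpy(float)
    y = data[spec.outcome].to_numpy(float)
    return ml.MixedFit(
        spec=spec, fixed=fixed, fixed_se=fixed * 0 + 1.0, tau00=0.1,
        tau11=0.1 if spec.random_slope else 0.0, sigma2=1.0, loglik=0.0,
        converged=True, boundary=False, blup_intercepts=u0, blup_slopes=u1,
        fitted_fixed=lp, fitted_random=rnd, residuals=y - lp - rnd,
        index=data.index)


class TestElasticity:
    @pytest.mark.parametrize("beta,xbar,mu,expected", [
        (0.710, 0.287, 1.52, 0.134),   # early marriage
        (0.221, 0.436, 1.52, 0.063),   # less-than-secondary education
    ])
    def test_published_rows(self, beta, xbar, mu, expected):
        assert dec.elasticity(beta, xbar, mu) == pytest.approx(expected,
                                                               abs=5e-4)

    def test_zero_coefficient(self):
        assert dec.elasticity(0.0, 0.5, 1.2) == 0.0

    def test_zero_mean_outcome(self):
        with pytest.raises(ZeroDivisionError):
            dec.elasticity(1.0, 0.5, 0.0)


class TestPctContribution:
    def test_early_marriage_share(self):
        eta = dec.elasticity(0.710, 0.287, 1.52)
        assert dec.pct_contribution(eta * -0.272, -0.141) == pytest.approx(
            25.9, abs=0.15)

    def test_health_system_share(self):
        eta = dec.elasticity(0.495, 0.217, 1.52)
        contribution = eta * -0.445
        assert contribution == pytest.approx(-0.031, abs=5e-4)
        assert dec.pct_contribution(contribution, -0.141) == pytest.approx(
            22.3, abs=0.15)

    def test_full_share_is_hundred(self):
        assert dec.pct_contribution(-0.141, -0.141) == 100.0

    def test_area_random_effect_row(self):
        # metropolitan area: BLUP -0.192, population share 0.090, CI 0.686
        eta = dec.elasticity(-0.192, 0.090, 1.52)
        contribution = eta * 0.686
        assert contribution == pytest.approx(-0.008, abs=5e-4)
        assert dec.pct_contribution(contribution, -0.141) == pytest.approx(
            5.527, abs=0.05)


class TestToyDecomposition:
    @pytest.fixture()
    def toy(self):
        data = pd.DataFrame({
            "area_id": [0, 0, 0, 1, 1, 1],
            "x1": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
            "x2": [0.0, 1.0, 1.0, 0.0, 1.0, 0.0],
            "weight": [1.0, 2.0, 1.0, 1.5, 1.0, 0.5],
            "wealth_score": [3.0, 1.0, 2.0, 6.0, 5.0, 4.0],
        })
        spec = ml.ModelSpec(outcome="y", individual_covariates=("x1", "x2"))
        lp = 0.4 + 0.9 * data["x1"] - 0.5 * data["x2"]
        rng = np.random.default_rng(8)
        data["y"] = lp + rng.normal(0, 0.3, 6)
        fit = make_fit(spec, {"intercept": 0.4, "x1": 0.9, "x2": -0.5}, data)
        ranks = weighted_fractional_rank(data["wealth_score"], data["weight"])
        return data, fit, ranks

    def test_fixed_rows_sum_to_predictor_ci(self, toy):
        data, fit, ranks = toy
        w = data["weight"].to_numpy()
        mu = weighted_mean(data["y"], w)
        rows = dec.decompose_fixed(fit, data, ranks, w, mu)
        total = sum(r.contribution for r in rows)
        # oracle: brute-force CI of the fixed predictor, rescaled to mu
        pred = fit.fitted_fixed
        expected = brute_force_ci(pred, ranks.ranks, w) * \
            weighted_mean(pred, w) / mu
        assert total == pytest.approx(expected, abs=1e-12)

    def test_random_rows_sum_to_blup_component_ci(self, toy):
        data, fit, ranks = toy
        spec = ml.ModelSpec(outcome="y",
                            individual_covariates=("x1", "x2"),
                            random_slope="x1")
        fit2 = make_fit(spec, fit.fixed.to_dict(), data,
                        u0=[0.3, -0.3], u1=[-0.2, 0.1])
        w = data["weight"].to_numpy()
        mu = weighted_mean(data["y"], w)
        rows = dec.decompose_random(fit2, data, ranks, w, mu)
        total = sum(r.contribution for r in rows)
        rnd = fit2.fitted_random
        from parityineq.concentration import weighted_cov
        expected = 2 * weighted_cov(rnd, ranks.ranks, w) / mu
        assert total == pytest.approx(expected, abs=1e-12)

    def test_perfect_fit_residual_zero(self, toy):
        data, fit, ranks = toy
        data = data.copy()
        data["y"] = fit.fitted_fixed          # zero-residual outcome
        fit2 = make_fit(fit.spec, fit.fixed.to_dict(), data)
        w = data["weight"].to_numpy()
        table = dec.decompose(fit2, data, ranks, w)
        assert table.residual_term == pytest.approx(0.0, abs=1e-14)
        assert table.ci_hat == pytest.approx(table.ci_observed, abs=1e-12)

    def test_closure_identity(self, toy):
        data, fit, ranks = toy
        table = dec.decompose(fit, data, ranks, data["weight"].to_numpy())
        gap = table.ci_observed - (table.ci_hat + table.residual_term)
        assert abs(gap) < 1e-10

    def test_closure_violation_raises(self, toy):
        data, fit, ranks = toy
        with pytest.raises(dec.ClosureError):
            dec.assemble_table(
                dec.decompose_fixed(fit, data, ranks), [],
                data["y"].to_numpy(), ranks,
                predicted=fit.fitted_fixed + 10 * data["wealth_score"].to_numpy())

    def test_uncorrelated_covariate_contributes_nothing(self):
        data = pd.DataFrame({
            "area_id": 0, "x1": [1.0, 0.0, 0.0, 1.0],
            "weight": 1.0, "wealth_score": [1.0, 2.0, 3.0, 4.0]})
        data["y"] = 1.0 + data["x1"]
        spec = ml.ModelSpec(outcome="y", individual_covariates=("x1",))
        fit = make_fit(spec, {"intercept": 1.0, "x1": 5.0}, data)
        ranks = weighted_fractional_rank(data["wealth_score"], data["weight"])
        row = dec.decompose_fixed(fit, data, ranks)[0]
        assert row.c_k == pytest.approx(0.0, abs=1e-15)  # x1 symmetric in rank
        assert row.contribution == pytest.approx(0.0, abs=1e-15)


@pytest.fixture(scope="module")
def table(default_dataset, default_fits):
    m = default_dataset.model_sample
    w = m["weight"].to_numpy()
    ranks = weighted_fractional_rank(m["wealth_score"], w)
    return dec.decompose(default_fits[3], m, ranks, w)


class TestSyntheticDecomposition:
    def test_exact_closure_on_weighted_data(self, table):
        gap = table.ci_observed - (table.ci_hat + table.residual_term)
        assert abs(gap) < 1e-10

    def test_fixed_subtotal_matches_predictor_ci(self, table, default_dataset,
                                                 default_fits):
        m = default_dataset.model_sample
        w = m["weight"].to_numpy()
        ranks = weighted_fractional_rank(m["wealth_score"], w)
        from parityineq.concentration import weighted_cov
        expected = 2 * weighted_cov(default_fits[3].fitted_fixed, ranks.ranks,
                                    w) / table.mu
        assert table.ci_hat_fixed == pytest.approx(expected, abs=1e-10)

    def test_tier_shares_sum_to_hundred(self, table):
        assert sum(table.tier_pct.values()) == pytest.approx(100.0, abs=1e-8)

    def test_rank_reversal_negates_everything_but_percentages(
            self, default_dataset, default_fits):
        m = default_dataset.model_sample
        w = m["weight"].to_numpy()
        ranks = weighted_fractional_rank(m["wealth_score"], w)
        fwd = dec.decompose(default_fits[3], m, ranks, w)
        rev = dec.decompose(default_fits[3], m, ranks.reversed(), w)
        assert rev.ci_hat == pytest.approx(-fwd.ci_hat, abs=1e-12)
        for rf, rb in zip(fwd.rows, rev.rows):
            assert rb.c_k == pytest.approx(-rf.c_k, abs=1e-12)
            assert rb.contribution == pytest.approx(-rf.contribution,
                                                    abs=1e-12)
            if rf.pct is not None:
                assert rb.pct == pytest.approx(rf.pct, abs=1e-8)

    def test_single_determinant_share_approaches_hundred(self):
        """With one wealth-graded covariate, no area effects and vanishing
        noise, that covariate takes the whole predicted-outcome CI."""
        from parityineq import synthetic as syn
        fe = {"intercept": 0.5, "married_lt18": 0.9}
        grads = {k: v for k, v in syn.GeneratorConfig().wealth_gradient.items()}
        cfg = syn.GeneratorConfig(
            seed=9, n_areas=10, women_per_area=400, fixed_effects=fe,
            tau00=0.0, tau11=0.0, sigma2=1e-18)
        ds = syn.generate_population(cfg)
        m = ds.model_sample
        w = m["weight"].to_numpy()
        ranks = weighted_fractional_rank(m["wealth_score"], w)
        spec = ml.ModelSpec(individual_covariates=("married_lt18",))
        fit = make_fit(spec, fe, m)
        table = dec.decompose(fit, m, ranks, w)
        em = [r for r in table.rows if r.name == "married_lt18"][0]
        assert em.pct == pytest.approx(100.0, abs=1e-6)
        assert table.residual_term == pytest.approx(0.0, abs=1e-9)


class TestRankRows:
    @pytest.fixture()
    def ranked_table(self):
        rows = [dec.DecompRow(f"area_{i}", dec.TIER_RANDOM_INTERCEPT,
                              0.0, 0.1, 0.0, 0.0, c)
                for i, c in enumerate([-0.03, 0.01, 0.05, -0.05, 0.0])]
        return dec.DecompTable(rows=rows, mu=1.0, ci_observed=0.0,
                               ci_hat=-0.02, ci_hat_fixed=0.0,
                               ci_hat_random=-0.02, residual_term=0.0)

    def test_hand_sorted_order(self, ranked_table):
        top = dec.rank_rows(ranked_table, dec.TIER_RANDOM_INTERCEPT, 3)
        assert [r.name for r in top] == ["area_2", "area_3", "area_0"]

    def test_tie_broken_by_name(self, ranked_table):
        top = dec.rank_rows(ranked_table, dec.TIER_RANDOM_INTERCEPT, 5)
        assert [r.name for r in top[:2]] == ["area_2", "area_3"]

    def test_k_larger_than_rows(self, ranked_table):
        assert len(dec.rank_rows(ranked_table,
                                 dec.TIER_RANDOM_INTERCEPT, 99)) == 5

    def test_k_zero_empty(self, ranked_table):
        assert dec.rank_rows(ranked_table, dec.TIER_RANDOM_INTERCEPT, 0) == []
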