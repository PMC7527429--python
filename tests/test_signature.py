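"""Cox screening, lasso-Cox risk model, risk score and stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.duration.hazard_regression import PHReg

from conftest import random_survival
from metprog import synthetic
from metprog.signature import (
    RiskModel,
    cox_newton,
    cox_score_test,
    lasso_cox,
    risk_score,
    screen_genes,
    stratify_median,
    univariate_cox,
)
from metprog.surveval import log_rank

# the eight published signature coefficients of the ovarian-cancer
# metabolic risk index, used as a fixed numeric check of the linear score
PUBLISHED_COEFFS = {
    "ENPP1": 0.0347,
    "FH": -0.010,
    "CYP2E1": 0.690,
    "HPGDS": 0.124,
    "ADCY9": 0.068,
    "NDUFA5": -0.031,
    "ADH1B": 0.049,
    "PYGB": 0.016,
}


def efron_loglik_1d(beta, x, time, event):
    """Independent scalar Efron partial likelihood for grid-search oracles."""
    theta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        d = dead.sum()
        S = theta[time >= t].sum()
        s = theta[dead].sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(S - ell / d * s)
    return ll


class TestUnivariateCox:
    def test_sign_equivariance(self):
        rng = np.random.default_rng(1)
        t, e = random_survival(rng, 50)
        x = rng.normal(size=50)
        a = univariate_cox(x, t, e)
        b = univariate_cox(-x, t, e)
        assert a.beta == pytest.approx(-b.beta, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_matches_brute_force_grid_small(self):
        """Newton estimate sits at the grid maximum of the partial likelihood."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.ones(5, dtype=int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        fit = univariate_cox(x, time, event)
        grid = np.linspace(fit.beta - 0.5, fit.beta + 0.5, 20001)
        lls = [efron_loglik_1d(b, x, time, event) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.beta) < 1e-4

    def test_matches_statsmodels_on_random_datasets(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(30, 80))
            t = rng.exponential(4, n)
            if rng.integers(2):
                t = np.ceil(t)  # force tied event times
            e = (rng.uniform(size=n) < 0.7).astype(int)
            if e.sum() == 0:
                e[0] = 1
            x = rng.normal(size=n)
            fit = univariate_cox(x, t, e)
            ref = PHReg(t, x[:, None], status=e, ties="efron").fit(
                method="newton", tol=1e-12, disp=False
            )
            assert abs(fit.beta - ref.params[0]) < 1e-6
            assert abs(fit.se - ref.bse[0]) < 1e-6

    def test_hazard_ratio_and_ci_consistency(self):
        rng = np.random.default_rng(6)
        t, e = random_survival(rng, 60)
        fit = univariate_cox(rng.normal(size=60), t, e)
        assert fit.hr == pytest.approx(np.exp(fit.beta))
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_score_test_equals_log_rank(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 50
            t = rng.exponential(3, n)
            e = (rng.uniform(size=n) < 0.7).astype(int)
            x = (rng.uniform(size=n) < 0.5).astype(float)
            if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
                continue
            lr = log_rank(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
            assert abs(cox_score_test(x, t, e) - lr.chi_square) < 1e-8

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(np.ones(10), np.arange(1, 11.0), np.ones(10, dtype=int))

    def test_separation_flagged_and_capped(self):
        # covariate perfectly orders the event times: monotone likelihood
        time = np.arange(1.0, 9.0)
        x = -time
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = univariate_cox(x, time, np.ones(8, dtype=int))
        assert np.isfinite(fit.beta)
        assert not fit.converged


class TestScreening:
    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(4)
        t, e = random_survival(rng, 40)
        fits = [univariate_cox(rng.normal(size=40), t, e, gene=f"g{i}") for i in range(5)]
        assert screen_genes(fits, alpha=0.0) == []

    def test_null_pass_rate_near_alpha(self):
        """With no survival signal ~5% of genes pass the p<0.05 screen."""
        rng = np.random.default_rng(5)
        n = 100
        t, e = random_survival(rng, n)
        fits = [
            univariate_cox(rng.normal(size=n), t, e, gene=f"g{i}") for i in range(200)
        ]
        frac = len(screen_genes(fits, alpha=0.05)) / 200
        assert 0.005 <= frac <= 0.12

    def test_planted_prognostic_genes_all_pass(self, bundle):
        """Strong planted effects at n=400 are all recovered by the screen."""
        tum = bundle.cohort.annotation.index[
            bundle.cohort.annotation["group"] == "tumour"
        ]
        X = np.log2(bundle.cohort.expression.loc[list(bundle.prognostic_genes), tum] + 1)
        fits = [
            univariate_cox(
                X.loc[g], bundle.survival["time"], bundle.survival["event"], gene=g
            )
            for g in bundle.prognostic_genes
        ]
        assert set(screen_genes(fits)) == set(bundle.prognostic_genes)
        # planted hazard direction is recovered in the sign of beta
        for f in fits:
            assert np.sign(f.beta) == np.sign(bundle.beta_true[f.gene])


def toy_survival_frame(rng, n, betas):
    """Gene x sample expression plus survival driven by the given betas."""
    p = len(betas)
    X = pd.DataFrame(
        rng.normal(size=(p, n)), index=[f"g{i}" for i in range(p)],
        columns=[f"s{i}" for i in range(n)],
    )
    eta = np.asarray(betas) @ X.to_numpy()
    t = rng.exponential(1.0 / (0.2 * np.exp(eta)))
    c = rng.exponential(25.0, size=n)
    e = (t <= c).astype(int)
    return X, np.minimum(t, c), e


class TestLassoCox:
    def test_infinite_penalty_gives_zero_model(self):
        rng = np.random.default_rng(7)
        X, t, e = toy_survival_frame(rng, 60, [0.5, -0.5, 0.0])
        model = lasso_cox(X, t, e, lambda_=1e6)
        assert all(v == 0.0 for v in model.coefficients.values())
        assert model.active_genes == ()

    def test_zero_penalty_matches_newton_cox(self):
        """lambda=0 coordinate descent equals the unpenalized fit."""
        rng = np.random.default_rng(8)
        X, t, e = toy_survival_frame(rng, 120, [0.8, -0.4])
        model = lasso_cox(X, t, e, lambda_=0.0)
        beta_ref, _, _ = cox_newton(X.to_numpy().T, t, e)
        for b_model, b_ref in zip(
            (model.coefficients[g] for g in model.genes), beta_ref
        ):
            assert abs(b_model - b_ref) < 1e-4

    def test_planted_support_recovered(self):
        """2 true + 8 null genes at n=300: CV keeps both true genes."""
        rng = np.random.default_rng(9)
        X, t, e = toy_survival_frame(rng, 300, [0.8, -0.8] + [0.0] * 8)
        model = lasso_cox(X, t, e, cv_folds=10, seed=9)
        assert {"g0", "g1"} <= set(model.active_genes)

    def test_active_set_monotone_in_lambda(self):
        from metprog.signature import _lasso_path

        rng = np.random.default_rng(10)
        X, t, e = toy_survival_frame(rng, 150, [0.9, -0.6, 0.3, 0.0, 0.0])
        Xs = X.to_numpy().T
        Xs = (Xs - Xs.mean(0)) / Xs.std(0)
        lambdas = np.geomspace(1.0, 1e-3, 30)  # decreasing penalty
        betas = _lasso_path(Xs, t, e, lambdas)
        sizes = [(b != 0).sum() for b in betas]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_cutoff_is_training_median(self):
        rng = np.random.default_rng(11)
        X, t, e = toy_survival_frame(rng, 80, [0.7, -0.7])
        model = lasso_cox(X, t, e, lambda_=0.01)
        scores = risk_score(X, model)
        assert model.cutoff == pytest.approx(float(scores.median()))

    def test_single_gene_rejected(self):
        rng = np.random.default_rng(12)
        X, t, e = toy_survival_frame(rng, 40, [0.5])
        with pytest.raises(ValueError, match="two genes"):
            lasso_cox(X, t, e, lambda_=0.1)


class TestRiskScore:
    def _published_model(self):
        return RiskModel(
            coefficients=dict(PUBLISHED_COEFFS),
            cutoff=0.0,
            lambda_=0.0,
            genes=tuple(PUBLISHED_COEFFS),
        )

    def test_unit_expression_sums_published_coefficients(self):
        X = pd.DataFrame(1.0, index=list(PUBLISHED_COEFFS), columns=["p1", "p2"])
        scores = risk_score(X, self._published_model())
        assert np.allclose(scores, 0.9407)

    def test_zero_expression_zero_score(self):
        X = pd.DataFrame(0.0, index=list(PUBLISHED_COEFFS), columns=["p1"])
        assert risk_score(X, self._published_model()).iloc[0] == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(
            rng.uniform(0, 10, size=(8, 5)), index=list(PUBLISHED_COEFFS),
            columns=[f"s{i}" for i in range(5)],
        )
        model = self._published_model()
        assert np.allclose(risk_score(2 * X, model), 2 * risk_score(X, model))

    def test_missing_gene_listed_in_error(self):
        X = pd.DataFrame(1.0, index=["ENPP1", "FH"], columns=["p1"])
        with pytest.raises(KeyError, match="CYP2E1"):
            risk_score(X, self._published_model())


class TestStratifyMedian:
    def test_even_split(self):
        labels, cutoff = stratify_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert cutoff == 2.5
        assert list(labels) == ["low", "low", "high", "high"]

    def test_score_at_median_goes_low(self):
        labels, cutoff = stratify_median(pd.Series([1.0, 2.0, 3.0]))
        assert cutoff == 2.0
        assert list(labels) == ["low", "low", "high"]

    def test_balanced_groups_on_random_scores(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            n = int(rng.integers(4, 200))
            labels, _ = stratify_median(pd.Series(rng.normal(size=n)))
            assert abs((labels == "high").sum() - (labels == "low").sum()) <= 1

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(15)
        scores = pd.Series(rng.normal(size=51))
        base, _ = stratify_median(scores)
        for f in (np.exp, lambda s: s**3, lambda s: 5 * s - 2):
            labels, _ = stratify_median(f(scores))
            assert (labels == base).all()

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            stratify_median(pd.Series([1.0, 1.0, 1.0]))
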