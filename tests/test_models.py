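"""Component/full model fitting: CV honesty, oracle equivalences, recombination."""

import numpy as np
import pytest

from content import adjusted_r2
from content.models import (
    ContentComponentRegressor,
    ContentRegressor,
    export_weights,
    fit_full,
    select_best_model,
)


class TestComponentRegressor:
    def test_perfectly_predictable_signal(self, rng):
        n, m = 80, 10
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = G[:, 1].copy()
        est = ContentComponentRegressor(outer_cv=None, inner_cv=5, random_state=0).fit(G, y)
        assert est.cv_r2_ > 0.99
        assert est.lrt_p_ < 1e-10

    def test_zero_penalty_matches_ols(self, rng):
        # n >> M: the elastic net at a vanishing penalty equals least squares
        n, m = 400, 5
        G = rng.normal(size=(n, m))
        beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = G @ beta + 0.1 * rng.normal(size=n)
        est = ContentComponentRegressor(outer_cv=None, inner_cv=3, n_alphas=[1e-9],
                                        max_iter=50_000, tol=1e-10, random_state=0).fit(G, y)
        X = np.column_stack([np.ones(n), G])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(est.coef_ - ols[1:]).max() < 1e-6
        assert est.intercept_ == pytest.approx(ols[0], abs=1e-6)

    def test_infinite_penalty_gives_null_model(self, rng):
        n, m = 60, 8
        G = rng.normal(size=(n, m))
        y = rng.normal(size=n)
        est = ContentComponentRegressor(outer_cv=None, inner_cv=3, n_alphas=[1e9],
                                        random_state=0).fit(G, y)
        assert est.null_model_
        assert np.all(est.coef_ == 0)
        assert np.ptp(est.predict(G)) == 0

    def test_honest_cv_under_permutation(self, rng):
        # permuting y destroys any apparent out-of-fold R2
        n, m = 100, 40
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = G @ rng.normal(0, 0.3, size=m)
        vals = []
        for r in range(8):
            yp = rng.permutation(y)
            est = ContentComponentRegressor(outer_cv=None, inner_cv=5, n_alphas=8,
                                            random_state=r).fit(G, yp)
            vals.append(est.cv_adj_r2_)
        assert np.mean(vals) < 0.05

    def test_null_pipeline_not_anticonservative(self, rng):
        # h2 = 0: CV R2 near zero and the LRT does not over-reject
        n, m = 60, 30
        hits, reps = 0, 25
        r2s = []
        for r in range(reps):
            G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            y = rng.normal(size=n)
            est = ContentComponentRegressor(outer_cv=None, inner_cv=4, n_alphas=6,
                                            random_state=r).fit(G, y)
            r2s.append(est.cv_r2_)
            hits += est.lrt_p_ < 0.05
        assert np.mean(r2s) < 0.1
        assert hits / reps <= 0.2

    def test_requires_minimum_samples(self, rng):
        with pytest.raises(ValueError):
            ContentComponentRegressor().fit(rng.normal(size=(10, 5)), rng.normal(size=10))

    def test_nested_and_fast_modes_agree_on_strong_signal(self, rng):
        n, m = 90, 12
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = G @ np.array([1.0, -1.0] + [0.0] * 10) + 0.3 * rng.normal(size=n)
        nested = ContentComponentRegressor(outer_cv=5, inner_cv=4, random_state=0).fit(G, y)
        fast = ContentComponentRegressor(outer_cv=None, inner_cv=4, random_state=0).fit(G, y)
        assert nested.cv_r2_ > 0.8 and fast.cv_r2_ > 0.8


class TestFullModel:
    def test_expression_equal_to_shared_prediction(self, rng):
        n = 50
        sh = rng.normal(size=n)
        sp = rng.normal(size=n)
        fit = fit_full(sh, sh, sp, shared_coef=np.ones(3), specific_coef=np.zeros(3))
        assert fit.w_shared == pytest.approx(1.0, abs=1e-10)
        assert fit.w_specific == pytest.approx(0.0, abs=1e-10)
        assert fit.cv_r2 == pytest.approx(1.0)

    def test_sign_realignment_of_specific_component(self, rng):
        n = 200
        signal = rng.normal(size=n)
        E = signal + 0.1 * rng.normal(size=n)
        fit = fit_full(E, 0.0 * signal + rng.normal(size=n) * 0, -signal,
                       shared_coef=np.zeros(2), specific_coef=np.ones(2))
        assert fit.w_specific == pytest.approx(-1.0, abs=0.05)
        assert fit.dropped == "shared"

    def test_noise_predictors_give_nonpositive_adjusted_r2(self, rng):
        vals = []
        for _ in range(200):
            n = 40
            fit = fit_full(rng.normal(size=n), rng.normal(size=n), rng.normal(size=n))
            vals.append(fit.cv_adj_r2)
        assert np.mean(vals) <= 0.01

    def test_combined_weights_are_stated_linear_combination(self, rng):
        n, m = 40, 6
        sh_pred, sp_pred = rng.normal(size=n), rng.normal(size=n)
        E = sh_pred + 0.5 * sp_pred + 0.1 * rng.normal(size=n)
        b, g = rng.normal(size=m), rng.normal(size=m)
        fit = fit_full(E, sh_pred, sp_pred, shared_coef=b, specific_coef=g)
        assert np.abs(fit.coef - (fit.w_shared * b + fit.w_specific * g)).max() < 1e-12


class TestSelection:
    def test_argmax_and_tie_breaks(self):
        assert select_best_model({"shared": 0.2, "specific": 0.5, "full": 0.4}) == "specific"
        assert select_best_model({"shared": 0.4, "full": 0.4}) == "shared"  # fewer predictors
        assert select_best_model({"specific": 0.1}) == "specific"
        assert select_best_model({"full": np.nan}) is None

    def test_shared_architecture_prefers_shared_or_full(self, small_preprocessed):
        panel, truth, pre = small_preprocessed
        # gene 0 of the small study has substantial shared heritability
        fit = ContentRegressor(outer_cv=None, inner_cv=5, random_state=0).fit(
            panel.dosages(0), pre[0])
        labels = [v for v in fit.best_model_.values() if v is not None]
        assert labels  # at least one context fitted
        assert any(v in ("shared", "full") for v in labels)


@pytest.fixture(scope="module")
def fitted(small_preprocessed):
    panel, _, pre = small_preprocessed
    fit = ContentRegressor(outer_cv=None, inner_cv=5, random_state=0).fit(
        panel.dosages(0), pre[0])
    return {"gene0": fit}, {"gene0": panel.snp_ids(0)}


class TestExportWeights:

    def test_nominal_threshold_filters(self, fitted):
        fits, snps = fitted
        full_table = export_weights(fits, snps, threshold=1.0)
        filtered = export_weights(fits, snps, threshold=1e-300)
        assert len(filtered) == 0
        assert len(full_table) > 0
        assert list(full_table.columns) == ["gene", "context", "model", "snp", "a1", "a2", "weight"]

    def test_full_weights_are_linear_combination(self, fitted):
        fits, snps = fitted
        fit = fits["gene0"]
        table = export_weights(fits, snps, threshold=1.0)
        ctx = fit.context_ids_[0]
        fu = fit.full_fits_[ctx]
        sub = table[(table.context == ctx) & (table.model == "full")]
        expect = fu.coef
        got = np.zeros_like(expect)
        idx = {s: i for i, s in enumerate(snps["gene0"])}
        for _, row in sub.iterrows():
            got[idx[row.snp]] = row.weight
        assert np.abs(got - expect).max() < 1e-12
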