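"""Genetic predictors of decomposed expression components.

For each gene, an elastic net is fit to the context-shared component of
expression (one value per individual) and to each context-specific deviation,
with honest out-of-fold predictions from cross-validation.  A per-context
"full" model then recombines the two predicted components by ordinary least
squares — the fitted recombination weights re-sign the specific deviation when
needed — yielding a single combined cis-SNP weight vector per context
(``w_shared * beta_hat + w_specific * gamma_hat_c``).  Significance of every
model is assessed with a Gaussian likelihood ratio test against an
intercept-only null (1 df for component models, 2 df for the full model).
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold


@contextmanager
def _quiet_solver():
    """Coordinate descent runs with a bounded iteration budget by design."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield

from ._stats import adjusted_r2, lrt_significance

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentFit",
    "FullFit",
    "GeneModels",
    "ContentComponentRegressor",
    "ContentRegressor",
    "fit_component",
    "fit_full",
    "select_best_model",
    "export_weights",
]


@dataclass
class ComponentFit:
    """A fitted penalized predictor of one expression component."""

    component: str  # "shared" | "specific:<context>"
    coef: np.ndarray  # dosage-scale SNP weights (refit on all data)
    intercept: float
    alpha: float  # selected penalty
    rows: np.ndarray  # indices into the individual pool the fit used
    oof_prediction: np.ndarray  # honest out-of-fold predictions, aligned with rows
    cv_r2: float
    cv_adj_r2: float
    lrt_stat: float
    lrt_p: float
    null_model: bool  # all weights zero (prediction is the intercept)


@dataclass
class FullFit:
    """Recombination of the shared and specific predictors for one context."""

    context: str
    w_shared: float
    w_specific: float
    intercept: float
    coef: np.ndarray  # combined dosage-scale weights
    rows: np.ndarray
    prediction: np.ndarray  # recombined out-of-fold component predictions
    cv_r2: float
    cv_adj_r2: float
    lrt_stat: float
    lrt_p: float
    dropped: str | None  # component dropped because its prediction was constant


@dataclass
class GeneModels:
    """All fitted models of one gene plus the per-context best-model labels."""

    gene_id: str
    shared: ComponentFit
    specific: dict[str, ComponentFit]
    full: dict[str, FullFit]
    #: per context: adjusted R2 of each model's prediction against the observed
    #: expression of that context (the quantity model selection compares)
    observed_adj_r2: dict[str, dict[str, float]]
    best_model: dict[str, str | None]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


class ContentComponentRegressor(RegressorMixin, BaseEstimator):
    """Cross-validated elastic net for one expression component.

    Genotypes are standardized within each training split; exported
    coefficients are returned on the dosage scale.  Two cross-validation
    layouts are available:

    * ``outer_cv`` set (default 10): nested CV.  The outer folds produce
      out-of-fold predictions from models whose penalty was selected by an
      inner ``inner_cv``-fold search on the outer-training split only, so the
      predictions are never informed by the predicted individuals.  A final
      whole-data inner CV selects the penalty of the exported weights.
    * ``outer_cv=None``: the penalty is selected once by ``inner_cv``-fold CV
      on all data and out-of-fold predictions are produced at that penalty.
      Cheaper, with slight optimism confined to the penalty choice.

    Attributes (after ``fit``): ``coef_``, ``intercept_``, ``alpha_``,
    ``oof_prediction_``, ``cv_r2_``, ``cv_adj_r2_``, ``lrt_stat_``,
    ``lrt_p_``, ``null_model_``.
    """

    def __init__(self, l1_ratio: float = 0.5, n_alphas: int = 15,
                 outer_cv: int | None = 10, inner_cv: int = 10,
                 max_iter: int = 1000, tol: float = 1e-3,
                 min_samples: int = 20, random_state: int | None = 0):
        self.l1_ratio = l1_ratio
        self.n_alphas = n_alphas
        self.outer_cv = outer_cv
        self.inner_cv = inner_cv
        self.max_iter = max_iter
        self.tol = tol
        self.min_samples = min_samples
        self.random_state = random_state

    def _encv(self) -> ElasticNetCV:
        return ElasticNetCV(
            l1_ratio=self.l1_ratio, alphas=self.n_alphas, cv=self.inner_cv,
            max_iter=self.max_iter, tol=self.tol, precompute=True,
            random_state=self.random_state,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ContentComponentRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.size
        if n < self.min_samples:
            raise ValueError(f"need at least {self.min_samples} individuals, got {n}")
        if not np.all(np.isfinite(X)):
            raise ValueError("genotypes contain non-finite values")
        self.n_features_in_ = X.shape[1]

        if y.std() == 0:
            self._set_null(X, y)
            return self

        oof = np.empty(n)
        folds: list[np.ndarray] = []
        with _quiet_solver():
            if self.outer_cv is not None:
                outer = KFold(self.outer_cv, shuffle=True, random_state=self.random_state)
                for tr, te in outer.split(X):
                    Xs, mean, sd = _standardize(X[tr])
                    m = self._encv().fit(Xs, y[tr])
                    oof[te] = m.predict((X[te] - mean) / sd)
                    folds.append(te)
                Xs, mean, sd = _standardize(X)
                final = self._encv().fit(Xs, y)
            else:
                Xs, mean, sd = _standardize(X)
                final = self._encv().fit(Xs, y)
                inner = KFold(self.inner_cv, shuffle=True, random_state=self.random_state)
                for tr, te in inner.split(X):
                    Xt, mt, st = _standardize(X[tr])
                    m = ElasticNet(alpha=final.alpha_, l1_ratio=self.l1_ratio,
                                   max_iter=self.max_iter, tol=self.tol,
                                   precompute=True).fit(Xt, y[tr])
                    oof[te] = m.predict((X[te] - mt) / st)
                    folds.append(te)
        # center predictions within each fold: the fold models' intercepts are
        # (minus) the held-out fold's mean in disguise, and that training-mean
        # leakage inflates the squared correlation under the null
        for te in folds:
            oof[te] += y.mean() - oof[te].mean()

        self.alpha_ = float(final.alpha_)
        self.coef_ = final.coef_ / sd  # back to dosage scale
        self.intercept_ = float(final.intercept_ - self.coef_ @ mean)
        self.oof_prediction_ = oof
        self.null_model_ = bool(np.all(final.coef_ == 0))
        if self.null_model_:
            logger.debug("all elastic-net weights zero: null model (intercept only)")
        self.cv_r2_ = adjusted_r2(y, oof, 0)  # p=0 -> plain squared correlation
        self.cv_adj_r2_ = adjusted_r2(y, oof, 1)
        self.lrt_stat_, self.lrt_p_ = lrt_significance(y, oof)
        return self

    def _set_null(self, X: np.ndarray, y: np.ndarray) -> None:
        n = y.size
        self.alpha_ = np.inf
        self.coef_ = np.zeros(X.shape[1])
        self.intercept_ = float(y.mean())
        self.oof_prediction_ = np.full(n, y.mean())
        self.null_model_ = True
        self.cv_r2_ = 0.0
        self.cv_adj_r2_ = adjusted_r2(y, np.zeros(n), 1) if n > 2 else 0.0
        self.lrt_stat_, self.lrt_p_ = 0.0, 1.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def to_component_fit(self, component: str, rows: np.ndarray) -> ComponentFit:
        return ComponentFit(
            component=component, coef=self.coef_, intercept=self.intercept_,
            alpha=self.alpha_, rows=rows, oof_prediction=self.oof_prediction_,
            cv_r2=self.cv_r2_, cv_adj_r2=self.cv_adj_r2_,
            lrt_stat=self.lrt_stat_, lrt_p=self.lrt_p_, null_model=self.null_model_,
        )


def fit_component(y: np.ndarray, G: np.ndarray, component: str = "shared",
                  rows: np.ndarray | None = None, **kwargs) -> ComponentFit:
    """Functional wrapper over :class:`ContentComponentRegressor`."""
    est = ContentComponentRegressor(**kwargs).fit(G, y)
    if rows is None:
        rows = np.arange(len(y))
    return est.to_component_fit(component, np.asarray(rows))


def fit_full(E_c: np.ndarray, shared_pred: np.ndarray, specific_pred: np.ndarray,
             context: str = "", rows: np.ndarray | None = None,
             shared_coef: np.ndarray | None = None,
             specific_coef: np.ndarray | None = None,
             shared_intercept: float = 0.0,
             specific_intercept: float = 0.0) -> FullFit:
    """Recombine component predictions for one context by OLS.

    Regresses the observed expression of the context on the out-of-fold shared
    and specific predictions (with intercept).  The fitted weights implicitly
    re-sign the specific deviation.  A component whose prediction is constant
    is dropped and the model degenerates to a single-predictor fit.
    """
    E_c = np.asarray(E_c, dtype=float)
    n = E_c.size
    preds = {"shared": np.asarray(shared_pred, float), "specific": np.asarray(specific_pred, float)}
    active = [k for k, v in preds.items() if v.std() > 0]
    dropped = None if len(active) == 2 else (set(preds) - set(active)).pop() if active else "both"
    if not active:
        w = {"shared": 0.0, "specific": 0.0}
        fitted = np.full(n, E_c.mean())
        intercept = float(E_c.mean())
        stat, p = 0.0, 1.0
        df = 2
    else:
        X = np.column_stack([np.ones(n)] + [preds[k] for k in active])
        coefs, *_ = np.linalg.lstsq(X, E_c, rcond=None)
        intercept = float(coefs[0])
        w = {"shared": 0.0, "specific": 0.0}
        for k, v in zip(active, coefs[1:]):
            w[k] = float(v)
        fitted = X @ coefs
        stat, p = lrt_significance(E_c, X[:, 1:])
        df = len(active)
    M = 0 if shared_coef is None else len(shared_coef)
    combined = np.zeros(M)
    if shared_coef is not None:
        combined = w["shared"] * shared_coef + w["specific"] * np.asarray(specific_coef)
    comb_intercept = intercept + w["shared"] * shared_intercept + w["specific"] * specific_intercept
    return FullFit(
        context=context, w_shared=w["shared"], w_specific=w["specific"],
        intercept=comb_intercept, coef=combined,
        rows=np.arange(n) if rows is None else np.asarray(rows),
        prediction=fitted,
        cv_r2=adjusted_r2(E_c, fitted, 0),
        cv_adj_r2=adjusted_r2(E_c, fitted, df),
        lrt_stat=stat, lrt_p=p, dropped=dropped,
    )


class ContentRegressor(BaseEstimator):
    """Per-gene multi-context genetic predictor of expression.

    ``fit(G, E)`` takes an (I, M) dosage matrix over the individual pool and an
    (I, C) expression matrix with NaN marking individuals unobserved in a
    context.  The expression is (optionally) standardized per context,
    decomposed into the between-individual shared component and
    within-individual specific deviations, and an elastic net is fit per
    component; per-context full models recombine the two predictions.

    ``predict(G, context, model)`` returns the genetic prediction for new
    dosages with ``model`` one of ``"shared"``, ``"specific"``, ``"full"``.
    """

    def __init__(self, l1_ratio: float = 0.5, n_alphas: int = 15,
                 outer_cv: int | None = 10, inner_cv: int = 10,
                 max_iter: int = 1000, tol: float = 1e-3,
                 standardize: bool = True, min_samples: int = 20,
                 context_ids: list[str] | None = None,
                 random_state: int | None = 0):
        self.l1_ratio = l1_ratio
        self.n_alphas = n_alphas
        self.outer_cv = outer_cv
        self.inner_cv = inner_cv
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.min_samples = min_samples
        self.context_ids = context_ids
        self.random_state = random_state

    def _component(self) -> ContentComponentRegressor:
        return ContentComponentRegressor(
            l1_ratio=self.l1_ratio, n_alphas=self.n_alphas, outer_cv=self.outer_cv,
            inner_cv=self.inner_cv, max_iter=self.max_iter, tol=self.tol,
            min_samples=self.min_samples, random_state=self.random_state,
        )

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ContentRegressor":
        G = np.asarray(X, dtype=float)
        E = np.asarray(Y, dtype=float).copy()
        I, C = E.shape
        self.n_features_in_ = G.shape[1]
        ctx_ids = self.context_ids or [f"context{c}" for c in range(C)]
        if len(ctx_ids) != C:
            raise ValueError("context_ids length does not match expression columns")

        if self.standardize:
            for c in range(C):
                obs = ~np.isnan(E[:, c])
                v = E[obs, c]
                if obs.sum() >= 2 and v.std() > 0:
                    E[obs, c] = (v - v.mean()) / v.std()

        shared = np.nanmean(E, axis=1)
        specific = E - shared[:, None]

        shared_rows = np.flatnonzero(~np.isnan(shared))
        est = self._component().fit(G[shared_rows], shared[shared_rows])
        self.shared_fit_ = est.to_component_fit("shared", shared_rows)
        shared_oof = np.full(I, np.nan)
        shared_oof[shared_rows] = est.oof_prediction_

        self.specific_fits_ = {}
        self.full_fits_ = {}
        self.observed_adj_r2_ = {}
        self.best_model_ = {}
        for c, ctx in enumerate(ctx_ids):
            rows = np.flatnonzero(~np.isnan(E[:, c]))
            if rows.size < self.min_samples:
                self.specific_fits_[ctx] = None
                self.full_fits_[ctx] = None
                self.observed_adj_r2_[ctx] = {}
                self.best_model_[ctx] = None
                continue
            est_c = self._component().fit(G[rows], specific[rows, c])
            sfit = est_c.to_component_fit(f"specific:{ctx}", rows)
            self.specific_fits_[ctx] = sfit
            ffit = fit_full(
                E[rows, c], shared_oof[rows], est_c.oof_prediction_, context=ctx,
                rows=rows, shared_coef=self.shared_fit_.coef,
                specific_coef=sfit.coef,
                shared_intercept=self.shared_fit_.intercept,
                specific_intercept=sfit.intercept,
            )
            self.full_fits_[ctx] = ffit
            scores = {
                "shared": adjusted_r2(E[rows, c], shared_oof[rows], 1),
                "specific": adjusted_r2(E[rows, c], est_c.oof_prediction_, 1),
                "full": ffit.cv_adj_r2,
            }
            self.observed_adj_r2_[ctx] = scores
            self.best_model_[ctx] = select_best_model(scores)
        self.context_ids_ = ctx_ids
        return self

    def predict(self, X: np.ndarray, context: str, model: str = "full") -> np.ndarray:
        G = np.asarray(X, dtype=float)
        if model == "shared":
            f = self.shared_fit_
            return G @ f.coef + f.intercept
        if model == "specific":
            f = self.specific_fits_[context]
            return G @ f.coef + f.intercept
        if model == "full":
            f = self.full_fits_[context]
            return G @ f.coef + f.intercept
        raise ValueError(f"unknown model {model!r}")

    def to_gene_models(self, gene_id: str) -> GeneModels:
        return GeneModels(
            gene_id=gene_id, shared=self.shared_fit_,
            specific=self.specific_fits_, full=self.full_fits_,
            observed_adj_r2=self.observed_adj_r2_, best_model=self.best_model_,
        )


_MODEL_ORDER = {"shared": 0, "specific": 1, "full": 2}


def select_best_model(scores: dict[str, float]) -> str | None:
    """Model with the greatest cross-validated adjusted R-squared.

    Ties prefer fewer predictors (shared/specific over full), then
    lexicographic order.
    """
    finite = {k: v for k, v in scores.items() if np.isfinite(v)}
    if not finite:
        return None
    return min(finite, key=lambda k: (-finite[k], _MODEL_ORDER.get(k, 9), k))


def export_weights(fits: dict[str, "ContentRegressor"],
                   snp_ids: dict[str, list[str]],
                   threshold: float = 0.1,
                   a1: str = "A", a2: str = "B") -> pd.DataFrame:
    """Weight table for downstream TWAS, one row per (gene, context, model, SNP).

    A model is exported when its LRT p-value is below ``threshold`` (the
    nominal forwarding rule; 1.0 exports everything).  Full-model rows carry
    the combined weights ``w_shared * beta + w_specific * gamma_c``; shared
    weights are repeated for every context so each context receives a single
    weight vector per model.
    """
    records: list[tuple] = []
    for gene, fit in fits.items():
        snps = snp_ids[gene]
        for ctx in fit.context_ids_:
            sh = fit.shared_fit_
            if sh is not None and sh.lrt_p < threshold and not sh.null_model:
                for s, w in zip(snps, sh.coef):
                    if w != 0:
                        records.append((gene, ctx, "shared", s, a1, a2, w))
            sp = fit.specific_fits_.get(ctx)
            if sp is not None and sp.lrt_p < threshold and not sp.null_model:
                for s, w in zip(snps, sp.coef):
                    if w != 0:
                        records.append((gene, ctx, "specific", s, a1, a2, w))
            fu = fit.full_fits_.get(ctx)
            if fu is not None and fu.lrt_p < threshold and np.any(fu.coef != 0):
                for s, w in zip(snps, fu.coef):
                    if w != 0:
                        records.append((gene, ctx, "full", s, a1, a2, w))
    return pd.DataFrame.from_records(
        records, columns=["gene", "context", "model", "snp", "a1", "a2", "weight"]
    )
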