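"""Comparator predictors: per-context elastic net and a joint group-LASSO fit.

The context-by-context baseline fits an independent cross-validated elastic net
to the observed (non-decomposed) expression of every context, mirroring the
classic single-tissue TWAS weight-training recipe.  The joint baseline fits all
contexts at once under a group-LASSO penalty that forces each SNP's
coefficients to be jointly zero or nonzero across contexts (the published
UTMOST objective, reimplemented here rather than wrapped); per-context losses
are weighted by 1/(2 n_c) so contexts with unequal sample sizes contribute
comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from ._group_lasso import lambda_max, solve_path
from ._stats import adjusted_r2, lrt_significance
from .models import ComponentFit, ContentComponentRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "JointFit",
    "ContextByContextRegressor",
    "GroupLassoRegressor",
    "fit_context_by_context",
    "fit_group_lasso",
]


@dataclass
class JointFit:
    """Summary of a fitted joint group-LASSO model."""

    coef: np.ndarray  # (M, C) dosage-scale coefficients, rows jointly (non)zero
    intercepts: np.ndarray  # (C,)
    penalty: float
    penalty_path: np.ndarray
    cv_r2: dict[str, float]
    cv_adj_r2: dict[str, float]
    lrt_p: dict[str, float]
    n_per_context: dict[str, int]
    converged: bool


class ContextByContextRegressor(BaseEstimator):
    """Independent elastic net per context on observed expression.

    Same cross-validation and scoring machinery as the component models; on a
    single-context study this is exactly a lone elastic-net fit.
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

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ContextByContextRegressor":
        G = np.asarray(X, dtype=float)
        E = np.asarray(Y, dtype=float)
        if E.ndim == 1:
            E = E[:, None]
        I, C = E.shape
        self.n_features_in_ = G.shape[1]
        ctx_ids = self.context_ids or [f"context{c}" for c in range(C)]
        self.context_fits_ = {}
        for c, ctx in enumerate(ctx_ids):
            rows = np.flatnonzero(~np.isnan(E[:, c]))
            if rows.size < self.min_samples:
                self.context_fits_[ctx] = None
                continue
            y = E[rows, c]
            if self.standardize and y.std() > 0:
                y = (y - y.mean()) / y.std()
            est = ContentComponentRegressor(
                l1_ratio=self.l1_ratio, n_alphas=self.n_alphas,
                outer_cv=self.outer_cv, inner_cv=self.inner_cv,
                max_iter=self.max_iter, tol=self.tol,
                min_samples=self.min_samples, random_state=self.random_state,
            ).fit(G[rows], y)
            self.context_fits_[ctx] = est.to_component_fit(f"context:{ctx}", rows)
        self.context_ids_ = ctx_ids
        return self

    def predict(self, X: np.ndarray, context: str) -> np.ndarray:
        f = self.context_fits_[context]
        return np.asarray(X, dtype=float) @ f.coef + f.intercept


class GroupLassoRegressor(BaseEstimator):
    """Joint multi-context predictor with SNP-level group sparsity.

    ``fit(G, E)`` minimizes ``sum_c RSS_c / (2 n_c) + lam * sum_m ||B_m.||_2``
    by block-coordinate descent on per-context standardized genotypes, with the
    penalty chosen by ``cv``-fold cross-validation over a geometric path and a
    final whole-data refit.  Missing individuals in a context simply drop from
    that context's loss term.

    Attributes: ``coef_`` (M x C, dosage scale), ``intercepts_``, ``lambda_``,
    ``oof_predictions_`` (per context, at the selected penalty), ``cv_r2_``,
    ``cv_adj_r2_``, ``lrt_p_``, ``converged_``.
    """

    def __init__(self, n_lambdas: int = 8, lambda_min_ratio: float = 0.05,
                 cv: int = 5, tol: float = 1e-6, max_sweeps: int = 10_000,
                 standardize: bool = True, min_samples: int = 2,
                 context_ids: list[str] | None = None,
                 random_state: int | None = 0):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.standardize = standardize
        self.min_samples = min_samples
        self.context_ids = context_ids
        self.random_state = random_state

    @staticmethod
    def _stack(G, E, rows_per_ctx):
        """Standardize per context and stack designs/outcomes."""
        Xs, ys, stats = [], [], []
        for rows, c in rows_per_ctx:
            Gc = G[rows]
            mu, sd = Gc.mean(axis=0), Gc.std(axis=0)
            sd_safe = np.where(sd > 0, sd, 1.0)
            y = E[rows, c]
            ym = y.mean()
            Xs.append((Gc - mu) / sd_safe)
            ys.append(y - ym)
            stats.append((mu, sd_safe, ym))
        offsets = np.concatenate([[0], np.cumsum([x.shape[0] for x in Xs])]).astype(np.int64)
        return np.vstack(Xs), np.concatenate(ys), offsets, stats

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "GroupLassoRegressor":
        G = np.asarray(X, dtype=float)
        E = np.asarray(Y, dtype=float).copy()
        I, C = E.shape
        self.n_features_in_ = G.shape[1]
        ctx_ids = self.context_ids or [f"context{c}" for c in range(C)]

        if self.standardize:
            for c in range(C):
                obs = ~np.isnan(E[:, c])
                v = E[obs, c]
                if obs.sum() >= 2 and v.std() > 0:
                    E[obs, c] = (v - v.mean()) / v.std()

        rows_per_ctx = []
        for c in range(C):
            rows = np.flatnonzero(~np.isnan(E[:, c]))
            if rows.size < self.min_samples:
                raise ValueError(f"context {ctx_ids[c]} has fewer than {self.min_samples} observations")
            rows_per_ctx.append((rows, c))

        Xall, yall, offsets, _ = self._stack(G, E, rows_per_ctx)
        lmax = lambda_max(Xall, yall, offsets)
        if lmax == 0:
            lmax = 1.0
        path = np.geomspace(lmax, lmax * self.lambda_min_ratio, self.n_lambdas)
        self.lambda_path_ = path

        # cross-validate the penalty over folds of the individual pool
        folds = KFold(self.cv, shuffle=True, random_state=self.random_state)
        pool = np.arange(I)
        cv_loss = np.zeros(path.size)
        oof = [np.full((rows.size, path.size), np.nan) for rows, _ in rows_per_ctx]
        for tr_pool, te_pool in folds.split(pool):
            tr_mask = np.zeros(I, dtype=bool)
            tr_mask[tr_pool] = True
            tr_rows = [(rows[tr_mask[rows]], c) for rows, c in rows_per_ctx]
            Xtr, ytr, off_tr, stats = self._stack(G, E, tr_rows)
            Bpath, _ = solve_path(Xtr, ytr, off_tr, path, self.tol, self.max_sweeps)
            for k, (rows, c) in enumerate(rows_per_ctx):
                te = rows[~tr_mask[rows]]
                if te.size == 0:
                    continue
                mu, sd, ym = stats[k]
                Xte = (G[te] - mu) / sd
                pred = np.tensordot(Xte, Bpath[:, :, k].T, axes=([1], [0])) + ym  # (n_te, L)
                resid2 = (E[te, c][:, None] - pred) ** 2
                cv_loss += resid2.sum(axis=0) / (2 * te.size)
                # store fold-centered predictions for scoring: the training-set
                # intercept leaks the held-out fold's mean and would otherwise
                # inflate the null squared correlation
                oof[k][~tr_mask[rows]] = pred - pred.mean(axis=0)
        best = int(np.argmin(cv_loss))
        self.lambda_ = float(path[best])

        # final whole-data refit, warm-started down the path to the selected penalty
        Bpath, self.converged_ = solve_path(Xall, yall, offsets, path[: best + 1],
                                            self.tol, self.max_sweeps)
        if not self.converged_:
            logger.warning("group LASSO did not fully converge; returning best iterate")
        Bstd = Bpath[best]  # (M, C-stacked order)

        M = G.shape[1]
        self.coef_ = np.zeros((M, C))
        self.intercepts_ = np.zeros(C)
        stats = [
            ((G[rows]).mean(axis=0), np.where(G[rows].std(axis=0) > 0, G[rows].std(axis=0), 1.0), E[rows, c].mean())
            for rows, c in rows_per_ctx
        ]
        self.cv_r2_, self.cv_adj_r2_, self.lrt_p_ = {}, {}, {}
        self.oof_predictions_ = {}
        self.rows_ = {}
        for k, (rows, c) in enumerate(rows_per_ctx):
            mu, sd, ym = stats[k]
            self.coef_[:, c] = Bstd[:, k] / sd
            self.intercepts_[c] = ym - self.coef_[:, c] @ mu
            ctx = ctx_ids[c]
            pred = oof[k][:, best]
            y = E[rows, c]
            self.oof_predictions_[ctx] = pred
            self.rows_[ctx] = rows
            self.cv_r2_[ctx] = adjusted_r2(y, pred, 0)
            self.cv_adj_r2_[ctx] = adjusted_r2(y, pred, 1)
            _, self.lrt_p_[ctx] = lrt_significance(y, pred)
        self.context_ids_ = ctx_ids
        return self

    def predict(self, X: np.ndarray, context: str) -> np.ndarray:
        c = self.context_ids_.index(context)
        return np.asarray(X, dtype=float) @ self.coef_[:, c] + self.intercepts_[c]

    def to_joint_fit(self) -> JointFit:
        return JointFit(
            coef=self.coef_, intercepts=self.intercepts_, penalty=self.lambda_,
            penalty_path=self.lambda_path_, cv_r2=self.cv_r2_,
            cv_adj_r2=self.cv_adj_r2_, lrt_p=self.lrt_p_,
            n_per_context={c: len(r) for c, r in self.rows_.items()},
            converged=self.converged_,
        )


def fit_context_by_context(G: np.ndarray, E: np.ndarray, **kwargs) -> dict[str, ComponentFit]:
    """Functional wrapper: per-context elastic-net fits for one gene."""
    est = ContextByContextRegressor(**kwargs).fit(G, E)
    return est.context_fits_


def fit_group_lasso(G: np.ndarray, E: np.ndarray, folds: int = 5, **kwargs) -> JointFit:
    """Functional wrapper: joint group-LASSO fit for one gene."""
    est = GroupLassoRegressor(cv=folds, **kwargs).fit(G, E)
    return est.to_joint_fit()
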