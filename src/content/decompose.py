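"""Multilevel decomposition of repeated-measures expression.

Expression measured for the same individuals across several contexts (tissues,
cell types) is split, per gene, into a between-individual component — the mean
of an individual's expression over their observed contexts, shared by every
context — and within-individual deviations from that mean, one per context.
The two components reconstruct the (residualized, centered, scaled) expression
exactly at every observed entry, the deviations of an individual sum to zero
over their observed contexts, and with complete data the components are
globally orthogonal.

An optional grouped variant inserts a group-shared level (e.g. a brain-shared
component over the brain tissues) between the global mean and the deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "DecomposedExpression",
    "MultilevelDecomposer",
    "residualize",
    "center_scale",
    "decompose",
    "decompose_grouped",
]


@dataclass
class ExpressionStudy:
    """Observed expression for J genes over a pool of individuals and C contexts.

    ``expression[j, i, c]`` is NaN when individual i was not measured in
    context c (the observation pattern is allowed to differ between genes).
    ``covariates`` optionally maps a context id to a DataFrame indexed by
    individual id.
    """

    expression: np.ndarray  # (J, I, C), NaN = unobserved
    gene_ids: list[str]
    individual_ids: list[str]
    context_ids: list[str]
    covariates: dict[str, pd.DataFrame] | None = None
    context_groups: dict[str, str] | None = None
    #: gene-contexts excluded from modeling, with reasons
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        J, I, C = self.expression.shape
        if (len(self.gene_ids), len(self.individual_ids), len(self.context_ids)) != (J, I, C):
            raise ValueError("id lists do not match expression dimensions")
        if np.any(np.isinf(self.expression)):
            raise ValueError("expression contains non-finite observed values")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_contexts(self) -> int:
        return self.expression.shape[2]

    def observed(self, j: int) -> np.ndarray:
        """Boolean (I, C) observation mask for gene j."""
        return ~np.isnan(self.expression[j])

    def copy(self) -> "ExpressionStudy":
        return ExpressionStudy(
            expression=self.expression.copy(),
            gene_ids=list(self.gene_ids),
            individual_ids=list(self.individual_ids),
            context_ids=list(self.context_ids),
            covariates=self.covariates,
            context_groups=self.context_groups,
            exclusions=list(self.exclusions),
        )


@dataclass
class DecomposedExpression:
    """Context-shared and context-specific expression components per gene."""

    shared: np.ndarray  # (J, I), NaN where individual unobserved in all contexts
    specific: np.ndarray  # (J, I, C), NaN where unobserved
    mask: np.ndarray  # (J, I, C) bool
    gene_ids: list[str]
    individual_ids: list[str]
    context_ids: list[str]
    group_shared: dict[str, np.ndarray] | None = None  # group id -> (J, I)
    context_groups: dict[str, str] | None = None


def _covariate_matrix(df: pd.DataFrame, individuals: list[str], rows: np.ndarray) -> np.ndarray:
    sub = df.reindex([individuals[i] for i in np.flatnonzero(rows)])
    if sub.isna().any().any():
        raise ValueError("covariates missing for observed individuals")
    return sub.to_numpy(dtype=float)


def residualize(study: ExpressionStudy) -> ExpressionStudy:
    """Replace each gene-context vector by OLS residuals on that context's covariates.

    An intercept is always included; constant and collinear covariate columns
    are dropped with a warning.  Contexts without a covariate table are only
    mean-centered.
    """
    out = study.copy()
    E = out.expression
    J, I, C = E.shape
    for c, ctx in enumerate(study.context_ids):
        cov = (study.covariates or {}).get(ctx)
        for j in range(J):
            obs = ~np.isnan(E[j, :, c])
            n = int(obs.sum())
            if n == 0:
                continue
            y = E[j, obs, c]
            if cov is None:
                E[j, obs, c] = y - y.mean()
                continue
            X = _covariate_matrix(cov, study.individual_ids, obs)
            keep = X.std(axis=0) > 0
            if not keep.all():
                logger.warning("context %s: dropping %d constant covariate columns", ctx, int((~keep).sum()))
            X = X[:, keep]
            X = np.column_stack([np.ones(n), X])
            if n <= X.shape[1]:
                raise ValueError(f"context {ctx}: n={n} <= number of covariates")
            q, r = np.linalg.qr(X)
            rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(abs(np.diag(r)).max(), 1)))
            if rank < X.shape[1]:
                logger.warning("context %s: covariates rank deficient, dropping collinear columns", ctx)
                q = q[:, :rank]
            E[j, obs, c] = y - q @ (q.T @ y)
    return out


def center_scale(study: ExpressionStudy) -> ExpressionStudy:
    """Standardize each gene-context over its observed individuals.

    Mean 0 and population (1/n) variance 1.  Gene-contexts with fewer than two
    observations or zero variance are excluded (set to NaN) and recorded in
    ``exclusions``.
    """
    out = study.copy()
    E = out.expression
    J, I, C = E.shape
    for j in range(J):
        for c in range(C):
            obs = ~np.isnan(E[j, :, c])
            n = int(obs.sum())
            if n == 0:
                continue
            y = E[j, obs, c]
            sd = y.std()  # population convention
            if n < 2 or sd == 0:
                out.exclusions.append(
                    (study.gene_ids[j], study.context_ids[c], "zero variance" if n >= 2 else "n < 2")
                )
                logger.warning(
                    "excluding %s / %s: %s", study.gene_ids[j], study.context_ids[c],
                    "zero variance" if n >= 2 else "fewer than 2 observations",
                )
                E[j, :, c] = np.nan
                continue
            E[j, obs, c] = (y - y.mean()) / sd
    return out


def decompose(study: ExpressionStudy) -> DecomposedExpression:
    """Split expression into between-individual (shared) and within-individual
    (specific) components.

    The shared value of individual i is the mean over i's observed contexts;
    the specific value in context c is the observed value minus that mean.
    Individuals observed in a single context get a zero specific value there.
    """
    E = study.expression
    mask = ~np.isnan(E)
    with warnings.catch_warnings():
        # individuals unobserved in every context legitimately yield NaN means
        warnings.simplefilter("ignore", RuntimeWarning)
        shared = np.nanmean(E, axis=2)  # (J, I); NaN if unobserved everywhere
    specific = E - shared[:, :, None]
    return DecomposedExpression(
        shared=shared,
        specific=specific,
        mask=mask,
        gene_ids=list(study.gene_ids),
        individual_ids=list(study.individual_ids),
        context_ids=list(study.context_ids),
    )


def decompose_grouped(study: ExpressionStudy, groups: dict[str, str]) -> DecomposedExpression:
    """Decomposition with an intermediate group-shared level.

    ``groups`` maps every context id to a group label.  For each group with at
    least two contexts, the group-shared component of individual i is the mean
    over i's observed contexts in the group minus i's global shared value, and
    the specific component becomes observed - shared - group_shared.  Singleton
    groups are collapsed (their group-shared component would coincide with the
    specific deviation) with a warning.
    """
    missing = [c for c in study.context_ids if c not in groups]
    if missing:
        raise ValueError(f"contexts without a group assignment: {missing}")
    base = decompose(study)
    E = study.expression
    labels = np.array([groups[c] for c in study.context_ids])
    group_shared: dict[str, np.ndarray] = {}
    specific = base.specific.copy()
    for g in dict.fromkeys(labels):  # preserve context order
        cols = labels == g
        if cols.sum() < 2:
            logger.warning("group %s has a single context; collapsed into the specific component", g)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gmean = np.nanmean(E[:, :, cols], axis=2)
        gs = gmean - base.shared
        gs[np.isnan(gs)] = np.nan
        group_shared[g] = gs
        specific[:, :, cols] = E[:, :, cols] - gmean[:, :, None]
    return DecomposedExpression(
        shared=base.shared,
        specific=specific,
        mask=base.mask,
        gene_ids=base.gene_ids,
        individual_ids=base.individual_ids,
        context_ids=base.context_ids,
        group_shared=group_shared or None,
        context_groups=dict(groups) if group_shared else None,
    )


class MultilevelDecomposer(TransformerMixin, BaseEstimator):
    """Transformer wrapping residualize -> center/scale -> decompose.

    Parameters
    ----------
    residualize : bool
        Regress out per-context covariates (when the study carries them).
    standardize : bool
        Center and scale each gene-context before decomposing.
    groups : dict or None
        Optional context -> group mapping for a grouped decomposition.
    """

    def __init__(self, residualize: bool = True, standardize: bool = True,
                 groups: dict[str, str] | None = None):
        self.residualize = residualize
        self.standardize = standardize
        self.groups = groups

    def fit(self, X: ExpressionStudy, y=None):  # noqa: D102 - sklearn protocol
        if not isinstance(X, ExpressionStudy):
            raise TypeError("MultilevelDecomposer operates on ExpressionStudy inputs")
        self.n_features_in_ = X.n_contexts
        return self

    def transform(self, X: ExpressionStudy) -> DecomposedExpression:
        study = X
        if self.residualize:
            study = residualize(study)
        if self.standardize:
            study = center_scale(study)
        self.processed_study_ = study
        if self.groups is not None:
            return decompose_grouped(study, self.groups)
        return decompose(study)
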