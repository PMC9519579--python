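"""Individual-level TWAS for simulation studies and AUC-based power evaluation.

Expression is imputed into an external genotype cohort as the dosage-weight
product, each gene-context-model imputation is tested against the phenotype
with a simple linear regression (the individual-level equivalent of the
summary-statistic association a TWAS pipeline reports), and gene discovery is
scored by the maximum absolute association statistic across contexts (and
models), summarized as the area under the ROC curve over causal versus
non-causal genes.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .models import ContentRegressor
from .baselines import ContextByContextRegressor, GroupLassoRegressor
from .simulate import (
    ExternalCohort,
    PhenotypeConfig,
    SimConfig,
    simulate_phenotype,
    simulate_study,
)

logger = logging.getLogger(__name__)

Z_CAP = 40.0  # numerical cap on reported |Z|; AUC is rank-based so this is inert

__all__ = ["impute_expression", "associate", "gene_auc", "run_twas_power_study"]


def impute_expression(weights: pd.DataFrame, dosages: pd.DataFrame) -> pd.DataFrame:
    """Impute expression for every (gene, context, model) in a weight table.

    ``dosages`` is an individuals x SNP-id DataFrame.  Any weight SNP absent
    from the cohort raises a KeyError naming the missing ids — weights are
    never silently subset.  Returns an individuals x (gene, context, model)
    DataFrame; constant imputations (e.g. all-zero weights) are kept but
    flagged with a warning, and excluded later by :func:`associate`.
    """
    missing = sorted(set(weights["snp"]) - set(dosages.columns))
    if missing:
        raise KeyError(f"weight SNPs absent from cohort genotypes: {missing}")
    cols, keys = [], []
    for key, grp in weights.groupby(["gene", "context", "model"], sort=False):
        imp = dosages[grp["snp"]].to_numpy(dtype=float) @ grp["weight"].to_numpy()
        if imp.std() == 0:
            logger.warning("constant imputation for %s", key)
        cols.append(imp)
        keys.append(key)
    return pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(dosages), 0)),
        index=dosages.index,
        columns=pd.MultiIndex.from_tuples(keys, names=["gene", "context", "model"]),
    )


def associate(imputed: pd.DataFrame, phenotype: np.ndarray) -> pd.DataFrame:
    """Association Z and p of each imputed column with the phenotype.

    Simple linear regression of the phenotype on the standardized imputation;
    the t statistic is reported as Z (|Z| capped at 40) with a two-sided normal
    p-value.  Constant imputations are excluded with a logged reason.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 individuals for association")
    X = imputed.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.info("excluding %d constant imputations from association", int((~keep).sum()))
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    ys = (y - y.mean()) / y.std()
    r = Xs.T @ ys / n
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    z = np.clip(t, -Z_CAP, Z_CAP)
    index = imputed.columns[keep]
    if isinstance(index, pd.MultiIndex) and index.nlevels == 3 and all(
        name is None for name in index.names
    ):
        index = index.set_names(["gene", "context", "model"])
    out = pd.DataFrame({"z": z, "p": 2 * stats.norm.sf(np.abs(z))}, index=index)
    return out.reset_index()


def gene_auc(ztable: pd.DataFrame, causal_genes) -> float:
    """AUC of gene discovery from the maximum |Z| per gene.

    ``ztable`` needs columns ``gene`` and ``z``; the score of a gene is the
    maximum of |Z| over its rows (contexts, and models when several are
    included).  The AUC is the Mann-Whitney statistic over causal versus
    non-causal genes; both classes must be present.
    """
    scores = ztable.assign(absz=lambda d: d["z"].abs()).groupby("gene")["absz"].max()
    labels = scores.index.isin(set(causal_genes))
    if labels.all() or not labels.any():
        raise ValueError("need both causal and non-causal genes to compute an AUC")
    return _auc(scores.to_numpy(), labels)


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def run_twas_power_study(
    sim_config: SimConfig,
    pheno_config: PhenotypeConfig,
    h2_settings=(0.1, 0.2, 0.4),
    methods=("content_full", "content_specific", "content_shared"),
    n_replicates: int = 100,
    p_forward: float = 0.1,
    fit_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """TWAS power simulation: mean gene-discovery AUC per method and setting.

    For every total expression heritability in ``h2_settings`` one study is
    simulated (per-gene shared proportion drawn Unif(0,1), every context
    eligible for specific effects) and the predictors are trained once; the
    ``n_replicates`` phenotype draws (fresh causal gene-context pairs each
    time) reuse the trained weights, mirroring a design where many phenotypes
    are generated over one expression panel.  Genes without any forwarded
    model (nominal LRT p >= ``p_forward``) score 0.  Returns a tidy DataFrame
    with columns setting, method, auc, se, n_replicates.
    """
    fit_params = dict(fit_params or {})
    need_content = any(m.startswith("content") for m in methods)
    records = []
    for setting in h2_settings:
        cfg = replace(
            sim_config,
            h2_shared=setting / 2,
            h2_specific=setting / 2,
            uniform_shared_proportion=True,
            frac_contexts_with_specific=1.0,
            seed=int(np.random.default_rng([seed, int(setting * 1000)]).integers(2**31)),
        )
        panel, truth, study = simulate_study(cfg)
        pre = _preprocess(study)
        J, C = cfg.n_genes, cfg.n_contexts
        cohort = ExternalCohort(panel.maf, pheno_config.external_cohort_size, seed=cfg.seed)

        # true genetic components in the external cohort (for the phenotype)
        comps = np.empty((pheno_config.external_cohort_size, J, C), dtype=np.float32)
        imputations = []  # per gene: (standardized imputation matrix, column metadata)
        for j in range(J):
            G_ext = cohort.genotypes(j).astype(float)
            comps[:, j] = cohort.genetic_components(truth, j).astype(np.float32)
            cols, meta = [], []
            G_train = panel.dosages(j)
            if need_content:
                fit = ContentRegressor(outer_cv=None, random_state=seed, **fit_params).fit(G_train, pre[j])
                _collect_content(fit, G_ext, p_forward, cols, meta)
            if "cbc" in methods:
                cbc = ContextByContextRegressor(outer_cv=None, random_state=seed, **fit_params).fit(G_train, pre[j])
                for ctx, f in cbc.context_fits_.items():
                    if f is not None and f.lrt_p < p_forward and not f.null_model:
                        cols.append(G_ext @ f.coef)
                        meta.append(("cbc", ctx))
            if "grouplasso" in methods:
                gl = GroupLassoRegressor(random_state=seed).fit(G_train, pre[j])
                for ctx in gl.context_ids_:
                    if gl.lrt_p_[ctx] < p_forward and np.any(gl.coef_[:, gl.context_ids_.index(ctx)] != 0):
                        cols.append(G_ext @ gl.coef_[:, gl.context_ids_.index(ctx)])
                        meta.append(("grouplasso", ctx))
            X = np.column_stack(cols) if cols else np.empty((G_ext.shape[0], 0))
            sd = X.std(axis=0)
            keep = sd > 0
            X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
            imputations.append((X.astype(np.float32), [m for m, k in zip(meta, keep) if k]))

        n = pheno_config.external_cohort_size
        Y = np.empty((n, n_replicates), dtype=np.float32)
        causal_sets = []
        for r in range(n_replicates):
            pcfg = replace(pheno_config, seed=int(np.random.default_rng([seed, 11, r]).integers(2**31)))
            res = simulate_phenotype(pcfg, truth, comps)
            y = res.phenotype
            Y[:, r] = (y - y.mean()) / y.std()
            causal_sets.append(set(res.causal_genes))

        # per-method per-gene per-replicate max-|Z| scores
        scores = {m: np.zeros((J, n_replicates)) for m in methods}
        for j, (X, meta) in enumerate(imputations):
            if X.shape[1] == 0:
                continue
            r_corr = (X.T.astype(np.float64) @ Y.astype(np.float64)) / n
            r_corr = np.clip(r_corr, -1 + 1e-15, 1 - 1e-15)
            absz = np.abs(np.clip(r_corr * np.sqrt((n - 2) / (1 - r_corr ** 2)), -Z_CAP, Z_CAP))
            tags = np.array([m for m, _ in meta])
            for m in methods:
                if m == "content_all":
                    mask = np.char.startswith(tags.astype(str), "content")
                else:
                    mask = tags == m
                if mask.any():
                    scores[m][j] = absz[mask].max(axis=0)

        labels = np.zeros((J, n_replicates), dtype=bool)
        for r, cs in enumerate(causal_sets):
            labels[list(cs), r] = True
        for m in methods:
            aucs = np.array([_auc(scores[m][:, r], labels[:, r]) for r in range(n_replicates)])
            records.append({
                "setting": setting, "method": m, "auc": float(aucs.mean()),
                "se": float(aucs.std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else np.nan,
                "n_replicates": n_replicates,
            })
    return pd.DataFrame.from_records(records)


def _preprocess(study) -> np.ndarray:
    """Residualize/center-scale a study and return the (J, I, C) array."""
    from .decompose import center_scale, residualize

    return center_scale(residualize(study)).expression


def _collect_content(fit: ContentRegressor, G_ext: np.ndarray, p_forward: float,
                     cols: list, meta: list) -> None:
    sh = fit.shared_fit_
    sh_ok = sh is not None and sh.lrt_p < p_forward and not sh.null_model
    if sh_ok:
        # the shared weight vector is identical across contexts, so one
        # imputation column represents every context's shared model
        cols.append(G_ext @ sh.coef)
        meta.append(("content_shared", "all"))
    for ctx in fit.context_ids_:
        sp = fit.specific_fits_.get(ctx)
        if sp is not None and sp.lrt_p < p_forward and not sp.null_model:
            cols.append(G_ext @ sp.coef)
            meta.append(("content_specific", ctx))
        fu = fit.full_fits_.get(ctx)
        if fu is not None and fu.lrt_p < p_forward and np.any(fu.coef != 0):
            cols.append(G_ext @ fu.coef)
            meta.append(("content_full", ctx))
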