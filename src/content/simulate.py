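"""Generative model for multi-context expression studies with known architecture.

Genotypes, sparse context-shared / context-specific genetic effects, expression
with equicorrelated intra-individual noise, and polygenic phenotypes built from
the true genetically regulated expression of selected gene-context pairs.  Every
draw is reproducible from a single integer seed.

The generative model, briefly: for each gene, cis-dosages are independent
binomial draws ``G_im ~ Bin(2, p_m)`` with ``p_m ~ Unif[0.05, 0.50]``.  A
Bernoulli(pi) mask selects causal SNPs; shared effects are
``beta_m ~ N(0, h2_shared / (M * pi))`` on that mask.  Context-specific effects
live (mostly) on the shared-causal SNPs with variance
``h2_specific / (lambda * M * pi)``; a Poisson(lambda) number of truly specific
eQTLs is additionally placed on SNPs with no shared effect.  Expression is
``E_c = G beta + G gamma_c (+ G beta_group) + eps_c`` where the intra-individual
noise vector across the C contexts is multivariate normal with variances
``1 - h2_shared - h2_specific(c)`` and equicorrelation rho.  Phenotypes are
``y = E delta + eps`` over the standardized true genetic expression of randomly
selected gene-context pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decompose import ExpressionStudy

__all__ = [
    "SimConfig",
    "PhenotypeConfig",
    "GenotypePanel",
    "SimTruth",
    "PhenotypeResult",
    "ExternalCohort",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_expression",
    "simulate_phenotype",
    "simulate_study",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """A requested simulation is infeasible (e.g. not enough non-causal SNPs)."""


@dataclass
class SimConfig:
    """Parameters of the expression-study generator.

    Defaults reproduce the GTEx-guided study conditions: 20 contexts, 500
    cis-SNPs per gene, per-context sample sizes uniform on 75..410 drawn from a
    common pool, shared/specific cis-heritabilities 0.3/0.1, causal probability
    pi = 0.05, Poisson rate 1 for truly context-specific eQTLs.
    """

    n_genes: int = 100
    n_contexts: int = 20
    n_snps_per_gene: int = 500
    sample_size_range: tuple[int, int] = (75, 410)
    h2_shared: float = 0.3
    h2_specific: float = 0.1
    causal_prob: float = 0.05
    frac_contexts_with_specific: float = 0.5
    truly_specific_rate: float = 1.0
    rho: float = 0.0
    #: draw each gene's shared proportion of total heritability from Unif(0,1)
    #: (total = h2_shared + h2_specific); used by the TWAS power simulations.
    uniform_shared_proportion: bool = False
    #: rescale effect sizes so the realized genetic variance of every component
    #: equals its target heritability exactly.  Default on: the stated h2 values
    #: are variance shares of expression.  When off, effect sizes keep the raw
    #: N(0, h2/(M*pi)) law, whose realized variance on unstandardized dosages is
    #: attenuated by the 2p(1-p) dosage variance.
    rescale_realized_h2: bool = True
    brain_subset: tuple[int, ...] | None = None
    h2_group: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_contexts, self.n_snps_per_gene) <= 0:
            raise ConfigurationError("dimensions must be positive")
        lo, hi = self.sample_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("sample_size_range must satisfy 0 < lo <= hi")
        h2g = self.h2_group if self.brain_subset else 0.0
        if not (0 <= self.h2_shared and 0 <= self.h2_specific and 0 <= h2g):
            raise ConfigurationError("heritabilities must be non-negative")
        if self.h2_shared + self.h2_specific + h2g >= 1:
            raise ConfigurationError("h2_shared + h2_specific (+ h2_group) must be < 1")
        if not 0 < self.causal_prob <= 1:
            raise ConfigurationError("causal_prob must be in (0, 1]")
        if not 0 <= self.rho < 1:
            raise ConfigurationError("rho must be in [0, 1)")
        if not 0 <= self.frac_contexts_with_specific <= 1:
            raise ConfigurationError("frac_contexts_with_specific must be in [0, 1]")
        if self.truly_specific_rate < 0:
            raise ConfigurationError("truly_specific_rate must be >= 0")
        if self.brain_subset is not None:
            bad = [c for c in self.brain_subset if not 0 <= c < self.n_contexts]
            if bad:
                raise ConfigurationError(f"brain_subset contexts out of range: {bad}")

    @property
    def pool_size(self) -> int:
        return self.sample_size_range[1]


@dataclass
class PhenotypeConfig:
    """Parameters of the TWAS phenotype generator."""

    n_causal_genes: int = 100
    contexts_per_gene: int = 3
    var_explained: float = 0.2
    external_cohort_size: int = 10000
    #: if True use the printed noise variance 1 - var_explained/n_pairs instead of
    #: targeting total phenotypic variance 1 (noise variance 1 - var_explained).
    literal_noise_variance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.var_explained < 1:
            raise ConfigurationError("var_explained must be in [0, 1)")
        if min(self.n_causal_genes, self.contexts_per_gene) <= 0:
            raise ConfigurationError("causal-pair counts must be positive")

    @property
    def n_pairs(self) -> int:
        return self.n_causal_genes * self.contexts_per_gene


@dataclass
class GenotypePanel:
    """Cis-genotypes for every gene over a common pool of individuals.

    ``genotypes[j]`` is the pool_size x M dosage matrix of gene j (entries in
    {0, 1, 2}); ``maf[j, m]`` is the allele frequency the m-th SNP was drawn at.
    """

    genotypes: np.ndarray  # (J, I, M) int8
    maf: np.ndarray  # (J, M)
    gene_ids: list[str]
    individual_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[2]

    def snp_ids(self, j: int) -> list[str]:
        return [f"{self.gene_ids[j]}_snp{m}" for m in range(self.n_snps)]

    def dosages(self, j: int) -> np.ndarray:
        return self.genotypes[j].astype(float)


@dataclass
class SimTruth:
    """True effect sizes and causal masks underlying a simulated study."""

    beta_shared: np.ndarray  # (J, M)
    beta_specific: np.ndarray  # (J, C, M)
    beta_group: np.ndarray | None  # (J, M) additional effects of brain-subset contexts
    group_contexts: tuple[int, ...] | None
    shared_causal: np.ndarray  # (J, M) bool, the Bernoulli(pi) masks
    specific_causal: np.ndarray  # (J, C, M) bool
    truly_specific: np.ndarray  # (J, C, M) bool, Poisson additions (disjoint from shared_causal)
    has_specific: np.ndarray  # (J, C) bool: context carries specific heritability
    h2_shared: np.ndarray  # (J,)
    h2_specific: np.ndarray  # (J,)

    def total_effects(self, j: int, c: int) -> np.ndarray:
        """True per-SNP effect on expression of gene j in context c."""
        b = self.beta_shared[j] + self.beta_specific[j, c]
        if self.beta_group is not None and self.group_contexts and c in self.group_contexts:
            b = b + self.beta_group[j]
        return b

    def genetic_component(self, G: np.ndarray, j: int, c: int, which: str = "total") -> np.ndarray:
        """True genetic expression component of gene j, context c for dosages G."""
        if which == "shared":
            b = self.beta_shared[j]
        elif which == "specific":
            b = self.beta_specific[j, c]
        elif which == "total":
            b = self.total_effects(j, c)
        else:
            raise ValueError(f"unknown component {which!r}")
        return np.asarray(G, dtype=float) @ b


@dataclass
class PhenotypeResult:
    phenotype: np.ndarray  # (n_external,)
    causal_pairs: list[tuple[int, int]]  # (gene index, context index)
    effects: np.ndarray  # delta, aligned with causal_pairs
    causal_genes: np.ndarray  # unique gene indices


def _rng(config_seed: int, stream: int, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng([config_seed, stream])


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw the per-gene cis-genotype panels.

    Loci are independent with MAF ~ Unif[0.05, 0.50] and dosages Bin(2, MAF);
    there is no LD and there are no rare variants.
    """
    rng = _rng(config.seed, 1, rng)
    J, I, M = config.n_genes, config.pool_size, config.n_snps_per_gene
    maf = rng.uniform(0.05, 0.50, size=(J, M))
    geno = rng.binomial(2, maf[:, None, :], size=(J, I, M)).astype(np.int8)
    return GenotypePanel(
        genotypes=geno,
        maf=maf,
        gene_ids=[f"gene{j}" for j in range(J)],
        individual_ids=[f"ind{i}" for i in range(I)],
    )


def simulate_effects(
    config: SimConfig,
    panel: GenotypePanel,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Draw sparse shared and specific effect sizes.

    Shared effects: Bernoulli(pi) causal mask, N(0, h2_shared/(M pi)) sizes.
    Specific effects live on the shared-causal SNPs (subsampled at rate
    min(1, lambda)) with variance h2_specific/(lambda M pi), for the configured
    fraction of contexts; those contexts additionally receive Poisson(lambda)
    truly specific eQTLs on SNPs without a shared effect, drawn from the same
    normal law.
    """
    rng = _rng(config.seed, 2, rng)
    J, C, M = config.n_genes, config.n_contexts, config.n_snps_per_gene
    pi, lam = config.causal_prob, config.truly_specific_rate

    h2_tot = config.h2_shared + config.h2_specific
    if config.uniform_shared_proportion:
        u = rng.uniform(0, 1, size=J)
        h2_sh, h2_sp = u * h2_tot, (1 - u) * h2_tot
    else:
        h2_sh = np.full(J, config.h2_shared)
        h2_sp = np.full(J, config.h2_specific)

    shared_causal = rng.random((J, M)) < pi
    beta_shared = rng.normal(0.0, 1.0, size=(J, M)) * shared_causal
    beta_shared *= np.sqrt(h2_sh / (M * pi))[:, None]

    n_spec_ctx = int(round(config.frac_contexts_with_specific * C))
    has_specific = np.zeros((J, C), dtype=bool)
    specific_causal = np.zeros((J, C, M), dtype=bool)
    truly_specific = np.zeros((J, C, M), dtype=bool)
    beta_specific = np.zeros((J, C, M))
    # per-SNP sd of specific effects; effective only when lambda > 0
    spec_sd = np.sqrt(h2_sp / (max(lam, 1.0) * M * pi)) if lam > 0 else np.zeros(J)

    for j in range(J):
        if n_spec_ctx == 0 or lam == 0:
            continue
        ctx = rng.choice(C, size=n_spec_ctx, replace=False)
        has_specific[j, ctx] = True
        shared_idx = np.flatnonzero(shared_causal[j])
        non_causal = np.flatnonzero(~shared_causal[j])
        for c in ctx:
            if lam >= 1:
                sub = shared_idx
            else:  # subsample the shared-causal SNPs at rate lambda
                sub = shared_idx[rng.random(shared_idx.size) < lam]
            specific_causal[j, c, sub] = True
            k = rng.poisson(lam)
            if k > non_causal.size:
                raise SimulationError(
                    f"gene {j}: {k} truly specific eQTLs requested but only "
                    f"{non_causal.size} non-causal SNPs available"
                )
            if k > 0:
                extra = rng.choice(non_causal, size=k, replace=False)
                specific_causal[j, c, extra] = True
                truly_specific[j, c, extra] = True
            mask = specific_causal[j, c]
            beta_specific[j, c, mask] = rng.normal(0.0, spec_sd[j], size=int(mask.sum()))

    beta_group: np.ndarray | None = None
    if config.brain_subset and config.h2_group > 0:
        grp_sd = np.sqrt(config.h2_group / (max(lam, 1.0) * M * pi))
        beta_group = np.zeros((J, M))
        for j in range(J):
            idx = np.flatnonzero(shared_causal[j])
            beta_group[j, idx] = rng.normal(0.0, grp_sd, size=idx.size)

    if config.rescale_realized_h2:
        for j in range(J):
            G = panel.genotypes[j].astype(float)
            var = np.var(G @ beta_shared[j])
            if var > 0 and h2_sh[j] > 0:
                beta_shared[j] *= np.sqrt(h2_sh[j] / var)
            for c in range(C):
                var = np.var(G @ beta_specific[j, c])
                if var > 0 and h2_sp[j] > 0:
                    beta_specific[j, c] *= np.sqrt(h2_sp[j] / var)
            if beta_group is not None:
                var = np.var(G @ beta_group[j])
                if var > 0:
                    beta_group[j] *= np.sqrt(config.h2_group / var)

    return SimTruth(
        beta_shared=beta_shared,
        beta_specific=beta_specific,
        beta_group=beta_group,
        group_contexts=config.brain_subset,
        shared_causal=shared_causal,
        specific_causal=specific_causal,
        truly_specific=truly_specific,
        has_specific=has_specific,
        h2_shared=h2_sh,
        h2_specific=h2_sp,
    )


def _noise_covariance(config: SimConfig, truth: SimTruth, j: int) -> np.ndarray:
    C = config.n_contexts
    h2g = config.h2_group if (config.brain_subset and config.h2_group > 0) else 0.0
    sigma2 = 1.0 - truth.h2_shared[j] - truth.h2_specific[j] * truth.has_specific[j]
    if h2g:
        grp = np.zeros(C)
        grp[list(config.brain_subset)] = h2g
        sigma2 = sigma2 - grp
    if np.any(sigma2 <= 0):
        raise SimulationError(f"gene {j}: non-positive residual variance")
    sd = np.sqrt(sigma2)
    cov = config.rho * np.outer(sd, sd)
    np.fill_diagonal(cov, sigma2)
    return cov


def simulate_expression(
    config: SimConfig,
    panel: GenotypePanel,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> ExpressionStudy:
    """Simulate the observed expression study.

    Expression is the sum of the true genetic components and an intra-individual
    noise vector that is equicorrelated (rho) across contexts with per-context
    variance 1 - h2_shared - h2_specific(c).  Each context observes a uniformly
    drawn number of individuals from the common pool, so individuals are not
    necessarily measured in every context; every individual is observed in at
    least one context.
    """
    rng = _rng(config.seed, 3, rng)
    J, I, C = config.n_genes, config.pool_size, config.n_contexts
    E = np.empty((J, I, C))
    for j in range(J):
        cov = _noise_covariance(config, truth, j)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rho checked at config
            raise SimulationError(f"gene {j}: noise covariance not positive definite") from exc
        eps = rng.standard_normal((I, C)) @ L.T
        G = panel.genotypes[j].astype(float)
        genetic = G @ (truth.beta_shared[j][:, None] + truth.beta_specific[j].T)
        if truth.beta_group is not None and config.brain_subset:
            grp = G @ truth.beta_group[j]
            genetic[:, list(config.brain_subset)] += grp[:, None]
        E[j] = genetic + eps

    lo, hi = config.sample_size_range
    observed = np.zeros((I, C), dtype=bool)
    for c in range(C):
        n_c = int(rng.integers(lo, hi + 1))
        observed[rng.choice(I, size=n_c, replace=False), c] = True
    # guarantee every pool individual is observed somewhere by swapping them in
    # for an individual that is observed elsewhere (keeps context sizes fixed)
    for i in np.flatnonzero(~observed.any(axis=1)):
        c = int(rng.integers(C))
        members = np.flatnonzero(observed[:, c])
        removable = members[observed[members].sum(axis=1) > 1]
        victim = rng.choice(removable if removable.size else members)
        observed[victim, c] = False
        observed[i, c] = True
    E[:, ~observed] = np.nan

    return ExpressionStudy(
        expression=E,
        gene_ids=list(panel.gene_ids),
        individual_ids=list(panel.individual_ids),
        context_ids=[f"context{c}" for c in range(C)],
    )


class ExternalCohort:
    """A large independent genotype cohort drawn at the panel's allele frequencies.

    Per-gene genotype matrices are generated lazily and deterministically so the
    full cohort never has to be held in memory at once.
    """

    def __init__(self, maf: np.ndarray, n_individuals: int, seed: int):
        self.maf = np.asarray(maf)
        self.n_individuals = int(n_individuals)
        self.seed = int(seed)

    def genotypes(self, j: int) -> np.ndarray:
        rng = np.random.default_rng([self.seed, 7, j])
        return rng.binomial(2, self.maf[j][None, :], size=(self.n_individuals, self.maf.shape[1])).astype(np.int8)

    def genetic_components(self, truth: SimTruth, j: int) -> np.ndarray:
        """True total genetic expression (n x C) of gene j in this cohort."""
        G = self.genotypes(j).astype(float)
        C = truth.beta_specific.shape[1]
        out = np.empty((self.n_individuals, C))
        for c in range(C):
            out[:, c] = truth.genetic_component(G, j, c, "total")
        return out


def simulate_phenotype(
    cfg: PhenotypeConfig,
    truth: SimTruth,
    components: np.ndarray,
    rng: np.random.Generator | None = None,
) -> PhenotypeResult:
    """Draw a phenotype from the genetic expression of random gene-context pairs.

    ``components`` is the (n_individuals, J, C) array of true total genetic
    expression in the external cohort.  ``n_causal_genes`` genes are selected
    among genes whose genetic components are non-degenerate, and
    ``contexts_per_gene`` contexts per gene; each selected pair's component is
    standardized and receives an effect delta ~ N(0, var_explained / n_pairs).
    Noise variance is 1 - var_explained so that Var(y) is approximately 1 (the
    printed alternative 1 - var_explained/n_pairs is available via
    ``literal_noise_variance``).
    """
    rng = _rng(cfg.seed, 4, rng)
    n, J, C = components.shape
    sds = components.std(axis=0)  # (J, C)
    eligible = np.flatnonzero((sds > 0).sum(axis=1) >= cfg.contexts_per_gene)
    if eligible.size < cfg.n_causal_genes:
        raise SimulationError(
            f"only {eligible.size} genes with >= {cfg.contexts_per_gene} heritable "
            f"contexts; {cfg.n_causal_genes} requested"
        )
    genes = rng.choice(eligible, size=cfg.n_causal_genes, replace=False)
    pairs: list[tuple[int, int]] = []
    cols = []
    for j in genes:
        ctx = rng.choice(np.flatnonzero(sds[j] > 0), size=cfg.contexts_per_gene, replace=False)
        for c in ctx:
            pairs.append((int(j), int(c)))
            x = components[:, j, c]
            cols.append((x - x.mean()) / x.std())
    Emat = np.column_stack(cols)
    k = cfg.n_pairs
    delta = rng.normal(0.0, np.sqrt(cfg.var_explained / k), size=k)
    noise_var = 1 - cfg.var_explained / k if cfg.literal_noise_variance else 1 - cfg.var_explained
    y = Emat @ delta + rng.normal(0.0, np.sqrt(noise_var), size=n)
    return PhenotypeResult(phenotype=y, causal_pairs=pairs, effects=delta, causal_genes=np.unique(genes))


def simulate_study(
    config: SimConfig,
) -> tuple[GenotypePanel, SimTruth, ExpressionStudy]:
    """Convenience wrapper: genotypes, effects and expression from one config."""
    panel = simulate_genotypes(config)
    truth = simulate_effects(config, panel)
    study = simulate_expression(config, panel, truth)
    return panel, truth, study
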