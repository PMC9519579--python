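"""Readers and writers for the tool's TSV tables, plus VCF genotype import.

All tables are tab-separated with fixed lowercase headers.  Round trips are
lossless for strings and integers and accurate to better than 1e-12 for
floats.  SNPs are identified by id string; genomic coordinates are not used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decompose import ExpressionStudy

__all__ = [
    "ParseError",
    "read_genotypes",
    "write_genotypes",
    "read_genotypes_vcf",
    "read_expression",
    "write_expression",
    "read_covariates",
    "read_truth",
    "write_truth",
    "read_weights",
    "write_weights",
    "read_summary",
    "write_summary",
    "read_phenotype",
    "write_phenotype",
]

_FLOAT_FMT = "%.17g"
MODEL_LABELS = {"shared", "specific", "full", "cbc", "grouplasso"}


class ParseError(ValueError):
    """A malformed input table."""


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # pandas messages carry the line number
        raise ParseError(f"{path}: {exc}") from exc


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing} (line 1)")


def write_genotypes(path, dosages: pd.DataFrame) -> None:
    """Individuals x SNPs dosage matrix; index column 'individual'."""
    dosages.to_csv(path, sep="\t", index_label="individual")


def read_genotypes(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col="individual")
    values = df.to_numpy()
    if not np.isin(values, [0, 1, 2]).all():
        raise ParseError(f"{path}: dosages must be 0, 1 or 2")
    return df.astype(np.int8)


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Dosage matrix from a diploid VCF (GT field; alt-allele count).

    Individuals with any missing genotype in the file are excluded.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        dose = np.full(len(samples), -1, dtype=np.int16)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            dose[i] = sum(1 for a in alleles if a > 0)
        rows.append(dose)
        ids.append(vid)
    mat = np.array(rows).T  # individuals x snps
    keep = (mat >= 0).all(axis=1)
    return pd.DataFrame(mat[keep], index=np.array(samples)[keep], columns=ids).astype(np.int8)


def write_expression(path, study: ExpressionStudy) -> None:
    """Long-format expression table: gene, context, individual, value."""
    J, I, C = study.expression.shape
    recs = []
    for j in range(J):
        for c in range(C):
            obs = np.flatnonzero(~np.isnan(study.expression[j, :, c]))
            for i in obs:
                recs.append((study.gene_ids[j], study.context_ids[c],
                             study.individual_ids[i], study.expression[j, i, c]))
    pd.DataFrame(recs, columns=["gene", "context", "individual", "value"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_expression(path) -> ExpressionStudy:
    df = _read_tsv(path)
    _require(df, ["gene", "context", "individual", "value"], path)
    genes = list(dict.fromkeys(df["gene"]))
    contexts = list(dict.fromkeys(df["context"]))
    individuals = list(dict.fromkeys(df["individual"]))
    gi = {g: k for k, g in enumerate(genes)}
    ci = {c: k for k, c in enumerate(contexts)}
    ii = {i: k for k, i in enumerate(individuals)}
    E = np.full((len(genes), len(individuals), len(contexts)), np.nan)
    E[df["gene"].map(gi), df["individual"].map(ii), df["context"].map(ci)] = df["value"]
    return ExpressionStudy(expression=E, gene_ids=genes,
                           individual_ids=individuals, context_ids=contexts)


def read_covariates(path) -> pd.DataFrame:
    """Individuals x covariates table indexed by individual id."""
    return _read_tsv(path, index_col="individual")


def write_truth(path, records: pd.DataFrame) -> None:
    """True effect table: gene, context ('shared' for shared effects), snp, effect."""
    _require(records, ["gene", "context", "snp", "effect"], path)
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_truth(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ["gene", "context", "snp", "effect"], path)
    return df


def write_weights(path, weights: pd.DataFrame) -> None:
    _require(weights, ["gene", "context", "model", "snp", "a1", "a2", "weight"], path)
    weights.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_weights(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ["gene", "context", "model", "snp", "a1", "a2", "weight"], path)
    unknown = set(df["model"]) - MODEL_LABELS
    if unknown:
        raise ParseError(f"{path}: unknown model labels {sorted(unknown)}")
    return df


def write_summary(path, summary: pd.DataFrame) -> None:
    _require(summary, ["gene", "context", "model", "cv_r2", "cv_adj_r2", "lrt_p", "n"], path)
    summary.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_summary(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ["gene", "context", "model", "cv_r2", "cv_adj_r2", "lrt_p", "n"], path)
    return df


def write_phenotype(path, phenotype: np.ndarray, individual_ids) -> None:
    pd.DataFrame({"individual": individual_ids, "phenotype": phenotype}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_phenotype(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ["individual", "phenotype"], path)
    return df
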