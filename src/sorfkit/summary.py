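"""Descriptive characterization of the peptide catalogue.

Start-codon usage, length distributions stratified by host-transcript
type, per-gene peptide counts, and associations between phenotype scores
and externally supplied per-ORF covariates (e.g. coding-potential or
conservation scores, which this package consumes but never computes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .orflib import DEFAULT_START_CODONS

HIT_CLASSES = ("pro_proliferative", "anti_proliferative")


def start_codon_usage(catalogue: pd.DataFrame) -> pd.Series:
    """Fraction of catalogue entries using each allowed start codon."""
    if catalogue.empty:
        raise ValueError("empty catalogue")
    frac = (
        catalogue["start_codon"]
        .value_counts(normalize=True)
        .reindex(DEFAULT_START_CODONS, fill_value=0.0)
    )
    frac.name = "fraction"
    return frac


def length_and_origin_summary(catalogue: pd.DataFrame) -> dict:
    """Peptide-length distributions by host type, per-gene counts, category mix.

    Host type is ``ncRNA`` for ``novel_nc`` entries and ``mRNA`` for
    CDS-relative categories (u/alt/d and annotated).
    """
    if catalogue.empty:
        raise ValueError("empty catalogue")
    df = catalogue.assign(
        peptide_length=catalogue["peptide"].str.len(),
        host_type=np.where(catalogue["category"] == "novel_nc", "ncRNA", "mRNA"),
    )
    length_by_host = (
        df.groupby("host_type")["peptide_length"]
        .agg(["count", "median", "mean", "min", "max"])
    )
    gene_col = "gene_name" if "gene_name" in df.columns else "gene_id"
    per_gene = df.groupby(gene_col)["peptide"].nunique().sort_values(ascending=False)
    per_gene.name = "n_peptides"
    category_fractions = df["category"].value_counts(normalize=True)
    category_fractions.name = "fraction"
    return {
        "length_by_host": length_by_host,
        "per_gene_counts": per_gene,
        "category_fractions": category_fractions,
    }


def covariate_association(
    phenotypes: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Associate |phenotype score| with per-ORF covariates.

    For each covariate column: Spearman rho against the absolute body
    score, and a two-sided rank-sum contrast of the covariate between hit
    (pro/anti-proliferative) and non-hit ORFs. Raw p-values are reported
    alongside Benjamini-Hochberg adjusted ones across the whole battery.
    """
    if "orf_id" not in covariates.columns:
        raise ValueError("covariates must carry an orf_id column")
    joined = phenotypes.merge(covariates, on="orf_id", how="inner")
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} ORFs shared between phenotypes and "
            f"covariates; need at least 3"
        )
    abs_score = joined["body_score"].abs()
    is_hit = joined["hit_class"].isin(HIT_CLASSES)
    cov_cols = [c for c in covariates.columns if c != "orf_id"]
    rows = []
    for col in cov_cols:
        vals = pd.to_numeric(joined[col], errors="raise")
        if not np.isfinite(vals).all():
            raise ValueError(f"covariate {col!r} contains non-finite values")
        rho, rho_p = stats.spearmanr(abs_score, vals)
        rows.append({"covariate": col, "test": "spearman_abs_score",
                     "statistic": float(rho), "p_value": float(rho_p)})
        hit_vals, non_vals = vals[is_hit], vals[~is_hit]
        if len(hit_vals) and len(non_vals):
            u, u_p = stats.mannwhitneyu(hit_vals, non_vals,
                                        alternative="two-sided")
            rows.append({"covariate": col, "test": "ranksum_hit_vs_nonhit",
                         "statistic": float(u), "p_value": float(u_p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
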