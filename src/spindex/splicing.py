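"""Exon-level splicing indexes and differential exon-usage testing.

The Splicing Index (SI) of exon *e* in sample *s* is

    SI(e, s) = exon RPKM(e, s) / gene RPKM(g(e), s)

computed on post-replacement abundances (exon floor: 1 read; gene floor:
10 reads).  Two filters precede the calculation: an exon is analysed only
if (1) its gene passed the Reliable Quantification Threshold (~50 reads in
at least one sample) and (2) the exon itself was detected (at least one
read) in at least one sample.  SI is reported NA in any sample where the
gene count falls below 50 reads, and every exon-level statistic is NA as
soon as one sample's SI is NA.

Between-genotype differences are tested per exon by one-way ANOVA on the
raw SI ratios plus a Tukey HSD contrast; with two groups the Tukey
adjusted p-value coincides with the ANOVA p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import anova_rows
from .matrix import AbundanceMatrix, CountMatrix, ExonCountMatrix

__all__ = [
    "filter_exons",
    "splicing_index",
    "exon_anova_tukey",
    "splicing_table",
    "gene_summary",
    "top_spliced_genes",
]


def filter_exons(
    exon_counts: ExonCountMatrix, reliable_genes, min_reads: int = 1
) -> pd.Index:
    """Exons of reliable genes with at least ``min_reads`` in >= 1 sample."""
    reliable = pd.Index(reliable_genes)
    gene_ok = exon_counts.gene_of.isin(reliable)
    exon_ok = (exon_counts.counts >= min_reads).any(axis=1)
    return exon_counts.counts.index[gene_ok & exon_ok]


def splicing_index(
    exon_rpkm: AbundanceMatrix,
    gene_rpkm: AbundanceMatrix,
    gene_counts: CountMatrix,
    gene_of: pd.Series,
    k_quant: int = 50,
) -> pd.DataFrame:
    """Per-exon, per-sample SI table; NaN where the gene count is < ``k_quant``.

    ``exon_rpkm`` must already be floored at the 1-read equivalent and
    ``gene_rpkm`` at the 10-read equivalent, so the denominator is strictly
    positive.
    """
    exons = exon_rpkm.values.index
    genes = gene_of.loc[exons]
    gvals = gene_rpkm.values.loc[genes].to_numpy()
    if (gvals <= 0).any():
        raise ValueError("gene RPKM must be positive after replacement")
    si = exon_rpkm.values.to_numpy() / gvals
    gcounts = gene_counts.counts.loc[genes].to_numpy()
    si = np.where(gcounts < k_quant, np.nan, si)
    out = pd.DataFrame(si, index=exons, columns=exon_rpkm.values.columns)
    out.index.name = "exon_id"
    return out


def exon_anova_tukey(si: pd.DataFrame, design) -> pd.DataFrame:
    """Per-exon ANOVA across genotypes on SI values, with Tukey HSD.

    Returns columns ``F``, ``p``, ``tukey_diff`` (group A - group B mean
    SI), ``tukey_p`` and ``significant`` (p < 0.05).  Every statistic is
    NaN for an exon whose SI is NA in one or more samples; ``significant``
    is pandas NA there.
    """
    a = si[design.samples_a].to_numpy()
    b = si[design.samples_b].to_numpy()
    has_na = np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1)
    f = np.full(len(si), np.nan)
    p = np.full(len(si), np.nan)
    diff = np.full(len(si), np.nan)
    ok = ~has_na
    if ok.any():
        f[ok], p[ok] = anova_rows(a[ok], b[ok])
        diff[ok] = a[ok].mean(axis=1) - b[ok].mean(axis=1)
    out = pd.DataFrame(
        {
            "F": f,
            "p": p,
            "tukey_diff": diff,
            # For exactly two groups the studentized-range (Tukey) adjusted
            # p equals the one-way ANOVA p: q = sqrt(2)|t| and F = t^2.
            "tukey_p": p,
        },
        index=si.index,
    )
    sig = pd.array(out["p"] < 0.05, dtype="boolean")
    sig[has_na] = pd.NA
    out["significant"] = sig
    return out


def splicing_table(si: pd.DataFrame, stats: pd.DataFrame, gene_of: pd.Series) -> pd.DataFrame:
    """Join SI values and statistics into the full per-exon results table."""
    out = si.copy()
    out.insert(0, "gene_id", gene_of.loc[si.index].to_numpy())
    for col in ("p", "tukey_p", "significant"):
        out[col] = stats[col]
    return out


def gene_summary(stats: pd.DataFrame, gene_of: pd.Series) -> pd.DataFrame:
    """Per-gene roll-up: exon count, significant-exon count, minimum exon p."""
    df = pd.DataFrame(
        {
            "gene_id": gene_of.loc[stats.index].to_numpy(),
            "p": stats["p"],
            "significant": stats["significant"].fillna(False).astype(bool),
        }
    )
    grp = df.groupby("gene_id", sort=True)
    out = pd.DataFrame(
        {
            "n_exons": grp.size(),
            "n_significant": grp["significant"].sum().astype(int),
            "min_p": grp["p"].min(),
        }
    )
    out.index.name = "gene_id"
    return out


def top_spliced_genes(summary: pd.DataFrame, min_exons: int = 10, n_top: int | None = None) -> pd.DataFrame:
    """Genes with >= ``min_exons`` analysed exons, ranked by minimum exon p."""
    sel = summary[summary["n_exons"] >= min_exons].sort_values("min_p")
    return sel.head(n_top) if n_top is not None else sel
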