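"""Two-group differential expression and Venn detection classification.

The differential-expression call is a one-way fixed-effects ANOVA between
the two genotype groups (df = 1, n_A + n_B - 2), run by default on the
log2 of post-replacement RPKM, combined with the group-mean fold change
A/B.  Fold change is reported as NA when the mean raw count of *both*
groups falls below the Reliable Detection Threshold (50 reads/gene), so
ratios of unreliable abundances are never interpreted.

The Venn stage classifies each gene by detection pattern across the six
samples: detected in every sample of both groups ("common"), detected in
all of one group but missed in at least one sample of the other
("unique_A"/"unique_B"), or missed in at least one sample of each group
("excluded" from the diagram).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import AbundanceMatrix, CountMatrix, Design

__all__ = [
    "anova_two_group",
    "anova_rows",
    "fold_change",
    "fold_change_table",
    "call_de",
    "classify_venn",
    "de_table",
    "DECalls",
]

K_DET = 10
VENN_CLASSES = ("unique_A", "unique_B", "common", "excluded")


def anova_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way two-group ANOVA: F and p for each row.

    ``a`` is (m, n_A) and ``b`` is (m, n_B).  Degenerate rows with zero
    between- and within-group sum of squares get F = 0, p = 1; rows with
    zero within-group variance but distinct means get F = inf, p = 0.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 observations per group")
    grand = (a.sum(axis=1) + b.sum(axis=1)) / (n_a + n_b)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ssb = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    ssw = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df_w = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / df_w)
    # ssw == 0: identical within-group values. Equal means -> no signal.
    both_zero = (ssw == 0) & np.isclose(ssb, 0.0)
    f = np.where(both_zero, 0.0, f)
    f = np.where((ssw == 0) & ~both_zero, np.inf, f)
    p = stats.f.sf(f, 1, df_w)
    p = np.where(both_zero, 1.0, p)
    return f, p


def anova_two_group(values_a, values_b) -> tuple[float, float]:
    """One-way ANOVA for a single gene; returns (F, p) with df = (1, n-2)."""
    f, p = anova_rows(np.asarray(values_a)[None, :], np.asarray(values_b)[None, :])
    return float(f[0]), float(p[0])


def fold_change(
    rpkm_a, rpkm_b, count_mean_a: float, count_mean_b: float, k_quant: int = 50
) -> float:
    """Group-mean RPKM ratio A/B, or NaN when both count means are < k_quant."""
    if count_mean_a < k_quant and count_mean_b < k_quant:
        return float("nan")
    return float(np.mean(rpkm_a) / np.mean(rpkm_b))


def fold_change_table(
    abundance: AbundanceMatrix, counts: CountMatrix, k_quant: int = 50
) -> pd.DataFrame:
    """Vectorised fold changes for every gene in ``abundance``.

    Returns columns ``mean_A``, ``mean_B`` (post-replacement RPKM group
    means) and ``fold_change`` (NaN encodes NA).
    """
    design = counts.design
    vals = abundance.values
    mean_a = vals[design.samples_a].mean(axis=1)
    mean_b = vals[design.samples_b].mean(axis=1)
    cm = counts.counts.loc[vals.index]
    cmean_a = cm[design.samples_a].mean(axis=1)
    cmean_b = cm[design.samples_b].mean(axis=1)
    fc = mean_a / mean_b
    fc[(cmean_a < k_quant) & (cmean_b < k_quant)] = np.nan
    return pd.DataFrame(
        {"mean_A": mean_a, "mean_B": mean_b, "fold_change": fc}
    )


def de_table(
    abundance: AbundanceMatrix,
    counts: CountMatrix,
    k_quant: int = 50,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-gene DE records: group means, fold change (NA allowed), F, p.

    The ANOVA runs on log2(post-replacement RPKM) by default; the
    replacement floor guarantees strictly positive values.  A
    Benjamini-Hochberg column (``p_adj_info``) is attached for information
    only; the DE call itself uses the raw p-value.
    """
    design = counts.design
    vals = abundance.values
    mat = np.log2(vals.to_numpy()) if log_scale else vals.to_numpy()
    idx_a = [vals.columns.get_loc(s) for s in design.samples_a]
    idx_b = [vals.columns.get_loc(s) for s in design.samples_b]
    f, p = anova_rows(mat[:, idx_a], mat[:, idx_b])
    out = fold_change_table(abundance, counts, k_quant=k_quant)
    out["F"] = f
    out["p"] = p
    from statsmodels.stats.multitest import multipletests

    out["p_adj_info"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
    fc = out["fold_change"]
    out["direction"] = np.select(
        [fc > 1, fc < 1], ["up", "down"], default="none"
    )
    out.loc[fc.isna(), "direction"] = "none"
    out.index.name = "gene_id"
    return out


@dataclass(frozen=True)
class DECalls:
    de: pd.Index          # p < p_cut
    fc_filtered: pd.Index  # additionally |fold change| beyond fc_cut
    up: pd.Index
    down: pd.Index


def call_de(records: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 1.5) -> DECalls:
    """Apply the significance and fold-change cuts to a DE table.

    ``de``: strict p < p_cut.  ``fc_filtered``: also fold change >= fc_cut
    or <= 1/fc_cut (two-sided); NA fold changes never pass.  ``up``/``down``
    split the fc-filtered set by direction.
    """
    sig = records["p"] < p_cut
    fc = records["fold_change"]
    passes_fc = (fc >= fc_cut) | (fc <= 1.0 / fc_cut)
    passes_fc &= fc.notna()
    de = records.index[sig]
    fc_filtered = records.index[sig & passes_fc]
    up = records.index[sig & passes_fc & (fc > 1)]
    down = records.index[sig & passes_fc & (fc < 1)]
    return DECalls(de=de, fc_filtered=fc_filtered, up=up, down=down)


def classify_venn(counts: CountMatrix, k_det: int = K_DET) -> pd.Series:
    """Detection-pattern class per gene: unique_A / unique_B / common / excluded.

    A gene is *detected* in a sample iff its count exceeds ``k_det`` (the
    default 10 means the cell escaped the gene-level replacement floor).
    The four classes are disjoint and exhaustive.
    """
    design = counts.design
    det = counts.counts > k_det
    all_a = det[design.samples_a].all(axis=1)
    all_b = det[design.samples_b].all(axis=1)
    cls = np.select(
        [all_a & all_b, all_a & ~all_b, ~all_a & all_b],
        ["common", "unique_A", "unique_B"],
        default="excluded",
    )
    out = pd.Series(cls, index=counts.counts.index, name="venn_class")
    out.index.name = "gene_id"
    return out
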