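"""Synthetic two-group exon-level RNA-seq counts with known ground truth.

Emulates the study design the pipeline targets: two genotype groups of
three biological replicates, ~19,000 multi-exon genes, negative-binomial
read counts with library-size variation, a planted fraction of
differentially expressed (DE) genes, a planted fraction of genes with
differential exon usage (DEU), and a planted fraction of genes whose
expected maximum count sits near the 50-read reliability threshold so the
boundary rules are exercised on both sides.

Counts for exon *e* in sample *s* are drawn

    NB(mean = baseline_e * group_effect * exon_multiplier * lib_factor_s,
       variance = mu + mu^2 * dispersion)

and gene-level counts are defined downstream as the sum of exon counts,
which makes the length-weighted splicing-index identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gtf
from .matrix import Design, ExonCountMatrix

__all__ = ["SimParams", "SimTruth", "simulate_dataset", "write_fixture"]

GROUP_A = "mutant"
GROUP_B = "control"


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults emulate the target study's conditions."""

    n_genes: int = 19_000
    exons_per_gene: tuple[int, int] = (4, 12)
    exon_length_bases: tuple[int, int] = (80, 300)
    n_per_group: int = 3
    mean_expression_log2: tuple[float, float] = (5.0, 2.0)  # (mu, sigma)
    nb_dispersion: float = 0.05
    library_size_factors: tuple[float, ...] | None = None  # None: draw U(0.8, 1.2)
    frac_de: float = 0.05
    de_log2fc: tuple[float, float] = (0.585, 3.0)  # |log2 FC| range, 1.5x to 8x
    frac_deu: float = 0.02
    deu_exon_multiplier: float = 3.0
    frac_boundary: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 1:
            raise ParameterError("n_genes and n_per_group must be positive")
        for name in ("exons_per_gene", "exon_length_bases", "de_log2fc"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name}: min {lo} > max {hi}")
        if self.exons_per_gene[0] < 1 or self.exon_length_bases[0] < 1:
            raise ParameterError("exon counts and lengths must be >= 1")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be positive")
        for name in ("frac_de", "frac_deu", "frac_boundary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.frac_de + self.frac_deu > 1.0:
            raise ParameterError("frac_de + frac_deu must not exceed 1")
        if self.deu_exon_multiplier <= 0 or self.deu_exon_multiplier == 1.0:
            raise ParameterError("deu_exon_multiplier must be positive and != 1")
        if self.library_size_factors is not None:
            lf = np.asarray(self.library_size_factors, dtype=float)
            if lf.ndim != 1 or len(lf) != 2 * self.n_per_group:
                raise ParameterError(
                    "library_size_factors must list one factor per sample"
                )
            if (lf <= 0).any():
                raise ParameterError("library_size_factors must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Planted-effect bookkeeping: one row per gene and one per exon."""

    genes: pd.DataFrame  # gene_id, is_de, log2fc, is_deu, deu_exons, deu_multiplier, is_boundary
    exons: pd.DataFrame  # exon_id, gene_id, expected_baseline_count


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, variance = mu + mu^2 * dispersion) via size r = 1/dispersion."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    nz = mean > 0
    out[nz] = rng.negative_binomial(r, p[nz])
    return out


def simulate_dataset(
    params: SimParams,
) -> tuple[dict[str, GeneModel], ExonCountMatrix, SimTruth]:
    """Draw one complete dataset; identical params + seed give identical output."""
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    n_samples = 2 * params.n_per_group
    samples = [f"{GROUP_A}_{i + 1}" for i in range(params.n_per_group)] + [
        f"{GROUP_B}_{i + 1}" for i in range(params.n_per_group)
    ]
    group = pd.Series(
        [GROUP_A] * params.n_per_group + [GROUP_B] * params.n_per_group,
        index=samples,
        name="group",
    )
    design = Design(groups=group, group_a=GROUP_A, group_b=GROUP_B)
    if params.library_size_factors is None:
        lib_factors = rng.uniform(0.8, 1.2, size=n_samples)
    else:
        lib_factors = np.asarray(params.library_size_factors, dtype=float)

    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    n_exons = rng.integers(
        params.exons_per_gene[0], params.exons_per_gene[1] + 1, size=n
    )
    mu, sigma = params.mean_expression_log2
    base_mean = np.exp2(rng.normal(mu, sigma, size=n))

    # Planted roles are disjoint: a gene is DE, DEU or boundary, never two.
    n_de = int(round(params.frac_de * n))
    n_deu = int(round(params.frac_deu * n))
    n_boundary = int(round(params.frac_boundary * n))
    if n_de + n_deu + n_boundary > n:
        raise ParameterError("planted fractions exceed the gene count")
    perm = rng.permutation(n)
    de_idx = perm[:n_de]
    deu_idx = perm[n_de : n_de + n_deu]
    boundary_idx = perm[n_de + n_deu : n_de + n_deu + n_boundary]

    # Boundary genes: rescale so the expected max per-sample gene count
    # lands in [30, 70], straddling the 50-read reliability rule.
    target = rng.uniform(30.0, 70.0, size=n_boundary)
    base_mean[boundary_idx] = target / lib_factors.max()

    log2fc = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc[de_idx] = sign * rng.uniform(
        params.de_log2fc[0], params.de_log2fc[1], size=n_de
    )

    models: dict[str, GeneModel] = {}
    exon_ids: list[str] = []
    exon_gene: list[str] = []
    exon_base_mean: list[np.ndarray] = []
    exon_mult_a: list[np.ndarray] = []  # group-A-only exon multipliers (DEU)
    deu_exons_per_gene: dict[str, list[str]] = {}
    is_deu = np.zeros(n, dtype=bool)
    is_deu[deu_idx] = True
    pos = 1
    for i in range(n):
        k = int(n_exons[i])
        lengths = rng.integers(
            params.exon_length_bases[0], params.exon_length_bases[1] + 1, size=k
        )
        exons = []
        ids = []
        for j in range(k):
            eid = f"{gene_ids[i]}.E{j + 1}"
            exons.append((eid, pos, pos + int(lengths[j]) - 1))
            ids.append(eid)
            pos += int(lengths[j]) + 100  # gap keeps exons disjoint
        models[gene_ids[i]] = GeneModel(gene_ids[i], "chrS", tuple(exons))
        share = lengths / lengths.sum()
        exon_ids.extend(ids)
        exon_gene.extend([gene_ids[i]] * k)
        exon_base_mean.append(base_mean[i] * share)
        mult = np.ones(k)
        if is_deu[i] and k >= 2:
            j_aff = int(rng.integers(k))
            mult[j_aff] = params.deu_exon_multiplier
            deu_exons_per_gene[gene_ids[i]] = [ids[j_aff]]
        exon_mult_a.append(mult)

    exon_base = np.concatenate(exon_base_mean)
    mult_a = np.concatenate(exon_mult_a)
    gene_of = pd.Series(exon_gene, index=pd.Index(exon_ids, name="exon_id"), name="gene_id")

    gene_fc_a = np.exp2(log2fc)  # applied to group A only
    fc_per_exon = pd.Series(gene_fc_a, index=gene_ids).loc[exon_gene].to_numpy()

    counts = np.empty((len(exon_ids), n_samples), dtype=np.int64)
    for s in range(n_samples):
        in_a = group.iloc[s] == GROUP_A
        mean_s = exon_base * lib_factors[s]
        if in_a:
            mean_s = mean_s * fc_per_exon * mult_a
        counts[:, s] = _nb_draws(rng, mean_s, params.nb_dispersion)

    matrix = ExonCountMatrix(
        counts=pd.DataFrame(counts, index=gene_of.index, columns=samples),
        gene_of=gene_of,
        design=design,
    )
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    is_boundary = np.zeros(n, dtype=bool)
    is_boundary[boundary_idx] = True
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": is_de,
            "log2fc": log2fc,
            "is_deu": is_deu,
            "deu_exons": [
                ",".join(deu_exons_per_gene.get(g, [])) for g in gene_ids
            ],
            "deu_multiplier": np.where(is_deu, params.deu_exon_multiplier, 1.0),
            "is_boundary": is_boundary,
        }
    ).set_index("gene_id")
    truth_exons = pd.DataFrame(
        {
            "gene_id": gene_of.to_numpy(),
            "expected_baseline_count": exon_base,
        },
        index=gene_of.index,
    )
    return models, matrix, SimTruth(genes=truth_genes, exons=truth_exons)


def write_fixture(
    dataset: tuple[dict[str, GeneModel], ExonCountMatrix, SimTruth], out_dir
) -> dict[str, Path]:
    """Write exon counts, sample sheet, GTF and truth tables as UTF-8 TSV/GTF.

    The files round-trip losslessly through :mod:`spindex.io` readers.
    """
    models, matrix, truth = dataset
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "exon_counts": out / "exon_counts.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "gtf": out / "annotation.gtf",
        "truth_genes": out / "truth_genes.tsv",
        "truth_exons": out / "truth_exons.tsv",
    }
    table = matrix.counts.copy()
    table.insert(0, "gene_id", matrix.gene_of.to_numpy())
    table.to_csv(paths["exon_counts"], sep="\t", index=True, index_label="exon_id")
    sheet = matrix.design.groups.rename("group").to_frame()
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=True, index_label="sample_id")
    write_gtf(models, paths["gtf"])
    truth.genes.to_csv(paths["truth_genes"], sep="\t")
    truth.exons.to_csv(paths["truth_exons"], sep="\t", index_label="exon_id")
    return paths
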