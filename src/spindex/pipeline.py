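"""End-to-end pipeline: quantify -> DE (+ Venn) -> cluster -> splicing -> ORA.

`run_pipeline` reads the exon-count / sample-sheet / GTF (/ GMT) inputs
named in a :class:`PipelineConfig`, runs every stage with the configured
thresholds, writes all result tables plus a run manifest, and returns the
in-memory result bundle.  Deterministic given inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, annotation, cluster, diffexpr, enrichment, io, quantify, splicing
from .matrix import CountMatrix, ExonCountMatrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_stages"]

log = logging.getLogger("spindex")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for one pipeline run.

    Every printed cut-off of the analysis lives here: the ~50-read
    reliability threshold, the 10-read gene / 1-read exon replacement
    floors, the Venn detection threshold, and the p < 0.05 /
    fold-change > 1.5 calling rules.
    """

    exon_counts: str | Path = ""
    sample_sheet: str | Path = ""
    gtf: str | Path = ""
    gmt: str | Path | None = None
    out_dir: str | Path = "spindex_out"
    k_quant: int = 50
    k_floor_gene: int = 10
    k_floor_exon: int = 1
    k_det: int = 10
    p_cut: float = 0.05
    fc_cut: float = 1.5
    de_log_scale: bool = True
    group_a: str | None = None
    group_b: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_quant", "k_floor_gene", "k_floor_exon", "k_det"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.p_cut <= 1:
            raise ValueError("p_cut must lie in (0, 1]")
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")


@dataclass
class PipelineResult:
    gene_counts: CountMatrix
    reliable_genes: pd.Index
    gene_abundance: object
    de_records: pd.DataFrame
    de_calls: diffexpr.DECalls
    venn: pd.Series
    cluster_result: cluster.ClusterResult | None
    splicing_records: pd.DataFrame | None
    splicing_summary: pd.DataFrame | None
    enrichment_records: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_stages(
    exon_matrix: ExonCountMatrix,
    models,
    config: PipelineConfig,
    gene_sets: enrichment.GeneSetCollection | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs (no file I/O)."""
    cfg = config

    # ---- quantify ----
    gene_counts = exon_matrix.gene_counts()
    library_sizes = gene_counts.library_sizes()
    reliable = quantify.filter_reliable(gene_counts, k_quant=cfg.k_quant)
    log.info("reliable genes: %d / %d", len(reliable), len(gene_counts.counts))
    reliable_counts = CountMatrix(
        gene_counts.counts.loc[reliable], gene_counts.design
    )
    gene_ab = quantify.apply_replacement(
        reliable_counts, models, k_floor=cfg.k_floor_gene, library_sizes=library_sizes
    )

    # ---- diffexpr + venn ----
    de_records = diffexpr.de_table(
        gene_ab, reliable_counts, k_quant=cfg.k_quant, log_scale=cfg.de_log_scale
    )
    calls = diffexpr.call_de(de_records, p_cut=cfg.p_cut, fc_cut=cfg.fc_cut)
    venn = diffexpr.classify_venn(reliable_counts, k_det=cfg.k_det)
    de_records = de_records.join(venn)
    log.info(
        "DE genes: %d (p<%g); %d pass the fold-change filter (%d up / %d down)",
        len(calls.de), cfg.p_cut, len(calls.fc_filtered), len(calls.up), len(calls.down),
    )

    # ---- cluster ----
    cluster_result = None
    if len(calls.de) >= 2:
        prepped = cluster.preprocess(gene_ab.values, calls.de)
        cluster_result = cluster.cluster_matrix(prepped)

    # ---- splicing ----
    splicing_records = splicing_summary = None
    retained_exons = splicing.filter_exons(exon_matrix, reliable)
    if len(retained_exons):
        exon_sub = ExonCountMatrix(
            counts=exon_matrix.counts.loc[retained_exons],
            gene_of=exon_matrix.gene_of.loc[retained_exons],
            design=exon_matrix.design,
        )
        exon_ab = quantify.apply_replacement(
            exon_sub, models, k_floor=cfg.k_floor_exon, library_sizes=library_sizes
        )
        si = splicing.splicing_index(
            exon_ab, gene_ab, reliable_counts, exon_sub.gene_of, k_quant=cfg.k_quant
        )
        stats = splicing.exon_anova_tukey(si, exon_matrix.design)
        splicing_records = splicing.splicing_table(si, stats, exon_sub.gene_of)
        splicing_summary = splicing.gene_summary(stats, exon_sub.gene_of)

    # ---- enrichment ----
    enrichment_records = None
    if gene_sets is not None:
        focus = enrichment.select_focus(
            de_records, gene_sets.universe, p_cut=cfg.p_cut, fc_cut=cfg.fc_cut
        )
        enrichment_records = enrichment.ora(focus, gene_sets)

    n_sig_exons = (
        int(splicing_records["significant"].fillna(False).sum())
        if splicing_records is not None
        else 0
    )
    manifest = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(cfg).items()
        },
        "n_genes_annotated": int(len(gene_counts.counts)),
        "n_genes_reliable": int(len(reliable)),
        "n_de": int(len(calls.de)),
        "n_fc_filtered": int(len(calls.fc_filtered)),
        "n_up": int(len(calls.up)),
        "n_down": int(len(calls.down)),
        "venn": {k: int(v) for k, v in venn.value_counts().items()},
        "n_exons_total": int(len(exon_matrix.counts)),
        "n_exons_retained": int(len(retained_exons)),
        "n_exons_significant": n_sig_exons,
        "n_enriched_sets": (
            int(enrichment_records["enriched"].sum())
            if enrichment_records is not None
            else None
        ),
    }
    return PipelineResult(
        gene_counts=gene_counts,
        reliable_genes=reliable,
        gene_abundance=gene_ab,
        de_records=de_records,
        de_calls=calls,
        venn=venn,
        cluster_result=cluster_result,
        splicing_records=splicing_records,
        splicing_summary=splicing_summary,
        enrichment_records=enrichment_records,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-file pipeline run: read inputs, run stages, write outputs."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = io.read_sample_sheet(cfg.sample_sheet, cfg.group_a, cfg.group_b)
    exon_matrix = io.read_counts(cfg.exon_counts, design)
    if not isinstance(exon_matrix, ExonCountMatrix):
        raise StageError("read", ValueError("exon count file must carry a gene_id column"))
    models = annotation.read_gtf(cfg.gtf)

    gene_sets = None
    if cfg.gmt:
        gene_counts = exon_matrix.gene_counts()
        reliable = quantify.filter_reliable(gene_counts, k_quant=cfg.k_quant)
        gene_sets = enrichment.read_gmt(cfg.gmt, universe=reliable)

    result = run_stages(exon_matrix, models, cfg, gene_sets=gene_sets)

    io.write_table(result.de_records, out / "de_results.tsv", index_label="gene_id")
    io.write_table(result.venn.to_frame(), out / "venn.tsv", index_label="gene_id")
    if result.cluster_result is not None:
        cluster.write_cdt(result.cluster_result, out / "clustered")
        io.write_table(
            result.cluster_result.ordered, out / "clustered_matrix.tsv",
            index_label="gene_id",
        )
    if result.splicing_records is not None:
        io.write_table(
            result.splicing_records, out / "splicing_results.tsv", index_label="exon_id"
        )
        io.write_table(
            result.splicing_summary, out / "splicing_gene_summary.tsv",
            index_label="gene_id",
        )
    if result.enrichment_records is not None:
        io.write_table(
            result.enrichment_records, out / "enrichment.tsv", index_label="set_id"
        )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
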