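"""RPKM quantification with reliability thresholds and replacement floors.

RPKM (reads per kilobase of feature per million mapped reads) for a feature
of length ``L`` bases with ``c`` reads in a library of ``N`` reads is

    RPKM = c * 1e9 / (L * N)

Three threshold rules shape the downstream analysis:

* **Reliable Quantification Threshold** (default 50 reads): a gene is kept
  for analysis only if it reaches at least ``k_quant`` reads in one or more
  samples; below that, technical replicates would not reproduce its RPKM.
* **Replacement floor** (default 10 reads per gene, 1 read per exon): RPKM
  values whose count is at or below ``k_floor`` are replaced by the
  across-sample average of the RPKM equivalent of ``k_floor`` reads, so
  fold changes cannot blow up on near-zero denominators.
* Library size here is the per-sample column sum of gene-level counts,
  the normalisation basis shared by gene- and exon-level RPKM.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationError, GeneModel
from .matrix import AbundanceMatrix, CountMatrix, ExonCountMatrix

__all__ = [
    "rpkm",
    "rpkm_equivalent",
    "filter_reliable",
    "apply_replacement",
    "K_QUANT",
    "K_FLOOR_GENE",
    "K_FLOOR_EXON",
]

K_QUANT = 50
K_FLOOR_GENE = 10
K_FLOOR_EXON = 1


def rpkm(count, length, library_size):
    """RPKM = count * 1e9 / (length * library_size); vectorised.

    Raises ``ValueError`` on non-positive length or library size.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (length <= 0).any():
        raise ValueError("feature length must be positive")
    if (library_size <= 0).any():
        raise ValueError("library size must be positive")
    if (count < 0).any():
        raise ValueError("count must be non-negative")
    out = count * 1e9 / (length * library_size)
    return float(out) if out.ndim == 0 else out


def rpkm_equivalent(k, length, library_size):
    """The RPKM a feature of ``length`` would have at exactly ``k`` reads."""
    return rpkm(k, length, library_size)


def filter_reliable(counts: CountMatrix, k_quant: int = K_QUANT) -> pd.Index:
    """Entities reaching at least ``k_quant`` reads in one or more samples.

    Returns the retained entity index; the complement is the set of
    "unquantified" entities.  Monotone: adding reads never drops an entity.
    """
    keep = (counts.counts >= k_quant).any(axis=1)
    return counts.counts.index[keep]


def _entity_lengths(
    counts: CountMatrix | ExonCountMatrix, models: Mapping[str, GeneModel]
) -> pd.Series:
    if isinstance(counts, ExonCountMatrix):
        lengths = {}
        for exon_id, gene_id in counts.gene_of.items():
            try:
                gm = models[gene_id]
            except KeyError:
                raise AnnotationError(
                    f"gene {gene_id!r} (of exon {exon_id!r}) missing from annotation"
                ) from None
            lengths[exon_id] = gm.exon_length(exon_id)
        return pd.Series(lengths, dtype=float).loc[counts.counts.index]
    lengths = {}
    for gene_id in counts.counts.index:
        try:
            lengths[gene_id] = models[gene_id].gene_length
        except KeyError:
            raise AnnotationError(
                f"gene {gene_id!r} missing from annotation"
            ) from None
    return pd.Series(lengths, dtype=float).loc[counts.counts.index]


def apply_replacement(
    counts: CountMatrix | ExonCountMatrix,
    models: Mapping[str, GeneModel],
    k_floor: int = K_FLOOR_GENE,
    library_sizes: pd.Series | None = None,
) -> AbundanceMatrix:
    """Compute RPKM and replace low-count cells by the floor value.

    For entity ``g`` the floor is the mean over samples of the RPKM
    equivalent of ``k_floor`` reads; cells with count <= ``k_floor`` get
    that value and a ``floored`` flag, all others the raw RPKM.

    ``library_sizes`` defaults to this matrix's own column sums; pass the
    gene-level library sizes explicitly when flooring exon counts so both
    levels share one normalisation basis per sample.  Idempotent by
    construction: floored cells re-floor to the same value.
    """
    frame = counts.counts
    if library_sizes is None:
        library_sizes = frame.sum(axis=0)
    library_sizes = library_sizes.loc[frame.columns].astype(float)
    lengths = _entity_lengths(counts, models)

    raw = (
        frame.to_numpy(dtype=float)
        * 1e9
        / (lengths.to_numpy()[:, None] * library_sizes.to_numpy()[None, :])
    )
    # floor(g): mean over samples of rpkm_equivalent(k_floor, L_g, N_s)
    floor_per_sample = (
        float(k_floor) * 1e9 / (lengths.to_numpy()[:, None] * library_sizes.to_numpy()[None, :])
    )
    floors = floor_per_sample.mean(axis=1)

    low = frame.to_numpy() <= k_floor
    values = np.where(low, floors[:, None], raw)
    return AbundanceMatrix(
        values=pd.DataFrame(values, index=frame.index, columns=frame.columns),
        floored=pd.DataFrame(low, index=frame.index, columns=frame.columns),
        k_floor=k_floor,
        lengths=lengths,
        library_sizes=library_sizes,
    )
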