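"""Gene models: exon intervals and the kilobase denominators of RPKM.

Coordinates follow the GTF dialect: 1-based, inclusive on both ends, so an
exon spanning ``start..end`` has length ``end - start + 1`` bases.  A gene's
length is the length of the *union* of its exon intervals, which equals the
sum of exon lengths when exons are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["GeneModel", "read_gtf", "write_gtf"]


class AnnotationError(KeyError):
    """Raised when an entity is missing from, or malformed in, the annotation."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as a set of exon intervals on one chromosome.

    Parameters
    ----------
    gene_id : str
    chrom : str
    exons : tuple of (exon_id, start, end)
        1-based inclusive intervals.
    """

    gene_id: str
    chrom: str
    exons: tuple[tuple[str, int, int], ...]
    _exon_lengths: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id!r} has no exons")
        lengths: dict[str, int] = {}
        for exon_id, start, end in self.exons:
            if end < start or start < 1:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exon {exon_id!r} has invalid "
                    f"interval [{start}, {end}]"
                )
            lengths[exon_id] = end - start + 1
        object.__setattr__(self, "_exon_lengths", lengths)

    def exon_length(self, exon_id: str) -> int:
        try:
            return self._exon_lengths[exon_id]
        except KeyError:
            raise AnnotationError(
                f"exon {exon_id!r} not in gene {self.gene_id!r}"
            ) from None

    @property
    def exon_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.exons)

    @property
    def gene_length(self) -> int:
        """Length in bases of the union of exon intervals."""
        ivs = sorted((start, end) for _, start, end in self.exons)
        total = 0
        cur_start, cur_end = ivs[0]
        for start, end in ivs[1:]:
            if start > cur_end + 1:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        total += cur_end - cur_start + 1
        return total


def _require_gffutils():
    import gffutils

    return gffutils


def read_gtf(path) -> dict[str, GeneModel]:
    """Read exon features from a GTF file into :class:`GeneModel` objects.

    Only ``exon`` features are used; the attributes ``gene_id`` and
    ``exon_id`` are required and every other attribute is ignored.
    """
    gffutils = _require_gffutils()
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    by_gene: dict[str, list[tuple[str, int, int]]] = {}
    chroms: dict[str, str] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            gene_id = feat.attributes["gene_id"][0]
            exon_id = feat.attributes["exon_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"exon feature at {feat.seqid}:{feat.start}-{feat.end} lacks "
                f"required attribute {exc}"
            ) from None
        by_gene.setdefault(gene_id, []).append((exon_id, feat.start, feat.end))
        chroms.setdefault(gene_id, feat.seqid)
    return {
        gid: GeneModel(gid, chroms[gid], tuple(exons))
        for gid, exons in by_gene.items()
    }


def write_gtf(models: Iterable[GeneModel] | Mapping[str, GeneModel], path) -> None:
    """Write exon features (one line per exon) in GTF format."""
    if isinstance(models, Mapping):
        models = models.values()
    with open(path, "w", encoding="utf-8") as fh:
        for gm in models:
            for exon_id, start, end in gm.exons:
                attrs = f'gene_id "{gm.gene_id}"; exon_id "{exon_id}";'
                fh.write(
                    f"{gm.chrom}\tspindex\texon\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                )
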