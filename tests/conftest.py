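import numpy as np
import pandas as pd
import pytest

from spindex.annotation import GeneModel
from spindex.matrix import CountMatrix, Design, ExonCountMatrix

A, B = "mutant", "control"


def two_group_design(n_per_group: int = 3) -> Design:
    samples = [f"{A}_{i+1}" for i in range(n_per_group)] + [
        f"{B}_{i+1}" for i in range(n_per_group)
    ]
    groups = pd.Series([A] * n_per_group + [B] * n_per_group, index=samples)
    return Design(groups=groups, group_a=A, group_b=B)


@pytest.fixture
def design() -> Design:
    return two_group_design(3)


def gene_counts(rows: dict[str, list[int]], design: Design) -> CountMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=design.samples)
    df.index.name = "gene_id"
    return CountMatrix(counts=df.astype(np.int64), design=design)


def exon_counts(
    rows: dict[str, list[int]], gene_of: dict[str, str], design: Design
) -> ExonCountMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=design.samples)
    df.index.name = "exon_id"
    return ExonCountMatrix(
        counts=df.astype(np.int64),
        gene_of=pd.Series(gene_of, name="gene_id"),
        design=design,
    )


def single_exon_models(ids, length: int = 1000) -> dict[str, GeneModel]:
    return {
        g: GeneModel(g, "chr1", ((f"{g}.E1", 1, length),)) for g in ids
    }
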