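"""Hierarchically cluster differentially expressed genes, Cluster-3.0 style.

log2 RPKM rows are median-centred, similarity is centred (Pearson)
correlation, and merging uses average linkage; both genes and samples are
clustered and written as TreeView .cdt/.gtr/.atr files.
"""

import tempfile
from pathlib import Path

from spindex import SimParams, simulate_dataset
from spindex.cluster import cluster_matrix, preprocess, write_cdt
from spindex.pipeline import PipelineConfig, run_stages

models, matrix, _ = simulate_dataset(
    SimParams(n_genes=800, frac_de=0.08, de_log2fc=(1.5, 2.5), seed=3)
)
result = run_stages(matrix, models, PipelineConfig())

prepped = preprocess(result.gene_abundance.values, result.de_calls.de)
clustered = cluster_matrix(prepped)
print(f"clustered {len(prepped)} DE genes x {prepped.shape[1]} samples")
print(f"gene tree merges: {len(clustered.gene_tree.merges)} (always n-1)")
print("sample order after clustering:", [prepped.columns[j] for j in clustered.sample_order])
# replicates of the same genotype should sit together in the sample tree
first_merge = clustered.sample_tree.merges[0]
print(
    f"first sample merge joins columns {first_merge.left} and {first_merge.right} "
    f"at similarity {first_merge.similarity:.3f}"
)
with tempfile.TemporaryDirectory() as d:
    paths = write_cdt(clustered, Path(d) / "heatmap")
    print("TreeView files written:", ", ".join(Path(p).name for p in paths.values()))
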