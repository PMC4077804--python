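import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spindex.annotation import GeneModel
from spindex.matrix import CountMatrix
from spindex.quantify import apply_replacement, filter_reliable
from spindex.splicing import (
    exon_anova_tukey,
    filter_exons,
    gene_summary,
    splicing_index,
    top_spliced_genes,
)

from conftest import exon_counts, gene_counts, single_exon_models


@pytest.fixture
def libs(design):
    return pd.Series(1_000_000, index=design.samples, dtype=float)


class TestFilterExons:
    def test_rules(self, design):
        em = exon_counts(
            {
                "keep.E1": [1, 0, 0, 0, 0, 0],
                "zero.E1": [0, 0, 0, 0, 0, 0],
                "orph.E1": [90, 90, 90, 90, 90, 90],
            },
            {"keep.E1": "keep", "zero.E1": "keep", "orph.E1": "unreliable"},
            design,
        )
        kept = filter_exons(em, ["keep"])
        assert "keep.E1" in kept          # one read in one sample suffices
        assert "zero.E1" not in kept      # never detected
        assert "orph.E1" not in kept      # gene below reliability threshold


def _two_exon_setup(design, counts_e1, counts_e2, exon_len=500):
    gene = GeneModel(
        "g", "chr1", (("g.E1", 1, exon_len), ("g.E2", 1000, 1000 + exon_len - 1))
    )
    em = exon_counts(
        {"g.E1": counts_e1, "g.E2": counts_e2},
        {"g.E1": "g", "g.E2": "g"},
        design,
    )
    gene_cm = em.gene_counts()
    return gene, em, gene_cm


class TestSplicingIndex:
    def test_single_exon_gene_has_si_one(self, design, libs):
        models = single_exon_models(["g"], length=800)
        em = exon_counts({"g.E1": [200] * 6}, {"g.E1": "g"}, design)
        gene_cm = em.gene_counts()
        exon_ab = apply_replacement(em, models, k_floor=1, library_sizes=libs)
        gene_ab = apply_replacement(gene_cm, models, k_floor=10, library_sizes=libs)
        si = splicing_index(exon_ab, gene_ab, gene_cm, em.gene_of)
        np.testing.assert_allclose(si.loc["g.E1"], 1.0)

    def test_hand_computed_two_exon_gene(self, design, libs):
        # equal-length exons, counts 30 and 90 -> gene count 120; exon RPKM
        # shares are 1/4 and 3/4 of twice the gene RPKM -> SI 0.5 and 1.5
        gene, em, gene_cm = _two_exon_setup(design, [30] * 6, [90] * 6)
        models = {"g": gene}
        exon_ab = apply_replacement(em, models, k_floor=1, library_sizes=libs)
        gene_ab = apply_replacement(gene_cm, models, k_floor=10, library_sizes=libs)
        si = splicing_index(exon_ab, gene_ab, gene_cm, em.gene_of)
        np.testing.assert_allclose(si.loc["g.E1"], 0.5)
        np.testing.assert_allclose(si.loc["g.E2"], 1.5)

    def test_na_where_gene_count_below_50(self, design, libs):
        gene, em, gene_cm = _two_exon_setup(
            design, [30, 30, 30, 24, 30, 30], [90, 90, 90, 25, 90, 90]
        )
        models = {"g": gene}
        exon_ab = apply_replacement(em, models, k_floor=1, library_sizes=libs)
        gene_ab = apply_replacement(gene_cm, models, k_floor=10, library_sizes=libs)
        si = splicing_index(exon_ab, gene_ab, gene_cm, em.gene_of)
        bad_sample = design.samples[3]  # gene count 49 there
        assert si[bad_sample].isna().all()
        assert si.drop(columns=bad_sample).notna().all().all()

    def test_length_weighted_si_sums_to_one(self, design, libs):
        # disjoint exons, no floored or NA cells: sum_e SI * len_e / gene_len = 1
        rng = np.random.default_rng(4)
        lengths = [300, 150, 450]
        gene = GeneModel(
            "g",
            "chr1",
            tuple(
                (f"g.E{i+1}", start, start + L - 1)
                for i, (start, L) in enumerate(zip([1, 1000, 2000], lengths))
            ),
        )
        counts = rng.integers(40, 400, size=(3, 6))
        em = exon_counts(
            {f"g.E{i+1}": counts[i].tolist() for i in range(3)},
            {f"g.E{i+1}": "g" for i in range(3)},
            design,
        )
        gene_cm = em.gene_counts()
        exon_ab = apply_replacement(em, {"g": gene}, k_floor=1, library_sizes=libs)
        gene_ab = apply_replacement(gene_cm, {"g": gene}, k_floor=10, library_sizes=libs)
        si = splicing_index(exon_ab, gene_ab, gene_cm, em.gene_of)
        weights = np.array(lengths) / gene.gene_length
        total = (si.to_numpy() * weights[:, None]).sum(axis=0)
        np.testing.assert_allclose(total, 1.0, rtol=1e-10)

    def test_si_invariant_to_library_scaling(self, design, libs):
        gene, em, gene_cm = _two_exon_setup(design, [60] * 6, [80] * 6)
        models = {"g": gene}

        def si_with(libsizes):
            exon_ab = apply_replacement(em, models, k_floor=0, library_sizes=libsizes)
            gene_ab = apply_replacement(gene_cm, models, k_floor=0, library_sizes=libsizes)
            return splicing_index(exon_ab, gene_ab, gene_cm, em.gene_of)

        pd.testing.assert_frame_equal(si_with(libs), si_with(libs * 7.0))


class TestExonAnovaTukey:
    def test_na_sample_propagates_to_all_statistics(self, design):
        si = pd.DataFrame(
            [[1.0, 1.1, 0.9, np.nan, 1.0, 1.0], [1.0, 1.1, 0.9, 0.5, 0.6, 0.4]],
            index=["e_na", "e_ok"],
            columns=design.samples,
        )
        out = exon_anova_tukey(si, design)
        assert np.isnan(out.loc["e_na", "p"])
        assert out.loc["e_na", "significant"] is pd.NA
        assert out.loc["e_ok", "p"] < 0.05
        assert bool(out.loc["e_ok", "significant"])

    def test_identical_groups(self, design):
        si = pd.DataFrame(
            [[1.0, 1.2, 0.8, 1.0, 1.2, 0.8]], index=["e"], columns=design.samples
        )
        out = exon_anova_tukey(si, design)
        assert out.loc["e", "F"] == 0.0
        assert out.loc["e", "p"] == 1.0
        assert not out.loc["e", "significant"]

    def test_tukey_p_equals_anova_p_for_two_groups(self, design):
        rng = np.random.default_rng(8)
        si = pd.DataFrame(
            rng.uniform(0.2, 2.0, size=(20, 6)), columns=design.samples
        )
        out = exon_anova_tukey(si, design)
        for i in range(20):
            ref = stats.tukey_hsd(
                si.iloc[i][design.samples_a].to_numpy(),
                si.iloc[i][design.samples_b].to_numpy(),
            )
            assert out["tukey_p"].iloc[i] == pytest.approx(
                ref.pvalue[0, 1], abs=1e-8
            )


class TestGeneSummary:
    def test_rollup_and_top_ranking(self, design):
        stats_df = pd.DataFrame(
            {
                "p": [0.01, 0.2, np.nan, 0.001],
                "significant": pd.array([True, False, pd.NA, True], dtype="boolean"),
            },
            index=["a.E1", "a.E2", "a.E3", "b.E1"],
        )
        gene_of = pd.Series(
            {"a.E1": "a", "a.E2": "a", "a.E3": "a", "b.E1": "b"}
        )
        summary = gene_summary(stats_df, gene_of)
        assert summary.loc["a", "n_exons"] == 3
        assert summary.loc["a", "n_significant"] == 1
        assert summary.loc["a", "min_p"] == pytest.approx(0.01)
        top = top_spliced_genes(summary, min_exons=3)
        assert top.index.tolist() == ["a"]
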