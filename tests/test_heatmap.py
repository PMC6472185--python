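"""Z-scoring, hierarchical clustering and the four comparison layouts."""

import numpy as np
import pandas as pd
import pytest

from nctools.exceptions import ValidationError
from nctools.filtering import FilterSpec
from nctools.heatmap import (
    build_heatmap,
    export_heatmap,
    hcluster,
    order_samples,
    zscore_rows,
)
from nctools.matrix import ExpressionMatrix
from nctools.normalize import normalize_cartridge
from nctools.simulate import PlantedClusters, SimulationSpec, simulate_cartridge

from helpers import naive_average_linkage, scipy_merge_sequence


def as_matrix(values: np.ndarray, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=samples or [f"s{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(
        values=df,
        code_class=pd.Series("Endogenous", index=df.index, name="code_class"),
        stage="normalized",
    )


class TestZscore:
    def test_simple_row(self):
        z = zscore_rows(as_matrix(np.array([[1.0, 2.0, 3.0]])))
        assert np.allclose(z.values.to_numpy(), [[-1.0, 0.0, 1.0]])
        assert z.stage == "zscored"

    def test_constant_row_becomes_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_rows(as_matrix(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])))
        assert np.allclose(z.values.iloc[0], 0.0)

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValidationError):
            zscore_rows(as_matrix(np.array([[1.0], [2.0]])))

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(21)
        z = zscore_rows(as_matrix(rng.uniform(1.0, 500.0, (40, 9)))).values.to_numpy()
        assert np.abs(z.mean(axis=1)).max() <= 1e-9
        assert np.abs(z.std(axis=1, ddof=1) - 1.0).max() <= 1e-9

    def test_zscore_commutes_with_permutation(self):
        rng = np.random.default_rng(22)
        matrix = as_matrix(rng.uniform(1.0, 100.0, (6, 5)))
        rows = rng.permutation(6)
        cols = rng.permutation(5)
        z_then_permute = zscore_rows(matrix).values.iloc[rows, cols]
        permuted = ExpressionMatrix(
            values=matrix.values.iloc[rows, cols],
            code_class=matrix.code_class.iloc[rows],
            stage="normalized",
        )
        assert np.allclose(z_then_permute, zscore_rows(permuted).values)


class TestHcluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        values = np.array([[1.0, 1.0], [9.0, 9.0], [1.0, 1.0], [30.0, -4.0]])
        dend = hcluster(pd.DataFrame(values, index=list("abcd")))
        first = dend.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 2}
        assert first[2] == 0.0

    def test_two_items_single_merge_input_leaf_order(self):
        dend = hcluster(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["x", "y"]))
        assert dend.merges.shape == (1, 4)
        assert dend.leaf_order == [0, 1]

    @pytest.mark.parametrize("n_items", [5, 6, 7, 8])
    def test_matches_naive_agglomeration_oracle(self, n_items):
        rng = np.random.default_rng(100 + n_items)
        points = rng.normal(0.0, 1.0, (n_items, 4))
        dend = hcluster(pd.DataFrame(points))
        got = scipy_merge_sequence(dend.merges, n_items)
        expected = naive_average_linkage(points)
        for (set_a, h_a), (set_b, h_b) in zip(got, expected):
            assert set_a == set_b
            assert h_a == pytest.approx(h_b, abs=1e-9)

    def test_permutation_equivariant_partitions(self):
        rng = np.random.default_rng(23)
        points = rng.normal(0.0, 1.0, (8, 3))
        perm = rng.permutation(8)
        base = hcluster(pd.DataFrame(points)).cut(3)
        permuted = hcluster(pd.DataFrame(points[perm])).cut(3)
        # same partition: co-membership must be identical under the permutation
        for i in range(8):
            for j in range(8):
                assert (base[perm[i]] == base[perm[j]]) == (permuted[i] == permuted[j])

    def test_single_item_is_an_error(self):
        with pytest.raises(ValidationError):
            hcluster(pd.DataFrame([[1.0, 2.0]], index=["only"]))


def meta_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "sample_order"])


class TestOrderSamples:
    def test_type_i_orders_one_patient_chronologically(self):
        meta = meta_frame(
            [("t3", "P1", 3), ("t1", "P1", 1), ("t4", "P1", 4), ("t2", "P1", 2)]
        )
        assert order_samples(meta, "I") == ["t1", "t2", "t3", "t4"]

    def test_type_i_rejects_multiple_patients(self):
        meta = meta_frame([("a", "P1", 1), ("b", "P2", 1)])
        with pytest.raises(ValidationError, match="single patient"):
            order_samples(meta, "I")

    def test_type_ii_takes_first_sample_per_patient(self):
        meta = meta_frame(
            [("a1", "P1", 1), ("a2", "P1", 2), ("b1", "P2", 1),
             ("b2", "P2", 2), ("c1", "P3", 1)]
        )
        assert order_samples(meta, "II") == ["a1", "b1", "c1"]

    def test_type_iii_takes_second_sample_per_patient(self):
        meta = meta_frame(
            [("a1", "P1", 1), ("a2", "P1", 2), ("b1", "P2", 1), ("b2", "P2", 2)]
        )
        assert order_samples(meta, "III") == ["a2", "b2"]

    def test_type_iii_names_the_patient_missing_a_second_sample(self):
        meta = meta_frame([("a1", "P1", 1), ("a2", "P1", 2), ("b1", "P2", 1)])
        with pytest.raises(ValidationError, match="P2"):
            order_samples(meta, "III")

    def test_type_iv_groups_first_then_second_samples(self):
        meta = meta_frame(
            [("a1", "P1", 1), ("a2", "P1", 2), ("b1", "P2", 1), ("b2", "P2", 2)]
        )
        assert order_samples(meta, "IV") == ["a1", "b1", "a2", "b2"]


class TestBuildHeatmap:
    def test_type_i_four_samples_top_30_genes(self):
        patients = tuple(("P1", i + 1) for i in range(4))
        cartridge, _ = simulate_cartridge(
            SimulationSpec(
                n_lanes=4, n_endogenous=60, n_housekeeping=8, patients=patients, seed=31
            )
        )
        result = normalize_cartridge(cartridge)
        hm = build_heatmap(
            result.matrix,
            filter_spec=FilterSpec("count", 30),
            analysis_type="I",
            sample_meta=cartridge.sample_meta(),
        )
        assert hm.zmatrix.shape == (30, 4)
        assert hm.sample_dendrogram is None  # type layouts keep their order
        assert hm.sample_order == [0, 1, 2, 3]

    def test_free_mode_passthrough_clusters_both_axes(self):
        rng = np.random.default_rng(32)
        matrix = as_matrix(rng.uniform(5.0, 400.0, (12, 5)))
        hm = build_heatmap(matrix)
        assert hm.zmatrix.shape == (12, 5)
        assert hm.sample_dendrogram is not None
        assert sorted(hm.gene_order) == list(range(12))

    def test_planted_gene_blocks_are_the_top_split(self):
        cartridge, truth = simulate_cartridge(
            SimulationSpec(
                n_lanes=8,
                n_endogenous=24,
                n_housekeeping=6,
                endo_noise_sd=0.1,
                planted_clusters=PlantedClusters(block_size=8, amplitude=3.0),
                seed=33,
            )
        )
        result = normalize_cartridge(cartridge)
        endo = result.matrix.of_class("Endogenous")
        block_genes = list(truth.cluster_blocks[0]) + list(truth.cluster_blocks[1])
        hm = build_heatmap(endo.subset_genes(block_genes))
        labels = hm.gene_dendrogram.cut(2)
        first = set(labels[: len(truth.cluster_blocks[0])])
        second = set(labels[len(truth.cluster_blocks[0]):])
        assert first.isdisjoint(second)  # top split == planted partition

    def test_export_writes_all_artifacts(self, tmp_path):
        rng = np.random.default_rng(34)
        hm = build_heatmap(as_matrix(rng.uniform(5.0, 50.0, (6, 4))))
        export_heatmap(hm, tmp_path)
        for name in (
            "heatmap_zmatrix.tsv",
            "heatmap_gene_order.txt",
            "heatmap_sample_order.txt",
            "heatmap_genes.nwk",
            "heatmap_samples.nwk",
        ):
            assert (tmp_path / name).exists()
        newick = (tmp_path / "heatmap_genes.nwk").read_text()
        assert newick.strip().endswith(";") and newick.count("(") == 5
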