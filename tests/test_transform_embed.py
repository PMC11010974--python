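"""Scaling, merging, PCA initialization and t-SNE contract tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import NearestNeighbors

from hspcmap.channels import GROUP_COL, MARKERS, PATIENT_COL, TSNE1, TSNE2
from hspcmap.errors import (
    ConfigError,
    DegenerateInputError,
    MetadataError,
    ParameterError,
)
from hspcmap.transform_embed import (
    EmbedParams,
    biexponential_transform,
    merge_cohort,
    pca_initialize,
    scale_expression,
    split_groups,
    tsne_embed,
)


def _scaled_table(pid: str, group: str, n: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, len(MARKERS))), columns=list(MARKERS))
    df[PATIENT_COL] = pid
    df[GROUP_COL] = group
    return df


class TestBiexponentialTransform:
    def test_zero_maps_to_zero(self):
        assert biexponential_transform(0.0) == 0.0

    def test_odd_symmetry(self):
        x = np.linspace(-1e6, 1e6, 101)
        f = biexponential_transform(x, 150.0)
        np.testing.assert_allclose(f, -biexponential_transform(-x, 150.0))

    def test_strictly_monotonic(self):
        x = np.linspace(-1e5, 1e5, 10_001)
        assert (np.diff(biexponential_transform(x, 150.0)) > 0).all()

    def test_log_regime_decade_spacing(self):
        c = 150.0
        gap = biexponential_transform(1e6 * c, c) - biexponential_transform(1e5 * c, c)
        assert abs(gap - np.log(10)) < 1e-3

    def test_linear_near_zero(self):
        c = 150.0
        assert biexponential_transform(1e-3, c) == pytest.approx(1e-3 / c, rel=1e-6)

    def test_invalid_cofactor_rejected(self):
        with pytest.raises(ConfigError, match="cofactor"):
            biexponential_transform(1.0, cofactor=0.0)


class TestMergeCohort:
    def test_row_counts_add_up(self):
        merged = merge_cohort(
            [_scaled_table("a", "CR", 100), _scaled_table("b", "AD", 100, seed=1)]
        )
        assert len(merged) == 200

    def test_split_by_patient_roundtrip(self):
        t1 = _scaled_table("a", "CR", 80)
        t2 = _scaled_table("b", "AD", 50, seed=1)
        merged = merge_cohort([t1, t2])
        back = merged.loc[merged[PATIENT_COL] == "a", list(MARKERS)].reset_index(drop=True)
        pd.testing.assert_frame_equal(back, t1[list(MARKERS)])

    def test_capped_totals(self):
        from hspcmap.pregating import cap_cells

        sizes = [1500, 700, 129]
        tables = []
        for i, n in enumerate(sizes):
            t = cap_cells(_scaled_table(f"p{i}", "CR" if i else "AD", n, seed=i), 1000, seed=i)
            tables.append(t)
        merged = merge_cohort(tables)
        assert len(merged) == sum(min(n, 1000) for n in sizes)

    def test_duplicate_patient_across_groups_rejected(self):
        with pytest.raises(MetadataError, match="more than one group"):
            merge_cohort(
                [_scaled_table("a", "CR", 10), _scaled_table("a", "AD", 10, seed=1)]
            )

    def test_scale_expression_keeps_annotations(self):
        raw = pd.DataFrame(
            {m: np.abs(np.random.default_rng(0).normal(1000, 100, 20)) for m in MARKERS}
        )
        raw["FSC-A"] = 1.0  # non-marker channels are dropped
        raw[PATIENT_COL] = "p"
        raw[GROUP_COL] = "CR"
        scaled = scale_expression(raw, 150.0)
        assert list(scaled.columns) == [*MARKERS, PATIENT_COL, GROUP_COL]
        np.testing.assert_allclose(
            scaled["CD34"], np.arcsinh(raw["CD34"] / 150.0)
        )


class TestPcaInitialize:
    def test_component_count_capped_at_features(self):
        X = np.random.default_rng(0).normal(size=(200, 5))
        proj, init = pca_initialize(X, pca_dims=50)
        assert proj.shape == (200, 5)
        assert init.shape == (200, 2)

    def test_variance_only_axis_dominates_first_component(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(0, 10, 500), rng.normal(0, 0.01, 500)])
        proj, _ = pca_initialize(X, pca_dims=2)
        np.testing.assert_allclose(
            np.abs(np.corrcoef(proj[:, 0], X[:, 0])[0, 1]), 1.0, atol=1e-3
        )

    def test_explained_variance_non_increasing(self):
        X = np.random.default_rng(2).normal(size=(300, 5)) * [5, 4, 3, 2, 1]
        proj, _ = pca_initialize(X, pca_dims=5)
        variances = proj.var(axis=0)
        assert (np.diff(variances) <= 1e-12).all()

    def test_init_scaled_to_1e4(self):
        X = np.random.default_rng(3).normal(size=(400, 5))
        _, init = pca_initialize(X, pca_dims=5)
        assert init[:, 0].std() == pytest.approx(1e-4, rel=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError, match="constant"):
            pca_initialize(np.ones((50, 5)), pca_dims=5)


def _two_cluster_matrix(n_per: int = 300, sep: float = 50.0) -> pd.DataFrame:
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, size=(n_per, len(MARKERS)))
    b = rng.normal(sep, 1, size=(n_per, len(MARKERS)))
    df = pd.DataFrame(np.vstack([a, b]), columns=list(MARKERS))
    df[PATIENT_COL] = ["p1"] * n_per + ["p2"] * n_per
    df[GROUP_COL] = ["CR"] * n_per + ["AD"] * n_per
    df["_cluster"] = [0] * n_per + [1] * n_per
    return df


def _knn_purity(coords: np.ndarray, labels: np.ndarray, k: int = 10) -> float:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    same = labels[idx[:, 1:]] == labels[:, None]
    return float(same.mean())


class TestTsneEmbed:
    def test_same_seed_identical_coordinates(self):
        matrix = _two_cluster_matrix(120, sep=5.0).drop(columns=["_cluster"])
        params = EmbedParams(perplexity=20, n_iter=300, seed=3)
        a = tsne_embed(matrix, params)
        b = tsne_embed(matrix, params)
        np.testing.assert_array_equal(a[TSNE1].to_numpy(), b[TSNE1].to_numpy())
        np.testing.assert_array_equal(a[TSNE2].to_numpy(), b[TSNE2].to_numpy())

    def test_output_shape_appends_two_columns(self):
        matrix = _two_cluster_matrix(100, sep=5.0).drop(columns=["_cluster"])
        out = tsne_embed(matrix, EmbedParams(perplexity=15, n_iter=260, seed=0))
        assert list(out.columns) == list(matrix.columns) + [TSNE1, TSNE2]
        assert len(out) == len(matrix)

    def test_separated_clusters_stay_pure_in_embedding(self):
        matrix = _two_cluster_matrix(300, sep=50.0)
        clusters = matrix.pop("_cluster").to_numpy()
        out = tsne_embed(matrix, EmbedParams(perplexity=30, n_iter=400, seed=1))
        coords = out[[TSNE1, TSNE2]].to_numpy()
        assert _knn_purity(coords, clusters) >= 0.99

    def test_too_few_cells_raises_with_suggestion(self):
        matrix = _two_cluster_matrix(30, sep=5.0).drop(columns=["_cluster"])
        with pytest.raises(ParameterError, match="perplexity"):
            tsne_embed(matrix, EmbedParams(perplexity=70, n_iter=300, seed=0))


class TestSplitGroups:
    def test_partition_and_coordinate_sharing(self, embedded_cohort):
        full, cr, ad = split_groups(embedded_cohort)
        assert len(cr) + len(ad) == len(full)
        assert set(cr.index).isdisjoint(ad.index)
        pd.testing.assert_frame_equal(
            full.loc[cr.index, [TSNE1, TSNE2]], cr[[TSNE1, TSNE2]]
        )

    def test_per_patient_split_roundtrip(self, embedded_cohort):
        _, cr, _ = split_groups(embedded_cohort)
        for pid, sub in cr.groupby(PATIENT_COL):
            assert (sub[GROUP_COL] == "CR").all()
            assert len(sub) > 0
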