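"""Correlation, correlation-matrix PCA and Ward clustering."""

import numpy as np
import pandas as pd
import pytest

from metalrisk.core_data import ConcentrationTable
from metalrisk.source_stats import (
    cut,
    pca_correlation,
    pearson_matrix,
    to_newick,
    ward_cluster,
)
from metalrisk.synthetic_data import SyntheticConfig, generate


def _table(values: np.ndarray, columns=None) -> ConcentrationTable:
    columns = columns or [f"E{i}" for i in range(values.shape[1])]
    return ConcentrationTable(
        "water",
        pd.DataFrame(values, index=[f"S{i}" for i in range(len(values))],
                     columns=columns),
    )


class TestPearson:
    def test_survey_values(self, water):
        res = pearson_matrix(water)
        assert round(res.r.at["As", "V"], 3) == 0.928
        assert round(res.r.at["Pb", "Cd"], 3) == 0.819
        assert res.flags.at["As", "V"] == "p<0.01"
        assert res.n == 9

    def test_self_correlation_unit_diagonal(self, water):
        res = pearson_matrix(water)
        assert np.allclose(np.diag(res.r.to_numpy()), 1.0)
        assert np.allclose(res.r.to_numpy(), res.r.to_numpy().T)
        assert (res.r.abs().to_numpy() <= 1.0 + 1e-12).all()

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.lognormal(size=(9, 12))
        res = pearson_matrix(_table(x))
        for i in range(12):
            for j in range(12):
                xi, xj = x[:, i], x[:, j]
                cov = np.mean((xi - xi.mean()) * (xj - xj.mean()))
                oracle = cov / (xi.std() * xj.std())
                assert abs(res.r.iloc[i, j] - oracle) < 1e-12

    def test_p_values_match_scipy_pairwise(self, water):
        from scipy.stats import pearsonr

        res = pearson_matrix(water)
        for a, b in [("As", "V"), ("Pb", "Cd"), ("Se", "Hg")]:
            _, p = pearsonr(water.values[a], water.values[b])
            assert res.p.at[a, b] == pytest.approx(p, rel=1e-9)

    def test_constant_column_reported_missing(self):
        x = np.ones((5, 2))
        x[:, 1] = [1, 2, 3, 4, 5]
        res = pearson_matrix(_table(x))
        assert np.isnan(res.r.iloc[0, 1])
        assert res.flags.iloc[0, 1] == ""

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            pearson_matrix(_table(np.ones((2, 3))))


class TestPCA:
    def test_survey_pc1_variance_and_dominant_loading(self, water):
        res = pca_correlation(water)
        assert res.variance_fraction[0] * 100 == pytest.approx(32.30, abs=0.5)
        pc1 = res.loadings["PC1"]
        assert pc1.abs().idxmax() == "Ni"

    def test_variance_fractions_sum_to_one_descending(self, water):
        res = pca_correlation(water)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_loadings_orthonormal_and_reconstruct(self, water):
        res = pca_correlation(water)
        v = res.loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)
        corr = np.corrcoef(water.values.to_numpy(), rowvar=False)
        assert np.allclose(v @ np.diag(res.eigenvalues) @ v.T, corr, atol=1e-10)

    def test_rank_one_data_gives_single_component(self):
        base = np.linspace(1, 5, 8)
        x = np.outer(base, [1.0, 2.0, 0.5])
        res = pca_correlation(_table(x))
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_planted_blocks_recovered_in_leading_components(self):
        """Two ρ=0.9 element blocks land on PC1/PC2 with coherent loadings in
        nearly all replicates."""
        blocks = (["E0", "E1", "E2"], ["E3", "E4", "E5"])
        elements = [f"E{i}" for i in range(8)]
        config_kw = dict(
            n_sites=100,
            elements=elements,
            log_mean={e: 0.0 for e in elements},
            log_sd={e: 1.0 for e in elements},
            correlation_blocks=[(blocks[0], 0.9), (blocks[1], 0.9)],
        )
        hits = 0
        for seed in range(100):
            table, _ = generate(SyntheticConfig(seed=seed, **config_kw))
            res = pca_correlation(table)
            found = set()
            for pc in ("PC1", "PC2"):
                load = res.loadings[pc]
                for b, names in enumerate(blocks):
                    sub = load[names]
                    if (sub.abs() > 0.25).all() and len(set(np.sign(sub))) == 1:
                        found.add(b)
            hits += found == {0, 1}
        assert hits >= 95


class TestWardClustering:
    def test_identical_sites_merge_first_at_zero_height(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [10.0, 20.0]])
        tree = ward_cluster(_table(x))
        assert tree.merges[0, 2] == pytest.approx(0.0)
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 1}

    def test_heights_monotone_nondecreasing(self, water, sediment):
        for table in (water, sediment):
            heights = ward_cluster(table).merges[:, 2]
            assert (np.diff(heights) >= -1e-12).all()

    def test_water_three_clusters_isolate_b3(self, water):
        groups = cut(ward_cluster(water), 3)
        b3 = groups["B3"]
        assert (groups == b3).sum() == 1
        same = lambda a, b: groups[a] == groups[b]
        assert same("A1", "C") and same("A1", "B2") and same("A1", "A4")
        assert same("A2", "B4") and same("A2", "A3") and same("A2", "B1")

    def test_k_bounds(self, water):
        tree = ward_cluster(water)
        with pytest.raises(ValueError):
            cut(tree, 10)
        assert cut(tree, 1).nunique() == 1
        assert cut(tree, 9).nunique() == 9

    def test_planted_site_clusters_recovered(self):
        elements = ["As", "Cd", "Pb"]
        config = SyntheticConfig(
            n_sites=20,
            elements=elements,
            log_mean={e: 0.0 for e in elements},
            log_sd={e: 0.2 for e in elements},
            site_clusters=[(list(range(10)), {"Cd": 10.0})],
            seed=0,
        )
        table, truth = generate(config)
        groups = cut(ward_cluster(table), 2)
        # exact recovery up to label permutation
        a = groups.to_numpy()
        b = truth.cluster_labels.to_numpy()
        assert len({(x, y) for x, y in zip(a, b)}) == 2

    def test_newick_export_parses(self, water):
        text = to_newick(ward_cluster(water))
        assert text.endswith(";")
        for site in water.sites:
            assert site in text
        assert text.count("(") == text.count(")")
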