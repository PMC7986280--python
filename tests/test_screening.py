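"""Screening stage: standardization, distances, Ward clustering, PCA and
contrast-pair selection against brute-force / closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from metscreen.screening import (
    build_screening_bundle,
    cut_clusters,
    euclidean_distances,
    heatmap_bins,
    pca_biplot,
    select_contrast_pair,
    select_contrast_pair_by_priority,
    ward_linkage,
    zscore,
)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(size=(10, 5)),
        index=[f"G{i:02d}" for i in range(10)],
        columns=list("abcde"),
    )


def planted_groups(n_per=5, sep=20.0, seed=1):
    """Three tight trait-space groups far apart."""
    rng = np.random.default_rng(seed)
    blocks = []
    for c in range(3):
        blocks.append(rng.normal(loc=c * sep, scale=0.5, size=(n_per, 4)))
    m = pd.DataFrame(
        np.vstack(blocks),
        index=[f"G{i:02d}" for i in range(3 * n_per)],
        columns=list("wxyz"),
    )
    truth = np.repeat([0, 1, 2], n_per)
    return m, truth


class TestZscore:
    def test_two_point_column(self):
        z = zscore(pd.DataFrame({"a": [1.0, 3.0]}))
        assert np.allclose(z["a"], [-0.7071067811865475, 0.7071067811865475])

    def test_columns_have_zero_mean_unit_sd(self, random_matrix):
        z = zscore(random_matrix)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0)

    def test_already_standardized_unchanged(self, random_matrix):
        z = zscore(random_matrix)
        pd.testing.assert_frame_equal(zscore(z), z)

    def test_constant_column_dropped_with_warning(self, random_matrix):
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore(random_matrix.assign(flat=3.0))
        assert "flat" not in z.columns

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            zscore(pd.DataFrame({"a": [1.0]}))


class TestDistances:
    def test_3_4_5(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["p", "q"])
        d = euclidean_distances(m)
        assert d.loc["p", "q"] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["p", "q"])
        assert euclidean_distances(m).loc["p", "q"] == 0.0

    def test_matches_double_loop_oracle(self, random_matrix):
        d = euclidean_distances(random_matrix).to_numpy()
        x = random_matrix.to_numpy()
        for i in range(len(x)):
            for j in range(len(x)):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((x[i] - x[j]) ** 2).sum()), abs=1e-10
                )

    def test_metric_properties(self, random_matrix):
        d = euclidean_distances(random_matrix).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestWard:
    def test_cut_at_n_gives_singletons(self, random_matrix):
        link = ward_linkage(random_matrix)
        labels = cut_clusters(link, len(random_matrix), random_matrix.index)
        assert labels.nunique() == len(random_matrix)

    def test_k_above_n_rejected(self, random_matrix):
        link = ward_linkage(random_matrix)
        with pytest.raises(ValueError):
            cut_clusters(link, 11, random_matrix.index)

    def test_merge_heights_nondecreasing(self, random_matrix):
        for variant in ("D2", "D"):
            link = ward_linkage(random_matrix, variant=variant)
            assert (np.diff(link[:, 2]) >= -1e-12).all()

    def test_planted_groups_recovered_at_k3(self):
        m, truth = planted_groups()
        link = ward_linkage(zscore(m))
        labels = cut_clusters(link, 3, m.index)
        assert rand_score(truth, labels) == 1.0

    def test_two_group_cut_rand_one(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.5, size=(8, 3))
        b = rng.normal(12, 0.5, size=(8, 3))
        m = pd.DataFrame(np.vstack([a, b]), index=[f"G{i}" for i in range(16)])
        labels = cut_clusters(ward_linkage(zscore(m)), 2, m.index)
        assert rand_score(np.repeat([0, 1], 8), labels) == 1.0


class TestPca:
    def test_two_column_eigenvalues_closed_form(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        y = 0.6 * x + rng.normal(scale=0.8, size=300)
        z = zscore(pd.DataFrame({"x": x, "y": y}))
        r = np.corrcoef(z["x"], z["y"])[0, 1]
        res = pca_biplot(z)
        assert res.eigenvalues[0] == pytest.approx(1 + abs(r), rel=1e-10)
        assert res.eigenvalues[1] == pytest.approx(1 - abs(r), rel=1e-10)

    def test_percent_variance_sums_to_100(self, random_matrix):
        res = pca_biplot(zscore(random_matrix))
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_single_informative_direction(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        z = zscore(pd.DataFrame({"a": x, "b": 2 * x, "c": -x}))
        res = pca_biplot(z)
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_sign_convention_deterministic(self, random_matrix):
        res = pca_biplot(zscore(random_matrix))
        for comp in res.eigenvectors.columns:
            col = res.eigenvectors[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_scores_reproduce_from_eigenvectors(self, random_matrix):
        z = zscore(random_matrix)
        res = pca_biplot(z)
        assert np.allclose(
            res.scores.to_numpy(), z.to_numpy() @ res.eigenvectors.to_numpy()
        )


class TestHeatmapBins:
    def test_two_bins_on_extremes(self):
        m = pd.DataFrame([[-1.0, 1.0], [1.0, -1.0]], index=["p", "q"],
                         columns=["a", "b"])
        link_r = ward_linkage(m)
        link_c = ward_linkage(m.T)
        bins = heatmap_bins(m, link_r, link_c, n_bins=2)
        assert set(np.unique(bins.to_numpy())) == {0, 1}

    def test_orders_are_bijections(self, random_matrix):
        z = zscore(random_matrix)
        bins = heatmap_bins(z, ward_linkage(z), ward_linkage(z.T), n_bins=5)
        assert sorted(bins.index) == sorted(z.index)
        assert sorted(bins.columns) == sorted(z.columns)

    def test_manual_binning(self):
        m = pd.DataFrame([[0.0, 1.0], [2.0, 4.0]], index=["p", "q"],
                         columns=["a", "b"])
        bins = heatmap_bins(m, ward_linkage(m), ward_linkage(m.T), n_bins=4)
        flat = {
            (r, c): bins.loc[r, c] for r in bins.index for c in bins.columns
        }
        assert flat[("p", "a")] == 0 and flat[("q", "b")] == 3
        assert flat[("p", "b")] == 1 and flat[("q", "a")] == 2

    def test_too_few_bins_rejected(self, random_matrix):
        z = zscore(random_matrix)
        with pytest.raises(ValueError):
            heatmap_bins(z, ward_linkage(z), ward_linkage(z.T), n_bins=1)


class TestContrastPair:
    def _panel_with_extremes(self, seed=0):
        """30-genotype panel; one planted high-SOD/high-yield genotype and
        one planted low one, far outside the bulk."""
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(
            rng.normal(10, 1.0, size=(30, 4)),
            index=[f"G{i+1:02d}" for i in range(30)],
            columns=["SOD", "Yld", "PRL", "GR"],
        )
        m.loc["G28", ["SOD", "Yld"]] = 25.0
        m.loc["G03", ["SOD", "Yld"]] = -5.0
        return m

    def test_planted_extremes_selected(self):
        m = self._panel_with_extremes()
        bundle = build_screening_bundle(m, k=3)
        pair = select_contrast_pair(bundle, target_traits=("SOD", "Yld"))
        assert {pair.high, pair.low} == {"G28", "G03"}
        assert pair.high == "G28"

    def test_pair_members_in_different_clusters(self):
        m = self._panel_with_extremes(seed=5)
        bundle = build_screening_bundle(m, k=3)
        pair = select_contrast_pair(bundle, target_traits=("SOD", "Yld"))
        assert bundle.clusters[pair.high] != bundle.clusters[pair.low]

    def test_alternates_come_from_own_clusters(self):
        m = self._panel_with_extremes()
        bundle = build_screening_bundle(m, k=3)
        pair = select_contrast_pair(bundle, target_traits=("SOD", "Yld"))
        for g in pair.alternates_high:
            assert bundle.clusters[g] == bundle.clusters[pair.high]
        for g in pair.alternates_low:
            assert bundle.clusters[g] == bundle.clusters[pair.low]

    def test_single_cluster_rejected(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        bundle = build_screening_bundle(m, k=2)
        bundle.clusters[:] = 1
        with pytest.raises(ValueError, match="one cluster"):
            select_contrast_pair(bundle, target_traits=[0, 1])

    def test_deterministic_under_row_permutation(self):
        m = self._panel_with_extremes(seed=2)
        b1 = build_screening_bundle(m, k=3)
        b2 = build_screening_bundle(m.sample(frac=1.0, random_state=3), k=3)
        p1 = select_contrast_pair(b1, target_traits=("SOD", "Yld"))
        p2 = select_contrast_pair(b2, target_traits=("SOD", "Yld"))
        assert (p1.high, p1.low) == (p2.high, p2.low)

    def test_stress_condition_takes_precedence(self):
        m_stress = self._panel_with_extremes(seed=0)
        m_normal = self._panel_with_extremes(seed=0).rename(
            index={"G28": "G10", "G10": "G28"}
        )
        bundles = {
            "normal": build_screening_bundle(m_normal, k=3),
            "stress": build_screening_bundle(m_stress, k=3),
        }
        pair = select_contrast_pair_by_priority(
            bundles, target_traits=("SOD", "Yld")
        )
        assert pair.trace["deciding_condition"] == "stress"
        assert pair.high == "G28"
        assert pair.trace["per_condition"]["normal"][0] == "G10"
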