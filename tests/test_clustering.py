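import numpy as np
import pytest
from scipy.stats import f_oneway
from sklearn.cluster import KMeans as SKKMeans
from sklearn.metrics import adjusted_rand_score

from metamem.clustering import (
    anova_rows_to_frame,
    canonicalize_clusters,
    cluster_feature_anovas,
    cluster_profiles,
    composition_table,
    kmeans,
)
from metamem.datamodel import CANONICAL_COLUMNS, FeatureMatrix


def zmatrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"v{j}" for j in range(values.shape[1]))
    return FeatureMatrix(
        values=values,
        column_labels=labels,
        row_ids=tuple(f"r{i}" for i in range(values.shape[0])),
        scale="zscored",
    )


class TestKMeans:
    def test_exact_singleton_partition(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        sol = kmeans(pts, k=3, restarts=5, seed=0)
        assert sol.inertia == pytest.approx(0.0)
        assert sorted(sol.assignments.tolist()) == [1, 2, 3]

    def test_k_equals_one_closed_form(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 2))
        sol = kmeans(pts, k=1, restarts=3, seed=0)
        assert np.allclose(sol.centroids[0], pts.mean(axis=0))
        assert sol.inertia == pytest.approx(((pts - pts.mean(0)) ** 2).sum())

    @pytest.mark.parametrize("seed", range(10))
    def test_well_separated_gaussians_recovered(self, seed):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
        truth = np.repeat([0, 1, 2], 20)
        pts = centers[truth] + rng.normal(0, 0.5, size=(60, 2))
        sol = kmeans(pts, k=3, restarts=20, seed=seed)
        assert adjusted_rand_score(truth, sol.assignments) == 1.0

    def test_matches_sklearn_inertia(self):
        """Best-of-restarts objective agrees with the reference implementation."""
        rng = np.random.default_rng(7)
        pts = np.vstack(
            [rng.normal(c, 0.7, size=(25, 2)) for c in ([0, 0], [4, 1], [1, 5])]
        )
        ours = kmeans(pts, k=3, restarts=30, seed=0)
        ref = SKKMeans(n_clusters=3, n_init=30, random_state=0).fit(pts)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)

    def test_determinism_and_validation(self):
        pts = np.random.default_rng(0).normal(size=(12, 2))
        a = kmeans(pts, k=3, restarts=5, seed=42)
        b = kmeans(pts, k=3, restarts=5, seed=42)
        assert np.array_equal(a.assignments, b.assignments)
        with pytest.raises(ValueError):
            kmeans(pts[:2], k=3)


class TestCanonicalization:
    def _toy_solution(self):
        # 6 young in one tight cloud, 3+3 old split into two clouds
        pts = np.array(
            [[1.0, -1.0]] * 6 + [[-1.0, -1.0]] * 3 + [[1.0, 1.0]] * 3
        ) + np.random.default_rng(0).normal(0, 0.05, size=(12, 2))
        ages = np.array(["young"] * 6 + ["old"] * 6)
        pacc = np.array([0.0] * 6 + [1.2] * 3 + [-1.2] * 3)
        z = np.random.default_rng(1).normal(size=(12, 18))
        z[:, CANONICAL_COLUMNS.index("postdiction_accuracy_assoc")] = pacc
        features = zmatrix(z - z.mean(0), labels=CANONICAL_COLUMNS)
        return pts, ages, features

    def test_labels_follow_age_and_calibration(self):
        pts, ages, features = self._toy_solution()
        sol = canonicalize_clusters(kmeans(pts, k=3, seed=0), ages, features)
        assert np.all(sol.assignments[:6] == 1)
        assert np.all(sol.assignments[6:9] == 2)  # high associate calibration
        assert np.all(sol.assignments[9:] == 3)

    def test_invariant_to_raw_label_permutation(self):
        pts, ages, features = self._toy_solution()
        base = kmeans(pts, k=3, seed=0)
        from metamem.clustering import ClusterSolution

        perm = {1: 3, 2: 1, 3: 2}
        permuted = ClusterSolution(
            assignments=np.array([perm[a] for a in base.assignments]),
            centroids=base.centroids[[1, 2, 0]],
            inertia=base.inertia,
            restarts=base.restarts,
            seed=base.seed,
        )
        a = canonicalize_clusters(base, ages, features)
        b = canonicalize_clusters(permuted, ages, features)
        assert np.array_equal(a.assignments, b.assignments)

    def test_non_three_k_passthrough_with_warning(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        sol = kmeans(pts, k=2, seed=0)
        with pytest.warns(UserWarning):
            out = canonicalize_clusters(sol, ["young"] * 10, zmatrix(np.zeros((10, 1))))
        assert out is sol


class TestProfiles:
    def test_single_cluster_profile_is_zero(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(20, 5))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        prof = cluster_profiles(zmatrix(z), np.ones(20, dtype=int))
        assert np.abs(prof[(1, "mean")].to_numpy()).max() < 1e-12

    def test_weighted_cluster_means_conserve_zero(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(30, 4))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        assignments = rng.integers(1, 4, size=30)
        prof = cluster_profiles(zmatrix(z), assignments)
        total = np.zeros(4)
        for lab in (1, 2, 3):
            total += (assignments == lab).sum() * prof[(lab, "mean")].to_numpy()
        assert np.abs(total / 30).max() < 1e-9

    def test_singleton_cluster_se_missing(self):
        z = np.array([[0.0], [1.0], [-1.0]])
        prof = cluster_profiles(zmatrix(z), np.array([1, 2, 2]))
        assert np.isnan(prof[(1, "se")].iloc[0])
        assert np.isfinite(prof[(2, "se")].iloc[0])


class TestClusterAnovas:
    def test_printed_fixture_decomposition(self):
        # groups {1,2,3} vs {7,8,9}: SSB = 54, SSW = 4, F = 54, eta2 = 54/58
        values = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        rows = cluster_feature_anovas(
            zmatrix(values), np.array([1, 1, 1, 2, 2, 2]), m_tests=1
        )
        assert rows[0].F == pytest.approx(54.0, abs=1e-10)
        assert rows[0].partial_eta_squared == pytest.approx(54 / 58, abs=1e-12)
        assert rows[0].df_between == 1 and rows[0].df_within == 4

    def test_matches_scipy_f_oneway_oracle(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(24, 6))
        assignments = np.repeat([1, 2, 3], 8)
        z[assignments == 2] += 0.8
        rows = cluster_feature_anovas(zmatrix(z), assignments, m_tests=6)
        for j, row in enumerate(rows):
            groups = [z[assignments == lab, j] for lab in (1, 2, 3)]
            F, p = f_oneway(*groups)
            assert row.F == pytest.approx(F, abs=1e-10)
            assert row.p_raw == pytest.approx(p, abs=1e-12)

    def test_matches_regression_decomposition_oracle(self):
        """Partial eta squared equals SS_between/(SS_between+SS_within) from an
        explicit least-squares decomposition onto group indicators."""
        rng = np.random.default_rng(8)
        y = rng.normal(size=18)
        assignments = np.repeat([1, 2, 3], 6)
        y[assignments == 3] += 1.5
        rows = cluster_feature_anovas(zmatrix(y[:, None]), assignments, m_tests=1)
        design = np.column_stack([(assignments == lab).astype(float) for lab in (1, 2, 3)])
        fitted = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        ssb = ((fitted - y.mean()) ** 2).sum()
        ssw = ((y - fitted) ** 2).sum()
        assert rows[0].partial_eta_squared == pytest.approx(ssb / (ssb + ssw), abs=1e-10)

    def test_constant_shift_null(self):
        z = np.tile(np.linspace(-1, 1, 12)[:, None], (1, 3))
        rows = cluster_feature_anovas(zmatrix(z), np.tile([1, 2, 3], 4), m_tests=3)
        assert not any(r.significant for r in rows)

    def test_degenerate_cluster_sizes_rejected(self):
        z = np.zeros((4, 2))
        with pytest.raises(ValueError, match="\\[2\\]"):
            cluster_feature_anovas(zmatrix(z), np.array([1, 1, 1, 2]))

    def test_frame_export(self):
        values = np.random.default_rng(0).normal(size=(9, 2))
        rows = cluster_feature_anovas(zmatrix(values), np.repeat([1, 2, 3], 3))
        frame = anova_rows_to_frame(rows)
        assert list(frame.index) == ["v0", "v1"]
        assert (frame["p_bonferroni"] >= frame["p_raw"]).all()


class TestComposition:
    def test_single_group(self):
        table = composition_table(np.ones(5, dtype=int), ["young"] * 5)
        assert table.loc[1, "young"] == 5
        assert table.loc[1, "old"] == 0

    def test_marginals_conserved(self):
        rng = np.random.default_rng(1)
        assignments = rng.integers(1, 4, size=50)
        ages = rng.choice(["young", "old"], size=50)
        table = composition_table(assignments, ages)
        assert table["young"].sum() == (ages == "young").sum()
        assert table["old"].sum() == (ages == "old").sum()
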