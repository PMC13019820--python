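import numpy as np
import pytest

from conftest import make_morphometry
from psychocortex.cohort import SyntheticConfig, generate_cohort
from psychocortex.gradients import (
    GradientSet,
    StructuralCovarianceGradients,
    build_affinity,
    compression_stats,
    diffusion_embedding,
    partition_compression,
    procrustes_align,
    structural_covariance,
)


class TestStructuralCovariance:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        C = structural_covariance(rng.standard_normal((40, 12)))
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T, atol=1e-12)

    def test_collinear_parcels_fully_correlated(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        X = np.column_stack([X, X[:, 0]])
        C = structural_covariance(X)
        assert C[0, 3] == pytest.approx(1.0)

    def test_matches_naive_pairwise_loops(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((35, 10))
        C = structural_covariance(X)
        for i in range(10):
            for j in range(10):
                assert C[i, j] == pytest.approx(
                    np.corrcoef(X[:, i], X[:, j])[0, 1], abs=1e-10
                )

    def test_zero_variance_parcel_flagged_with_zero_row(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        X[:, 2] = 7.0
        C = structural_covariance(X)
        assert C[2, 2] == 1.0
        assert np.all(C[2, [0, 1, 3, 4]] == 0.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            structural_covariance(np.random.default_rng(0).standard_normal((10, 5)))


class TestAffinity:
    def test_identical_rows_reach_unit_affinity(self):
        C = np.ones((4, 4)) * 0.5
        np.fill_diagonal(C, 1.0)
        A = build_affinity(C, sparsity=0.0)
        assert A[0, 1] == pytest.approx(
            A[1, 0]
        )  # symmetric; rows of this C are permutations with equal profiles

    def test_orthogonal_profiles_have_half_affinity(self):
        # two disconnected blocks: cross-block sparsified rows are orthogonal
        C = np.eye(6)
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        A = build_affinity(C, sparsity=0.0)
        assert A[0, 3] == pytest.approx(0.5)
        assert A[0, 1] == pytest.approx(1.0)

    def test_sparsity_retains_top_fraction(self, atlas360):
        from psychocortex.cohort import make_covariance_model

        K = make_covariance_model(atlas360, 1.0)
        p = 360
        keep = int(round(0.1 * p))
        C = K.copy()
        # count retained entries per row before the angle transform
        retained = np.sort(C, axis=1)[:, -keep:]
        assert retained.shape[1] == 36
        A = build_affinity(K, sparsity=0.9)
        assert A.shape == (p, p)
        assert (A >= 0).all() and (A <= 1 + 1e-12).all()

    def test_all_negative_row_rejected(self):
        C = -np.ones((5, 5))
        with pytest.raises(ValueError):
            build_affinity(C, sparsity=0.0)


class TestDiffusionEmbedding:
    def test_two_block_affinity_separates_blocks_by_sign(self):
        A = np.full((20, 20), 0.01)
        A[:10, :10] = 1.0
        A[10:, 10:] = 1.0
        g = diffusion_embedding(A, n_components=3)
        first = g.component(0)
        assert np.ptp(np.sign(first[:10])) == 0
        assert np.sign(first[0]) != np.sign(first[10])

    def test_requested_component_count_returned(self):
        rng = np.random.default_rng(4)
        M = rng.uniform(0.1, 1.0, (40, 40))
        A = (M + M.T) / 2
        g = diffusion_embedding(A, n_components=10)
        assert g.n_components == 10
        assert np.all(np.diff(np.abs(g.eigenvalues)) <= 1e-12)

    def test_variance_explained_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(5)
        M = rng.uniform(0.1, 1.0, (30, 30))
        g = diffusion_embedding((M + M.T) / 2, n_components=8)
        ve = g.variance_explained
        assert np.all(np.diff(ve) <= 1e-12)
        assert 0 <= ve.sum() <= 1 + 1e-9

    def test_loadings_invariant_to_relabeling(self):
        rng = np.random.default_rng(6)
        M = rng.uniform(0.1, 1.0, (25, 25))
        A = (M + M.T) / 2
        g = diffusion_embedding(A, n_components=3)
        perm = rng.permutation(25)
        gp = diffusion_embedding(A[np.ix_(perm, perm)], n_components=3)
        for k in range(3):
            a, b = g.component(k)[perm], gp.component(k)
            assert min(
                np.abs(a - b).max(), np.abs(a + b).max()
            ) < 1e-8

    def test_disconnected_graph_reports_component_sizes(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="components"):
            diffusion_embedding(A)

    def test_gradient_recovers_planted_ap_axis(self):
        cohort = generate_cohort(
            SyntheticConfig(n_subjects={"low": 400}, seed=0)
        )
        model = StructuralCovarianceGradients(
            cohort.ct, cohort.subjects["group"], atlas=cohort.atlas
        )
        res = model.fit()
        r = np.corrcoef(res.template.component(0), cohort.atlas.ap_axis)[0, 1]
        assert abs(r) >= 0.9


class TestProcrustes:
    def _random_set(self, seed, p=50, k=4):
        rng = np.random.default_rng(seed)
        L = rng.standard_normal((p, k))
        ev = np.sort(rng.uniform(0.1, 1, k))[::-1]
        return GradientSet(L, ev, ev / ev.sum(), label=f"s{seed}")

    def test_self_alignment_is_identity(self):
        g = self._random_set(0)
        aligned = procrustes_align(g, g)
        assert np.allclose(aligned.loadings, g.loadings, atol=1e-10)
        assert aligned.aligned_to == g.label

    def test_sign_flips_are_recovered(self):
        g = self._random_set(1)
        flipped = GradientSet(
            g.loadings * np.array([1, -1, 1, -1]), g.eigenvalues,
            g.variance_explained, label="flip",
        )
        aligned = procrustes_align(flipped, g)
        assert np.allclose(aligned.loadings, g.loadings, atol=1e-10)

    def test_alignment_never_increases_distance(self):
        for seed in range(10):
            src = self._random_set(seed)
            tpl = self._random_set(seed + 100)
            aligned = procrustes_align(src, tpl)
            before = np.linalg.norm(src.loadings - tpl.loadings)
            after = np.linalg.norm(aligned.loadings - tpl.loadings)
            assert after <= before + 1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            procrustes_align(self._random_set(0, k=3), self._random_set(1, k=4))


class TestCompression:
    def test_identical_sets_show_no_compression(self):
        rng = np.random.default_rng(7)
        L = rng.standard_normal((360, 2))
        ev = np.array([0.5, 0.3])
        a = GradientSet(L, ev, ev / ev.sum(), label="a", aligned_to="t")
        b = GradientSet(L.copy(), ev, ev / ev.sum(), label="b", aligned_to="t")
        out = compression_stats(a, b)
        assert out.ks_D == 0.0 and out.range_ratio == pytest.approx(1.0)

    def test_range_ratio_is_plain_arithmetic(self):
        rng = np.random.default_rng(8)
        lo = GradientSet(rng.standard_normal((360, 1)), np.array([0.5]),
                         np.array([1.0]), label="lo", aligned_to="t")
        hi = GradientSet(0.6 * rng.standard_normal((360, 1)), np.array([0.5]),
                         np.array([1.0]), label="hi", aligned_to="t")
        out = compression_stats(lo, hi)
        expected = np.ptp(hi.component(0)) / np.ptp(lo.component(0))
        assert out.range_ratio == pytest.approx(expected)

    def test_unaligned_inputs_rejected(self):
        rng = np.random.default_rng(9)
        a = GradientSet(rng.standard_normal((360, 1)), np.array([0.5]),
                        np.array([1.0]))
        with pytest.raises(ValueError):
            compression_stats(a, a)

    def test_planted_compression_detected_end_to_end(self):
        detected_rr = detected_ks = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cohort = generate_cohort(
                SyntheticConfig(
                    n_subjects={"low": 300, "high": 300},
                    compression_c=0.3,
                    seed=seed,
                )
            )
            res = StructuralCovarianceGradients(
                cohort.ct, cohort.subjects["group"], atlas=cohort.atlas
            ).fit()
            detected_rr += res.compression.range_ratio < 1
            detected_ks += res.compression.ks_p < 0.05
        assert detected_rr >= n_seeds - 1
        assert detected_ks >= n_seeds - 1


class TestPartitionCompression:
    def _aligned_pair(self, atlas, shrink=1.0, seed=0):
        rng = np.random.default_rng(seed)
        base = np.sort(rng.standard_normal(atlas.n_parcels))[:, None]
        lo = GradientSet(base, np.array([0.5]), np.array([1.0]),
                         label="low", aligned_to="t")
        hi = GradientSet(shrink * base + 0.01 * rng.standard_normal(base.shape),
                         np.array([0.5]), np.array([1.0]),
                         label="high", aligned_to="t")
        return lo, hi

    def test_class_partition_runs_four_tests(self, atlas360):
        lo, hi = self._aligned_pair(atlas360, shrink=0.6)
        out = partition_compression(lo, hi, atlas360, "class")
        assert out["n_tests"] == 4
        assert len(out["per_label"]) == 4

    def test_network_partition_runs_seven_tests(self, atlas360):
        lo, hi = self._aligned_pair(atlas360, shrink=0.6)
        out = partition_compression(lo, hi, atlas360, "network")
        assert out["n_tests"] == 7
        assert len(out["per_label"]) == 7

    def test_identical_loadings_flag_nothing(self, atlas360):
        rng = np.random.default_rng(1)
        L = rng.standard_normal((360, 1))
        lo = GradientSet(L, np.array([0.5]), np.array([1.0]),
                         label="low", aligned_to="t")
        hi = GradientSet(L.copy(), np.array([0.5]), np.array([1.0]),
                         label="high", aligned_to="t")
        out = partition_compression(lo, hi, atlas360, "class")
        assert not any(r["compression_oriented"] for r in out["per_label"])
        assert all(np.isnan(r["p"]) for r in out["per_label"])

    def test_global_shrink_is_compression_oriented(self, atlas360):
        lo, hi = self._aligned_pair(atlas360, shrink=0.5)
        out = partition_compression(lo, hi, atlas360, "network")
        flags = [r["compression_oriented"] for r in out["per_label"]]
        # extreme-median networks must be pulled toward the center
        assert sum(flags) >= 4
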