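import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from microtraj import (
    AbundanceProfile,
    DistanceMatrix,
    SampleMetadata,
    bray_curtis,
    distance_to_plane,
    fit_plane,
    paired_t,
    pcoa,
    plane_distance_series,
    score_plane_correlation,
    simulate_cohort,
    SimConfig,
)
from microtraj.ordination import OrdinationError, PlaneFitError


def _profile(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = [f"sp{j}" for j in range(rows.shape[1])]
    return AbundanceProfile(pd.DataFrame(rows, index=ids, columns=cols))


class TestBrayCurtis:
    def test_hand_computed_values(self):
        dm = bray_curtis(_profile([[0.5, 0.5], [0.25, 0.75], [0.5, 0.5]]))
        assert dm.values[0, 1] == pytest.approx(0.25)
        assert dm.values[0, 2] == 0.0

    def test_disjoint_supports_give_one(self):
        dm = bray_curtis(_profile([[1.0, 0.0], [0.0, 1.0]]))
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_all_zero_pair_defined_as_zero(self):
        dm = bray_curtis(_profile([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == pytest.approx(1.0)

    def test_single_sample_is_an_error(self):
        with pytest.raises(OrdinationError):
            bray_curtis(_profile([[1.0, 2.0]]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0.0, 25.0), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        )
    )
    def test_symmetry_bounds_and_identity(self, rows):
        dm = bray_curtis(_profile(rows))
        v = dm.values
        assert np.allclose(v, v.T)
        assert (v >= 0).all() and (v <= 1 + 1e-12).all()
        assert np.allclose(np.diag(v), 0.0)


class TestPCoA:
    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(12, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        emb = pcoa(DistanceMatrix(list(range(12)), d), k=3)
        recon = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1
        )
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_matches_skbio_embedding_distances(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(8), size=10) * 100
        dm = bray_curtis(_profile(x))
        emb = pcoa(dm, k=3)
        ref = skbio_ord.pcoa(
            skbio_stats.DistanceMatrix(dm.values, [str(i) for i in range(10)]),
            method="eigh",
        )
        ref_coords = ref.samples.to_numpy()[:, :3]
        d_ours = np.linalg.norm(emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1)
        d_ref = np.linalg.norm(ref_coords[:, None] - ref_coords[None, :], axis=-1)
        np.testing.assert_allclose(d_ours, d_ref, atol=1e-8)

    def test_identical_samples_coincide(self):
        d = np.array(
            [[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        emb = pcoa(DistanceMatrix(["a", "b", "c"], d), k=2)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-10)

    def test_eigenvalues_descending_and_positive(self, small_cohort):
        emb = pcoa(bray_curtis(small_cohort[0]), k=3)
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()
        assert (emb.eigenvalues > 0).all()

    def test_k_reduced_with_warning_for_degenerate_input(self):
        # three collinear points have exactly 1 positive axis
        pts = np.array([[0.0], [1.0], [2.0]])
        d = np.abs(pts - pts.T)
        with pytest.warns(UserWarning, match="reduced"):
            emb = pcoa(DistanceMatrix(["a", "b", "c"], d), k=3)
        assert emb.coordinates.shape[1] == 1

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(OrdinationError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.5, 0.0]]))


class TestFitPlane:
    def test_coplanar_points_have_zero_residuals(self):
        rng = np.random.default_rng(2)
        uv = rng.normal(size=(7, 2))
        basis = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]]) / np.array([1.0, np.sqrt(2)])[:, None]
        pts = uv @ basis + np.array([5.0, -2.0, 3.0])
        plane = fit_plane(pts)
        residuals = (pts - plane.centroid) @ plane.normal
        np.testing.assert_allclose(residuals, 0.0, atol=1e-10)

    def test_symmetric_four_point_set_gives_z_plane(self):
        delta = 1e-3
        pts = [(1, 0, delta), (-1, 0, delta), (0, 1, -delta), (0, -1, -delta)]
        plane = fit_plane(pts)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(plane.centroid, [0, 0, 0], atol=1e-12)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 3))
        rot = scipy.stats.special_ortho_group.rvs(3, random_state=4)
        base = fit_plane(pts)
        rotated = fit_plane(pts @ rot.T)
        np.testing.assert_allclose(rotated.centroid, rot @ base.centroid, atol=1e-10)
        got = rot @ base.normal
        if np.dot(got, rotated.normal) < 0:
            got = -got
        np.testing.assert_allclose(rotated.normal, got, atol=1e-10)

    def test_orthogonal_residuals_are_minimal(self):
        # perturbing the fitted normal never decreases the residual sum
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3)) * np.array([3.0, 2.0, 0.3])
        plane = fit_plane(pts)
        centered = pts - plane.centroid
        best = ((centered @ plane.normal) ** 2).sum()
        for _ in range(50):
            n = plane.normal + rng.normal(scale=1e-3, size=3)
            n /= np.linalg.norm(n)
            assert ((centered @ n) ** 2).sum() >= best - 1e-12

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(PlaneFitError, match="collinear"):
            fit_plane(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(PlaneFitError, match="3 points"):
            fit_plane([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])


class TestDistanceToPlane:
    def test_point_on_plane_and_unit_offset(self):
        plane = fit_plane([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)])
        assert distance_to_plane(plane.centroid, plane) == 0.0
        assert distance_to_plane(plane.centroid + plane.normal, plane) == pytest.approx(1.0)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(6, 3))
        point = rng.normal(size=3)
        rot = scipy.stats.special_ortho_group.rvs(3, random_state=7)
        base = distance_to_plane(point, fit_plane(pts))
        rotated = distance_to_plane(rot @ point, fit_plane(pts @ rot.T))
        assert rotated == pytest.approx(base, abs=1e-10)

    def test_non_finite_point_rejected(self):
        plane = fit_plane([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)])
        with pytest.raises(OrdinationError):
            distance_to_plane([np.nan, 0, 0], plane)


class TestPlaneDistanceSeries:
    def test_samples_on_their_plane_have_zero_distance(self, default_cohort):
        profile, meta = default_cohort[0], default_cohort[1]
        emb = pcoa(bray_curtis(profile), k=3)
        series = plane_distance_series(emb, meta, "normal", "model")
        assert set(series.data.index) == set(profile.sample_ids)
        assert (series.data[["dist_hp", "dist_dp"]] >= 0).all().all()

    def test_identical_groups_give_identical_distances(self, default_cohort):
        profile, meta = default_cohort[0], default_cohort[1]
        emb = pcoa(bray_curtis(profile), k=3)
        series = plane_distance_series(emb, meta, "normal", "normal")
        np.testing.assert_allclose(series.data["dist_hp"], series.data["dist_dp"])

    def test_sample_order_invariance(self, small_cohort):
        profile, meta = small_cohort[0], small_cohort[1]
        emb = pcoa(bray_curtis(profile), k=3)
        a = plane_distance_series(emb, meta, "normal", "model").data
        perm = np.random.default_rng(8).permutation(len(profile.sample_ids))
        shuffled = AbundanceProfile(profile.data.iloc[perm])
        emb2 = pcoa(bray_curtis(shuffled), k=3)
        b = plane_distance_series(emb2, meta, "normal", "model").data
        joined = a.join(b, lsuffix="_a", rsuffix="_b")
        np.testing.assert_allclose(joined["dist_hp_a"], joined["dist_hp_b"], atol=1e-8)

    def test_full_reversion_brings_treated_near_healthy(self):
        cfg = SimConfig(seed=9, n_rats_per_group=5, n_species=80, n_signal_species=3,
                        n_drift_species=20, reversion_fraction=1.0, response_sd=0.0)
        profile, meta, _, _ = simulate_cohort(cfg)
        emb = pcoa(bray_curtis(profile), k=3)
        series = plane_distance_series(emb, meta, "normal", "model")
        last_tp = sorted(set(meta.data["timepoint"]))[-1]
        treated = series.data[
            (series.data["group"] == "lcasei") & (series.data["timepoint"] == last_tp)
        ]
        assert treated["dist_hp"].mean() < treated["dist_dp"].mean()

    def test_insufficient_group_samples_name_the_timepoint(self, small_cohort):
        profile, meta = small_cohort[0], small_cohort[1]
        keep = [s for s in profile.sample_ids if not s.startswith("normal_r01")
                or not s.endswith("TP3")]
        # drop normal rats at TP3 down to 2 samples
        drop = [s for s in profile.sample_ids
                if s.startswith("normal_r0") and s.endswith("TP3")][:2]
        keep = [s for s in profile.sample_ids if s not in drop]
        sub = AbundanceProfile(profile.data.loc[keep])
        emb = pcoa(bray_curtis(sub), k=3)
        with pytest.raises(OrdinationError, match="TP3"):
            plane_distance_series(emb, meta, "normal", "model")


class TestPairedT:
    def test_matches_scipy_on_regular_input(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(a, b)
        ref = scipy.stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_alternating_differences_give_t_zero(self):
        res = paired_t([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_three_differences(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)) ~ 3.464, p(df=2) ~ 0.0742
        res = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.p_value == pytest.approx(0.0742, abs=5e-4)

    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0], [1.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_zero_variance_nonzero_mean_flagged(self):
        res = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert res.degenerate and res.p_value == 0.0

    def test_short_input_rejected(self):
        with pytest.raises(OrdinationError):
            paired_t([1.0], [2.0])


class TestScorePlaneCorrelation:
    def test_constant_score_is_degenerate(self, small_cohort):
        profile, meta = small_cohort[0], small_cohort[1]
        emb = pcoa(bray_curtis(profile), k=3)
        series = plane_distance_series(emb, meta, "normal", "model")
        flat = SampleMetadata(meta.data.assign(arthritis_score=1.0).reset_index())
        hp, dp = score_plane_correlation(series, flat)
        assert hp.degenerate and dp.degenerate

    def test_shuffled_scores_have_near_zero_mean_coefficient(self, small_cohort):
        profile, meta = small_cohort[0], small_cohort[1]
        emb = pcoa(bray_curtis(profile), k=3)
        series = plane_distance_series(emb, meta, "normal", "model")
        rng = np.random.default_rng(12)
        ccs = []
        for _ in range(30):
            shuffled = SampleMetadata(
                meta.data.assign(
                    arthritis_score=rng.permutation(meta.data["arthritis_score"].to_numpy())
                ).reset_index()
            )
            hp, _ = score_plane_correlation(series, shuffled)
            ccs.append(hp.coefficient)
        assert abs(np.mean(ccs)) < 0.05
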