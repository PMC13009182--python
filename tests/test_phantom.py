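import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from shuntvalve import (
    PhantomOutOfBoundsError,
    PhantomSpec,
    PoseJitter,
    angle_to_setting,
    canonical_markers,
    cohort_manifest,
    grouped_split,
    make_cohort,
    make_phantom,
    marker_centroids,
    plan_cohort,
    predict_from_labelmap,
    predict_from_markers,
)
from shuntvalve.phantom import DEFAULT_DIMENSIONS, ValveDimensions


class TestCanonicalMarkers:
    def test_angle_zero_magnet_positions(self):
        m = canonical_markers(0.0)
        d = DEFAULT_DIMENSIONS
        np.testing.assert_allclose(m.get("magnet_with_ball"), (d.magnet_offset, 0, 0))
        np.testing.assert_allclose(m.get("magnet_without_ball"), (-d.magnet_offset, 0, 0))
        np.testing.assert_allclose(m.get("rotating_construct"), (0, 0, 0))
        np.testing.assert_allclose(m.get("rhs_marker"), (d.rhs_offset, 0, 0))

    def test_self_consistency_with_angle_measurement(self):
        """The generator and the measurement share one sign convention."""
        for truth in (-67.5, 0.0, 22.5, 112.5, 247.5):
            r = predict_from_markers(canonical_markers(truth))
            assert r.angle_deg == pytest.approx(truth, abs=1e-9)

    def test_expected_angle_of_setting_8_maps_back(self):
        r = predict_from_markers(canonical_markers(247.5))
        assert r.setting == 8

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            canonical_markers(math.inf)


class TestMakePhantom:
    def test_default_phantom_recovers_setting(self):
        grid, labels, truth = make_phantom(PhantomSpec(setting=4, seed=1))
        assert truth.truth_setting == 4
        counts = [int((labels.labels == l).sum()) for l in range(1, 6)]
        assert all(c > 0 for c in counts)
        assert predict_from_labelmap(labels).setting == 4

    def test_deterministic_given_seed(self):
        a = make_phantom(PhantomSpec(setting=6, seed=11))
        b = make_phantom(PhantomSpec(setting=6, seed=11))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_noiseless_identity_pose_angle_within_one_degree(self):
        """Rasterisation alone perturbs the angle by well under a degree."""
        spec = PhantomSpec(angle_deg=22.5, noise_sd=0.0, blur_sigma=0.0, seed=0)
        _, labels, _ = make_phantom(spec)
        assert predict_from_labelmap(labels).angle_deg == pytest.approx(22.5, abs=1.0)

    def test_truth_record_is_consistent(self):
        _, _, truth = make_phantom(PhantomSpec(angle_deg=100.0, seed=2))
        assert truth.truth_setting == angle_to_setting(truth.truth_angle_deg).setting
        r = predict_from_markers(truth.markers)
        assert r.angle_deg == pytest.approx(100.0, abs=1e-9)

    def test_out_of_bounds_translation_rejected(self):
        with pytest.raises(PhantomOutOfBoundsError, match="out of bounds"):
            make_phantom(PhantomSpec(setting=4, translation_mm=(40.0, 0.0, 0.0)))

    def test_exactly_one_of_setting_or_angle(self):
        with pytest.raises(ValueError):
            PhantomSpec(setting=4, angle_deg=10.0).resolve_angle()
        with pytest.raises(ValueError):
            PhantomSpec().resolve_angle()

    def test_label_centroids_near_truth_markers(self):
        grid, labels, truth = make_phantom(
            PhantomSpec(setting=5, rotation_deg=(20, -35, 60), seed=3)
        )
        measured = marker_centroids(labels)
        for name, truth_pt in truth.markers.centroids.items():
            err = np.linalg.norm(measured.get(name) - truth_pt)
            assert err < 0.35, f"{name} centroid off by {err:.3f} mm"

    def test_voxel_counts_match_analytic_volumes(self):
        """Rasterised marker volumes track the analytic solid volumes.

        Tight (20%) for markers several voxels across; looser for the
        RHS sphere and tip capsule whose radii are close to one voxel.
        """
        d = DEFAULT_DIMENSIONS
        voxel = 0.6**3
        analytic = {
            "magnet_with_ball": 4 / 3 * math.pi * d.magnet_radius**3,
            "magnet_without_ball": 4 / 3 * math.pi * d.magnet_radius**3,
            "rotating_construct": 2 * math.pi**2 * d.ring_radius * d.ring_tube_radius**2,
            "rhs_marker": 4 / 3 * math.pi * d.rhs_radius**3,
            "distal_tip": math.pi * d.tip_radius**2 * d.tip_length
            + 4 / 3 * math.pi * d.tip_radius**3,
        }
        tolerances = {
            "magnet_with_ball": 0.2,
            "magnet_without_ball": 0.2,
            "rotating_construct": 0.2,
            "rhs_marker": 0.5,
            "distal_tip": 0.5,
        }
        _, labels, _ = make_phantom(PhantomSpec(setting=3, rotation_deg=(15, 40, -25), seed=9))
        measured = marker_centroids(labels)
        for name, volume in analytic.items():
            expected = volume / voxel
            count = measured.voxel_counts[name]
            assert abs(count - expected) / expected <= tolerances[name], (
                f"{name}: {count} voxels vs analytic {expected:.1f}"
            )

    def test_custom_dimensions_respected(self):
        dims = ValveDimensions(tip_offset=20.0)
        _, _, truth = make_phantom(PhantomSpec(setting=4, seed=0, noise_sd=0.0), dims)
        rc = truth.markers.get("rotating_construct")
        tip = truth.markers.get("distal_tip")
        assert np.linalg.norm(tip - rc) == pytest.approx(20.0, abs=1e-9)


class TestCohorts:
    def test_one_hot_weights(self):
        plans = plan_cohort(12, setting_weights=[0, 0, 0, 0, 1, 0, 0, 0], seed=5)
        assert all(p["truth_setting"] == 5 for p in plans)
        for p in plans:
            lo, hi = (5 - 3) * 45.0, (5 - 2) * 45.0
            assert lo <= p["truth_angle_deg"] < hi

    def test_identical_seeds_identical_manifests(self):
        a = cohort_manifest(plan_cohort(30, seed=7))
        b = cohort_manifest(plan_cohort(30, seed=7))
        assert a.equals(b)

    def test_setting_histogram_matches_weights(self):
        """Empirical histogram is within multinomial sampling error of weights."""
        weights = np.array([3, 8, 12, 25, 15, 9, 5, 3], dtype=float)
        n = 300
        plans = plan_cohort(n, setting_weights=weights, seed=7)
        observed = np.bincount([p["truth_setting"] for p in plans], minlength=9)[1:]
        expected = weights / weights.sum() * n
        _, p_value = stats.chisquare(observed, expected)
        assert p_value > 1e-3

    def test_invalid_cohort_args(self):
        with pytest.raises(ValueError):
            plan_cohort(0)
        with pytest.raises(ValueError):
            plan_cohort(5, setting_weights=[1, 2, 3])
        with pytest.raises(ValueError):
            plan_cohort(5, setting_weights=[0] * 8)

    def test_make_cohort_returns_cases_and_manifest(self):
        cases, manifest = make_cohort(
            3, seed=2, base=PhantomSpec(setting=4, noise_sd=0.0),
            pose_jitter=PoseJitter(max_rotation_deg=30.0, max_translation_mm=1.0),
        )
        assert len(cases) == 3 and len(manifest) == 3
        for (grid, labels, truth), row in zip(cases, manifest.itertuples()):
            assert truth.truth_setting == row.truth_setting
            assert predict_from_labelmap(labels).status == "ok"


class TestGroupedSplit:
    def test_groups_never_straddle_the_split(self):
        import pandas as pd

        rows = []
        for patient, size in [("A", 3), ("B", 3), ("C", 2), ("D", 2)]:
            rows += [{"case_id": f"{patient}{i}", "patient_id": patient} for i in range(size)]
        manifest = pd.DataFrame(rows)
        out = grouped_split(manifest, train_fraction=0.8, seed=0)
        spans = out.groupby("patient_id")["split"].nunique()
        assert (spans == 1).all()
        assert set(out["split"]) == {"train", "test"}

    def test_split_fraction_roughly_honoured(self):
        manifest = cohort_manifest(plan_cohort(80, seed=1))
        out = grouped_split(manifest, train_fraction=0.8, seed=3)
        frac = (out["split"] == "train").mean()
        assert 0.7 <= frac <= 0.95

    def test_invalid_fraction(self):
        manifest = cohort_manifest(plan_cohort(5, seed=0))
        with pytest.raises(ValueError):
            grouped_split(manifest, train_fraction=1.0)
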