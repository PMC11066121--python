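import numpy as np
import pytest

from emnav.errors import InvalidParams, WrongRole
from emnav.geometry import Point3, Pose6DoF, UnitQuaternion
from emnav.registration import horn_register
from emnav.tracking import (
    GroundTruth,
    NoiseModel,
    TrackingVolume,
    digitize_fiducials,
    read_session_log,
    sample_noisy_pose,
    simulate_pointer_touch,
    simulate_target_approach,
    stage_rng,
    stage_seed,
    write_session_log,
)

ZERO = NoiseModel.zero()


@pytest.fixture(scope="module")
def truth(default_phantom):
    return GroundTruth.build(default_phantom, seed=11)


def _pose(x=0.0, y=0.0, z=300.0):
    return Pose6DoF(Point3(x, y, z), UnitQuaternion.identity())


class TestSeedSplitting:
    def test_stage_seeds_differ_between_stages(self):
        assert stage_seed(1, "phantom") != stage_seed(1, "placement")

    def test_stage_seed_below_2_31(self):
        assert 0 <= stage_seed(123456, "approach") < 2**31

    def test_stage_rng_reproducible(self):
        a = stage_rng(5, "x").normal(size=4)
        b = stage_rng(5, "x").normal(size=4)
        assert np.array_equal(a, b)


class TestSampleNoisyPose:
    def test_zero_noise_leaves_pose_unchanged(self):
        pose = _pose()
        s = sample_noisy_pose(pose, ZERO, np.random.default_rng(0))
        assert s.pose.position == pose.position
        assert np.allclose(s.pose.orientation.as_array(), (1, 0, 0, 0))
        assert s.valid

    def test_positional_noise_rms_matches_chi_expectation(self):
        # per-axis sigma 0.2 -> RMS 3-D offset 0.2 * sqrt(3)
        pose = _pose()
        rng = np.random.default_rng(42)
        noise = NoiseModel(sigma_pos=0.2, sigma_rot_deg=0.0, operator_sigma=0.0)
        offsets = [
            np.linalg.norm(
                sample_noisy_pose(pose, noise, rng).pose.position.as_array()
                - pose.position.as_array()
            )
            for _ in range(10_000)
        ]
        rms = np.sqrt(np.mean(np.square(offsets)))
        assert rms == pytest.approx(0.2 * np.sqrt(3.0), rel=0.03)

    def test_orientation_noise_is_a_valid_rotation(self):
        pose = _pose()
        noise = NoiseModel(sigma_pos=0.0, sigma_rot_deg=5.0, operator_sigma=0.0)
        s = sample_noisy_pose(pose, noise, np.random.default_rng(1))
        assert np.linalg.norm(s.pose.orientation.as_array()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_outside_volume_flagged_invalid(self):
        s = sample_noisy_pose(_pose(z=900.0), ZERO, np.random.default_rng(0))
        assert not s.valid

    def test_custom_volume_extents(self):
        vol = TrackingVolume(min_corner=(-1, -1, -1), max_corner=(1, 1, 1))
        s = sample_noisy_pose(_pose(z=0.0), ZERO, np.random.default_rng(0), vol)
        assert s.valid


class TestPointerTouch:
    def test_zero_noise_maps_fiducial_through_inverse(self, truth):
        fid = truth.phantom.fiducials[0]
        p = simulate_pointer_touch(fid, truth, ZERO, np.random.default_rng(0))
        back = truth.tracking_to_image.apply(p)
        assert np.allclose(back.as_array(), fid.position.as_array(), atol=1e-9)

    def test_target_marker_rejected(self, truth):
        target = truth.phantom.targets[0]
        with pytest.raises(WrongRole):
            simulate_pointer_touch(target, truth, ZERO, np.random.default_rng(0))

    def test_noise_free_digitization_registers_to_truth(self, truth):
        pairs = digitize_fiducials(truth, ZERO, np.random.default_rng(0))
        res = horn_register(pairs)
        assert np.allclose(
            res.transform.matrix(), truth.tracking_to_image.matrix(), atol=1e-9
        )
        assert res.fre == pytest.approx(0.0, abs=1e-9)

    def test_subset_digitization(self, truth):
        pairs = digitize_fiducials(
            truth, ZERO, np.random.default_rng(0), ids=["F1", "F2", "F3"]
        )
        assert pairs.ids == ("F1", "F2", "F3")


class TestTargetApproach:
    def test_sample_count_is_duration_times_rate(self, truth):
        samples = simulate_target_approach(
            truth.phantom.targets[0], truth, ZERO, duration=2.0, rate=25.0,
            rng=np.random.default_rng(0),
        )
        assert len(samples) == 50
        times = [s.t for s in samples]
        assert times == sorted(times)

    def test_zero_noise_final_tip_hits_target_exactly(self, truth):
        for target in truth.phantom.targets:
            samples = simulate_target_approach(
                target, truth, ZERO, duration=1.0, rate=20.0,
                rng=np.random.default_rng(0),
            )
            final = samples[-1]
            tip_track = final.pose.tip(5.0)
            tip_image = truth.tracking_to_image.apply(tip_track)
            assert np.allclose(
                tip_image.as_array(), target.position.as_array(), atol=1e-9
            )

    def test_operator_error_follows_chi_distribution_mean(self, truth):
        # mean final tip-to-target distance for per-axis sigma s is the
        # chi(3) mean: s * sqrt(2) * Gamma(2) / Gamma(3/2) = 1.5958 s
        noise = NoiseModel(sigma_pos=0.0, sigma_rot_deg=0.0, operator_sigma=1.5)
        rng = np.random.default_rng(77)
        target = truth.phantom.targets[0]
        dists = []
        for _ in range(1000):
            samples = simulate_target_approach(
                target, truth, noise, duration=0.5, rate=4.0, rng=rng
            )
            tip = truth.tracking_to_image.apply(samples[-1].pose.tip(5.0))
            dists.append(tip.distance_to(target.position))
        assert np.mean(dists) == pytest.approx(1.5 * 1.5957691, rel=0.05)

    def test_deterministic_given_seeded_rng(self, truth):
        noise = NoiseModel()
        runs = []
        for _ in range(2):
            samples = simulate_target_approach(
                truth.phantom.targets[2], truth, noise, duration=1.0, rate=10.0,
                rng=np.random.default_rng(123),
            )
            runs.append([s.to_json_dict() for s in samples])
        assert runs[0] == runs[1]

    def test_invalid_duration_or_role(self, truth):
        with pytest.raises(InvalidParams):
            simulate_target_approach(
                truth.phantom.targets[0], truth, ZERO, duration=0.0, rate=10.0,
                rng=np.random.default_rng(0),
            )
        with pytest.raises(WrongRole):
            simulate_target_approach(
                truth.phantom.fiducials[0], truth, ZERO, duration=1.0, rate=10.0,
                rng=np.random.default_rng(0),
            )


class TestSessionLog:
    def test_json_lines_round_trip(self, truth, tmp_path):
        samples = simulate_target_approach(
            truth.phantom.targets[0], truth, NoiseModel(), duration=1.0, rate=10.0,
            rng=np.random.default_rng(3),
        )
        path = tmp_path / "session.jsonl"
        write_session_log(samples, path)
        back = read_session_log(path)
        assert len(back) == len(samples)
        for a, b in zip(samples, back):
            assert a.t == b.t and a.valid == b.valid
            assert np.allclose(
                a.pose.position.as_array(), b.pose.position.as_array()
            )
            assert np.allclose(
                a.pose.orientation.as_array(), b.pose.orientation.as_array()
            )
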