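import numpy as np
import pytest

from emnav.errors import CountMismatch, DegenerateFiducials, EmptyInput
from emnav.geometry import random_rigid_transform
from emnav.registration import (
    FiducialPairSet,
    RegistrationResult,
    check_fiducial_geometry,
    compute_fre,
    horn_register,
    monte_carlo_fre,
    monte_carlo_tre,
)

from conftest import kabsch


def _random_points(seed, n=6, scale=100.0):
    return np.random.default_rng(seed).uniform(-scale, scale, (n, 3))


def _pairs(moving, fixed):
    ids = tuple(f"F{i}" for i in range(len(moving)))
    return FiducialPairSet(ids, moving, fixed)


class TestComputeFre:
    @pytest.mark.parametrize(
        "residuals, expected",
        [
            (np.zeros((4, 3)), 0.0),
            ([(3, 0, 0), (0, 4, 0)], np.sqrt((9 + 16) / 2)),
            ([(1, 0, 0), (0, 1, 0), (0, 0, 1)], 1.0),
        ],
    )
    def test_rms_of_residual_norms(self, residuals, expected):
        assert compute_fre(residuals) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInput):
            compute_fre(np.empty((0, 3)))


class TestFiducialGeometry:
    def test_collinear_flagged(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
        assert not check_fiducial_geometry(line).ok

    def test_triangle_ok(self):
        assert check_fiducial_geometry([(0, 0, 0), (1, 0, 0), (0, 1, 0)]).ok

    def test_random_constellation_ok(self):
        assert check_fiducial_geometry(_random_points(3)).ok

    def test_too_few_points(self):
        with pytest.raises(CountMismatch):
            check_fiducial_geometry([(0, 0, 0), (1, 1, 1)])


class TestPairSet:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(CountMismatch):
            FiducialPairSet(("a", "b", "c"), np.zeros((3, 3)), np.zeros((4, 3)))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(CountMismatch):
            FiducialPairSet(("a", "b"), np.zeros((2, 3)), np.zeros((2, 3)))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(CountMismatch):
            FiducialPairSet(("a", "a", "b"), np.zeros((3, 3)), np.zeros((3, 3)))

    def test_subset_by_id(self):
        pts = _random_points(0)
        ps = _pairs(pts, pts)
        sub = ps.subset(["F1", "F3", "F5"])
        assert sub.ids == ("F1", "F3", "F5")
        assert np.allclose(sub.moving, pts[[1, 3, 5]])

    def test_csv_round_trip(self, tmp_path):
        pts = _random_points(1)
        ps = _pairs(pts, pts + 2.0)
        path = tmp_path / "pairs.csv"
        ps.to_csv(path)
        back = FiducialPairSet.from_csv(path)
        assert back.ids == ps.ids
        assert np.allclose(back.moving, ps.moving, atol=1e-5)
        assert np.allclose(back.fixed, ps.fixed, atol=1e-5)


class TestHornRegister:
    def test_identity_when_sets_coincide(self):
        pts = _random_points(2, n=4)
        res = horn_register(_pairs(pts, pts))
        assert np.allclose(res.transform.matrix(), np.eye(4), atol=1e-12)
        assert res.fre == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        pts = _random_points(3, n=4)
        res = horn_register(_pairs(pts + np.array([10.0, 0.0, 0.0]), pts))
        assert np.allclose(
            res.transform.translation.as_array(), (-10, 0, 0), atol=1e-9
        )
        assert res.fre == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_recovery_of_known_transform(self, seed):
        T = random_rigid_transform(seed)
        moving = _random_points(seed + 1000)
        fixed = T.transform_points(moving)
        res = horn_register(_pairs(moving, fixed))
        assert np.allclose(res.transform.matrix(), T.matrix(), atol=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_svd_oracle_on_noisy_data(self, seed):
        rng = np.random.default_rng(seed)
        moving = _random_points(seed)
        T = random_rigid_transform(seed)
        fixed = T.transform_points(moving) + rng.normal(0, 1.0, moving.shape)
        res = horn_register(_pairs(moving, fixed))
        R, t = kabsch(moving, fixed)
        assert np.allclose(res.transform.matrix()[:3, :3], R, atol=1e-9)
        assert np.allclose(res.transform.translation.as_array(), t, atol=1e-9)

    def test_registration_direction_moving_to_fixed(self):
        T = random_rigid_transform(5)
        moving = _random_points(5)
        fixed = T.transform_points(moving)
        res = horn_register(_pairs(moving, fixed))
        mapped = res.transform.transform_points(moving)
        assert np.allclose(mapped, fixed, atol=1e-9)

    def test_fre_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(9)
        moving = _random_points(9)
        fixed = moving + rng.normal(0, 0.5, moving.shape)
        base = horn_register(_pairs(moving, fixed)).fre
        for seed in range(10):
            Q = random_rigid_transform(seed)
            moved = horn_register(
                _pairs(Q.transform_points(moving), Q.transform_points(fixed))
            ).fre
            assert moved == pytest.approx(base, abs=1e-9)

    def test_collinear_fiducials_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateFiducials):
            horn_register(_pairs(line, line))

    def test_residual_fre_consistency(self):
        rng = np.random.default_rng(12)
        moving = _random_points(12)
        fixed = moving + rng.normal(0, 0.3, moving.shape)
        res = horn_register(_pairs(moving, fixed))
        assert res.fre == pytest.approx(compute_fre(res.residuals), abs=1e-12)

    def test_subset_restricts_fit(self):
        pts = _random_points(4)
        res = horn_register(_pairs(pts, pts), subset=["F0", "F2", "F4"])
        assert res.ids == ("F0", "F2", "F4")
        assert len(res.residuals) == 3


class TestMonteCarlo:
    def test_tre_zero_noise_is_zero(self, identity_pairs, centroid_target):
        assert monte_carlo_tre(identity_pairs, centroid_target, 0.0, 100, 1) == 0.0

    def test_tre_deterministic_in_seed(self, identity_pairs, centroid_target):
        a = monte_carlo_tre(identity_pairs, centroid_target, 0.3, 500, 42)
        b = monte_carlo_tre(identity_pairs, centroid_target, 0.3, 500, 42)
        assert a == b

    def test_fre_and_tre_monotone_in_sigma(self, identity_pairs, centroid_target):
        sigmas = [0.0, 0.1, 0.3, 1.0]
        fres = [monte_carlo_fre(identity_pairs, s, 2000, 7) for s in sigmas]
        tres = [
            monte_carlo_tre(identity_pairs, centroid_target, s, 2000, 7)
            for s in sigmas
        ]
        assert fres == sorted(fres)
        assert tres == sorted(tres)

    def test_invalid_arguments(self, identity_pairs, centroid_target):
        with pytest.raises(ValueError):
            monte_carlo_tre(identity_pairs, centroid_target, -0.1, 10, 0)
        with pytest.raises(ValueError):
            monte_carlo_tre(identity_pairs, centroid_target, 0.1, 0, 0)


class TestRegistrationResultCsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        moving = _random_points(3)
        T = random_rigid_transform(3)
        fixed = T.transform_points(moving) + rng.normal(0, 0.3, moving.shape)
        res = horn_register(_pairs(moving, fixed))
        path = tmp_path / "reg.csv"
        res.to_csv(path)
        back = RegistrationResult.from_csv(path)
        assert np.allclose(back.transform.matrix(), res.transform.matrix(), atol=1e-9)
        assert back.fre == pytest.approx(res.fre, abs=1e-9)
        assert np.allclose(back.residuals, res.residuals, atol=1e-9)
        assert back.ids == res.ids
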