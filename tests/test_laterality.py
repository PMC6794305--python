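"""Sign restriction, hemisphere folding, laterality maps and ROI extraction."""

import numpy as np
import pytest

from emocert import laterality as lat

GRID = (8, 6, 4)


def _vol(data, **kw):
    return lat.StatVolume(data=data, **kw)


def _random_vol(rng, grid=GRID):
    return _vol(rng.normal(size=grid))


class TestSignRestrict:
    def test_all_positive_activation_is_identity(self):
        v = _vol(np.abs(np.random.default_rng(0).normal(size=GRID)) + 0.1)
        out = lat.sign_restrict(v, "activation")
        assert np.array_equal(out.data, v.data)

    def test_partition_identity(self, rng):
        v = _random_vol(rng)
        act = lat.sign_restrict(v, "activation")
        deact = lat.sign_restrict(v, "deactivation")
        assert np.array_equal(act.data + deact.data, v.data)
        assert np.all(act.data >= 0) and np.all(deact.data <= 0)

    def test_deactivation_example(self):
        v = _vol(np.array([-2.0, 0.0, 3.0]).reshape(1, 1, 3).repeat(2, axis=0))
        out = lat.sign_restrict(v, "deactivation")
        assert np.array_equal(out.data[0, 0], [-2.0, 0.0, 0.0])

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            lat.sign_restrict(_random_vol(rng), "both")


class TestFold:
    def test_mirror_symmetric_volume_halves_identical(self, rng):
        half = rng.normal(size=(4, 6, 4))
        v = _vol(np.concatenate([half, half[::-1]], axis=0))
        left, right = lat.fold_hemispheres(v)
        assert np.array_equal(left, right)

    def test_impulse_lands_at_mirrored_index(self):
        data = np.zeros(GRID)
        data[6, 2, 1] = 5.0  # right hemisphere voxel (x >= 4)
        left, right = lat.fold_hemispheres(_vol(data))
        assert right[8 - 1 - 6, 2, 1] == 5.0
        assert not np.any(left)

    def test_fold_of_mirrored_volume_swaps_halves(self, rng):
        v = _random_vol(rng)
        l1, r1 = lat.fold_hemispheres(v)
        l2, r2 = lat.fold_hemispheres(lat.mirror(v))
        assert np.array_equal(l2, r1) and np.array_equal(r2, l1)

    def test_odd_extent_rejected(self):
        with pytest.raises(lat.SpaceError):
            lat.fold_hemispheres(_vol(np.zeros((7, 6, 4))))

    def test_wrong_space_tag_rejected(self):
        with pytest.raises(lat.SpaceError):
            lat.laterality_map(_vol(np.zeros(GRID), space="native"), "activation")


class TestLateralityMap:
    def test_symmetric_volume_zero_in_both_modes(self, rng):
        half = rng.normal(size=(4, 6, 4))
        v = _vol(np.concatenate([half, half[::-1]], axis=0))
        for mode in ("activation", "deactivation"):
            assert not np.any(lat.laterality_map(v, mode).data)

    def test_activation_hand_example(self):
        data = np.zeros(GRID)
        data[6, 2, 1] = 3.0  # right ROI voxel
        data[1, 2, 1] = 1.0  # mirrored left voxel
        out = lat.laterality_map(_vol(data), "activation")
        assert out.data[1, 2, 1] == pytest.approx(2.0)  # right-leaning

    def test_deactivation_hand_example(self):
        data = np.zeros(GRID)
        data[6, 2, 1] = -3.0
        data[1, 2, 1] = -1.0
        out = lat.laterality_map(_vol(data), "deactivation")
        # negative => right-lateralized deactivation per convention
        assert out.data[1, 2, 1] == pytest.approx(-2.0)
        assert "right" in out.convention

    def test_mirror_antisymmetry(self, rng):
        v = _vol(np.abs(rng.normal(size=GRID)))  # positive so restriction is identity
        fwd = lat.laterality_map(v, "activation").data
        rev = lat.laterality_map(lat.mirror(v), "activation").data
        assert np.allclose(rev, -fwd)


def _ball_mask(grid, center, r, n_target=None):
    ix = np.indices(grid, dtype=float)
    d2 = sum((ix[a] - center[a]) ** 2 for a in range(3))
    prob = np.where(d2 <= r * r, 1.0, 0.0)
    if n_target is not None:
        flat = np.argsort(d2.ravel())[:n_target]
        prob = np.zeros(np.prod(grid))
        prob[flat] = 1.0
        prob = prob.reshape(grid)
    return prob


class TestExtractROI:
    GRID = (16, 16, 12)

    def test_uniform_volume_mean(self):
        prob = _ball_mask(self.GRID, (4, 8, 6), 4, n_target=150)
        mask = lat.ROIMask(prob=prob, name="LB", hemisphere="left")
        out = lat.extract_roi(_vol(np.full(self.GRID, 2.5)), mask)
        assert out.mean == pytest.approx(2.5)
        assert out.valid

    @pytest.mark.parametrize("n,valid", [(99, False), (100, True)])
    def test_min_voxel_boundary(self, n, valid):
        prob = _ball_mask(self.GRID, (4, 8, 6), 4, n_target=n)
        mask = lat.ROIMask(prob=prob, name="CM", hemisphere="left")
        out = lat.extract_roi(_vol(np.zeros(self.GRID)), mask)
        assert out.n_voxels == n
        assert out.valid is valid

    def test_planted_effect_recovery(self):
        rng = np.random.default_rng(21)
        prob = _ball_mask(self.GRID, (4, 8, 6), 5, n_target=500)
        mask = lat.ROIMask(prob=prob, name="SP", hemisphere="left")
        data = rng.normal(0.0, 1.0, size=self.GRID)
        data[prob >= 0.95] += 3.0
        out = lat.extract_roi(_vol(data), mask)
        se = 1.0 / np.sqrt(500)
        assert abs(out.mean - 3.0) < 3 * se

    def test_grid_mismatch_rejected(self):
        mask = lat.ROIMask(prob=np.ones((4, 4, 4)), name="LB")
        with pytest.raises(ValueError):
            lat.extract_roi(_vol(np.zeros(self.GRID)), mask)

    def test_laterality_volume_extraction_and_leaning(self):
        data = np.zeros(self.GRID)
        prob = np.zeros(self.GRID)
        prob[2:7, 4:12, 2:10] = 1.0  # left-hemisphere ROI, 320 voxels
        data[2:7, 4:12, 2:10] = 1.0  # left activation
        data[9:14, 4:12, 2:10] = 3.0  # mirrored right activation
        lmap = lat.laterality_map(_vol(data), "activation")
        mask = lat.ROIMask(prob=prob, name="LB", hemisphere="left")
        out = lat.extract_roi(lmap, mask)
        assert out.mean == pytest.approx(2.0)
        assert out.leaning == "right"
        assert out.valid


class TestSexContrast:
    def test_identical_groups_zero_and_antisymmetry(self, rng):
        vols = [_random_vol(rng, (8, 8, 6)) for _ in range(3)]
        diff, _ = lat.sex_contrast(vols, vols)
        assert np.allclose(diff.data, 0.0)
        other = [_random_vol(rng, (8, 8, 6)) for _ in range(3)]
        d1, _ = lat.sex_contrast(vols, other)
        d2, _ = lat.sex_contrast(other, vols)
        assert np.allclose(d1.data, -d2.data)

    def test_planted_female_effect_confined_to_roi(self):
        rng = np.random.default_rng(3)
        grid = (16, 16, 12)
        prob = np.zeros(grid)
        prob[10:13, 6:10, 4:8] = 1.0  # right AMG stand-in
        mask = lat.ROIMask(prob=prob, name="LB", hemisphere="right", min_voxels=10)
        f = [
            _vol(rng.normal(0, 0.1, grid) + np.where(prob >= 0.95, 2.0, 0.0))
            for _ in range(4)
        ]
        m = [_vol(rng.normal(0, 0.1, grid)) for _ in range(4)]
        diff, stats = lat.sex_contrast(f, m, masks=[mask])
        inside = diff.data[prob >= 0.95].mean()
        outside = np.abs(diff.data[prob < 0.95]).mean()
        assert inside > 1.5 and outside < 0.2
        assert float(stats["p"].iloc[0]) < 0.01

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            lat.sex_contrast([_random_vol(rng)], [_random_vol(rng), _random_vol(rng)])


class TestNiftiIO:
    def test_roundtrip(self, tmp_path, rng):
        v = _vol(rng.normal(size=GRID), voxel_size=(2.0, 2.0, 3.0))
        p = tmp_path / "vol.nii.gz"
        lat.write_volume(p, v)
        back = lat.read_volume(p)
        assert back.data.shape == GRID
        assert back.voxel_size == (2.0, 2.0, 3.0)
        assert np.allclose(back.data, v.data, atol=1e-6)
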