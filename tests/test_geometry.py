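"""Voxel-mask geometry: volume, area, sphericity, distances, intensity."""

import numpy as np
import pytest

import testisx as tx
from testisx.geometry import ball_mask


def prolate_area(a, c):
    """Analytic surface area of a prolate spheroid with semi-axes a=b < c."""
    e = np.sqrt(1 - (a / c) ** 2)
    return 2 * np.pi * a**2 * (1 + c / (a * e) * np.arcsin(e))


class TestMaskMetrics:
    def test_single_voxel_volume(self):
        mask = tx.VoxelMask(np.ones((1, 1, 1)), (1.0, 1.0, 1.0))
        v, a = tx.mask_metrics(mask)
        assert v == 1.0 and a > 0

    def test_ball_volume_within_five_percent(self):
        v, _ = tx.mask_metrics(ball_mask(10))
        assert v == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_ball_area_within_five_percent(self):
        _, a = tx.mask_metrics(ball_mask(10))
        assert a == pytest.approx(4 * np.pi * 100, rel=0.05)

    def test_convergence_with_resolution(self):
        # rel. error of V and A shrinks as voxels per radius grow
        errors = []
        for r in (5, 10, 20):
            v, a = tx.mask_metrics(ball_mask(r))
            errors.append(
                abs(a - 4 * np.pi * r**2) / (4 * np.pi * r**2)
                + abs(v - 4 / 3 * np.pi * r**3) / (4 / 3 * np.pi * r**3)
            )
        assert errors[2] < errors[0]

    def test_anisotropic_voxels_respected(self):
        mask = tx.VoxelMask(np.ones((2, 2, 2)), (2.0, 1.0, 1.0))
        v, _ = tx.mask_metrics(mask)
        assert v == 8 * 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            tx.mask_metrics(tx.VoxelMask(np.zeros((3, 3, 3))))


class TestSphericity:
    def test_sphere_is_one(self):
        r = 3.7
        v, a = 4 / 3 * np.pi * r**3, 4 * np.pi * r**2
        assert tx.sphericity(v, a) == pytest.approx(1.0)

    def test_cube_closed_form(self):
        s = 5.0
        assert tx.sphericity(s**3, 6 * s**2) == pytest.approx(
            (np.pi / 6) ** (1 / 3)
        )

    def test_digitized_shapes_at_most_one_plus_eps(self):
        for mask in (ball_mask(10), ball_mask(15)):
            v, a = tx.mask_metrics(mask)
            assert tx.sphericity(v, a) <= 1.02

    def test_elongation_strictly_decreases_sphericity(self):
        # fixed volume prolate spheroids: psi falls as the aspect ratio grows
        volume = 4 / 3 * np.pi  # unit sphere volume
        psis = []
        for ratio in (1.0001, 1.5, 2.5, 4.0, 8.0):
            a = (1 / ratio) ** (1 / 3)
            c = a * ratio
            psis.append(tx.sphericity(volume, prolate_area(a, c)))
        assert all(x > y for x, y in zip(psis, psis[1:]))
        assert psis[0] == pytest.approx(1.0, abs=1e-4)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            tx.sphericity(0.0, 1.0)


class TestCorrectedVolume:
    def test_unit_density(self):
        assert tx.corrected_volume(22.3, 22.3) == pytest.approx(1.0)

    def test_copy_number_correction(self):
        assert tx.corrected_volume(10.0, 22.7, copy_number=2) == pytest.approx(
            0.22026, rel=1e-3
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tx.corrected_volume(1.0, 0.0)
        with pytest.raises(ValueError):
            tx.corrected_volume(1.0, 22.3, copy_number=0)


class TestMinEdgeDistance:
    @staticmethod
    def _mask(coords, shape=(9, 9, 9), vs=(1.0, 1.0, 1.0)):
        return tx.VoxelMask.from_coordinates(coords, shape, vs)

    def test_overlap_gives_zero(self):
        a = self._mask([(1, 1, 1), (1, 1, 2)])
        b = self._mask([(1, 1, 2), (1, 1, 3)])
        assert tx.min_edge_distance(a, b) == 0.0

    def test_axis_separation(self):
        a = self._mask([(1, 1, 1)])
        b = self._mask([(1, 1, 4)])
        assert tx.min_edge_distance(a, b) == pytest.approx(3.0)

    def test_anisotropic_z_spacing(self):
        vs = (2.0, 1.0, 1.0)
        a = self._mask([(1, 1, 1)], vs=vs)
        b = self._mask([(2, 1, 1)], vs=vs)
        assert tx.min_edge_distance(a, b) == pytest.approx(2.0)

    def test_symmetry_and_triangle_inequality(self):
        a = self._mask([(0, 0, 0)])
        b = self._mask([(0, 4, 0), (0, 4, 1)])
        c = self._mask([(6, 4, 4)])
        dab = tx.min_edge_distance(a, b)
        assert dab == tx.min_edge_distance(b, a)
        assert tx.min_edge_distance(a, c) <= dab + tx.min_edge_distance(b, c)

    def test_grid_mismatch_rejected(self):
        a = self._mask([(0, 0, 0)])
        b = tx.VoxelMask.from_coordinates([(0, 0, 0)], (4, 4, 4))
        with pytest.raises(ValueError):
            tx.min_edge_distance(a, b)


class TestTerritoryIntensityRatio:
    @staticmethod
    def _setup():
        shape = (6, 6, 6)
        territory = tx.VoxelMask.from_coordinates([(1, 1, 1), (1, 1, 2)], shape)
        auto1 = tx.VoxelMask.from_coordinates([(3, 3, 3), (3, 3, 4)], shape)
        auto2 = tx.VoxelMask.from_coordinates([(4, 1, 1), (4, 1, 2)], shape)
        background = tx.VoxelMask.from_coordinates([(5, 5, 5)], shape)
        return shape, territory, (auto1, auto2), background

    def test_identical_composition_gives_zero(self):
        shape, terr, autos, bg = self._setup()
        total = np.full(shape, 10.0)
        signal = 0.4 * total  # same signal share in every territory
        total[bg.grid] = 2.0  # dim background with the same composition
        signal[bg.grid] = 0.8
        ratio = tx.territory_intensity_ratio(signal, total, terr, autos, bg)
        assert ratio == pytest.approx(0.0, abs=1e-9)

    def test_halved_signal_gives_minus_one(self):
        shape, terr, autos, bg = self._setup()
        total = np.full(shape, 10.0)
        signal = np.full(shape, 4.0)
        signal[terr.grid] = 2.0
        signal[bg.grid] = 0.0
        total[bg.grid] = 0.0
        ratio = tx.territory_intensity_ratio(signal, total, terr, autos, bg)
        assert ratio == pytest.approx(-1.0)

    def test_background_equal_to_total_is_missing(self):
        shape, terr, autos, bg = self._setup()
        total = np.full(shape, 10.0)
        signal = np.full(shape, 5.0)
        with pytest.warns(UserWarning):
            ratio = tx.territory_intensity_ratio(signal, total, terr, autos, bg)
        assert np.isnan(ratio)

    def test_grid_mismatch_rejected(self):
        shape, terr, autos, bg = self._setup()
        with pytest.raises(ValueError):
            tx.territory_intensity_ratio(
                np.zeros((3, 3, 3)), np.zeros((3, 3, 3)), terr, autos, bg
            )
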