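import numpy as np
import pytest

from eegtopo.features import FeatureFrame
from eegtopo.montage_layout import (
    DEFAULT_60_LABELS,
    DEFAULT_64_LABELS,
    SMALL_16_LABELS,
    standard_positions,
)
from eegtopo.topomap import (
    IdentityNormalizer,
    ImageSequence,
    MinMaxNormalizer,
    Montage,
    TopoImage,
    aep_project,
    assemble_rgb,
    default_montage,
    interpolate_grid,
    make_sequence,
)


def random_montage(n=20, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n, 3))
    pos[:, 2] = np.abs(pos[:, 2])  # upper hemisphere
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage([f"e{i}" for i in range(n)], pos)


class TestMontage:
    def test_standard_positions_are_unit(self):
        pos = standard_positions(DEFAULT_64_LABELS)
        np.testing.assert_allclose(np.linalg.norm(pos, axis=1), 1.0, atol=1e-9)

    def test_vertex_at_apex(self):
        pos = standard_positions(["Cz"])
        np.testing.assert_allclose(pos[0], [0.0, 0.0, 1.0], atol=1e-12)

    def test_left_right_symmetry(self):
        pos = standard_positions(["F3", "F4"])
        assert pos[0, 0] == pytest.approx(-pos[1, 0])  # mirrored across midline
        assert pos[0, 1] == pytest.approx(pos[1, 1])
        assert pos[0, 2] == pytest.approx(pos[1, 2])

    def test_frontal_is_anterior(self):
        pos = dict(zip(["Fpz", "Oz"], standard_positions(["Fpz", "Oz"])))
        assert pos["Fpz"][1] > 0 > pos["Oz"][1]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Montage(["a", "a"], np.array([[0, 0, 1.0], [0, 1.0, 0]]))

    def test_non_unit_position_rejected(self):
        with pytest.raises(ValueError, match="unit sphere"):
            Montage(["a"], np.array([[0.0, 0.0, 2.0]]))

    def test_json_round_trip(self, tmp_path):
        m = default_montage(SMALL_16_LABELS)
        m.to_json(tmp_path / "m.json")
        back = Montage.from_json(tmp_path / "m.json")
        assert back.labels == m.labels
        np.testing.assert_allclose(back.positions3d, m.positions3d)

    def test_subset_preserves_order(self):
        m = default_montage(SMALL_16_LABELS)
        sub = m.subset(["Cz", "Fp1"])
        assert sub.labels == ["Cz", "Fp1"]


class TestAepProject:
    def test_apex_maps_to_origin(self):
        m = Montage(["apex"], np.array([[0.0, 0.0, 1.0]]))
        aep_project(m)
        np.testing.assert_allclose(m.positions2d[0], [0.0, 0.0], atol=1e-12)

    def test_equator_point_closed_form(self):
        m = Montage(["eq"], np.array([[1.0, 0.0, 0.0]]))
        aep_project(m)
        np.testing.assert_allclose(m.positions2d[0], [np.pi / 2, 0.0], atol=1e-12)

    def test_planar_radius_proportional_to_arc(self):
        m = aep_project(random_montage(40, seed=3))
        arcs = np.arccos(np.clip(m.positions3d[:, 2], -1, 1))
        radii = np.linalg.norm(m.positions2d, axis=1)
        np.testing.assert_allclose(radii, arcs, atol=1e-9)

    def test_radial_ordering_preserved(self):
        m = aep_project(random_montage(30, seed=5))
        arcs = np.arccos(np.clip(m.positions3d[:, 2], -1, 1))
        radii = np.linalg.norm(m.positions2d, axis=1)
        np.testing.assert_array_equal(np.argsort(arcs), np.argsort(radii))


class TestInterpolateGrid:
    def test_output_is_32x32(self):
        m = default_montage(SMALL_16_LABELS)
        grid = interpolate_grid(m.positions2d, np.ones(16))
        assert grid.shape == (32, 32)

    def test_constant_field_reproduced(self):
        m = default_montage(DEFAULT_60_LABELS)
        grid = interpolate_grid(m.positions2d, np.full(60, 3.25))
        in_hull = grid != 0.0
        assert in_hull.sum() > 200
        np.testing.assert_allclose(grid[in_hull], 3.25, atol=1e-6)

    def test_linear_field_reproduced(self):
        m = default_montage(DEFAULT_60_LABELS)
        pts = m.positions2d
        values = 2.0 * pts[:, 0] - 1.5 * pts[:, 1] + 4.0
        grid = interpolate_grid(pts, values)
        # rebuild grid coordinates the same way to compare against the field
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        center = (lo + hi) / 2
        half = np.max(hi - lo) / 2 * 1.1
        xs = np.linspace(center[0] - half, center[0] + half, 32)
        ys = np.linspace(center[1] + half, center[1] - half, 32)
        gx, gy = np.meshgrid(xs, ys)
        expected = 2.0 * gx - 1.5 * gy + 4.0
        in_hull = grid != 0.0
        np.testing.assert_allclose(grid[in_hull], expected[in_hull], atol=1e-6)

    def test_interpolant_passes_through_data(self):
        from scipy.interpolate import CloughTocher2DInterpolator

        m = default_montage(SMALL_16_LABELS)
        rng = np.random.default_rng(0)
        values = rng.random(16)
        interp = CloughTocher2DInterpolator(m.positions2d, values)
        at_points = interp(m.positions2d)
        np.testing.assert_allclose(at_points, values, atol=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 6), np.linspace(0, 2, 6)])
        with pytest.raises(ValueError, match="collinear"):
            interpolate_grid(pts, np.ones(6))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            interpolate_grid(np.array([[0, 0], [1, 0], [0, 1.0]]), np.ones(3))

    def test_value_count_mismatch_rejected(self):
        m = default_montage(SMALL_16_LABELS)
        with pytest.raises(ValueError, match="one value per electrode"):
            interpolate_grid(m.positions2d, np.ones(5))

    def test_custom_grid_size(self):
        m = default_montage(SMALL_16_LABELS)
        assert interpolate_grid(m.positions2d, np.ones(16), grid_size=16).shape == (16, 16)


class TestNormalizers:
    def test_minmax_maps_to_unit_interval(self, rng):
        images = rng.standard_normal((10, 32, 32, 3)) * 5 + 2
        norm = MinMaxNormalizer().fit(images)
        out = norm.transform(images)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert out.max() == pytest.approx(1.0)

    def test_heldout_frames_clipped(self, rng):
        train = rng.random((5, 32, 32, 3))
        norm = MinMaxNormalizer().fit(train)
        held_out = rng.random((3, 32, 32, 3)) * 10 - 5
        out = norm.transform(held_out)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_degenerate_band_maps_to_zero(self):
        images = np.ones((4, 8, 8, 3))
        images[..., 1] = np.linspace(0, 1, 4)[:, None, None]
        norm = MinMaxNormalizer().fit(images)
        out = norm.transform(images)
        assert np.all(out[..., 0] == 0.0)  # constant band
        assert out[..., 1].max() == pytest.approx(1.0)

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="fitted"):
            MinMaxNormalizer().transform(np.zeros((2, 2, 3)))

    def test_identity_passthrough(self, rng):
        x = rng.standard_normal((4, 4, 3))
        np.testing.assert_array_equal(IdentityNormalizer().transform(x), x)


class TestAssembleRgb:
    def test_constant_grids_minmax_convention(self):
        grids = [np.full((8, 8), v) for v in (1.0, 2.0, 3.0)]
        norm = MinMaxNormalizer().fit(np.stack(grids, axis=-1))
        img = assemble_rgb(grids, norm)
        # per-band fit: each constant band is degenerate -> all zeros
        assert np.all(img.pixels == 0.0)

    def test_identity_keeps_unit_pixels(self, rng):
        grids = [rng.random((8, 8)) for _ in range(3)]
        img = assemble_rgb(grids, IdentityNormalizer())
        np.testing.assert_array_equal(img.pixels, np.stack(grids, axis=-1))

    def test_shape_mismatch_rejected(self):
        grids = [np.zeros((8, 8)), np.zeros((8, 8)), np.zeros((4, 4))]
        with pytest.raises(ValueError, match="mismatched"):
            assemble_rgb(grids, IdentityNormalizer())

    def test_wrong_band_count_rejected(self):
        with pytest.raises(ValueError, match="3 band grids"):
            assemble_rgb([np.zeros((8, 8))] * 2, IdentityNormalizer())


class TestMakeSequence:
    def frames(self, n_frames, n_channels, seed=0):
        rng = np.random.default_rng(seed)
        return [
            FeatureFrame(i, rng.random((n_channels, 3)), "fuzzyen") for i in range(n_frames)
        ]

    def test_six_frames_six_images(self):
        m = default_montage(SMALL_16_LABELS)
        seq = make_sequence(self.frames(6, 16), m, IdentityNormalizer(), trial_ref="t")
        assert len(seq.frames) == 6
        assert seq.as_array().shape == (6, 32, 32, 3)

    def test_single_frame(self):
        m = default_montage(SMALL_16_LABELS)
        seq = make_sequence(self.frames(1, 16), m, IdentityNormalizer())
        assert len(seq.frames) == 1

    def test_channel_mismatch_rejected(self):
        m = default_montage(SMALL_16_LABELS)
        with pytest.raises(ValueError, match="montage"):
            make_sequence(self.frames(2, 10), m, IdentityNormalizer())

    def test_unprojected_montage_rejected(self):
        m = Montage(list(SMALL_16_LABELS), standard_positions(SMALL_16_LABELS))
        with pytest.raises(ValueError, match="projected"):
            make_sequence(self.frames(1, 16), m, IdentityNormalizer())

    def test_permutation_invariance(self):
        # a generic (random) montage avoids co-circular points whose Delaunay
        # triangulation is permutation-dependent
        m = aep_project(random_montage(16, seed=21))
        frames = self.frames(2, 16, seed=9)
        seq = make_sequence(frames, m, IdentityNormalizer())

        perm = np.random.default_rng(0).permutation(16)
        m_perm = Montage([m.labels[i] for i in perm], m.positions3d[perm])
        aep_project(m_perm)
        frames_perm = [FeatureFrame(f.window_index, f.values[perm], "fuzzyen") for f in frames]
        seq_perm = make_sequence(frames_perm, m_perm, IdentityNormalizer())
        # the Clough-Tocher gradient solve is iterative: identical to ~1e-7
        for a, b in zip(seq.frames, seq_perm.frames):
            np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-6)

    def test_deterministic(self):
        m = default_montage(SMALL_16_LABELS)
        frames = self.frames(3, 16, seed=2)
        a = make_sequence(frames, m, IdentityNormalizer()).as_array()
        b = make_sequence(frames, m, IdentityNormalizer()).as_array()
        np.testing.assert_array_equal(a, b)


class TestTopoImage:
    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            TopoImage(np.zeros((32, 32)), 0)

    def test_nonfinite_rejected(self):
        bad = np.zeros((4, 4, 3))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            TopoImage(bad, 0)

    def test_png_export(self, tmp_path):
        pytest.importorskip("PIL")
        from eegtopo.topomap import save_png

        img = TopoImage(np.random.default_rng(0).random((32, 32, 3)), 0)
        save_png(img, tmp_path / "frame.png")
        assert (tmp_path / "frame.png").stat().st_size > 0
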