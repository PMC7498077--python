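"""Organ meshes: closed-form volumes, shape classification, validity."""

import numpy as np
import pytest

from tuberoot import (
    TuberShapeClass,
    classify_tuber,
    generate_axis,
    root_tube_mesh,
    seed_potato_mesh,
    tuber_mesh,
    underground_stem_mesh,
)


class TestSeedPotato:
    def test_hemisphere_volume_within_2_percent(self):
        r = 20.0
        mesh = seed_potato_mesh(2 * r, 2 * r, r, resolution=48)
        assert mesh.volume() == pytest.approx((2 / 3) * np.pi * r ** 3,
                                              rel=0.02)

    def test_minimal_resolution_is_closed(self):
        tm = seed_potato_mesh(10, 8, 4, resolution=4).as_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent

    @pytest.mark.parametrize("dims", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_nonpositive_dims_rejected(self, dims):
        with pytest.raises(ValueError):
            seed_potato_mesh(*dims)


class TestUndergroundStem:
    def test_single_frustum_matches_closed_form(self):
        HD, RD, rD = 100.0, 10.0, 0.5
        mesh = underground_stem_mesh(HD, RD, rD, n_segments=1, jitter=0,
                                     resolution=96)
        r_top = RD * (1 - rD)
        expected = np.pi * HD / 3 * (RD ** 2 + RD * r_top + r_top ** 2)
        assert mesh.volume() == pytest.approx(expected, rel=0.02)

    def test_zero_rate_gives_cylinder(self):
        mesh = underground_stem_mesh(50, 5, 0.0, n_segments=4, jitter=0,
                                     resolution=64)
        radii = np.linalg.norm(mesh.vertices[:, :2], axis=1)
        ring = radii[radii > 1e-9]  # exclude the cap centers
        assert np.allclose(ring, 5, atol=1e-9)

    def test_jittered_stem_reproducible_under_seed(self):
        kw = dict(HD=80, RD=6, rD=0.3, n_segments=8, jitter=1.0)
        m1 = underground_stem_mesh(**kw, rng=np.random.default_rng(4))
        m2 = underground_stem_mesh(**kw, rng=np.random.default_rng(4))
        assert np.array_equal(m1.vertices, m2.vertices)

    def test_full_taper_rejected(self):
        with pytest.raises(ValueError):
            underground_stem_mesh(10, 5, 1.0)


class TestClassifyTuber:
    @pytest.mark.parametrize(
        "dims,expected",
        [
            ((50, 50, 50), TuberShapeClass.SPHERICAL),
            ((60, 50, 45), TuberShapeClass.ELLIPSOID),   # ratio 1.2
            ((90, 50, 45), TuberShapeClass.ELONGATED),   # ratio 1.8 boundary
            ((57, 50, 45), TuberShapeClass.SPHERICAL),   # ratio 1.14
            ((57.5, 50, 45), TuberShapeClass.ELLIPSOID),  # ratio 1.15 boundary
        ],
    )
    def test_aspect_ratio_thresholds(self, dims, expected):
        assert classify_tuber(*dims) == expected

    def test_unsorted_dims_are_sorted(self):
        assert classify_tuber(45, 90, 50) == TuberShapeClass.ELONGATED

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            classify_tuber(50, 0, 40)


class TestTuberMesh:
    def test_sphere_volume_within_2_percent(self):
        r = 20.0
        mesh = tuber_mesh((0, 0, 0), 2 * r, 2 * r, 2 * r, resolution=32)
        assert mesh.volume() == pytest.approx((4 / 3) * np.pi * r ** 3,
                                              rel=0.02)

    def test_centroid_translates_with_center(self):
        tm = tuber_mesh((10, 0, 0), 40, 40, 40, resolution=32).as_trimesh()
        assert np.allclose(tm.center_mass, [10, 0, 0], atol=1e-6)

    def test_resolution_doubling_at_least_halves_volume_error(self):
        r = 20.0
        exact = (4 / 3) * np.pi * r ** 3
        errs = [
            abs(tuber_mesh((0, 0, 0), 2 * r, 2 * r, 2 * r, resolution=n)
                .volume() - exact)
            for n in (16, 32, 64)
        ]
        assert errs[1] <= errs[0] / 2
        assert errs[2] <= errs[1] / 2

    def test_ellipsoid_volume_formula(self):
        L, W, H = 90, 60, 40
        mesh = tuber_mesh((0, 0, 0), L, W, H, resolution=64)
        assert mesh.volume() == pytest.approx(np.pi / 6 * L * W * H, rel=0.01)


class TestRootTube:
    def test_cylinder_surface_area_within_2_percent(self):
        axis = generate_axis((0, 0, 0), 90, 0, 100, 1, r0=2, r_tip=2)
        tm = root_tube_mesh(axis, resolution=48).as_trimesh()
        expected = 2 * np.pi * 2 * 100 + 2 * np.pi * 2 ** 2
        assert tm.area == pytest.approx(expected, rel=0.02)

    def test_cone_tip_has_no_degenerate_faces(self):
        axis = generate_axis((0, 0, 0), 120, 30, 60, 1, phi_axial_deg=45,
                             r0=2, r_tip=0)
        mesh = root_tube_mesh(axis, resolution=12)
        v = mesh.vertices[mesh.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )
        assert (areas > 1e-12).all()
        assert mesh.as_trimesh().is_watertight

    def test_vertex_count_is_rings_times_resolution_plus_caps(self):
        axis = generate_axis((0, 0, 0), 100, 0, 30, 1, r0=1.5, r_tip=0.5)
        res = 10
        mesh = root_tube_mesh(axis, resolution=res)
        n_rings = len(axis.points)
        assert len(mesh.vertices) == n_rings * res + 2  # 2 cap centers

    def test_single_point_axis_rejected(self):
        from tuberoot import RootAxis

        bad = RootAxis(points=np.zeros((1, 3)), l_unit=1, theta0_deg=0,
                       eta0_deg=0, r0=1, r_tip=0.5)
        with pytest.raises(ValueError):
            root_tube_mesh(bad)


def test_randomized_meshes_are_valid():
    """Validity holds across 1000 random parameter draws (all organ kinds)."""
    rng = np.random.default_rng(2024)
    for i in range(250):
        m1 = seed_potato_mesh(rng.uniform(20, 90), rng.uniform(20, 90),
                              rng.uniform(10, 60), resolution=8)
        m2 = underground_stem_mesh(
            rng.uniform(40, 200), rng.uniform(2, 10), rng.uniform(0, 0.9),
            n_segments=int(rng.integers(1, 10)), jitter=rng.uniform(0, 1),
            rng=rng, resolution=8,
        )
        m3 = tuber_mesh(rng.normal(size=3) * 50, rng.uniform(20, 120),
                        rng.uniform(20, 90), rng.uniform(20, 70),
                        resolution=8)
        r0 = rng.uniform(0.5, 4)
        axis = generate_axis(
            rng.normal(size=3) * 30, rng.uniform(0, 180),
            rng.uniform(0, 360), rng.uniform(5, 80), 1.0,
            phi_axial_deg=rng.uniform(-90, 90), r0=r0,
            r_tip=rng.uniform(0, r0),
        )
        m4 = root_tube_mesh(axis, resolution=8)
        for m in (m1, m2, m3, m4):
            assert np.isfinite(m.vertices).all()
            assert m.faces.min() >= 0
            assert m.faces.max() < len(m.vertices)
            v = m.vertices[m.faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
            )
            assert (areas > 1e-12).all()
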