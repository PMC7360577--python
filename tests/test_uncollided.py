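import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdose.fixtures import _one_group_lib, _uniform_phantom
from ctdose.phantom import VoxelPhantom, build_water_cylinder
from ctdose.source import BeamSet, make_cone_beam, make_point_source
from ctdose.uncollided import (
    FluenceField,
    aperture_mask,
    first_collision_source,
    trace_path,
    uncollided_fluence,
    voxel_sigma_t,
)
from ctdose.xs import XSLibrary, make_test_material, standard_library


def _phantom(shape=(10, 10, 10), spacing=5.0):
    return _uniform_phantom(shape, spacing, mat_idx=1, density=1.0)


class TestTracePath:
    def test_axis_aligned_row(self):
        p = _phantom((10, 3, 3), 5.0)
        segs = trace_path(p, (-10.0, 7.5, 7.5), (60.0, 7.5, 7.5))
        assert len(segs) == 10
        assert all(L == pytest.approx(5.0, abs=1e-9) for (_, L) in segs)
        assert [idx[0] for idx, _ in segs] == list(range(10))

    def test_single_voxel_main_diagonal(self):
        p = _phantom((1, 1, 1), 7.0)
        segs = trace_path(p, (-1.0, -1.0, -1.0), (8.0, 8.0, 8.0))
        total = sum(L for _, L in segs)
        assert total == pytest.approx(7.0 * np.sqrt(3.0), rel=1e-9)

    def test_outside_segment_gives_empty_list(self):
        p = _phantom((4, 4, 4), 10.0)
        assert trace_path(p, (100.0, 100.0, 100.0), (200.0, 100.0, 100.0)) == []

    def test_coincident_endpoints_rejected(self):
        p = _phantom()
        with pytest.raises(ValueError):
            trace_path(p, (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_chords_match_dense_sampling_oracle(self, seed):
        # brute-force oracle: sample many points along the segment, bin by
        # voxel membership, chord ~ fraction * in-grid length
        rng = np.random.default_rng(seed)
        p = _phantom((6, 5, 4), 8.0)
        a = rng.uniform(-20, 70, 3)
        b = rng.uniform(-20, 60, 3)
        if np.allclose(a, b):
            return
        segs = trace_path(p, a, b)
        n = 400_000
        t = (np.arange(n) + 0.5) / n
        pts = a[None, :] + t[:, None] * (b - a)[None, :]
        idx = np.floor((pts - p.origin) / p.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(p.shape)), axis=1)
        seg_len = np.linalg.norm(b - a)
        total_in = inside.mean() * seg_len
        assert sum(L for _, L in segs) == pytest.approx(total_in, abs=3 * seg_len / n * 50)
        counts = {}
        for row, ok in zip(map(tuple, idx), inside):
            if ok:
                counts[row] = counts.get(row, 0) + 1
        for (vox, L) in segs:
            approx = counts.get(vox, 0) / n * seg_len
            assert L == pytest.approx(approx, abs=seg_len * 3e-4)


class TestUncollidedFluence:
    def test_vacuum_inverse_square(self):
        lib = _one_group_lib(1.0, 0.0)
        body = _uniform_phantom((16, 16, 16), 10.0, mat_idx=0, density=0.0)
        src = make_point_source((-120.0, 80.0, 80.0), [1.0])
        phi = uncollided_fluence(body, BeamSet([src]), lib)
        xc, yc, zc = body.voxel_centers()
        X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
        d = np.sqrt((X + 120.0) ** 2 + (Y - 80.0) ** 2 + (Z - 80.0) ** 2) / 10.0
        ana = 1.0 / (4.0 * np.pi * d**2)
        sel = d > 2.0
        assert np.max(np.abs(phi[0][sel] - ana[sel]) / ana[sel]) < 1e-9

    def test_beer_lambert_attenuation(self):
        # uniform absorber: fluence = geometric / attenuated by exp(-sigma * path)
        lib = _one_group_lib(0.5, 0.0)
        body = _uniform_phantom((20, 5, 5), 10.0, mat_idx=1, density=1.0)
        src = make_point_source((-100.0, 25.0, 25.0), [1.0])
        phi = uncollided_fluence(body, BeamSet([src]), lib)
        st_vox = voxel_sigma_t(body, lib)
        for i in (3, 10, 17):
            c = np.array([(i + 0.5) * 10.0, 25.0, 25.0])
            d_cm = np.linalg.norm(c - src.position) / 10.0
            tau = sum(
                L / 10.0 * st_vox[0][vox] for vox, L in trace_path(body, src.position, c)
            )
            expect = np.exp(-tau) / (4 * np.pi * d_cm**2)
            assert phi[0][i, 2, 2] == pytest.approx(expect, rel=1e-9)

    def test_water_cylinder_falls_by_e_over_one_mfp(self):
        lib = standard_library()
        body = build_water_cylinder((64, 64, 16), (50.0, 50.0, 12.5))
        src = make_point_source((250.0, -250.0, 62.5), np.full(7, 1 / 7))
        phi = uncollided_fluence(body, BeamSet([src]), lib)
        g = 6  # 10-20 keV group
        sigma = lib["water"].sigma_t[g]
        # two water voxels along the beam; geometric 1/d^2 factored out, the
        # residual decay must be Beer-Lambert at the group cross section
        j0, j1 = 33, 34
        c0 = phi[g][32, j0, 8]
        c1 = phi[g][32, j1, 8]
        xc, yc, zc = body.voxel_centers()
        p0 = np.array([xc[32], yc[j0], zc[8]])
        p1 = np.array([xc[32], yc[j1], zc[8]])
        g0 = np.linalg.norm(p0 - src.position) ** -2
        g1 = np.linalg.norm(p1 - src.position) ** -2
        atten_ratio = (c0 / g0) / (c1 / g1)
        expected = np.exp(sigma * np.linalg.norm(p1 - p0) / 10.0)
        assert atten_ratio == pytest.approx(expected, rel=0.02)

    def test_source_on_voxel_center_rejected(self):
        lib = _one_group_lib(1.0, 0.0)
        body = _phantom((4, 4, 4), 10.0)
        src = make_point_source((5.0, 5.0, 5.0), [1.0])  # center of voxel (0,0,0)
        with pytest.raises(ValueError, match="coincides"):
            uncollided_fluence(body, BeamSet([src]), lib)

    def test_aperture_edge_voxels_included(self):
        lib = _one_group_lib(0.0, 0.0)
        body = _uniform_phantom((9, 9, 1), 10.0, mat_idx=0, density=0.0)
        src = make_cone_beam((45.0, 45.0, -200.0), (0, 0, 1), 12.0, [1.0])
        mask = aperture_mask(body, src)
        phi = uncollided_fluence(body, BeamSet([src]), lib)
        assert np.array_equal(phi[0] > 0, mask)


class TestFluenceFieldInvariants:
    def test_total_is_sum(self):
        u = np.random.default_rng(0).random((2, 3, 3, 3))
        c = np.random.default_rng(1).random((2, 3, 3, 3))
        f = FluenceField(u, c)
        assert np.allclose(f.total, u + c, rtol=1e-12)

    def test_negative_values_rejected(self):
        u = np.ones((1, 2, 2, 2))
        bad = -np.ones((1, 2, 2, 2))
        with pytest.raises(ValueError):
            FluenceField(u, bad)

    def test_non_finite_rejected(self):
        u = np.ones((1, 2, 2, 2))
        v = np.ones((1, 2, 2, 2))
        v[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            FluenceField(v, u)


class TestFirstCollisionSource:
    def test_pure_absorber_gives_zero_moments(self):
        lib = _one_group_lib(1.0, 0.0)
        body = _phantom((4, 4, 4), 10.0)
        phi = np.ones((1, 1, 4, 4, 4))
        fcs = first_collision_source(body, lib, phi, [(-50.0, 20.0, 20.0)], L=1)
        assert np.all(fcs.q0 == 0)
        assert np.all(fcs.q1 == 0)

    def test_isotropic_scatterer_has_zero_first_moment(self):
        lib = _one_group_lib(1.0, 0.5, mu_bar=0.0)
        body = _phantom((4, 4, 4), 10.0)
        phi = np.random.default_rng(2).random((1, 1, 4, 4, 4))
        fcs = first_collision_source(body, lib, phi, [(-50.0, 20.0, 20.0)], L=1)
        assert np.all(fcs.q1 == 0)
        assert np.allclose(fcs.q0[0], 0.5 * phi[0, 0])

    def test_single_voxel_arithmetic(self):
        groups_lib = XSLibrary(
            _one_group_lib(1.0, 0.0).groups,
            [make_test_material("m", [1.0], 0.2, 1.0, 0.0)],
        )
        body = _uniform_phantom((1, 1, 1), 10.0, mat_idx=0, density=1.0)
        phi = np.full((1, 1, 1, 1, 1), 3.0)
        fcs = first_collision_source(body, groups_lib, phi, [(-50.0, 5.0, 5.0)], L=0)
        assert fcs.q0[0, 0, 0, 0] == pytest.approx(0.6)

    def test_balance_invariant_on_water_fixture(self):
        lib = standard_library()
        body = build_water_cylinder((32, 32, 8), (50.0, 50.0, 12.5))
        src = make_cone_beam((750.0, 250.0, 62.5), (-1, 0, 0), 15.0, np.full(7, 1 / 7))
        phi, per = uncollided_fluence(body, BeamSet([src]), lib, per_source=True)
        fcs = first_collision_source(body, lib, per, [src.position], L=1)
        s_out = np.array([m.sigma_s_out() for m in lib.materials])
        scale = body.density / np.array([m.reference_density for m in lib.materials])[body.material_index]
        expect = np.zeros(body.shape)
        for g in range(7):
            expect += s_out[body.material_index, g] * scale * phi[g]
        got = fcs.q0.sum(axis=0)
        sel = expect > 0
        assert np.max(np.abs(got[sel] - expect[sel]) / expect[sel]) < 1e-10

    def test_order_beyond_library_rejected(self):
        lib = _one_group_lib(1.0, 0.5)
        body = _phantom((2, 2, 2), 10.0)
        with pytest.raises(ValueError):
            first_collision_source(body, lib, np.ones((1, 1, 2, 2, 2)), [(-5.0, 5.0, 5.0)], L=2)
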