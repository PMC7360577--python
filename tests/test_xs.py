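import math

import numpy as np
import pytest

from ctdose.xs import (
    EnergyGroupStructure,
    MaterialXS,
    XSLibrary,
    XSParseError,
    XSValidationError,
    load_xs_library,
    macroscopic_xs,
    make_test_material,
    mean_free_path,
    seven_group_structure,
    standard_library,
    water_attenuation,
    water_mfp_mm,
    write_xs_library,
)


class TestEnergyGroupStructure:
    def test_seven_group_layout(self):
        g = seven_group_structure()
        assert g.G == 7
        assert g.boundaries[0] == 100.0 and g.boundaries[-1] == 10.0
        assert g.midpoint(0) == 87.5

    def test_boundary_energy_belongs_to_group_it_bounds_from_above(self):
        g = seven_group_structure()
        # groups are half-open (lower, upper]; 20 keV sits in the 10-20 group
        assert g.group_of(20.0) == 6
        assert g.group_of(100.0) == 0
        assert g.group_of(10.0) is None
        assert g.group_of(150.0) is None

    @pytest.mark.parametrize("bad", [(10.0, 20.0), (100.0, 100.0, 10.0), (-5.0,)])
    def test_invalid_boundaries_rejected(self, bad):
        with pytest.raises(XSValidationError):
            EnergyGroupStructure(bad)


class TestMakeTestMaterial:
    def test_pure_absorber_has_no_scatter(self):
        m = make_test_material("abs", [1.0, 2.0], 0.0)
        assert np.all(m.scatter_moments == 0)
        assert np.allclose(m.sigma_a(), m.sigma_t)

    def test_full_within_group_scatterer_conserves(self):
        m = make_test_material("sc", [1.0, 1.0, 1.0], 1.0, 1.0, 0.0)
        assert np.allclose(m.sigma_a(), 0.0, atol=1e-15)

    def test_half_scatter_row_sums(self):
        m = make_test_material("half", np.ones(4), 0.5, 0.7)
        assert np.allclose(m.scatter_moments[0].sum(axis=1), 0.5)

    def test_first_moment_scaling(self):
        m = make_test_material("aniso", [2.0], 0.5, 1.0, 0.2)
        assert np.allclose(m.scatter_moments[1], 3 * 0.2 * m.scatter_moments[0])

    @pytest.mark.parametrize(
        "kwargs",
        [dict(scatter_ratio_c=1.5), dict(scatter_ratio_c=0.5, mu_bar=0.5),
         dict(scatter_ratio_c=0.5, within_group_fraction=-0.1)],
    )
    def test_range_violations(self, kwargs):
        with pytest.raises(XSValidationError):
            make_test_material("bad", [1.0], **{"within_group_fraction": 1.0, "mu_bar": 0.0, **kwargs})


class TestDensityScaling:
    def test_identity_and_void_limits(self):
        m = make_test_material("m", [1.0, 2.0], 0.5)
        same = macroscopic_xs(m, m.reference_density)
        assert np.array_equal(same.sigma_t, m.sigma_t)
        void = macroscopic_xs(m, 0.0)
        assert np.all(void.sigma_t == 0) and np.all(void.scatter_moments == 0)

    def test_linearity(self):
        m = make_test_material("m", [0.3, 0.7], 0.4, 0.8, 0.1)
        a = macroscopic_xs(m, 0.4)
        b = macroscopic_xs(m, 1.1)
        c = macroscopic_xs(m, 1.5)
        assert np.allclose(a.sigma_t + b.sigma_t, c.sigma_t, rtol=1e-12)
        assert np.allclose(
            a.scatter_moments + b.scatter_moments, c.scatter_moments, rtol=1e-12
        )

    def test_negative_density_rejected(self):
        with pytest.raises(XSValidationError):
            macroscopic_xs(make_test_material("m", [1.0], 0.0), -1.0)


class TestMeanFreePath:
    def test_unit_cross_section_is_10mm(self):
        m = make_test_material("m", [1.0], 0.0)
        assert mean_free_path(m, 0) == pytest.approx(10.0)

    def test_zero_cross_section_signals_infinite(self):
        m = make_test_material("m", [0.0], 0.0)
        assert math.isinf(mean_free_path(m, 0))

    def test_water_mfp_20_and_100_kev(self):
        # coherent-excluded water attenuation fixture
        assert water_mfp_mm(20.0) == pytest.approx(13.9, abs=0.3)
        assert water_mfp_mm(100.0) == pytest.approx(60.6, abs=1.0)

    def test_water_mfp_monotone_increasing(self):
        e = np.linspace(10.0, 100.0, 40)
        mfp = np.array([water_mfp_mm(x) for x in e])
        assert np.all(np.diff(mfp) > 0)


class TestStandardLibrary:
    def test_invariants_on_all_materials(self, stdlib):
        G = stdlib.G
        lower = np.tril(np.ones((G, G), dtype=bool))  # allowed region (g_to >= g_from)
        for m in stdlib.materials:
            assert np.all(m.sigma_a() >= -1e-12), m.name
            assert np.all(m.scatter_moments[0][~lower.T] == 0), m.name
            assert np.all(m.scatter_moments[0] >= 0)

    def test_water_scattering_ratio_rises_with_energy(self, stdlib):
        w = stdlib["water"]
        c = w.sigma_s_out() / w.sigma_t
        # photoelectric dominates at low energy (high group index)
        assert c[0] > 0.9 and c[-1] < 0.2

    def test_bone_more_attenuating_than_water(self, stdlib):
        assert np.all(stdlib["bone"].sigma_t > stdlib["water"].sigma_t)

    def test_attenuation_components_positive(self):
        e = np.array([12.0, 33.0, 95.0])
        assert np.all(water_attenuation(e, "photoelectric") > 0)
        assert np.all(water_attenuation(e, "incoherent") > 0)


class TestLibraryIO:
    def test_round_trip(self, tmp_path, stdlib):
        p = tmp_path / "lib.xs"
        write_xs_library(stdlib, p)
        back = load_xs_library(p)
        assert back.names == stdlib.names
        assert back.groups.boundaries == stdlib.groups.boundaries
        for a, b in zip(back.materials, stdlib.materials):
            assert np.allclose(a.sigma_t, b.sigma_t, rtol=1e-10)
            assert np.allclose(a.scatter_moments, b.scatter_moments, rtol=1e-10, atol=1e-15)

    def test_upscatter_entry_rejected(self, tmp_path):
        p = tmp_path / "bad.xs"
        p.write_text(
            "groups: 2\nboundaries: 100 50 10\nlegendre_order: 0\n"
            "material: m\nreference_density: 1\nsigma_t: 1 1\n"
            "moment: 0\n0.1 0.1\n0.2 0.1\n"  # (g_from=1 -> g_to=0) upscatter
        )
        with pytest.raises(XSValidationError, match="upscatter"):
            load_xs_library(p)

    def test_parse_error_carries_line_number(self, tmp_path):
        p = tmp_path / "bad.xs"
        p.write_text("groups: 2\nboundaries: 100 50\nlegendre_order: 0\n")
        with pytest.raises(XSParseError, match=":2:"):
            load_xs_library(p)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        p = tmp_path / "ok.xs"
        p.write_text(
            "# header\ngroups: 1\nboundaries: 100 10\n\nlegendre_order: 0\n"
            "material: m  # trailing\nreference_density: 2\nsigma_t: 0.5\nmoment: 0\n0.25\n"
        )
        lib = load_xs_library(p)
        assert lib["m"].reference_density == 2.0
        assert lib["m"].sigma_t[0] == 0.5
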