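"""Phantom construction, density conversions and ground-truth projections."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryopxct import constants
from cryopxct.config import OpticsConfig, reconstruction_pixel_size
from cryopxct.phantom import (
    DEFAULT_DENSITIES,
    LABELS,
    ComplexProjection,
    PhantomSpec,
    build_phantom,
    delta_beta_from_electron_density,
    ground_truth_projection,
    mass_density_from_electron_density,
    project_delta,
)

WATER_NE = 0.3344  # e/Å³
LAM_620 = constants.wavelength_m(6.20)


class TestOptics:
    def test_wavelength_at_620_kev(self):
        assert LAM_620 == pytest.approx(1.99975e-10, rel=1e-5)

    def test_published_geometry_pixel_size(self):
        # 6.20 keV, 7.33 m, 452 px of 75 µm pitch -> 43.25 nm object pixel
        p = reconstruction_pixel_size(OpticsConfig())
        assert p == pytest.approx(43.25, rel=1e-3)

    def test_pixel_size_closed_form(self):
        # 12.4 keV, 1 m, N=100, 100 µm pitch: p = λ/0.01 ≈ 10.0 nm
        opt = OpticsConfig(
            photon_energy_kev=12.4,
            detector_distance_m=1.0,
            detector_region_px=100,
            detector_pixel_pitch_m=100e-6,
            probe_diameter_m=1e-7,
        )
        assert opt.pixel_size_nm == pytest.approx(10.0, rel=1e-3)

    def test_doubling_n_halves_pixel(self):
        a = OpticsConfig(detector_region_px=226)
        b = OpticsConfig(detector_region_px=452)
        assert a.pixel_size_nm == pytest.approx(2 * b.pixel_size_nm, rel=1e-12)

    def test_positive_geometry_enforced(self):
        with pytest.raises(ValueError):
            OpticsConfig(detector_distance_m=-1.0)


class TestDensityConversions:
    def test_water_delta(self):
        d, b = delta_beta_from_electron_density(WATER_NE, LAM_620, 0.005)
        assert d == pytest.approx(6.0e-6, rel=2e-2)
        assert b == pytest.approx(0.005 * d, rel=1e-12)

    def test_vacuum(self):
        d, b = delta_beta_from_electron_density(0.0, LAM_620)
        assert d == 0.0 and b == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.01, 10.0), st.floats(0.01, 1.0))
    def test_linearity(self, scale, ne):
        d1, _ = delta_beta_from_electron_density(ne, LAM_620)
        d2, _ = delta_beta_from_electron_density(scale * ne, LAM_620)
        assert d2 == pytest.approx(scale * d1, rel=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            delta_beta_from_electron_density(np.array([-0.1]), LAM_620)

    def test_water_mass_density(self):
        # 0.3344e24 e/cm³ × 1.86 g/mol / N_A ≈ 1.033 g/cm³
        assert mass_density_from_electron_density(WATER_NE) == pytest.approx(
            1.033, abs=0.002
        )

    def test_medium_mass_density(self):
        assert mass_density_from_electron_density(0.40) == pytest.approx(1.235, abs=0.002)

    def test_mass_density_zero_and_linear(self):
        assert mass_density_from_electron_density(0.0) == 0.0
        r = mass_density_from_electron_density(np.array([0.1, 0.2]))
        assert r[1] == pytest.approx(2 * r[0], rel=1e-12)


class TestBuildPhantom:
    def test_empty_feature_list_uniform_block(self):
        spec = PhantomSpec(
            shape=(16, 32, 32), n_axons=0, n_cells=0, n_vacuoles=0,
            densities={**DEFAULT_DENSITIES, "medium": 0.40},
        )
        p = build_phantom(spec, seed=1)
        assert set(np.unique(p.labels)) == {LABELS["air"], LABELS["medium"]}
        assert np.all(p.electron_density[p.labels == LABELS["medium"]] == np.float32(0.40))
        assert np.all(p.electron_density[p.labels == LABELS["air"]] == 0.0)

    def test_density_ordering_matches_observed_tissue(self):
        """Lipid vacuoles < myelin < medium; nucleus < cytoplasm."""
        p = build_phantom(PhantomSpec(), seed=1)
        assert p.median_density("vacuole_lipid") < p.median_density("myelin")
        assert p.median_density("myelin") < p.median_density("medium")
        assert p.median_density("nucleus") < p.median_density("cytoplasm")

    def test_determinism(self):
        a = build_phantom(PhantomSpec(shape=(16, 48, 48)), seed=3)
        b = build_phantom(PhantomSpec(shape=(16, 48, 48)), seed=3)
        assert np.array_equal(a.electron_density, b.electron_density)
        assert np.array_equal(a.labels, b.labels)

    def test_air_is_zero_density_everywhere(self):
        p = build_phantom(PhantomSpec(shape=(16, 48, 48)), seed=5)
        assert np.all(p.electron_density >= 0)
        assert np.all(p.electron_density[p.labels == LABELS["air"]] == 0)

    def test_support_strictly_inside_grid(self):
        p = build_phantom(PhantomSpec(shape=(16, 48, 48)), seed=5)
        sup = p.support_mask
        assert not sup[0].any() and not sup[-1].any()
        assert not sup[:, 0].any() and not sup[:, -1].any()

    def test_oversized_feature_rejected(self):
        spec = PhantomSpec(
            shape=(16, 32, 32), n_axons=0, n_cells=0, n_vacuoles=1,
            vacuole_diameter_um=40.0, voxel_size_nm=600.0,
        )
        with pytest.raises(ValueError, match="fit"):
            build_phantom(spec, seed=1)


@pytest.fixture(scope="module")
def cylinder():
    """Uniform vertical cylinder phantom with known chord geometry."""
    spec = PhantomSpec(
        shape=(8, 64, 64), support_shape="cylinder", support_fraction=0.6,
        n_axons=0, n_cells=0, n_vacuoles=0, voxel_size_nm=100.0,
    )
    return build_phantom(spec, seed=0)


class TestGroundTruthProjection:

    def test_chord_length_profile(self, cylinder):
        """φ(x) = −(2π/λ)·δ·2√(R²−x²): analytic chord oracle."""
        proj = ground_truth_projection(cylinder, 0.0, LAM_620, beta_over_delta=0.0)
        delta, _ = delta_beta_from_electron_density(0.40, LAM_620)
        nx = cylinder.shape[1]
        c = (nx - 1) / 2.0
        x = np.arange(nx) - c
        r_sup = np.sqrt(cylinder.support_mask.sum() / np.pi)
        chord = 2.0 * np.sqrt(np.clip(r_sup**2 - x**2, 0, None))
        expected = -2 * np.pi / LAM_620 * delta * chord * cylinder.voxel_size_nm * 1e-9
        mid = proj.phase[4]
        interior = np.abs(x) < 0.8 * r_sup
        assert np.abs(mid - expected)[interior].max() < 0.05 * np.abs(expected).max()
        # deepest (most negative) phase equals the on-axis chord value
        assert mid.min() == pytest.approx(expected.min(), rel=0.02)

    def test_empty_phantom_unit_transmission(self):
        spec = PhantomSpec(shape=(8, 32, 32), n_axons=0, n_cells=0, n_vacuoles=0,
                           densities={k: 0.0 for k in DEFAULT_DENSITIES})
        p = build_phantom(spec, seed=0)
        proj = ground_truth_projection(p, 45.0, LAM_620)
        np.testing.assert_allclose(proj.transmission, 1.0, atol=1e-12)

    def test_passivity(self, cylinder):
        proj = ground_truth_projection(cylinder, 10.0, LAM_620)
        assert np.all(np.abs(proj.transmission) <= 1.0 + 1e-12)

    def test_mirror_symmetry_0_vs_180(self, cylinder):
        a = ground_truth_projection(cylinder, 0.0, LAM_620)
        b = ground_truth_projection(cylinder, 180.0, LAM_620)
        np.testing.assert_allclose(
            a.phase, b.phase[:, ::-1], atol=1e-6 * np.abs(a.phase).max()
        )

    def test_mass_conservation_across_angles(self):
        """Total projected δ is angle-invariant to 1e−3 (rotation quality)."""
        phan = build_phantom(PhantomSpec(shape=(8, 128, 128)), seed=2)
        delta, _ = delta_beta_from_electron_density(phan.electron_density, LAM_620)
        totals = [
            project_delta(delta, a, phan.voxel_size_nm * 1e-9).sum()
            for a in (0.0, 17.0, 45.0, 90.0, 133.0)
        ]
        assert np.ptp(totals) / np.abs(totals[0]) < 1e-3

    def test_angle_range_validated(self, cylinder):
        with pytest.raises(ValueError):
            ground_truth_projection(cylinder, -5.0, LAM_620)
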