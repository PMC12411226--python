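import numpy as np
import pytest

from lietsim import _tmm
from lietsim import photonic_g as pg
from lietsim.electronic_h import ElectronicBands, spectral_electronic_contribution
from lietsim.emission_combine import find_peak

SMALL = dict(n_harmonics=15)


class TestExcitationAndGrid:
    def test_s_polarized_emission_request_rejected(self, char_device):
        with pytest.raises(pg.PolarizationError):
            pg.farfield_amplitude(char_device, 0.3, 46.0, 650.0, polarization="s")

    def test_rcwa_solver_rejects_s_polarization(self, char_device):
        exc = pg.PlaneWaveExcitation(650.0, 0.3, polarization="s")
        with pytest.raises(pg.PolarizationError):
            pg.rcwa_solve(char_device, exc)

    def test_excitation_validation(self):
        with pytest.raises(ValueError):
            pg.PlaneWaveExcitation(650.0, theta_rad=2.0)
        with pytest.raises(ValueError):
            pg.PlaneWaveExcitation(650.0, polarization="x")

    def test_dipole_grid_validation(self, char_device):
        with pytest.raises(ValueError, match="non-empty"):
            pg.DipoleGrid(x_nm=np.array([]))
        with pytest.raises(ValueError, match="z_frac"):
            pg.DipoleGrid(x_nm=np.array([10.0]), z_frac=1.0)
        grid = pg.DipoleGrid.under_wire(char_device, n_x=15)
        assert grid.x_nm.size == 15
        assert np.all((grid.x_nm > 0) & (grid.x_nm < 92.0))


class TestStackBuilder:
    @pytest.mark.parametrize("style,thickness", [("conformal", 25.0), ("conformal", 45.0), ("fill", 45.0), ("fill", 70.0)])
    def test_segments_span_the_period(self, char_device, style, thickness):
        dev = char_device.with_overlayer(thickness, "PMMA", style)
        _, layers, _, gap = pg.build_stack(dev, 650.0)
        for ld in layers:
            if ld.segments is not None:
                assert sum(w for w, _ in ld.segments) == pytest.approx(400.0)
        assert layers[gap].eps == pytest.approx(1.76**2)

    def test_total_patterned_height_consistent(self, char_device):
        dev = char_device.with_overlayer(45.0, "PMMA", "conformal")
        _, layers, _, gap = pg.build_stack(dev, 650.0)
        above_gap = sum(l.thickness for l in layers[gap + 1 :])
        # wire stack 55 nm plus the 45 nm conformal cap
        assert above_gap == pytest.approx(100.0)

    def test_conformal_thicker_than_wire_rejected(self, char_device):
        dev = char_device.with_overlayer(80.0, "PMMA", "conformal")
        with pytest.raises(ValueError, match="conformal"):
            pg.build_stack(dev, 650.0)

    def test_fill_style_excess_becomes_planar_film(self, char_device):
        dev = char_device.with_overlayer(80.0, "PMMA", "fill")
        _, layers, _, _ = pg.build_stack(dev, 650.0)
        assert layers[-1].homogeneous
        assert layers[-1].thickness == pytest.approx(80.0 - 55.0)


class TestEquationThreeStructure:
    def test_single_dipole_is_g_squared(self, char_device):
        g = pg.farfield_amplitude(char_device, 0.25, 46.0, 650.0, **SMALL)
        grid = pg.DipoleGrid(x_nm=np.array([46.0]))
        val = pg.angle_resolved_photonic(char_device, 650.0, 0.25, grid=grid, **SMALL)
        assert val == pytest.approx(abs(g) ** 2, rel=1e-9)

    def test_incoherent_sum_over_identical_groups(self, char_device):
        grid1 = pg.DipoleGrid(x_nm=np.array([46.0]))
        grid3 = pg.DipoleGrid(x_nm=np.array([46.0, 46.0, 46.0]))
        v1 = pg.angle_resolved_photonic(char_device, 650.0, 0.25, grid=grid1, **SMALL)
        v3 = pg.angle_resolved_photonic(char_device, 650.0, 0.25, grid=grid3, **SMALL)
        assert v3 == pytest.approx(3.0 * v1, rel=1e-9)

    def test_coherent_in_phase_addition_along_wire(self, char_device):
        grid1 = pg.DipoleGrid(x_nm=np.array([46.0]), n_j=1)
        grid4 = pg.DipoleGrid(x_nm=np.array([46.0]), n_j=4)
        v1 = pg.angle_resolved_photonic(char_device, 650.0, 0.25, grid=grid1, **SMALL)
        v4 = pg.angle_resolved_photonic(char_device, 650.0, 0.25, grid=grid4, **SMALL)
        assert v4 == pytest.approx(16.0 * v1, rel=1e-9)

    def test_mirror_symmetry(self, char_device):
        # mirror-partner dipoles under the symmetric wire see equal |g| at
        # opposite polar angles
        w = char_device.grating.wire_width
        for x in (16.0, 30.0):
            g_plus = pg.farfield_amplitude(char_device, 0.3, x, 650.0, **SMALL)
            g_minus = pg.farfield_amplitude(char_device, -0.3, w - x, 650.0, **SMALL)
            assert abs(g_plus) == pytest.approx(abs(g_minus), rel=1e-6)


class TestReciprocityOracle:
    def test_reciprocity_equals_direct_dipole_emission_planar(self, char_device, materials):
        """Grating removed (continuous films): the reciprocity-route |g| and
        the source-driven dipole-sheet route agree to 1% at every angle."""
        lam = 650.0
        k0 = 2.0 * np.pi / lam
        eps_sub, layer_defs, eps_sup, gap = pg.build_stack(
            char_device, lam, materials, planarize="film"
        )
        planar = [(l.eps, l.thickness) for l in layer_defs]
        z_gap = sum(l.thickness for l in layer_defs[:gap]) + 2.5
        n_sub = np.sqrt(eps_sub).real
        ratios = []
        for s in np.linspace(0.05, 0.75, 8):
            kx = k0 * s
            drv = _tmm.solve(k0, kx, eps_sub, planar, eps_sup, pol="p", a_inc=n_sub)
            _, _, ez = _tmm.fields_at(drv, z_gap)
            b_sub, _ = _tmm.dipole_sheet_emission(k0, kx, eps_sub, planar, eps_sup, gap, 2.5)
            kz_sub = np.sqrt(eps_sub * k0**2 - kx**2 + 0j)
            g_direct = kx * kz_sub * b_sub / n_sub
            ratios.append(abs(g_direct) / abs(ez))
        ratios = np.asarray(ratios)
        assert np.max(np.abs(ratios / ratios[0] - 1.0)) < 0.01


class TestPhotonicContribution:
    lam = np.arange(540.0, 781.0, 12.0)

    @pytest.fixture(scope="class")
    def g_bare(self, char_device):
        return pg.photonic_contribution(
            char_device, self.lam, na=0.8, n_theta=8, n_harmonics=21, normalize=False
        )

    def test_nonnegative(self, g_bare):
        assert np.all(g_bare.values >= 0.0)

    def test_monotone_in_na(self, char_device, g_bare):
        g_small = pg.photonic_contribution(
            char_device, self.lam, na=0.3, n_theta=8, n_harmonics=21, normalize=False
        )
        # nested angular domains, non-negative integrand
        assert np.all(g_bare.values - g_small.values >= -1e-15 * g_bare.values.max())

    def test_lattice_band_enhanced_over_film_reference(self, char_device, g_bare, materials):
        th = np.linspace(0.0, np.arcsin(0.8), 8)
        film = []
        for lam in self.lam:
            k0 = 2.0 * np.pi / lam
            eps_sub, layer_defs, eps_sup, gap = pg.build_stack(
                char_device, lam, materials, planarize="film"
            )
            planar = [(l.eps, l.thickness) for l in layer_defs]
            z_gap = sum(l.thickness for l in layer_defs[:gap]) + 2.5
            vals = []
            for t in th:
                kx = k0 * np.sin(t)
                drv = _tmm.solve(k0, kx, eps_sub, planar, eps_sup, pol="p", a_inc=1.52)
                _, _, ez = _tmm.fields_at(drv, z_gap)
                vals.append(abs(ez * (pg.LAMBDA_REF_NM / lam) ** 2) ** 2)
            film.append(np.trapezoid(np.asarray(vals) * np.sin(th), th))
        # antenna-mediated outcoupling enhances the 500-750 nm band by orders
        # of magnitude over the unpatterned junction
        ratio = g_bare.values / (np.asarray(film) * 15.0)  # 15 dipoles vs 1
        sel = self.lam <= 750.0
        assert np.all(ratio[sel] > 10.0)

    def test_overlayer_redshifts_emission_peak(self, char_device):
        h = spectral_electronic_contribution(ElectronicBands(), 2.8, self.lam)
        g_pmma = pg.photonic_contribution(
            char_device.with_overlayer(45.0, "PMMA"), self.lam,
            na=0.8, n_theta=8, n_harmonics=21, normalize=False,
        )
        g_bare = pg.photonic_contribution(
            char_device, self.lam, na=0.8, n_theta=8, n_harmonics=21, normalize=False
        )
        peak_bare, _ = find_peak(self.lam, h.values * g_bare.values, (550.0, 750.0))
        peak_pmma, _ = find_peak(self.lam, h.values * g_pmma.values, (550.0, 750.0))
        assert peak_pmma > peak_bare + 10.0

    def test_coarse_angular_grid_warns(self, char_device):
        with pytest.warns(pg.QuadratureWarning):
            pg.photonic_contribution(
                char_device, [650.0, 660.0], na=0.8, n_theta=5, n_harmonics=15
            )

    def test_azimuth_integration_runs(self, char_device):
        g = pg.photonic_contribution(
            char_device, [640.0, 660.0], na=0.3, n_theta=6, n_phi=3, n_harmonics=15
        )
        assert np.all(g.values >= 0.0)
        assert g.values.max() == pytest.approx(1.0)


class TestRcwaSolveWrapper:
    def test_energy_balance_real_materials(self, char_device):
        exc = pg.PlaneWaveExcitation(650.0, np.deg2rad(21.0))
        res = pg.rcwa_solve(char_device, exc, n_harmonics=21)
        assert res.R + res.T + res.absorption_per_layer().sum() == pytest.approx(
            1.0, abs=1e-6
        )

    def test_convergence_check_mechanism(self, char_device):
        # a deliberately coarse harmonic count on a metallic grating either
        # converges or warns with both values attached
        import warnings

        exc = pg.PlaneWaveExcitation(650.0, np.deg2rad(36.0))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res11 = pg.rcwa_solve(char_device, exc, n_harmonics=11, check_convergence=True)
        res31 = pg.rcwa_solve(char_device, exc, n_harmonics=31)
        rel = abs(res11.R - res31.R) / res31.R
        warned = any(issubclass(w.category, pg.ConvergenceWarning) for w in caught)
        if rel > 0.02:
            assert warned, "coarse solve disagrees with fine solve but did not warn"

    def test_harmonics_floor(self, char_device):
        exc = pg.PlaneWaveExcitation(650.0, 0.2)
        with pytest.raises(ValueError, match="11"):
            pg.rcwa_solve(char_device, exc, n_harmonics=9)


class TestAngularMapContainers:
    def test_hdf5_round_trip(self, char_device, tmp_path):
        lam = np.array([640.0, 660.0, 680.0])
        th = np.deg2rad([0.0, 15.0])
        amap = pg.photonic_map(char_device, lam, th, n_harmonics=11)
        path = tmp_path / "map.h5"
        amap.to_hdf5(path)
        back = pg.AngularEmissionMap.from_hdf5(path)
        assert np.allclose(back.values, amap.values)
        assert np.allclose(back.wavelength_nm, lam)

    def test_dataframe_long_format(self, char_device):
        lam = np.array([640.0, 660.0])
        th = np.deg2rad([0.0, 15.0, 30.0])
        amap = pg.photonic_map(char_device, lam, th, n_harmonics=11)
        df = amap.to_dataframe()
        assert list(df.columns) == ["lambda_nm", "theta_deg", "G_arb"]
        assert len(df) == 6
        assert (df["G_arb"] >= 0).all()

    def test_k_parallel_convention(self, char_device):
        amap = pg.AngularEmissionMap(
            wavelength_nm=np.array([628.3185307179587]),
            theta_rad=np.array([np.pi / 6]),
            values=np.ones((1, 1)),
        )
        # (2 pi / lambda) sin(theta) in 1/um: 0.01 nm^-1 * 0.5 * 1e3
        assert amap.k_parallel_per_um()[0, 0] == pytest.approx(5.0)
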