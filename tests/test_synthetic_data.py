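import json

import numpy as np
import pytest

from lietsim import synthetic_data as sd
from lietsim.device_config import default_device
from lietsim.electronic_h import ElectronicBands
from lietsim.emission_combine import EmissionSpectrum
from lietsim.iv_simmons import BarrierParams, fit_simmons
from lietsim.sensing_metrics import limit_of_detection

LAM = np.arange(600.0, 700.5, 0.25)


def model_spectrum(amp=200.0):
    vals = amp * (0.5 + np.exp(-((LAM - 650.0) ** 2) / (2 * 20.0**2)))
    return EmissionSpectrum(LAM.copy(), vals, 2.8, 0.3, "sensing")


class TestNoiseModel:
    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            sd.NoiseModel(kind="poisson_counts", scale=1.0, seed=None)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            sd.NoiseModel(kind="salt_and_pepper", scale=1.0, seed=0)

    def test_zero_scale_is_exact(self):
        noise = sd.NoiseModel(kind="multiplicative_gaussian", scale=0.0, seed=0)
        vals = np.linspace(1.0, 5.0, 11)
        assert np.array_equal(noise.apply(vals), vals)


class TestSynthSpectrum:
    def test_determinism_same_seed(self):
        noise = sd.NoiseModel(kind="poisson_counts", scale=10.0, seed=99)
        raw1, smooth1, _ = sd.synth_spectrum(model_spectrum(), noise)
        raw2, smooth2, _ = sd.synth_spectrum(model_spectrum(), noise)
        assert np.array_equal(raw1.intensity, raw2.intensity)
        assert np.array_equal(smooth1.intensity, smooth2.intensity)

    def test_zero_noise_identity(self):
        noise = sd.NoiseModel(kind="multiplicative_gaussian", scale=0.0, seed=0)
        raw, _, manifest = sd.synth_spectrum(model_spectrum(), noise)
        assert np.array_equal(raw.intensity, model_spectrum().intensity)
        assert manifest["smooth_points"] == 10  # 2.5 nm at 0.25 nm sampling

    def test_poisson_mean_matches_model(self):
        # law of large numbers: the mean of 500 replicates is within 1% of
        # the model at every wavelength.  Expected counts are kept >= 2000 so
        # that 1% corresponds to >= 10 standard errors of the mean (at 100
        # counts it would only be ~2 sigma and single-point excursions are
        # statistically guaranteed over a few hundred wavelengths).
        model = model_spectrum(amp=200.0)
        counts_per_unit = 20.0
        acc = np.zeros(LAM.size)
        n_rep = 500
        for k in range(n_rep):
            noise = sd.NoiseModel(kind="poisson_counts", scale=counts_per_unit, seed=1000 + k)
            raw, _, _ = sd.synth_spectrum(model, noise)
            acc += raw.intensity
        mean = acc / n_rep
        sel = model.intensity * counts_per_unit >= 2000.0
        assert sel.all()
        assert np.all(np.abs(mean[sel] - model.intensity[sel]) / model.intensity[sel] < 0.01)

    def test_smoothing_reduces_variance(self):
        noise = sd.NoiseModel(kind="poisson_counts", scale=1.0, seed=5)
        raw, smooth, _ = sd.synth_spectrum(model_spectrum(), noise)
        model = model_spectrum().intensity
        assert np.std(smooth.intensity - model) < np.std(raw.intensity - model)

    def test_unresolvable_window_rejected(self):
        coarse = EmissionSpectrum(np.arange(600.0, 700.0, 5.0), np.ones(20), 2.8, 0.3)
        noise = sd.NoiseModel(kind="poisson_counts", scale=1.0, seed=0)
        with pytest.raises(sd.SmoothingError):
            sd.synth_spectrum(coarse, noise, smooth_window_nm=2.5)


class TestSynthIV:
    params = BarrierParams(2.62, 3.2)

    def test_zero_noise_exact_forward_model(self):
        from lietsim.iv_simmons import simmons_j

        noise = sd.NoiseModel(kind="multiplicative_gaussian", scale=0.0, seed=0)
        v = np.linspace(0.1, 2.4, 50)
        iv = sd.synth_iv(self.params, v, noise)
        assert np.array_equal(iv.current_density, simmons_j(v, self.params))

    def test_seeded_noise_reproducible(self):
        noise = sd.NoiseModel(kind="multiplicative_gaussian", scale=0.01, seed=42)
        v = np.linspace(0.1, 2.4, 50)
        iv1 = sd.synth_iv(self.params, v, noise)
        iv2 = sd.synth_iv(self.params, v, noise)
        assert np.array_equal(iv1.current_density, iv2.current_density)
        assert iv1.meta["seed"] == 42

    def test_fit_recovers_parameters(self):
        noise = sd.NoiseModel(kind="multiplicative_gaussian", scale=0.01, seed=7)
        v = np.linspace(0.1, 2.4, 200)
        iv = sd.synth_iv(self.params, v, noise)
        fitted, _ = fit_simmons(iv)
        assert fitted.phi_bar_ev == pytest.approx(2.62, rel=0.05)
        assert fitted.delta_s_nm == pytest.approx(3.2, rel=0.05)


class TestEmissionImage:
    def test_uniform_image_zero_cv(self):
        noise = sd.NoiseModel(kind="poisson_counts", scale=0.0, seed=0)
        img = sd.synth_emission_image(10.0, [], noise)
        assert img.coefficient_of_variation() == 0.0

    def test_defect_line_increases_cv(self):
        noise = sd.NoiseModel(kind="poisson_counts", scale=0.0, seed=0)
        clean = sd.synth_emission_image(10.0, [], noise)
        defective = sd.synth_emission_image(
            10.0, [sd.DefectLine(row=30, width_px=2, attenuation=0.5)], noise
        )
        assert defective.coefficient_of_variation() > clean.coefficient_of_variation()
        # excluding the defect rows restores uniformity
        assert defective.coefficient_of_variation(exclude_defects=True) == pytest.approx(0.0)

    def test_poisson_cv_matches_analytic(self):
        # per-pixel CV of Poisson counts with mean base*scale is
        # 1/sqrt(base*scale)
        base, scale = 50.0, 40.0
        noise = sd.NoiseModel(kind="poisson_counts", scale=scale, seed=11)
        img = sd.synth_emission_image(base, [], noise, shape=(256, 256))
        assert img.coefficient_of_variation() == pytest.approx(
            1.0 / np.sqrt(base * scale), rel=0.05
        )

    def test_defect_outside_image_rejected(self):
        noise = sd.NoiseModel(kind="poisson_counts", scale=0.0, seed=0)
        with pytest.raises(ValueError, match="outside"):
            sd.synth_emission_image(10.0, [sd.DefectLine(row=127, width_px=5)], noise)

    def test_minimum_shape(self):
        noise = sd.NoiseModel(kind="poisson_counts", scale=0.0, seed=0)
        with pytest.raises(ValueError, match="64"):
            sd.synth_emission_image(10.0, [], noise, shape=(32, 64))


class TestMassThicknessMapping:
    def test_closed_form(self):
        # 1000 * 14 pg / (1.4 g/cm^3 * 1000 um^2) = 10 nm
        assert sd.mass_to_thickness_nm(14.0, 1.4, 1000.0) == pytest.approx(10.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            sd.mass_to_thickness_nm(-1.0)
        with pytest.raises(ValueError):
            sd.mass_to_thickness_nm(1.0, density_g_cm3=0.0)


class TestDoseSeries:
    @pytest.fixture(scope="class")
    def series(self, sensing_device):
        noise = sd.NoiseModel(kind="poisson_counts", scale=100.0, seed=21)
        return sd.analyte_dose_series(
            [5.0, 15.0, 30.0, 50.0],
            sensing_device,
            ElectronicBands(),
            noise,
            replicates=3,
            wavelength_nm=np.arange(604.0, 716.1, 8.0),
            n_theta=4,
            n_phi=1,
            n_harmonics=11,
        )

    def test_monotone_mean_response(self, series):
        responses, _, _ = series
        means = [r.response_mean for r in responses]
        assert np.all(np.diff(means) > 0)

    def test_feeds_limit_of_detection_directly(self, series):
        responses, noise_level, _ = series
        out = limit_of_detection(responses, noise_level)
        assert out["threshold"] == pytest.approx(3 * noise_level)

    def test_manifest_records_seed_and_mapping(self, series, tmp_path):
        _, _, manifest = series
        assert manifest["noise"]["seed"] == 21
        assert manifest["thicknesses_nm"][0] == pytest.approx(
            sd.mass_to_thickness_nm(5.0)
        )
        path = tmp_path / "manifest.json"
        sd.write_manifest(path, manifest)
        assert json.loads(path.read_text())["replicates"] == 3

    def test_noiseless_limit_monotone_with_zero_spread(self, sensing_device):
        noise = sd.NoiseModel(kind="multiplicative_gaussian", scale=0.0, seed=0)
        responses, noise_level, _ = sd.analyte_dose_series(
            [10.0, 30.0, 50.0],
            sensing_device,
            ElectronicBands(),
            noise,
            replicates=2,
            wavelength_nm=np.arange(604.0, 716.1, 8.0),
            n_theta=4,
            n_phi=1,
            n_harmonics=11,
        )
        assert noise_level == 0.0
        assert all(r.response_sd == 0.0 for r in responses)
        means = [r.response_mean for r in responses]
        assert np.all(np.diff(means) > 0)

    def test_dose_beyond_solver_range_rejected(self, sensing_device):
        noise = sd.NoiseModel(kind="poisson_counts", scale=100.0, seed=0)
        with pytest.raises(ValueError, match="100"):
            sd.analyte_dose_series(
                [500.0], sensing_device, ElectronicBands(), noise, replicates=2
            )

    def test_masses_must_ascend(self, sensing_device):
        noise = sd.NoiseModel(kind="poisson_counts", scale=100.0, seed=0)
        with pytest.raises(ValueError, match="ascending"):
            sd.analyte_dose_series(
                [30.0, 10.0], sensing_device, ElectronicBands(), noise, replicates=2
            )


class TestImagePng:
    def test_png_is_16bit_grayscale(self, tmp_path):
        from PIL import Image

        noise = sd.NoiseModel(kind="poisson_counts", scale=50.0, seed=2)
        img = sd.synth_emission_image(40.0, [sd.DefectLine(row=20)], noise)
        path = tmp_path / "emission.png"
        img.save_png(path)
        back = Image.open(path)
        assert back.size == (128, 128)
        arr = np.asarray(back)
        assert arr.dtype == np.uint16 or arr.dtype == np.int32
        assert arr.max() == 65535
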