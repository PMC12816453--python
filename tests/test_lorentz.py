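import numpy as np
import pytest

from cestpipe.errors import (InsufficientDataError, InvalidInputError,
                             InvalidParameterError, NonPhysicalFitError)
from cestpipe.lorentz import (LorentzFitResult, aptw_config, compute_zlab_zref,
                              dg2_config, fit_pools, lorentz_eval, model_eval)
from cestpipe.zspec import OffsetAxis, ZSpectrum


class TestLorentzEval:
    def test_peak_value_at_center(self):
        assert lorentz_eval(0.1, 3.5, 1.0, 3.5) == pytest.approx(0.1)

    def test_half_maximum_at_half_width(self):
        assert lorentz_eval(0.1, 3.5, 1.0, 4.0) == pytest.approx(0.05)
        assert lorentz_eval(0.1, 3.5, 1.0, 3.0) == pytest.approx(0.05)

    def test_null_pool_is_zero_everywhere(self, axis):
        assert np.all(lorentz_eval(0.0, 3.5, 1.0, axis.offsets_ppm) == 0.0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            lorentz_eval(0.1, 3.5, 0.0, 3.5)


class TestModelEval:
    def test_all_zero_amplitudes_give_baseline(self, axis):
        z = model_eval(np.zeros(5), np.zeros(5), np.ones(5), 1.0, axis)
        assert np.all(z.z == 1.0)

    def test_single_pool_matches_lorentz_eval_pointwise(self, axis):
        z = model_eval([0.1], [3.5], [1.0], 1.0, axis)
        expected = 1.0 - lorentz_eval(0.1, 3.5, 1.0, axis.offsets_ppm)
        assert np.allclose(z.z, expected, atol=1e-15)

    def test_superposition(self, axis, aptw_truth):
        full = model_eval(aptw_truth["amplitudes"], aptw_truth["centers"],
                          aptw_truth["widths"], 1.0, axis).z
        assembled = np.ones(len(axis))
        for a, c, w in zip(aptw_truth["amplitudes"], aptw_truth["centers"],
                           aptw_truth["widths"]):
            assembled -= lorentz_eval(a, c, w, axis.offsets_ppm)
        assert np.max(np.abs(full - assembled)) < 1e-12


class TestFitPools:
    def test_noiseless_recovery_aptw(self, aptw_spectrum, aptw, aptw_truth):
        fit = fit_pools(aptw_spectrum, aptw)
        assert fit.converged
        rel = np.abs(fit.amplitudes - aptw_truth["amplitudes"]) / aptw_truth["amplitudes"]
        assert np.all(rel < 0.01)
        assert np.all(np.abs(fit.centers_ppm - aptw_truth["centers"]) < 0.02)
        assert fit.z_base == pytest.approx(1.0, abs=1e-6)

    def test_noisy_recovery_median_amide_error(self, axis, aptw, aptw_truth):
        rng = np.random.default_rng(7)
        truth = model_eval(aptw_truth["amplitudes"], aptw_truth["centers"],
                           aptw_truth["widths"], 1.0, axis).z
        errs = []
        for _ in range(100):
            z = ZSpectrum(truth + rng.normal(0, 0.005, truth.shape), axis)
            fit = fit_pools(z, aptw)
            a = fit.pool("amide")[0]
            errs.append(abs(a - 0.05) / 0.05)
        assert np.median(errs) < 0.10

    def test_flat_spectrum_fits_null_amplitudes(self, axis, aptw):
        fit = fit_pools(ZSpectrum(np.ones(len(axis)), axis), aptw)
        assert np.all(fit.amplitudes < 1e-4)

    def test_fit_is_deterministic(self, aptw_spectrum, aptw):
        f1 = fit_pools(aptw_spectrum, aptw)
        f2 = fit_pools(aptw_spectrum, aptw)
        assert np.array_equal(f1.amplitudes, f2.amplitudes)
        assert f1.rss == f2.rss

    def test_fit_idempotence_on_model_output(self, aptw_spectrum, aptw, axis):
        f1 = fit_pools(aptw_spectrum, aptw)
        regen = model_eval(f1.amplitudes, f1.centers_ppm, f1.widths_ppm,
                           f1.z_base, axis)
        f2 = fit_pools(regen, aptw)
        assert np.allclose(f2.amplitudes, f1.amplitudes, rtol=1e-6)
        assert np.allclose(f2.widths_ppm, f1.widths_ppm, rtol=1e-6)

    def test_recovery_degrades_monotonically_with_noise(self, axis, aptw, aptw_truth):
        rng = np.random.default_rng(13)
        truth = model_eval(aptw_truth["amplitudes"], aptw_truth["centers"],
                           aptw_truth["widths"], 1.0, axis).z
        medians = []
        for sd in (0.0, 0.002, 0.005, 0.01):
            errs = []
            for _ in range(20):
                z = truth + (rng.normal(0, sd, truth.shape) if sd else 0.0)
                fit = fit_pools(ZSpectrum(z, axis), aptw)
                errs.append(abs(fit.pool("amide")[0] - 0.05) / 0.05)
            medians.append(np.median(errs))
        assert np.all(np.diff(medians) >= 0)

    def test_dg2_recovery(self, axis):
        cfg = dg2_config()
        amps = np.array([0.85, 0.012, 0.035, 0.010, 0.011])
        cens = np.array([0.0, 0.66, 1.28, 2.08, 2.88])
        wids = np.array([1.4, 0.8, 0.8, 0.8, 0.8])
        fit = fit_pools(model_eval(amps, cens, wids, 1.0, axis), cfg)
        assert fit.converged
        assert np.all(np.abs(fit.amplitudes - amps) / amps < 0.01)
        assert fit.pool("dg2")[0] == pytest.approx(0.035, rel=0.01)

    def test_too_few_offsets_raises(self, aptw):
        ax = OffsetAxis(np.linspace(3, -3, 20))
        with pytest.raises(InsufficientDataError):
            fit_pools(ZSpectrum(np.ones(20), ax), aptw)

    def test_all_nan_spectrum_raises(self, axis, aptw):
        with pytest.raises(InvalidInputError):
            fit_pools(ZSpectrum(np.full(len(axis), np.nan), axis), aptw)


class TestZlabZref:
    def make_fit(self, amps, cens, wids, z_base=1.0):
        return LorentzFitResult(
            pool_names=("water", "amide", "amine", "mt", "noe"),
            amplitudes=np.asarray(amps, float), centers_ppm=np.asarray(cens, float),
            widths_ppm=np.asarray(wids, float), z_base=z_base, rss=0.0,
            converged=True, n_iter=1)

    def test_direct_arithmetic(self, aptw):
        # label contributes 0.2 at delta, others sum to 0.1 there
        fit = self.make_fit([0.1, 0.2, 0, 0, 0], [3.5, 3.5, 2.2, -2, -3.5],
                            [1e9, 1.0, 1, 6, 3])
        zl, zr = compute_zlab_zref(fit, aptw, 3.5)
        assert zl == pytest.approx(0.7, abs=1e-9)
        assert zr == pytest.approx(0.9, abs=1e-9)

    def test_zero_label_amplitude_makes_lab_equal_ref(self, aptw):
        fit = self.make_fit([0.85, 0.0, 0.03, 0.1, 0.08],
                            [0, 3.5, 2.2, -2, -3.5], [1.4, 1, 1.5, 6, 3])
        zl, zr = compute_zlab_zref(fit, aptw)
        assert zl == zr

    def test_only_label_pool_makes_ref_equal_base(self, aptw):
        fit = self.make_fit([0, 0.2, 0, 0, 0], [0, 3.5, 2.2, -2, -3.5],
                            [1.4, 1, 1.5, 6, 3])
        zl, zr = compute_zlab_zref(fit, aptw)
        assert zr == pytest.approx(1.0)

    def test_nonphysical_zlab_raises(self, aptw):
        fit = self.make_fit([0.9, 0.15, 0, 0, 0], [3.5, 3.5, 2.2, -2, -3.5],
                            [1e9, 1, 1, 6, 3])
        with pytest.raises(NonPhysicalFitError):
            compute_zlab_zref(fit, aptw, 3.5)

    def test_identity_zref_minus_zlab_is_label_lorentzian(self, aptw):
        rng = np.random.default_rng(3)
        for _ in range(200):
            amps = rng.uniform(0.01, 0.3, 5)
            wids = rng.uniform(0.5, 5.0, 5)
            fit = self.make_fit(amps, [0, 3.5, 2.2, -2, -3.5], wids)
            zl, zr = compute_zlab_zref(fit, aptw, 3.5)
            label = lorentz_eval(amps[1], 3.5, wids[1], 3.5)
            assert abs((zr - zl) - label) < 1e-12
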