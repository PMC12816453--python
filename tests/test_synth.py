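import numpy as np
import pytest

from cestpipe.b0 import estimate_b0_shift
from cestpipe.errors import DesignError, InvalidParameterError
from cestpipe.lorentz import aptw_config, model_eval
from cestpipe.synth import (CohortDesign, PhantomDesign, generate_cohort,
                            generate_phantom, polynomial_b0_field,
                            simulate_bm_zspectrum,
                            simulate_zspectrum_lorentzian,
                            single_pool_cw_steady_state, TABLE_APTW)
from cestpipe.zspec import ZSpectrum, cest_axis


class TestLorentzianGenerator:
    def test_noiseless_matches_model_eval(self, axis, aptw_truth):
        z, sat, ref = simulate_zspectrum_lorentzian(
            aptw_truth["amplitudes"], aptw_truth["centers"],
            aptw_truth["widths"], axis)
        expected = model_eval(aptw_truth["amplitudes"], aptw_truth["centers"],
                              aptw_truth["widths"], 1.0, axis).z
        assert np.max(np.abs(z - expected)) < 1e-12
        assert np.allclose(sat / ref, z)

    def test_b0_shift_moves_water_minimum(self, axis):
        z, _, _ = simulate_zspectrum_lorentzian([0.85], [0.0], [1.4], axis,
                                                b0_shift_ppm=0.15)
        shift, _ = estimate_b0_shift(ZSpectrum(z, axis))
        assert shift == pytest.approx(0.15, abs=0.005)

    def test_fixed_seed_reproducible(self, axis):
        out = [simulate_zspectrum_lorentzian(
            [0.85], [0.0], [1.4], axis, noise_sd=0.01,
            rng=np.random.default_rng(77))[0] for _ in range(2)]
        assert np.array_equal(out[0], out[1])

    def test_negative_noise_rejected(self, axis):
        with pytest.raises(InvalidParameterError):
            simulate_zspectrum_lorentzian([0.85], [0.0], [1.4], axis, noise_sd=-1)

    def test_rician_noise_is_nonnegative_and_biased_up_at_the_dip(self, axis):
        rng = np.random.default_rng(55)
        zs = np.array([simulate_zspectrum_lorentzian(
            [0.999], [0.0], [1.4], axis, noise_sd=0.05, rng=rng,
            noise_model="rician")[0] for _ in range(300)])
        assert (zs >= 0).all()
        i0 = int(np.argmin(np.abs(axis.offsets_ppm)))
        assert zs[:, i0].mean() > 0.001  # floor bias where true Z ~ 0


class TestBlochMcConnellOracle:
    def test_water_only_limit_matches_closed_form(self, axis):
        zbm = simulate_bm_zspectrum(axis, f_b=0.0, k_b=0.0, sat_duration_s=30.0)
        ss = single_pool_cw_steady_state(axis, t1_s=2.0, t2_s=0.07, b1_uT=3.0)
        assert np.max(np.abs(zbm.z - ss)) < 1e-4

    def test_dip_deepens_when_solute_fraction_doubles(self, axis):
        i = int(np.argmin(np.abs(axis.offsets_ppm - 3.5)))
        z1 = simulate_bm_zspectrum(axis, f_b=0.001, k_b=50.0, sat_duration_s=20.0)
        z2 = simulate_bm_zspectrum(axis, f_b=0.002, k_b=50.0, sat_duration_s=20.0)
        assert z2.z[i] < z1.z[i]

    def test_agrees_with_lorentzian_generator_on_dip_location(self, axis):
        # slow exchange, low fraction: both generators put the solute dip
        # within 0.05 ppm of +3.5
        zbm = simulate_bm_zspectrum(axis, f_b=0.002, k_b=30.0, b1_uT=1.0,
                                    sat_duration_s=20.0)
        zl = model_eval([0.5, 0.05], [0.0, 3.5], [1.0, 0.8], 1.0, axis)
        for z in (zbm, zl):
            sub = (axis.offsets_ppm > 2.5) & (axis.offsets_ppm < 4.5)
            loc = axis.offsets_ppm[sub][np.argmin(z.z[sub])]
            assert abs(loc - 3.5) <= 0.05

    def test_invalid_fraction_rejected(self, axis):
        with pytest.raises(InvalidParameterError):
            simulate_bm_zspectrum(axis, f_b=0.5, k_b=50.0)


class TestB0Surface:
    def test_amplitude_and_smoothness(self):
        f = polynomial_b0_field((32, 32), amplitude_ppm=0.2)
        assert np.abs(f).max() == pytest.approx(0.2)
        assert np.abs(np.diff(f, axis=0)).max() < 0.05  # smooth surface


class TestPhantom:
    def test_label_amplitudes_follow_slope_times_concentration(self):
        design = PhantomDesign(grid_shape=(32, 32), vial_radius=2.0,
                               amp_per_unit=0.002)
        bundle = generate_phantom(design, seed=0)
        truth = bundle.truth
        for v, conc in enumerate(design.concentrations, start=1):
            amps = truth.loc[truth["vial"] == v, "label_amp"].unique()
            assert amps.size == 1
            assert amps[0] == pytest.approx(0.002 * conc)
        assert sorted(truth["label_amp"].unique()) == pytest.approx(
            [0.009, 0.018, 0.027, 0.036, 0.045])

    def test_deterministic_under_seed(self):
        design = PhantomDesign(grid_shape=(24, 24), vial_radius=2.0, noise_sd=0.01)
        b1 = generate_phantom(design, seed=5)
        b2 = generate_phantom(design, seed=5)
        assert np.array_equal(b1.cest.sat_images, b2.cest.sat_images)
        assert np.array_equal(b1.wassr.sat_images, b2.wassr.sat_images)

    def test_overlapping_vials_rejected(self):
        with pytest.raises(DesignError):
            generate_phantom(PhantomDesign(
                grid_shape=(32, 32), vial_radius=4.0,
                vial_centers=((16, 10), (16, 12), (16, 20), (16, 24), (16, 28))))

    def test_truth_table_reconstructs_generator_inputs(self):
        design = PhantomDesign(grid_shape=(32, 32), vial_radius=2.0)
        bundle = generate_phantom(design, seed=1)
        row = bundle.truth.iloc[0]
        amps = np.zeros(5)
        cfg = __import__("cestpipe.lorentz", fromlist=["dg2_config"]).dg2_config()
        names = [p.name for p in cfg.pools]
        amps[names.index("water")] = design.water_amp
        amps[cfg.label_index] = row["label_amp"]
        for i, nm in enumerate(names):
            if nm.startswith("dg") and i != cfg.label_index:
                amps[i] = design.other_pool_fraction * row["label_amp"]
        z, _, _ = simulate_zspectrum_lorentzian(
            amps, [p.center_ppm for p in cfg.pools],
            [p.width_init for p in cfg.pools], cest_axis(),
            b0_shift_ppm=row["b0_ppm"])
        observed = bundle.cest.sat_images[int(row["y"]), int(row["x"])] / 1000.0
        assert np.max(np.abs(observed - z)) < 1e-12


class TestCohort:
    def test_calibrated_group_means_match_targets(self):
        design = CohortDesign(seed=3, noise_sd=0.0, b0_amplitude_ppm=0.0,
                              image_shape=(6, 6), roi_halfwidth=1)
        subjects, truth = generate_cohort(design)
        assert len(subjects) == 39
        for group, (mean, sd) in TABLE_APTW["arex"].items():
            vals = truth.loc[truth["group"] == group, "target_value"]
            assert vals.mean() == pytest.approx(mean, rel=0.15)

    def test_pipeline_measured_group_means_match_targets(self):
        # render each subject, run the full pipeline, compare ROI-mean AREX
        # against the design's group targets
        from cestpipe.pipeline import process_stack
        from cestpipe.stats import roi_mean
        design = CohortDesign(seed=3, noise_sd=0.002, image_shape=(8, 8),
                              roi_halfwidth=1)
        subjects, truth = generate_cohort(design)
        truth = truth.set_index("subject_id")
        measured: dict = {}
        for sid, bundle in subjects.items():
            b = bundle["pre"]
            res = process_stack(b.cest, b.wassr, b.t1_series, preset="aptw")
            m, _ = roi_mean(res.maps["arex"], b.roi_labels > 0)
            measured.setdefault(truth.loc[sid, "group"], []).append(m)
        for group, (mean, sd) in TABLE_APTW["arex"].items():
            assert np.mean(measured[group]) == pytest.approx(mean, rel=0.15)

    def test_identical_groups_rarely_significant(self):
        # null calibration at the subject level: all groups share parameters
        from cestpipe.stats import compare_groups, CohortTable
        import pandas as pd
        rng = np.random.default_rng(6)
        n_sig = 0
        reps = 200
        for _ in range(reps):
            rows = []
            i = 0
            for g in ("A", "B", "C"):
                for v in rng.normal(0.03, 0.01, 12):
                    i += 1
                    rows.append({"subject_id": f"S{i}", "group": g,
                                 "metric_name": "arex", "value": v})
            r = compare_groups(CohortTable(pd.DataFrame(rows)), "arex")
            if r.significant_pairs():
                n_sig += 1
        assert n_sig / reps <= 0.10

    def test_pre_post_pairs_emitted(self):
        design = CohortDesign(seed=1, pre_post=True, image_shape=(6, 6),
                              group_sizes={"A": 3, "B": 3, "C": 3},
                              targets={"arex": {"A": (0.02, 0.005),
                                                "B": (0.03, 0.005),
                                                "C": (0.04, 0.005)}})
        subjects, truth = generate_cohort(design)
        first = next(iter(subjects.values()))
        assert "pre" in first and "post" in first
        assert (truth["post_label_amp"] > truth["label_amp"]).all()

    def test_invalid_design_rejected(self):
        with pytest.raises(DesignError):
            CohortDesign(group_sizes={"A": 2, "B": 5, "C": 5}).validate()
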