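import dataclasses
import json
import math

import numpy as np
import pytest

from petquant import (
    PhantomConfig,
    check_grid_compatible,
    compute_patient_metrics,
    generate_cohort,
    generate_truth,
    label_lesions,
    load_mask,
    load_suv_volume,
    perturb_reading,
    rasterize_patient,
    run_agreement_study,
    simulate_cohort_records,
    simulate_patient,
    with_perturbation,
)
from petquant.phantom import TruthLesion, _rng
from conftest import make_mask


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("small_lesion_omit_prob", 1.5),
        ("lesion_count_mean", 0.0),
        ("boundary_jitter_mm", -1.0),
        ("omit_volume_threshold_cm3", 0.0),
        ("n_patients", 0),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field):
            PhantomConfig(**{field: value})

    def test_grid_too_small_for_lesions(self):
        with pytest.raises(ValueError, match="grid extent"):
            PhantomConfig(grid_shape=(8, 8, 8), spacing_mm=(2, 2, 2),
                          radius_range_mm=(5, 30))

    def test_peak_must_exceed_background(self):
        with pytest.raises(ValueError, match="background"):
            PhantomConfig(suv_peak_range=(0.5, 2.0), background_suv=1.0)


class TestGenerateTruth:
    def test_at_least_one_lesion_always(self, small_config):
        cfg = dataclasses.replace(small_config, lesion_count_mean=1e-6,
                                  n_patients=20)
        assert all(len(p) >= 1 for p in generate_truth(cfg))

    def test_same_seed_identical_cohorts(self, small_config):
        assert generate_truth(small_config) == generate_truth(small_config)

    def test_different_seeds_differ(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert generate_truth(small_config) != generate_truth(other)

    def test_radius_distribution(self):
        # log-uniform radii: all inside the range, mean of log within 3 SE
        cfg = PhantomConfig(n_patients=300, seed=5, lesion_count_mean=6.0)
        radii = np.array([l.radius_mm for p in generate_truth(cfg) for l in p])
        assert len(radii) > 1000
        lo, hi = cfg.radius_range_mm
        assert radii.min() >= lo and radii.max() <= hi
        logs = np.log(radii)
        mu = (math.log(lo) + math.log(hi)) / 2
        se = (math.log(hi) - math.log(lo)) / math.sqrt(12) / math.sqrt(len(radii))
        assert abs(logs.mean() - mu) < 3 * se

    def test_lesions_never_touch(self, small_config):
        max_sp = max(small_config.spacing_mm)
        for patient in generate_truth(small_config):
            for i, a in enumerate(patient):
                for b in patient[i + 1:]:
                    gap = np.linalg.norm(np.array(a.center_mm) - b.center_mm)
                    assert gap >= a.radius_mm + b.radius_mm + 2 * max_sp - 1e-9

    def test_congested_config_reports_error(self):
        cfg = PhantomConfig(grid_shape=(24, 24, 24), spacing_mm=(4, 4, 4),
                            radius_range_mm=(20, 30), lesion_count_mean=12,
                            boundary_jitter_mm=0.0, n_patients=1, seed=0)
        with pytest.raises(RuntimeError, match="congested|place"):
            generate_truth(cfg)


class TestRasterize:
    def test_tiny_sphere_single_voxel(self, small_config):
        # radius 0.4 * spacing centered exactly on a voxel center
        sp = small_config.spacing_mm[0]
        les = TruthLesion(center_mm=(10 * sp, 10 * sp, 10 * sp),
                          radius_mm=0.4 * sp, suv_peak=10.0)
        vol, mask = rasterize_patient([les], small_config, "p0")
        assert mask.n_foreground == 1
        assert mask.values[10, 10, 10] == 1

    def test_no_lesions_uniform_background(self, small_config):
        cfg = dataclasses.replace(small_config, background_suv=0.0)
        vol, mask = rasterize_patient([], cfg, "p0")
        assert mask.n_foreground == 0
        assert np.all(vol.values == 0)

    @pytest.mark.parametrize("spacing,rtol", [(2.0, 0.15), (1.0, 0.05)])
    def test_sphere_volume_converges_to_analytic(self, spacing, rtol):
        r = 10.0
        cfg = PhantomConfig(grid_shape=(32, 32, 32) if spacing == 2 else (64, 64, 64),
                            spacing_mm=(spacing,) * 3, radius_range_mm=(5, 12),
                            boundary_jitter_mm=0.0, n_patients=1, seed=0)
        center = (16 * spacing + 0.3,) * 3
        _, mask = rasterize_patient([TruthLesion(center, r, 10.0)], cfg, "p0")
        vox_cm3 = spacing ** 3 / 1000
        analytic = 4 / 3 * math.pi * r ** 3 / 1000
        assert mask.n_foreground * vox_cm3 == pytest.approx(analytic, rel=rtol)

    def test_each_lesion_connected_and_count_matches(self, small_config):
        truth = generate_truth(small_config)[0]
        vol, mask = rasterize_patient(truth, small_config, "p0")
        comps = label_lesions(mask, connectivity=26)
        assert len(comps) == len(truth)

    def test_suv_peaks_at_center_and_background_outside(self, small_config):
        truth = generate_truth(small_config)[1]
        vol, mask = rasterize_patient(truth, small_config, "p1")
        bg = small_config.background_suv
        assert np.all(vol.values[mask.values == 0] == bg)
        assert vol.values.max() <= max(l.suv_peak for l in truth) + 1e-9
        assert vol.values.max() > bg


class TestPerturbReading:
    def test_zero_perturbation_is_identity(self, small_config):
        cfg = with_perturbation(small_config, boundary_jitter_mm=0.0,
                                small_lesion_omit_prob=0.0)
        truth = generate_truth(cfg)[0]
        _, true_mask = rasterize_patient(truth, cfg, "p0")
        out = perturb_reading(true_mask, cfg, _rng(cfg, 0, 1), "A")
        np.testing.assert_array_equal(out.values, true_mask.values)

    def test_omit_prob_one_drops_all_small_lesions(self, small_config):
        cfg = dataclasses.replace(small_config, small_lesion_omit_prob=1.0,
                                  boundary_jitter_mm=0.0,
                                  omit_volume_threshold_cm3=1e9)
        truth = generate_truth(cfg)[0]
        _, true_mask = rasterize_patient(truth, cfg, "p0")
        out = perturb_reading(true_mask, cfg, _rng(cfg, 0, 1), "A")
        assert out.n_foreground == 0

    def test_omission_rate_is_binomial(self):
        # grid of 1728 isolated single-voxel lesions, omit probability 0.5
        values = np.zeros((24, 24, 24), int)
        values[::2, ::2, ::2] = 1
        true_mask = make_mask(values, spacing=(4, 4, 4))
        n = int(values.sum())
        cfg = PhantomConfig(grid_shape=(24, 24, 24), spacing_mm=(4, 4, 4),
                            small_lesion_omit_prob=0.5, boundary_jitter_mm=0.0,
                            omit_volume_threshold_cm3=1.0, seed=0,
                            radius_range_mm=(5, 12))
        out = perturb_reading(true_mask, cfg, np.random.default_rng(123), "A")
        kept = out.n_foreground
        se = math.sqrt(n * 0.25)
        assert abs((n - kept) - 0.5 * n) < 3 * se

    def test_large_lesions_never_omitted(self, small_config):
        cfg = dataclasses.replace(small_config, small_lesion_omit_prob=1.0,
                                  boundary_jitter_mm=0.0,
                                  omit_volume_threshold_cm3=1e-9)
        truth = generate_truth(cfg)[0]
        _, true_mask = rasterize_patient(truth, cfg, "p0")
        out = perturb_reading(true_mask, cfg, _rng(cfg, 0, 1), "A")
        np.testing.assert_array_equal(out.values, true_mask.values)


class TestGenerateCohort:
    def test_file_count_and_manifest(self, small_config, tmp_path):
        manifest = generate_cohort(small_config, tmp_path)
        niftis = list(tmp_path.glob("*.nii.gz"))
        assert len(niftis) == 3 * small_config.n_patients
        assert (tmp_path / "manifest.json").exists()
        assert len(manifest["patients"]) == small_config.n_patients

    def test_determinism_across_directories(self, small_config, tmp_path):
        m1 = generate_cohort(small_config, tmp_path / "run1", compress=False)
        m2 = generate_cohort(small_config, tmp_path / "run2", compress=False)
        assert m1 == m2
        for pat in m1["patients"]:
            for key in ("suv", "mask_a", "mask_b"):
                b1 = (tmp_path / "run1" / pat["files"][key]).read_bytes()
                b2 = (tmp_path / "run2" / pat["files"][key]).read_bytes()
                assert b1 == b2  # byte-identical outputs

    def test_zero_perturbation_readers_identical(self, small_config, tmp_path):
        cfg = with_perturbation(small_config, boundary_jitter_mm=0.0,
                                small_lesion_omit_prob=0.0)
        generate_cohort(cfg, tmp_path)
        for i in range(cfg.n_patients):
            a = load_mask(tmp_path / f"P{i:03d}_mask_A.nii.gz", "A")
            b = load_mask(tmp_path / f"P{i:03d}_mask_B.nii.gz", "B")
            np.testing.assert_array_equal(a.values, b.values)

    def test_manifest_metrics_match_reloaded_pipeline(self, small_config, tmp_path):
        manifest = generate_cohort(small_config, tmp_path)
        pat = manifest["patients"][0]
        vol = load_suv_volume(tmp_path / pat["files"]["suv"],
                              patient_id=pat["patient_id"])
        for reader, key in (("A", "mask_a"), ("B", "mask_b")):
            mask = load_mask(tmp_path / pat["files"][key], reader_id=reader,
                             patient_id=pat["patient_id"])
            assert check_grid_compatible(vol, mask)
            for min_vol, label in ((None, "all"), (3.0, "ge3cm3")):
                rec = compute_patient_metrics(vol, mask, min_volume_cm3=min_vol)
                exp = next(e for e in pat["expected_metrics"]
                           if e["reader_id"] == reader and e["filter_label"] == label)
                assert rec.mtv_cm3 == pytest.approx(exp["mtv_cm3"], rel=1e-6)
                assert rec.tlg == pytest.approx(exp["tlg"], rel=1e-6)
                assert rec.dmax_cm == pytest.approx(exp["dmax_cm"], rel=1e-6, abs=1e-12)
                assert rec.n_lesions == exp["n_lesions"]


class TestCohortStatistics:
    def test_median_mtv_in_clinical_magnitude_band(self):
        # defaults emulate an untreated aggressive-lymphoma cohort: the
        # pooled median MTV should be of order hundreds of cm^3
        cfg = PhantomConfig(n_patients=40, seed=1)
        records = simulate_cohort_records(cfg, min_volumes=(None,))
        mtv = [r.mtv_cm3 for r in records]
        assert 100 <= float(np.median(mtv)) <= 1000

    def test_systematic_dilation_of_reader_b_gives_negative_mtv_bias(self):
        import scipy.ndimage as ndi
        neg = 0
        reps = 20
        for k in range(reps):
            cfg = PhantomConfig(n_patients=6, seed=300 + k,
                                grid_shape=(32, 32, 48), spacing_mm=(4, 4, 4),
                                radius_range_mm=(5, 18), lesion_count_mean=3.0)
            records = []
            for i in range(cfg.n_patients):
                vol, true_mask, mask_a, _, _ = simulate_patient(cfg, i)
                grown = ndi.binary_dilation(mask_a.values.astype(bool))
                mask_b = dataclasses.replace(mask_a, reader_id="B",
                                             values=grown.astype(np.uint8))
                records.append(compute_patient_metrics(vol, mask_a))
                records.append(compute_patient_metrics(vol, mask_b))
            reports = run_agreement_study(records)
            neg += reports["MTV"].bias < 0
        assert neg >= 0.95 * reps
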