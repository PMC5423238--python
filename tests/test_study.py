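import filecmp
from pathlib import Path

import numpy as np
import pytest

from zcspec import StudyConfig, report_tables, run_study
from zcspec.errors import ValidationError


@pytest.fixture(scope="module")
def noise_free_bundle():
    cfg = StudyConfig(master_seed=0, noise_sd_au=0.0, baseline_drift_au=0.0,
                      tablet_content_rsd=0.0, reference_sd_rel=0.0,
                      excipient_baseline_au=0.0)
    return run_study(cfg)


@pytest.fixture(scope="module")
def default_bundle():
    return run_study(StudyConfig(master_seed=7))


class TestNoiseFreeExactness:
    def test_every_error_is_zero(self, noise_free_bundle):
        pa = noise_free_bundle.precision_accuracy
        assert pa.error_pct.abs().max() < 1e-9
        assert pa.cv_pct.max() < 1e-9

    def test_every_recovery_is_100(self, noise_free_bundle):
        rec = noise_free_bundle.recovery
        assert (rec.recovery_pct - 100.0).abs().max() < 0.1

    def test_calibration_is_perfectly_linear(self, noise_free_bundle):
        cal = noise_free_bundle.calibration
        assert (cal.r.abs() >= 1.0 - 1e-9).all()
        assert (cal.sd_slope.abs() < 1e-9 * cal.slope.abs()).all()


class TestSeededReproducibility:
    def test_same_seed_gives_bit_identical_reports(self, tmp_path):
        cfg = StudyConfig(master_seed=42)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        report_tables(run_study(cfg), d1)
        report_tables(run_study(cfg), d2)
        for f1 in sorted(d1.iterdir()):
            f2 = d2 / f1.name
            assert filecmp.cmp(f1, f2, shallow=False), f1.name

    def test_different_seeds_differ(self):
        pa1 = run_study(StudyConfig(master_seed=1)).precision_accuracy
        pa2 = run_study(StudyConfig(master_seed=2)).precision_accuracy
        assert not pa1.equals(pa2)


class TestDefaultNoiseStudy:
    def test_precision_and_accuracy_meet_assay_bounds(self, default_bundle):
        pa = default_bundle.precision_accuracy
        assert pa.cv_pct.max() < 2.5
        assert pa.error_pct.abs().max() < 1.8

    def test_calibration_r_meets_linearity_standard(self, default_bundle):
        assert (default_bundle.calibration.r.abs() >= 0.997).all()

    def test_selected_pair_respects_thresholds(self, default_bundle):
        sel = default_bundle.selection
        assert sel["residual_a"] <= 0.02 and sel["residual_b"] <= 0.02
        assert sel["stability_a_nm"] <= 0.2 and sel["stability_b_nm"] <= 0.2

    def test_method_comparison_is_equivalent_with_critical_values(self, default_bundle):
        mc = default_bundle.method_comparison
        assert mc.equivalent.all()
        assert np.allclose(mc.t_crit, 4.303, atol=5e-4)
        assert np.allclose(mc.f_crit, 19.00, atol=5e-3)

    def test_precision_table_has_paper_design_shape(self, default_bundle):
        pa = default_bundle.precision_accuracy
        # 2 analytes x 3 levels x (3 within-day rows + 1 between-day row)
        assert len(pa) == 2 * 3 * 4
        assert set(pa[pa.scope == "within_day"].n) == {3}
        assert set(pa[pa.scope == "between_day"].n) == {9}


class TestInterferenceImmunity:
    def test_doubling_partner_changes_readback_under_one_percent(
            self, noise_free_bundle, models, noise_free):
        from zcspec import amplitude_at, derivative, quantify, simulate_spectrum
        sel = noise_free_bundle.selection
        order, dl = sel["order"], sel["delta_lambda_nm"]
        bup, nal = models
        for target, partner, wl_key, c_t, c_p in (
                (bup, nal, "wavelength_a_nm", 50.0, 12.5),
                (nal, bup, "wavelength_b_nm", 12.5, 50.0)):
            curve = noise_free_bundle.curves[target.name]
            reads = []
            for factor in (1.0, 2.0):
                spec = simulate_spectrum([(target, c_t), (partner, factor * c_p)],
                                         noise_free)
                amp = amplitude_at(derivative(spec, order, dl), sel[wl_key])
                reads.append(quantify(amp, curve).concentration_ugml)
            assert abs(reads[1] - reads[0]) / reads[0] < 0.01


class TestMonteCarloUnbiasedness:
    def test_between_day_means_unbiased_over_repeated_studies(self):
        # repeated full studies: the grand mean of found concentrations at
        # each level must sit within Monte-Carlo error of the nominal
        runs = 60
        errs: dict[tuple[str, float], list[float]] = {}
        for seed in range(runs):
            pa = run_study(StudyConfig(master_seed=1000 + seed)).precision_accuracy
            bd = pa[pa.scope == "between_day"]
            for _, row in bd.iterrows():
                errs.setdefault((row.analyte, row.level_ugml), []).append(row.error_pct)
        for (analyte, level), es in errs.items():
            mean = np.mean(es)
            se = np.std(es, ddof=1) / np.sqrt(len(es))
            assert abs(mean) < max(4 * se, 0.05), (analyte, level, mean, se)


class TestReportTables:
    def test_tables_written_with_identical_csv_and_json_numbers(
            self, default_bundle, tmp_path):
        import json
        import pandas as pd
        paths = report_tables(default_bundle, tmp_path)
        for name in ("calibration", "precision_accuracy", "recovery"):
            df_csv = pd.read_csv(tmp_path / f"{name}.csv")
            records = json.loads((tmp_path / f"{name}.json").read_text())
            df_json = pd.DataFrame(records)
            num = df_csv.select_dtypes("number")
            for col in num.columns:
                np.testing.assert_allclose(
                    num[col].to_numpy(dtype=float),
                    pd.to_numeric(df_json[col]).to_numpy(dtype=float),
                    rtol=0, atol=1e-12, err_msg=f"{name}.{col}")
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "selection.json").exists()

    def test_incomplete_bundle_rejected_with_missing_stages(self, default_bundle):
        import copy
        broken = copy.copy(default_bundle)
        broken.recovery = broken.recovery.iloc[0:0]
        with pytest.raises(ValidationError, match="recovery"):
            report_tables(broken, "unused")


class TestStudyConfigYaml:
    def test_roundtrip_from_yaml(self, tmp_path):
        text = """
master_seed: 5
noise_sd_au: 0.001
search_orders: [3]
search_delta_lambdas: [28.0]
validation_levels_b: [5.0, 12.5, 20.0]
grid: {start_nm: 200.0, stop_nm: 350.0, step_nm: 0.1}
"""
        path = tmp_path / "cfg.yaml"
        path.write_text(text)
        cfg = StudyConfig.from_yaml(path)
        assert cfg.master_seed == 5
        assert cfg.search_orders == (3,)
        assert cfg.grid.step_nm == 0.1
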