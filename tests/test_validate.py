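import math

import numpy as np
import pandas as pd
import pytest

from zcspec import (
    ConcentrationDesign, QuantResult, accuracy_precision, compare_methods,
    f_critical, paired_t, standard_addition_recovery, t_critical,
    two_sample_t, variance_ratio_f,
)
from zcspec.errors import DomainError, ValidationError


def _design_and_results(found_by_level_day):
    """Build a matching design table + quant results from a mapping
    {(level, day): [found values]}."""
    rows, results = [], []
    for (level, day), founds in found_by_level_day.items():
        for rep, found in enumerate(founds, start=1):
            sid = f"s_{level:g}_{day}_{rep}"
            rows.append({"sample_id": sid, "bup_ugml": level, "nal_ugml": 12.5,
                         "level": level, "day": day, "replicate": rep})
            results.append(QuantResult(sample_id=sid, analyte="bup",
                                       concentration_ugml=found,
                                       amplitude=0.0, in_range=True))
    design = ConcentrationDesign(pd.DataFrame(rows), ("bup", "nal"))
    return design, results


class TestAccuracyPrecision:
    def test_error_pct_matches_hand_computed_values(self):
        # mean found 19.97 at nominal 20 -> -0.15%; 49.95 at 50 -> -0.10%
        design, results = _design_and_results({
            (20.0, 1): [19.97, 19.97, 19.97],
            (50.0, 1): [49.95, 49.95, 49.95],
        })
        table = accuracy_precision(results, design).table
        within = table[table.scope == "within_day"].set_index("level_ugml")
        assert within.loc[20.0, "error_pct"] == pytest.approx(-0.15)
        assert within.loc[50.0, "error_pct"] == pytest.approx(-0.10)
        assert within["cv_pct"].abs().max() < 1e-9

    def test_within_day_and_between_day_pooling(self):
        design, results = _design_and_results({
            (20.0, d): [20.0 + 0.1 * d, 20.1 + 0.1 * d, 19.9 + 0.1 * d]
            for d in (1, 2, 3)
        })
        table = accuracy_precision(results, design).table
        within = table[table.scope == "within_day"]
        between = table[table.scope == "between_day"]
        assert list(within.n) == [3, 3, 3]
        assert list(between.n) == [9]
        found_all = [20.0 + 0.1 * d + off for d in (1, 2, 3) for off in (0, 0.1, -0.1)]
        assert between.mean_found_ugml.iloc[0] == pytest.approx(np.mean(found_all))
        assert between.sd_found_ugml.iloc[0] == pytest.approx(np.std(found_all, ddof=1))

    def test_cv_definition_on_random_table(self, rng):
        founds = list(rng.normal(50, 1, 3))
        design, results = _design_and_results({(50.0, 1): founds})
        row = accuracy_precision(results, design).table.iloc[0]
        assert row.cv_pct == pytest.approx(100 * np.std(founds, ddof=1) / np.mean(founds))
        assert row.error_pct == pytest.approx(100 * (np.mean(founds) - 50) / 50)

    def test_unmatched_sample_id_is_a_join_error(self):
        design, results = _design_and_results({(20.0, 1): [20.0, 20.0, 20.0]})
        results.append(QuantResult("ghost", "bup", 20.0, 0.0, True))
        with pytest.raises(ValidationError, match="ghost"):
            accuracy_precision(results, design)


class TestStandardAdditionRecovery:
    def _base(self, conc=50.0):
        return QuantResult("base", "bup", conc, 0.0, True)

    def _spiked(self, conc):
        return QuantResult("spiked", "bup", conc, 0.0, True)

    def test_exact_increment_is_100_percent(self):
        rep = standard_addition_recovery(
            self._base(50.0), [(10.0, self._spiked(60.0)),
                               (20.0, self._spiked(70.0))])
        assert np.allclose(rep.table.recovery_pct, 100.0)
        assert rep.mean_recovery_pct == pytest.approx(100.0)

    def test_recovery_arithmetic(self):
        rep = standard_addition_recovery(self._base(50.0),
                                         [(10.0, self._spiked(60.5))])
        assert rep.table.recovery_pct.iloc[0] == pytest.approx(105.0)

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(DomainError):
            standard_addition_recovery(self._base(), [(0.0, self._spiked(50.0))])


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        t, df = two_sample_t(2.0, 0.05, 3, 2.0, 0.05, 3)
        assert t == 0.0
        assert df == 4

    def test_pooled_t_on_printed_tablet_summaries(self):
        # summaries rounded to 2 dp give |t| ~ 0.42 by the pooled formula
        t, df = two_sample_t(2.01, 0.04, 3, 2.02, 0.01, 3)
        assert abs(t) == pytest.approx(0.42, abs=0.005)
        assert df == 4

    def test_zero_variance_with_different_means_is_infinite(self):
        t, _ = two_sample_t(2.0, 0.0, 3, 2.1, 0.0, 3)
        assert math.isinf(t)

    def test_antisymmetric_under_group_exchange(self, rng):
        m1, s1, m2, s2 = 10.0, 1.0, 11.5, 0.5
        t_ab, _ = two_sample_t(m1, s1, 4, m2, s2, 6)
        t_ba, _ = two_sample_t(m2, s2, 6, m1, s1, 4)
        assert t_ab == pytest.approx(-t_ba)

    def test_small_groups_rejected(self):
        with pytest.raises(DomainError):
            two_sample_t(1.0, 0.1, 1, 2.0, 0.1, 3)


class TestPairedT:
    def test_matches_scipy_on_random_differences(self, rng):
        from scipy import stats
        a = rng.normal(2.0, 0.05, 5)
        b = rng.normal(2.0, 0.05, 5)
        t, df = paired_t(a - b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert df == 4


class TestVarianceRatioF:
    def test_printed_tablet_ratio(self):
        # reference-method SD 0.01 vs test-method SD 0.04 -> 0.0625 (0.063 at 3 dp)
        f = variance_ratio_f(0.01, 0.04)
        assert f == pytest.approx(0.0625, rel=1e-12)
        assert round(f, 3) in (0.062, 0.063)  # 0.0625 prints as 0.063 half-up

    def test_equal_sds_give_unity(self):
        assert variance_ratio_f(0.02, 0.02) == pytest.approx(1.0)

    def test_exchange_maps_to_reciprocal(self):
        assert variance_ratio_f(0.04, 0.01) == pytest.approx(16.0)
        assert (variance_ratio_f(0.04, 0.01)
                == pytest.approx(1 / variance_ratio_f(0.01, 0.04)))

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            variance_ratio_f(0.01, 0.0)


class TestCriticalValues:
    def test_t_critical_matches_published_table_at_df2(self):
        assert t_critical(2, 0.05) == pytest.approx(4.303, abs=5e-4)

    def test_f_critical_matches_published_table_at_2_2(self):
        assert f_critical(2, 2, 0.05) == pytest.approx(19.00, abs=5e-3)

    def test_t_critical_normal_limit(self):
        assert t_critical(10 ** 7, 0.05) == pytest.approx(1.960, abs=5e-4)

    @pytest.mark.parametrize("call", [
        lambda: t_critical(0, 0.05), lambda: t_critical(2, 1.5),
        lambda: f_critical(0, 2, 0.05), lambda: f_critical(2, 2, 0.0),
    ])
    def test_invalid_arguments_rejected(self, call):
        with pytest.raises(DomainError):
            call()


class TestCompareMethods:
    def test_equivalence_requires_both_tests_inside_critical(self, rng):
        a = [2.01, 1.98, 2.03]
        b = [2.02, 2.01, 2.02]
        mc = compare_methods(a, b, t_mode="paired")
        assert mc.t_df == 2
        assert mc.t_crit == pytest.approx(4.303, abs=5e-4)
        assert mc.f_crit == pytest.approx(19.00, abs=5e-3)
        assert mc.equivalent == (abs(mc.t_stat) <= mc.t_crit and mc.f_stat <= mc.f_crit)

    def test_match_paper_puts_reference_variance_in_numerator(self):
        a = [2.01, 2.05, 1.97]  # test method, larger scatter
        b = [2.02, 2.02, 2.03]  # reference, tighter
        mc = compare_methods(a, b, match_paper=True)
        assert mc.f_stat == pytest.approx(np.var(b, ddof=1) / np.var(a, ddof=1))
        assert mc.f_stat < 1.0

    def test_pooled_mode_uses_summary_degrees_of_freedom(self):
        mc = compare_methods([2.0, 2.1, 1.9], [2.05, 2.0, 1.95, 2.0],
                             t_mode="pooled")
        assert mc.t_df == 5
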