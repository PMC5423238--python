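"""Assay validation statistics.

Within-day / between-day accuracy and precision (CV% and Error%),
standard-addition recovery, and method comparison against a reference
method by the two-sample t-test and the variance-ratio F-test with their
critical values.

Conventions
-----------
CV (%)    = 100 * SD / mean of found concentrations (sample SD, ddof=1).
Error (%) = 100 * (mean found - nominal) / nominal; negative values mean
            under-recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import QuantResult
from .errors import DomainError, ValidationError
from .io import ConcentrationDesign

__all__ = [
    "PrecisionAccuracyReport",
    "RecoveryReport",
    "MethodComparison",
    "accuracy_precision",
    "standard_addition_recovery",
    "two_sample_t",
    "paired_t",
    "variance_ratio_f",
    "t_critical",
    "f_critical",
    "compare_methods",
]


@dataclass
class PrecisionAccuracyReport:
    """Tidy accuracy/precision table.

    One row per (analyte, level, scope[, day]): within_day rows pool the
    replicates of a single day at one level (n = replicates); between_day
    rows pool all days at one level (n = days * replicates).
    """

    table: pd.DataFrame

    COLUMNS = ("analyte", "level_ugml", "scope", "day", "nominal_ugml",
               "mean_found_ugml", "sd_found_ugml", "cv_pct", "error_pct", "n")


@dataclass
class RecoveryReport:
    """Standard-addition recovery per spike level plus mean +/- SD."""

    table: pd.DataFrame  # columns: added_ugml, found_ugml, recovery_pct
    mean_recovery_pct: float
    sd_recovery_pct: float


@dataclass
class MethodComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    t_df: int
    f_stat: float
    t_crit: float
    f_crit: float
    alpha: float
    equivalent: bool
    t_mode: str = "pooled"


def _stats_row(found: np.ndarray, nominal: float) -> tuple[float, float, float, float]:
    mean = float(np.mean(found))
    sd = float(np.std(found, ddof=1)) if len(found) >= 2 else math.nan
    cv = 100.0 * sd / mean if mean != 0 else math.inf
    err = 100.0 * (mean - nominal) / nominal
    return mean, sd, cv, err


def accuracy_precision(
    results: list[QuantResult],
    nominals: ConcentrationDesign,
) -> PrecisionAccuracyReport:
    """Build the within-day / between-day accuracy and precision table.

    Every result must join (by sample_id) to a design row carrying the
    nominal concentration of its analyte plus day and level metadata.
    """
    design = nominals.table.set_index("sample_id")
    rows = []
    for r in results:
        if r.sample_id not in design.index:
            raise ValidationError(f"sample_id '{r.sample_id}' not found in design")
        d = design.loc[r.sample_id]
        rows.append({
            "analyte": r.analyte,
            "level_ugml": float(d["level"]),
            "day": int(d["day"]),
            "nominal_ugml": float(d[f"{r.analyte}_ugml"]),
            "found_ugml": r.concentration_ugml,
        })
    df = pd.DataFrame(rows)
    out = []
    for (analyte, level, day), grp in df.groupby(["analyte", "level_ugml", "day"]):
        nominal = float(grp["nominal_ugml"].iloc[0])
        mean, sd, cv, err = _stats_row(grp["found_ugml"].to_numpy(), nominal)
        out.append(dict(analyte=analyte, level_ugml=level, scope="within_day",
                        day=day, nominal_ugml=nominal, mean_found_ugml=mean,
                        sd_found_ugml=sd, cv_pct=cv, error_pct=err, n=len(grp)))
    for (analyte, level), grp in df.groupby(["analyte", "level_ugml"]):
        nominal = float(grp["nominal_ugml"].iloc[0])
        mean, sd, cv, err = _stats_row(grp["found_ugml"].to_numpy(), nominal)
        out.append(dict(analyte=analyte, level_ugml=level, scope="between_day",
                        day=pd.NA, nominal_ugml=nominal, mean_found_ugml=mean,
                        sd_found_ugml=sd, cv_pct=cv, error_pct=err, n=len(grp)))
    table = pd.DataFrame(out, columns=list(PrecisionAccuracyReport.COLUMNS))
    return PrecisionAccuracyReport(table=table)


def standard_addition_recovery(
    base: QuantResult,
    spiked: list[tuple[float, QuantResult]],
) -> RecoveryReport:
    """Classical standard-addition recovery.

    recovery% per spike = 100 * (found_spiked - found_base) / added.
    """
    rows = []
    for added, res in spiked:
        if added <= 0:
            raise DomainError(f"spike amount must be positive, got {added}")
        found_increment = res.concentration_ugml - base.concentration_ugml
        rows.append({
            "added_ugml": float(added),
            "found_ugml": float(res.concentration_ugml),
            "recovery_pct": 100.0 * found_increment / added,
        })
    table = pd.DataFrame(rows)
    rec = table["recovery_pct"].to_numpy()
    return RecoveryReport(
        table=table,
        mean_recovery_pct=float(np.mean(rec)),
        sd_recovery_pct=float(np.std(rec, ddof=1)) if len(rec) >= 2 else math.nan,
    )


def two_sample_t(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic and its df (n_a + n_b - 2).

    Degenerate zero-variance input: t = 0 if the means agree, +/-inf if
    they differ.
    """
    if n_a < 2 or n_b < 2:
        raise DomainError("both groups need n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise DomainError("standard deviations must be non-negative")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / df
    diff = mean_a - mean_b
    if sp2 == 0:
        return (0.0 if diff == 0 else math.copysign(math.inf, diff)), df
    t = diff / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return float(t), df


def paired_t(differences: "np.ndarray | list[float]") -> tuple[float, int]:
    """Paired t statistic on per-item differences; df = n - 1."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise DomainError("paired t needs >= 2 differences")
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0:
        return (0.0 if mean == 0 else math.copysign(math.inf, mean)), len(d) - 1
    return mean / (sd / math.sqrt(len(d))), len(d) - 1


def variance_ratio_f(sd_num: float, sd_den: float) -> float:
    """F = sd_num^2 / sd_den^2; the numerator/denominator assignment is
    the caller's choice."""
    if sd_den <= 0:
        raise DomainError("denominator SD must be positive")
    if sd_num < 0:
        raise DomainError("numerator SD must be non-negative")
    return float(sd_num ** 2 / sd_den ** 2)


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-tailed Student t critical value at significance ``alpha``."""
    if df < 1:
        raise DomainError(f"df must be >= 1, got {df}")
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def f_critical(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-tail F critical value at significance ``alpha``."""
    if df1 < 1 or df2 < 1:
        raise DomainError("both df must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def compare_methods(
    values_test: "np.ndarray | list[float]",
    values_ref: "np.ndarray | list[float]",
    alpha: float = 0.05,
    t_mode: str = "paired",
    match_paper: bool = True,
) -> MethodComparison:
    """Full method-comparison verdict between a test and a reference method.

    ``t_mode`` "paired" uses per-sample differences (df = n - 1, the
    convention matching a critical value of 4.303 for n = 3); "pooled" uses
    the independent two-sample statistic (df = n_a + n_b - 2).
    ``match_paper`` puts the reference method's variance in the F numerator.
    The methods are judged equivalent iff |t| <= t_crit and F <= F_crit.
    """
    a = np.asarray(values_test, dtype=float)
    b = np.asarray(values_ref, dtype=float)
    mean_a, sd_a = float(np.mean(a)), float(np.std(a, ddof=1))
    mean_b, sd_b = float(np.mean(b)), float(np.std(b, ddof=1))
    if t_mode == "paired":
        if len(a) != len(b):
            raise DomainError("paired comparison needs equal-length groups")
        t, df = paired_t(a - b)
    elif t_mode == "pooled":
        t, df = two_sample_t(mean_a, sd_a, len(a), mean_b, sd_b, len(b))
    else:
        raise DomainError(f"unknown t_mode '{t_mode}'")
    sd_num, sd_den = (sd_b, sd_a) if match_paper else (sd_a, sd_b)
    f_df = ((len(b) - 1, len(a) - 1) if match_paper
            else (len(a) - 1, len(b) - 1))
    if sd_den == 0:
        # degenerate zero-variance group (e.g. noise-free simulation)
        f = 0.0 if sd_num == 0 else math.inf
    else:
        f = variance_ratio_f(sd_num, sd_den)
    tc = t_critical(df, alpha)
    fc = f_critical(*f_df, alpha)
    return MethodComparison(
        mean_a=mean_a, sd_a=sd_a, n_a=len(a),
        mean_b=mean_b, sd_b=sd_b, n_b=len(b),
        t_stat=float(t), t_df=df, f_stat=float(f),
        t_crit=tc, f_crit=fc, alpha=alpha,
        equivalent=bool(abs(t) <= tc and f <= fc), t_mode=t_mode,
    )
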