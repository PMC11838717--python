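"""End-to-end orchestration: agreement, precision and risk stages.

These functions take in-memory cohorts (see :mod:`urised.cohort`) or tidy
QC frames and return tidy result frames; the CLI is a thin wrapper that
reads/writes CSV around them.  Values are kept at full precision here —
rounding happens only at the presentation layer.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import build_contingency, weighted_kappa, with_acceptability
from .cohort import column, validate_cohort
from .errors import InputError, UndefinedKappaError
from .grading import PARAMETERS, MergeMap, default_merge_maps, merge_categories
from .precision import PrecisionExperiment, ep15_precision, precision_verdict
from .risk import (
    DEFAULT_ERROR_TAXONOMY,
    DEFAULT_FALSE_POSITIVE_BANDS,
    OccurrenceBinning,
    RiskMatrix,
    RiskReport,
    assess_risks,
    false_positive_frequency,
    risk_report,
)


def compare_analyzers(
    cohort: pd.DataFrame,
    state: str = "pre",
    weight_scheme: str = "linear",
    rule: str = "ci_lower",
    threshold: float = 0.6,
    merge_maps: Mapping[str, MergeMap] | None = None,
    parameters: Sequence[str] = PARAMETERS,
) -> pd.DataFrame:
    """Per-parameter agreement of one review state against the reference.

    For each parameter the reference categories (``_ref``) and the chosen
    comparison state (``_pre`` or ``_post``) are merged per the merge map,
    cross-tabulated and summarised by weighted kappa.  Parameters whose
    table is degenerate (kappa undefined) are flagged rather than dropped.
    """
    if state not in ("pre", "post"):
        raise InputError(f"state must be 'pre' or 'post', got {state!r}")
    merge_maps = merge_maps if merge_maps is not None else default_merge_maps()
    validate_cohort(cohort, parameters=parameters, states=("ref", state))
    rows = []
    for param in parameters:
        mm = merge_maps[param]
        ref = merge_categories(cohort[column(param, "ref")], mm)
        cmp_ = merge_categories(cohort[column(param, state)], mm)
        table = build_contingency(
            zip(ref, cmp_), mm.level_labels(), parameter=param
        )
        try:
            result = with_acceptability(
                weighted_kappa(table, weight_scheme), rule, threshold
            )
            rows.append(
                {
                    "parameter": param,
                    "n": result.n,
                    "kappa": result.kappa,
                    "se": result.se,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "agreement_pct": result.percent_agreement,
                    "acceptable": result.acceptable,
                    "rule": rule,
                    "note": "",
                }
            )
        except UndefinedKappaError as exc:
            rows.append(
                {
                    "parameter": param,
                    "n": table.n,
                    "kappa": math.nan,
                    "se": math.nan,
                    "ci_low": math.nan,
                    "ci_high": math.nan,
                    "agreement_pct": 100.0 * np.trace(table.counts) / table.n,
                    "acceptable": False,
                    "rule": rule,
                    "note": f"kappa undefined: {exc}",
                }
            )
    return pd.DataFrame(rows)


def run_risk_analysis(
    cohort: pd.DataFrame,
    binning: OccurrenceBinning | None = None,
    matrix: RiskMatrix | None = None,
    occurrence_overrides: Mapping[str, int] | None = None,
) -> tuple[RiskReport, pd.DataFrame]:
    """Missed-element risk assessment plus the false-positive table."""
    report = risk_report(
        assess_risks(
            cohort,
            DEFAULT_ERROR_TAXONOMY,
            binning=binning,
            matrix=matrix,
            occurrence_overrides=occurrence_overrides,
        )
    )
    fp_rows = []
    for band in DEFAULT_FALSE_POSITIVE_BANDS:
        count, pct = false_positive_frequency(cohort, band.parameter, band.condition)
        fp_rows.append(
            {
                "parameter": band.parameter,
                "category": band.condition.label(),
                "count": count,
                "frequency_pct": pct,
            }
        )
    return report, pd.DataFrame(fp_rows)


def run_precision(
    qc: pd.DataFrame,
    thresholds: Mapping[str, float],
    declared_intervals: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Precision verification from a tidy QC frame.

    ``qc`` columns: ``analyte, level, day, replicate, value``.  Each
    (analyte, level) pair must form a complete days × replicates grid.
    ``thresholds`` maps analyte → allowable CV (%).
    """
    required = {"analyte", "level", "day", "replicate", "value"}
    missing = required - set(qc.columns)
    if missing:
        raise InputError(f"QC frame is missing columns: {sorted(missing)}")
    rows = []
    for (analyte, level), grp in qc.groupby(["analyte", "level"], sort=True):
        wide = grp.pivot(index="day", columns="replicate", values="value")
        if wide.isna().any().any():
            raise InputError(
                f"{analyte} {level}: incomplete days × replicates grid"
            )
        if analyte not in thresholds:
            raise InputError(f"no CV threshold declared for analyte {analyte!r}")
        interval = (
            declared_intervals.get((analyte, str(level)))
            if declared_intervals
            else None
        )
        exp = PrecisionExperiment(
            analyte=str(analyte),
            level=str(level),
            data=wide.to_numpy(),
            declared_interval=interval,
        )
        res = ep15_precision(exp)
        verdict = precision_verdict(
            res, thresholds[analyte], interval, exp.data if interval else None
        )
        rows.append(
            {
                "analyte": res.analyte,
                "level": res.level,
                "days": res.days,
                "replicates": res.replicates,
                "grand_mean": res.grand_mean,
                "s_r": res.s_r,
                "s_b": res.s_b,
                "s_wl": res.s_wl,
                "cv_within_run_pct": res.cv_within_run,
                "cv_between_run_pct": res.cv_between_run,
                "threshold_pct": verdict.threshold_pct,
                "passed": verdict.passed,
                "failures": "; ".join(verdict.failures),
            }
        )
    return pd.DataFrame(rows)
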