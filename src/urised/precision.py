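"""Precision verification from a days × replicates QC design.

A quality-control material is measured ``n`` times per day over ``d``
consecutive days (5×5 by default).  A one-way random-effects decomposition
of that design yields the repeatability (within-run) standard deviation
``s_r`` and the within-laboratory standard deviation ``s_wl``::

    s_r²  = Σ_d Σ_i (x_di − x̄_d)² / (d (n − 1))        pooled within-day
    s_b²  = max(0, Var(day means) − s_r²/n)             between-day component
    s_wl² = s_r² + s_b²

Coefficients of variation are reported against the grand mean; in this
package the "within-run" CV is ``100·s_r/mean`` and the "between-run" CV is
``100·s_wl/mean`` (the standard reading of a day×replicate verification
design, where between-run imprecision is total within-laboratory
imprecision).  A verification passes when both CVs are at or below the
declared threshold and, if an acceptable value interval is declared for the
material, every raw measurement lies inside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class PrecisionExperiment:
    """Replicate QC measurements: ``data[day, replicate]``."""

    analyte: str
    level: str
    data: np.ndarray
    declared_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.data, dtype=float)
        if x.ndim != 2:
            raise InputError("data must be a 2-D days × replicates matrix")
        d, n = x.shape
        if d < 2 or n < 2:
            raise InputError(f"need at least 2 days and 2 replicates, got {d}×{n}")
        if not np.all(np.isfinite(x)):
            raise InputError("data must be complete and finite (no missing cells)")
        if np.any(x < 0):
            raise InputError("measurements must be >= 0")
        x.setflags(write=False)
        object.__setattr__(self, "data", x)
        if self.declared_interval is not None:
            lo, hi = self.declared_interval
            if not lo <= hi:
                raise InputError("declared interval must satisfy low <= high")


@dataclass(frozen=True)
class PrecisionResult:
    analyte: str
    level: str
    grand_mean: float
    s_r: float
    s_b: float
    s_wl: float
    cv_within_run: float
    cv_between_run: float
    days: int
    replicates: int


@dataclass(frozen=True)
class PrecisionVerdict:
    passed: bool
    threshold_pct: float
    failures: tuple[str, ...] = field(default=())


def ep15_precision(exp: PrecisionExperiment) -> PrecisionResult:
    """Variance components and CVs of a days × replicates experiment."""
    x = exp.data
    d, n = x.shape
    day_means = x.mean(axis=1)
    s_r2 = float(((x - day_means[:, None]) ** 2).sum()) / (d * (n - 1))
    day_var = float(np.var(day_means, ddof=1))
    s_b2 = max(0.0, day_var - s_r2 / n)  # negative component clamped
    s_wl = math.sqrt(s_r2 + s_b2)
    s_r = math.sqrt(s_r2)
    mean = float(x.mean())
    if mean == 0.0:
        if s_wl > 0.0:
            raise InputError(
                f"{exp.analyte} {exp.level}: grand mean is 0 with nonzero "
                "dispersion; CV is undefined"
            )
        cv_within = cv_between = 0.0
    else:
        cv_within = 100.0 * s_r / mean
        cv_between = 100.0 * s_wl / mean
    return PrecisionResult(
        analyte=exp.analyte,
        level=exp.level,
        grand_mean=mean,
        s_r=s_r,
        s_b=math.sqrt(s_b2),
        s_wl=s_wl,
        cv_within_run=cv_within,
        cv_between_run=cv_between,
        days=d,
        replicates=n,
    )


def precision_verdict(
    result: PrecisionResult,
    threshold_pct: float,
    declared_interval: tuple[float, float] | None = None,
    measurements: np.ndarray | None = None,
) -> PrecisionVerdict:
    """Pass/fail against a CV threshold and an optional declared interval.

    Both CVs must be at or below ``threshold_pct`` (inclusive).  If a
    declared acceptable interval is given, every raw measurement must lie in
    it; pass ``measurements`` (the experiment's data) to enable that check.
    """
    if threshold_pct <= 0:
        raise InputError("threshold must be > 0")
    failures: list[str] = []
    if result.cv_within_run > threshold_pct:
        failures.append(
            f"within-run CV {result.cv_within_run:.1f}% > {threshold_pct:g}%"
        )
    if result.cv_between_run > threshold_pct:
        failures.append(
            f"between-run CV {result.cv_between_run:.1f}% > {threshold_pct:g}%"
        )
    if declared_interval is not None:
        if measurements is None:
            raise InputError("declared interval given but no measurements to check")
        lo, hi = declared_interval
        x = np.asarray(measurements, dtype=float)
        n_out = int(((x < lo) | (x > hi)).sum())
        if n_out:
            failures.append(
                f"{n_out} measurement(s) outside declared interval [{lo:g}, {hi:g}]"
            )
    return PrecisionVerdict(
        passed=not failures, threshold_pct=float(threshold_pct), failures=tuple(failures)
    )
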