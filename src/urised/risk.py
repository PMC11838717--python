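"""Severity × occurrence risk analysis of unreviewed analyzer results.

If the comparison analyzer's automatic image evaluation were reported
without operator review, some sediment elements would be missed: a sample
whose pre-review result is negative but whose post-review result is
positive is a missed-element (false-negative) error.  A fixed taxonomy of
23 such errors (E01–E23) pairs each sediment parameter and missed category
band with a patient-harm severity level:

S1  minimal harm, likely sample contamination
S2  repeat sample needed, no further harm
S3  delayed therapy from the missed element
S4  misdiagnosis with potentially life-threatening consequences

Each error's frequency is ``100 × count / N`` over the included cohort,
rounded half-up to one decimal, then binned into occurrence categories
O1 (< 1.0%), O2 (1–9%), O3 (10–19%), O4 (20–49%), O5 (≥ 50%).  A
severity × occurrence acceptability matrix in the style of ISO 14971
assigns each error a low / intermediate / high risk class; the default
matrix scores ``s + o`` (low ≤ 4, intermediate 5–6, high ≥ 7), which is
monotone along both axes, and can be overridden cell by cell.

The converse error — positive before review, negative after — is a false
positive; its frequency is quantified per parameter and category band but
carries no harm severity (the cost is rework, not a missed finding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import column
from .errors import ConfigError, InputError
from .grading import NEG, category_label

SEVERITY_LEVELS = (1, 2, 3, 4)
OCCURRENCE_LEVELS = (1, 2, 3, 4, 5)
RISK_CLASSES = ("low", "intermediate", "high")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero, as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoryCondition:
    """A contiguous band of positive categories, e.g. exactly +1 or ≥ +2."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not 1 <= self.lo <= self.hi <= 4:
            raise ConfigError(f"invalid category band [{self.lo}, {self.hi}]")

    def contains(self, category: int) -> bool:
        return self.lo <= category <= self.hi

    def label(self, max_category: int = 4) -> str:
        if self.lo == self.hi:
            return category_label(self.lo)
        if self.hi >= max_category:
            return f"≥ {category_label(self.lo)}"
        return f"{category_label(self.lo)} to {category_label(self.hi)}"


@dataclass(frozen=True)
class ErrorDefinition:
    """A missed-element error: parameter, post-review band, harm severity."""

    error_id: str
    parameter: str
    condition: CategoryCondition
    severity: int

    def __post_init__(self) -> None:
        if self.severity not in SEVERITY_LEVELS:
            raise ConfigError(f"{self.error_id}: severity must be one of S1..S4")


def _e(eid, param, lo, hi, sev):
    return ErrorDefinition(eid, param, CategoryCondition(lo, hi), sev)


#: The 23-error missed-element taxonomy with patient-harm severities.
DEFAULT_ERROR_TAXONOMY: tuple[ErrorDefinition, ...] = (
    _e("E01", "RBC", 1, 1, 1),
    _e("E02", "RBC", 2, 2, 3),
    _e("E03", "RBC", 3, 4, 4),
    _e("E04", "WBC", 1, 1, 1),
    _e("E05", "WBC", 2, 2, 2),
    _e("E06", "WBC", 3, 4, 4),
    _e("E07", "EPI", 1, 1, 1),
    _e("E08", "EPI", 2, 2, 3),
    _e("E09", "EPI", 3, 4, 4),
    _e("E10", "NEC", 1, 1, 2),
    _e("E11", "NEC", 2, 4, 3),
    _e("E12", "hyaline_casts", 1, 1, 1),
    _e("E13", "hyaline_casts", 2, 4, 3),
    _e("E14", "pathological_casts", 1, 1, 4),
    _e("E15", "bacteria", 1, 1, 1),
    _e("E16", "bacteria", 2, 3, 2),
    _e("E17", "total_crystals", 1, 1, 2),
    _e("E18", "total_crystals", 2, 4, 3),
    _e("E19", "CaOx", 1, 4, 2),
    _e("E20", "mucus", 1, 1, 1),
    _e("E21", "mucus", 2, 4, 2),
    _e("E22", "yeasts", 1, 1, 2),
    _e("E23", "yeasts", 2, 4, 3),
)


@dataclass(frozen=True)
class FalsePositiveDefinition:
    """A false-positive band: positive pre-review, negative post-review."""

    parameter: str
    condition: CategoryCondition


#: Parameter/category bands monitored for automatic-evaluation false positives.
DEFAULT_FALSE_POSITIVE_BANDS: tuple[FalsePositiveDefinition, ...] = (
    FalsePositiveDefinition("NEC", CategoryCondition(1, 1)),
    FalsePositiveDefinition("NEC", CategoryCondition(2, 4)),
    FalsePositiveDefinition("hyaline_casts", CategoryCondition(1, 1)),
    FalsePositiveDefinition("hyaline_casts", CategoryCondition(2, 4)),
    FalsePositiveDefinition("pathological_casts", CategoryCondition(1, 1)),
)


@dataclass(frozen=True)
class OccurrenceBinning:
    """Half-open frequency bins mapping an error frequency (%) to O1..O5.

    ``edges = (e1, e2, e3, e4)`` yields O1 = [0, e1), O2 = [e1, e2),
    O3 = [e2, e3), O4 = [e3, e4), O5 = [e4, 100].
    """

    edges: tuple[float, float, float, float] = (1.0, 10.0, 20.0, 50.0)

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        object.__setattr__(self, "edges", e)
        if len(e) != 4 or any(b <= a for a, b in zip(e, e[1:])):
            raise ConfigError("occurrence bin edges must be 4 increasing values")
        if e[0] <= 0 or e[-1] > 100:
            raise ConfigError("occurrence bin edges must lie in (0, 100]")

    def categorize(self, frequency_pct: float) -> int:
        if not 0.0 <= frequency_pct <= 100.0:
            raise InputError(f"frequency {frequency_pct!r} outside [0, 100]")
        for level, edge in enumerate(self.edges, start=1):
            if frequency_pct < edge:
                return level
        return 5


@dataclass(frozen=True)
class RiskMatrix:
    """Severity × occurrence → risk class, monotone along both axes.

    The default scores severity index plus occurrence index: low when
    ``s + o ≤ 4``, intermediate for 5–6, high for ≥ 7.  ``overrides`` maps
    ``(severity, occurrence)`` to a class and must keep the matrix monotone.
    """

    overrides: Mapping[tuple[int, int], str] | None = None

    def __post_init__(self) -> None:
        if self.overrides:
            for (s, o), cls in self.overrides.items():
                if s not in SEVERITY_LEVELS or o not in OCCURRENCE_LEVELS:
                    raise ConfigError(f"override cell (S{s}, O{o}) out of range")
                if cls not in RISK_CLASSES:
                    raise ConfigError(
                        f"risk class {cls!r} not one of {RISK_CLASSES}"
                    )
            self._check_monotone()

    def _check_monotone(self) -> None:
        rank = {c: i for i, c in enumerate(RISK_CLASSES)}
        for s in SEVERITY_LEVELS:
            for o in OCCURRENCE_LEVELS:
                here = rank[self.classify(s, o)]
                if s > 1 and rank[self.classify(s - 1, o)] > here:
                    raise ConfigError("risk matrix not monotone in severity")
                if o > 1 and rank[self.classify(s, o - 1)] > here:
                    raise ConfigError("risk matrix not monotone in occurrence")

    def classify(self, severity: int, occurrence: int) -> str:
        if severity not in SEVERITY_LEVELS or occurrence not in OCCURRENCE_LEVELS:
            raise InputError(f"invalid cell (S{severity}, O{occurrence})")
        if self.overrides and (severity, occurrence) in self.overrides:
            return self.overrides[(severity, occurrence)]
        score = severity + occurrence
        if score <= 4:
            return "low"
        if score <= 6:
            return "intermediate"
        return "high"


@dataclass(frozen=True)
class RiskAssessment:
    error_id: str
    parameter: str
    condition_label: str
    severity: int
    count: int
    frequency_pct: float
    occurrence: int
    risk_class: str


def detect_errors(
    cohort: pd.DataFrame,
    definitions: Sequence[ErrorDefinition] = DEFAULT_ERROR_TAXONOMY,
) -> dict[str, int]:
    """Count samples triggering each missed-element error.

    A sample counts toward an error when the comparison analyzer's
    pre-review category is negative and its post-review category falls in
    the error's band.  Because the bands of one parameter are disjoint, a
    sample triggers at most one error per parameter (it may trigger errors
    on several parameters).
    """
    counts: dict[str, int] = {}
    for d in definitions:
        pre_col, post_col = column(d.parameter, "pre"), column(d.parameter, "post")
        for col in (pre_col, post_col):
            if col not in cohort.columns:
                raise InputError(f"cohort is missing review-state column {col!r}")
        pre = cohort[pre_col]
        post = cohort[post_col]
        hit = (pre == NEG) & (post >= d.condition.lo) & (post <= d.condition.hi)
        counts[d.error_id] = int(hit.sum())
    return counts


def error_frequency(count: int, total: int = 463) -> float:
    """Error frequency in percent, rounded half-up to one decimal."""
    if total <= 0:
        raise InputError("total sample count must be > 0")
    if not 0 <= count <= total:
        raise InputError(f"count {count} outside [0, {total}]")
    return round_half_up(100.0 * count / total, 1)


def occurrence_category(
    frequency_pct: float, binning: OccurrenceBinning | None = None
) -> int:
    """Occurrence level O1..O5 (returned as 1..5) of a frequency."""
    binning = binning if binning is not None else OccurrenceBinning()
    return binning.categorize(frequency_pct)


def classify_risk(
    severity: int, occurrence: int, matrix: RiskMatrix | None = None
) -> str:
    matrix = matrix if matrix is not None else RiskMatrix()
    return matrix.classify(severity, occurrence)


def false_positive_frequency(
    cohort: pd.DataFrame,
    parameter: str,
    condition: CategoryCondition,
    total: int | None = None,
) -> tuple[int, float]:
    """Count and frequency of false positives for one parameter band.

    A false positive is a sample whose pre-review category falls in the band
    but whose post-review category is negative — the mirror image of a
    missed-element error, so no sample-parameter pair can be both.
    """
    pre_col, post_col = column(parameter, "pre"), column(parameter, "post")
    for col in (pre_col, post_col):
        if col not in cohort.columns:
            raise InputError(f"cohort is missing review-state column {col!r}")
    pre = cohort[pre_col]
    post = cohort[post_col]
    hit = (post == NEG) & (pre >= condition.lo) & (pre <= condition.hi)
    count = int(hit.sum())
    n = total if total is not None else len(cohort)
    return count, error_frequency(count, n)


def assess_risks(
    cohort: pd.DataFrame,
    definitions: Sequence[ErrorDefinition] = DEFAULT_ERROR_TAXONOMY,
    binning: OccurrenceBinning | None = None,
    matrix: RiskMatrix | None = None,
    occurrence_overrides: Mapping[str, int] | None = None,
    total: int | None = None,
) -> list[RiskAssessment]:
    """Full per-error risk assessment of a cohort.

    ``occurrence_overrides`` maps error ids to externally assigned
    occurrence levels (1..5); when an override disagrees with the binned
    frequency a warning is emitted and the override wins.  This supports
    reproducing published occurrence assignments that used a different
    binning than the stated one.
    """
    binning = binning if binning is not None else OccurrenceBinning()
    matrix = matrix if matrix is not None else RiskMatrix()
    counts = detect_errors(cohort, definitions)
    n = total if total is not None else len(cohort)
    out = []
    for d in definitions:
        count = counts[d.error_id]
        freq = error_frequency(count, n)
        occ = binning.categorize(freq)
        if occurrence_overrides and d.error_id in occurrence_overrides:
            override = occurrence_overrides[d.error_id]
            if override not in OCCURRENCE_LEVELS:
                raise ConfigError(
                    f"{d.error_id}: occurrence override must be 1..5"
                )
            if override != occ:
                warnings.warn(
                    f"{d.error_id}: computed occurrence O{occ} (frequency "
                    f"{freq}%) overridden to O{override}",
                    stacklevel=2,
                )
            occ = override
        out.append(
            RiskAssessment(
                error_id=d.error_id,
                parameter=d.parameter,
                condition_label=d.condition.label(),
                severity=d.severity,
                count=count,
                frequency_pct=freq,
                occurrence=occ,
                risk_class=matrix.classify(d.severity, occ),
            )
        )
    return out


@dataclass(frozen=True)
class RiskReport:
    """Aggregated risk-analysis results for a cohort."""

    assessments: tuple[RiskAssessment, ...]
    identified_errors: int  # errors observed at least once
    class_counts: Mapping[str, int]  # risk class -> number of identified errors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "error_id": [a.error_id for a in self.assessments],
                "parameter": [a.parameter for a in self.assessments],
                "missed_category": [a.condition_label for a in self.assessments],
                "severity": [f"S{a.severity}" for a in self.assessments],
                "count": [a.count for a in self.assessments],
                "frequency_pct": [a.frequency_pct for a in self.assessments],
                "occurrence": [f"O{a.occurrence}" for a in self.assessments],
                "risk_class": [a.risk_class for a in self.assessments],
            }
        )

    def matrix_text(self, matrix: RiskMatrix | None = None) -> str:
        """Severity × occurrence grid of identified error ids (aligned text)."""
        matrix = matrix if matrix is not None else RiskMatrix()
        cells: dict[tuple[int, int], list[str]] = {}
        for a in self.assessments:
            if a.count > 0:
                cells.setdefault((a.severity, a.occurrence), []).append(a.error_id)
        header = ["", "S1", "S2", "S3", "S4"]
        rows = [header]
        for o in reversed(OCCURRENCE_LEVELS):
            row = [f"O{o}"]
            for s in SEVERITY_LEVELS:
                ids = ", ".join(sorted(cells.get((s, o), [])))
                cls = matrix.classify(s, o)
                row.append(f"{ids} [{cls}]" if ids else f"[{cls}]")
            rows.append(row)
        widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(r, widths)) for r in rows
        )


def risk_report(assessments: Iterable[RiskAssessment]) -> RiskReport:
    """Summarise assessments: identified errors and risk-class tallies."""
    assessments = tuple(assessments)
    identified = [a for a in assessments if a.count > 0]
    class_counts = {cls: 0 for cls in RISK_CLASSES}
    for a in identified:
        class_counts[a.risk_class] += 1
    return RiskReport(
        assessments=assessments,
        identified_errors=len(identified),
        class_counts=class_counts,
    )
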