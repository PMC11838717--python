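"""Paired-analyzer cohort container and CSV round-trip.

A cohort is a :class:`pandas.DataFrame` with one row per urine sample and,
for every sediment parameter, one ordinal category per review state:

``<parameter>_ref``
    reference analyzer result after operator review (the comparison
    standard),
``<parameter>_pre``
    comparison analyzer result after automatic image evaluation, before any
    operator review,
``<parameter>_post``
    comparison analyzer result after operator review.

Categories are stored as small integers (0 = ``Neg`` .. 4 = ``+4``)
in memory and as the literals ``Neg, +1, +2, +3, +4`` (case-sensitive) in
CSV.  Optional ``<parameter>_conc`` columns hold latent concentrations in
particles/µL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import pandas as pd

from .errors import InputError
from .grading import PARAMETERS, category_label, parse_category

#: Review states, in analysis order.
STATES: tuple[str, ...] = ("ref", "pre", "post")


@dataclass(frozen=True)
class SampleRecord:
    """One specimen: category per parameter per review state."""

    sample_id: str
    categories: dict[str, dict[str, int]]  # parameter -> state -> category

    def category(self, parameter: str, state: str) -> int:
        try:
            return self.categories[parameter][state]
        except KeyError:
            raise InputError(
                f"sample {self.sample_id}: missing {parameter!r}/{state!r}"
            ) from None


def column(parameter: str, state: str) -> str:
    return f"{parameter}_{state}"


def validate_cohort(
    frame: pd.DataFrame,
    parameters: Sequence[str] = PARAMETERS,
    states: Sequence[str] = STATES,
) -> None:
    """Raise :class:`InputError` on missing columns or invalid categories."""
    if "sample_id" not in frame.columns:
        raise InputError("cohort is missing the 'sample_id' column")
    for p in parameters:
        for s in states:
            col = column(p, s)
            if col not in frame.columns:
                raise InputError(f"cohort is missing column {col!r}")
            vals = frame[col]
            if vals.isna().any():
                raise InputError(f"column {col!r} contains missing values")
            bad = vals[(vals < 0) | (vals > 4)]
            if len(bad):
                raise InputError(f"column {col!r} has out-of-range categories")


def records(
    frame: pd.DataFrame,
    parameters: Sequence[str] = PARAMETERS,
    states: Sequence[str] = STATES,
) -> Iterator[SampleRecord]:
    """Iterate a cohort frame as :class:`SampleRecord` objects."""
    for _, row in frame.iterrows():
        cats = {
            p: {s: int(row[column(p, s)]) for s in states} for p in parameters
        }
        yield SampleRecord(sample_id=str(row["sample_id"]), categories=cats)


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write a cohort with categories rendered as report literals."""
    out = frame.copy()
    for col in out.columns:
        if col.endswith(("_ref", "_pre", "_post")):
            out[col] = out[col].map(lambda v: category_label(int(v)))
    out.to_csv(path, index=False)


def read_cohort_csv(path, require_all: bool = True) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Category literals are parsed case-sensitively; unknown literals raise an
    :class:`InputError` naming the offending column and the allowed set.
    """
    frame = pd.read_csv(path, dtype=str)
    if frame.empty:
        raise InputError(f"{path}: empty cohort file")
    if "sample_id" not in frame.columns:
        raise InputError(f"{path}: missing 'sample_id' column")
    for col in frame.columns:
        if col.endswith(("_ref", "_pre", "_post")):
            try:
                frame[col] = frame[col].map(parse_category)
            except InputError as exc:
                raise InputError(f"{path}, column {col!r}: {exc}") from None
        elif col.endswith("_conc"):
            try:
                frame[col] = frame[col].astype(float)
            except ValueError:
                raise InputError(
                    f"{path}, column {col!r}: non-numeric concentration"
                ) from None
    if require_all:
        validate_cohort(frame)
    return frame
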