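"""Ordered-categorical agreement between two analyzers.

Agreement between the reference analyzer (results after operator review)
and the comparison analyzer is summarised per sediment parameter by
Cohen's weighted kappa on the k×k contingency table of (merged) ordinal
categories, together with exact percent agreement and an acceptability
verdict.

With agreement weights ``w_ij`` (1 on the diagonal), observed cell
proportions ``p_ij`` and marginals ``p_i., p_.j``::

    p_o = Σ w_ij p_ij          (weighted observed agreement)
    p_e = Σ w_ij p_i. p_.j     (weighted chance agreement)
    κ_w = (p_o − p_e) / (1 − p_e)

The default weights are linear, ``w_ij = 1 − |i−j|/(k−1)``; quadratic and
unweighted schemes are selectable.  For k = 2 all schemes coincide with the
classical unweighted kappa.  The standard error is the large-sample
(non-null) weighted-kappa variance of Fleiss, Cohen & Everitt, and the 95%
confidence interval is the Wald interval ``κ ± 1.96·se`` truncated to
[−1, 1].  A result is "acceptable" under the study rule when the lower 95%
confidence limit is at least 0.6 (a plain point-estimate rule is also
available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError, UndefinedKappaError

#: 97.5th percentile of the standard normal distribution.
Z_95 = 1.959963984540054

WEIGHT_SCHEMES = ("linear", "quadratic", "unweighted")
ACCEPTABILITY_RULES = ("ci_lower", "point_estimate")


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts of reference (rows) vs comparison (columns) categories."""

    parameter: str
    levels: tuple[str, ...]
    counts: np.ndarray
    # rows: reference analyzer after operator review; columns: comparison.

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise InputError("counts must be a square matrix")
        if counts.shape[0] != len(self.levels):
            raise InputError("counts dimension must match number of levels")
        if counts.shape[0] < 2:
            raise InputError("at least 2 levels required")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
                raise InputError("counts must be non-negative integers")
            counts = np.round(counts).astype(np.int64)
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        if self.n == 0:
            raise InputError("contingency table is empty (n = 0)")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class KappaResult:
    """Weighted kappa with its uncertainty and the agreement summary."""

    parameter: str
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    percent_agreement: float
    weight_scheme: str
    n: int
    acceptable: bool | None = None
    rule: str | None = None


def build_contingency(
    pairs: Iterable[tuple[int, int]],
    levels: Sequence[str] | int,
    parameter: str = "",
) -> ContingencyTable:
    """Count (reference, comparison) category pairs into a k×k table.

    ``levels`` is either the ordered level labels or their number; category
    values index the levels.
    """
    if isinstance(levels, int):
        labels = tuple(str(i) for i in range(levels))
    else:
        labels = tuple(levels)
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    n = 0
    for ref, cmp_ in pairs:
        if not (0 <= ref < k and 0 <= cmp_ < k):
            raise InputError(
                f"pair ({ref}, {cmp_}) outside declared levels 0..{k - 1}"
            )
        counts[ref, cmp_] += 1
        n += 1
    if n == 0:
        raise InputError("no category pairs supplied")
    return ContingencyTable(parameter=parameter, levels=labels, counts=counts)


def agreement_weights(k: int, weight_scheme: str = "linear") -> np.ndarray:
    """k×k agreement weight matrix (1 on the diagonal, 0 at the corners)."""
    if weight_scheme not in WEIGHT_SCHEMES:
        raise InputError(
            f"unknown weight scheme {weight_scheme!r}; allowed: {WEIGHT_SCHEMES}"
        )
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :])
    if weight_scheme == "unweighted":
        return (dist == 0).astype(float)
    scaled = dist / (k - 1)
    if weight_scheme == "linear":
        return 1.0 - scaled
    return 1.0 - scaled**2


def kappa_from_proportions(
    p: np.ndarray, weight_scheme: str = "linear"
) -> tuple[float, float, float]:
    """(κ_w, p_o, p_e) for a joint probability table.

    Used both for observed tables (``p = counts / n``) and for population
    joint distributions when computing a closed-form expected kappa.
    """
    p = np.asarray(p, dtype=float)
    w = agreement_weights(p.shape[0], weight_scheme)
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pr, pc)).sum())
    if 1.0 - pe < 1e-12:
        raise UndefinedKappaError(
            "chance agreement equals 1 (both raters confined to one identical "
            "category); kappa is undefined for this table"
        )
    return (po - pe) / (1.0 - pe), po, pe


def percent_agreement(table: ContingencyTable) -> float:
    """Exact (merged-)category agreement as a percentage of samples."""
    return 100.0 * float(np.trace(table.counts)) / table.n


def weighted_kappa(
    table: ContingencyTable, weight_scheme: str = "linear"
) -> KappaResult:
    """Weighted Cohen's kappa with large-sample SE and Wald 95% CI.

    The variance is the non-null large-sample form (Fleiss–Cohen–Everitt)::

        var = [ Σ p_ij (w_ij − (w̄_i. + w̄_.j)(1−κ))²  −  (κ − p_e(1−κ))² ]
              / ( n (1−p_e)² )

    with row/column average weights ``w̄_i. = Σ_j w_ij p_.j`` and
    ``w̄_.j = Σ_i w_ij p_i.``.
    """
    n = table.n
    p = table.counts / n
    kappa, po, pe = kappa_from_proportions(p, weight_scheme)
    w = agreement_weights(table.k, weight_scheme)
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    wbar_row = w @ pc  # w̄_i.
    wbar_col = w.T @ pr  # w̄_.j
    resid = w - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
    var = (
        float((p * resid**2).sum()) - (kappa - pe * (1.0 - kappa)) ** 2
    ) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    ci_low = max(-1.0, kappa - Z_95 * se)
    ci_high = min(1.0, kappa + Z_95 * se)
    return KappaResult(
        parameter=table.parameter,
        kappa=kappa,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        percent_agreement=percent_agreement(table),
        weight_scheme=weight_scheme,
        n=n,
    )


def acceptability(
    result: KappaResult, rule: str = "ci_lower", threshold: float = 0.6
) -> bool:
    """Acceptability verdict for an agreement result.

    ``ci_lower`` (the study rule) requires the lower 95% confidence limit to
    reach the threshold; ``point_estimate`` requires only the kappa estimate
    itself.  Both comparisons are inclusive.
    """
    if rule not in ACCEPTABILITY_RULES:
        raise InputError(
            f"unknown acceptability rule {rule!r}; allowed: {ACCEPTABILITY_RULES}"
        )
    if rule == "ci_lower":
        return result.ci_low >= threshold
    return result.kappa >= threshold


def with_acceptability(
    result: KappaResult, rule: str = "ci_lower", threshold: float = 0.6
) -> KappaResult:
    """Return a copy of ``result`` with the verdict and rule recorded."""
    return replace(result, acceptable=acceptability(result, rule, threshold), rule=rule)
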