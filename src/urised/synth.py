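"""Synthetic paired-analyzer cohorts and the bundled reference fixture.

Two generators live here.

:func:`generate_cohort` draws stochastic cohorts with the structure the
analysis assumes: each sample carries a latent particle concentration
(zero-inflated log-normal), the reference analyzer reports its graded
category, the comparison analyzer's pre-review category is drawn from a
per-parameter misclassification matrix conditioned on the reference
category, and operator review restores the reference category with a
configurable fidelity probability.  All randomness flows from one explicit
seed.

:func:`study_fixture` deterministically reconstructs a 463-sample cohort
whose summary statistics equal the published counts of the UAS 800 vs
UAS 60 comparison study this package models: per-parameter category
marginals for all three review states, per-error missed-element counts, and
false-positive counts.  The full joint cross-tabulations behind those
marginals were never published; the fixture fills them by a deterministic
greedy allocation that fixes every constrained cell and then maximises
diagonal (agreeing) mass.  Fixture joints are therefore a stated
convention, NOT the study's unpublished raw data, and agreement statistics
computed on the fixture are not comparable to the study's published kappas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import kappa_from_proportions
from .cohort import column
from .errors import ConfigError, InputError
from .grading import (
    PARAMETERS,
    GradingScheme,
    MergeMap,
    default_merge_maps,
    default_schemes,
)
from .risk import (
    DEFAULT_ERROR_TAXONOMY,
    DEFAULT_FALSE_POSITIVE_BANDS,
    ErrorDefinition,
)

#: Included sample count of the reference study cohort.
STUDY_N = 463

# Per-parameter category marginals (merged reporting levels) of the
# reference cohort, for the three review states: reference analyzer after
# review ("ref"), comparison analyzer before review ("pre") and after
# review ("post").  Level order follows the default merge maps.
STUDY_MARGINALS: Mapping[str, Mapping[str, tuple[int, ...]]] = {
    "RBC": {
        "ref": (193, 172, 44, 12, 42),
        "pre": (261, 111, 41, 9, 41),
        "post": (242, 133, 37, 12, 39),
    },
    "WBC": {
        "ref": (156, 181, 75, 20, 31),
        "pre": (205, 133, 78, 18, 29),
        "post": (176, 170, 70, 18, 29),
    },
    "WBC_clumps": {"ref": (449, 14), "pre": (453, 10), "post": (447, 16)},
    "EPI": {
        "ref": (272, 106, 62, 12, 11),
        "pre": (314, 84, 50, 8, 7),
        "post": (278, 125, 42, 10, 8),
    },
    "NEC": {"ref": (323, 116, 24), "pre": (298, 149, 16), "post": (357, 88, 18)},
    "hyaline_casts": {
        "ref": (412, 43, 8),
        "pre": (215, 229, 19),
        "post": (413, 38, 12),
    },
    "pathological_casts": {"ref": (458, 5), "pre": (381, 82), "post": (457, 6)},
    "bacteria": {
        "ref": (36, 164, 177, 86),
        "pre": (79, 119, 165, 100),
        "post": (34, 176, 165, 88),
    },
    "total_crystals": {
        "ref": (359, 81, 23),
        "pre": (443, 8, 12),
        "post": (356, 87, 20),
    },
    "CaOx": {"ref": (445, 18), "pre": (450, 13), "post": (442, 21)},
    "mucus": {
        "ref": (199, 164, 70, 30),
        "pre": (335, 64, 39, 25),
        "post": (197, 197, 46, 23),
    },
    "yeasts": {"ref": (444, 19), "pre": (446, 17), "post": (444, 19)},
    "sperm": {"ref": (460, 3), "pre": (463, 0), "post": (461, 2)},
}

#: Missed-element sample counts per error id in the reference cohort.
STUDY_ERROR_COUNTS: Mapping[str, int] = {
    "E01": 23, "E02": 0, "E03": 0, "E04": 32, "E05": 0, "E06": 0,
    "E07": 40, "E08": 0, "E09": 0, "E10": 2, "E11": 0, "E12": 1,
    "E13": 0, "E14": 1, "E15": 44, "E16": 2, "E17": 79, "E18": 11,
    "E19": 10, "E20": 139, "E21": 1, "E22": 4, "E23": 3,
}

#: False-positive sample counts per monitored band, aligned with
#: :data:`urised.risk.DEFAULT_FALSE_POSITIVE_BANDS`.
STUDY_FALSE_POSITIVE_COUNTS: tuple[int, ...] = (61, 0, 196, 3, 77)

#: Occurrence categories the reference study assigned to each error.  Three
#: of these (E15, E18, E19) disagree with the stated frequency bins; pass
#: :func:`study_occurrence_overrides` to reproduce the published matrix.
STUDY_OCCURRENCE: Mapping[str, int] = {
    "E01": 2, "E02": 1, "E03": 1, "E04": 2, "E05": 1, "E06": 1,
    "E07": 2, "E08": 1, "E09": 1, "E10": 1, "E11": 1, "E12": 1,
    "E13": 1, "E14": 1, "E15": 3, "E16": 1, "E17": 3, "E18": 1,
    "E19": 1, "E20": 4, "E21": 1, "E22": 1, "E23": 1,
}


def study_occurrence_overrides() -> dict[str, int]:
    """Published occurrence assignments that differ from the stated bins."""
    from .risk import OccurrenceBinning, error_frequency

    binning = OccurrenceBinning()
    out = {}
    for eid, occ in STUDY_OCCURRENCE.items():
        freq = error_frequency(STUDY_ERROR_COUNTS[eid], STUDY_N)
        if binning.categorize(freq) != occ:
            out[eid] = occ
    return out


# ---------------------------------------------------------------------------
# Deterministic fixture reconstruction
# ---------------------------------------------------------------------------


def _expand_marginal(
    merged: Sequence[int],
    groups: Sequence[Sequence[int]],
    demands: Mapping[int, int],
) -> list[int]:
    """Expand merged-level totals to raw categories.

    Constrained raw categories (``demands``) receive exactly their demanded
    mass; each group's remainder goes to its lowest raw member.
    """
    n_raw = sum(len(g) for g in groups)
    raw = [0] * n_raw
    for total, group in zip(merged, groups):
        rest = total
        for cat in group[1:]:
            d = demands.get(cat, 0)
            raw[cat] = d
            rest -= d
        low_demand = demands.get(group[0], 0)
        if rest < low_demand:
            raise AssertionError(
                f"marginal group {tuple(group)} (total {total}) cannot hold its "
                f"constrained cells"
            )
        raw[group[0]] = rest
    return raw


def _joint_pre_post(
    parameter: str,
    scheme: GradingScheme,
    merge_map: MergeMap,
    definitions: Sequence[ErrorDefinition] = DEFAULT_ERROR_TAXONOMY,
) -> np.ndarray:
    """Raw-category joint table of (pre-review, post-review) counts."""
    m = scheme.n_categories
    marg = STUDY_MARGINALS[parameter]
    fixed: dict[tuple[int, int], int] = {}
    # Missed-element constraints occupy row 0 (pre-review negative); the
    # whole band is fixed, with the count placed on its lowest category.
    for d in definitions:
        if d.parameter != parameter:
            continue
        span = range(d.condition.lo, min(d.condition.hi, m - 1) + 1)
        for j in span:
            fixed[(0, j)] = 0
        fixed[(0, d.condition.lo)] = STUDY_ERROR_COUNTS[d.error_id]
    # False-positive constraints occupy column 0 symmetrically.
    for band, count in zip(DEFAULT_FALSE_POSITIVE_BANDS, STUDY_FALSE_POSITIVE_COUNTS):
        if band.parameter != parameter:
            continue
        span = range(band.condition.lo, min(band.condition.hi, m - 1) + 1)
        for i in span:
            fixed[(i, 0)] = 0
        fixed[(band.condition.lo, 0)] = count

    row_demand: dict[int, int] = {}
    col_demand: dict[int, int] = {}
    for (i, j), c in fixed.items():
        row_demand[i] = row_demand.get(i, 0) + c
        col_demand[j] = col_demand.get(j, 0) + c
    rows = _expand_marginal(marg["pre"], merge_map.groups, row_demand)
    cols = _expand_marginal(marg["post"], merge_map.groups, col_demand)

    joint = np.zeros((m, m), dtype=np.int64)
    r_resid = np.array(rows, dtype=np.int64)
    c_resid = np.array(cols, dtype=np.int64)
    for (i, j), c in fixed.items():
        joint[i, j] = c
        r_resid[i] -= c
        c_resid[j] -= c
    if (r_resid < 0).any() or (c_resid < 0).any():
        raise AssertionError(
            f"{parameter}: constrained cells exceed a marginal total"
        )
    # Greedy fill, diagonal (agreement) first, then by ordinal distance.
    order = sorted(
        ((i, j) for i in range(m) for j in range(m) if (i, j) not in fixed),
        key=lambda ij: (abs(ij[0] - ij[1]), ij[0], ij[1]),
    )
    for i, j in order:
        take = min(r_resid[i], c_resid[j])
        if take > 0:
            joint[i, j] += take
            r_resid[i] -= take
            c_resid[j] -= take
    if r_resid.any() or c_resid.any():
        raise AssertionError(f"{parameter}: greedy allocation left residual mass")
    return joint


def _fixture_triples(
    parameter: str, scheme: GradingScheme, merge_map: MergeMap
) -> list[tuple[int, int, int]]:
    """(ref, pre, post) raw-category triples for one parameter, sorted."""
    joint = _joint_pre_post(parameter, scheme, merge_map)
    pairs: list[tuple[int, int]] = []
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            pairs.extend([(i, j)] * int(joint[i, j]))
    # Couple the reference marginal comonotonically with the post-review
    # category: review restores agreement with the reference, so aligning
    # sorted reference values with post-sorted samples maximises it.
    pairs.sort(key=lambda ij: (ij[1], ij[0]))
    ref_raw = _expand_marginal(
        STUDY_MARGINALS[parameter]["ref"], merge_map.groups, {}
    )
    ref_values = [cat for cat, count in enumerate(ref_raw) for _ in range(count)]
    return [(r, i, j) for r, (i, j) in zip(ref_values, pairs)]


def study_fixture() -> pd.DataFrame:
    """Deterministic 463-sample cohort matching the study's summary counts.

    Per-parameter merged-level marginals equal the published category
    distributions for all three review states; missed-element counts equal
    the published per-error counts; false-positive counts equal the
    published per-band counts.  Construction order is deterministic, so the
    frame is byte-identical across runs.
    """
    schemes = default_schemes()
    merge_maps = default_merge_maps(schemes)
    data: dict[str, list[int]] = {}
    for param in PARAMETERS:
        triples = _fixture_triples(param, schemes[param], merge_maps[param])
        if len(triples) != STUDY_N:
            raise AssertionError(f"{param}: fixture has {len(triples)} samples")
        data[column(param, "ref")] = [t[0] for t in triples]
        data[column(param, "pre")] = [t[1] for t in triples]
        data[column(param, "post")] = [t[2] for t in triples]
    frame = pd.DataFrame(data)
    frame.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(STUDY_N)])
    return frame


# ---------------------------------------------------------------------------
# Stochastic cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterModel:
    """Generative model of one sediment parameter.

    ``prevalence`` is the probability a sample truly contains the element;
    positive samples draw a log-normal concentration (``meanlog``/``sdlog``
    on the natural-log scale, particles/µL).  ``misclassification`` is the
    row-stochastic matrix ``M[true category, observed pre-review category]``
    of the comparison analyzer's automatic evaluation; operator review
    restores the true category with probability ``review_fidelity``,
    otherwise the pre-review category stands.
    """

    prevalence: float
    meanlog: float
    sdlog: float
    misclassification: tuple[tuple[float, ...], ...]
    review_fidelity: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("prevalence must be in [0, 1]")
        if not 0.0 <= self.review_fidelity <= 1.0:
            raise ConfigError("review fidelity must be in [0, 1]")
        if self.sdlog <= 0:
            raise ConfigError("sdlog must be > 0")
        m = np.asarray(self.misclassification, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConfigError("misclassification matrix must be square")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("misclassification rows must be probabilities summing to 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.misclassification, dtype=float)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic paired-analyzer cohort."""

    parameters: Mapping[str, ParameterModel]
    n_samples: int = STUDY_N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")


def default_misclassification(
    n_categories: int, false_positive_rate: float = 0.03, fidelity: float = 0.85
) -> tuple[tuple[float, ...], ...]:
    """Stylised automatic-evaluation error matrix.

    A truly negative sample is mis-read as ``+1`` with probability
    ``false_positive_rate``; a positive category keeps its level with
    probability ``fidelity`` and otherwise spills to its ordinal neighbours
    (folded at the scale ends).
    """
    if not 0.0 <= false_positive_rate < 1.0 or not 0.0 < fidelity <= 1.0:
        raise ConfigError("rates must be probabilities")
    k = n_categories
    m = np.zeros((k, k))
    m[0, 0] = 1.0 - false_positive_rate
    m[0, 1] = false_positive_rate
    spill = (1.0 - fidelity) / 2.0
    for i in range(1, k):
        m[i, i] = fidelity
        m[i, max(i - 1, 0)] += spill
        m[i, min(i + 1, k - 1)] += spill
    return tuple(tuple(row) for row in m)


# Pre-review false-positive rates reflecting the parameters the comparison
# analyzer over-calls most (casts and non-squamous epithelial cells).
_DEFAULT_FP_RATES = {"hyaline_casts": 0.45, "pathological_casts": 0.17, "NEC": 0.12}


def default_cohort_config(seed: int = 0, n_samples: int = STUDY_N) -> CohortConfig:
    """Study-scale default configuration.

    Prevalences follow the reference cohort's positivity rates; positive
    concentrations are log-normal, centred between each parameter's first
    two cutoffs with sdlog 1.0 so graded positives spread over several
    report levels.
    """
    schemes = default_schemes()
    params = {}
    for p, scheme in schemes.items():
        marg = STUDY_MARGINALS[p]["ref"]
        prevalence = 1.0 - marg[0] / STUDY_N
        c = scheme.cutoffs
        anchor = math.sqrt(c[0] * c[1]) if len(c) > 1 else 2.0 * c[0]
        params[p] = ParameterModel(
            prevalence=prevalence,
            meanlog=math.log(anchor),
            sdlog=1.0,
            misclassification=default_misclassification(
                scheme.n_categories,
                false_positive_rate=_DEFAULT_FP_RATES.get(p, 0.03),
            ),
            review_fidelity=0.9,
        )
    return CohortConfig(parameters=params, n_samples=n_samples, seed=seed)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    schemes = default_schemes()
    n = config.n_samples
    data: dict[str, np.ndarray] = {}
    for param, model in config.parameters.items():
        if param not in schemes:
            raise ConfigError(f"unknown parameter {param!r}")
        scheme = schemes[param]
        k = scheme.n_categories
        if model.matrix.shape[0] != k:
            raise ConfigError(
                f"{param}: misclassification matrix must be {k}×{k}"
            )
        positive = rng.random(n) < model.prevalence
        conc = np.where(
            positive, rng.lognormal(model.meanlog, model.sdlog, size=n), 0.0
        )
        ref = np.searchsorted(np.asarray(scheme.cutoffs), conc, side="right")
        cum = np.cumsum(model.matrix, axis=1)
        pre = (rng.random(n)[:, None] > cum[ref]).sum(axis=1)
        reviewed = rng.random(n) < model.review_fidelity
        post = np.where(reviewed, ref, pre)
        data[column(param, "conc")] = np.round(conc, 3)
        data[column(param, "ref")] = ref.astype(np.int64)
        data[column(param, "pre")] = pre.astype(np.int64)
        data[column(param, "post")] = post.astype(np.int64)
    frame = pd.DataFrame(data)
    frame.insert(0, "sample_id", [f"G{i + 1:05d}" for i in range(n)])
    return frame


# ---------------------------------------------------------------------------
# Closed-form expected agreement (oracle for parameter recovery)
# ---------------------------------------------------------------------------


def expected_kappa(
    misclassification: np.ndarray,
    marginal: Sequence[float],
    weight_scheme: str = "linear",
) -> float:
    """Population weighted kappa implied by a misclassification model.

    The joint distribution of (reference category, observed category) is
    ``p_ij = marginal_i · M_ij``; the population kappa is computed from it
    in closed form.
    """
    m = np.asarray(misclassification, dtype=float)
    marg = np.asarray(marginal, dtype=float)
    if m.shape[0] != len(marg):
        raise InputError("marginal length must match matrix dimension")
    if (marg < 0).any() or not math.isclose(float(marg.sum()), 1.0, abs_tol=1e-9):
        raise InputError("marginal must be a probability vector")
    if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise InputError("matrix rows must be probabilities summing to 1")
    joint = marg[:, None] * m
    return kappa_from_proportions(joint, weight_scheme)[0]


def category_marginal(model: ParameterModel, scheme: GradingScheme) -> np.ndarray:
    """Reference-category distribution implied by a generative model."""
    k = scheme.n_categories
    probs = np.zeros(k)
    cdf_vals = [
        0.5 * (1.0 + math.erf((math.log(c) - model.meanlog) / (model.sdlog * math.sqrt(2))))
        for c in scheme.cutoffs
    ]
    probs[0] = (1.0 - model.prevalence) + model.prevalence * cdf_vals[0]
    for i in range(1, k - 1):
        probs[i] = model.prevalence * (cdf_vals[i] - cdf_vals[i - 1])
    probs[k - 1] = model.prevalence * (1.0 - cdf_vals[-1])
    return probs


def calibrate_misclassification(
    target_kappa: float,
    marginal: Sequence[float],
    weight_scheme: str = "linear",
    tol: float = 1e-9,
) -> np.ndarray:
    """Misclassification matrix achieving a target population kappa.

    The family ``M(ε) = (1−ε)·I + ε·U`` (U has identical rows equal to the
    marginal of a uniform mix) interpolates from perfect agreement (κ=1 at
    ε=0) to independence (κ=0 at ε=1); the expected kappa is continuous and
    decreasing in ε, so bisection finds the target.
    """
    marg = np.asarray(marginal, dtype=float)
    k = len(marg)
    if not 0.0 < target_kappa < 1.0:
        raise InputError("target kappa must be in (0, 1)")
    identity = np.eye(k)
    uniform = np.full((k, k), 1.0 / k)

    def kappa_at(eps: float) -> float:
        return expected_kappa((1 - eps) * identity + eps * uniform, marg, weight_scheme)

    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if kappa_at(mid) > target_kappa:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    eps = 0.5 * (lo + hi)
    return (1 - eps) * identity + eps * uniform


def simulate_agreement_table(
    marginal: Sequence[float],
    misclassification: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial draw of an n-sample (reference, observed) count table."""
    marg = np.asarray(marginal, dtype=float)
    m = np.asarray(misclassification, dtype=float)
    joint = (marg[:, None] * m).ravel()
    return rng.multinomial(n, joint).reshape(len(marg), len(marg))
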