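# Methods

## Grading model

Automated sediment analyzers report each of 13 parameters on an ordinal
scale derived from a particle concentration (particles/µL). The bundled
cutoffs are the manufacturer's declared reporting bounds. Because the
instrument documentation prints gapped decimal ranges (RBC `+1` 1.1–9.1,
`+2` 9.2–34.1, …), a convention is needed to make grading total on the
concentration axis. `urised` uses half-open intervals
`[lower_k, lower_{k+1})` built from each category's printed lower bound:

- open-topped categories (`> x`) start at the next representable value at
  the printed resolution (RBC `+4` = `[45.6, ∞)`);
- where a negative bound and the `+1` lower bound disagree beyond the
  printed resolution (bacteria `Neg < 15` vs `+1` from 16), the negative
  bound wins (`+1` = `[15, 31)`), keeping coverage gap-free;
- two-level parameters (WBC clumps, pathological casts, sperm) have a
  single cutoff and `+1` is the only positive level.

Whether the instruments apply inclusive or exclusive comparisons exactly at
a cutoff is not documented; this convention is a design choice, made once,
and property-tested for totality and monotonicity.

Merging: agreement analysis uses order-preserving merge maps that collapse
sparse upper categories (NEC, hyaline casts, total crystals `+2..+4`; CaOx
and yeasts `+1..+4`; mucus `+3..+4`). Merge maps are validated to be
contiguous ordered partitions, and merging commutes with tabulation.

## Agreement statistics

Weighted Cohen's kappa with agreement weights `w_ij = 1 − |i−j|/(k−1)`
(linear; quadratic and unweighted selectable). The observed and chance
agreements are `p_o = Σ w_ij p_ij` and `p_e = Σ w_ij p_i· p_·j`, and
`κ_w = (p_o − p_e)/(1 − p_e)`. Linear weights are the default because the
commercial statistics packages laboratories typically use default to them;
for k = 2 every scheme reduces to the classical unweighted kappa.

The standard error is the non-null large-sample variance of Fleiss, Cohen
& Everitt; the 95% interval is Wald, `κ ± 1.96·se`, truncated to [−1, 1].
No continuity correction is applied to zero cells. Degenerate tables with
`p_e = 1` (both raters confined to one identical level — e.g. a parameter
absent from a whole cohort) raise an explicit undefined-kappa error, which
the pipeline converts to a flagged NaN row rather than dropping the
parameter.

Acceptability: the default rule requires the lower 95% confidence limit to
be ≥ 0.6 (inclusive); a point-estimate rule (`κ ≥ 0.6`) is exposed as a
configuration choice because laboratory practice varies between the two
readings, and the applied rule is recorded in every report row.

Verification in the test suite is dual-route: the implementation is checked
against the closed-form 2×2 kappa on an exhaustive grid (all tables with
n ≤ 50), against `statsmodels`' independent implementation (estimate and
SE to 1e-10), against a multinomial bootstrap SE (within 15% relative at
n = 60), and against a coverage simulation (93–97% at n = 463).

## Precision verification

A complete d×n days × replicates design (default 5×5) is decomposed as

    s_r²  = Σ_d Σ_i (x_di − x̄_d)² / (d(n−1))      repeatability
    s_b²  = max(0, Var(day means) − s_r²/n)        between-day component
    s_wl² = s_r² + s_b²                            within-laboratory

with the negative-component clamp that is standard for verification
designs. Terminology: the pipeline equates "within-run" with the
repeatability CV (`100·s_r/mean`) and "between-run" with the
within-laboratory CV (`100·s_wl/mean`) — the standard reading of a
day × replicate design, since day-to-day drift is what distinguishes the
two. A verification passes when both CVs are at or below the declared
threshold (inclusive) and, when an acceptable interval is declared for the
control material, every raw measurement lies inside it. An all-zero
control (blank) reports 0.0% CVs; a zero mean with nonzero dispersion is
rejected as undefined. Missing-cell designs are rejected rather than
imputed.

Simulation checks use σ_r = σ_b = 1 on a mean-50 material; over 2,000
replicates the mean estimated `s_r` and `s_wl` are within 5% of truth (the
small residual bias is the usual Jensen shrinkage of an estimated SD plus
the clamp).

## Risk analysis

The error taxonomy fixes 23 missed-element errors (parameter × post-review
category band) with severities S1–S4 assigned by clinical significance,
from contamination-level findings (mucus, squamous cells at +1) to missed
pathological casts (S4). Detection is purely categorical: a sample counts
toward an error when the comparison analyzer's pre-review category is
negative and its post-review category falls in the band; bands within a
parameter are disjoint, so a sample triggers at most one error per
parameter. The mirror-image false positives (positive pre-review, negative
after review) are tallied for the bands the automatic evaluation is known
to over-call (NEC, hyaline and pathological casts); by construction no
sample-parameter pair can be both.

Frequencies are `100·count/N` rounded half-up to one decimal **before**
occurrence binning, matching how printed reports round. The denominator is
the included-sample count (463 in the reference cohort), not the number of
submitted specimens; exclusions (insufficient volume, catheter samples,
delays, image-evaluation failures) are upstream of this package's input.

Occurrence bins are half-open: O1 [0, 1), O2 [1, 10), O3 [10, 20),
O4 [20, 50), O5 [50, 100]. The reference study's published occurrence
column contradicts these bins for three errors (E15 at 9.5% → printed O3;
E18 at 2.4% and E19 at 2.2% → printed O1); the source of those assignments
is not recoverable. Both behaviours are supported: computed binning is the
default, and explicit per-error occurrence overrides (the bundled
`study_occurrence_overrides()`) reproduce the published matrix, with a
warning whenever an override disagrees with the computed bin — never a
silent fix.

The default risk matrix scores severity plus occurrence indices: low when
`s + o ≤ 4`, intermediate for 5–6, high for ≥ 7. This rule reproduces every
published cell (green: S1×O1–O3, S2×O1–O2, S3×O1; yellow: S1×O4, S2×O3,
S4×O1), is monotone along both axes, and extends the same logic to cells
the study never realised (e.g. S4×O2 and above). Overrides are validated
cell-by-cell for completeness and monotonicity.

## Synthetic cohorts

`generate_cohort` emulates the paired-analyzer measurement process: a
sample is truly positive for a parameter with probability π (defaults:
the reference cohort's positivity rates); positive samples draw a
log-normal concentration (default meanlog at the geometric mean of the
first two cutoffs, sdlog 1.0 — chosen so graded positives spread over
several report levels, as real cohorts do); the reference category is the
graded concentration; the comparison analyzer's pre-review category is
drawn from a row-stochastic misclassification matrix conditioned on the
reference category (defaults: 0.85 diagonal fidelity with adjacent-level
spill, and elevated negative→+1 false-positive rates for hyaline casts
0.45, pathological casts 0.17, NEC 0.12, reflecting the elements digital
image evaluation over-calls); operator review restores the reference
category with probability 0.9, otherwise the pre-review value stands. One
explicit seed drives everything; no global generator state.

The closed-form `expected_kappa` of a (marginal, misclassification) pair is
the population weighted kappa of the implied joint `p_ij = π_i M_ij`; it
serves as the recovery oracle, and `calibrate_misclassification` bisects a
mixture-with-independence family to hit any target kappa.

What the generator does **not** emulate: particle degradation between the
two analyzers' runs (any systematic shift is only implicit in the
misclassification matrix), correlation between parameters within a sample,
operator-specific review behaviour, and day-to-day instrument drift.
Passing recovery tests therefore shows the estimators are correct under the
assumed measurement model, not that the model captures every feature of
real paired cohorts.

## The reference fixture

`study_fixture` rebuilds a 463-sample cohort whose per-parameter marginal
category counts (all three review states), missed-element counts and
false-positive counts equal the published summary tables of the two-analyzer
comparison study the package models. The published record contains only
marginals and those off-diagonal counts, so the fixture fills the remaining
joint cells deterministically: constrained cells are fixed first (missed
elements in the pre-negative row, false positives in the post-negative
column, each band's count placed on its lowest category and the rest of the
band zeroed), then remaining mass is allocated greedily by ordinal distance
(diagonal first), and the reference state is coupled comonotonically with
the post-review state. Every table-derived count is re-derived by
independent recounting in the test suite. Two published inconsistencies are
preserved as printed: the occurrence column discrepancies above, and a
narrative RBC false-negative count of 22 (4.8%) where the error table says
23 (5.0%) — the fixture follows the table.

## Numerical choices and problem sizes

- Rounding half-up (decimal, not banker's) to one decimal at the
  presentation layer only; all internal computation at full precision.
- CI truncation to [−1, 1]; SE variance floored at 0 before the square
  root.
- Greedy fixture tie-breaks: cells ordered by (|i−j|, row, column);
  deterministic, no randomness in fixtures.
- Category literals `Neg, +1, +2, +3, +4` are case-sensitive in CSV.
- Simulation sizes used by the checks: exhaustive 2×2 grid to n = 50
  (~316k tables); 10,000 bootstrap replicates per SE check; 1,000 tables
  for CI coverage; 500 cohorts × 3 agreement regimes for kappa recovery;
  2,000 replicates for precision recovery. These sizes give Monte-Carlo
  error comfortably below the tolerances they are checked against.

## Limitations

- The fixture's joint tables are a convention; kappas computed on it are
  fixture properties, not re-derivations of the study's published kappas
  (which cannot be recomputed from marginals alone).
- Wald intervals for kappa degrade near |κ| = 1 and for very sparse
  tables; the degenerate case is refused explicitly, but heavily sparse
  tables still rely on asymptotics.
- Trueness/bias verification against peer-group means is out of scope; the
  precision stage checks CVs and a declared interval only.
- No numeric (particles/µL) method comparison is implemented — the
  pipeline is deliberately categorical, mirroring how these analyzers are
  compared in practice.
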