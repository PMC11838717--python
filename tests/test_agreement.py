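"""Weighted kappa: oracles, invariances, acceptability rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import urised as u
from urised.errors import InputError, UndefinedKappaError


def table(counts, parameter="x"):
    counts = np.asarray(counts)
    return u.ContingencyTable(parameter, tuple(map(str, range(len(counts)))), counts)


def closed_form_2x2(a, b, c, d):
    """Independent textbook Cohen's kappa for a 2×2 table."""
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    return (po - pe) / (1 - pe)


class TestBuildContingency:
    def test_direct_count(self):
        t = u.build_contingency([(0, 0), (1, 0), (1, 1)], ("Neg", "+1"))
        assert t.counts.tolist() == [[1, 0], [1, 1]]
        assert t.n == 3

    def test_identical_pairs_are_diagonal(self):
        t = u.build_contingency([(2, 2)] * 7 + [(0, 0)] * 3, 3)
        assert np.trace(t.counts) == t.n == 10

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            u.build_contingency([], 2)

    def test_unseen_level_rejected(self):
        with pytest.raises(InputError):
            u.build_contingency([(0, 3)], 2)

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=60))
    @settings(derandomize=True, deadline=None)
    def test_marginals_match_brute_force_recount(self, pairs):
        t = u.build_contingency(pairs, 4)
        refs = [p[0] for p in pairs]
        for level in range(4):
            assert t.row_marginals()[level] == refs.count(level)
        assert t.n == len(pairs)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        r = u.weighted_kappa(table(np.diag([5, 3, 2])))
        assert r.kappa == pytest.approx(1.0)
        assert r.percent_agreement == 100.0

    def test_kappa_one_iff_diagonal(self):
        r = u.weighted_kappa(table([[5, 1], [0, 4]]))
        assert r.kappa < 1.0

    @pytest.mark.parametrize(
        "cells",
        [(10, 2, 3, 15), (1, 1, 1, 1), (20, 0, 5, 3), (7, 9, 2, 2), (0, 3, 4, 10)],
    )
    def test_2x2_matches_closed_form(self, cells):
        a, b, c, d = cells
        r = u.weighted_kappa(table([[a, b], [c, d]]))
        assert r.kappa == pytest.approx(closed_form_2x2(a, b, c, d), abs=1e-12)

    def test_k2_weighted_equals_unweighted(self):
        t = table([[12, 5], [3, 30]])
        for scheme in ("linear", "quadratic"):
            assert u.weighted_kappa(t, scheme).kappa == pytest.approx(
                u.weighted_kappa(t, "unweighted").kappa, abs=1e-12
            )

    def test_matches_statsmodels_kappa_and_se(self):
        """Independent implementation cross-check on random ordinal tables."""
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 25, size=(k, k))
            counts[np.diag_indices(k)] += rng.integers(3, 30, size=k)
            for wt, scheme in (("linear", "linear"), ("quadratic", "quadratic")):
                sm = cohens_kappa(counts, wt=wt)
                r = u.weighted_kappa(table(counts), scheme)
                assert r.kappa == pytest.approx(sm.kappa, abs=1e-10)
                assert r.se == pytest.approx(float(np.sqrt(sm.var_kappa)), abs=1e-10)

    def test_point_estimate_symmetric_in_raters(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 10, size=(4, 4))
        counts[0, 0] += 5
        assert u.weighted_kappa(table(counts)).kappa == pytest.approx(
            u.weighted_kappa(table(counts.T)).kappa, abs=1e-12
        )

    def test_invariant_under_level_order_reversal(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 10, size=(4, 4))
        counts[np.diag_indices(4)] += 5
        rev = counts[::-1, ::-1]
        r1, r2 = u.weighted_kappa(table(counts)), u.weighted_kappa(table(rev))
        assert r1.kappa == pytest.approx(r2.kappa, abs=1e-12)
        assert r1.se == pytest.approx(r2.se, abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 12, size=(3, 3)) + np.eye(3, dtype=int)
            r = u.weighted_kappa(table(counts))
            assert -1.0 <= r.ci_low <= r.kappa <= r.ci_high <= 1.0

    def test_degenerate_table_raises(self):
        with pytest.raises(UndefinedKappaError, match="chance agreement"):
            u.weighted_kappa(table([[10, 0], [0, 0]]))


class TestPercentAgreement:
    def test_examples(self):
        assert u.percent_agreement(table(np.diag([3, 4]))) == 100.0
        assert u.percent_agreement(table([[1, 1], [0, 2]])) == 75.0
        assert u.percent_agreement(table(np.ones((3, 3), dtype=int))) == pytest.approx(
            100 / 3
        )

    def test_merging_never_decreases_agreement(self):
        """Collapsing adjacent levels can only move mass onto the diagonal."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            counts = rng.integers(0, 8, size=(5, 5))
            counts[0, 0] += 1  # ensure n > 0
            cut = int(rng.integers(1, 4))
            groups = tuple(
                (lvl,) for lvl in range(cut)
            ) + (tuple(range(cut, 5)),)
            mm = u.MergeMap("x", groups)
            merged = np.zeros((mm.n_levels, mm.n_levels), dtype=int)
            for i, gi in enumerate(mm.groups):
                for j, gj in enumerate(mm.groups):
                    merged[i, j] = counts[np.ix_(gi, gj)].sum()
            assert u.percent_agreement(table(merged)) >= u.percent_agreement(
                table(counts)
            )


class TestAcceptability:
    def make(self, kappa, lo, hi):
        return u.KappaResult("x", kappa, 0.05, lo, hi, 90.0, "linear", 463)

    def test_strong_agreement_is_acceptable(self):
        assert u.acceptability(self.make(0.83, 0.69, 0.98), "ci_lower")

    def test_ci_lower_below_threshold_is_not(self):
        assert not u.acceptability(self.make(0.57, 0.51, 0.62), "ci_lower")

    def test_point_rule_boundary_inclusive(self):
        assert u.acceptability(self.make(0.60, 0.45, 0.75), "point_estimate")

    def test_rule_recorded(self):
        r = u.with_acceptability(self.make(0.7, 0.65, 0.75), "ci_lower")
        assert r.acceptable is True and r.rule == "ci_lower"

    def test_unknown_rule_rejected(self):
        with pytest.raises(InputError):
            u.acceptability(self.make(0.7, 0.6, 0.8), "majority_vote")
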