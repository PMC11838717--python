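"""Synthetic cohorts and the deterministic reference fixture."""

import numpy as np
import pandas as pd
import pytest

import urised as u
from urised.errors import ConfigError, InputError, UndefinedKappaError


class TestStudyFixture:
    def test_marginals_recounted_for_every_state(self, fixture_cohort, merge_maps):
        for param, marg in u.STUDY_MARGINALS.items():
            mm = merge_maps[param]
            for state in ("ref", "pre", "post"):
                merged = u.merge_categories(fixture_cohort[f"{param}_{state}"], mm)
                counts = np.bincount(merged, minlength=mm.n_levels)
                assert tuple(counts) == tuple(marg[state]), (param, state)

    def test_missed_element_counts_recounted_independently(self, fixture_cohort):
        """Recount with direct boolean logic, not via detect_errors."""
        for d in u.DEFAULT_ERROR_TAXONOMY:
            pre = fixture_cohort[f"{d.parameter}_pre"].to_numpy()
            post = fixture_cohort[f"{d.parameter}_post"].to_numpy()
            n = int(
                ((pre == 0) & (post >= d.condition.lo) & (post <= d.condition.hi)).sum()
            )
            assert n == u.STUDY_ERROR_COUNTS[d.error_id], d.error_id

    def test_false_positive_counts_recounted_independently(self, fixture_cohort):
        for band, expected in zip(
            u.DEFAULT_FALSE_POSITIVE_BANDS, u.STUDY_FALSE_POSITIVE_COUNTS
        ):
            pre = fixture_cohort[f"{band.parameter}_pre"].to_numpy()
            post = fixture_cohort[f"{band.parameter}_post"].to_numpy()
            n = int(
                ((post == 0) & (pre >= band.condition.lo) & (pre <= band.condition.hi)).sum()
            )
            assert n == expected, (band.parameter, band.condition)

    def test_reference_negative_marginal_example(self, fixture_cohort):
        assert (fixture_cohort["RBC_ref"] == 0).sum() == 193

    def test_deterministic(self, fixture_cohort):
        again = u.study_fixture()
        pd.testing.assert_frame_equal(fixture_cohort, again)


class TestGenerateCohort:
    def test_identity_misclassification_makes_states_agree(self):
        k = 5
        model = u.ParameterModel(
            prevalence=0.5,
            meanlog=2.0,
            sdlog=1.0,
            misclassification=tuple(tuple(row) for row in np.eye(k)),
            review_fidelity=0.3,
        )
        frame = u.generate_cohort(
            u.CohortConfig(parameters={"RBC": model}, n_samples=200, seed=1)
        )
        assert (frame["RBC_pre"] == frame["RBC_ref"]).all()
        assert (frame["RBC_post"] == frame["RBC_ref"]).all()

    def test_reference_category_is_graded_concentration(self):
        frame = u.generate_cohort(u.default_cohort_config(seed=2, n_samples=100))
        scheme = u.default_schemes()["WBC"]
        graded = [scheme.grade(c) for c in frame["WBC_conc"]]
        assert graded == frame["WBC_ref"].tolist()

    def test_same_seed_reproduces_byte_identical_csv(self, tmp_path):
        paths = []
        for i in range(2):
            p = tmp_path / f"c{i}.csv"
            u.write_cohort_csv(
                u.generate_cohort(u.default_cohort_config(seed=99, n_samples=50)), p
            )
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_zero_prevalence_parameter_flagged_as_undefined_kappa(self):
        model = u.ParameterModel(
            prevalence=0.0,
            meanlog=0.0,
            sdlog=1.0,
            misclassification=tuple(tuple(row) for row in np.eye(2)),
        )
        frame = u.generate_cohort(
            u.CohortConfig(parameters={"sperm": model}, n_samples=50, seed=3)
        )
        assert (frame["sperm_ref"] == 0).all()
        report = u.compare_analyzers(frame, state="pre", parameters=("sperm",))
        assert np.isnan(report.loc[0, "kappa"])
        assert "undefined" in report.loc[0, "note"]

    def test_invalid_matrix_rows_rejected(self):
        with pytest.raises(ConfigError, match="summing to 1"):
            u.ParameterModel(0.5, 0.0, 1.0, ((0.5, 0.4), (0.0, 1.0)))


class TestExpectedKappa:
    def test_identity_matrix_gives_one(self):
        marg = [0.4, 0.4, 0.2]
        assert u.expected_kappa(np.eye(3), marg) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        m = np.full((3, 3), 1 / 3)
        assert u.expected_kappa(m, [1 / 3] * 3) == pytest.approx(0.0, abs=1e-12)

    def test_matches_large_simulation(self):
        marg = np.array([0.5, 0.3, 0.2])
        m = np.array([[0.8, 0.15, 0.05], [0.2, 0.6, 0.2], [0.1, 0.2, 0.7]])
        truth = u.expected_kappa(m, marg)
        rng = np.random.default_rng(12)
        counts = u.simulate_agreement_table(marg, m, 10**6, rng)
        empirical = u.weighted_kappa(
            u.ContingencyTable("x", ("a", "b", "c"), counts)
        ).kappa
        assert empirical == pytest.approx(truth, abs=0.005)

    def test_degenerate_marginal_undefined(self):
        with pytest.raises(UndefinedKappaError):
            u.expected_kappa(np.eye(2), [1.0, 0.0])

    def test_more_discordance_never_raises_expected_kappa(self):
        """Mixing extra uniform (independent) mass into the observation
        matrix is a mean-preserving increase in discordance."""
        marg = np.array([0.5, 0.3, 0.2])
        uniform = np.full((3, 3), 1 / 3)
        base = np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.2, 0.8]])
        kappas = [
            u.expected_kappa((1 - eps) * base + eps * uniform, marg)
            for eps in np.linspace(0, 1, 11)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(kappas, kappas[1:]))

    def test_calibration_hits_target(self):
        marg = np.array(u.STUDY_MARGINALS["RBC"]["ref"]) / u.STUDY_N
        for target in (0.2, 0.5, 0.8):
            m = u.calibrate_misclassification(target, marg)
            assert u.expected_kappa(m, marg) == pytest.approx(target, abs=1e-6)

    def test_category_marginal_is_a_distribution(self):
        cfg = u.default_cohort_config()
        for param, model in cfg.parameters.items():
            marg = u.category_marginal(model, u.default_schemes()[param])
            assert marg.sum() == pytest.approx(1.0)
            assert (marg >= 0).all()


class TestCohortIO:
    def test_csv_round_trip_preserves_categories(self, fixture_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        u.write_cohort_csv(fixture_cohort, path)
        back = u.read_cohort_csv(path)
        pd.testing.assert_frame_equal(fixture_cohort, back)

    def test_unknown_literal_names_column_and_allowed_set(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = ["sample_id"] + [
            f"{p}_{s}" for p in u.PARAMETERS for s in ("ref", "pre", "post")
        ]
        row = ["S1"] + ["Neg"] * (len(header) - 1)
        row[1] = "negative"
        path.write_text(",".join(header) + "\n" + ",".join(row) + "\n")
        with pytest.raises(InputError, match="RBC_ref.*Neg, \\+1"):
            u.read_cohort_csv(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("sample_id\n")
        with pytest.raises(InputError, match="empty"):
            u.read_cohort_csv(path)

    def test_records_expose_categories(self, fixture_cohort):
        rec = next(u.records(fixture_cohort.head(1)))
        assert rec.sample_id == "S0001"
        assert rec.category("RBC", "ref") in range(5)
        with pytest.raises(InputError):
            rec.category("RBC", "shaken")
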