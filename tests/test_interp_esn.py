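"""Monthly interpolation, skip sampling and the probability readout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esntsc.interp_esn import (
    InterpESN,
    IrregularCohort,
    Participant,
    StackedStates,
    build_stacked_matrix,
    fit_prob_classifier,
    forecast_truncate,
    interpolate_monthly,
    predict_participant,
    skip_select,
)


def participant(times, values, outcome=0, pid="P1"):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return Participant(id=pid, visit_times=np.asarray(times, dtype=float),
                       visit_values=values, outcome=outcome)


class TestInterpolation:
    def test_linear_midpoint(self):
        ms = interpolate_monthly(participant([0, 2], [1.0, 3.0]))
        assert np.array_equal(ms.months, [0, 1, 2])
        assert np.allclose(ms.values[:, 0], [1.0, 2.0, 3.0])

    def test_knots_reproduced_exactly(self):
        vals = [0.3, -1.2, 4.5, 0.0]
        ms = interpolate_monthly(participant([0, 1, 2, 3], vals))
        assert np.allclose(ms.values[:, 0], vals)
        assert ms.m == 4

    def test_markers_interpolated_independently(self):
        vals = np.column_stack([[0.0, 3.0], [5.0, 5.0]])
        ms = interpolate_monthly(participant([0, 3], vals))
        assert np.allclose(ms.values[:, 0], [0, 1, 2, 3])
        assert np.allclose(ms.values[:, 1], 5.0)

    def test_fractional_last_visit_appended(self):
        ms = interpolate_monthly(participant([0.0, 2.5], [0.0, 5.0]))
        assert np.allclose(ms.months, [0, 1, 2, 2.5])
        assert ms.values[-1, 0] == 5.0  # exact last screen retained

    def test_grid_starts_at_first_record(self):
        ms = interpolate_monthly(participant([100.0, 103.0], [1.0, 4.0]))
        assert ms.months[0] == 0.0
        assert np.allclose(ms.values[:, 0], [1, 2, 3, 4])

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            Participant(id="x", visit_times=np.array([0.0, 0.0]),
                        visit_values=np.zeros((2, 1)), outcome=0)


class TestSkipSelect:
    def test_worked_example(self):
        assert skip_select(10, 4).tolist() == [2, 6, 10]

    def test_no_skip_keeps_everything(self):
        assert skip_select(7, 1).tolist() == [1, 2, 3, 4, 5, 6, 7]

    def test_single_point_kept(self):
        assert skip_select(1, 3).tolist() == [1]

    def test_invalid_skip_rejected(self):
        with pytest.raises(ValueError):
            skip_select(5, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=st.integers(1, 100), tau=st.integers(1, 100))
    def test_matches_backward_enumeration_oracle(self, n, tau):
        oracle = []
        j = n
        while j >= 1:
            oracle.append(j)
            j -= tau
        oracle = sorted(oracle)
        got = skip_select(n, tau).tolist()
        assert got == oracle
        assert n in got
        assert len(got) == -(-n // tau)  # ceil(n / tau)


def _toy_states(lengths, M=4, seed=0):
    rng = np.random.default_rng(seed)
    return [rng.standard_normal((m, M)) for m in lengths]


class TestStacking:
    def test_full_stack_row_count(self):
        lengths = [5, 8, 3]
        stacked = build_stacked_matrix(_toy_states(lengths), [0, 1, 0],
                                       ["a", "b", "c"], tau=1)
        assert stacked.X.shape[0] == sum(lengths) == len(stacked.y)

    def test_skip_rows_and_replicated_labels(self):
        stacked = build_stacked_matrix(_toy_states([10]), [1], ["a"], tau=4)
        assert stacked.X.shape[0] == 3
        assert stacked.y.tolist() == [1, 1, 1]

    def test_identical_series_opposite_labels(self):
        S = _toy_states([6])[0]
        stacked = build_stacked_matrix([S, S.copy()], [0, 1], ["a", "b"], tau=2)
        half = stacked.X.shape[0] // 2
        assert np.array_equal(stacked.X[:half], stacked.X[half:])
        assert set(stacked.y[:half]) == {0} and set(stacked.y[half:]) == {1}

    def test_provenance_records_last_month(self):
        months = [np.array([0.0, 1.0, 2.0, 2.6])]
        stacked = build_stacked_matrix(_toy_states([4]), [1], ["a"], tau=2,
                                       months=months)
        assert stacked.row_index[-1] == ("a", 2.6)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_stacked_matrix([], [], [], tau=1)


def _separable_stack(n_per=40, gap=6.0, M=5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_per, M)),
                   rng.standard_normal((n_per, M)) + gap])
    y = np.array([0] * n_per + [1] * n_per)
    idx = [("p", float(i)) for i in range(2 * n_per)]
    blocks = [slice(0, n_per), slice(n_per, 2 * n_per)]
    return StackedStates(X=X, y=y, row_index=idx, blocks=blocks)


class TestProbabilityReadout:
    def test_separable_probabilities_confident_and_valid(self):
        stacked = _separable_stack()
        clf = fit_prob_classifier(stacked)
        proba = clf.predict_proba(stacked.X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.all((proba > 0) & (proba < 1))
        pos = proba[:, int(np.argmax(clf.classes_))]
        correct = np.where(stacked.y == 1, pos, 1 - pos)
        assert np.all(correct >= 0.9)

    def test_single_class_rejected(self):
        stacked = _separable_stack()
        bad = StackedStates(X=stacked.X, y=np.zeros_like(stacked.y),
                            row_index=stacked.row_index, blocks=stacked.blocks)
        with pytest.raises(ValueError):
            fit_prob_classifier(bad)

    def test_prediction_reads_only_final_row(self):
        stacked = _separable_stack()
        clf = fit_prob_classifier(stacked)
        rows = stacked.X[:5].copy()
        p1 = predict_participant(clf, rows)
        rows[:4] = 999.0  # earlier rows must not matter
        assert predict_participant(clf, rows) == p1
        assert predict_participant(clf, rows[-1:]) == p1


class TestForecastTruncate:
    def test_truncation_arithmetic(self):
        stacked, excluded = forecast_truncate(_toy_states([12]), [1], ["a"],
                                              gamma=6, tau=1)
        assert stacked.X.shape[0] == 6
        assert excluded == []

    def test_short_participant_excluded(self):
        stacked, excluded = forecast_truncate(_toy_states([5, 12]), [0, 1],
                                              ["short", "long"], gamma=6, tau=1)
        assert excluded == ["short"]
        assert set(stacked.y) == {1}

    def test_gamma_zero_rejected(self):
        with pytest.raises(ValueError):
            forecast_truncate(_toy_states([10]), [1], ["a"], gamma=0)

    def test_all_too_short_rejected(self):
        with pytest.raises(ValueError):
            forecast_truncate(_toy_states([4, 5]), [0, 1], ["a", "b"], gamma=6)


class TestPipeline:
    def test_fit_predict_shapes_and_determinism(self, cohort):
        model = InterpESN(M=20, seed=3).fit(cohort)
        p1, y1, excl = model.predict_proba(cohort)
        assert len(p1) == cohort.N and len(y1) == cohort.N and excl == []
        assert np.all((p1 > 0) & (p1 < 1))
        model2 = InterpESN(M=20, seed=3).fit(cohort)
        p2, _, _ = model2.predict_proba(cohort)
        assert np.array_equal(p1, p2)

    def test_forecast_excludes_short_participants(self, cohort):
        model = InterpESN(M=20, seed=3).fit(cohort)
        probs, outs, excl = model.predict_proba(cohort, gamma=6)
        short = [p.id for p in cohort.participants
                 if len(interp_months(p)) - 6 < 1]
        assert sorted(excl) == sorted(short)
        assert len(probs) == cohort.N - len(excl)

    def test_year_unit_cohort_converted_to_months(self):
        p_years = participant([50.0, 50.25], [1.0, 4.0])
        cohort_y = IrregularCohort(participants=[p_years], marker_names=["m"],
                                   time_unit="years")
        ms = interpolate_monthly(p_years,
                                 times_in_months=cohort_y.times_in_months(p_years))
        assert ms.m == 4  # 3 months span -> months 0..3
        assert np.allclose(ms.values[:, 0], [1, 2, 3, 4])


def interp_months(p):
    return interpolate_monthly(p).months
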