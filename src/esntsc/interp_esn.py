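"""Interpolation echo state network for irregular longitudinal series.

Screening-style biomarker data consist of a handful of visits per
participant at uneven times.  The method fits a piecewise-linear curve
through each participant's visits, resamples it on a monthly grid since the
first record, drives a fixed random reservoir with the resampled sequence
(state reset per participant), and stacks a subset of the per-month internal
states into a design matrix: every tau-th state counted backwards from the
last timestamp ("skip sampling"), the last timestamp always retained because
the most recent screen carries the most clinical relevance.  A linear SVM
with calibrated probability outputs is trained on the stacked states, each
row labelled with its participant's outcome; a participant's prediction is
the probability at their final retained row.

Truncating the test-side sequences gamma months before their last record
turns the same trained model into a gamma-month-ahead forecaster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .reservoir import ReservoirSpec, ReservoirWeights, build_reservoir, run_sequence

__all__ = [
    "Participant",
    "IrregularCohort",
    "MonthlySeries",
    "StackedStates",
    "interpolate_monthly",
    "skip_select",
    "build_stacked_matrix",
    "fit_prob_classifier",
    "predict_participant",
    "forecast_truncate",
    "InterpESN",
]


@dataclass
class Participant:
    """One screened participant: visit times, marker values and outcome.

    ``visit_times`` are strictly increasing, in months unless the cohort
    declares otherwise; ``visit_values`` is an (n_visits, k) matrix.
    """

    id: object
    visit_times: np.ndarray
    visit_values: np.ndarray
    outcome: int

    def __post_init__(self) -> None:
        self.visit_times = np.asarray(self.visit_times, dtype=float)
        self.visit_values = np.atleast_2d(np.asarray(self.visit_values, dtype=float))
        if self.visit_values.shape[0] != self.visit_times.shape[0]:
            raise ValueError(f"participant {self.id}: times and values disagree in length")
        if len(self.visit_times) < 2:
            raise ValueError(f"participant {self.id}: needs >= 2 visits")
        d = np.diff(self.visit_times)
        if np.any(d <= 0):
            raise ValueError(f"participant {self.id}: visit times must strictly increase")

    @property
    def n_visits(self) -> int:
        return len(self.visit_times)

    @property
    def k(self) -> int:
        return self.visit_values.shape[1]


@dataclass
class IrregularCohort:
    """A set of participants sharing a marker panel, with binary outcomes."""

    participants: List[Participant]
    marker_names: Sequence[str]
    time_unit: str = "months"  # "months" or "years"

    def __post_init__(self) -> None:
        k = len(self.marker_names)
        for p in self.participants:
            if p.k != k:
                raise ValueError(f"participant {p.id} has {p.k} markers, cohort declares {k}")

    @property
    def N(self) -> int:
        return len(self.participants)

    @property
    def k(self) -> int:
        return len(self.marker_names)

    def outcomes(self) -> np.ndarray:
        return np.array([p.outcome for p in self.participants])

    def times_in_months(self, p: Participant) -> np.ndarray:
        return p.visit_times * 12.0 if self.time_unit == "years" else p.visit_times

    def subset(self, indices: Sequence[int]) -> "IrregularCohort":
        return IrregularCohort(
            participants=[self.participants[i] for i in indices],
            marker_names=self.marker_names,
            time_unit=self.time_unit,
        )


@dataclass
class MonthlySeries:
    """A participant resampled on a monthly grid since their first record."""

    id: object
    months: np.ndarray  # (m,) grid, starts at 0; final point may be fractional
    values: np.ndarray  # (m, k)
    outcome: int

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass
class StackedStates:
    """Design matrix of retained internal states with replicated labels.

    ``row_index`` records (participant id, month) provenance per row, and
    ``blocks`` the slice of rows belonging to each participant in order.
    """

    X: np.ndarray
    y: np.ndarray
    row_index: List[Tuple[object, float]]
    blocks: List[slice]

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y) or len(self.y) != len(self.row_index):
            raise ValueError("rows, labels and provenance must align")


def interpolate_monthly(
    participant: Participant, times_in_months: Optional[np.ndarray] = None
) -> MonthlySeries:
    """Linearly interpolate a participant's visits onto a monthly grid.

    The grid runs over integer months 0, 1, ..., floor(span) measured from
    the first visit; no extrapolation past the last visit.  When the last
    visit falls strictly between grid points its exact value is appended as
    an extra final row, so the most recent screen is always represented.
    """
    t = times_in_months if times_in_months is not None else participant.visit_times
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"participant {participant.id}: duplicate or unsorted visit times")
    rel = t - t[0]
    span = rel[-1]
    grid = np.arange(math.floor(span) + 1, dtype=float)
    cols = [np.interp(grid, rel, participant.visit_values[:, j])
            for j in range(participant.k)]
    months = grid
    values = np.column_stack(cols)
    if span > grid[-1]:
        months = np.append(grid, span)
        values = np.vstack([values, participant.visit_values[-1]])
    return MonthlySeries(id=participant.id, months=months, values=values,
                         outcome=participant.outcome)


def skip_select(n: int, tau: int) -> np.ndarray:
    """Indices retained by backward skip sampling, 1-based and increasing.

    Starting from the last index n, step backwards by tau while the index
    stays >= 1: {n, n - tau, n - 2 tau, ...}.  The last index is always
    included; tau = 1 keeps everything.
    """
    if tau < 1:
        raise ValueError(f"skip tau must be >= 1, got {tau}")
    if n < 1:
        raise ValueError(f"sequence length must be >= 1, got {n}")
    idx = np.arange(n, 0, -tau)
    return idx[::-1].copy()


def build_stacked_matrix(
    states: Sequence[np.ndarray],
    outcomes: Sequence[int],
    ids: Sequence[object],
    tau: int,
    months: Optional[Sequence[np.ndarray]] = None,
) -> StackedStates:
    """Stack skip-selected state rows across participants.

    ``states[i]`` is the (m_i, M) trajectory of participant i (from
    :func:`esntsc.reservoir.run_sequence`, reset per participant); the
    outcome is replicated once per retained row.
    """
    if len(states) == 0:
        raise ValueError("cannot stack an empty cohort")
    rows, labels, prov, blocks = [], [], [], []
    start = 0
    for i, S in enumerate(states):
        sel = skip_select(S.shape[0], tau) - 1  # to 0-based
        rows.append(S[sel])
        labels.extend([outcomes[i]] * len(sel))
        mo = months[i] if months is not None else np.arange(S.shape[0], dtype=float)
        prov.extend((ids[i], float(mo[j])) for j in sel)
        blocks.append(slice(start, start + len(sel)))
        start += len(sel)
    return StackedStates(
        X=np.vstack(rows), y=np.asarray(labels), row_index=prov, blocks=blocks
    )


def fit_prob_classifier(stacked: StackedStates, C: float = 1.0, seed: int = 0):
    """Linear SVM with Platt-calibrated probability outputs.

    The sigmoid (Platt) calibration is fitted on cross-validated decision
    values of the linear SVM, so predicted probabilities are usable as
    screening risks.
    """
    if len(np.unique(stacked.y)) < 2:
        raise ValueError("training labels contain a single class")
    base = SVC(kernel="linear", C=C, random_state=seed)
    clf = CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)
    clf.fit(stacked.X, stacked.y)
    return clf


def predict_participant(handle, participant_rows: np.ndarray) -> float:
    """Positive-class probability at a participant's final retained row.

    Earlier rows contribute only through the recurrent state already folded
    into the last row; the last screen is the clinically decisive one.
    """
    rows = np.atleast_2d(participant_rows)
    if rows.shape[0] < 1:
        raise ValueError("participant has no retained rows")
    proba = handle.predict_proba(rows[-1:])
    pos_col = int(np.argmax(handle.classes_))  # positive class = larger label
    return float(proba[0, pos_col])


def forecast_truncate(
    states: Sequence[np.ndarray],
    outcomes: Sequence[int],
    ids: Sequence[object],
    gamma: int,
    tau: int = 1,
    months: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[StackedStates, List[object]]:
    """Test-side truncation for gamma-month-ahead forecasting.

    Keeps only the first m_i - gamma state rows of each participant before
    skip selection; participants too short to truncate (m_i - gamma < 1)
    are excluded and their ids returned.  The training side is untouched.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1; use the standard path for gamma = 0")
    kept_states, kept_out, kept_ids, kept_months, excluded = [], [], [], [], []
    for i, S in enumerate(states):
        m = S.shape[0]
        if m - gamma < 1:
            excluded.append(ids[i])
            continue
        kept_states.append(S[: m - gamma])
        kept_out.append(outcomes[i])
        kept_ids.append(ids[i])
        if months is not None:
            kept_months.append(months[i][: m - gamma])
    if not kept_states:
        raise ValueError(f"gamma={gamma} leaves no usable participant")
    stacked = build_stacked_matrix(
        kept_states, kept_out, kept_ids, tau,
        months=kept_months if months is not None else None,
    )
    return stacked, excluded


class InterpESN:
    """End-to-end interpolation-ESN classifier / forecaster.

    Parameters
    ----------
    M, a, rho, seed, input_scale : reservoir hyperparameters.
    tau : int
        Skip-sampling step for the training design matrix (recommended
        range 3-6; larger skips cost less and decorrelate rows).
    standardize : bool
        Z-score each marker with training-split mean/SD before
        interpolation (applied identically to test participants).
    C : float
        SVM regularisation weight.
    """

    def __init__(
        self,
        M: int = 50,
        a: float = 0.9,
        rho: float = 0.95,
        seed: int = 0,
        input_scale: float = 1.0,
        tau: int = 4,
        standardize: bool = True,
        C: float = 1.0,
    ) -> None:
        self.M = M
        self.a = a
        self.rho = rho
        self.seed = seed
        self.input_scale = input_scale
        self.tau = tau
        self.standardize = standardize
        self.C = C
        self.spec_: Optional[ReservoirSpec] = None
        self.weights_: Optional[ReservoirWeights] = None
        self.clf_ = None
        self.marker_mean_: Optional[np.ndarray] = None
        self.marker_sd_: Optional[np.ndarray] = None

    # -- internals ---------------------------------------------------------
    def _ensure_reservoir(self, k: int) -> None:
        if self.spec_ is None or self.spec_.k != k:
            self.spec_ = ReservoirSpec(
                M=self.M, a=self.a, rho=self.rho, k=k,
                seed=self.seed, input_scale=self.input_scale,
            )
            self.weights_ = build_reservoir(self.spec_)

    def _standardized(self, p: Participant) -> Participant:
        if not self.standardize:
            return p
        vals = (p.visit_values - self.marker_mean_) / self.marker_sd_
        return Participant(id=p.id, visit_times=p.visit_times,
                           visit_values=vals, outcome=p.outcome)

    def _trajectories(self, cohort: IrregularCohort):
        """Monthly series and state trajectories for every participant."""
        series, states = [], []
        for p in cohort.participants:
            q = self._standardized(p)
            ms = interpolate_monthly(q, times_in_months=cohort.times_in_months(q))
            traj = run_sequence(ms.values, self.weights_, self.spec_, sample_id=p.id)
            series.append(ms)
            states.append(traj.states)
        return series, states

    # -- API ---------------------------------------------------------------
    def fit(self, train: IrregularCohort) -> "InterpESN":
        self._ensure_reservoir(train.k)
        if self.standardize:
            allvals = np.vstack([p.visit_values for p in train.participants])
            self.marker_mean_ = allvals.mean(axis=0)
            sd = allvals.std(axis=0, ddof=0)
            self.marker_sd_ = np.where(sd > 0, sd, 1.0)
        series, states = self._trajectories(train)
        stacked = build_stacked_matrix(
            states,
            [s.outcome for s in series],
            [s.id for s in series],
            self.tau,
            months=[s.months for s in series],
        )
        self.clf_ = fit_prob_classifier(stacked, C=self.C, seed=self.seed)
        return self

    def predict_proba(
        self, test: IrregularCohort, gamma: int = 0
    ) -> Tuple[np.ndarray, np.ndarray, List[object]]:
        """Per-participant positive-class probabilities.

        Returns (probabilities, outcomes, excluded_ids); with gamma > 0 the
        prediction uses only states up to gamma months before each
        participant's last record, and participants with too few monthly
        points are excluded.
        """
        if self.clf_ is None:
            raise RuntimeError("fit before predict")
        series, states = self._trajectories(test)
        probs, outs, excluded = [], [], []
        for s, S in zip(series, states):
            m = S.shape[0]
            if gamma > 0:
                if m - gamma < 1:
                    excluded.append(s.id)
                    continue
                S = S[: m - gamma]
            probs.append(predict_participant(self.clf_, S))
            outs.append(s.outcome)
        return np.asarray(probs), np.asarray(outs), excluded
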