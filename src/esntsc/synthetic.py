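"""Synthetic data with the structure each classifier assumes.

Two generators:

* :func:`gen_regular` — equal-length labelled series whose classes differ in
  the timing and magnitude of a high-variance burst inside a class-specific
  window, against a Gaussian noise floor.  This is the regime the
  differential encoding targets: classes are separated by local change
  level, not by mean level.

* :func:`gen_cohort` — an irregular screening-style cohort: a few visits per
  participant at uneven intervals, a standardized marker panel, and a binary
  outcome.  Controls fluctuate around a flat baseline; cases follow the same
  baseline until an onset some months before their last visit, after which a
  marker subset rises linearly — the canonical picture of a tumour biomarker
  climbing towards diagnosis.  A ``slope_only`` variant makes cases rise *to*
  the control baseline at the last visit, so the two groups share the
  last-visit marginal distribution and all separation lives in trajectory
  shape; this isolates what a longitudinal method can see that a
  last-value-only baseline cannot.

Everything is seed-deterministic; regenerating with the same spec is
bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .diff_esn import RegularDataset
from .interp_esn import IrregularCohort, Participant

__all__ = [
    "ClassArchetype",
    "RegularGenSpec",
    "CohortGenSpec",
    "gen_regular",
    "gen_cohort",
    "add_test_noise",
    "DEFAULT_NOISE_SCALES",
]

# Test-noise multipliers studied for robustness (sigma = scale * max|train|).
DEFAULT_NOISE_SCALES = (0.02, 0.05)


@dataclass(frozen=True)
class ClassArchetype:
    """One class of regular series: a variance burst inside a time window.

    Inside ``[burst_start, burst_end]`` (1-based, inclusive) the noise is
    scaled by (1 + amplitude); amplitude 0 means no burst at all.
    """

    burst_start: int = 40
    burst_end: int = 60
    amplitude: float = 0.0
    noise_sd: float = 1.0

    def validate(self, T: int) -> None:
        if not (1 <= self.burst_start <= self.burst_end <= T):
            raise ValueError(f"burst window [{self.burst_start}, {self.burst_end}] not in [1, {T}]")
        if self.amplitude < 0:
            raise ValueError("burst amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")


@dataclass(frozen=True)
class RegularGenSpec:
    """Spec for a balanced regular TSC dataset (train and test)."""

    N_per_class: int = 50
    T: int = 100
    k: int = 1
    classes: Tuple[ClassArchetype, ...] = (
        ClassArchetype(amplitude=0.0),
        ClassArchetype(amplitude=2.0),
    )
    seed: int = 0

    def validate(self) -> None:
        if self.N_per_class < 1 or self.T < 2 or self.k < 1 or len(self.classes) < 2:
            raise ValueError("need N_per_class >= 1, T >= 2, k >= 1 and >= 2 classes")
        for c in self.classes:
            c.validate(self.T)


def _draw_regular(spec: RegularGenSpec, rng: np.random.Generator, tag: str) -> RegularDataset:
    N = spec.N_per_class * len(spec.classes)
    series = np.empty((N, spec.T, spec.k))
    labels = np.empty(N, dtype=int)
    i = 0
    for ci, arch in enumerate(spec.classes, start=1):
        for _ in range(spec.N_per_class):
            x = arch.noise_sd * rng.standard_normal((spec.T, spec.k))
            lo, hi = arch.burst_start - 1, arch.burst_end  # to 0-based half-open
            x[lo:hi] *= 1.0 + arch.amplitude
            series[i] = x
            labels[i] = ci
            i += 1
    return RegularDataset(series=series, labels=labels, split_tag=tag)


def gen_regular(spec: RegularGenSpec) -> Tuple[RegularDataset, RegularDataset]:
    """Generate disjoint, balanced train and test sets from one stream."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    train = _draw_regular(spec, rng, "train")
    test = _draw_regular(spec, rng, "test")
    return train, test


@dataclass(frozen=True)
class CohortGenSpec:
    """Spec for an irregular screening cohort.

    Defaults emulate a small nested case-control screening panel: 222
    participants, 2-6 visits each at 4-10 month gaps, 6 standardized
    markers, and cases whose affected markers rise by ``rise_rate_per_month``
    from ``onset_months_before_last`` months before their final visit.
    """

    N: int = 222
    case_fraction: float = 0.5
    k: int = 6
    visit_count_range: Tuple[int, int] = (2, 6)
    gap_range_months: Tuple[float, float] = (4.0, 10.0)
    onset_months_before_last: float = 18.0
    rise_rate_per_month: float = 0.12
    affected_markers: Optional[Tuple[int, ...]] = None  # default: first half of panel
    noise_sd: float = 1.0
    baseline: float = 0.0
    slope_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.N < 2:
            raise ValueError("cohort needs N >= 2")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        lo, hi = self.visit_count_range
        if lo < 2 or hi < lo:
            raise ValueError("visit counts must be >= 2 and ordered")
        glo, ghi = self.gap_range_months
        if glo <= 0 or ghi < glo:
            raise ValueError("visit gaps must be positive and ordered")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")
        if any(j < 0 or j >= self.k for j in self.affected()):
            raise ValueError("affected_markers out of range")

    def affected(self) -> Tuple[int, ...]:
        """Markers carrying the case signal; first half of the panel if unset."""
        if self.affected_markers is not None:
            return self.affected_markers
        return tuple(range(max(1, self.k // 2)))


def _case_mean(spec: CohortGenSpec, t: np.ndarray, t_last: float) -> np.ndarray:
    """Mean trajectory of an affected marker for a case, at times t (months)."""
    if spec.slope_only:
        # rises linearly to the control baseline at the last visit: the
        # last-visit marginal matches controls, only the slope differs
        return spec.baseline - spec.rise_rate_per_month * (t_last - t)
    onset = t_last - spec.onset_months_before_last
    return spec.baseline + spec.rise_rate_per_month * np.maximum(0.0, t - onset)


def gen_cohort(spec: CohortGenSpec) -> IrregularCohort:
    """Generate one irregular cohort with case/control marker trajectories."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_cases = int(round(spec.N * spec.case_fraction))
    outcomes = np.zeros(spec.N, dtype=int)
    outcomes[rng.permutation(spec.N)[:n_cases]] = 1
    participants: List[Participant] = []
    lo, hi = spec.visit_count_range
    glo, ghi = spec.gap_range_months
    for i in range(spec.N):
        n_visits = int(rng.integers(lo, hi + 1))
        gaps = rng.uniform(glo, ghi, size=n_visits - 1)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        values = spec.baseline + spec.noise_sd * rng.standard_normal((n_visits, spec.k))
        if outcomes[i] == 1:
            for j in spec.affected():
                values[:, j] += _case_mean(spec, times, times[-1]) - spec.baseline
        participants.append(
            Participant(id=f"P{i:04d}", visit_times=times,
                        visit_values=values, outcome=int(outcomes[i]))
        )
    names = [f"marker_{j + 1}" for j in range(spec.k)]
    return IrregularCohort(participants=participants, marker_names=names,
                           time_unit="months")


def add_test_noise(
    data: RegularDataset,
    scale: float,
    train_ref: RegularDataset,
    seed: int = 0,
) -> RegularDataset:
    """Perturb a test set with Gaussian noise scaled to the training range.

    The noise SD is ``scale * max|train observations|`` — the robustness
    protocol's convention — added i.i.d. to every test observation.
    Returns a new dataset; the input is untouched.
    """
    if scale < 0:
        raise ValueError("noise scale must be >= 0")
    if scale == 0:
        return RegularDataset(series=data.series.copy(), labels=data.labels.copy(),
                              split_tag=data.split_tag)
    sigma = scale * float(np.max(np.abs(train_ref.series)))
    rng = np.random.default_rng(seed)
    noisy = data.series + sigma * rng.standard_normal(data.series.shape)
    out = RegularDataset(series=noisy, labels=data.labels.copy(), split_tag=data.split_tag)
    out.noise_sigma = sigma  # record the realised SD for reports
    return out
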