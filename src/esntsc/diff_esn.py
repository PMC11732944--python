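"""Differential echo state network classifier for regular time series.

Each equal-length labelled series is first replaced by its adjacent pairwise
differences (static suppression: only change carries information, and most
transformed observations sit near zero).  The differenced series drives a
fixed random reservoir, the per-neuron variance of the state trajectory is
taken as a fixed-length "hallmark" feature vector, and a linear support
vector machine is trained on the stacked hallmarks.  Nothing is ever
backpropagated: the reservoir weights stay frozen.

Because the difference transform cancels additive constants, the whole
pipeline is exactly invariant to shifting any series by a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .reservoir import (
    ReservoirSpec,
    ReservoirWeights,
    StateTrajectory,
    build_reservoir,
    iterate_batch_states,
)

__all__ = [
    "RegularDataset",
    "VarianceFeatures",
    "diff_transform",
    "variance_hallmark",
    "featurize_dataset",
    "fit_diff_classifier",
    "predict_labels",
    "DiffESN",
]


@dataclass
class RegularDataset:
    """Equal-length labelled time series: (N, T, k) array plus N labels."""

    series: np.ndarray  # (N, T, k)
    labels: np.ndarray  # (N,)
    split_tag: str = ""

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim == 2:  # univariate shorthand (N, T)
            self.series = self.series[:, :, None]
        if self.series.ndim != 3:
            raise ValueError("series must have shape (N, T, k)")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.series.shape[0],):
            raise ValueError("labels must be one per sample")
        if self.series.shape[1] < 2:
            raise ValueError("series must have length T >= 2")

    @property
    def N(self) -> int:
        return self.series.shape[0]

    @property
    def T(self) -> int:
        return self.series.shape[1]

    @property
    def k(self) -> int:
        return self.series.shape[2]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class VarianceFeatures:
    """Stacked per-sample reservoir variance hallmarks with aligned labels."""

    X: np.ndarray  # (N, M)
    y: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("feature rows and labels must align")


def diff_transform(seq: np.ndarray) -> np.ndarray:
    """Adjacent pairwise differences of a sequence, length n -> n - 1."""
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    if seq.shape[0] < 2:
        raise ValueError("differencing needs a sequence of length >= 2")
    return np.diff(seq, axis=0)


def variance_hallmark(traj: StateTrajectory, ddof: int = 0) -> np.ndarray:
    """Per-neuron variance over time of a state trajectory.

    Population variance (ddof=0) by default: the hallmark is a per-sample
    summary rather than an estimator, and with equal-length series the
    alternative (ddof=1) is a uniform column rescaling that a linear
    classifier absorbs.
    """
    if traj.n < 2:
        raise ValueError("variance hallmark needs at least 2 states")
    return np.var(traj.states, axis=0, ddof=ddof)


def featurize_dataset(
    data: RegularDataset,
    weights: ReservoirWeights,
    spec: ReservoirSpec,
    ddof: int = 0,
) -> VarianceFeatures:
    """Difference every sample, drive the reservoir, take state variances.

    The reservoir state is reset to zero per sample.  The variance is
    accumulated online across the batch (first and second moments), so no
    (N, T, M) trajectory tensor is materialised.
    """
    if data.k != spec.k:
        raise ValueError(f"dataset has k={data.k} features but reservoir expects {spec.k}")
    diffed = np.diff(data.series, axis=1)  # (N, T-1, k)
    n_steps = diffed.shape[1]
    if n_steps < 2:
        raise ValueError("need at least 2 differenced steps for a variance")
    s1 = np.zeros((data.N, spec.M))
    s2 = np.zeros((data.N, spec.M))
    for X in iterate_batch_states(diffed, weights, spec.a):
        s1 += X
        s2 += X * X
    denom = n_steps - (1 if ddof else 0)
    var = s2 / denom - (s1 / n_steps) * (s1 / denom)
    np.maximum(var, 0.0, out=var)  # clip negative round-off
    return VarianceFeatures(X=var, y=data.labels.copy())


def fit_diff_classifier(
    feat: VarianceFeatures,
    C: float = 1.0,
    standardize: bool = False,
    max_iter: int = 20000,
):
    """Fit the linear SVM readout on variance hallmarks.

    One-vs-rest for multiclass problems.  Raw variances are used by default;
    ``standardize=True`` z-scores the columns first (fitted on this data).
    """
    if len(np.unique(feat.y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = LinearSVC(C=C, max_iter=max_iter)
    if standardize:
        from sklearn.pipeline import make_pipeline

        clf = make_pipeline(StandardScaler(), clf)
    clf.fit(feat.X, feat.y)
    return clf


def predict_labels(handle, feat: VarianceFeatures) -> np.ndarray:
    """Hard labels for every feature row, drawn from the training label set."""
    if feat.X.shape[0] == 0:
        return np.empty(0, dtype=feat.y.dtype)
    return handle.predict(feat.X)


class DiffESN:
    """End-to-end differential-ESN classifier with a scikit-learn-ish API.

    Parameters mirror the reservoir hyperparameters; the readout is a
    linear SVM on the per-neuron state variances of the differenced input.

    Examples
    --------
    >>> model = DiffESN(M=50, a=0.9, seed=3)
    >>> model.fit(train).error_rate(test)  # doctest: +SKIP
    """

    def __init__(
        self,
        M: int = 50,
        a: float = 0.9,
        rho: float = 0.95,
        seed: int = 0,
        input_scale: float = 1.0,
        C: float = 1.0,
        standardize: bool = False,
        ddof: int = 0,
    ) -> None:
        self.M = M
        self.a = a
        self.rho = rho
        self.seed = seed
        self.input_scale = input_scale
        self.C = C
        self.standardize = standardize
        self.ddof = ddof
        self.spec_: Optional[ReservoirSpec] = None
        self.weights_: Optional[ReservoirWeights] = None
        self.clf_ = None

    def _ensure_reservoir(self, k: int) -> None:
        if self.spec_ is None or self.spec_.k != k:
            self.spec_ = ReservoirSpec(
                M=self.M, a=self.a, rho=self.rho, k=k,
                seed=self.seed, input_scale=self.input_scale,
            )
            self.weights_ = build_reservoir(self.spec_)

    def featurize(self, data: RegularDataset) -> VarianceFeatures:
        self._ensure_reservoir(data.k)
        return featurize_dataset(data, self.weights_, self.spec_, ddof=self.ddof)

    def fit(self, train: RegularDataset) -> "DiffESN":
        feat = self.featurize(train)
        self.clf_ = fit_diff_classifier(feat, C=self.C, standardize=self.standardize)
        return self

    def predict(self, data: RegularDataset) -> np.ndarray:
        if self.clf_ is None:
            raise RuntimeError("fit before predict")
        return predict_labels(self.clf_, self.featurize(data))

    def error_rate(self, test: RegularDataset) -> float:
        pred = self.predict(test)
        return float(np.mean(pred != test.labels))
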