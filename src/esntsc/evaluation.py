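"""Evaluation protocols: error rate, ROC AUC, seed and split robustness.

The reservoir weights are random, so a single error rate tells little;
robustness is assessed by re-running the full pipeline over many reservoir
seeds (regular data) or over many random 50-50 participant splits
(cohort data), summarising each metric distribution by its mean and a
normal-approximation 95% confidence interval.  A last-visit logistic
regression serves as the non-longitudinal baseline for cohort problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

from .diff_esn import DiffESN, RegularDataset
from .interp_esn import InterpESN, IrregularCohort

__all__ = [
    "EvaluationReport",
    "error_rate",
    "roc_auc",
    "mean_ci",
    "seed_robustness",
    "split_robustness",
    "last_point_baseline",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def error_rate(y_true: Sequence, y_pred: Sequence) -> float:
    """Fraction of misclassified positions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    return float(np.mean(y_true != y_pred))


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (rank formulation, ties counted half).

    Equals the probability that a random positive outscores a random
    negative, with ties worth 1/2.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def mean_ci(values: Sequence[float]) -> Tuple[float, float, float]:
    """Mean and normal-approximation 95% CI of the mean (SD / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if len(v) < 2:
        return m, m, m
    half = Z95 * float(v.std(ddof=1)) / np.sqrt(len(v))
    return m, m - half, m + half


@dataclass
class EvaluationReport:
    """Per-run metric values with their mean and 95% CI."""

    metric: str  # "error_rate" | "roc_auc"
    values: np.ndarray
    config: Dict = field(default_factory=dict)
    baseline_values: Optional[np.ndarray] = None  # paired comparator, if any

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError(f"{self.metric} values must lie in [0, 1]")

    @property
    def n_runs(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return mean_ci(self.values)[0]

    @property
    def ci(self) -> Tuple[float, float]:
        _, lo, hi = mean_ci(self.values)
        return lo, hi

    def to_dict(self) -> Dict:
        m, lo, hi = mean_ci(self.values)
        d = {
            "metric": self.metric,
            "n_runs": self.n_runs,
            "mean": m,
            "ci95": [lo, hi],
            "values": self.values.tolist(),
            "config": self.config,
        }
        if self.baseline_values is not None:
            bm, blo, bhi = mean_ci(self.baseline_values)
            d["baseline"] = {
                "mean": bm,
                "ci95": [blo, bhi],
                "values": np.asarray(self.baseline_values).tolist(),
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        """Delimited per-run dump plus the summary line (figure-ready)."""
        m, lo, hi = mean_ci(self.values)
        lines = [f"run\t{self.metric}"]
        lines += [f"{i}\t{v:.6f}" for i, v in enumerate(self.values)]
        lines.append(f"# mean {m:.4f} (95% CI {lo:.4f}-{hi:.4f}), n={self.n_runs}")
        return "\n".join(lines)


def seed_robustness(
    protocol: Callable[[object, int], float],
    dataset,
    n_seeds: int = 50,
    base_seed: int = 0,
    metric: str = "error_rate",
    config: Optional[Dict] = None,
) -> EvaluationReport:
    """Re-run a pipeline under fresh random reservoir connections.

    ``protocol(dataset, seed)`` must rebuild the reservoir from the seed and
    return one metric value; seeds are base_seed, base_seed+1, ...
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds for a robustness check")
    values = [protocol(dataset, base_seed + s) for s in range(n_seeds)]
    cfg = dict(config or {})
    cfg.update({"n_seeds": n_seeds, "base_seed": base_seed})
    return EvaluationReport(metric=metric, values=np.asarray(values), config=cfg)


def diff_esn_protocol(
    train: RegularDataset,
    test: RegularDataset,
    M: int = 50,
    a: float = 0.9,
    rho: float = 0.95,
    **kwargs,
) -> Callable[[object, int], float]:
    """Standard seed-robustness protocol for the differential ESN.

    Returns a callable suitable for :func:`seed_robustness`; the dataset
    argument is ignored (the closure holds the train/test pair)."""

    def run(_dataset, seed: int) -> float:
        model = DiffESN(M=M, a=a, rho=rho, seed=seed, **kwargs)
        return model.fit(train).error_rate(test)

    return run


def split_robustness(
    cohort: IrregularCohort,
    n_splits: int = 50,
    frac: float = 0.5,
    base_seed: int = 0,
    gamma: int = 0,
    with_baseline: bool = False,
    model_factory: Optional[Callable[[int], InterpESN]] = None,
    max_redraws: int = 100,
) -> EvaluationReport:
    """Repeated random 50-50 splits of an irregular cohort, scored by AUC.

    Per split: participants are halved at random (no stratification), the
    model standardizes markers on the training half, fits, and the test-half
    participants are scored; a split leaving a single outcome class on
    either side is redrawn (and counted).  With ``gamma`` > 0 the test-side
    sequences are truncated for forecasting.  ``with_baseline`` also runs
    the last-visit logistic regression on each split for a paired
    comparison.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    y_all = cohort.outcomes()
    if len(np.unique(y_all)) < 2:
        raise ValueError("cohort must contain both outcome classes")
    if model_factory is None:
        model_factory = lambda seed: InterpESN(seed=seed)
    aucs, base_aucs = [], []
    n_redraws = 0
    rng = np.random.default_rng(base_seed)
    for s in range(n_splits):
        for _ in range(max_redraws):
            perm = rng.permutation(cohort.N)
            n_train = int(round(frac * cohort.N))
            tr_idx, te_idx = perm[:n_train], perm[n_train:]
            ok = (len(np.unique(y_all[tr_idx])) == 2
                  and len(np.unique(y_all[te_idx])) == 2)
            if ok:
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw a split with both classes on each side")
        train, test = cohort.subset(tr_idx), cohort.subset(te_idx)
        model = model_factory(base_seed + s)
        model.fit(train)
        probs, outs, _excluded = model.predict_proba(test, gamma=gamma)
        aucs.append(roc_auc(outs, probs))
        if with_baseline:
            base_aucs.append(last_point_baseline(train, test))
    cfg = {"n_splits": n_splits, "frac": frac, "base_seed": base_seed,
           "gamma": gamma, "n_redraws": n_redraws}
    return EvaluationReport(
        metric="roc_auc",
        values=np.asarray(aucs),
        config=cfg,
        baseline_values=np.asarray(base_aucs) if with_baseline else None,
    )


def last_point_baseline(
    train: IrregularCohort, test: IrregularCohort, seed: int = 0
) -> float:
    """AUC of a logistic regression on each participant's last raw visit.

    The non-longitudinal reference: only the final marker panel enters the
    model, standardized on the training half.
    """

    def last_rows(c: IrregularCohort) -> np.ndarray:
        return np.vstack([p.visit_values[-1] for p in c.participants])

    y_tr, y_te = train.outcomes(), test.outcomes()
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class")
    scaler = StandardScaler().fit(last_rows(train))
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(scaler.transform(last_rows(train)), y_tr)
    pos = int(np.argmax(clf.classes_))
    scores = clf.predict_proba(scaler.transform(last_rows(test)))[:, pos]
    return roc_auc(y_te, scores)
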