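"""Readers and writers for the two dataset dialects plus config files.

Regular datasets use the benchmark-archive delimited dialect: one series
per row, the class label in the first column, equal lengths per file, tab
or comma delimited.  Irregular cohorts use a long-format CSV with one row
per visit: ``id,time,marker_1,...,marker_k,outcome``.  Parsers reject
malformed rows (ragged lengths, non-numeric or missing cells) with the row
location; nothing is silently repaired.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .diff_esn import RegularDataset
from .interp_esn import IrregularCohort, Participant

__all__ = [
    "read_regular",
    "write_regular",
    "read_cohort",
    "write_cohort",
    "load_config",
    "normalize_labels",
]

log = logging.getLogger("esntsc")


def normalize_labels(labels: np.ndarray) -> Tuple[np.ndarray, Dict[int, object]]:
    """Map arbitrary label names to 0..C-1, returning the inverse mapping."""
    uniq = sorted(set(labels.tolist()), key=str)
    fwd = {lab: i for i, lab in enumerate(uniq)}
    inv = {i: lab for lab, i in fwd.items()}
    return np.array([fwd[l] for l in labels]), inv


def read_regular(path, delimiter: str = "\t") -> RegularDataset:
    """Parse a delimited regular-series file (label first, then T values)."""
    rows: List[np.ndarray] = []
    labels: List[object] = []
    T: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(delimiter) if delimiter != "," else line.split(",")
            if len(cells) < 3:
                raise ValueError(f"{path}:{lineno}: row has fewer than 1 label + 2 values")
            label = cells[0]
            try:
                values = np.array([float(c) for c in cells[1:]])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({e})") from None
            if np.any(~np.isfinite(values)):
                raise ValueError(f"{path}:{lineno}: missing or non-finite value")
            if T is None:
                T = len(values)
            elif len(values) != T:
                raise ValueError(
                    f"{path}:{lineno}: ragged row (length {len(values)}, expected {T})"
                )
            # labels are usually integers in the archive dialect
            try:
                label = int(label)
            except ValueError:
                try:
                    label = float(label)
                    label = int(label) if label.is_integer() else label
                except ValueError:
                    pass
            labels.append(label)
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty file")
    return RegularDataset(series=np.stack(rows)[:, :, None], labels=np.array(labels))


def write_regular(data: RegularDataset, path, delimiter: str = "\t") -> None:
    """Write a univariate regular dataset in the delimited dialect."""
    if data.k != 1:
        raise ValueError("the delimited dialect is per-feature; write each feature separately")
    with open(path, "w") as fh:
        for i in range(data.N):
            cells = [str(data.labels[i])] + [repr(float(v)) for v in data.series[i, :, 0]]
            fh.write(delimiter.join(cells) + "\n")


def read_cohort(path) -> IrregularCohort:
    """Parse a long-format cohort CSV into participants, sorted by time.

    Participants with a single visit are dropped (a lone screen has no
    trajectory); the count is logged and stored on the cohort as
    ``n_excluded_single_visit``.  Conflicting outcomes within a participant
    or duplicate visit times are rejected.
    """
    df = pd.read_csv(path)
    required = {"id", "time", "outcome"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    marker_cols = [c for c in df.columns if c.startswith("marker_")]
    if not marker_cols:
        raise ValueError(f"{path}: no marker_* columns found")
    marker_cols = sorted(marker_cols, key=lambda c: int(c.split("_")[1]))
    if df[marker_cols + ["time"]].isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    participants: List[Participant] = []
    n_excluded = 0
    for pid, grp in df.groupby("id", sort=True):
        outs = grp["outcome"].unique()
        if len(outs) != 1:
            raise ValueError(f"{path}: participant {pid} has conflicting outcomes {outs}")
        grp = grp.sort_values("time")
        times = grp["time"].to_numpy(dtype=float)
        if len(times) < 2:
            n_excluded += 1
            continue
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: participant {pid} has duplicate visit times")
        participants.append(
            Participant(id=pid, visit_times=times,
                        visit_values=grp[marker_cols].to_numpy(dtype=float),
                        outcome=int(outs[0]))
        )
    if not participants:
        raise ValueError(f"{path}: no participant with >= 2 visits")
    cohort = IrregularCohort(participants=participants, marker_names=marker_cols)
    cohort.n_excluded_single_visit = n_excluded
    if n_excluded:
        log.info("excluded %d participant(s) with a single timestamp", n_excluded)
    return cohort


def write_cohort(cohort: IrregularCohort, path) -> None:
    """Write a cohort as long-format CSV (one row per visit)."""
    records = []
    for p in cohort.participants:
        for j in range(p.n_visits):
            row = {"id": p.id, "time": p.visit_times[j]}
            row.update({name: p.visit_values[j, m]
                        for m, name in enumerate(cohort.marker_names)})
            row["outcome"] = p.outcome
            records.append(row)
    cols = ["id", "time", *cohort.marker_names, "outcome"]
    pd.DataFrame.from_records(records)[cols].to_csv(path, index=False)


def load_config(path) -> Dict:
    """Load a flat YAML config (e.g. reservoir.M, reservoir.a, ...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
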