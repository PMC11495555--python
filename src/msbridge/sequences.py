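"""Microstate sequence statistics: coverage distributions and the resting
two-step joint matrix.

A back-fitted recording yields an integer microstate label per sample plus
condition segments. From these the pipeline derives, per subject:

* the coverage distribution ``pi`` — the probability of each microstate
  within a condition, pooling all segments of that condition and (by
  default) excluding *boundary microstates*, i.e. the first and last
  maximal same-label run of every segment, whose true duration is truncated
  by the segment edge;
* the resting joint matrix ``Q_ij = Prob[k_{t-1} = i, k_t = j]`` over
  consecutive samples, counted strictly within segments (never across a
  segment boundary), after the resting phase has been cut into 2-second
  windows to mirror the trial duration;
* a paired t-test for transition asymmetry ``Q_ij`` vs ``Q_ji`` across
  subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateDistributionError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "Segment",
    "MicrostateSequence",
    "CoverageDistribution",
    "JointTransitionMatrix",
    "segment_rest",
    "coverage",
    "joint_probability",
    "asymmetry_test",
    "write_sequence",
    "read_sequence",
]

REST_LABEL = "rest"


@dataclass(frozen=True)
class Segment:
    """Half-open interval ``[start, end)`` of samples under one condition."""

    start: int
    end: int
    condition: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidParameterError(f"empty segment [{self.start}, {self.end})")


@dataclass
class MicrostateSequence:
    """Integer microstate label per sample with condition segments."""

    labels: np.ndarray
    segments: list[Segment]
    srate: float
    n_states: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.srate <= 0:
            raise InvalidParameterError("srate must be positive")
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise InvalidParameterError(f"segments overlap: {a} and {b}")
        for s in segs:
            if s.start < 0 or s.end > self.labels.size:
                raise InvalidParameterError(f"segment {s} outside label array")
        self.segments = segs
        if self.n_states is None:
            self.n_states = int(self.labels.max()) + 1 if self.labels.size else 0

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.segments:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen


@dataclass
class CoverageDistribution:
    """Probability over the K microstates for one subject x condition."""

    pi: np.ndarray
    condition: str
    n_samples: int

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("pi must be a probability vector")

    @property
    def K(self) -> int:
        return self.pi.size


@dataclass
class JointTransitionMatrix:
    """Joint probability of consecutive microstate pairs; sums to 1."""

    Q: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != self.Q.shape[1]:
            raise InvalidParameterError("Q must be square")
        if np.any(self.Q < 0) or abs(self.Q.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("Q entries must be >= 0 and sum to 1")

    @property
    def K(self) -> int:
        return self.Q.shape[0]

    def row_marginal(self) -> np.ndarray:
        """Distribution of ``k_{t-1}``."""
        return self.Q.sum(axis=1)

    def col_marginal(self) -> np.ndarray:
        """Distribution of ``k_t``."""
        return self.Q.sum(axis=0)


# ---------------------------------------------------------------------------
# operations


def segment_rest(
    seq: MicrostateSequence, window_s: float = 2.0, rest_label: str = REST_LABEL
) -> MicrostateSequence:
    """Cut resting segments into consecutive non-overlapping windows.

    Each rest segment is split into ``window_s``-second windows (the trial
    duration); a trailing partial window is discarded. Non-rest segments
    pass through unchanged.

    Raises
    ------
    InsufficientDataError
        If no rest segment is as long as one window.
    """
    if window_s <= 0:
        raise InvalidParameterError("window_s must be positive")
    w = int(round(window_s * seq.srate))
    rest_segments = [s for s in seq.segments if s.condition == rest_label]
    if not rest_segments:
        raise InsufficientDataError(f"no segment labeled '{rest_label}'")
    new_segments: list[Segment] = []
    n_windows = 0
    for s in seq.segments:
        if s.condition != rest_label:
            new_segments.append(s)
            continue
        start = s.start
        while start + w <= s.end:
            new_segments.append(Segment(start, start + w, rest_label))
            start += w
            n_windows += 1
    if n_windows == 0:
        raise InsufficientDataError(
            f"rest shorter than one {window_s}-s window ({w} samples)"
        )
    return MicrostateSequence(
        labels=seq.labels, segments=new_segments, srate=seq.srate, n_states=seq.n_states
    )


def _run_bounds(labels: np.ndarray) -> np.ndarray:
    """Start indices of maximal same-label runs, plus the end sentinel."""
    change = np.flatnonzero(np.diff(labels)) + 1
    return np.concatenate(([0], change, [labels.size]))


def coverage(
    seq: MicrostateSequence,
    condition: str,
    drop_boundary_runs: bool = True,
) -> CoverageDistribution:
    """Coverage distribution ``pi`` of one condition.

    Samples are pooled over all segments of the condition. With
    ``drop_boundary_runs`` the first and last maximal same-label run of each
    segment are excluded before counting (truncated states carry no duration
    information); a segment consisting of a single run is then dropped
    entirely.

    Raises
    ------
    InsufficientDataError
        If the condition has no segments.
    DegenerateDistributionError
        If boundary exclusion removes every sample.
    """
    segs = [s for s in seq.segments if s.condition == condition]
    if not segs:
        raise InsufficientDataError(f"no segment with condition '{condition}'")
    K = seq.n_states or int(seq.labels.max()) + 1
    counts = np.zeros(K, dtype=float)
    for s in segs:
        lab = seq.labels[s.start : s.end]
        if drop_boundary_runs:
            bounds = _run_bounds(lab)
            if len(bounds) <= 3:  # one or two runs: everything is boundary
                continue
            lab = lab[bounds[1] : bounds[-2]]
        counts += np.bincount(lab, minlength=K)[:K]
    total = counts.sum()
    if total == 0:
        raise DegenerateDistributionError(
            f"all samples of condition '{condition}' excluded as boundary runs"
        )
    return CoverageDistribution(pi=counts / total, condition=condition, n_samples=int(total))


def joint_probability(
    seq: MicrostateSequence,
    condition: str = REST_LABEL,
    drop_boundary_runs: bool = False,
) -> JointTransitionMatrix:
    """Joint matrix ``Q_ij`` of consecutive label pairs within a condition.

    Ordered pairs ``(k_{t-1}, k_t)`` are counted within each segment of the
    condition only — never across segment boundaries — and normalized by
    the total pair count. Boundary-run exclusion is available for symmetry
    with :func:`coverage` but defaults to off for Q.

    Raises
    ------
    InsufficientDataError
        If no within-segment pair exists.
    """
    segs = [s for s in seq.segments if s.condition == condition]
    if not segs:
        raise InsufficientDataError(f"no segment with condition '{condition}'")
    K = seq.n_states or int(seq.labels.max()) + 1
    counts = np.zeros((K, K), dtype=float)
    n_pairs = 0
    for s in segs:
        lab = seq.labels[s.start : s.end]
        if drop_boundary_runs:
            bounds = _run_bounds(lab)
            if len(bounds) <= 3:
                continue
            lab = lab[bounds[1] : bounds[-2]]
        if lab.size < 2:
            continue
        np.add.at(counts, (lab[:-1], lab[1:]), 1.0)
        n_pairs += lab.size - 1
    if n_pairs == 0:
        raise InsufficientDataError(
            f"condition '{condition}' yields zero consecutive pairs"
        )
    return JointTransitionMatrix(Q=counts / n_pairs, n_pairs=n_pairs)


def asymmetry_test(
    cohort_Q: TypingSequence[JointTransitionMatrix], alpha: float = 0.05
) -> pd.DataFrame:
    """Paired t-test of ``Q_ij`` vs ``Q_ji`` across subjects, per pair i < j.

    Returns a DataFrame with columns ``i, j, t, p, significant, undefined``.
    When the per-subject differences have zero variance the t statistic is
    undefined: a zero mean is reported as non-significant with the
    ``undefined`` flag set, while a nonzero mean difference with zero
    variance is a perfectly consistent asymmetry and is reported with
    ``t = +/-inf`` and ``p = 0``.

    Raises
    ------
    InsufficientDataError
        With fewer than 3 subjects.
    InvalidParameterError
        If the matrices differ in K.
    """
    if len(cohort_Q) < 3:
        raise InsufficientDataError("asymmetry test needs >= 3 subjects")
    K = cohort_Q[0].K
    if any(q.K != K for q in cohort_Q):
        raise InvalidParameterError("all Q matrices must share the same K")
    stacked = np.stack([q.Q for q in cohort_Q])  # subjects x K x K
    rows = []
    n = stacked.shape[0]
    for i in range(K):
        for j in range(i + 1, K):
            d = stacked[:, i, j] - stacked[:, j, i]
            mean, sd = d.mean(), d.std(ddof=1)
            if sd == 0.0:
                if mean == 0.0:
                    rows.append(
                        {"i": i, "j": j, "t": np.nan, "p": np.nan,
                         "significant": False, "undefined": True}
                    )
                else:
                    rows.append(
                        {"i": i, "j": j, "t": np.inf if mean > 0 else -np.inf,
                         "p": 0.0, "significant": True, "undefined": False}
                    )
                continue
            t = mean / (sd / np.sqrt(n))
            p = 2.0 * sps.t.sf(abs(t), df=n - 1)
            rows.append(
                {"i": i, "j": j, "t": t, "p": p,
                 "significant": bool(p < alpha), "undefined": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization


def write_sequence(seq: MicrostateSequence, csv_path: str | Path) -> None:
    """CSV of (sample, label) plus a JSON segment table sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"sample": np.arange(seq.labels.size), "label": seq.labels}
    ).to_csv(csv_path, index=False)
    meta = {
        "srate": seq.srate,
        "n_states": seq.n_states,
        "segments": [
            {"start": s.start, "end": s.end, "condition": s.condition}
            for s in seq.segments
        ],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_sequence(csv_path: str | Path) -> MicrostateSequence:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    segments = [
        Segment(int(s["start"]), int(s["end"]), str(s["condition"]))
        for s in meta["segments"]
    ]
    return MicrostateSequence(
        labels=df["label"].to_numpy(),
        segments=segments,
        srate=float(meta["srate"]),
        n_states=meta.get("n_states"),
    )
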