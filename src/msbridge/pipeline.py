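"""High-level orchestration: recordings -> templates -> sequences -> costs.

Thin compositions of the module-level operations, shared by the CLI and by
end-to-end analyses in code. Each step consumes the previous step's output
type, so the functions chain naturally:

``fit_group_templates`` (peaks + two-level clustering, optional CV-based K
selection) -> ``backfit_cohort`` -> ``cohort_coverage_tables`` (per-subject
pi and resting Q) -> ``cohort_transition_costs`` (one bridge solve per
subject x condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .eeg import EEGRecording, detect_gfp_peaks, global_field_power, sample_peak_maps
from .exceptions import InsufficientDataError, InvalidParameterError
from .microstates import (
    ClusterFitResult,
    TemplateSet,
    backfit_sequence,
    select_k,
    two_level_fit,
)
from .sequences import (
    REST_LABEL,
    CoverageDistribution,
    JointTransitionMatrix,
    MicrostateSequence,
    coverage,
    joint_probability,
    segment_rest,
)
from .bridge import transition_cost_per_condition
from .synthetic import ITI_LABEL, parse_condition_label

__all__ = [
    "extract_peak_maps",
    "fit_group_templates",
    "backfit_cohort",
    "subject_distributions",
    "cohort_transition_costs",
    "SubjectDistributions",
]


def extract_peak_maps(
    recordings: Sequence[EEGRecording],
    n_peaks: int = 10_000,
    min_separation: int = 1,
    seed: int | None = None,
) -> list[np.ndarray]:
    """GFP-peak topographies per subject, ``n_peaks`` sampled per recording.

    If a recording has fewer than ``n_peaks`` GFP peaks, all of its peaks
    are used (the study's 10000-peak draw presumes long recordings).
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    seeds = ss.spawn(len(recordings))
    out = []
    for rec, s in zip(recordings, seeds):
        g = detect_gfp_peaks(global_field_power(rec), min_separation=min_separation)
        if g.n_peaks == 0:
            raise InsufficientDataError("recording has no GFP peaks")
        n = min(n_peaks, g.n_peaks)
        out.append(sample_peak_maps(rec, g, n, seed=int(s.generate_state(1)[0] % (2**31))))
    return out


def fit_group_templates(
    recordings: Sequence[EEGRecording],
    K: int | None = None,
    k_range: Iterable[int] | None = None,
    n_peaks: int = 10_000,
    restarts: int = 50,
    seed: int | None = None,
) -> tuple[TemplateSet, ClusterFitResult | None]:
    """Peak extraction plus two-level clustering; CV-selects K if a range
    is given instead of a fixed K."""
    if (K is None) == (k_range is None):
        raise InvalidParameterError("provide exactly one of K or k_range")
    peak_maps = extract_peak_maps(recordings, n_peaks=n_peaks, seed=seed)
    if k_range is not None:
        fit = select_k(peak_maps, k_range, restarts=restarts, seed=seed)
        return fit.templates[fit.selected_K], fit
    return two_level_fit(peak_maps, K, restarts=restarts, seed=seed), None


def backfit_cohort(
    recordings: Sequence[EEGRecording], templates: TemplateSet
) -> list[MicrostateSequence]:
    return [backfit_sequence(rec, templates) for rec in recordings]


@dataclass
class SubjectDistributions:
    """Per-subject resting dynamics and coverage distributions."""

    Q: JointTransitionMatrix
    pi_rest: CoverageDistribution
    task_pis: list[CoverageDistribution]


def subject_distributions(
    seq: MicrostateSequence,
    window_s: float = 2.0,
    drop_boundary_runs: bool = True,
    q_drop_boundary_runs: bool = False,
) -> SubjectDistributions:
    """Resting Q (over 2-s windows) and coverage per condition.

    Rest is windowed to the trial duration before both Q and the resting
    coverage are computed; task conditions pool their trials. Inter-trial
    gap segments are excluded.
    """
    windowed = segment_rest(seq, window_s=window_s)
    Q = joint_probability(windowed, REST_LABEL, drop_boundary_runs=q_drop_boundary_runs)
    pi_rest = coverage(windowed, REST_LABEL, drop_boundary_runs=drop_boundary_runs)
    task_pis = []
    for cond in windowed.conditions():
        if cond in (REST_LABEL, ITI_LABEL):
            continue
        task_pis.append(coverage(windowed, cond, drop_boundary_runs=drop_boundary_runs))
    return SubjectDistributions(Q=Q, pi_rest=pi_rest, task_pis=task_pis)


def cohort_transition_costs(
    sequences: Sequence[MicrostateSequence],
    window_s: float = 2.0,
    drop_boundary_runs: bool = True,
    pseudocount: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> pd.DataFrame:
    """Bridge cost per subject x condition, long format.

    Returns columns ``subject, condition, congruency, pc, cost,
    iterations, marginal_error``. Condition labels of the form
    ``<congruency>_<PC>`` are split into design columns; other labels get
    empty design columns.
    """
    rows = []
    for s_idx, seq in enumerate(sequences):
        dists = subject_distributions(
            seq, window_s=window_s, drop_boundary_runs=drop_boundary_runs
        )
        table = transition_cost_per_condition(
            dists.Q,
            dists.pi_rest,
            dists.task_pis,
            pseudocount=pseudocount,
            tol=tol,
            max_iter=max_iter,
        )
        for _, r in table.iterrows():
            try:
                congruency, pc = parse_condition_label(r["condition"])
            except ValueError:
                congruency, pc = "", ""
            rows.append(
                {
                    "subject": s_idx,
                    "condition": r["condition"],
                    "congruency": congruency,
                    "pc": pc,
                    "cost": r["cost"],
                    "iterations": int(r["iterations"]),
                    "marginal_error": r["marginal_error"],
                }
            )
    return pd.DataFrame(rows)
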