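"""Synthetic ground-truth cohorts for end-to-end validation.

Real microstate analyses start from recordings that cannot ship with a
package, so every pipeline stage here is validated on simulated cohorts
with known structure:

* K unit-norm, zero-mean scalp topographies with bounded pairwise
  correlation (rejection-sampled);
* metastable Markov label dynamics — a chain with stationary distribution
  ``pi`` and a persistence parameter ``p_stay`` controlling dwell times,
  ``T = p_stay * I + (1 - p_stay) * 1 pi^T`` (stationary distribution
  exactly ``pi``, geometric dwell times);
* condition-dependent stationary distributions obtained by logit shifts of
  the resting ``pi`` with ``p_stay`` held fixed, so task conditions move
  coverage without changing metastability — mirroring the study design of
  a resting session plus six task conditions (congruent/incongruent x
  PC25/PC50/PC75);
* EEG rendering ``v_t = +/- s_t * a_{k_t} + noise`` with a rectified
  10 Hz sinusoid amplitude envelope (GFP peaks resembling alpha-band
  dynamics), per-sample polarity flips, and channel noise scaled to a
  target amplitude-to-noise ratio. Inter-trial gaps are rendered as noise
  only and annotated for exclusion.

The default configuration matches the study design: 44 subjects, 64
channels, 7 states, 500 -> preprocessed 250 Hz (the generator renders at
250 Hz directly), a 4-minute rest session, and 2-second trials.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .eeg import Annotation, EEGRecording
from .exceptions import GenerationError, InvalidParameterError
from .sequences import REST_LABEL, MicrostateSequence, Segment
from .stats import CONDITIONS, PC_CODES

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_templates",
    "transition_from_stationary",
    "stationary_distribution",
    "logit_shift",
    "default_condition_effects",
    "generate_markov_sequence",
    "render_eeg",
    "generate_cohort",
    "condition_label",
    "parse_condition_label",
]

ITI_LABEL = "iti"


def condition_label(congruency: str, pc: str) -> str:
    return f"{congruency}_{pc}"


def parse_condition_label(label: str) -> tuple[str, str]:
    congruency, pc = label.split("_", 1)
    return congruency, pc


@dataclass
class SyntheticConfig:
    """Study-design parameters for a simulated cohort.

    Defaults follow the emulated design: 44 subjects, 64 channels, 7
    microstates, 250 Hz (post-preprocessing rate), 240 s of rest, 2-s
    trials. ``p_stay = 0.95`` yields mean dwell times near 80 ms at
    250 Hz, within the canonical 60-120 ms microstate duration range.
    ``n_trials = 24`` per condition approximates a typical conflict-task
    block length. ``condition_effects`` maps condition labels to K-vectors
    of logit shifts applied to the resting stationary distribution; when
    None, a graded default emulating the congruency x PC modulation is
    used.
    """

    n_channels: int = 64
    K_true: int = 7
    n_subjects: int = 44
    srate: float = 250.0
    rest_duration_s: float = 240.0
    trial_duration_s: float = 2.0
    iti_duration_s: float = 0.5
    n_trials: int = 24
    p_stay: float = 0.95
    condition_effects: dict[str, np.ndarray] | None = None
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_stay < 1.0):
            raise InvalidParameterError("p_stay must be in (0, 1)")
        if self.snr <= 0:
            raise InvalidParameterError("snr must be positive")
        if self.trial_duration_s <= 0 or self.rest_duration_s <= 0:
            raise InvalidParameterError("durations must be positive")
        if self.K_true >= self.n_channels:
            raise InvalidParameterError("K_true must be < n_channels")


@dataclass
class GroundTruth:
    """Everything the generator knows: templates, dynamics, label paths."""

    templates: np.ndarray  # K_true x channels
    transitions: dict[str, np.ndarray]  # condition label -> row-stochastic matrix
    stationary: dict[str, np.ndarray]  # condition label -> stationary pi
    sequences: list[MicrostateSequence] = field(default_factory=list)


# ---------------------------------------------------------------------------
# topographies


def generate_templates(
    n_channels: int,
    K_true: int,
    seed: int | None = None,
    max_abs_corr: float = 0.6,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Rejection-sample K zero-mean unit-norm maps with pairwise
    ``|corr| < max_abs_corr``.

    Raises
    ------
    GenerationError
        If the rejection budget is exhausted (too many templates for the
        channel count / correlation bound).
    """
    if K_true >= n_channels:
        raise InvalidParameterError("K_true must be < n_channels")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < K_true:
        if tries >= max_tries:
            raise GenerationError(
                f"could not draw {K_true} maps with pairwise |corr| < "
                f"{max_abs_corr} in {max_tries} tries; reduce K_true or relax "
                "the bound"
            )
        tries += 1
        a = rng.standard_normal(n_channels)
        a -= a.mean()
        a /= np.linalg.norm(a)
        if all(abs(np.dot(a, b)) < max_abs_corr for b in accepted):
            accepted.append(a)
    return np.vstack(accepted)


# ---------------------------------------------------------------------------
# label dynamics


def transition_from_stationary(pi: np.ndarray, p_stay: float) -> np.ndarray:
    """Metastable chain ``T = p_stay I + (1 - p_stay) 1 pi^T``.

    Its stationary distribution is exactly ``pi`` and its second-largest
    eigenvalue is ``p_stay``, so dwell times are geometric with mean
    ``1 / ((1 - p_stay)(1 - pi_k))`` in state k.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("pi must be a probability vector")
    K = pi.size
    return p_stay * np.eye(K) + (1.0 - p_stay) * np.tile(pi, (K, 1))


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (pi^T T = pi^T)."""
    T = np.asarray(transition, dtype=float)
    K = T.shape[0]
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidParameterError("transition rows must sum to 1")
    A = np.vstack([T.T - np.eye(K), np.ones(K)])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def logit_shift(pi: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Tilt a distribution: ``pi' propto pi * exp(shift)``."""
    pi = np.asarray(pi, dtype=float)
    shifted = pi * np.exp(np.asarray(shift, dtype=float))
    return shifted / shifted.sum()


def default_condition_effects(K: int) -> dict[str, np.ndarray]:
    """Graded logit shifts emulating the congruency x PC modulation.

    All conditions share one fixed zero-sum direction; the scale grows
    with PC level for incongruent trials and shrinks for congruent ones,
    so incongruent conditions sit farther from rest on average and the
    congruency gap widens with PC — the qualitative pattern the transition
    cost is meant to detect.
    """
    d = np.array([(-1.0) ** k for k in range(K)])
    d -= d.mean()
    d /= np.linalg.norm(d)
    effects = {}
    for congruency, pc in CONDITIONS:
        pc_code = PC_CODES[pc]
        if congruency == "incongruent":
            scale = 0.35 + 0.20 * pc_code
        else:
            scale = 0.20 - 0.10 * pc_code
        effects[condition_label(congruency, pc)] = scale * d
    return effects


def generate_markov_sequence(
    T: int,
    transition: np.ndarray,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a label path of length ``T`` from a row-stochastic chain.

    The initial state is drawn from ``init`` (default: the chain's
    stationary distribution). Bit-reproducible under a fixed seed.
    """
    P = np.asarray(transition, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidParameterError("transition rows must sum to 1")
    rng = np.random.default_rng(seed)
    start = stationary_distribution(P) if init is None else np.asarray(init, float)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    rows = [c.tolist() for c in cum]  # python lists + bisect: ~10x faster scalar lookups
    r = rng.random(T).tolist()
    s = int(np.searchsorted(np.cumsum(start), rng.random(), side="right"))
    s = min(s, P.shape[0] - 1)
    br = bisect.bisect_right
    path = [0] * T
    for t in range(T):
        path[t] = s
        s = br(rows[s], r[t])
    return np.asarray(path, dtype=int)


# ---------------------------------------------------------------------------
# EEG rendering


def _envelope(n: int, srate: float, freq: float, floor: float, t0: int = 0) -> np.ndarray:
    t = (np.arange(t0, t0 + n)) / srate
    return floor + np.abs(np.sin(2.0 * np.pi * freq * t))


def render_eeg(
    path: np.ndarray,
    templates: np.ndarray,
    snr: float,
    seed: int | None = None,
    srate: float = 250.0,
    envelope_hz: float = 10.0,
    envelope_floor: float = 0.2,
) -> EEGRecording:
    """Render a label path into a noisy multichannel recording.

    ``v_t = sign_t * s_t * a_{k_t} + noise`` with ``s_t`` a strictly
    positive rectified-sinusoid envelope, random per-sample polarity flips
    (oscillatory-phase realism: clustering must be sign-invariant), and
    i.i.d. Gaussian channel noise scaled so the overall signal-to-noise
    amplitude ratio equals ``snr``. Samples labeled ``-1`` (gaps) carry
    noise only.
    """
    path = np.asarray(path, dtype=int)
    A = np.asarray(templates, dtype=float)
    K, C = A.shape
    if path.size and path.max() >= K:
        raise InvalidParameterError("label path refers to states beyond K_true")
    rng = np.random.default_rng(seed)
    s = _envelope(path.size, srate, envelope_hz, envelope_floor)
    signs = rng.choice([-1.0, 1.0], size=path.size)
    active = path >= 0
    data = np.zeros((C, path.size))
    data[:, active] = A[path[active]].T * (s[active] * signs[active])[None, :]
    # ||a_k|| = 1, so mean squared signal amplitude per channel is s^2 / C
    sigma = float(np.sqrt(np.mean(s[active] ** 2) / C) / snr) if active.any() else 1.0
    if np.isfinite(snr):
        data += rng.normal(scale=sigma, size=data.shape)
    return EEGRecording(data=data, srate=srate)


# ---------------------------------------------------------------------------
# cohort


def _subject_layout(cfg: SyntheticConfig) -> tuple[int, list[tuple[int, int, str]]]:
    """Sample counts and (start, end, label) layout of one subject session."""
    rest_n = int(round(cfg.rest_duration_s * cfg.srate))
    trial_n = int(round(cfg.trial_duration_s * cfg.srate))
    iti_n = int(round(cfg.iti_duration_s * cfg.srate))
    layout: list[tuple[int, int, str]] = [(0, rest_n, REST_LABEL)]
    cursor = rest_n
    for congruency, pc in CONDITIONS:
        label = condition_label(congruency, pc)
        for _ in range(cfg.n_trials):
            if iti_n > 0:
                layout.append((cursor, cursor + iti_n, ITI_LABEL))
                cursor += iti_n
            layout.append((cursor, cursor + trial_n, label))
            cursor += trial_n
    return cursor, layout


def generate_cohort(
    cfg: SyntheticConfig, render: bool = True
) -> tuple[GroundTruth, list[EEGRecording]]:
    """Generate a full cohort: ground truth and (optionally) rendered EEG.

    Per subject the resting phase is one long draw from the baseline chain;
    each trial is an independent draw from its condition's chain (started
    at that chain's stationary distribution), separated by inter-trial
    gaps that carry no state. Ground-truth label sequences (with segments)
    are always produced; set ``render=False`` to skip EEG rendering when
    only label-level analyses are needed.

    All randomness derives from ``cfg.seed`` via spawned seed sequences,
    so cohorts are bit-reproducible.
    """
    root = np.random.SeedSequence(cfg.seed)
    tmpl_ss, *subject_ss = root.spawn(1 + cfg.n_subjects)
    templates = generate_templates(
        cfg.n_channels, cfg.K_true, seed=int(tmpl_ss.generate_state(1)[0] % (2**31))
    )
    pi_rest = np.full(cfg.K_true, 1.0 / cfg.K_true)
    effects = (
        default_condition_effects(cfg.K_true)
        if cfg.condition_effects is None
        else {k: np.asarray(v, float) for k, v in cfg.condition_effects.items()}
    )
    transitions = {REST_LABEL: transition_from_stationary(pi_rest, cfg.p_stay)}
    stationary = {REST_LABEL: pi_rest}
    for label, shift in effects.items():
        pi_c = logit_shift(pi_rest, shift)
        transitions[label] = transition_from_stationary(pi_c, cfg.p_stay)
        stationary[label] = pi_c

    n_samples, layout = _subject_layout(cfg)
    truth = GroundTruth(templates=templates, transitions=transitions, stationary=stationary)
    recordings: list[EEGRecording] = []
    for s_idx in range(cfg.n_subjects):
        chain_ss, render_ss = subject_ss[s_idx].spawn(2)
        chain_seeds = chain_ss.spawn(len(layout))
        labels = np.full(n_samples, -1, dtype=int)
        segments: list[Segment] = []
        annotations: list[Annotation] = []
        for (start, end, label), seg_ss in zip(layout, chain_seeds):
            annotations.append(Annotation(start, end - start, label))
            if label == ITI_LABEL:
                continue
            seed = int(seg_ss.generate_state(1)[0] % (2**31))
            labels[start:end] = generate_markov_sequence(
                end - start, transitions[label], seed=seed
            )
            segments.append(Segment(start, end, label))
        truth.sequences.append(
            MicrostateSequence(
                labels=labels, segments=segments, srate=cfg.srate, n_states=cfg.K_true
            )
        )
        if render:
            rec = render_eeg(
                labels,
                templates,
                cfg.snr,
                seed=int(render_ss.generate_state(1)[0] % (2**31)),
                srate=cfg.srate,
            )
            rec.annotations = annotations
            recordings.append(rec)
    return truth, recordings
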