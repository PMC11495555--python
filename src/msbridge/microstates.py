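"""Polarity-invariant modified k-means microstate clustering.

EEG microstates are quasi-stable scalp topographies; because the polarity
of a topography flips with the oscillatory phase, clustering must be
invariant to the sign of each map. The modified k-means achieves this by
assigning each map to the template with the largest *squared* projection
and updating each template to the principal eigenvector of its members'
scatter matrix.

The module provides the subject-level fit, the two-level (subject then
group) fit used for cohorts, the cross-validation (CV) criterion for
choosing the number of microstates K, and polarity-invariant back-fitting
of templates to continuous recordings.

Quantities
----------
GEV (global explained variance)
    ``sum_i GFP_i^2 * corr^2(v_i, a_{L_i}) / sum_i GFP_i^2`` where corr is
    the Pearson spatial correlation across channels of average-referenced
    maps; for unit-norm zero-mean templates this equals
    ``sum_i (a_{L_i} . v_i)^2 / sum_i ||v_i||^2``.
residual noise
    ``sigma^2 = sum_i (v_i . v_i - (a_{L_i} . v_i)^2) / (n (C - 1))`` with
    C the channel count.
CV criterion
    ``sigma^2 * ((C - 1) / (C - 1 - K))^2``; the selected K minimizes CV
    (ties break to the smaller K).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .eeg import EEGRecording, average_reference
from .exceptions import InvalidParameterError, SchemaError
from .sequences import MicrostateSequence, Segment

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSet",
    "ClusterFitResult",
    "modified_kmeans_fit",
    "two_level_fit",
    "select_k",
    "backfit_sequence",
    "backfit_labels",
    "spatial_correlation",
    "write_templates",
    "read_templates",
]


@dataclass
class TemplateSet:
    """K unit-norm, zero-mean microstate topographies with fit diagnostics."""

    maps: np.ndarray  # K x channels
    gev: float
    residual_noise: float
    cv: float = float("nan")
    seed: int | None = None
    restarts: int = 1
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise InvalidParameterError("maps must be a K x channels matrix, K >= 1")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class ClusterFitResult:
    """Per-K diagnostics table and the CV-selected number of microstates."""

    table: pd.DataFrame  # columns: K, gev, residual_noise, cv
    selected_K: int
    templates: dict[int, TemplateSet] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across channels of two average-referenced maps."""
    a = a - np.mean(a)
    b = b - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _normalize_template(a: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm, deterministic sign (largest-|component| positive)."""
    a = a - a.mean()
    nrm = np.linalg.norm(a)
    if nrm > 0:
        a = a / nrm
    i = int(np.argmax(np.abs(a)))
    if a[i] < 0:
        a = -a
    return a


def _assign(V: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-invariant assignment: argmax_k (a_k . v_i)^2, ties -> lowest k."""
    proj = V @ A.T  # n x K
    sq = proj**2
    labels = np.argmax(sq, axis=1)  # np.argmax returns first (lowest) maximizer
    return labels, sq


def _fit_metrics(V: np.ndarray, A: np.ndarray, labels: np.ndarray, sq: np.ndarray):
    n, C = V.shape
    best_sq = sq[np.arange(n), labels]
    total_sq = np.einsum("ij,ij->i", V, V)
    denom = total_sq.sum()
    gev = float(best_sq.sum() / denom) if denom > 0 else 0.0
    sigma2 = float((total_sq - best_sq).sum() / (n * (C - 1)))
    return gev, max(sigma2, 0.0)  # guard tiny negative rounding in exact fits


def _single_kmeans_run(
    V: np.ndarray, K: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, float]:
    n, C = V.shape
    init_idx = rng.choice(n, size=K, replace=False)
    A = np.vstack([_normalize_template(V[i].copy()) for i in init_idx])
    prev_gev = -np.inf
    labels, sq = _assign(V, A)
    for _ in range(max_iter):
        # template update: principal eigenvector of each cluster's scatter
        for k in range(K):
            members = V[labels == k]
            if members.shape[0] == 0:
                # re-seed from the worst-fit map
                best_sq = sq[np.arange(n), labels]
                total_sq = np.einsum("ij,ij->i", V, V)
                with np.errstate(invalid="ignore", divide="ignore"):
                    fit = np.where(total_sq > 0, best_sq / total_sq, 1.0)
                worst = int(np.argmin(fit))
                logger.info("empty cluster %d re-seeded from map %d", k, worst)
                A[k] = _normalize_template(V[worst].copy())
                continue
            S = members.T @ members
            _, vec = eigh(S, subset_by_index=(C - 1, C - 1))
            A[k] = _normalize_template(vec[:, 0])
        labels, sq = _assign(V, A)
        gev, _ = _fit_metrics(V, A, labels, sq)
        if prev_gev > -np.inf and abs(gev - prev_gev) <= tol * max(abs(prev_gev), 1e-300):
            break
        prev_gev = gev
    gev, sigma2 = _fit_metrics(V, A, labels, sq)
    return A, labels, gev, sigma2


# ---------------------------------------------------------------------------
# public fitting API


def modified_kmeans_fit(
    maps: np.ndarray,
    K: int,
    restarts: int = 50,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> TemplateSet:
    """Fit K polarity-invariant microstate templates to topographic maps.

    Iterates (a) assignment of each map to the template maximizing the
    squared projection and (b) template update to the principal eigenvector
    of its members' scatter, until the relative GEV change falls below
    ``tol`` or ``max_iter`` is reached. The best of ``restarts`` random
    initializations (by GEV) is returned.

    Parameters
    ----------
    maps
        n x channels array; rows are average-referenced internally.
    K
        Number of templates; requires ``n > K``.
    """
    V = average_reference(np.asarray(maps, dtype=float))
    n, C = V.shape
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    if K >= n:
        raise InvalidParameterError(f"K = {K} must be < number of maps n = {n}")
    if restarts < 1:
        raise InvalidParameterError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, float] | None = None
    for _ in range(restarts):
        A, _, gev, sigma2 = _single_kmeans_run(V, K, rng, tol, max_iter)
        if best is None or gev > best[0]:
            best = (gev, A, sigma2)
    assert best is not None
    gev, A, sigma2 = best
    return TemplateSet(
        maps=A, gev=gev, residual_noise=sigma2, seed=seed, restarts=restarts
    )


def two_level_fit(
    subject_peak_maps: Sequence[np.ndarray],
    K: int,
    restarts: int = 50,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> TemplateSet:
    """Subject-level fits pooled into a group-level modified k-means fit.

    Each subject's peak maps are clustered with the same K; the resulting
    subject templates (unit weight each) are pooled and clustered again at
    the group level. Diagnostics of the returned set are recomputed against
    the pooled *peak maps* of all subjects, so GEV/residual noise describe
    how well the group maps explain the data rather than the intermediate
    templates.
    """
    if len(subject_peak_maps) < 1:
        raise InvalidParameterError("at least one subject is required")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = ss.spawn(len(subject_peak_maps) + 1)
    pooled_templates = []
    for s, maps in enumerate(subject_peak_maps):
        try:
            tset = modified_kmeans_fit(
                maps,
                K,
                restarts=restarts,
                seed=int(child_seeds[s].generate_state(1)[0] % (2**31)),
                tol=tol,
                max_iter=max_iter,
            )
        except Exception as exc:  # annotate with the offending subject
            raise type(exc)(f"subject {s}: {exc}") from exc
        pooled_templates.append(tset.maps)
    pooled = np.vstack(pooled_templates)
    if pooled.shape[0] == K:
        # a single subject pools exactly K templates: they ARE the group maps
        group = TemplateSet(
            maps=np.vstack([_normalize_template(m.copy()) for m in pooled]),
            gev=0.0, residual_noise=0.0,
        )
    else:
        group_seed = int(child_seeds[-1].generate_state(1)[0] % (2**31))
        group = modified_kmeans_fit(
            pooled, K, restarts=restarts, seed=group_seed, tol=tol, max_iter=max_iter
        )
    # recompute diagnostics against the pooled peak maps
    all_maps = average_reference(np.vstack([np.asarray(m, float) for m in subject_peak_maps]))
    labels, sq = _assign(all_maps, group.maps)
    gev, sigma2 = _fit_metrics(all_maps, group.maps, labels, sq)
    group.gev = gev
    group.residual_noise = sigma2
    group.seed = seed
    return group


def select_k(
    subject_peak_maps: Sequence[np.ndarray],
    k_range: Iterable[int],
    restarts: int = 50,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterFitResult:
    """Choose the number of microstates by the cross-validation criterion.

    For each K a two-level fit is computed and evaluated on the pooled peak
    maps: residual noise ``sigma^2`` and ``CV = sigma^2 ((C-1)/(C-1-K))^2``.
    The selected K minimizes CV; ties break to the smaller K. Values of K
    with ``K >= C - 1`` leave CV undefined and are skipped with a warning.
    """
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise InvalidParameterError("k_range is empty")
    C = np.asarray(subject_peak_maps[0]).shape[1]
    rows = []
    templates: dict[int, TemplateSet] = {}
    all_maps = average_reference(np.vstack([np.asarray(m, float) for m in subject_peak_maps]))
    for K in k_values:
        if K >= C - 1:
            logger.warning("K = %d >= C - 1 = %d leaves CV undefined; skipped", K, C - 1)
            continue
        tset = two_level_fit(
            subject_peak_maps, K, restarts=restarts, seed=seed, tol=tol, max_iter=max_iter
        )
        labels, sq = _assign(all_maps, tset.maps)
        gev, sigma2 = _fit_metrics(all_maps, tset.maps, labels, sq)
        cv = sigma2 * ((C - 1) / (C - 1 - K)) ** 2
        tset.cv = cv
        templates[K] = tset
        rows.append({"K": K, "gev": gev, "residual_noise": sigma2, "cv": cv})
    if not rows:
        raise InvalidParameterError("no K in k_range admits a defined CV criterion")
    table = pd.DataFrame(rows)
    # argmin with ties to the smaller K (table is K-sorted)
    selected = int(table.loc[table["cv"].idxmin(), "K"])
    return ClusterFitResult(table=table, selected_K=selected, templates=templates)


# ---------------------------------------------------------------------------
# back-fitting


def backfit_labels(maps: np.ndarray, templates: TemplateSet) -> np.ndarray:
    """Label each map by highest absolute spatial correlation (ties -> lowest)."""
    V = average_reference(np.asarray(maps, dtype=float))
    labels, _ = _assign(V, templates.maps)
    return labels


def backfit_sequence(rec: EEGRecording, templates: TemplateSet) -> MicrostateSequence:
    """Label every time point of a preprocessed recording.

    Each average-referenced map is assigned to the template with the highest
    absolute spatial correlation (equivalently, minimum Euclidean distance
    after polarity alignment); no temporal smoothing is applied. Annotation
    intervals become the sequence's segments.

    Raises
    ------
    SchemaError
        If both the recording and the template set carry channel names and
        they do not match.
    """
    if templates.channel_names is not None:
        missing = [c for c in templates.channel_names if c not in rec.channel_names]
        extra = [c for c in rec.channel_names if c not in templates.channel_names]
        if missing or extra:
            raise SchemaError(
                f"channel mismatch: missing from recording {missing}, "
                f"unexpected {extra}"
            )
        order = [rec.channel_names.index(c) for c in templates.channel_names]
        data = rec.data[order]
    else:
        if rec.n_channels != templates.n_channels:
            raise SchemaError(
                f"recording has {rec.n_channels} channels, templates expect "
                f"{templates.n_channels}"
            )
        data = rec.data
    labels = backfit_labels(data.T, templates)
    segments = [Segment(a.onset, a.onset + a.duration, a.label) for a in rec.annotations]
    return MicrostateSequence(
        labels=labels, segments=segments, srate=rec.srate, n_states=templates.K
    )


# ---------------------------------------------------------------------------
# serialization


def write_templates(tset: TemplateSet, csv_path: str | Path) -> None:
    """Templates as CSV (rows = templates, columns = channels) + JSON metadata."""
    csv_path = Path(csv_path)
    cols = tset.channel_names or [f"ch{i:03d}" for i in range(tset.n_channels)]
    pd.DataFrame(tset.maps, columns=cols).to_csv(csv_path, index=False)
    meta = {
        "K": tset.K,
        "gev": tset.gev,
        "residual_noise": tset.residual_noise,
        "cv": tset.cv,
        "seed": tset.seed,
        "restarts": tset.restarts,
        "channel_names": tset.channel_names,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_templates(csv_path: str | Path) -> TemplateSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    cv = meta.get("cv")
    return TemplateSet(
        maps=df.to_numpy(),
        gev=float(meta["gev"]),
        residual_noise=float(meta["residual_noise"]),
        cv=float("nan") if cv is None else float(cv),
        seed=meta.get("seed"),
        restarts=int(meta.get("restarts", 1)),
        channel_names=meta.get("channel_names"),
    )
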