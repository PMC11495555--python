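"""Shared fixtures and independent oracles.

The bridge-cost oracle here minimizes D_KL(P || Q) over the transportation
polytope directly, by exact cyclic coordinate descent on 2x2 subtables
(each move preserves both marginals; the optimal step solves a quadratic
in closed form). It shares no code path with the Sinkhorn solver.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from msbridge import SyntheticConfig, generate_cohort, spatial_correlation


def plan_kl(P: np.ndarray, Q: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(P > 0, P * np.log(P / Q), 0.0)
    return float(t.sum())


def bridge_cost_bruteforce(
    Qm: np.ndarray,
    pi0: np.ndarray,
    piT: np.ndarray,
    sweeps: int = 5000,
    tol: float = 1e-14,
) -> float:
    """Minimize KL(P||Q) over the marginal polytope by coordinate descent.

    Moves mass d along e_ij + e_kl - e_il - e_kj; the unconstrained optimum
    of the 1-D restriction solves (1-c) d^2 + b d + cc = 0 with
    c = Q_ij Q_kl / (Q_il Q_kj).
    """
    K = Qm.shape[0]
    P = np.outer(pi0, piT).astype(float)
    quads = [
        (i, j, k, l)
        for i in range(K)
        for k in range(i + 1, K)
        for j in range(K)
        for l in range(K)
        if l != j
    ]
    for _ in range(sweeps):
        moved = 0.0
        for i, j, k, l in quads:
            lo, hi = -min(P[i, j], P[k, l]), min(P[i, l], P[k, j])
            if hi <= lo:
                continue
            c = (Qm[i, j] * Qm[k, l]) / (Qm[i, l] * Qm[k, j])
            a = 1.0 - c
            b = (P[i, j] + P[k, l]) + c * (P[i, l] + P[k, j])
            cc = P[i, j] * P[k, l] - c * P[i, l] * P[k, j]
            if abs(a) < 1e-15:
                d = -cc / b if b != 0 else 0.0
            else:
                disc = b * b - 4 * a * cc
                if disc < 0:
                    continue
                roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
                cands = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
                if not cands:
                    continue
                d = cands[0]
            d = float(np.clip(d, lo, hi))
            P[i, j] += d
            P[k, l] += d
            P[i, l] -= d
            P[k, j] -= d
            moved = max(moved, abs(d))
        if moved < tol:
            break
    return plan_kl(np.clip(P, 0.0, None), Qm)


def best_template_matching(fitted: np.ndarray, truth: np.ndarray) -> list[float]:
    """|spatial corr| per ground-truth map under the best permutation."""
    K = truth.shape[0]
    best = None
    for perm in itertools.permutations(range(fitted.shape[0]), K):
        corrs = [abs(spatial_correlation(fitted[perm[k]], truth[k])) for k in range(K)]
        if best is None or sum(corrs) > sum(best):
            best = corrs
    return best


@pytest.fixture(scope="session")
def rendered_cohort():
    """Rendered rest-only cohort with known 4-state structure (snr 10)."""
    cfg = SyntheticConfig(
        n_channels=16,
        K_true=4,
        n_subjects=6,
        srate=125.0,
        rest_duration_s=80.0,
        n_trials=0,
        snr=10.0,
        seed=11,
    )
    truth, recordings = generate_cohort(cfg)
    return cfg, truth, recordings


@pytest.fixture(scope="session")
def label_cohort():
    """Label-level cohort with the default graded condition effects."""
    cfg = SyntheticConfig(
        n_channels=16,
        K_true=5,
        n_subjects=8,
        srate=125.0,
        rest_duration_s=120.0,
        n_trials=24,
        p_stay=0.9,
        seed=21,
    )
    truth, _ = generate_cohort(cfg, render=False)
    return cfg, truth
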