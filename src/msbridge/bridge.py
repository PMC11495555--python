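"""Schrodinger-bridge transition cost between microstate distributions.

Given the resting two-step joint matrix ``Q_ij`` and two coverage
distributions — resting ``pi0`` and task ``piT`` — the transition cost is
the value of the discrete (static) Schrodinger bridge problem

    Cost = min_{P in U} D_KL(P || Q)
         = min_{P in U} sum_ij C_ij P_ij - H(P),

with transportation cost matrix ``C_ij = -log Q_ij``, plan entropy
``H(P) = -sum_ij P_ij log P_ij``, and feasible set

    U = { P >= 0, sum_ij P_ij = 1,
          sum_j P_ij = pi0_i, sum_i P_ij = piT_j }.

This is entropy-regularized optimal transport with regularization weight
fixed at 1: the Gibbs kernel is exactly Q, so no epsilon knob exists. The
unique optimum has the diagonal-scaling form ``P = diag(u) Q diag(v)`` and
is found by Sinkhorn's alternating updates; the implementation switches to
log-domain (potential) updates when the multipliers overflow. Costs are in
nats (natural logarithm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, rel_entr

from .exceptions import (
    ConvergenceError,
    InfeasibleMarginalsError,
    InvalidParameterError,
    SupportViolationError,
)
from .sequences import CoverageDistribution, JointTransitionMatrix

__all__ = [
    "TransportProblem",
    "BridgeSolution",
    "transportation_cost_matrix",
    "sinkhorn_bridge",
    "transition_cost_per_condition",
    "kl_divergence",
]

_STABILIZE_AT = 1e30


def _as_prob_vector(x) -> np.ndarray:
    if isinstance(x, CoverageDistribution):
        return np.asarray(x.pi, dtype=float)
    v = np.asarray(x, dtype=float)
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("marginal must be a probability vector")
    return v


@dataclass
class TransportProblem:
    """Resting dynamics Q, marginals pi0/piT, and the cost matrix C = -log Q."""

    Q: JointTransitionMatrix
    pi0: np.ndarray
    piT: np.ndarray
    C: np.ndarray
    pseudocount: float = 0.0

    @classmethod
    def from_distributions(
        cls,
        Q: JointTransitionMatrix,
        pi0,
        piT,
        pseudocount: float = 0.0,
    ) -> "TransportProblem":
        pi0 = _as_prob_vector(pi0)
        piT = _as_prob_vector(piT)
        if pi0.size != Q.K or piT.size != Q.K:
            raise InvalidParameterError("marginals must have length K")
        C, Qs = transportation_cost_matrix(Q, pseudocount)
        return cls(Q=Qs, pi0=pi0, piT=piT, C=C, pseudocount=pseudocount)


@dataclass
class BridgeSolution:
    """Optimal plan, Sinkhorn multipliers, and the scalar transition cost."""

    P: np.ndarray
    u: np.ndarray
    v: np.ndarray
    cost: float
    iterations: int
    marginal_error: float


def transportation_cost_matrix(
    Q: JointTransitionMatrix, pseudocount: float = 0.0
) -> tuple[np.ndarray, JointTransitionMatrix]:
    """Elementwise ``C = -log Q``, optionally Laplace-smoothing Q first.

    With ``pseudocount > 0`` the underlying pair counts are smoothed,
    ``Q <- (counts + a) / (n_pairs + K^2 a)``, which removes zero entries
    (and hence infinite costs) from sparse estimates. With the default
    ``pseudocount = 0`` zero entries yield ``C = +inf``; feasibility is
    checked at solve time.

    Returns the cost matrix and the (possibly smoothed) joint matrix.
    """
    if pseudocount < 0:
        raise InvalidParameterError("pseudocount must be >= 0")
    Qm = np.asarray(Q.Q, dtype=float)
    if pseudocount > 0:
        counts = Qm * Q.n_pairs
        Qm = (counts + pseudocount) / (Q.n_pairs + Q.K**2 * pseudocount)
        Q = JointTransitionMatrix(Q=Qm, n_pairs=Q.n_pairs)
    with np.errstate(divide="ignore"):
        C = -np.log(Qm)
    return C, Q


def _check_feasibility(Qm: np.ndarray, pi0: np.ndarray, piT: np.ndarray) -> None:
    row_support = Qm.sum(axis=1) > 0
    col_support = Qm.sum(axis=0) > 0
    bad_rows = np.flatnonzero((pi0 > 0) & ~row_support)
    bad_cols = np.flatnonzero((piT > 0) & ~col_support)
    if bad_rows.size or bad_cols.size:
        raise InfeasibleMarginalsError(
            "marginals place mass on zero-support rows "
            f"{bad_rows.tolist()} / columns {bad_cols.tolist()} of Q; "
            "consider a pseudocount when building the cost matrix"
        )


def _plan_kl(P: np.ndarray, Qm: np.ndarray) -> float:
    """D_KL(P || Q) with the 0 log 0 = 0 convention."""
    return float(rel_entr(P, Qm).sum())


def sinkhorn_bridge(
    prob: TransportProblem, tol: float = 1e-10, max_iter: int = 100_000
) -> BridgeSolution:
    """Solve the discrete Schrodinger bridge by Sinkhorn iteration.

    Alternates ``u <- pi0 / (Q v)`` and ``v <- piT / (Q^T u)`` until the
    largest absolute violation of either marginal constraint by
    ``P = diag(u) Q diag(v)`` falls below ``tol``. If any multiplier
    exceeds 1e30 the iteration restarts in the log domain (potentials with
    log-sum-exp updates), which is overflow-safe.

    Returns
    -------
    BridgeSolution
        With ``cost = D_KL(P || Q)`` in nats; at the optimum this equals
        ``sum_ij C_ij P_ij - H(P)``.

    Raises
    ------
    InfeasibleMarginalsError
        If a marginal puts mass on a zero row/column of Q.
    ConvergenceError
        If max_iter is reached; the error carries the marginal violation.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be positive")
    if max_iter < 1:
        raise InvalidParameterError("max_iter must be >= 1")
    Qm = np.asarray(prob.Q.Q, dtype=float)
    pi0, piT = prob.pi0, prob.piT
    _check_feasibility(Qm, pi0, piT)

    u = np.ones(Qm.shape[0])
    v = np.ones(Qm.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        for it in range(1, max_iter + 1):
            Qv = Qm @ v
            u = np.where(pi0 > 0, pi0 / Qv, 0.0)
            Qtu = Qm.T @ u
            v = np.where(piT > 0, piT / Qtu, 0.0)
            if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
                return _sinkhorn_bridge_log(prob, tol, max_iter)
            if max(u.max(initial=0.0), v.max(initial=0.0)) > _STABILIZE_AT:
                return _sinkhorn_bridge_log(prob, tol, max_iter)
            P = u[:, None] * Qm * v[None, :]
            err = max(
                np.abs(P.sum(axis=1) - pi0).max(),
                np.abs(P.sum(axis=0) - piT).max(),
            )
            if err < tol:
                cost = _plan_kl(P, Qm)
                return BridgeSolution(
                    P=P, u=u, v=v, cost=max(cost, 0.0), iterations=it,
                    marginal_error=float(err),
                )
    raise ConvergenceError(
        f"Sinkhorn did not reach tol={tol} in {max_iter} iterations "
        f"(marginal violation {err:.3e})",
        marginal_error=float(err),
    )


def _sinkhorn_bridge_log(
    prob: TransportProblem, tol: float, max_iter: int
) -> BridgeSolution:
    """Log-domain Sinkhorn (potentials f, g; log-sum-exp updates)."""
    Qm = np.asarray(prob.Q.Q, dtype=float)
    pi0, piT = prob.pi0, prob.piT
    with np.errstate(divide="ignore"):
        logQ = np.log(Qm)
        log_pi0 = np.log(pi0)
        log_piT = np.log(piT)
    f = np.zeros(Qm.shape[0])
    g = np.zeros(Qm.shape[1])
    for it in range(1, max_iter + 1):
        f = np.where(pi0 > 0, log_pi0 - logsumexp(logQ + g[None, :], axis=1), -np.inf)
        g = np.where(piT > 0, log_piT - logsumexp(logQ + f[:, None], axis=0), -np.inf)
        logP = f[:, None] + logQ + g[None, :]
        P = np.exp(logP)
        err = max(
            np.abs(P.sum(axis=1) - pi0).max(),
            np.abs(P.sum(axis=0) - piT).max(),
        )
        if err < tol:
            cost = _plan_kl(P, Qm)
            return BridgeSolution(
                P=P, u=np.exp(f), v=np.exp(g), cost=max(cost, 0.0),
                iterations=it, marginal_error=float(err),
            )
    raise ConvergenceError(
        f"log-domain Sinkhorn did not reach tol={tol} in {max_iter} iterations "
        f"(marginal violation {err:.3e})",
        marginal_error=float(err),
    )


def transition_cost_per_condition(
    Q: JointTransitionMatrix,
    pi0: CoverageDistribution | np.ndarray,
    task_pis: Sequence[CoverageDistribution],
    pseudocount: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> pd.DataFrame:
    """One bridge solve per task condition against the shared resting Q.

    Returns a DataFrame ``(condition, cost, iterations, marginal_error)``
    sorted by condition name. Solver failures are re-raised tagged with the
    offending condition.
    """
    if len(task_pis) < 1:
        raise InvalidParameterError("at least one task condition is required")
    rows = []
    for piT in task_pis:
        prob = TransportProblem.from_distributions(Q, pi0, piT, pseudocount=pseudocount)
        try:
            sol = sinkhorn_bridge(prob, tol=tol, max_iter=max_iter)
        except (InfeasibleMarginalsError, ConvergenceError) as exc:
            raise type(exc)(f"condition '{piT.condition}': {exc}") from exc
        rows.append(
            {
                "condition": piT.condition,
                "cost": sol.cost,
                "iterations": sol.iterations,
                "marginal_error": sol.marginal_error,
            }
        )
    return pd.DataFrame(rows).sort_values("condition").reset_index(drop=True)


def kl_divergence(piA, piB) -> float:
    """``D_KL(piA || piB) = sum_k piA_k log(piA_k / piB_k)`` in nats.

    The global-modulation baseline: how far a task coverage distribution
    sits from rest, ignoring transition structure. ``0 log 0 = 0``.

    Raises
    ------
    SupportViolationError
        If piB has zero mass where piA does not (infinite divergence).
    """
    a = _as_prob_vector(piA)
    b = _as_prob_vector(piB)
    if a.size != b.size:
        raise InvalidParameterError("distributions must have equal length")
    if np.any((a > 0) & (b == 0)):
        raise SupportViolationError(
            "support violation: reference distribution has zero mass where "
            "the argument does not; divergence is infinite"
        )
    return float(rel_entr(a, b).sum())
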