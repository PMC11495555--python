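"""Group-level statistics: chance-level t-tests, BH-FDR, design coding,
Stroop-effect contrasts, and cost-RT association summaries.

The task design crosses stimulus congruency (congruent vs incongruent)
with the proportion of congruency (PC25/PC50/PC75), giving six conditions.
Fixed-effect predictors are contrast-coded: congruency -.5 (incongruent)
vs +.5 (congruent); PC -.5 / 0 / +.5; interaction = product. The Stroop
effect of any per-condition quantity is its incongruent-minus-congruent
difference within a PC level.

Full linear mixed-effects inference (random slopes, Satterthwaite degrees
of freedom) is delegated to external statistical tooling via the
long-format export; this module owns the design coding, per-outcome OLS
effect tables, the chance-level t-tests, BH-FDR over the full family of
fixed effects, and the pooled cost-RT slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    InvalidParameterError,
    MissingCellError,
    UndefinedStatisticError,
)

__all__ = [
    "CONGRUENCY_CODES",
    "PC_CODES",
    "CONDITIONS",
    "ConditionDesign",
    "condition_design",
    "chance_level",
    "ttest_vs_chance",
    "fdr_bh",
    "effect_table",
    "stroop_effect",
    "cost_rt_association",
    "make_long_table",
]

CONGRUENCY_CODES: dict[str, float] = {"incongruent": -0.5, "congruent": 0.5}
PC_CODES: dict[str, float] = {"PC25": -0.5, "PC50": 0.0, "PC75": 0.5}
#: the six task conditions, congruency x proportion-of-congruency
CONDITIONS: list[tuple[str, str]] = [
    (c, p) for c in ("congruent", "incongruent") for p in ("PC25", "PC50", "PC75")
]

FIXED_EFFECTS = ["intercept", "congruency", "pc", "congruency:pc"]


@dataclass(frozen=True)
class ConditionDesign:
    """Contrast codes for one condition cell."""

    congruency: str
    pc: str

    def __post_init__(self) -> None:
        if self.congruency not in CONGRUENCY_CODES:
            raise InvalidParameterError(f"unknown congruency '{self.congruency}'")
        if self.pc not in PC_CODES:
            raise InvalidParameterError(f"unknown PC level '{self.pc}'")

    @property
    def congruency_code(self) -> float:
        return CONGRUENCY_CODES[self.congruency]

    @property
    def pc_code(self) -> float:
        return PC_CODES[self.pc]

    @property
    def interaction(self) -> float:
        return self.congruency_code * self.pc_code


def condition_design(congruency: str, pc: str) -> ConditionDesign:
    return ConditionDesign(congruency, pc)


def chance_level(K: int) -> float:
    """Uniform-coverage chance probability, 1/K (0.1429 for K = 7)."""
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    return 1.0 / K


class TTestResult(NamedTuple):
    t: float
    p: float
    d: float
    mean: float
    se: float


def ttest_vs_chance(values: Sequence[float], null_value: float) -> TTestResult:
    """Two-tailed one-sample t-test of per-subject values against a null.

    Cohen's d is the mean difference over the sample standard deviation.

    Raises
    ------
    UndefinedStatisticError
        With fewer than 2 values or zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise UndefinedStatisticError("one-sample t-test needs n >= 2")
    sd = x.std(ddof=1)
    if x.min() == x.max():  # constant sample: variance is exactly zero
        if x[0] == null_value:
            return TTestResult(t=0.0, p=1.0, d=0.0, mean=float(x[0]), se=0.0)
        raise UndefinedStatisticError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(x, null_value)
    se = sd / np.sqrt(x.size)
    d = (x.mean() - null_value) / sd
    return TTestResult(
        t=float(res.statistic), p=float(res.pvalue), d=float(d),
        mean=float(x.mean()), se=float(se),
    )


def fdr_bh(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns ``(adjusted_p, reject)``; adjusted p-values are monotone and
    capped at 1, and rejections match the classical step-up rule at
    ``alpha``. An empty input yields empty arrays.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def effect_table(
    long_df: pd.DataFrame,
    value_col: str = "value",
    outcome_col: str = "outcome",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-outcome OLS fixed-effect table with family-wide BH-FDR.

    Expects a long-format table with columns ``subject``, ``outcome_col``,
    ``congruency_code``, ``pc_code``, and ``value_col`` (typically the
    task-minus-rest coverage change per microstate, or a cost). For each
    outcome an OLS fit of value on intercept + congruency + PC +
    interaction is computed; all fixed effects across outcomes form one
    FDR family (4 effects x K outcomes, n = 28 for seven microstates).
    """
    required = {"subject", outcome_col, "congruency_code", "pc_code", value_col}
    missing = required - set(long_df.columns)
    if missing:
        raise InvalidParameterError(f"long table missing columns {sorted(missing)}")
    rows = []
    for outcome, sub in long_df.groupby(outcome_col, sort=True):
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "congruency": sub["congruency_code"].to_numpy(),
                "pc": sub["pc_code"].to_numpy(),
                "congruency:pc": (sub["congruency_code"] * sub["pc_code"]).to_numpy(),
            }
        )
        fit = sm.OLS(sub[value_col].to_numpy(), X).fit()
        for name in FIXED_EFFECTS:
            rows.append(
                {
                    "outcome": outcome,
                    "effect": name,
                    "estimate": fit.params[name],
                    "se": fit.bse[name],
                    "t": fit.tvalues[name],
                    "p": fit.pvalues[name],
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"], table["significant"] = fdr_bh(table["p"].to_numpy(), alpha=alpha)
    return table


def stroop_effect(
    costs: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Incongruent-minus-congruent difference per subject x PC level.

    ``costs`` must have columns ``subject``, ``congruency``, ``pc`` and the
    value column; the contract is generic — applied to response times it
    yields the behavioral Stroop effect.

    Raises
    ------
    MissingCellError
        If a subject x PC cell lacks either congruency level.
    """
    required = {"subject", "congruency", "pc", value_col}
    missing = required - set(costs.columns)
    if missing:
        raise InvalidParameterError(f"cost table missing columns {sorted(missing)}")
    rows = []
    for (subject, pc), cell in costs.groupby(["subject", "pc"], sort=True):
        by_cong = cell.groupby("congruency")[value_col].mean()
        if "incongruent" not in by_cong or "congruent" not in by_cong:
            raise MissingCellError(
                f"subject {subject}, {pc}: need both congruency levels, "
                f"found {sorted(by_cong.index)}"
            )
        rows.append(
            {
                "subject": subject,
                "pc": pc,
                "delta": by_cong["incongruent"] - by_cong["congruent"],
            }
        )
    return pd.DataFrame(rows)


class AssociationResult(NamedTuple):
    slope: float
    t: float
    p: float
    per_pc: pd.DataFrame


def cost_rt_association(deltas: pd.DataFrame) -> AssociationResult:
    """Pooled slope of the cost Stroop effect on the RT Stroop effect.

    Fits OLS of ``delta_cost`` on ``delta_rt`` with PC-level intercepts
    (fixed effects), pooling subjects; also returns per-PC simple slopes.
    The full random-slope mixed model is delegated externally.

    Raises
    ------
    UndefinedStatisticError
        If the predictor is constant.
    InvalidParameterError
        With fewer than 3 subjects.
    """
    required = {"subject", "pc", "delta_cost", "delta_rt"}
    missing = required - set(deltas.columns)
    if missing:
        raise InvalidParameterError(f"delta table missing columns {sorted(missing)}")
    if deltas["subject"].nunique() < 3:
        raise InvalidParameterError("association needs >= 3 subjects")
    if np.isclose(deltas["delta_rt"].std(ddof=0), 0.0):
        raise UndefinedStatisticError("delta_rt is constant; slope undefined")
    X = pd.get_dummies(deltas["pc"], dtype=float)
    X["delta_rt"] = deltas["delta_rt"].to_numpy()
    fit = sm.OLS(deltas["delta_cost"].to_numpy(), X).fit()
    per_pc_rows = []
    for pc, sub in deltas.groupby("pc", sort=True):
        if sub["delta_rt"].std(ddof=0) == 0 or len(sub) < 3:
            per_pc_rows.append({"pc": pc, "slope": np.nan, "p": np.nan, "n": len(sub)})
            continue
        lr = sps.linregress(sub["delta_rt"], sub["delta_cost"])
        per_pc_rows.append({"pc": pc, "slope": lr.slope, "p": lr.pvalue, "n": len(sub)})
    return AssociationResult(
        slope=float(fit.params["delta_rt"]),
        t=float(fit.tvalues["delta_rt"]),
        p=float(fit.pvalues["delta_rt"]),
        per_pc=pd.DataFrame(per_pc_rows),
    )


def make_long_table(
    values: pd.DataFrame,
    value_col: str = "value",
    outcome_col: str = "outcome",
) -> pd.DataFrame:
    """Attach contrast codes to a (subject, outcome, congruency, pc, value)
    table, producing the long-format export consumed by mixed-model tools."""
    required = {"subject", outcome_col, "congruency", "pc", value_col}
    missing = required - set(values.columns)
    if missing:
        raise InvalidParameterError(f"table missing columns {sorted(missing)}")
    out = values.copy()
    out["congruency_code"] = out["congruency"].map(CONGRUENCY_CODES)
    out["pc_code"] = out["pc"].map(PC_CODES)
    if out["congruency_code"].isna().any() or out["pc_code"].isna().any():
        raise InvalidParameterError("unknown congruency or PC label in table")
    out["interaction_code"] = out["congruency_code"] * out["pc_code"]
    return out
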