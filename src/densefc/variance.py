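"""Stepwise proportional-variance-explained ledgers.

For an outcome (mean Fisher-z over a declared edge set, e.g. one network
cell or all edges), predictor blocks are added to a random-intercept
mixed model in a fixed order — (1) subject intercepts, (2) demographics,
(3) viewing condition, (4) head motion, (5) drowsiness, (6) affect — and
the change in conditional R² after each step is read as that block's
additional variance explained.  Negative changes are floored at zero, and
the floored increments are normalized to percent of their total.

Conditional R² follows the Nakagawa–Schielzeth definition for
random-intercept models:

    r2c = (var_f + var_b) / (var_f + var_b + var_e)

with var_f the variance of the fixed-effect linear predictor over the
observed data, var_b the subject-intercept variance and var_e the
residual variance.  All stepwise fits use ML so likelihoods are
comparable across models with different fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import canonical_cell, cell_name, parse_cell
from .edge_models import LMMFit, ObservationTable, fit_lmm

#: fixed block order of the stepwise procedure
BLOCK_ORDER = ("subject", "demographics", "condition", "motion", "drowsiness", "affect")

WHOLE_BRAIN = "whole_brain"


def r2c(var_fixed: float, var_random: float, var_resid: float) -> float:
    """Conditional R² of a random-intercept model from its variance parts."""
    denom = var_fixed + var_random + var_resid
    if denom <= 0:
        return 0.0
    return (var_fixed + var_random) / denom


def r2c_from_fit(fit: LMMFit, X: np.ndarray, column: int = 0) -> float:
    """Conditional R² of one fitted outcome column.

    var_fixed is the (sample) variance of X @ beta over the data; an
    intercept-only fixed part therefore contributes zero, so the
    subject-only step's r2c is the intraclass share.
    """
    if not fit.converged[column]:
        raise ValueError("cannot compute r2c from a non-converged fit")
    eta = X @ fit.beta[:, column]
    var_f = float(np.var(eta, ddof=1)) if len(eta) > 1 else 0.0
    return r2c(var_f, float(fit.sigma2_b[column]), float(fit.sigma2_e[column]))


@dataclass
class VarianceLedger:
    """Ordered record of one outcome's stepwise variance decomposition."""

    outcome: str
    affect: str
    steps: pd.DataFrame  # block, r2c_after, delta, delta_floored, percent
    total_explained: float
    flagged: bool = False

    def percent(self, block: str) -> float:
        row = self.steps.loc[self.steps["block"] == block, "percent"]
        return float(row.iloc[0])


def _block_columns(pred_columns: Sequence[str]) -> dict[str, list[str]]:
    cond = [c for c in pred_columns if c.startswith("cond_")]
    return {
        "subject": [],                       # random intercept enters at step 1
        "demographics": ["age_c", "sex_c"],
        "condition": ["session_c"] + cond,
        "motion": ["fd_c"],
        "drowsiness": ["drowsy_c"],
        "affect": ["affect"],
    }


def outcome_vector(table: ObservationTable, outcome: str) -> np.ndarray:
    """Mean Fisher-z per observation over the outcome's edge set.

    ``whole_brain`` averages all edges; a cell name (e.g. "DMN-DMN")
    averages that cell's edges.
    """
    if outcome == WHOLE_BRAIN:
        return table.Z.mean(axis=1)
    cell = parse_cell(outcome, table.partition.networks)
    idx = table.edge_index(cell)
    return table.Z[:, idx].mean(axis=1)


def stepwise_ledger(
    table: ObservationTable,
    outcome: str = WHOLE_BRAIN,
    affect: str = "positive",
    y: np.ndarray | None = None,
    exclude_sleep: bool = False,
) -> VarianceLedger:
    """Run the six-step stepwise r2c procedure for one outcome.

    Returns the per-step r2c, raw and floored increments, and each block's
    percent of the total (floored) variance explained.  If any step fails
    to converge the ledger is flagged and percents are suppressed (NaN).
    """
    tab = table.subset(~table.meta["sleep_flag"].to_numpy()) if exclude_sleep else table
    if y is None:
        y = outcome_vector(tab, outcome)
    y = np.asarray(y, dtype=float)
    pred = tab.predictors(affect)
    groups = tab.subject_codes()
    blocks = _block_columns(pred.columns)

    cols: list[str] = ["const"]
    rows = []
    prev = 0.0
    flagged = False
    for block in BLOCK_ORDER:
        cols = cols + blocks[block]
        X = pred[cols].to_numpy()
        fit = fit_lmm(X, y, groups, columns=cols, method="ml")
        if not fit.converged[0]:
            flagged = True
            rows.append({"block": block, "r2c_after": np.nan, "delta": np.nan})
            continue
        r2 = r2c_from_fit(fit, X)
        rows.append({"block": block, "r2c_after": r2, "delta": r2 - prev})
        prev = r2
    steps = pd.DataFrame(rows)
    steps["delta_floored"] = steps["delta"].clip(lower=0.0)
    total_floored = steps["delta_floored"].sum()
    if flagged or total_floored <= 0:
        steps["percent"] = np.nan
    else:
        steps["percent"] = 100.0 * steps["delta_floored"] / total_floored
    return VarianceLedger(
        outcome=outcome,
        affect=affect,
        steps=steps,
        total_explained=prev,
        flagged=flagged,
    )


def ledger_report(ledgers: Sequence[VarianceLedger]) -> pd.DataFrame:
    """Stack ledgers into a tidy (outcome × block) percent table.

    Blocks whose floored contribution is zero are omitted, mirroring how a
    stacked-proportion figure would drop predictors that only reduced the
    model's r2c.
    """
    if not ledgers:
        raise ValueError("no ledgers to report")
    rows = []
    for led in ledgers:
        for rec in led.steps.itertuples():
            if led.flagged or not np.isfinite(rec.percent) or rec.delta_floored <= 0:
                continue
            rows.append(
                {
                    "outcome": led.outcome,
                    "affect": led.affect,
                    "block": rec.block,
                    "percent": rec.percent,
                    "r2c_after": rec.r2c_after,
                }
            )
    return pd.DataFrame(rows, columns=["outcome", "affect", "block", "percent", "r2c_after"])


def ledgers_to_csv(ledgers: Sequence[VarianceLedger], path) -> None:
    frames = []
    for led in ledgers:
        df = led.steps.copy()
        df.insert(0, "outcome", led.outcome)
        df.insert(1, "affect", led.affect)
        df["flagged"] = led.flagged
        df["total_explained"] = led.total_explained
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.15g")
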