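"""Behavioral data preparation and association models.

Session-level self-report measures (PANAS-X positive/negative affect) and
run-level covariates (framewise displacement, drowsiness flags) are scored,
centered, and related to each other with random-intercept mixed models.

Centering scheme: affect is centered on each subject's own mean so its
coefficient captures within-subject day-to-day variation only; all other
covariates (age, sex, session index, head motion, drowsiness) are grand-mean
centered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: severity coding of the three post-scan sleepiness items
DROWSINESS_LEVELS = {"awake_difficulty": 3, "sleepy": 2, "tired": 1}

#: canonical viewing-condition order; the first is the model reference
CONDITION_ORDER = ("lowdemand", "movie", "clips")

RUN_COLUMNS = [
    "subject", "session", "condition", "run",
    "pa_raw", "na_raw", "age", "sex", "fd",
    "tired", "sleepy", "awake_difficulty",
]


@dataclass
class BehaviorTable:
    """Run-level behavioral table plus session/condition aggregations.

    ``runs`` holds one row per functional run with the columns in
    :data:`RUN_COLUMNS`.  Affect is a daily (session-level) measure and is
    therefore constant across a session's runs.
    """

    runs: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RUN_COLUMNS if c not in self.runs.columns]
        if missing:
            raise ValueError(f"behavior table missing columns: {missing}")

    @property
    def n_runs_per_condition(self) -> int:
        counts = self.runs.groupby(
            ["subject", "session", "condition"], sort=False
        ).size()
        if counts.nunique() != 1:
            raise ValueError("unequal run counts per (subject, session, condition)")
        return int(counts.iloc[0])

    @property
    def sessions(self) -> pd.DataFrame:
        """One row per (subject, session): affect, demographics, session-mean
        motion and drowsiness."""
        runs = self.runs
        run_level = runs.assign(_drowsy_run=run_drowsiness_level(runs))
        out = (
            run_level.groupby(["subject", "session"], sort=True)
            .agg(
                pa_raw=("pa_raw", "first"),
                na_raw=("na_raw", "first"),
                age=("age", "first"),
                sex=("sex", "first"),
                fd=("fd", "mean"),
            )
            .reset_index()
        )
        # session drowsiness = mean over conditions of the per-condition score
        cond = self.conditions
        sess_drowsy = cond.groupby(["subject", "session"])["drowsy"].mean()
        out = out.merge(sess_drowsy.rename("drowsy").reset_index(),
                        on=["subject", "session"])
        return out

    @property
    def conditions(self) -> pd.DataFrame:
        """One row per (subject, session, condition): motion, drowsiness
        score, sleep-likelihood flag."""
        runs = self.runs
        scores = score_drowsiness(runs)
        out = (
            runs.groupby(["subject", "session", "condition"], sort=True)
            .agg(
                pa_raw=("pa_raw", "first"),
                na_raw=("na_raw", "first"),
                age=("age", "first"),
                sex=("sex", "first"),
                fd=("fd", "mean"),
                sleep_flag=("awake_difficulty", "any"),
            )
            .reset_index()
        )
        out = out.merge(scores.reset_index(), on=["subject", "session", "condition"])
        return out

    def write_csv(self, path) -> None:
        df = self.runs.copy()
        for flag in ("tired", "sleepy", "awake_difficulty"):
            df[flag] = df[flag].astype(int)
        df.to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def read_csv(cls, path) -> "BehaviorTable":
        df = pd.read_csv(path)
        for flag in ("tired", "sleepy", "awake_difficulty"):
            df[flag] = df[flag].astype(bool)
        df["subject"] = df["subject"].astype(str)
        return cls(runs=df)


def run_drowsiness_level(runs: pd.DataFrame) -> pd.Series:
    """Per-run drowsiness level: the maximum endorsed item severity (0–3).

    Difficulty staying awake scores 3, feeling sleepy 2, feeling tired 1,
    no endorsement 0.
    """
    level = pd.Series(0, index=runs.index)
    for col, pts in DROWSINESS_LEVELS.items():
        level = level.where(~runs[col].astype(bool), other=level.clip(lower=pts))
    return level


def score_drowsiness(runs: pd.DataFrame, n_runs: int | None = None) -> pd.Series:
    """Per-condition drowsiness score: sum of the run levels over the
    condition's runs (0–6 with two runs).

    Raises if any (subject, session, condition) has a run count different
    from the rest (a missing run invalidates the sum).
    """
    level = run_drowsiness_level(runs)
    grouped = level.groupby(
        [runs["subject"], runs["session"], runs["condition"]], sort=True
    )
    counts = grouped.size()
    expected = n_runs if n_runs is not None else int(counts.max())
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(
            f"missing run(s): expected {expected} runs per condition, "
            f"got {bad.to_dict()}"
        )
    out = grouped.sum()
    out.name = "drowsy"
    out.index.names = ["subject", "session", "condition"]
    return out


def subject_mean_center(values, subjects) -> np.ndarray:
    """Center each value on its subject's mean (within-subject deviation)."""
    s = pd.Series(np.asarray(values, dtype=float))
    return (s - s.groupby(pd.Series(np.asarray(subjects)).values).transform("mean")).to_numpy()


def grand_mean_center(values) -> np.ndarray:
    """Center values on the overall mean."""
    v = np.asarray(values, dtype=float)
    return v - v.mean()


def flag_sleep_exclusions(table: BehaviorTable) -> pd.Series:
    """Boolean per (subject, session, condition): any constituent run reported
    difficulty staying awake.  Downstream analyses can be rerun on the
    complement as a sensitivity check."""
    cond = table.conditions
    return cond.set_index(["subject", "session", "condition"])["sleep_flag"]


def prepare_sessions(table: BehaviorTable) -> pd.DataFrame:
    """Session-level frame with the centering scheme applied.

    Adds subject-mean-centered affect (pa_c, na_c) and grand-mean-centered
    covariates (age_c, sex_c, session_c, fd_c, drowsy_c).  Motion and
    drowsiness are averaged within session here, as appropriate for the
    behavioral association models.
    """
    df = table.sessions.copy()
    df["pa_c"] = subject_mean_center(df["pa_raw"], df["subject"])
    df["na_c"] = subject_mean_center(df["na_raw"], df["subject"])
    for col in ("age", "sex", "session", "fd", "drowsy"):
        df[f"{col}_c"] = grand_mean_center(df[col])
    return df


def prepare_conditions(table: BehaviorTable) -> pd.DataFrame:
    """Observation-level (subject × session × condition) frame with the
    centering scheme applied; motion and drowsiness stay per-condition, as
    used by the connectivity models."""
    df = table.conditions.copy()
    sess = df.drop_duplicates(["subject", "session"])
    pa_c = pd.Series(
        subject_mean_center(sess["pa_raw"], sess["subject"]),
        index=pd.MultiIndex.from_frame(sess[["subject", "session"]]),
    )
    na_c = pd.Series(
        subject_mean_center(sess["na_raw"], sess["subject"]),
        index=pd.MultiIndex.from_frame(sess[["subject", "session"]]),
    )
    key = pd.MultiIndex.from_frame(df[["subject", "session"]])
    df["pa_c"] = pa_c.reindex(key).to_numpy()
    df["na_c"] = na_c.reindex(key).to_numpy()
    for col in ("age", "sex", "session", "fd", "drowsy"):
        df[f"{col}_c"] = grand_mean_center(df[col])
    return df


@dataclass
class AssocResult:
    """Random-intercept mixed-model slope with Wald 95% CI."""

    outcome: str
    predictor: str
    B: float
    ci_lo: float
    ci_hi: float
    p: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_lo <= self.B <= self.ci_hi):
            raise ValueError("CI does not bracket the estimate")


def fit_behavior_assoc(
    df: pd.DataFrame, outcome: str, predictor: str
) -> AssocResult:
    """Fit ``outcome ~ predictor + (1|subject)`` on session-level data.

    Uses REML with a Wald (normal-approximation) 95% CI and two-tailed p
    for the slope.  A singular or non-converged fit is returned flagged
    rather than raising.
    """
    n_subj = df["subject"].nunique()
    n_sess = df.groupby("subject")["session"].nunique().min()
    if n_subj < 2 or n_sess < 2:
        raise ValueError("need >=2 subjects with >=2 sessions each")
    exog = sm.add_constant(df[[predictor]].to_numpy())
    model = sm.MixedLM(df[outcome].to_numpy(), exog, groups=df["subject"].to_numpy())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError):
        # singular/degenerate fit: flagged, never silent
        return AssocResult(outcome, predictor, np.nan, np.nan, np.nan, np.nan, False)
    b = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    converged = bool(getattr(fit, "converged", True)) and np.isfinite(se)
    if not np.isfinite(se):
        return AssocResult(outcome, predictor, b, np.nan, np.nan, np.nan, False)
    zcrit = 1.959963984540054
    return AssocResult(
        outcome, predictor, b, b - zcrit * se, b + zcrit * se, p, converged
    )


def behavior_assoc_suite(df: pd.DataFrame) -> pd.DataFrame:
    """The standard behavioral association models, as a tidy table.

    PA~NA coupling plus each grand-mean-centered covariate against both
    subject-mean-centered affect measures, in separate models.
    """
    results = [fit_behavior_assoc(df, "pa_c", "na_c")]
    for valence in ("pa_c", "na_c"):
        for cov in ("sex_c", "age_c", "session_c", "fd_c", "drowsy_c"):
            results.append(fit_behavior_assoc(df, valence, cov))
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "predictor": r.predictor,
                "B": r.B,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "p": r.p,
                "converged": r.converged,
            }
            for r in results
        ]
    )
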