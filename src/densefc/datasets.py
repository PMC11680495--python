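"""Synthetic dense-sampling cohort generator.

Emulates the variance structure of a precision-imaging cohort: a modest
number of adults scanned repeatedly (default 24 subjects × 4 weekly
sessions × 3 passive-viewing conditions, two runs each), with

* dominant, stable subject-specific connectomes (between-subject SD well
  above observation noise, so subject identity explains the bulk of edge
  variance),
* viewing-condition effects concentrated in the visual network,
* a small (or zero) within-subject daily-affect effect on connectivity,
* PANAS-X affect scores, framewise displacement, and post-scan drowsiness
  ratings drawn to match the cohort's descriptive statistics
  (PA 26.51 ± 6.48, NA 11.86 ± 3.67, FD 0.08 ± 0.03 mm, condition
  drowsiness score mean ≈ 2).

Every injected effect is recorded in a :class:`GroundTruth` object so the
downstream estimators can be tested for parameter recovery.  All draws are
deterministic given ``params.seed``; each generation stage uses a named
substream of a single root seed so stages can be re-run independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import atlas
from .behavior import (
    BehaviorTable,
    CONDITION_ORDER as CONDITIONS,
    RUN_COLUMNS,
    subject_mean_center,
)
from .connectome import Connectome, ParcelTimeseries, build_edge_sets, edge_pairs

#: PANAS-X subscale bounds used for truncation
AFFECT_BOUNDS = (10.0, 50.0)

_STAGE = {"behavior": 1, "connectomes": 2, "timeseries": 3}


def _rng(seed: int, stage: str, *key: int) -> np.random.Generator:
    """Named substream: one root seed, one stream per (stage, key)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE[stage], *map(int, key)])
    )


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: cohort size and design from
    the scanning protocol; affect/motion/drowsiness distributions from the
    cohort descriptives; connectome variance components sized so subject
    identity dominates (roughly two-thirds of edge variance), condition
    effects are strongest in the visual network, and daily affect explains
    under a few percent of within-subject variance.
    """

    n_subjects: int = 24
    n_sessions: int = 4
    n_conditions: int = 3
    n_runs_per_condition: int = 2
    node_labels: Mapping[str, str] = field(default_factory=atlas.analysis_labels)

    # connectome variance structure (Fisher-z units)
    subject_sd: float = 0.15
    noise_sd: float = 0.10
    base_within: float = 0.30
    base_between: float = 0.10
    condition_effect: Mapping[str, float] = field(
        default_factory=lambda: {"VIS": 0.15}
    )
    #: ground-truth affect slope, z-units per PANAS point: scalar (all edges),
    #: or map of network-cell name ("VIS-VIS") to slope
    affect_beta: float | Mapping[str, float] = 0.004
    affect_valence: str = "positive"

    # nuisance effects on connectivity (uniform across edges)
    fd_beta: float = 0.3       # z per mm of framewise displacement
    drowsy_beta: float = 0.01  # z per drowsiness point
    age_beta: float = 0.0      # z per year
    sex_beta: float = 0.02     # z for male vs female

    # behavior distributions
    pa_mean: float = 26.51
    pa_sd: float = 6.48
    na_mean: float = 11.86
    na_sd: float = 3.67
    affect_icc: float = 0.5    # between-subject share of affect variance
    pa_session_slope: float = -0.75   # PANAS points per session
    na_session_slope: float = -0.47
    fd_mean: float = 0.08
    fd_sd: float = 0.03
    drowsiness_rates: Mapping[str, float] = field(
        default_factory=lambda: {"tired": 0.42, "sleepy": 0.25, "awake_difficulty": 0.10}
    )
    age_mean: float = 41.15
    age_sd: float = 3.60

    #: exactly-null mode: zeroes affect_beta, nuisance betas and session
    #: trends so permutation-null datasets are exactly exchangeable
    null_mode: bool = False

    n_volumes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "noise_sd", "pa_sd", "na_sd", "fd_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sessions < 2:
            raise ValueError("need n_sessions >= 2 (permutation needs >=2 blocks)")
        if not 1 <= self.n_conditions <= len(CONDITIONS):
            raise ValueError(f"n_conditions must be 1..{len(CONDITIONS)}")
        if not 0.0 <= self.affect_icc <= 1.0:
            raise ValueError("affect_icc must be in [0, 1]")
        nodes = list(self.node_labels)
        if len(set(nodes)) != len(nodes):
            raise ValueError("node_labels must cover every node exactly once")
        if self.affect_valence not in ("positive", "negative"):
            raise ValueError("affect_valence must be 'positive' or 'negative'")

    @property
    def conditions(self) -> tuple[str, ...]:
        return CONDITIONS[: self.n_conditions]

    @property
    def subjects(self) -> list[str]:
        return [f"sub{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class GroundTruth:
    """Injected effects of a generated dataset, for parameter recovery."""

    edges: list[tuple[str, str]]
    affect_beta: np.ndarray          # (E,) z per PANAS point
    affect_valence: str
    subject_intercepts: np.ndarray   # (n_subjects, E)
    condition_offsets: np.ndarray    # (n_conditions, E)
    fd_beta: float
    drowsy_beta: float
    age_beta: float
    sex_beta: float
    subjects: list[str]
    conditions: list[str]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "edges": [list(e) for e in self.edges],
            "affect_beta": self.affect_beta.tolist(),
            "affect_valence": self.affect_valence,
            "subject_intercepts": self.subject_intercepts.tolist(),
            "condition_offsets": self.condition_offsets.tolist(),
            "fd_beta": self.fd_beta,
            "drowsy_beta": self.drowsy_beta,
            "age_beta": self.age_beta,
            "sex_beta": self.sex_beta,
            "subjects": self.subjects,
            "conditions": self.conditions,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            edges=[tuple(e) for e in d["edges"]],
            affect_beta=np.asarray(d["affect_beta"]),
            affect_valence=d["affect_valence"],
            subject_intercepts=np.asarray(d["subject_intercepts"]),
            condition_offsets=np.asarray(d["condition_offsets"]),
            fd_beta=d["fd_beta"],
            drowsy_beta=d["drowsy_beta"],
            age_beta=d["age_beta"],
            sex_beta=d["sex_beta"],
            subjects=d["subjects"],
            conditions=d["conditions"],
            seed=d["seed"],
        )


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated-normal draws by resampling (exact for the bounded scale)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    out = rng.normal(mean, sd, size=size)
    if sd == 0:
        return np.clip(out, lo, hi)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd)
        bad = (out < lo) | (out > hi)
    return out


def generate_behavior(params: CohortParams) -> BehaviorTable:
    """Draw the run-level behavioral table for the cohort.

    Affect is a session-level (daily) measure composed of a stable subject
    mean, a linear session trend, and day-to-day variation, truncated to
    the PANAS-X subscale range by resampling; positive and negative affect
    are drawn independently (the cohort showed no within-subject PA–NA
    coupling).  Motion is drawn per run from a truncated normal; the three
    drowsiness items are independent per-run Bernoulli flags.
    """
    rng = _rng(params.seed, "behavior")
    S, K = params.n_subjects, params.n_sessions
    subjects = params.subjects
    sessions = np.arange(1, K + 1)

    age = rng.normal(params.age_mean, params.age_sd, size=S)
    sex = np.zeros(S, dtype=int)
    sex[S // 2:] = 1
    rng.shuffle(sex)

    pa_slope = 0.0 if params.null_mode else params.pa_session_slope
    na_slope = 0.0 if params.null_mode else params.na_session_slope
    trend_c = sessions - sessions.mean()

    def draw_affect(mean, sd, slope):
        sd_b = sd * np.sqrt(params.affect_icc)
        sd_w = sd * np.sqrt(1.0 - params.affect_icc)
        mu = _truncnorm(rng, mean, sd_b, *AFFECT_BOUNDS, size=(S,))
        target = mu[:, None] + slope * trend_c[None, :]
        return _truncnorm(rng, target, sd_w, *AFFECT_BOUNDS, size=(S, K))

    pa = draw_affect(params.pa_mean, params.pa_sd, pa_slope)
    na = draw_affect(params.na_mean, params.na_sd, na_slope)

    rows = []
    rates = params.drowsiness_rates
    for i, subj in enumerate(subjects):
        for k, sess in enumerate(sessions):
            for cond in params.conditions:
                for run in range(1, params.n_runs_per_condition + 1):
                    fd = _truncnorm(rng, params.fd_mean, params.fd_sd,
                                    0.01, np.inf, size=(1,))[0]
                    flags = {
                        item: bool(rng.random() < rates.get(item, 0.0))
                        for item in ("tired", "sleepy", "awake_difficulty")
                    }
                    rows.append(
                        (subj, int(sess), cond, run, pa[i, k], na[i, k],
                         age[i], int(sex[i]), fd,
                         flags["tired"], flags["sleepy"], flags["awake_difficulty"])
                    )
    runs = pd.DataFrame(rows, columns=RUN_COLUMNS)
    return BehaviorTable(runs=runs)


def _edge_beta_vector(params: CohortParams, edges, partition) -> np.ndarray:
    beta = np.zeros(len(edges))
    requested = params.affect_beta
    if np.isscalar(requested):
        beta[:] = float(requested)
        return beta
    edge_index = {e: i for i, e in enumerate(edges)}
    from .connectome import parse_cell

    for name, value in requested.items():
        cell = parse_cell(name, partition.networks)
        for e in partition[cell]:
            beta[edge_index[e]] = float(value)
    return beta


def generate_connectomes(
    params: CohortParams, behavior: BehaviorTable
) -> tuple[list[Connectome], GroundTruth]:
    """Draw one Fisher-z connectome per (subject, session, condition).

    Each edge z is: subject-specific intercept (stable connectome)
    + viewing-condition offset + affect slope × subject-mean-centered
    affect + uniform nuisance effects (motion, drowsiness, age, sex)
    + Gaussian observation noise.
    """
    rng = _rng(params.seed, "connectomes")
    nodes = list(params.node_labels)
    edges = edge_pairs(nodes)
    E = len(edges)
    partition = build_edge_sets(params.node_labels)
    merged = {n: atlas.merge_salience(net) for n, net in params.node_labels.items()}

    base = np.array(
        [params.base_within if merged[a] == merged[b] else params.base_between
         for a, b in edges]
    )
    subj_int = base[None, :] + rng.normal(
        0.0, params.subject_sd, size=(params.n_subjects, E)
    )

    # condition offsets: per affected network, a linear contrast across
    # conditions (sums to zero) applied to that network's within-cell edges
    C = params.n_conditions
    cond_offsets = np.zeros((C, E))
    contrast = np.arange(C) - (C - 1) / 2.0
    edge_index = {e: i for i, e in enumerate(edges)}
    for net, delta in params.condition_effect.items():
        if (net, net) not in partition.cells:
            continue
        for e in partition[(net, net)]:
            cond_offsets[:, edge_index[e]] += float(delta) * contrast

    if params.null_mode:
        beta = np.zeros(E)
        fd_beta = drowsy_beta = age_beta = sex_beta = 0.0
    else:
        beta = _edge_beta_vector(params, edges, partition)
        fd_beta, drowsy_beta = params.fd_beta, params.drowsy_beta
        age_beta, sex_beta = params.age_beta, params.sex_beta

    cond_df = behavior.conditions.set_index(["subject", "session", "condition"])
    sess_df = behavior.sessions
    raw_col = "pa_raw" if params.affect_valence == "positive" else "na_raw"
    centered = pd.Series(
        subject_mean_center(sess_df[raw_col], sess_df["subject"]),
        index=pd.MultiIndex.from_frame(sess_df[["subject", "session"]]),
    )
    fd0 = cond_df["fd"].mean()
    dr0 = cond_df["drowsy"].mean()
    age0 = sess_df["age"].mean()
    sex0 = sess_df["sex"].mean()

    subj_code = {s: i for i, s in enumerate(params.subjects)}
    conns: list[Connectome] = []
    n = len(nodes)
    iu = np.triu_indices(n, k=1)
    for subj in params.subjects:
        for sess in range(1, params.n_sessions + 1):
            aff_c = float(centered.loc[(subj, sess)])
            for ci, cond in enumerate(params.conditions):
                row = cond_df.loc[(subj, sess, cond)]
                zvec = (
                    subj_int[subj_code[subj]]
                    + cond_offsets[ci]
                    + beta * aff_c
                    + fd_beta * (row["fd"] - fd0)
                    + drowsy_beta * (row["drowsy"] - dr0)
                    + age_beta * (row["age"] - age0)
                    + sex_beta * (row["sex"] - sex0)
                    + rng.normal(0.0, params.noise_sd, size=E)
                )
                z = np.full((n, n), np.nan)
                z[iu] = zvec
                z.T[iu] = zvec
                conns.append(
                    Connectome(
                        z=z, nodes=nodes, subject=subj, session=sess,
                        condition=cond, labels=dict(params.node_labels),
                    )
                )
    truth = GroundTruth(
        edges=edges,
        affect_beta=beta,
        affect_valence=params.affect_valence,
        subject_intercepts=subj_int,
        condition_offsets=cond_offsets,
        fd_beta=fd_beta,
        drowsy_beta=drowsy_beta,
        age_beta=age_beta,
        sex_beta=sex_beta,
        subjects=params.subjects,
        conditions=list(params.conditions),
        seed=params.seed,
    )
    return conns, truth


def generate_timeseries(
    params: CohortParams, target: Connectome
) -> list[ParcelTimeseries]:
    """Draw Gaussian node timeseries whose population correlation matches a
    target connectome, as paired runs for the target's condition.

    The target z matrix is inverse-Fisher transformed; the implied
    correlation matrix must be positive definite.
    """
    n = len(target.nodes)
    r = np.tanh(np.nan_to_num(target.z, nan=0.0))
    np.fill_diagonal(r, 1.0)
    try:
        L = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        raise ValueError(
            "target correlation matrix is not positive definite for "
            f"(subject={target.subject}, session={target.session}, "
            f"condition={target.condition})"
        ) from None
    ci = CONDITIONS.index(target.condition) if target.condition in CONDITIONS else 0
    sid = str(target.subject)
    if sid.startswith("sub") and sid[3:].isdigit():
        subj_ix = int(sid[3:])
    else:  # stable across processes (built-in hash() is salted)
        subj_ix = zlib.crc32(sid.encode()) % (2**20)
    rng = _rng(params.seed, "timeseries", subj_ix, int(target.session), ci)
    out = []
    for run in range(1, params.n_runs_per_condition + 1):
        x = L @ rng.standard_normal((n, params.n_volumes))
        out.append(
            ParcelTimeseries(
                values=x, nodes=target.nodes, subject=target.subject,
                session=target.session, condition=target.condition, run=run,
            )
        )
    return out
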