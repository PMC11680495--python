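"""Constrained network-based statistic (cNBS) permutation inference.

Network-level observed effects are means of edgewise mixed-model t-values
over predefined within-/between-network edge sets ("cells").  The null is
built by refitting every edge after shuffling each subject's connectivity
across that subject's sessions: all rows from one session move together,
conditions stay matched to conditions, no data crosses subjects, and the
predictor columns are untouched.  One relabeling per subject per
permutation; when the relabeling space is small it is enumerated exactly,
otherwise relabelings are sampled uniformly (identity allowed).

Also provides the standardized effect size SES = (observed − null mean) /
null SD, Benjamini–Hochberg FDR within a hypothesis family, and the
multivariate pooling (mv-cNBS) that summarizes a grouping of cells by the
Euclidean norm of their effect vector scaled by the number of cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _iterperms, product as _iterproduct
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectome import canonical_cell, cell_name, parse_cell
from .edge_models import LMMFit, ObservationTable, fit_all_edges

Tail = Literal["greater", "less", "two_sided"]

#: exact enumeration is used when the relabeling space is at most this big
EXACT_SPACE_LIMIT = 100_000


def permutation_p(observed: float, null: np.ndarray, tail: Tail = "greater") -> float:
    """Sampled-permutation p-value, (1 + #{null at least as extreme}) / (1 + B).

    The add-one form counts the observed statistic as one realization of
    the null, so p is never 0.  Two-sided extremity is measured as
    |value − null mean|.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if tail == "greater":
        k = int(np.sum(null >= observed))
    elif tail == "less":
        k = int(np.sum(null <= observed))
    elif tail == "two_sided":
        mu = null.mean()
        k = int(np.sum(np.abs(null - mu) >= abs(observed - mu)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + null.size)


def exact_p(observed: float, null: np.ndarray, tail: Tail = "greater") -> float:
    """Exact permutation p over a fully enumerated null (which includes the
    identity relabeling, hence the observed statistic itself)."""
    null = np.asarray(null, dtype=float)
    if tail == "greater":
        k = int(np.sum(null >= observed))
    elif tail == "less":
        k = int(np.sum(null <= observed))
    elif tail == "two_sided":
        mu = null.mean()
        k = int(np.sum(np.abs(null - mu) >= abs(observed - mu)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return k / null.size


def ses(observed: float, null: np.ndarray) -> float:
    """Standardized effect size: (observed − null mean) / null SD.

    Returns NaN (with a warning) when the null is degenerate (zero SD).
    """
    null = np.asarray(null, dtype=float)
    sd = null.std(ddof=1) if null.size > 1 else 0.0
    if not np.isfinite(sd) or sd == 0.0:
        warnings.warn("null SD is zero; SES undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((observed - null.mean()) / sd)


def mv_statistic(effects: Sequence[float], normalization: str = "mean") -> float:
    """Pooled multivariate statistic over a grouping of network cells.

    ``mean``: Euclidean norm of the cell-effect vector divided by the
    number of cells K (the implemented reading of "average Euclidean
    distance"); ``rms``: norm divided by sqrt(K).  Either choice yields a
    valid permutation test since the same formula is applied to the null.
    """
    v = np.asarray(list(effects), dtype=float)
    if v.size == 0:
        raise ValueError("empty cell grouping")
    norm = float(np.linalg.norm(v))
    if normalization == "mean":
        return norm / v.size
    if normalization == "rms":
        return norm / math.sqrt(v.size)
    raise ValueError(f"unknown normalization {normalization!r}")


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values within one hypothesis family."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation plans


@dataclass
class PermutationPlan:
    """Per-permutation, per-subject session relabelings.

    ``assignment[b][i]`` is a permutation array over subject i's sessions:
    under permutation b, subject i's session s takes the connectivity
    observed at session ``sessions[i][assignment[b][i][s]]``.
    """

    subjects: list[str]
    sessions: list[np.ndarray]          # per subject, session labels in order
    assignment: np.ndarray | list       # (B, n_subjects) object/int arrays
    exact: bool
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.assignment)

    @staticmethod
    def space_size(session_counts: Sequence[int]) -> int:
        total = 1
        for c in session_counts:
            total *= math.factorial(int(c))
        return total

    @classmethod
    def _session_lists(cls, table: ObservationTable):
        subjects = table.subjects
        sessions = []
        for s in subjects:
            sess = np.array(
                sorted(table.meta.loc[table.meta["subject"] == s, "session"].unique())
            )
            if len(sess) < 2:
                warnings.warn(
                    f"subject {s} has a single session; left unpermuted",
                    RuntimeWarning,
                    stacklevel=3,
                )
            sessions.append(sess)
        return subjects, sessions

    @classmethod
    def sample(cls, table: ObservationTable, B: int, seed: int) -> "PermutationPlan":
        """B relabelings drawn uniformly (with replacement) from the product
        of per-subject session permutations; identity is allowed."""
        subjects, sessions = cls._session_lists(table)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
        assignment = [
            [
                rng.permutation(len(sess)) if len(sess) > 1 else np.arange(len(sess))
                for sess in sessions
            ]
            for _ in range(B)
        ]
        return cls(subjects, sessions, assignment, exact=False, seed=seed)

    @classmethod
    def enumerate(cls, table: ObservationTable) -> "PermutationPlan":
        """All relabelings (exact null); requires a small relabeling space."""
        subjects, sessions = cls._session_lists(table)
        size = cls.space_size([len(s) for s in sessions])
        if size > EXACT_SPACE_LIMIT:
            raise ValueError(
                f"relabeling space {size} too large to enumerate "
                f"(limit {EXACT_SPACE_LIMIT})"
            )
        per_subject = [
            [np.array(p) for p in _iterperms(range(len(sess)))] if len(sess) > 1
            else [np.arange(len(sess))]
            for sess in sessions
        ]
        assignment = [list(combo) for combo in _iterproduct(*per_subject)]
        return cls(subjects, sessions, assignment, exact=True)


class _RowPermuter:
    """Precomputed (subject, session, condition) → row map for fast
    application of many plan entries to one table."""

    def __init__(self, table: ObservationTable):
        meta = table.meta
        self.n = len(meta)
        index: dict[tuple, int] = {
            (r.subject, r.session, r.condition): i
            for i, r in enumerate(meta.itertuples())
        }
        self.per_subject: list[list[tuple[int, ...]]] = []
        self.sessions: list[list] = []
        for subj in table.subjects:
            sess = sorted(meta.loc[meta["subject"] == subj, "session"].unique())
            self.sessions.append(sess)
            blocks = []
            for s in sess:
                rows = tuple(
                    index.get((subj, s, cond), -1) for cond in table.conditions
                )
                blocks.append(rows)
            self.per_subject.append(blocks)

    def source_rows(self, entry: Sequence[np.ndarray]) -> np.ndarray:
        source = np.arange(self.n)
        for blocks, perm in zip(self.per_subject, entry):
            if len(perm) != len(blocks):
                raise ValueError(
                    f"plan entry has {len(perm)} sessions, table has {len(blocks)}"
                )
            for s_pos, src_pos in enumerate(perm):
                if s_pos == src_pos:
                    continue
                for dst, src in zip(blocks[s_pos], blocks[int(src_pos)]):
                    # condition present in both sessions: move the block;
                    # otherwise leave the row's own value in place
                    if dst >= 0 and src >= 0:
                        source[dst] = src
        return source


def permute_observations(table: ObservationTable, entry: Sequence[np.ndarray]) -> ObservationTable:
    """Apply one plan entry: within each subject, session blocks of edge
    values are reassigned to session labels; conditions stay matched and
    predictors untouched.  The inverse bijection restores the original."""
    return table.with_rows_permuted(_RowPermuter(table).source_rows(entry))


# ---------------------------------------------------------------------------
# null construction and the cNBS test


@dataclass
class NullResult:
    """Permutation null: per-permutation edge t-values and cell means."""

    edge_t: np.ndarray            # (B, E)
    cell_t: pd.DataFrame          # (B, n_cells), columns = cell names
    n_nonconverged: np.ndarray    # (B,) count of flagged edges per permutation
    exact: bool


def network_observed(edge_t: np.ndarray, member_idx: np.ndarray) -> float:
    """Cell-level observed effect: mean edge t over the cell's members.

    Non-finite (non-converged) edge values are dropped from the mean; an
    all-NaN or empty cell is an error.
    """
    member_idx = np.asarray(member_idx)
    if member_idx.size == 0:
        raise ValueError("empty network cell")
    vals = np.asarray(edge_t, dtype=float)[member_idx]
    if not np.isfinite(vals).any():
        raise ValueError("no finite edge statistic in cell")
    return float(np.nanmean(np.where(np.isfinite(vals), vals, np.nan)))


def _cell_means(edge_t: np.ndarray, cells: Mapping[str, np.ndarray]) -> np.ndarray:
    out = np.empty(len(cells))
    for k, idx in enumerate(cells.values()):
        vals = edge_t[idx]
        finite = np.isfinite(vals)
        out[k] = vals[finite].mean() if finite.any() else np.nan
    return out


def build_null(
    table: ObservationTable,
    affect: str = "positive",
    B: int = 1000,
    seed: int = 0,
    plan: PermutationPlan | None = None,
    exclude_sleep: bool = False,
    drop: Sequence[str] = (),
) -> NullResult:
    """Refit all edges under B session relabelings and record edge- and
    cell-level null statistics.

    When the relabeling space is at most :data:`EXACT_SPACE_LIMIT` the
    space is enumerated exactly instead of sampled.  Null refits use the
    same model specification and convergence policy as the observed fits.
    """
    tab = table.subset(~table.meta["sleep_flag"].to_numpy()) if exclude_sleep else table
    if plan is None:
        counts = [
            tab.meta.loc[tab.meta["subject"] == s, "session"].nunique()
            for s in tab.subjects
        ]
        space = PermutationPlan.space_size(counts)
        # exact null is both cheaper and better when the whole relabeling
        # space is no larger than the requested number of samples
        if space <= min(B, EXACT_SPACE_LIMIT):
            plan = PermutationPlan.enumerate(tab)
        else:
            plan = PermutationPlan.sample(tab, B=B, seed=seed)
    # empty cells (single-node networks have no within-network edges)
    # carry no statistic and are excluded from the null
    cells = {
        cell_name(c): tab.edge_index(c)
        for c in tab.partition
        if len(tab.partition[c]) > 0
    }
    # the design never changes under the relabelings — only edge values move
    from .edge_models import fit_lmm

    pred = tab.predictors(affect, drop=drop)
    X = pred.to_numpy()
    cols = list(pred.columns)
    groups = tab.subject_codes()
    permuter = _RowPermuter(tab)
    edge_t = np.empty((plan.B, tab.n_edges))
    nbad = np.zeros(plan.B, dtype=int)
    for b, entry in enumerate(plan.assignment):
        rows = permuter.source_rows(entry)
        fit = fit_lmm(X, tab.Z[rows], groups, columns=cols)
        edge_t[b] = fit.tvalue("affect")
        nbad[b] = int((~fit.converged).sum())
    cell_t = pd.DataFrame(
        np.vstack([_cell_means(edge_t[b], cells) for b in range(plan.B)]),
        columns=list(cells),
    )
    return NullResult(edge_t=edge_t, cell_t=cell_t, n_nonconverged=nbad, exact=plan.exact)


def cnbs_test(
    table: ObservationTable,
    affect: str = "positive",
    cells: Sequence[tuple[str, str]] | None = None,
    B: int = 1000,
    seed: int = 0,
    tails: Mapping[str, Tail] | Tail = "greater",
    exclude_sleep: bool = False,
    null: NullResult | None = None,
    apply_fdr: bool = True,
    drop: Sequence[str] = (),
) -> tuple[pd.DataFrame, NullResult]:
    """Full cNBS analysis for a family of network cells.

    Returns a tidy result frame (cell, n_edges, observed_t, null_mean,
    null_sd, ses, p, q, tail) and the null object (reusable across
    families and for mv-cNBS).  ``tails`` is either one tail for all cells
    or a per-cell-name map.
    """
    tab = table.subset(~table.meta["sleep_flag"].to_numpy()) if exclude_sleep else table
    if cells is None:
        cells = [c for c in tab.partition if len(tab.partition[c]) > 0]
    if null is None:
        null = build_null(
            table, affect=affect, B=B, seed=seed, exclude_sleep=exclude_sleep,
            drop=drop,
        )
    frame, _ = fit_all_edges(tab, affect=affect, drop=drop)
    tvals = frame["t"].to_numpy()

    rows = []
    for cell in cells:
        ctuple = (
            canonical_cell(cell, tab.partition.networks) if isinstance(cell, tuple)
            else parse_cell(cell, tab.partition.networks)
        )
        name = cell_name(ctuple)
        idx = tab.edge_index(ctuple)
        obs = network_observed(tvals, idx)
        cnull = null.cell_t[name].to_numpy()
        tail = tails.get(name, "greater") if isinstance(tails, Mapping) else tails
        p = (exact_p if null.exact else permutation_p)(obs, cnull, tail)
        rows.append(
            {
                "cell": name,
                "n_edges": len(idx),
                "observed_t": obs,
                "null_mean": float(cnull.mean()),
                "null_sd": float(cnull.std(ddof=1)),
                "ses": ses(obs, cnull),
                "p": p,
                "tail": tail,
            }
        )
    out = pd.DataFrame(rows)
    if apply_fdr:
        out["q"] = fdr_adjust(out["p"])
    return out, null


@dataclass
class MvEffect:
    """Pooled multivariate network effect for one cell grouping."""

    grouping: str
    observed: float
    p: float
    ses: float | None    # absent when the observed pooled effect does not
    null_mean: float     # exceed the null mean (one-sided pooled statistic)
    null_sd: float
    n_cells: int


def mv_cnbs(
    observed_cells: pd.Series | Mapping[str, float],
    null_cells: pd.DataFrame,
    groupings: Mapping[str, Sequence[str]],
    normalization: str = "mean",
    exact: bool = False,
) -> dict[str, MvEffect]:
    """Multivariate cNBS over cell groupings (e.g. whole brain / within-
    network only / between-network only).

    The same pooled statistic is computed from the observed cell effects
    and from each permutation's cell effects; the pooled statistic is
    non-negative, so the test is inherently one-sided (greater).  The SES
    is reported as absent (None) when the observed pooled effect is below
    the null mean.
    """
    observed_cells = pd.Series(dict(observed_cells))
    out: dict[str, MvEffect] = {}
    for name, members in groupings.items():
        members = list(members)
        if not members:
            raise ValueError(f"empty grouping {name!r}")
        missing = [m for m in members if m not in null_cells.columns]
        if missing:
            raise KeyError(f"grouping {name!r} references unknown cells {missing}")
        obs = mv_statistic(observed_cells[members], normalization)
        nulls = np.array(
            [mv_statistic(row, normalization) for row in null_cells[members].to_numpy()]
        )
        p = (exact_p if exact else permutation_p)(obs, nulls, "greater")
        mu = float(nulls.mean())
        out[name] = MvEffect(
            grouping=name,
            observed=obs,
            p=p,
            ses=(ses(obs, nulls) if obs >= mu else None),
            null_mean=mu,
            null_sd=float(nulls.std(ddof=1)),
            n_cells=len(members),
        )
    return out


def default_groupings(partition) -> dict[str, list[str]]:
    """Whole-brain / within-only / between-only cell groupings (non-empty
    cells only; single-node networks have no within-network cell)."""
    nonempty = [c for c in partition if len(partition[c]) > 0]
    return {
        "whole_brain": [cell_name(c) for c in nonempty],
        "within_only": [cell_name(c) for c in nonempty if c[0] == c[1]],
        "between_only": [cell_name(c) for c in nonempty if c[0] != c[1]],
    }
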