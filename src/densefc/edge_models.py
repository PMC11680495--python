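"""Edgewise random-intercept mixed models.

Each edge's Fisher-z connectivity is modelled as

    z ~ affect + age + sex + session + condition + motion + drowsiness
        + (1 | subject)

with subject-mean-centered affect (one valence per model) and grand-mean
centered covariates.  The affect coefficient's t-value (estimate / SE) is
the edge-level statistic; network-level inference averages it over edge
sets and compares against a session-permutation null, so no t-distribution
p-value is attached at the edge level.

The solver profiles the REML (or ML) criterion over the single variance
ratio sigma_b^2/sigma_e^2 using within/between-subject sufficient
statistics, vectorized across all edges — a whole 378-edge table refits in
milliseconds, which is what makes the permutation null affordable.  It is
validated against statsmodels MixedLM in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import atlas
from .behavior import BehaviorTable, prepare_conditions
from .connectome import (
    Connectome,
    EdgeSetPartition,
    build_edge_sets,
    cell_name,
    edge_name,
    edge_pairs,
)

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0

#: profile-search range for log variance ratio
_T_LO, _T_HI, _T_GRID = np.log(1e-8), np.log(1e4), 25
_GOLDEN_ITER = 26

META_COLUMNS = [
    "subject", "session", "condition",
    "pa_c", "na_c", "age_c", "sex_c", "session_c", "fd_c", "drowsy_c",
    "sleep_flag",
]


class ObservationTable:
    """Long-format analysis table: one row per (subject, session, condition).

    ``meta`` holds identifiers and centered predictors; ``Z`` is the
    (n_obs × n_edges) matrix of Fisher-z edge values in canonical edge
    order; ``labels`` is the node→network map that defines that order.
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        Z: np.ndarray,
        edges: Sequence[tuple[str, str]],
        labels: Mapping[str, str],
    ):
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        Z = np.asarray(Z, dtype=float)
        if Z.shape != (len(meta), len(edges)):
            raise ValueError(
                f"Z shape {Z.shape} != (n_obs={len(meta)}, n_edges={len(edges)})"
            )
        self.meta = meta.reset_index(drop=True)
        self.Z = Z
        self.edges = [tuple(e) for e in edges]
        self.labels = dict(labels)
        self.partition: EdgeSetPartition = build_edge_sets(self.labels)

    # -- basic structure ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.meta["subject"]))

    @property
    def conditions(self) -> list[str]:
        from .behavior import CONDITION_ORDER

        present = set(self.meta["condition"])
        ordered = [c for c in CONDITION_ORDER if c in present]
        return ordered + sorted(present - set(ordered))

    def subject_codes(self) -> np.ndarray:
        order = {s: i for i, s in enumerate(self.subjects)}
        return self.meta["subject"].map(order).to_numpy()

    def edge_index(self, cell: tuple[str, str]) -> np.ndarray:
        """Column indices of the edges in one network cell."""
        members = set(map(tuple, self.partition[cell]))
        return np.array([k for k, e in enumerate(self.edges) if e in members])

    # -- model design -------------------------------------------------------

    def predictors(
        self, affect: str = "positive", drop: Sequence[str] = ()
    ) -> pd.DataFrame:
        """Full fixed-effects design as named columns (const first).

        The viewing condition enters as treatment-coded dummies with the
        first condition (low-demand video) as reference.  ``drop`` names
        covariates to exclude (``age_c``, ``sex_c``, ``session_c``,
        ``condition``, ``fd_c``, ``drowsy_c``) — needed e.g. on tiny
        cohorts where subject-level covariates are inherently collinear.
        """
        if affect not in ("positive", "negative"):
            raise ValueError("affect must be 'positive' or 'negative'")
        drop = set(drop)
        aff_col = "pa_c" if affect == "positive" else "na_c"
        df = pd.DataFrame({"const": np.ones(len(self))})
        df["affect"] = self.meta[aff_col].to_numpy()
        for c in ("age_c", "sex_c", "session_c"):
            if c not in drop:
                df[c] = self.meta[c].to_numpy()
        if "condition" not in drop:
            for cond in self.conditions[1:]:
                df[f"cond_{cond}"] = (self.meta["condition"] == cond).astype(float)
        for c in ("fd_c", "drowsy_c"):
            if c not in drop:
                df[c] = self.meta[c].to_numpy()
        return df

    # -- row operations ------------------------------------------------------

    def subset(self, keep: np.ndarray) -> "ObservationTable":
        """Row-filtered copy (e.g., sleep-exclusion complement)."""
        keep = np.asarray(keep, dtype=bool)
        return ObservationTable(
            meta=self.meta.loc[keep].reset_index(drop=True),
            Z=self.Z[keep],
            edges=self.edges,
            labels=self.labels,
        )

    def with_rows_permuted(self, source_rows: np.ndarray) -> "ObservationTable":
        """Copy in which row i's edge values come from row source_rows[i];
        all predictor columns are untouched."""
        return ObservationTable(
            meta=self.meta, Z=self.Z[np.asarray(source_rows)],
            edges=self.edges, labels=self.labels,
        )

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        wide = self.meta.copy()
        zed = pd.DataFrame(
            self.Z, columns=[edge_name(a, b) for a, b in self.edges],
            index=wide.index,
        )
        return pd.concat([wide, zed], axis=1)

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["sleep_flag"] = df["sleep_flag"].astype(int)
        df.to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def read_csv(cls, path, labels: Mapping[str, str]) -> "ObservationTable":
        df = pd.read_csv(path)
        df["subject"] = df["subject"].astype(str)
        df["sleep_flag"] = df["sleep_flag"].astype(bool)
        edges = edge_pairs(list(labels))
        cols = [edge_name(a, b) for a, b in edges]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"observation CSV missing edge columns, e.g. {missing[:3]}")
        return cls(
            meta=df[META_COLUMNS], Z=df[cols].to_numpy(), edges=edges, labels=labels
        )


def build_observation_table(
    connectomes: Sequence[Connectome],
    behavior: BehaviorTable,
    labels: Mapping[str, str] | None = None,
) -> ObservationTable:
    """Join per-observation connectomes with prepared behavioral predictors."""
    if not connectomes:
        raise ValueError("no connectomes given")
    if labels is None:
        labels = connectomes[0].labels
        if not labels:
            raise ValueError("no node labels on connectomes; pass labels=")
    nodes = list(labels)
    edges = edge_pairs(nodes)
    prep = prepare_conditions(behavior).set_index(["subject", "session", "condition"])

    rows, zrows = [], []
    for conn in sorted(connectomes, key=lambda c: (c.subject, c.session, c.condition)):
        if list(conn.nodes) != nodes:
            raise ValueError(
                f"connectome {conn.key} node order differs from label table"
            )
        key = (conn.subject, conn.session, conn.condition)
        if key not in prep.index:
            raise ValueError(f"no behavior row for connectome observation {key}")
        b = prep.loc[key]
        rows.append(
            {
                "subject": conn.subject,
                "session": conn.session,
                "condition": conn.condition,
                "pa_c": b["pa_c"], "na_c": b["na_c"],
                "age_c": b["age_c"], "sex_c": b["sex_c"],
                "session_c": b["session_c"],
                "fd_c": b["fd_c"], "drowsy_c": b["drowsy_c"],
                "sleep_flag": bool(b["sleep_flag"]),
            }
        )
        zrows.append(conn.edge_vector(edges))
    meta = pd.DataFrame(rows)
    return ObservationTable(meta=meta, Z=np.vstack(zrows), edges=edges, labels=labels)


# ---------------------------------------------------------------------------
# profiled random-intercept LMM, vectorized over outcome columns


@dataclass
class LMMFit:
    """Fit of the same fixed-effect design to many outcome columns."""

    columns: list[str]           # fixed-effect names
    beta: np.ndarray             # (p, E)
    se: np.ndarray               # (p, E)
    sigma2_e: np.ndarray         # (E,) residual variance
    sigma2_b: np.ndarray         # (E,) random-intercept variance
    converged: np.ndarray        # (E,) bool
    method: str
    n: int

    def tvalue(self, column: str) -> np.ndarray:
        j = self.columns.index(column)
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta[j] / self.se[j]


class _Suff:
    """Within/between sufficient statistics for one design + outcome block."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, groups: np.ndarray):
        n, p = X.shape
        q = int(groups.max()) + 1
        m = np.bincount(groups, minlength=q).astype(float)
        if np.any(m == 0):
            raise ValueError("empty subject group")
        Xbar = np.zeros((q, p))
        np.add.at(Xbar, groups, X)
        Xbar /= m[:, None]
        Ybar = np.zeros((q, Y.shape[1]))
        np.add.at(Ybar, groups, Y)
        Ybar /= m[:, None]
        Xw = X - Xbar[groups]
        Yw = Y - Ybar[groups]
        self.n, self.p, self.q, self.m = n, p, q, m
        self.Xbar, self.Ybar = Xbar, Ybar
        self.Aw = Xw.T @ Xw
        self.cw = Xw.T @ Yw          # (p, E)
        self.dw = np.einsum("ne,ne->e", Yw, Yw)

    # shared variance ratio across all outcomes (grid stage)
    def crit_shared(self, rho: float, reml: bool) -> np.ndarray:
        w = self.m / (1.0 + self.m * rho)
        M = self.Aw + (self.Xbar * w[:, None]).T @ self.Xbar
        C = self.cw + self.Xbar.T @ (w[:, None] * self.Ybar)
        d = self.dw + np.einsum("q,qe->e", w, self.Ybar**2)
        beta = np.linalg.solve(M, C)
        rss = d - np.einsum("pe,pe->e", beta, C)
        ld0 = np.log1p(self.m * rho).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            lrss = np.log(rss)
        if reml:
            _, ldM = np.linalg.slogdet(M)
            return (self.n - self.p) * lrss + ld0 + ldM
        return self.n * lrss + ld0

    # per-outcome variance ratios (refinement + final stage)
    def _pieces(self, rho: np.ndarray):
        W = self.m[None, :] / (1.0 + np.outer(rho, self.m))        # (E, q)
        Me = self.Aw[None] + np.einsum("eq,qp,qr->epr", W, self.Xbar, self.Xbar)
        Ce = self.cw.T + np.einsum("eq,qp->ep", W * self.Ybar.T, self.Xbar)
        de = self.dw + np.einsum("eq,eq->e", W, (self.Ybar.T) ** 2)
        return W, Me, Ce, de

    def crit_per_edge(self, rho: np.ndarray, reml: bool) -> np.ndarray:
        _, Me, Ce, de = self._pieces(rho)
        beta = np.linalg.solve(Me, Ce[..., None])[..., 0]
        rss = de - np.einsum("ep,ep->e", beta, Ce)
        ld0 = np.log1p(np.outer(rho, self.m)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lrss = np.log(rss)
        if reml:
            _, ldM = np.linalg.slogdet(Me)
            return (self.n - self.p) * lrss + ld0 + ldM
        return self.n * lrss + ld0

    def finalize(self, rho: np.ndarray, reml: bool):
        _, Me, Ce, de = self._pieces(rho)
        beta = np.linalg.solve(Me, Ce[..., None])[..., 0]        # (E, p)
        rss = de - np.einsum("ep,ep->e", beta, Ce)
        dof = (self.n - self.p) if reml else self.n
        sigma2_e = rss / dof
        Minv = np.linalg.inv(Me)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(sigma2_e[:, None] * np.einsum("epp->ep", Minv))
        return beta.T, se.T, sigma2_e, rss


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(columns[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def fit_lmm(
    X: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray,
    columns: Sequence[str] | None = None,
    method: str = "reml",
) -> LMMFit:
    """Random-intercept LMM fit for every column of Y under one design X.

    Profiles the (RE)ML criterion over the variance ratio
    rho = sigma_b^2 / sigma_e^2 per outcome: a coarse log-grid bracket
    followed by golden-section refinement.  Outcomes with (numerically)
    zero residual variance are flagged non-converged with NaN statistics.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    reml = method == "reml"
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(groups)
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]
    columns = list(columns)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >=2 subjects")
    _check_rank(X, columns)

    s = _Suff(X, Y, groups)
    E = Y.shape[1]

    tgrid = np.linspace(_T_LO, _T_HI, _T_GRID)
    crit = np.empty((_T_GRID, E))
    for g, t in enumerate(tgrid):
        crit[g] = s.crit_shared(float(np.exp(t)), reml)
    crit = np.where(np.isfinite(crit), crit, np.inf)
    k = np.argmin(crit, axis=0)
    a = tgrid[np.clip(k - 1, 0, _T_GRID - 1)]
    b = tgrid[np.clip(k + 1, 0, _T_GRID - 1)]

    def _f(t: np.ndarray) -> np.ndarray:
        v = s.crit_per_edge(np.exp(t), reml)
        return np.where(np.isfinite(v), v, np.inf)

    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = _f(c), _f(d)
    for _ in range(_GOLDEN_ITER):
        left = fc < fd  # minimum is in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        new_c = np.where(left, b - _INVPHI * (b - a), d)
        new_d = np.where(left, c, a + _INVPHI * (b - a))
        fx = _f(np.where(left, new_c, new_d))
        new_fc = np.where(left, fx, fd)
        new_fd = np.where(left, fc, fx)
        c, d, fc, fd = new_c, new_d, new_fc, new_fd

    rho = np.exp((a + b) / 2.0)
    beta, se, sigma2_e, rss = s.finalize(rho, reml)
    scale = np.maximum(s.dw + np.einsum("q,qe->e", s.m, s.Ybar**2), 1.0)
    ok = np.isfinite(rss) & (rss > 1e-12 * scale) & np.all(np.isfinite(se), axis=0)
    beta[:, ~ok] = np.nan
    se[:, ~ok] = np.nan
    sigma2_e = np.where(ok, sigma2_e, np.nan)
    return LMMFit(
        columns=columns,
        beta=beta,
        se=se,
        sigma2_e=sigma2_e,
        sigma2_b=rho * sigma2_e,
        converged=ok,
        method=method,
        n=s.n,
    )


# ---------------------------------------------------------------------------


@dataclass
class EdgeFit:
    """Affect coefficient of one edge's mixed model."""

    edge: tuple[str, str]
    beta: float
    se: float
    t: float
    converged: bool


def fit_all_edges(
    table: ObservationTable,
    affect: str = "positive",
    exclude_sleep: bool = False,
    method: str = "reml",
    drop: Sequence[str] = (),
) -> tuple[pd.DataFrame, LMMFit]:
    """Fit the edgewise model at every edge; returns (tidy frame, raw fit).

    The tidy frame has one row per edge in canonical order with the affect
    term's estimate, SE, t and convergence flag.  Row order of the input
    table does not affect the estimates.
    """
    tab = table
    if exclude_sleep:
        tab = table.subset(~table.meta["sleep_flag"].to_numpy())
    pred = tab.predictors(affect, drop=drop)
    fit = fit_lmm(
        pred.to_numpy(), tab.Z, tab.subject_codes(),
        columns=list(pred.columns), method=method,
    )
    j = fit.columns.index("affect")
    merged = {n: atlas.merge_salience(net) for n, net in tab.labels.items()}
    from .connectome import canonical_cell

    nets = tab.partition.networks
    frame = pd.DataFrame(
        {
            "node_i": [e[0] for e in tab.edges],
            "node_j": [e[1] for e in tab.edges],
            "network_pair": [
                cell_name(canonical_cell((merged[a], merged[b]), nets))
                for a, b in tab.edges
            ],
            "beta": fit.beta[j],
            "se": fit.se[j],
            "t": fit.tvalue("affect"),
            "converged": fit.converged,
        }
    )
    return frame, fit


def fit_edge(
    edge: tuple[str, str],
    table: ObservationTable,
    affect: str = "positive",
    method: str = "reml",
    drop: Sequence[str] = (),
) -> EdgeFit:
    """Fit a single edge's mixed model (convenience wrapper)."""
    try:
        k = table.edges.index(tuple(edge))
    except ValueError:
        raise KeyError(f"edge {edge} not in table") from None
    pred = table.predictors(affect, drop=drop)
    fit = fit_lmm(
        pred.to_numpy(), table.Z[:, [k]], table.subject_codes(),
        columns=list(pred.columns), method=method,
    )
    j = fit.columns.index("affect")
    return EdgeFit(
        edge=tuple(edge),
        beta=float(fit.beta[j, 0]),
        se=float(fit.se[j, 0]),
        t=float(fit.tvalue("affect")[0]),
        converged=bool(fit.converged[0]),
    )
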