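"""Connectome construction from parcellated timeseries.

Functional connectivity for one observation (subject, session, viewing
condition) is the Pearson correlation between parcellated node
timeseries, Fisher z-transformed (z = atanh(r)).  The four subcortical
affective ROIs are averaged into a single SUBCTX node at the edge level,
and edges are partitioned into within-/between-network cells for
network-level inference.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import SUBCTX, SUBCORTICAL_NODES, merge_salience

#: |r| is clipped here before atanh so degenerate inputs stay finite
R_CLIP = 1.0 - 1e-12


@dataclass
class ParcelTimeseries:
    """Node × time matrix for one functional run."""

    values: np.ndarray  # (n_nodes, n_timepoints)
    nodes: Sequence[str]
    subject: str
    session: int
    condition: str
    run: str | int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodes = list(self.nodes)
        if self.values.ndim != 2:
            raise ValueError("timeseries values must be 2-D (nodes × time)")
        if self.values.shape[0] != len(self.nodes):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.nodes)} node labels"
            )
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time points")

    @property
    def key(self) -> tuple:
        return (self.subject, self.session, self.condition)


@dataclass
class Connectome:
    """Symmetric Fisher-z edge matrix for one observation.

    The diagonal is not a connectivity value and is stored as NaN.
    """

    z: np.ndarray  # (n_nodes, n_nodes), symmetric, NaN diagonal
    nodes: Sequence[str]
    subject: str
    session: int
    condition: str
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.nodes = list(self.nodes)
        n = len(self.nodes)
        if self.z.shape != (n, n):
            raise ValueError(f"z must be {n}×{n} to match node list")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.z[off], self.z.T[off], equal_nan=True):
            raise ValueError("z matrix is not symmetric")
        np.fill_diagonal(self.z, np.nan)

    @property
    def key(self) -> tuple:
        return (self.subject, self.session, self.condition)

    def edge_vector(self, pairs: Sequence[tuple[str, str]] | None = None) -> np.ndarray:
        """Upper-triangle edge values in canonical (i<j by node order) order."""
        idx = {n: k for k, n in enumerate(self.nodes)}
        if pairs is None:
            pairs = edge_pairs(self.nodes)
        return np.array([self.z[idx[a], idx[b]] for a, b in pairs])


def edge_pairs(nodes: Sequence[str]) -> list[tuple[str, str]]:
    """Canonical edge order: all unordered node pairs, upper triangle."""
    return list(combinations(nodes, 2))


def edge_name(a: str, b: str) -> str:
    return f"{a}|{b}"


def concat_condition_runs(runs: Sequence[ParcelTimeseries]) -> ParcelTimeseries:
    """Concatenate the runs of one viewing condition along time.

    All runs must share subject/session/condition and node order; the
    result's run label is "merged".
    """
    if not runs:
        raise ValueError("no runs to concatenate")
    first = runs[0]
    for r in runs[1:]:
        if r.key != first.key:
            raise ValueError(f"run keys differ: {r.key} vs {first.key}")
        if list(r.nodes) != list(first.nodes):
            raise ValueError("runs have different node lists/order")
    values = np.concatenate([r.values for r in runs], axis=1)
    return ParcelTimeseries(
        values=values,
        nodes=first.nodes,
        subject=first.subject,
        session=first.session,
        condition=first.condition,
        run="merged",
    )


def compute_fc(ts: ParcelTimeseries, labels: Mapping[str, str] | None = None) -> Connectome:
    """Pearson correlation between node timeseries, Fisher z-transformed.

    |r| is clipped to 1−1e−12 before atanh; a clip is reported via a
    RuntimeWarning because it signals a degenerate (collinear) node pair.
    """
    sd = ts.values.std(axis=1)
    dead = [ts.nodes[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"constant signal for node(s) {dead}: correlation undefined")
    r = np.corrcoef(ts.values)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) > R_CLIP):
        warnings.warn(
            "correlation magnitude at/near 1 clipped before Fisher transform",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    return Connectome(
        z=z,
        nodes=ts.nodes,
        subject=ts.subject,
        session=ts.session,
        condition=ts.condition,
        labels=dict(labels) if labels else {},
    )


def average_subcortex(
    conn: Connectome,
    subcortical_nodes: Sequence[str] = SUBCORTICAL_NODES,
    name: str = SUBCTX,
) -> Connectome:
    """Collapse the subcortical ROIs into one node by edge-z averaging.

    The merged node's edge to any remaining node is the arithmetic mean of
    that node's edges to the subcortical ROIs; internal subcortical edges
    are dropped.  The merged node is appended at the end of the node order.
    """
    idx = {n: k for k, n in enumerate(conn.nodes)}
    missing = [n for n in subcortical_nodes if n not in idx]
    if missing:
        raise ValueError(f"subcortical node(s) not present: {missing}")
    sub_ix = [idx[n] for n in subcortical_nodes]
    keep = [n for n in conn.nodes if n not in set(subcortical_nodes)]
    keep_ix = [idx[n] for n in keep]

    z_keep = conn.z[np.ix_(keep_ix, keep_ix)]
    z_merged = conn.z[np.ix_(sub_ix, keep_ix)].mean(axis=0)

    m = len(keep)
    z = np.full((m + 1, m + 1), np.nan)
    z[:m, :m] = z_keep
    z[m, :m] = z_merged
    z[:m, m] = z_merged

    labels = {n: conn.labels.get(n, "") for n in keep} if conn.labels else {}
    if labels:
        labels[name] = name
    return Connectome(
        z=z,
        nodes=keep + [name],
        subject=conn.subject,
        session=conn.session,
        condition=conn.condition,
        labels=labels,
    )


def average_subcortex_timeseries(
    ts: ParcelTimeseries,
    subcortical_nodes: Sequence[str] = SUBCORTICAL_NODES,
    name: str = SUBCTX,
) -> ParcelTimeseries:
    """Alternative subcortical collapse: average the raw timeseries of the
    subcortical ROIs into one channel *before* correlation (the default
    pipeline instead averages edge z-values after correlation; the two
    differ slightly because correlation is nonlinear)."""
    idx = {n: k for k, n in enumerate(ts.nodes)}
    missing = [n for n in subcortical_nodes if n not in idx]
    if missing:
        raise ValueError(f"subcortical node(s) not present: {missing}")
    sub_ix = [idx[n] for n in subcortical_nodes]
    keep = [n for n in ts.nodes if n not in set(subcortical_nodes)]
    keep_ix = [idx[n] for n in keep]
    values = np.vstack([ts.values[keep_ix], ts.values[sub_ix].mean(axis=0)])
    return ParcelTimeseries(
        values=values, nodes=keep + [name], subject=ts.subject,
        session=ts.session, condition=ts.condition, run=ts.run,
    )


def write_timeseries_tsv(ts: ParcelTimeseries, path) -> None:
    """Node × time TSV with node_id index (the run-file interchange)."""
    pd.DataFrame(ts.values, index=pd.Index(ts.nodes, name="node_id")).to_csv(
        path, sep="\t", float_format="%.15g"
    )


def read_timeseries_tsv(path, subject: str, session: int, condition: str,
                        run: str | int = 1) -> ParcelTimeseries:
    df = pd.read_csv(path, sep="\t", index_col="node_id")
    return ParcelTimeseries(
        values=df.to_numpy(), nodes=list(df.index), subject=subject,
        session=int(session), condition=condition, run=run,
    )


@dataclass
class EdgeSetPartition:
    """Disjoint map from unordered network pairs to their member edges."""

    cells: "OrderedDict[tuple[str, str], list[tuple[str, str]]]"
    networks: tuple[str, ...]

    def __getitem__(self, cell: tuple[str, str]) -> list[tuple[str, str]]:
        return self.cells[canonical_cell(cell, self.networks)]

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def within(self) -> list[tuple[str, str]]:
        return [c for c in self.cells if c[0] == c[1]]

    @property
    def between(self) -> list[tuple[str, str]]:
        return [c for c in self.cells if c[0] != c[1]]

    def n_edges(self) -> int:
        return sum(len(v) for v in self.cells.values())


def canonical_cell(cell: tuple[str, str], networks: Sequence[str]) -> tuple[str, str]:
    """Order a network pair by network appearance order (cells are unordered)."""
    a, b = cell
    order = {net: k for k, net in enumerate(networks)}
    if a not in order or b not in order:
        raise KeyError(f"unknown network in cell {cell}; known: {list(networks)}")
    return (a, b) if order[a] <= order[b] else (b, a)


def cell_name(cell: tuple[str, str]) -> str:
    return f"{cell[0]}-{cell[1]}"


def parse_cell(name: str, networks: Sequence[str]) -> tuple[str, str]:
    """Inverse of :func:`cell_name`, robust to network names containing '-'."""
    for i in range(1, len(name)):
        if name[i] != "-":
            continue
        a, b = name[:i], name[i + 1 :]
        if a in networks and b in networks:
            return canonical_cell((a, b), networks)
    raise ValueError(f"cannot parse cell name {name!r} with networks {list(networks)}")


def build_edge_sets(labels: Mapping[str, str]) -> EdgeSetPartition:
    """Partition all node pairs into within-/between-network cells.

    The salience parcel is merged into the cingulo-opercular network before
    partitioning.  For the default 9-network parcellation this yields
    9 within + 36 between = 45 cells covering all 378 edges.
    """
    merged = OrderedDict((n, merge_salience(net)) for n, net in labels.items())
    networks: list[str] = []
    for net in merged.values():
        if net not in networks:
            networks.append(net)
    cells: "OrderedDict[tuple[str, str], list[tuple[str, str]]]" = OrderedDict()
    for a, b in combinations(networks, 2):
        cells[(a, b)] = []
    for net in networks:
        cells[(net, net)] = []
    for i, j in edge_pairs(list(merged)):
        cell = canonical_cell((merged[i], merged[j]), networks)
        cells[cell].append((i, j))
    # drop empty between-cells only if a network is missing entirely (cannot
    # happen with a well-formed label table); keep deterministic cell order:
    ordered = OrderedDict()
    for net in networks:
        ordered[(net, net)] = cells[(net, net)]
    for a, b in combinations(networks, 2):
        ordered[(a, b)] = cells[(a, b)]
    return EdgeSetPartition(cells=ordered, networks=tuple(networks))


# ---------------------------------------------------------------------------
# I/O — long CSV (canonical interchange) and square TSV


def connectomes_to_long(conns: Iterable[Connectome]) -> pd.DataFrame:
    rows = []
    for c in conns:
        pairs = edge_pairs(c.nodes)
        z = c.edge_vector(pairs)
        for (a, b), val in zip(pairs, z):
            rows.append((c.subject, c.session, c.condition, a, b, val))
    return pd.DataFrame(
        rows, columns=["subject", "session", "condition", "node_i", "node_j", "z"]
    )


def write_connectomes_long(conns: Iterable[Connectome], path) -> None:
    connectomes_to_long(conns).to_csv(path, index=False, float_format="%.15g")


def read_connectomes_long(path, labels: Mapping[str, str]) -> list[Connectome]:
    """Read long-CSV connectomes; node order is taken from the label table."""
    df = pd.read_csv(path)
    nodes = list(labels)
    idx = {n: k for k, n in enumerate(nodes)}
    out = []
    for (subj, sess, cond), grp in df.groupby(
        ["subject", "session", "condition"], sort=True
    ):
        n = len(nodes)
        z = np.full((n, n), np.nan)
        for a, b, val in zip(grp["node_i"], grp["node_j"], grp["z"]):
            if a not in idx or b not in idx:
                raise ValueError(f"node {a!r} or {b!r} not in label table")
            z[idx[a], idx[b]] = val
            z[idx[b], idx[a]] = val
        out.append(
            Connectome(
                z=z,
                nodes=nodes,
                subject=str(subj),
                session=int(sess),
                condition=str(cond),
                labels=dict(labels),
            )
        )
    return out


def write_connectome_square(conn: Connectome, path) -> None:
    df = pd.DataFrame(conn.z, index=conn.nodes, columns=conn.nodes)
    df.to_csv(path, sep="\t", float_format="%.15g")


def read_connectome_square(path, subject: str, session: int, condition: str,
                           labels: Mapping[str, str] | None = None) -> Connectome:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Connectome(
        z=df.to_numpy(),
        nodes=list(df.columns),
        subject=subject,
        session=session,
        condition=condition,
        labels=dict(labels) if labels else {},
    )
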