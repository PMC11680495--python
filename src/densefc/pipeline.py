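"""End-to-end orchestration: config, validation, and reproducible runs.

A run executes behavior preparation → observation-table assembly →
behavioral association models → edgewise mixed models → cNBS / mv-cNBS
permutation inference → stepwise variance ledgers, either on a synthetic
cohort or on user-supplied tables.  Every output directory carries a
config hash and the seed; rerunning with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import atlas
from .behavior import BehaviorTable, behavior_assoc_suite, prepare_sessions
from .connectome import (
    build_edge_sets,
    cell_name,
    read_connectomes_long,
    write_connectomes_long,
)
from .datasets import CohortParams, generate_behavior, generate_connectomes
from .edge_models import ObservationTable, build_observation_table, fit_all_edges
from .inference import build_null, cnbs_test, default_groupings, mv_cnbs
from .variance import WHOLE_BRAIN, ledgers_to_csv, stepwise_ledger

#: network cells with directional a-priori hypotheses (within-network
#: connectivity of five networks; subcortex to default-mode and to
#: salience/cingulo-opercular)
HYPOTHESIZED_CELLS = (
    "DMN-DMN", "SAL/CO-SAL/CO", "FP-FP", "DAN-DAN", "VIS-VIS",
    "DMN-SUBCTX", "SAL/CO-SUBCTX",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    mode: str = "synthetic"                      # "synthetic" | "data"
    seed: int = 0
    permutations: int = 1000
    valences: tuple[str, ...] = ("positive", "negative")
    exclude_sleep: bool = False
    mv_normalization: str = "mean"               # "mean" | "rms"
    hypothesized_tail: str = "greater"
    tails: Mapping[str, str] = field(default_factory=dict)   # per-cell override
    hypothesized_cells: tuple[str, ...] | None = None
    variance_outcomes: tuple[str, ...] | None = None
    # data mode inputs
    labels_path: str | None = None
    behavior_path: str | None = None
    connectomes_path: str | None = None
    # synthetic mode generator overrides (CohortParams field -> value)
    generator: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "data"):
            raise ValueError("mode must be 'synthetic' or 'data'")
        if self.mode == "data":
            for attr in ("labels_path", "behavior_path", "connectomes_path"):
                if getattr(self, attr) is None:
                    raise ValueError(f"data mode requires {attr}")
        for v in self.valences:
            if v not in ("positive", "negative"):
                raise ValueError(f"unknown valence {v!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["valences"] = list(self.valences)
        if self.hypothesized_cells is not None:
            d["hypothesized_cells"] = list(self.hypothesized_cells)
        if self.variance_outcomes is not None:
            d["variance_outcomes"] = list(self.variance_outcomes)
        d["tails"] = dict(self.tails)
        d["generator"] = dict(self.generator)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        for key in ("valences", "hypothesized_cells", "variance_outcomes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_params(self) -> CohortParams:
        kwargs = dict(self.generator)
        kwargs.setdefault("seed", self.seed)
        return CohortParams(**kwargs)


@dataclass
class ValidationReport:
    violations: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(
    labels: Mapping[str, str],
    behavior: BehaviorTable,
    connectomes: Sequence,
) -> ValidationReport:
    """Structural checks before any model is fit.

    Verifies label coverage and node order, matrix symmetry (with the
    offending coordinates), behavior/connectome key alignment, and that
    every subject has at least two sessions (a permutation-feasibility
    warning otherwise).
    """
    violations: list[str] = []
    warns: list[str] = []
    nodes = list(labels)
    beh_keys = set(
        map(tuple, behavior.conditions[["subject", "session", "condition"]].to_numpy())
    )
    seen = set()
    for conn in connectomes:
        if list(conn.nodes) != nodes:
            violations.append(
                f"{conn.key}: node order does not match label table"
            )
        n = len(conn.nodes)
        off = ~np.eye(n, dtype=bool)
        asym = np.argwhere(off & ~np.isclose(conn.z, conn.z.T, equal_nan=True))
        if len(asym):
            i, j = asym[0]
            violations.append(
                f"{conn.key}: asymmetric z at ({conn.nodes[i]}, {conn.nodes[j]})"
            )
        if conn.key in seen:
            violations.append(f"duplicate connectome for {conn.key}")
        seen.add(conn.key)
        if conn.key not in beh_keys:
            violations.append(f"{conn.key}: no matching behavior row")
    for key in sorted(beh_keys - seen):
        warns.append(f"behavior observation {key} has no connectome")
    sess_counts = behavior.runs.groupby("subject")["session"].nunique()
    for subj, cnt in sess_counts.items():
        if cnt < 2:
            warns.append(
                f"subject {subj} has {cnt} session(s); permutation infeasible"
            )
    return ValidationReport(violations=violations, warnings=warns)


def _resolve_cells(config: RunConfig, partition) -> list[str]:
    if config.hypothesized_cells is not None:
        return list(config.hypothesized_cells)
    names = {cell_name(c) for c in partition}
    chosen = [c for c in HYPOTHESIZED_CELLS if c in names]
    return chosen or [cell_name(c) for c in partition.within]


def run_full(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline into ``outdir``; returns the run log.

    Outputs: input tables (synthetic mode), behavior association CSV, edge
    fit CSVs, cNBS result CSVs (hypothesized + exploratory families),
    mv-cNBS JSON, variance ledger CSV, and a log JSON stamped with the
    config hash and seed.  Stage failures abort with the stage named and
    remove partial outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def _path(name: str) -> Path:
        p = outdir / name
        created.append(p)
        return p

    log: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "setup"
    try:
        stage = "inputs"
        if config.mode == "synthetic":
            params = config.cohort_params()
            labels = dict(params.node_labels)
            behavior = generate_behavior(params)
            connectomes, truth = generate_connectomes(params, behavior)
            atlas.write_labels(labels, _path("labels.tsv"))
            behavior.write_csv(_path("behavior.csv"))
            write_connectomes_long(connectomes, _path("connectomes.csv"))
            truth.to_json(_path("ground_truth.json"))
        else:
            labels = atlas.read_labels(config.labels_path)
            behavior = BehaviorTable.read_csv(config.behavior_path)
            connectomes = read_connectomes_long(config.connectomes_path, labels)

        stage = "validate"
        report = validate_inputs(labels, behavior, connectomes)
        if not report.ok:
            raise ValueError("input validation failed: " + "; ".join(report.violations))
        log["stages"]["validate"] = {"warnings": report.warnings}

        stage = "behavior"
        sessions = prepare_sessions(behavior)
        assoc = behavior_assoc_suite(sessions)
        assoc.to_csv(_path("behavior_assoc.csv"), index=False, float_format="%.15g")

        stage = "observation_table"
        table = build_observation_table(connectomes, behavior, labels)
        table.write_csv(_path("observations.csv"))
        n_flagged = int(table.meta["sleep_flag"].sum())
        used = table.subset(~table.meta["sleep_flag"].to_numpy()) if config.exclude_sleep else table
        log["stages"]["observation_table"] = {
            "n_observations": len(table),
            "n_sleep_flagged": n_flagged,
            "n_observations_used": len(used),
            "n_edges": table.n_edges,
        }

        partition = table.partition
        hyp_cells = _resolve_cells(config, partition)
        mv_payload: dict = {}
        for valence in config.valences:
            tag = "pa" if valence == "positive" else "na"

            stage = f"edge_fits[{valence}]"
            frame, _ = fit_all_edges(
                table, affect=valence, exclude_sleep=config.exclude_sleep
            )
            frame.to_csv(
                _path(f"edge_fits_{tag}.csv"), index=False, float_format="%.15g"
            )
            log["stages"][f"edge_fits_{tag}"] = {
                "n_nonconverged": int((~frame["converged"]).sum())
            }

            stage = f"cnbs[{valence}]"
            null = build_null(
                table,
                affect=valence,
                B=config.permutations,
                seed=config.seed,
                exclude_sleep=config.exclude_sleep,
            )
            tails = {c: config.tails.get(c, config.hypothesized_tail) for c in hyp_cells}
            hyp, _ = cnbs_test(
                table, affect=valence, cells=hyp_cells, tails=tails,
                exclude_sleep=config.exclude_sleep, null=null,
            )
            hyp.to_csv(
                _path(f"cnbs_hypothesized_{tag}.csv"), index=False,
                float_format="%.15g",
            )
            expl, _ = cnbs_test(
                table, affect=valence, cells=None, tails="two_sided",
                exclude_sleep=config.exclude_sleep, null=null,
            )
            expl.to_csv(
                _path(f"cnbs_exploratory_{tag}.csv"), index=False,
                float_format="%.15g",
            )
            log["stages"][f"cnbs_{tag}"] = {
                "permutations": int(null.cell_t.shape[0]),
                "exact_null": bool(null.exact),
                "null_nonconverged_total": int(null.n_nonconverged.sum()),
            }

            stage = f"mv_cnbs[{valence}]"
            observed_cells = dict(zip(expl["cell"], expl["observed_t"]))
            mv = mv_cnbs(
                observed_cells,
                null.cell_t,
                default_groupings(partition),
                normalization=config.mv_normalization,
                exact=null.exact,
            )
            mv_payload[valence] = {
                name: {
                    "observed": eff.observed,
                    "p": eff.p,
                    "ses": eff.ses,
                    "null_mean": eff.null_mean,
                    "null_sd": eff.null_sd,
                    "n_cells": eff.n_cells,
                }
                for name, eff in mv.items()
            }

            stage = f"variance[{valence}]"
            outcomes = (
                list(config.variance_outcomes)
                if config.variance_outcomes is not None
                else [WHOLE_BRAIN] + hyp_cells
            )
            ledgers = [
                stepwise_ledger(
                    table, outcome=o, affect=valence,
                    exclude_sleep=config.exclude_sleep,
                )
                for o in outcomes
            ]
            ledgers_to_csv(ledgers, _path(f"variance_ledgers_{tag}.csv"))

        with open(_path("mv_cnbs.json"), "w") as fh:
            json.dump(mv_payload, fh, indent=1, sort_keys=True)

        stage = "log"
        with open(_path("run_log.json"), "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        config.to_yaml(_path("config.yaml"))
        return log
    except Exception as exc:
        for p in created:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
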