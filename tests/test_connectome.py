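"""Connectome construction: Fisher-z FC, subcortical averaging, edge sets."""

import numpy as np
import pandas as pd
import pytest

from densefc.atlas import analysis_labels, full_labels, toy_labels, read_labels, write_labels
from densefc.connectome import (
    Connectome,
    ParcelTimeseries,
    average_subcortex,
    build_edge_sets,
    compute_fc,
    concat_condition_runs,
    edge_pairs,
    read_connectomes_long,
    write_connectomes_long,
)
from densefc.datasets import CohortParams, generate_timeseries


def _ts(values, nodes=None, **kw):
    values = np.asarray(values, dtype=float)
    nodes = nodes or [f"n{i}" for i in range(values.shape[0])]
    defaults = dict(subject="s1", session=1, condition="lowdemand", run=1)
    defaults.update(kw)
    return ParcelTimeseries(values=values, nodes=nodes, **defaults)


class TestConcatRuns:
    def test_concatenates_time_dimension(self, rng):
        a = _ts(rng.normal(size=(4, 200)), run=1)
        b = _ts(rng.normal(size=(4, 200)), run=2)
        merged = concat_condition_runs([a, b])
        assert merged.values.shape == (4, 400)
        assert merged.run == "merged"
        np.testing.assert_array_equal(merged.values[:, :200], a.values)

    def test_single_run_is_identity(self, rng):
        a = _ts(rng.normal(size=(3, 50)))
        np.testing.assert_array_equal(concat_condition_runs([a]).values, a.values)

    def test_mismatched_inputs_rejected(self, rng):
        a = _ts(rng.normal(size=(3, 50)))
        with pytest.raises(ValueError, match="node"):
            concat_condition_runs([a, _ts(rng.normal(size=(4, 50)))])
        with pytest.raises(ValueError, match="keys"):
            concat_condition_runs([a, _ts(rng.normal(size=(3, 50)), session=2)])


class TestComputeFC:
    def test_closed_form_fisher_z(self, rng):
        # construct two channels with exact sample correlation 0.5
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        x = np.sin(t)
        y = 0.5 * x + np.sqrt(0.75) * np.cos(t)  # orthogonal basis => r = 0.5
        conn = compute_fc(_ts(np.vstack([x, y])))
        assert conn.z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-10)
        assert conn.z[0, 1] == pytest.approx(0.549306, abs=1e-6)

    def test_zero_correlation_maps_to_zero(self):
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        conn = compute_fc(_ts(np.vstack([np.sin(t), np.cos(t)])))
        assert conn.z[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_node_clipped_with_warning(self, rng):
        x = rng.normal(size=100)
        with pytest.warns(RuntimeWarning, match="clipped"):
            conn = compute_fc(_ts(np.vstack([x, x])))
        assert np.isfinite(conn.z[0, 1])
        assert conn.z[0, 1] > 10  # atanh near 1 is large but finite

    def test_constant_node_rejected(self, rng):
        vals = rng.normal(size=(3, 50))
        vals[1] = 2.5
        with pytest.raises(ValueError, match="n1"):
            compute_fc(_ts(vals))

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.normal(size=(5, 300))
        base = compute_fc(_ts(vals))
        scaled = vals.copy()
        scaled[2] = 7.0 - 3.2 * scaled[2]
        rescaled = compute_fc(_ts(scaled))
        off = ~np.eye(5, dtype=bool)
        mask = np.ones((5, 5), dtype=bool)
        mask[2, :] = mask[:, 2] = False
        np.testing.assert_allclose(
            rescaled.z[off & mask], base.z[off & mask], atol=1e-12
        )
        # row/col 2 flips sign only
        np.testing.assert_allclose(rescaled.z[2, [0, 1, 3, 4]],
                                   -base.z[2, [0, 1, 3, 4]], atol=1e-12)


class TestAverageSubcortex:
    def _conn(self, zvals):
        nodes = ["c1", "c2", "AMY_L", "AMY_R", "NAC_L", "NAC_R"]
        z = np.full((6, 6), np.nan)
        iu = np.triu_indices(6, 1)
        z[iu] = zvals
        z.T[iu] = zvals
        return Connectome(z=z, nodes=nodes, subject="s", session=1, condition="movie")

    def test_mean_of_four_edges(self):
        z = np.zeros(15)
        # edges c1-AMY_L, c1-AMY_R, c1-NAC_L, c1-NAC_R are positions 1..4
        z[1:5] = [0.1, 0.2, 0.3, 0.4]
        merged = average_subcortex(self._conn(z))
        assert merged.nodes == ["c1", "c2", "SUBCTX"]
        i, j = merged.nodes.index("c1"), merged.nodes.index("SUBCTX")
        assert merged.z[i, j] == pytest.approx(0.25)

    def test_equal_edges_preserved(self):
        z = np.full(15, 0.3)
        merged = average_subcortex(self._conn(z))
        assert merged.z[0, 2] == pytest.approx(0.3)

    def test_missing_node_rejected(self):
        conn = self._conn(np.zeros(15))
        with pytest.raises(ValueError, match="missing|not present"):
            average_subcortex(conn, subcortical_nodes=["AMY_L", "nope"])

    def test_timeseries_averaging_variant(self, rng):
        """Averaging subcortical channels before correlation gives a single
        SUBCTX node; it differs (slightly) from edge-level averaging since
        correlation is nonlinear."""
        from densefc.connectome import average_subcortex_timeseries

        nodes = ["c1", "c2", "AMY_L", "AMY_R", "NAC_L", "NAC_R"]
        ts = _ts(rng.normal(size=(6, 500)), nodes=nodes)
        merged_ts = average_subcortex_timeseries(ts)
        assert merged_ts.nodes == ["c1", "c2", "SUBCTX"]
        np.testing.assert_allclose(
            merged_ts.values[2], ts.values[2:].mean(axis=0)
        )
        conn = compute_fc(merged_ts)
        assert np.isfinite(conn.z[0, 2])

    def test_default_atlas_node_count(self, rng):
        labels = full_labels()
        n = len(labels)
        assert n == 31
        vals = rng.normal(size=(n, 600))
        conn = compute_fc(_ts(vals, nodes=list(labels)), labels)
        merged = average_subcortex(conn)
        assert len(merged.nodes) == 28


class TestEdgeSets:
    def test_default_partition_counts(self):
        part = build_edge_sets(analysis_labels())
        assert len(part) == 45
        assert len(part.within) == 9
        assert len(part.between) == 36
        assert part.n_edges() == 378  # C(28, 2)

    def test_within_cell_sizes(self):
        part = build_edge_sets(analysis_labels())
        assert len(part[("DMN", "DMN")]) == 15  # C(6,2)
        assert len(part[("DMN", "SUBCTX")]) == 6  # 6 x 1
        # salience parcel merged with cingulo-opercular: 6 nodes
        assert len(part[("SAL/CO", "SAL/CO")]) == 15

    def test_partition_is_disjoint_and_complete(self):
        labels = toy_labels(3, 3)
        part = build_edge_sets(labels)
        seen = [e for cell in part for e in part[cell]]
        assert len(seen) == len(set(seen)) == len(edge_pairs(list(labels)))

    def test_unknown_network_rejected(self):
        part = build_edge_sets(toy_labels())
        with pytest.raises(KeyError):
            part[("NET1", "BOGUS")]


class TestIO:
    def test_long_csv_roundtrip(self, tmp_path, toy_dataset, toy_params):
        conns, _ = toy_dataset
        path = tmp_path / "conn.csv"
        write_connectomes_long(conns[:5], path)
        back = read_connectomes_long(path, toy_params.node_labels)
        assert len(back) == 5
        orig = {c.key: c for c in conns[:5]}
        for c in back:
            np.testing.assert_allclose(c.z, orig[c.key].z, atol=1e-14, equal_nan=True)

    def test_labels_roundtrip(self, tmp_path):
        path = tmp_path / "labels.tsv"
        labels = analysis_labels()
        write_labels(labels, path)
        assert read_labels(path) == dict(labels)


class TestFisherRoundTrip:
    def test_timeseries_recover_target_z(self):
        """Simulated timeseries reproduce the target Fisher z within the
        sampling SD 1/sqrt(T-3)."""
        labels = toy_labels(2, 2)
        nodes = list(labels)
        z = np.full((4, 4), 0.0)
        z[0, 1] = z[1, 0] = np.arctanh(0.5)
        np.fill_diagonal(z, np.nan)
        target = Connectome(z=z, nodes=nodes, subject="s1", session=1,
                            condition="lowdemand")
        T = 10_000
        params = CohortParams(n_subjects=2, n_sessions=2, node_labels=labels,
                              n_volumes=T, n_runs_per_condition=1, seed=5)
        (run,) = generate_timeseries(params, target)
        got = compute_fc(run)
        assert got.z[0, 1] == pytest.approx(np.arctanh(0.5), abs=3 / np.sqrt(T - 3))

    def test_non_positive_definite_target_rejected(self):
        labels = toy_labels(2, 2)
        nodes = list(labels)
        z = np.arctanh(0.9) * np.ones((4, 4))
        z[0, 1] = z[1, 0] = np.arctanh(-0.9)  # inconsistent triangle
        np.fill_diagonal(z, np.nan)
        target = Connectome(z=z, nodes=nodes, subject="s9", session=2,
                            condition="movie")
        params = CohortParams(n_subjects=2, n_sessions=2, node_labels=labels, seed=0)
        with pytest.raises(ValueError, match="s9.*session=2.*movie"):
            generate_timeseries(params, target)
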