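"""Node → network label tables.

The analysis parcellation has 27 high-consensus cortical ROIs from nine
functional networks (default mode 6, salience 1, cingulo-opercular 5,
frontoparietal 5, dorsal attention 2, parietal-occipital 2, visual 2,
auditory 2, sensorimotor 2) plus 4 subcortical affective ROIs (bilateral
amygdala and nucleus accumbens).  The single salience parcel is grouped
with the cingulo-opercular network ("SAL/CO") and the four subcortical
ROIs are averaged into one "SUBCTX" node before network-level analysis,
leaving 28 analysis nodes in 9 networks and C(28,2)=378 edges in 45
within/between-network cells.
"""

from __future__ import annotations

from collections import OrderedDict

import pandas as pd

# Network short names used throughout (post salience/CO merge).
NETWORKS = ("DMN", "SAL/CO", "FP", "DAN", "PON", "VIS", "AUD", "SM", "SUBCTX")

#: cortical networks and ROI counts as parcellated (pre-merge)
_CORTICAL = OrderedDict(
    [
        ("DMN", 6),
        ("SAL", 1),
        ("CO", 5),
        ("FP", 5),
        ("DAN", 2),
        ("PON", 2),
        ("VIS", 2),
        ("AUD", 2),
        ("SM", 2),
    ]
)

#: subcortical affective ROIs (bilateral amygdala + nucleus accumbens)
SUBCORTICAL_NODES = ("AMY_L", "AMY_R", "NAC_L", "NAC_R")

SUBCTX = "SUBCTX"


def merge_salience(network: str) -> str:
    """Map raw network names onto analysis networks (SAL and CO -> SAL/CO)."""
    return "SAL/CO" if network in ("SAL", "CO") else network


def full_labels() -> "OrderedDict[str, str]":
    """31-node label map as parcellated: 27 cortical ROIs + 4 subcortical ROIs.

    Cortical networks keep their raw names (SAL separate from CO); the
    subcortical ROIs are labelled SUBCTX.  This is the label set for data
    entering :func:`densefc.connectome.average_subcortex`.
    """
    labels: "OrderedDict[str, str]" = OrderedDict()
    for net, n in _CORTICAL.items():
        for k in range(1, n + 1):
            labels[f"{net}_{k}"] = net
    for node in SUBCORTICAL_NODES:
        labels[node] = SUBCTX
    return labels


def analysis_labels() -> "OrderedDict[str, str]":
    """28-node label map after subcortical averaging and salience merge."""
    labels: "OrderedDict[str, str]" = OrderedDict()
    for net, n in _CORTICAL.items():
        for k in range(1, n + 1):
            labels[f"{net}_{k}"] = merge_salience(net)
    labels[SUBCTX] = SUBCTX
    return labels


def toy_labels(nodes_per_network: int = 3, n_networks: int = 3) -> "OrderedDict[str, str]":
    """Small label map for simulations and tests (default 9 nodes, 3 networks)."""
    labels: "OrderedDict[str, str]" = OrderedDict()
    for j in range(n_networks):
        net = f"NET{j + 1}"
        for k in range(1, nodes_per_network + 1):
            labels[f"{net}_{k}"] = net
    return labels


def labels_to_frame(labels: "OrderedDict[str, str] | dict[str, str]") -> pd.DataFrame:
    """Label map -> TSV-ready frame with columns node_id, node_name, network."""
    return pd.DataFrame(
        {
            "node_id": list(labels),
            "node_name": list(labels),
            "network": [labels[n] for n in labels],
        }
    )


def read_labels(path) -> "OrderedDict[str, str]":
    """Read a node→network label table from TSV (columns node_id, network).

    Node order in the file is canonical: every matrix produced downstream
    follows it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"node_id", "network"} - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    if df["node_id"].duplicated().any():
        dup = df.loc[df["node_id"].duplicated(), "node_id"].tolist()
        raise ValueError(f"duplicate node_id in label table: {dup}")
    return OrderedDict(zip(df["node_id"], df["network"]))


def write_labels(labels, path) -> None:
    labels_to_frame(labels).to_csv(path, sep="\t", index=False)
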