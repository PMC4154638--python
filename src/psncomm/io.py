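"""Writers for the tabular and graph artifacts of a pipeline run.

Matrices go out as residue-labelled CSV and as plain-text square matrices
(xPyder-compatible whitespace-separated ``.dat``); networks as GML and DOT;
paths and reports as JSON.  All writers are deterministic: identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np
import pandas as pd


def write_matrix_csv(matrix: np.ndarray, labels, path) -> None:
    """Square residue x residue matrix as a labelled CSV."""
    df = pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels))
    df.to_csv(path, float_format="%.6g")


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_square_dat(matrix: np.ndarray, path) -> None:
    """Plain-text square matrix, one row per line (xPyder-compatible)."""
    np.savetxt(path, np.asarray(matrix), fmt="%.6f")


def write_graph(graph: nx.Graph, path_gml=None, path_dot=None) -> None:
    """Write a weighted graph as GML and/or DOT."""
    if path_gml is not None:
        nx.write_gml(graph, str(path_gml))
    if path_dot is not None:
        _write_dot(graph, path_dot)


def _write_dot(graph: nx.Graph, path) -> None:
    # minimal DOT writer: node ids and float attributes only
    lines = ["graph G {"]
    for n in sorted(graph.nodes):
        lines.append(f'    "{n}";')
    for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        attrs = ", ".join(f"{k}={data[k]:.6g}" for k in sorted(data) if isinstance(data[k], (int, float)))
        attr_str = f" [{attrs}]" if attrs else ""
        lines.append(f'    "{u}" -- "{v}"{attr_str};')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_scan_csv(profile, path) -> None:
    df = pd.DataFrame(
        {"i_min": profile.i_min_values, "largest_cluster_size": profile.sizes}
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_paths_json(path_set, path, labels=None) -> None:
    payload = {
        "paths": [p.to_dict(labels) for p in path_set.paths],
        "direct_edges": [p.to_dict(labels) for p in path_set.direct_edges],
        "rejected": path_set.rejected,
    }
    write_json(payload, path)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
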