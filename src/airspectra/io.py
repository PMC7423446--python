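"""Tree file formats: the branch-table CSV dialect and GraphML export.

The tree CSV has one row per branch with header columns
``branch_id, prox_node, dist_node, radius_mm, length_mm`` and optional
``resistance`` (cmH2O s/l, overrides Poiseuille computation) and ``x, y, z``
(coordinates of the distal node, mm).  The root node is identified as the
unique ``prox_node`` that never appears as a ``dist_node``.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tree import AirwayTree, TreeValidationError, build_tree, poiseuille_resistances

__all__ = ["read_tree_csv", "write_tree_csv", "write_graphml"]

_REQUIRED = ["branch_id", "prox_node", "dist_node", "radius_mm", "length_mm"]


def read_tree_csv(path, compute_resistance: bool = True) -> AirwayTree:
    """Parse, validate and canonically order a tree from the CSV dialect.

    When no ``resistance`` column is present (and ``compute_resistance``),
    Poiseuille resistances are computed from the geometry.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TreeValidationError(f"{path}: malformed header, missing {missing}")
    dup = df["branch_id"][df["branch_id"].duplicated()]
    if not dup.empty:
        rows = (dup.index + 2).tolist()  # 1-based with header
        raise TreeValidationError(f"{path}: duplicate branch ids at rows {rows}")

    edges = list(zip(df["prox_node"], df["dist_node"]))
    resistance = None
    if "resistance" in df.columns and df["resistance"].notna().all():
        resistance = df["resistance"].to_numpy(dtype=float)
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = {
            d: (row.x, row.y, row.z)
            for d, row in zip(df["dist_node"], df.itertuples())
            if pd.notna(row.x)
        }
    try:
        tree = build_tree(
            edges,
            df["radius_mm"].to_numpy(dtype=float),
            df["length_mm"].to_numpy(dtype=float),
            resistance=resistance,
            coords=coords,
        )
    except TreeValidationError as err:
        raise type(err)(f"{path}: {err} (see rows 2..{len(df) + 1})") from err
    if tree.resistance is None and compute_resistance:
        poiseuille_resistances(tree)
    return tree


def write_tree_csv(tree: AirwayTree, path) -> None:
    """Write a tree in the branch-table dialect (canonical branch order)."""
    labels = tree.node_labels or list(range(tree.n_nodes))
    rows = {
        "branch_id": np.arange(1, tree.n_branches + 1),
        "prox_node": [labels[p] for p in tree.prox],
        "dist_node": [labels[j + 1] for j in range(tree.n_branches)],
        "radius_mm": tree.radius,
        "length_mm": tree.length,
    }
    if tree.resistance is not None:
        rows["resistance"] = tree.resistance
    if tree.coords is not None:
        dist_xyz = tree.coords[1:]
        rows["x"], rows["y"], rows["z"] = dist_xyz.T
    # %.17g guarantees bit-exact float round-tripping
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_graphml(tree: AirwayTree, path) -> None:
    """Export the same content as GraphML for interoperability."""
    g = nx.DiGraph()
    labels = tree.node_labels or list(range(tree.n_nodes))
    first_term = tree.n_nodes - tree.n_terminal
    for i, lbl in enumerate(labels):
        attrs = {"kind": "root" if i == 0 else
                 ("terminal" if i >= first_term else "internal")}
        if tree.coords is not None and np.isfinite(tree.coords[i]).all():
            attrs.update(x=float(tree.coords[i][0]), y=float(tree.coords[i][1]),
                         z=float(tree.coords[i][2]))
        g.add_node(str(lbl), **attrs)
    for j in range(tree.n_branches):
        attrs = {
            "branch_id": j + 1,
            "radius_mm": float(tree.radius[j]),
            "length_mm": float(tree.length[j]),
        }
        if tree.resistance is not None:
            attrs["resistance"] = float(tree.resistance[j])
        g.add_edge(str(labels[tree.prox[j]]), str(labels[j + 1]), **attrs)
    nx.write_graphml(g, Path(path))
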