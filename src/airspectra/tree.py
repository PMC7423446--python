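"""Rooted airway-tree data structure and index conventions.

An airway network is a rooted oriented tree: nodes are branch points, edges
("branches") are airways pointing from their proximal to their distal node.
The canonical node ordering is root first, then internal nodes, then terminal
nodes last; branches are indexed so that branch ``j`` has distal node
``j + 1``.  All operators in the package (incidence matrix, conductance
Laplacian, Maury operator) are built from this single object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .config import DEFAULT_CONFIG, PA_S_MM3_TO_CMH2O_S_L, RunConfig

__all__ = [
    "AirwayTree",
    "BlockPartition",
    "TreeValidationError",
    "CycleError",
    "DisconnectedTreeError",
    "MultipleRootsError",
    "GeometryError",
    "build_tree",
    "incidence_matrix",
    "poiseuille_resistances",
    "subtree_terminal_sets",
]


class TreeValidationError(ValueError):
    """Base class for invalid tree inputs."""


class CycleError(TreeValidationError):
    """The edge list contains a cycle (or a node with two parents)."""


class DisconnectedTreeError(TreeValidationError):
    """The edge list does not form a single connected component."""


class MultipleRootsError(TreeValidationError):
    """More than one node has no proximal branch."""


class GeometryError(TreeValidationError):
    """Nonpositive radius, length or resistance."""


@dataclass(frozen=True)
class BlockPartition:
    """Index bookkeeping separating root / internal / terminal blocks.

    Node blocks are always disjoint and exhaustive.  Terminal branches are
    exactly those whose distal node is terminal; on a degenerate tree whose
    root feeds a terminal node directly, the root branch is also terminal.
    """

    root_node_index: int
    internal_node_indices: np.ndarray
    terminal_node_indices: np.ndarray
    root_branch_index: int
    internal_branch_indices: np.ndarray
    terminal_branch_indices: np.ndarray


@dataclass(eq=False)
class AirwayTree:
    """Rooted oriented tree with per-branch geometry and resistance.

    Parameters
    ----------
    prox
        ``(E,)`` integer array; branch ``j`` points from node ``prox[j]`` to
        its distal node ``j + 1`` (canonical branch indexing).
    radius, length
        ``(E,)`` arrays, mm.
    resistance
        ``(E,)`` array, cmH2O s l^-1, or None if not yet assigned.
    n_terminal
        Number of terminal (leaf) nodes; they occupy the last ``n_terminal``
        node indices.
    coords
        Optional ``(V, 3)`` array of node coordinates, mm.
    node_labels
        Original input labels in canonical node order.
    meta
        Free-form provenance (generator parameters, seeds, constants used).
    """

    prox: np.ndarray
    radius: np.ndarray
    length: np.ndarray
    n_terminal: int
    resistance: np.ndarray | None = None
    coords: np.ndarray | None = None
    node_labels: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ sizes
    @property
    def n_branches(self) -> int:
        return len(self.prox)

    @property
    def n_nodes(self) -> int:
        return len(self.prox) + 1

    @property
    def n_internal(self) -> int:
        return self.n_nodes - self.n_terminal - 1

    # ------------------------------------------------------------- structure
    @property
    def terminal_node_indices(self) -> np.ndarray:
        return np.arange(self.n_nodes - self.n_terminal, self.n_nodes)

    @property
    def internal_node_indices(self) -> np.ndarray:
        return np.arange(1, self.n_nodes - self.n_terminal)

    @property
    def terminal_branch_indices(self) -> np.ndarray:
        return self.terminal_node_indices - 1

    def distal(self, j: int) -> int:
        return j + 1

    def children_nodes(self) -> list[list[int]]:
        """Per-node lists of child node indices, in branch order."""
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for j, p in enumerate(self.prox):
            out[p].append(j + 1)
        return out

    def children_branches(self) -> list[list[int]]:
        """Per-branch lists of child branch indices."""
        out: list[list[int]] = [[] for _ in range(self.n_branches)]
        for j, p in enumerate(self.prox):
            if p > 0:
                out[p - 1].append(j)
        return out

    def parent_branch(self, j: int) -> int | None:
        """Index of the branch feeding branch ``j``'s proximal node."""
        p = self.prox[j]
        return None if p == 0 else p - 1

    def partition(self) -> BlockPartition:
        return BlockPartition(
            root_node_index=0,
            internal_node_indices=self.internal_node_indices,
            terminal_node_indices=self.terminal_node_indices,
            root_branch_index=0,
            internal_branch_indices=np.arange(1, self.n_internal),
            terminal_branch_indices=self.terminal_branch_indices,
        )

    def is_terminal_branch(self) -> np.ndarray:
        mask = np.zeros(self.n_branches, dtype=bool)
        mask[self.terminal_branch_indices] = True
        return mask

    def horsfield_orders(self) -> np.ndarray:
        """Per-branch Horsfield order: terminals are 1, parents 1 + max(children)."""
        orders = np.ones(self.n_branches, dtype=int)
        kids = self.children_branches()
        for j in range(self.n_branches - 1, -1, -1):
            if kids[j]:
                orders[j] = 1 + max(orders[c] for c in kids[j])
        return orders

    def branch_generations(self) -> np.ndarray:
        """Weibel generation per branch (root branch is generation 0)."""
        gen = np.zeros(self.n_branches, dtype=int)
        for j in range(self.n_branches):
            p = self.prox[j]
            gen[j] = 0 if p == 0 else gen[p - 1] + 1
        return gen

    def path_to_root(self, j: int) -> list[int]:
        """Branch indices on the path from branch ``j`` up to the root branch."""
        path = [j]
        while self.prox[path[-1]] != 0:
            path.append(self.prox[path[-1]] - 1)
        return path

    def copy(self) -> "AirwayTree":
        return replace(
            self,
            prox=self.prox.copy(),
            radius=self.radius.copy(),
            length=self.length.copy(),
            resistance=None if self.resistance is None else self.resistance.copy(),
            coords=None if self.coords is None else self.coords.copy(),
            node_labels=list(self.node_labels),
            meta=dict(self.meta),
        )

    def require_resistance(self) -> np.ndarray:
        if self.resistance is None:
            raise GeometryError(
                "tree has no resistances; call poiseuille_resistances() first"
            )
        return self.resistance


# --------------------------------------------------------------------------
def build_tree(
    edge_list: Sequence[tuple[Hashable, Hashable]],
    radius: Sequence[float],
    length: Sequence[float],
    resistance: Sequence[float] | None = None,
    coords: Mapping[Hashable, Sequence[float]] | None = None,
) -> AirwayTree:
    """Validate an edge list and return a canonically ordered :class:`AirwayTree`.

    Edges are ``(proximal_label, distal_label)`` pairs with arbitrary hashable
    labels; ``radius``/``length``/``resistance`` align with the edge list.
    Nodes are reordered root / internal / terminal (BFS from the root,
    siblings in input order) and branches reindexed so branch ``j`` has
    distal node ``j + 1``.  The original labels are retained on the tree.
    """
    edges = list(edge_list)
    n_edges = len(edges)
    if n_edges == 0:
        raise TreeValidationError("empty edge list")
    radius = np.asarray(radius, dtype=float)
    length = np.asarray(length, dtype=float)
    if len(radius) != n_edges or len(length) != n_edges:
        raise TreeValidationError("radius/length must align with the edge list")
    if resistance is not None:
        resistance = np.asarray(resistance, dtype=float)
        if len(resistance) != n_edges:
            raise TreeValidationError("resistance must align with the edge list")
        if np.any(resistance <= 0):
            raise GeometryError("nonpositive resistance")
    if np.any(radius <= 0) or np.any(length <= 0):
        raise GeometryError("nonpositive radius or length")

    nodes: list[Hashable] = []
    seen: set = set()
    for u, v in edges:
        for x in (u, v):
            if x not in seen:
                seen.add(x)
                nodes.append(x)
    n_nodes = len(nodes)
    parent_of: dict = {}
    for k, (u, v) in enumerate(edges):
        if v in parent_of:
            raise CycleError(f"node {v!r} has more than one proximal branch")
        parent_of[v] = (u, k)
    roots = [x for x in nodes if x not in parent_of]
    if len(roots) == 0:
        raise CycleError("no root node: every node has a proximal branch")
    if len(roots) > 1:
        raise MultipleRootsError(f"multiple root nodes: {roots!r}")
    root = roots[0]
    if n_edges != n_nodes - 1:
        # unique parents + single root + wrong count -> a cycle somewhere
        raise CycleError(
            f"{n_edges} edges on {n_nodes} nodes cannot form a tree"
        )

    children: dict = {x: [] for x in nodes}
    for u, v in edges:
        children[u].append(v)

    # BFS from root, siblings in input order
    bfs: list = [root]
    head = 0
    while head < len(bfs):
        bfs.extend(children[bfs[head]])
        head += 1
    if len(bfs) != n_nodes:
        raise DisconnectedTreeError(
            f"{n_nodes - len(bfs)} node(s) unreachable from root {root!r}"
        )

    internal = [x for x in bfs[1:] if children[x]]
    terminal = [x for x in bfs[1:] if not children[x]]
    order = [root] + internal + terminal
    index_of = {x: i for i, x in enumerate(order)}

    prox = np.empty(n_edges, dtype=np.int64)
    rad = np.empty(n_edges)
    len_ = np.empty(n_edges)
    res = np.empty(n_edges) if resistance is not None else None
    for v, (u, k) in parent_of.items():
        j = index_of[v] - 1  # canonical branch index
        prox[j] = index_of[u]
        rad[j] = radius[k]
        len_[j] = length[k]
        if res is not None:
            res[j] = resistance[k]

    xyz = None
    if coords is not None:
        xyz = np.full((n_nodes, 3), np.nan)
        for lbl, c in coords.items():
            if lbl in index_of:
                xyz[index_of[lbl]] = np.asarray(c, dtype=float)

    return AirwayTree(
        prox=prox,
        radius=rad,
        length=len_,
        n_terminal=len(terminal),
        resistance=res,
        coords=xyz,
        node_labels=order,
    )


def incidence_matrix(tree: AirwayTree) -> sp.csr_matrix:
    """Node-branch incidence matrix ``N`` (|V| x |E|).

    Column ``j`` has +1 at the proximal node of branch ``j`` and -1 at its
    distal node, so every column sums to zero and the all-ones vector lies in
    the left null space.
    """
    e = tree.n_branches
    rows = np.concatenate([tree.prox, np.arange(1, e + 1)])
    cols = np.concatenate([np.arange(e), np.arange(e)])
    data = np.concatenate([np.ones(e), -np.ones(e)])
    return sp.csr_matrix((data, (rows, cols)), shape=(tree.n_nodes, e))


def poiseuille_resistances(
    tree: AirwayTree,
    viscosity: float | None = None,
    prefactor: float | None = None,
    config: RunConfig | None = None,
) -> AirwayTree:
    """Assign Poiseuille resistances ``r_j = prefactor * mu * l_j / a_j**4``.

    ``viscosity`` is the dynamic viscosity of air in Pa s; the result is
    converted to cmH2O s l^-1.  The tree is modified in place (and returned);
    the constants used are recorded in ``tree.meta``.
    """
    cfg = config or DEFAULT_CONFIG
    mu = cfg.air_viscosity_pa_s if viscosity is None else viscosity
    pre = cfg.poiseuille_prefactor if prefactor is None else prefactor
    if mu <= 0:
        raise GeometryError("viscosity must be positive")
    if np.any(tree.radius <= 0):
        raise GeometryError("zero or negative radius")
    r_pa_s_mm3 = pre * mu * tree.length / tree.radius**4
    tree.resistance = r_pa_s_mm3 * PA_S_MM3_TO_CMH2O_S_L
    tree.meta["poiseuille"] = {"viscosity_pa_s": mu, "prefactor": pre}
    return tree


def subtree_terminal_sets(tree: AirwayTree) -> list[frozenset[int]]:
    """For each branch, the set of terminal node indices in its distal subtree.

    The root branch maps to all terminals; a terminal branch maps to the
    singleton of its own distal node.  Every branch's set is the disjoint
    union of its children's sets.
    """
    sets: list[set[int]] = [set() for _ in range(tree.n_branches)]
    first_term = tree.n_nodes - tree.n_terminal
    for j in range(tree.n_branches - 1, -1, -1):
        d = j + 1
        if d >= first_term:
            sets[j].add(d)
        if tree.prox[j] > 0:
            sets[tree.prox[j] - 1] |= sets[j]
    return [frozenset(s) for s in sets]
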