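"""Built-in deterministic test trees and the demonstration morphometry table.

These fixtures exist so that every operator in the package can be exercised
without external data: the smallest bifurcating tree, a two-level
bifurcating 8-node tree, a trifurcating tree, a grid of asymmetric Weibel
trees and a small Horsfield-recursion tree.

The demonstration Horsfield table is a synthetic stand-in with plausible
airway dimensions and Fibonacci-like branching (orders ``g - 1, g - 2``); it
is NOT measured human morphometry.
"""

from __future__ import annotations

from .generators import (
    HorsfieldOrderSpec,
    HorsfieldTable,
    WeibelParams,
    horsfield_tree,
    weibel_tree,
)
from .tree import AirwayTree, build_tree, poiseuille_resistances

__all__ = ["fixture_trees", "demo_horsfield_table", "y_tree", "two_level_tree"]


def y_tree(resistance=(1.0, 2.0, 3.0)) -> AirwayTree:
    """Smallest bifurcating tree: root - junction - two terminals."""
    tree = build_tree(
        [(1, 2), (2, 3), (2, 4)],
        radius=[2.0, 1.5, 1.5],
        length=[12.0, 9.0, 9.0],
        resistance=resistance,
    )
    return tree


def two_level_tree(resistance=None) -> AirwayTree:
    """8-node, 7-branch two-level bifurcating tree (3 internal, 4 terminal nodes)."""
    edges = [(1, 2), (2, 3), (2, 4), (3, 5), (3, 6), (4, 7), (4, 8)]
    radius = [2.0, 1.6, 1.6, 1.2, 1.2, 1.2, 1.2]
    length = [r * 6 for r in radius]
    tree = build_tree(edges, radius, length, resistance=resistance)
    if resistance is None:
        poiseuille_resistances(tree)
    return tree


def demo_horsfield_table(n_orders: int = 10) -> HorsfieldTable:
    """Synthetic demonstration table: orders 1..n, children (g-1, g-2).

    Radii grow geometrically with order; lengths are three diameters.
    """
    orders = {}
    for g in range(1, n_orders + 1):
        radius = 0.3 * 1.35 ** (g - 1)
        kids = (g - 1, g - 2) if g > 1 else ()
        orders[g] = HorsfieldOrderSpec(
            child_orders=kids, mean_radius=radius, mean_length=6.0 * radius
        )
    return HorsfieldTable(orders)


def fixture_trees() -> dict[str, AirwayTree]:
    """Named deterministic test trees covering the package's tree shapes."""
    trees: dict[str, AirwayTree] = {
        "y_tree": y_tree(),
        "two_level": two_level_tree(),
        "trifurcating": poiseuille_resistances(build_tree(
            [(1, 2), (2, 3), (2, 4), (2, 5)],
            radius=[2.0, 1.2, 1.2, 1.2],
            length=[12.0, 7.2, 7.2, 7.2],
        )),
        "horsfield_demo": horsfield_tree(
            demo_horsfield_table(), root_order=10, termination_order=1,
            noise_fraction=0.0, seed=0,
        ),
    }
    for n in (1, 5, 9):
        for a in (0.0, 0.5, 0.98):
            trees[f"weibel_N{n}_A{a:g}"] = weibel_tree(
                WeibelParams(n_divisions=n, asymmetry=a)
            )
    return trees
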