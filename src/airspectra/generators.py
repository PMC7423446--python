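"""Model airway-tree generators and perturbations.

Implements the idealized geometries used throughout the package:

* **Asymmetric Weibel trees** — dyadic trees in which each parent branches
  into a major and a minor child with radius/length scale factors
  ``(1 + A/2)**(1/3)`` and ``(1 - A/2)**(1/3)``.  The cube root makes the two
  daughters' combined Poiseuille resistance and volume independent of the
  asymmetry parameter ``A``.
* **Horsfield-order recursion trees** — table-driven recursive branching in
  which a parent of order ``g`` spawns daughters of lower orders, terminating
  at a user-chosen order; branch dimensions are Gaussian perturbations of the
  table means.
* **Distal diameter assignment** — exponential diameter model
  ``log D(g) = (g - N) log R_dH + log D_N`` for branches below an anchor.
* **Random constrictions** — radius reductions on a random fraction of the
  branches of one Horsfield order, emulating obstructive airway disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .tree import AirwayTree, GeometryError, TreeValidationError, poiseuille_resistances

__all__ = [
    "WeibelParams",
    "HorsfieldTable",
    "ConstrictionSpec",
    "weibel_tree",
    "horsfield_tree",
    "assign_distal_diameters",
    "apply_constrictions",
]


@dataclass(frozen=True)
class WeibelParams:
    """Parameters of the asymmetric Weibel branching model.

    ``n_divisions`` bifurcations separate the root branch from the terminal
    branches (so the tree has ``n_divisions + 1`` generations and
    ``2**n_divisions`` terminal nodes).  ``asymmetry`` is the branching
    asymmetry ``A`` in [0, 1); at ``A = 0`` every branch has the dimensions of
    the trachea.  All airways have length = ``length_to_diameter`` x diameter.
    """

    n_divisions: int
    asymmetry: float = 0.0
    trachea_radius: float = DEFAULT_CONFIG.trachea_radius_mm
    length_to_diameter: float = DEFAULT_CONFIG.length_to_diameter

    def __post_init__(self):
        if self.n_divisions < 1:
            raise ValueError("n_divisions must be >= 1")
        if not 0.0 <= self.asymmetry < 1.0:
            raise ValueError("asymmetry must be in [0, 1)")
        if self.trachea_radius <= 0 or self.length_to_diameter <= 0:
            raise GeometryError("trachea_radius and length_to_diameter must be positive")


def weibel_tree(params: WeibelParams, config: RunConfig | None = None) -> AirwayTree:
    """Deterministic dyadic tree of ``params.n_divisions`` divisions.

    Arrays are assembled directly in canonical (breadth-first) order: the
    trachea is branch 0, generation ``g`` occupies branches
    ``2**g - 1 .. 2**(g+1) - 2``, and the ``2**N`` terminal branches come
    last.  The major child is listed first at each bifurcation.
    Poiseuille resistances are attached.
    """
    n = params.n_divisions
    a = params.asymmetry
    s_maj = (1.0 + a / 2.0) ** (1.0 / 3.0)
    s_min = (1.0 - a / 2.0) ** (1.0 / 3.0)

    n_branches = 2 ** (n + 1) - 1
    prox = np.empty(n_branches, dtype=np.int64)
    radius = np.empty(n_branches)
    prox[0] = 0
    radius[0] = params.trachea_radius
    for g in range(1, n + 1):
        off = 2**g - 1
        off_par = 2 ** (g - 1) - 1
        m = np.arange(2**g)
        par = off_par + m // 2
        prox[off + m] = par + 1  # distal node of parent branch
        radius[off + m] = radius[par] * np.where(m % 2 == 0, s_maj, s_min)
    length = 2.0 * params.length_to_diameter * radius

    tree = AirwayTree(
        prox=prox,
        radius=radius,
        length=length,
        n_terminal=2**n,
        node_labels=list(range(n_branches + 1)),
        meta={"generator": "weibel", "params": {
            "n_divisions": n, "asymmetry": a,
            "trachea_radius": params.trachea_radius,
            "length_to_diameter": params.length_to_diameter,
        }},
    )
    return poiseuille_resistances(tree, config=config)


# --------------------------------------------------------------------- tables
@dataclass(frozen=True)
class HorsfieldOrderSpec:
    child_orders: tuple[int, ...]
    mean_radius: float  # mm
    mean_length: float  # mm


@dataclass
class HorsfieldTable:
    """Per-order morphometry: child orders and mean dimensions.

    Child orders must be strictly less than the parent order.  Orders below
    the recursion's termination order are clamped up to it, so a table only
    needs to cover ``termination_order .. root_order``.
    """

    orders: dict[int, HorsfieldOrderSpec] = field(default_factory=dict)

    def __post_init__(self):
        for g, spec in self.orders.items():
            if any(c >= g for c in spec.child_orders):
                raise TreeValidationError(
                    f"order {g}: child orders {spec.child_orders} must be < parent order"
                )
            if spec.mean_radius <= 0 or spec.mean_length <= 0:
                raise GeometryError(f"order {g}: nonpositive mean dimensions")

    def __getitem__(self, g: int) -> HorsfieldOrderSpec:
        try:
            return self.orders[g]
        except KeyError:
            raise KeyError(f"Horsfield order {g} missing from table") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.orders, reverse=True):
            spec = self.orders[g]
            c = list(spec.child_orders) + [None] * (2 - len(spec.child_orders))
            rows.append({
                "order": g,
                "child_order_1": c[0],
                "child_order_2": c[1],
                "mean_radius_mm": spec.mean_radius,
                "mean_length_mm": spec.mean_length,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HorsfieldTable":
        df = pd.read_csv(path)
        orders = {}
        for _, row in df.iterrows():
            kids = tuple(
                int(row[c]) for c in ("child_order_1", "child_order_2")
                if c in row and pd.notna(row[c])
            )
            orders[int(row["order"])] = HorsfieldOrderSpec(
                child_orders=kids,
                mean_radius=float(row["mean_radius_mm"]),
                mean_length=float(row["mean_length_mm"]),
            )
        return cls(orders)


def _truncated_gaussian(rng, mean: float, sd: float, floor_frac: float) -> float:
    if sd == 0:
        return mean
    x = rng.normal(mean, sd)
    while x <= floor_frac * mean:
        x = rng.normal(mean, sd)
    return x


def horsfield_tree(
    table: HorsfieldTable,
    root_order: int,
    termination_order: int = 1,
    noise_fraction: float = 0.0,
    seed: int = 0,
    config: RunConfig | None = None,
) -> AirwayTree:
    """Recursive Horsfield-order expansion with Gaussian geometry noise.

    A branch of order ``g > termination_order`` spawns children with the
    table's child orders (clamped at ``termination_order``); branches at or
    below the termination order are terminal.  Radius and length are drawn
    independently per branch from Gaussians with the table means and standard
    deviation ``noise_fraction`` x mean; draws at or below 5% of the mean
    (configurable) are resampled.  Reproducible under ``seed``.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if root_order <= termination_order:
        raise TreeValidationError("root_order must exceed termination_order")
    cfg = config or DEFAULT_CONFIG
    rng = np.random.default_rng(seed)

    # breadth-first expansion so the edge list is already in canonical order
    edges: list[tuple[int, int]] = []
    radius: list[float] = []
    length: list[float] = []
    queue: list[tuple[int, int]] = [(0, root_order)]  # (prox label, branch order)
    next_label = 1
    head = 0
    while head < len(queue):
        prox_label, g = queue[head]
        head += 1
        spec = table[g]
        dist = next_label
        next_label += 1
        edges.append((prox_label, dist))
        radius.append(_truncated_gaussian(
            rng, spec.mean_radius, noise_fraction * spec.mean_radius,
            cfg.gaussian_resample_floor))
        length.append(_truncated_gaussian(
            rng, spec.mean_length, noise_fraction * spec.mean_length,
            cfg.gaussian_resample_floor))
        if g > termination_order:
            for c in spec.child_orders:
                queue.append((dist, max(c, termination_order)))

    from .tree import build_tree  # local import to avoid cycle at module load

    tree = build_tree(edges, radius, length)
    tree.meta.update({
        "generator": "horsfield",
        "params": {
            "root_order": root_order,
            "termination_order": termination_order,
            "noise_fraction": noise_fraction,
            "seed": seed,
        },
    })
    return poiseuille_resistances(tree, config=cfg)


def assign_distal_diameters(
    tree: AirwayTree,
    anchor_order: int,
    anchor_diameter: float,
    ratio: float = 1.15,
) -> AirwayTree:
    """Exponential diameter model for branches below an anchor Horsfield order.

    Branches with order ``g < anchor_order`` get diameter
    ``D(g) = anchor_diameter * ratio**(g - anchor_order)``; anchored branches
    (``g >= anchor_order``) keep their measured diameters.  Existing
    resistances are rescaled by the fourth power of the radius change.
    Returns a modified copy.
    """
    if anchor_diameter <= 0:
        raise GeometryError("anchor_diameter must be positive")
    out = tree.copy()
    orders = out.horsfield_orders()
    below = orders < anchor_order
    new_radius = out.radius.copy()
    new_radius[below] = 0.5 * anchor_diameter * ratio ** (
        orders[below].astype(float) - anchor_order
    )
    if out.resistance is not None:
        out.resistance = out.resistance * (out.radius / new_radius) ** 4
    out.radius = new_radius
    out.meta.setdefault("diameter_model", {}).update(
        {"anchor_order": anchor_order, "anchor_diameter": anchor_diameter,
         "ratio": ratio}
    )
    return out


@dataclass(frozen=True)
class ConstrictionSpec:
    """Random radius reductions on one Horsfield order.

    A fraction ``fraction`` of the branches at ``target_order`` is selected
    uniformly at random; each selected radius is multiplied by ``(1 - u)``
    with ``u ~ Uniform(reduction_range)`` ("reduce by 50-95%" by default).
    """

    target_order: int
    fraction: float
    reduction_range: tuple[float, float] = (0.50, 0.95)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        lo, hi = self.reduction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("reduction factors must lie in (0, 1)")


def apply_constrictions(
    tree: AirwayTree,
    spec: ConstrictionSpec,
    config: RunConfig | None = None,
) -> AirwayTree:
    """Return a copy of ``tree`` with random constrictions applied.

    For a fixed seed the selection is *nested* in the fraction: one
    permutation of the order's branches and one reduction draw per branch are
    generated up front, and ``fraction`` only decides how many of the
    permuted branches are taken.  Sweeping the fraction at a fixed seed
    therefore only ever adds constrictions, which makes resistance (and every
    Maury eigenvalue, by Weyl monotonicity) nondecreasing along the sweep.

    Resistances of the selected branches are rescaled by the fourth power of
    the radius reduction; topology, lengths and unselected radii are
    untouched.
    """
    cfg = config or DEFAULT_CONFIG
    orders = tree.horsfield_orders()
    candidates = np.flatnonzero(orders == spec.target_order)
    if candidates.size == 0:
        raise ValueError(f"no branches of Horsfield order {spec.target_order} in tree")

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(candidates.size)
    u_all = rng.uniform(*spec.reduction_range, size=candidates.size)
    k = math.ceil(spec.fraction * candidates.size)
    taken = perm[:k]
    selected = candidates[taken]
    u = u_all[taken]

    factor = u if cfg.constriction_mode == "multiply_by" else 1.0 - u
    out = tree.copy()
    out.radius[selected] = out.radius[selected] * factor
    if out.resistance is not None:
        out.resistance[selected] = out.resistance[selected] / factor**4
    out.meta.setdefault("constrictions", []).append({
        "target_order": int(spec.target_order),
        "fraction": float(spec.fraction),
        "reduction_range": list(spec.reduction_range),
        "seed": int(spec.seed),
        "mode": cfg.constriction_mode,
        "n_selected": int(k),
        "branches": selected.tolist(),
    })
    return out
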