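"""Weibel and Horsfield generators, diameter assignment, constrictions."""

import numpy as np
import pytest

from airspectra import (
    ConstrictionSpec,
    HorsfieldTable,
    WeibelParams,
    apply_constrictions,
    assign_distal_diameters,
    build_laplacian,
    demo_horsfield_table,
    horsfield_tree,
    solve_fixed_pressure,
    weibel_tree,
)
from airspectra.generators import HorsfieldOrderSpec

A_GRID = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98]


class TestWeibel:
    @pytest.mark.parametrize("n", [1, 3, 6, 9])
    def test_terminal_count_power_of_two(self, n):
        tree = weibel_tree(WeibelParams(n_divisions=n))
        assert tree.n_terminal == 2**n

    def test_symmetric_tree_has_uniform_branches(self):
        tree = weibel_tree(WeibelParams(n_divisions=4, asymmetry=0.0))
        assert np.allclose(tree.radius, tree.radius[0])
        assert np.allclose(tree.length, 6.0 * tree.radius[0])

    def test_extreme_asymmetry_minor_ratio(self):
        # minor child radius ratio (1 - 0.98/2)^(1/3) = 0.51^(1/3)
        tree = weibel_tree(WeibelParams(n_divisions=2, asymmetry=0.98))
        gen = tree.branch_generations()
        first_gen = np.flatnonzero(gen == 1)
        ratios = tree.radius[first_gen] / tree.radius[0]
        assert min(ratios) == pytest.approx(0.51 ** (1 / 3), rel=1e-12)
        assert max(ratios) == pytest.approx(1.49 ** (1 / 3), rel=1e-12)

    @pytest.mark.parametrize("a", [0.0, 0.5, 0.98])
    def test_generation_volume_independent_of_asymmetry(self, a):
        """Each generation's total airway volume is 2x its parent generation's,
        independent of the branching asymmetry."""
        tree = weibel_tree(WeibelParams(n_divisions=5, asymmetry=a))
        gen = tree.branch_generations()
        vol = np.pi * tree.radius**2 * tree.length
        v0 = vol[0]
        for g in range(6):
            assert np.sum(vol[gen == g]) == pytest.approx(2**g * v0, rel=1e-10)

    @pytest.mark.parametrize("a", [0.0, 0.5, 0.98])
    def test_daughter_parallel_resistance(self, a):
        """The two daughters' parallel resistance is half the parent's for all A."""
        tree = weibel_tree(WeibelParams(n_divisions=3, asymmetry=a))
        r = tree.resistance
        for j, kids in enumerate(tree.children_branches()):
            if kids:
                parallel = 1.0 / sum(1.0 / r[c] for c in kids)
                assert parallel == pytest.approx(r[j] / 2.0, rel=1e-12)

    @pytest.mark.parametrize("a", A_GRID)
    def test_equivalent_resistance_closed_form(self, a):
        """Series-parallel reduction gives R_eq = r_trachea (2 - 2^-N)."""
        n = 5
        tree = weibel_tree(WeibelParams(n_divisions=n, asymmetry=a))
        sol = solve_fixed_pressure(build_laplacian(tree), np.ones(tree.n_terminal))
        r_eq = 1.0 / sol.Q_root
        assert r_eq == pytest.approx(tree.resistance[0] * (2 - 2.0**-n), rel=1e-10)

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            WeibelParams(n_divisions=0)
        with pytest.raises(ValueError):
            WeibelParams(n_divisions=3, asymmetry=1.0)


class TestHorsfield:
    def test_symmetric_table_matches_weibel(self):
        """Children (g-1, g-1) with constant dimensions reproduce the
        symmetric Weibel topology and geometry exactly."""
        n = 4
        table = HorsfieldTable({
            g: HorsfieldOrderSpec(
                child_orders=(g - 1, g - 1) if g > 1 else (),
                mean_radius=9.0, mean_length=54.0)
            for g in range(1, n + 2)
        })
        ht = horsfield_tree(table, root_order=n + 1, termination_order=1)
        wt = weibel_tree(WeibelParams(n_divisions=n, asymmetry=0.0))
        assert ht.prox.tolist() == wt.prox.tolist()
        assert np.allclose(ht.radius, wt.radius)
        assert np.allclose(ht.length, wt.length)

    def test_fibonacci_recursion_count(self):
        """Children (g-1, g-2) from root order 5 give T(5) = 8 terminals."""
        tree = horsfield_tree(demo_horsfield_table(5), root_order=5)
        assert tree.n_terminal == 8

    def test_demo_table_count_matches_recursion_oracle(self):
        counts = {1: 1}

        def t(g):
            if g not in counts:
                counts[g] = t(g - 1) + t(max(g - 2, 1))
            return counts[g]

        tree = horsfield_tree(demo_horsfield_table(10), root_order=10)
        assert tree.n_terminal == t(10)  # 89

    def test_seed_determinism(self):
        table = demo_horsfield_table(6)
        a = horsfield_tree(table, 6, noise_fraction=0.2, seed=42)
        b = horsfield_tree(table, 6, noise_fraction=0.2, seed=42)
        c = horsfield_tree(table, 6, noise_fraction=0.2, seed=43)
        assert np.array_equal(a.radius, b.radius)
        assert a.prox.tolist() == c.prox.tolist()  # same topology
        assert not np.array_equal(a.radius, c.radius)  # different geometry

    def test_noise_respects_resample_floor(self):
        table = demo_horsfield_table(8)
        tree = horsfield_tree(table, 8, noise_fraction=0.5, seed=1)
        orders = tree.horsfield_orders()
        for j in range(tree.n_branches):
            mean = table[min(orders[j], 8)].mean_radius
            assert tree.radius[j] > 0.05 * mean

    def test_missing_order_raises(self):
        table = demo_horsfield_table(4)
        with pytest.raises(KeyError):
            horsfield_tree(table, root_order=6)

    def test_table_csv_round_trip(self, tmp_path):
        table = demo_horsfield_table(6)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = HorsfieldTable.from_csv(path)
        assert back.orders == table.orders


class TestDistalDiameters:
    def test_anchor_and_scaling(self):
        tree = horsfield_tree(demo_horsfield_table(6), root_order=6)
        out = assign_distal_diameters(tree, anchor_order=3, anchor_diameter=1.15)
        orders = out.horsfield_orders()
        # g = N - 1 with ratio 1.15 and D_N = 1.15 gives D = 1.0 mm
        assert np.allclose(out.radius[orders == 2], 0.5)
        assert np.allclose(out.radius[orders == 1], 0.5 / 1.15)
        # anchored branches keep measured radii
        assert np.array_equal(out.radius[orders >= 3], tree.radius[orders >= 3])

    def test_monotone_in_order(self):
        tree = horsfield_tree(demo_horsfield_table(8), root_order=8)
        out = assign_distal_diameters(tree, anchor_order=6, anchor_diameter=2.0)
        orders = out.horsfield_orders()
        diam = {g: 2 * out.radius[orders == g][0] for g in range(1, 6)}
        for g in range(1, 5):
            assert diam[g] < diam[g + 1]

    def test_resistance_rescaled_consistently(self):
        from airspectra import poiseuille_resistances

        tree = horsfield_tree(demo_horsfield_table(6), root_order=6)
        out = assign_distal_diameters(tree, anchor_order=3, anchor_diameter=1.0)
        fresh = out.copy()
        poiseuille_resistances(fresh)
        assert np.allclose(out.resistance, fresh.resistance, rtol=1e-12)

    def test_rejects_nonpositive_anchor(self):
        tree = horsfield_tree(demo_horsfield_table(4), root_order=4)
        with pytest.raises(Exception):
            assign_distal_diameters(tree, 2, 0.0)


class TestConstrictions:
    def test_zero_fraction_is_identity(self):
        tree = weibel_tree(WeibelParams(n_divisions=5))
        out = apply_constrictions(tree, ConstrictionSpec(target_order=3, fraction=0.0))
        assert np.array_equal(out.radius, tree.radius)
        assert np.array_equal(out.resistance, tree.resistance)

    def test_deterministic_full_constriction(self):
        """f=1 with a degenerate range halves every radius of the order,
        multiplying its resistance by 16."""
        tree = weibel_tree(WeibelParams(n_divisions=5))
        spec = ConstrictionSpec(
            target_order=3, fraction=1.0, reduction_range=(0.5, 0.5)
        )
        out = apply_constrictions(tree, spec)
        orders = tree.horsfield_orders()
        sel = orders == 3
        assert np.allclose(out.radius[sel], tree.radius[sel] / 2)
        assert np.allclose(out.resistance[sel], tree.resistance[sel] * 16)
        assert np.array_equal(out.radius[~sel], tree.radius[~sel])

    def test_preserves_topology_lengths_unselected(self):
        tree = weibel_tree(WeibelParams(n_divisions=6, asymmetry=0.4))
        out = apply_constrictions(
            tree, ConstrictionSpec(target_order=4, fraction=0.5, seed=9)
        )
        assert out.prox.tolist() == tree.prox.tolist()
        assert np.array_equal(out.length, tree.length)
        sel = out.meta["constrictions"][0]["branches"]
        mask = np.ones(tree.n_branches, bool)
        mask[sel] = False
        assert np.array_equal(out.radius[mask], tree.radius[mask])
        assert np.all(out.radius[sel] < tree.radius[sel])

    def test_peripheral_orders_have_more_branches(self):
        tree = weibel_tree(WeibelParams(n_divisions=8))
        orders = tree.horsfield_orders()
        assert np.sum(orders == 3) > np.sum(orders == 7)

    def test_nested_selection_under_fraction_sweep(self):
        """With one seed, increasing f only adds constricted branches."""
        tree = weibel_tree(WeibelParams(n_divisions=6))
        sets = []
        for f in (0.2, 0.4, 0.8):
            out = apply_constrictions(
                tree, ConstrictionSpec(target_order=3, fraction=f, seed=5)
            )
            sets.append(set(out.meta["constrictions"][0]["branches"]))
        assert sets[0] <= sets[1] <= sets[2]

    def test_absent_order_raises(self):
        tree = weibel_tree(WeibelParams(n_divisions=3))
        with pytest.raises(ValueError):
            apply_constrictions(tree, ConstrictionSpec(target_order=9, fraction=0.5))
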