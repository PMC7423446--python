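"""Conductance Laplacian assembly, flow solves, spectra and delta_L."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airspectra import (
    WeibelParams,
    build_laplacian,
    build_tree,
    delta_L,
    laplacian_modal_solution,
    laplacian_spectrum,
    solve_fixed_pressure,
    weibel_tree,
)
from airspectra.laplacian import assemble_internal_blocks

from conftest import make_random_tree


class TestAssembly:
    def test_y_tree_internal_laplacian(self, y_tree):
        system = build_laplacian(y_tree)
        assert system.internal_laplacian.toarray() == pytest.approx(
            np.array([[1 + 1 / 2 + 1 / 3]])
        )

    def test_path_graph_textbook_laplacian(self):
        tree = build_tree([(1, 2), (2, 3)], [1, 1], [1, 1], resistance=[1.0, 1.0])
        full = build_laplacian(tree).full_laplacian.toarray()
        assert np.allclose(full, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    @pytest.mark.parametrize("seed", range(6))
    def test_zero_row_sums_and_symmetry(self, seed):
        tree = make_random_tree(seed, n_nodes=30)
        full = build_laplacian(tree).full_laplacian
        assert np.allclose(full @ np.ones(tree.n_nodes), 0, atol=1e-12)
        assert (abs(full - full.T)).max() < 1e-12

    @pytest.mark.parametrize("seed", range(6))
    def test_block_assembly_matches_extraction(self, seed):
        tree = make_random_tree(seed, n_nodes=30)
        system = build_laplacian(tree)  # raises internally on mismatch
        blocks = assemble_internal_blocks(tree)
        assert np.allclose(
            system.internal_laplacian.toarray(), blocks.toarray(), atol=1e-13
        )

    def test_exactly_one_zero_eigenvalue(self, two_level):
        vals = np.linalg.eigvalsh(build_laplacian(two_level).full_laplacian.toarray())
        assert np.sum(np.abs(vals) < 1e-10) == 1

    def test_missing_resistance_raises(self):
        tree = build_tree([(1, 2)], [1.0], [1.0])
        with pytest.raises(Exception):
            build_laplacian(tree)


class TestFixedPressureSolve:
    def test_y_tree_hand_solution(self, y_tree):
        sol = solve_fixed_pressure(build_laplacian(y_tree), np.ones(2))
        assert sol.Q_terminal == pytest.approx([-3 / 11, -2 / 11])
        assert sol.Q_root == pytest.approx(5 / 11)
        assert sol.dP_internal == pytest.approx([5 / 11])

    def test_zero_pressure_zero_flux(self, two_level):
        sol = solve_fixed_pressure(build_laplacian(two_level), np.zeros(4))
        assert np.all(sol.q_branch == 0)
        assert sol.Q_root == 0

    def test_symmetric_weibel_uniform_fluxes(self):
        tree = weibel_tree(WeibelParams(n_divisions=5, asymmetry=0.0))
        sol = solve_fixed_pressure(build_laplacian(tree), np.ones(32))
        assert np.allclose(sol.Q_terminal, sol.Q_terminal[0], rtol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_invariants(self, seed):
        tree = make_random_tree(seed, n_nodes=40)
        rng = np.random.default_rng(seed + 100)
        dp = rng.uniform(0.5, 2.0, tree.n_terminal)
        sol = solve_fixed_pressure(build_laplacian(tree), dp)
        # flux conservation at internal nodes and global balance
        from airspectra import incidence_matrix

        node_flux = incidence_matrix(tree) @ sol.q_branch
        assert np.allclose(node_flux[1: tree.n_internal + 1], 0, atol=1e-12)
        assert sol.Q_root == pytest.approx(-np.sum(sol.Q_terminal), rel=1e-10)
        assert np.allclose(node_flux[tree.n_internal + 1:], sol.Q_terminal)

    @pytest.mark.parametrize("seed", range(4))
    def test_dense_operator_identity(self, seed):
        """Two-step sparse solve equals Gamma [B^T L_int^-1 B Gamma - I] dP_term."""
        tree = make_random_tree(seed, n_nodes=50)
        system = build_laplacian(tree)
        rng = np.random.default_rng(seed)
        dp = rng.uniform(-1, 2, tree.n_terminal)
        sol = solve_fixed_pressure(system, dp)
        g = system.terminal_conductances
        li = np.linalg.inv(system.internal_laplacian.toarray())
        b = system.coupling.toarray()
        dense = g * (b.T @ li @ b @ (g * dp) - dp)
        assert np.allclose(sol.Q_terminal, dense, rtol=1e-8, atol=1e-12)

    def test_wrong_length_rejected(self, y_tree):
        with pytest.raises(ValueError):
            solve_fixed_pressure(build_laplacian(y_tree), np.ones(3))


class TestSpectrum:
    def test_y_tree_single_mode(self, y_tree):
        dec = laplacian_spectrum(build_laplacian(y_tree))
        assert dec.eigenvalues == pytest.approx([11 / 6])

    @pytest.mark.parametrize("seed", range(4))
    def test_positive_orthonormal_reconstruction(self, seed):
        tree = make_random_tree(seed, n_nodes=35)
        system = build_laplacian(tree)
        dec = laplacian_spectrum(system)
        assert np.all(dec.eigenvalues > 0)
        assert np.all(np.diff(dec.eigenvalues) >= -1e-12)
        v = dec.eigenvectors
        assert np.allclose(v.T @ v, np.eye(dec.n_modes), atol=1e-10)
        recon = (v * dec.eigenvalues) @ v.T
        assert np.allclose(recon, system.internal_laplacian.toarray(), atol=1e-8)

    def test_partial_iterative_matches_dense(self):
        tree = weibel_tree(WeibelParams(n_divisions=6, asymmetry=0.5))
        system = build_laplacian(tree)
        full = laplacian_spectrum(system)
        part = laplacian_spectrum(system, n_modes=5)
        assert part.eigenvalues == pytest.approx(full.eigenvalues[:5], rel=1e-8)

    def test_too_many_modes_rejected(self, y_tree):
        with pytest.raises(ValueError):
            laplacian_spectrum(build_laplacian(y_tree), n_modes=2)


class TestModalSolution:
    def test_single_mode_reproduces_direct(self, y_tree):
        system = build_laplacian(y_tree)
        direct = solve_fixed_pressure(system, np.ones(2))
        modal, _ = laplacian_modal_solution(
            laplacian_spectrum(system), system, np.ones(2)
        )
        assert modal.Q_terminal == pytest.approx(direct.Q_terminal)

    def test_zero_modes_is_boundary_term(self, two_level):
        system = build_laplacian(two_level)
        dp = np.ones(4)
        sol, _ = laplacian_modal_solution(
            laplacian_spectrum(system), system, dp, n_modes=0
        )
        assert np.allclose(sol.dP_internal, 0)
        assert sol.Q_terminal == pytest.approx(-system.terminal_conductances * dp)

    @pytest.mark.parametrize("seed", range(4))
    def test_full_modal_equals_direct(self, seed):
        tree = make_random_tree(seed, n_nodes=40)
        system = build_laplacian(tree)
        rng = np.random.default_rng(seed)
        dp = rng.uniform(0.5, 2.0, tree.n_terminal)
        direct = solve_fixed_pressure(system, dp)
        modal, _ = laplacian_modal_solution(laplacian_spectrum(system), system, dp)
        err = np.linalg.norm(modal.Q_terminal - direct.Q_terminal)
        assert err <= 1e-8 * np.linalg.norm(direct.Q_terminal)

    def test_internal_pressure_error_monotone_in_coefficient_order(self):
        """Adding modes in decreasing |p_k| order can only reduce the
        internal-pressure reconstruction error (orthogonal contributions)."""
        tree = weibel_tree(WeibelParams(n_divisions=5, asymmetry=0.5))
        system = build_laplacian(tree)
        dp = np.ones(tree.n_terminal)
        dec = laplacian_spectrum(system)
        ref = solve_fixed_pressure(system, dp)
        _, p = laplacian_modal_solution(dec, system, dp)
        order = np.argsort(-np.abs(p), kind="stable")
        errs = []
        for m in [*range(0, dec.n_modes, 3), dec.n_modes]:
            sol, _ = laplacian_modal_solution(
                dec, system, dp, mode_indices=order[:m]
            )
            errs.append(np.linalg.norm(sol.dP_internal - ref.dP_internal))
        assert np.all(np.diff(errs) <= 1e-12)
        assert errs[-1] < 1e-10


class TestDeltaL:
    def test_closed_form_two_eigenvalues(self):
        assert delta_L(np.array([1.0, 2.0]), 1) == pytest.approx(1 / np.sqrt(5))

    def test_endpoints(self):
        vals = np.array([0.5, 1.0, 4.0])
        assert delta_L(vals, 0) == 1.0
        assert delta_L(vals, 3) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_dense_frobenius_oracle(self, seed):
        """Formula agrees with explicit ||L^-1 - partial||_F / ||L^-1||_F."""
        tree = make_random_tree(seed, n_nodes=20)
        system = build_laplacian(tree)
        dec = laplacian_spectrum(system)
        inv = np.linalg.inv(system.internal_laplacian.toarray())
        for m in range(dec.n_modes + 1):
            v = dec.eigenvectors[:, :m]
            partial = (v / dec.eigenvalues[:m]) @ v.T if m else np.zeros_like(inv)
            explicit = np.linalg.norm(inv - partial) / np.linalg.norm(inv)
            assert delta_L(dec.eigenvalues, m) == pytest.approx(explicit, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=30))
    def test_monotone_nonincreasing(self, vals):
        vals = np.sort(np.asarray(vals))
        deltas = [delta_L(vals, m) for m in range(len(vals) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(deltas, deltas[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta_L(np.array([1.0]), 2)
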