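"""Conductance Laplacian: block decomposition, sparse flow solves, spectra.

The conductance Laplacian of a resistive tree is ``L = N diag(r)^-1 N^T``
where ``N`` is the node-branch incidence matrix and ``r`` the branch
resistances.  Under pressure boundary conditions at the root and the
terminal nodes, the interior pressure drops satisfy the reduced system
``L_int dP_int = B Gamma_term dP_term`` whose sparse direct solution gives
the terminal fluxes ``Q_term = Gamma_term (B^T dP_int - dP_term)``.

Pressure drops are measured relative to the root, ``dP = P_1 - P``, so a
positive terminal pressure drop drives flow *into* the terminals (negative
terminal flux).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import DEFAULT_CONFIG, RunConfig
from .spectral import SpectralDecomposition, inverse_truncation_discrepancy
from .tree import AirwayTree, BlockPartition, incidence_matrix

__all__ = [
    "LaplacianSystem",
    "FlowSolution",
    "build_laplacian",
    "assemble_internal_blocks",
    "solve_fixed_pressure",
    "laplacian_spectrum",
    "laplacian_modal_solution",
    "delta_L",
]


@dataclass
class LaplacianSystem:
    """Conductance Laplacian of a tree together with its boundary blocks."""

    tree: AirwayTree
    full_laplacian: sp.csr_matrix  # |V| x |V|
    internal_laplacian: sp.csc_matrix  # n_int x n_int, SPD
    coupling: sp.csr_matrix  # B: n_int x |T| (internal nodes x terminal branches)
    terminal_conductances: np.ndarray  # gamma = 1 / r_term, length |T|
    partition: BlockPartition
    _lu: spla.SuperLU | None = field(default=None, repr=False)

    @property
    def n_internal(self) -> int:
        return self.internal_laplacian.shape[0]

    @property
    def n_terminal(self) -> int:
        return len(self.terminal_conductances)

    def factorize(self) -> spla.SuperLU | None:
        """Sparse LU of L_int, cached; None for trees with no internal nodes."""
        if self._lu is None and self.n_internal > 0:
            self._lu = spla.splu(self.internal_laplacian)
        return self._lu

    def solve_internal(self, rhs: np.ndarray) -> np.ndarray:
        if self.n_internal == 0:
            return np.zeros((0,) + rhs.shape[1:])
        return self.factorize().solve(rhs)


@dataclass
class FlowSolution:
    """Pressure drops and fluxes on a tree under fixed boundary conditions.

    Sign convention: ``q_branch[j] > 0`` is flow from proximal to distal;
    terminal fluxes are node in-fluxes, so terminals act as sinks
    (``Q_terminal < 0``) when gas flows from the root into the periphery,
    and mass conservation reads ``Q_root = -sum(Q_terminal)``.
    """

    dP_internal: np.ndarray
    dP_terminal: np.ndarray
    Q_terminal: np.ndarray
    q_branch: np.ndarray
    Q_root: float


def build_laplacian(
    tree: AirwayTree, config: RunConfig | None = None
) -> LaplacianSystem:
    """Assemble the full conductance Laplacian and its internal blocks.

    The internal block is both extracted from the full operator and
    re-assembled from its definition as
    ``sum_root r_b^-1 a_b a_b^T + N_int diag(r_int)^-1 N_int^T
    + B Gamma_term B^T``; the two must agree elementwise.
    """
    cfg = config or DEFAULT_CONFIG
    r = tree.require_resistance()
    n = incidence_matrix(tree)
    conductance = sp.diags(1.0 / r)
    full = (n @ conductance @ n.T).tocsr()

    part = tree.partition()
    n_int = tree.n_internal
    int_nodes = slice(1, 1 + n_int)
    l_int = full[int_nodes, int_nodes].tocsc()
    b = n[int_nodes, :][:, part.terminal_branch_indices].tocsr()
    gamma = 1.0 / r[part.terminal_branch_indices]

    l_int_blocks = assemble_internal_blocks(tree)
    diff = abs(l_int - l_int_blocks)
    scale = max(abs(l_int).max(), 1.0)
    if diff.count_nonzero() and diff.max() > 1e-12 * scale:
        raise AssertionError(
            "block assembly of L_int disagrees with extraction from L "
            f"(max abs diff {diff.max():.3e})"
        )

    return LaplacianSystem(
        tree=tree,
        full_laplacian=full,
        internal_laplacian=l_int,
        coupling=b,
        terminal_conductances=gamma,
        partition=part,
    )


def assemble_internal_blocks(tree: AirwayTree) -> sp.csc_matrix:
    """L_int assembled directly from its block-sum definition."""
    r = tree.require_resistance()
    n = incidence_matrix(tree)
    n_int = tree.n_internal
    part = tree.partition()
    int_rows = slice(1, 1 + n_int)

    is_term_branch = tree.is_terminal_branch()
    is_root_branch = tree.prox == 0
    internal_cols = np.flatnonzero(~is_term_branch & ~is_root_branch)
    root_cols = np.flatnonzero(is_root_branch & ~is_term_branch)

    l_int = sp.csc_matrix((n_int, n_int))
    # root-adjacent branches contribute r^-1 a a^T with a the indicator of
    # their (internal) distal node; for a single trachea this is the familiar
    # r_1^-1 a a^T with a = (1, 0, ..., 0)^T
    for j in root_cols:
        a = sp.csc_matrix(
            (np.ones(1), (np.array([j + 1 - 1]), np.zeros(1, dtype=int))),
            shape=(n_int, 1),
        )
        l_int = l_int + (a @ a.T) / r[j]
    if internal_cols.size:
        n_int_mat = n[int_rows, :][:, internal_cols]
        l_int = l_int + n_int_mat @ sp.diags(1.0 / r[internal_cols]) @ n_int_mat.T
    b = n[int_rows, :][:, part.terminal_branch_indices]
    gamma = sp.diags(1.0 / r[part.terminal_branch_indices])
    l_int = l_int + b @ gamma @ b.T
    return l_int.tocsc()


def solve_fixed_pressure(
    system: LaplacianSystem,
    dP_terminal: np.ndarray,
    config: RunConfig | None = None,
) -> FlowSolution:
    """Direct sparse solve of the flow problem for given terminal pressure drops."""
    cfg = config or DEFAULT_CONFIG
    dP_terminal = np.asarray(dP_terminal, dtype=float)
    if dP_terminal.shape != (system.n_terminal,):
        raise ValueError(
            f"dP_terminal must have length {system.n_terminal}, "
            f"got shape {dP_terminal.shape}"
        )
    gamma = system.terminal_conductances
    rhs = system.coupling @ (gamma * dP_terminal)
    dp_int = system.solve_internal(rhs)
    if system.n_internal > 0:
        resid = np.linalg.norm(system.internal_laplacian @ dp_int - rhs)
        scale = np.linalg.norm(rhs)
        if scale > 0 and resid > cfg.linear_residual_rtol * scale:
            warnings.warn(
                f"internal solve residual {resid / scale:.2e} exceeds "
                f"{cfg.linear_residual_rtol:.0e}",
                stacklevel=2,
            )
    q_term = gamma * (system.coupling.T @ dp_int - dP_terminal)

    tree = system.tree
    dp_full = np.concatenate([[0.0], dp_int, dP_terminal])
    q = (dp_full[1:] - dp_full[tree.prox]) / tree.require_resistance()
    q_root = float(np.sum(q[tree.prox == 0]))
    return FlowSolution(
        dP_internal=dp_int,
        dP_terminal=dP_terminal,
        Q_terminal=q_term,
        q_branch=q,
        Q_root=q_root,
    )


def laplacian_spectrum(
    system: LaplacianSystem,
    n_modes: int | None = None,
    config: RunConfig | None = None,
) -> SpectralDecomposition:
    """Eigen-decomposition of L_int, eigenvalues ascending.

    The full spectrum is computed densely (guarded by a size cap); a partial
    spectrum of the ``n_modes`` smallest eigenvalues is computed iteratively
    with shift-invert Lanczos, never forming a dense matrix.
    """
    cfg = config or DEFAULT_CONFIG
    dim = system.n_internal
    if n_modes is None:
        n_modes = dim
    if n_modes > dim:
        raise ValueError(f"n_modes={n_modes} exceeds dimension {dim}")

    if n_modes == dim or n_modes > dim - 2:
        if dim > cfg.dense_laplacian_eig_cap:
            raise ValueError(
                f"full dense decomposition of a {dim}-dimensional L_int exceeds "
                f"the size cap {cfg.dense_laplacian_eig_cap}; request fewer modes"
            )
        vals, vecs = np.linalg.eigh(system.internal_laplacian.toarray())
        vals, vecs = vals[:n_modes], vecs[:, :n_modes]
    else:
        try:
            vals, vecs = spla.eigsh(
                system.internal_laplacian, k=n_modes, sigma=0, which="LM"
            )
        except spla.ArpackNoConvergence as err:
            raise RuntimeError(
                f"Laplacian eigensolver failed to converge: "
                f"{len(err.eigenvalues)} of {n_modes} modes converged"
            ) from err
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    _check_residuals(system.internal_laplacian, vals, vecs, cfg.eig_residual_rtol)
    return SpectralDecomposition(
        operator="laplacian", eigenvalues=vals, eigenvectors=vecs, n_total=dim
    )


def _check_residuals(op, vals, vecs, rtol):
    if len(vals) == 0:
        return
    scale = float(np.max(np.abs(vals)))
    resid = np.linalg.norm(op @ vecs - vecs * vals, axis=0)
    worst = resid.max() / max(scale, 1e-300)
    if worst > rtol:
        warnings.warn(
            f"eigenpair residual {worst:.2e} exceeds {rtol:.0e}", stacklevel=3
        )


def laplacian_modal_solution(
    decomposition: SpectralDecomposition,
    system: LaplacianSystem,
    dP_terminal: np.ndarray,
    n_modes: int | None = None,
    mode_indices: np.ndarray | None = None,
) -> tuple[FlowSolution, np.ndarray]:
    """Truncated modal reconstruction of the fixed-pressure flow solution.

    ``dP_int`` is rebuilt from the selected Laplacian modes as
    ``sum_k (u_k^T B Gamma dP_term / lambda_k) u_k``; the terminal fluxes then
    follow from the boundary relation (whose ``-Gamma dP_term`` part is exact,
    not truncated).  Returns the flow solution and the full coefficient
    vector ``p_k`` for the available modes.
    """
    if decomposition.operator != "laplacian":
        raise ValueError("decomposition is not a Laplacian spectrum")
    dP_terminal = np.asarray(dP_terminal, dtype=float)
    gamma = system.terminal_conductances
    f = system.coupling @ (gamma * dP_terminal)
    coeff = (decomposition.eigenvectors.T @ f) / decomposition.eigenvalues

    if mode_indices is None:
        if n_modes is None:
            n_modes = decomposition.n_modes
        if n_modes > decomposition.n_modes:
            raise ValueError(
                f"n_modes={n_modes} exceeds available {decomposition.n_modes}"
            )
        mode_indices = np.arange(n_modes)
    dp_int = decomposition.eigenvectors[:, mode_indices] @ coeff[mode_indices]
    q_term = gamma * (system.coupling.T @ dp_int - dP_terminal)

    tree = system.tree
    dp_full = np.concatenate([[0.0], dp_int, dP_terminal])
    q = (dp_full[1:] - dp_full[tree.prox]) / tree.require_resistance()
    sol = FlowSolution(
        dP_internal=dp_int,
        dP_terminal=dP_terminal,
        Q_terminal=q_term,
        q_branch=q,
        Q_root=float(np.sum(q[tree.prox == 0])),
    )
    return sol, coeff


def delta_L(eigenvalues: np.ndarray, M: int) -> float:
    """Truncation discrepancy of the inverse internal Laplacian.

    ``eigenvalues`` is the complete nonzero spectrum in ascending order; the
    ``M`` smallest-eigenvalue modes are kept.  Equals
    ``sqrt(sum_excluded lambda^-2 / sum_all lambda^-2)``; 1 at ``M = 0``, 0 at
    the full spectrum, nonincreasing in ``M``.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if not 0 <= M <= len(eigenvalues):
        raise ValueError(f"M={M} out of range [0, {len(eigenvalues)}]")
    return inverse_truncation_discrepancy(eigenvalues[:M], eigenvalues)
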