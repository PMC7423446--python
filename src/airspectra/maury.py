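"""The Maury operator of a resistive tree and its spectral reduction.

The Maury matrix ``R`` is the |T| x |T| symmetric positive-definite operator
relating terminal pressure drops to terminal fluxes, ``R Q_term = -dP_term``.
Its entry ``(i, i')`` is the resistance of the shared root-path of terminals
``i`` and ``i'`` — equivalently the resistance distance from the root to
their lowest common ancestor — so ``R`` is the weighted adjacency matrix of a
complete graph (with self-loops) on the terminal nodes.

Three independent constructions are provided for cross-validation:

* ``maury_dense`` — the sparse-factor product ``T diag(r) T^T``;
* ``maury_lca`` — explicit shared-path resistance sums (the slow oracle);
* ``maury_schur`` — inversion of the Schur-complement form
  ``(Gamma - Gamma B^T L_int^-1 B Gamma)^-1``.

Eigenmodes are computed matrix-free from the sparse factors, so large-|T|
trees never require assembling the dense operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import DEFAULT_CONFIG, RunConfig
from .laplacian import build_laplacian, solve_fixed_pressure
from .spectral import SpectralDecomposition, inverse_truncation_discrepancy
from .tree import AirwayTree, incidence_matrix, subtree_terminal_sets

__all__ = [
    "SubtreeMaps",
    "MauryOperator",
    "subtree_maps",
    "maury_dense",
    "maury_lca",
    "maury_schur",
    "maury_spectrum",
    "flux_from_modes",
    "delta_R",
    "min_modes_for_accuracy",
]


@dataclass
class SubtreeMaps:
    """Sparse 0/1 descendant maps of a tree.

    ``S`` is ``(|V|-1) x |E|``: column ``j`` marks the nodes descended from
    branch ``j`` (row ``i`` is node ``i + 1``); its first column is all ones.
    ``T_map`` holds the final |T| rows of ``S`` (the terminal descendants),
    so row sums of ``T_map`` are root-to-terminal path lengths.
    """

    S: sp.csr_matrix
    T_map: sp.csr_matrix


def subtree_maps(tree: AirwayTree, validate: bool = True) -> SubtreeMaps:
    """Assemble the descendant maps; optionally assert ``S N^T = (e, -I)``."""
    rows, cols = [], []
    for i in range(1, tree.n_nodes):
        j = i - 1
        while True:
            rows.append(i - 1)
            cols.append(j)
            p = tree.prox[j]
            if p == 0:
                break
            j = p - 1
    s = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(tree.n_nodes - 1, tree.n_branches),
    )
    if validate:
        n = incidence_matrix(tree)
        prod = (s @ n.T).toarray()
        expected = np.hstack(
            [np.ones((tree.n_nodes - 1, 1)), -np.eye(tree.n_nodes - 1)]
        )
        if not np.array_equal(prod, expected):
            raise AssertionError("S N^T identity violated")
    t_map = s[tree.n_internal:, :].tocsr()
    return SubtreeMaps(S=s, T_map=t_map)


@dataclass
class MauryOperator:
    """Maury operator held as sparse factors ``T_map diag(r) T_map^T``.

    The dense matrix is stored only when explicitly assembled.
    """

    T_map: sp.csr_matrix
    resistance: np.ndarray
    dense: np.ndarray | None = None

    @property
    def n_terminal(self) -> int:
        return self.T_map.shape[0]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.T_map @ (self.resistance * (self.T_map.T @ v))

    def as_linear_operator(self) -> spla.LinearOperator:
        n = self.n_terminal
        return spla.LinearOperator(
            (n, n), matvec=self.matvec, matmat=self.matvec, dtype=float
        )

    def trace(self) -> float:
        """Sum of root-to-terminal path resistances."""
        return float((self.T_map @ self.resistance).sum())

    def toarray(self) -> np.ndarray:
        if self.dense is None:
            self.dense = (
                self.T_map @ sp.diags(self.resistance) @ self.T_map.T
            ).toarray()
        return self.dense


def maury_dense(
    tree: AirwayTree, config: RunConfig | None = None
) -> MauryOperator:
    """Dense Maury matrix from the sparse factors ``T diag(r) T^T``."""
    cfg = config or DEFAULT_CONFIG
    if tree.n_terminal > cfg.dense_maury_cap:
        raise ValueError(
            f"|T|={tree.n_terminal} exceeds dense cap {cfg.dense_maury_cap}; "
            "use maury_spectrum for the matrix-free path"
        )
    maps = subtree_maps(tree, validate=False)
    op = MauryOperator(T_map=maps.T_map, resistance=tree.require_resistance())
    op.toarray()
    return op


def maury_lca(tree: AirwayTree) -> MauryOperator:
    """Maury matrix from explicit shared-path resistance sums.

    Independent oracle: entry ``(i, i')`` is computed as the sum of branch
    resistances on the intersection of the two root-to-terminal paths
    (O(|T|^2 depth); intended for validation at test scale).
    """
    r = tree.require_resistance()
    term_branches = tree.terminal_branch_indices
    paths = [set(tree.path_to_root(j)) for j in term_branches]
    nt = tree.n_terminal
    dense = np.empty((nt, nt))
    for i in range(nt):
        for ip in range(i, nt):
            shared = paths[i] & paths[ip]
            dense[i, ip] = dense[ip, i] = sum(r[j] for j in shared)
    maps = subtree_maps(tree, validate=False)
    return MauryOperator(T_map=maps.T_map, resistance=r, dense=dense)


def maury_schur(tree: AirwayTree) -> MauryOperator:
    """Maury matrix by inverting ``Gamma - Gamma B^T L_int^-1 B Gamma``.

    Third independent construction (small instances only: dense |T| x |T|
    inversion).  Ill-conditioning of the inner matrix is reported.
    """
    system = build_laplacian(tree)
    gamma = system.terminal_conductances
    nt = system.n_terminal
    if system.n_internal > 0:
        bg = system.coupling @ sp.diags(gamma)
        x = system.solve_internal(bg.toarray())
        inner = np.diag(gamma) - gamma[:, None] * (system.coupling.T @ x)
    else:
        inner = np.diag(gamma)
    cond = np.linalg.cond(inner)
    if cond > 1e12:
        warnings.warn(
            f"Schur-form inner matrix condition number {cond:.2e}", stacklevel=2
        )
    dense = np.linalg.inv(inner)
    dense = 0.5 * (dense + dense.T)
    maps = subtree_maps(tree, validate=False)
    return MauryOperator(
        T_map=maps.T_map, resistance=tree.require_resistance(), dense=dense
    )


def maury_spectrum(
    tree: AirwayTree,
    n_modes: int | None = None,
    which: str = "largest",
    config: RunConfig | None = None,
) -> SpectralDecomposition:
    """Eigenmodes of the Maury operator, ordered by descending eigenvalue.

    Partial spectra are computed matrix-free with Lanczos iteration on the
    sparse factors (the operator action is ``v -> T diag(r) T^T v``); the
    dense |T| x |T| matrix is only formed for a full decomposition, and only
    below the configured size cap.
    """
    cfg = config or DEFAULT_CONFIG
    nt = tree.n_terminal
    if n_modes is None:
        n_modes = nt
    if n_modes > nt:
        raise ValueError(f"n_modes={n_modes} exceeds |T|={nt}")
    if which not in ("largest", "smallest"):
        raise ValueError("which must be 'largest' or 'smallest'")

    maps = subtree_maps(tree, validate=False)
    op = MauryOperator(T_map=maps.T_map, resistance=tree.require_resistance())

    if n_modes >= nt - 1:
        if nt > cfg.dense_maury_cap:
            raise ValueError(
                f"full spectrum of |T|={nt} exceeds dense cap "
                f"{cfg.dense_maury_cap}"
            )
        vals, vecs = np.linalg.eigh(op.toarray())
        vals, vecs = vals[::-1], vecs[:, ::-1]  # descending
        if which == "smallest":
            vals, vecs = vals[-n_modes:], vecs[:, -n_modes:]
        else:
            vals, vecs = vals[:n_modes], vecs[:, :n_modes]
    else:
        arpack_which = "LA" if which == "largest" else "SA"
        try:
            vals, vecs = spla.eigsh(
                op.as_linear_operator(), k=n_modes, which=arpack_which
            )
        except spla.ArpackNoConvergence as err:
            raise RuntimeError(
                f"Maury eigensolver failed to converge: "
                f"{len(err.eigenvalues)} of {n_modes} modes converged"
            ) from err
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    # residual check against the matrix-free operator action
    if len(vals):
        resid = np.linalg.norm(
            np.column_stack([op.matvec(vecs[:, k]) for k in range(vecs.shape[1])])
            - vecs * vals,
            axis=0,
        )
        mu1 = float(np.max(np.abs(vals)))
        if resid.max() > cfg.eig_residual_rtol * max(mu1, 1e-300):
            warnings.warn(
                f"Maury eigenpair residual {resid.max() / mu1:.2e} exceeds "
                f"{cfg.eig_residual_rtol:.0e}",
                stacklevel=2,
            )
    return SpectralDecomposition(
        operator="maury", eigenvalues=vals, eigenvectors=vecs, n_total=nt
    )


def flux_from_modes(
    decomposition: SpectralDecomposition,
    dP_terminal: np.ndarray,
    n_modes: int | None = None,
    mode_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Terminal fluxes reconstructed from Maury modes.

    ``Q_term = -sum_k (dP_term^T v_k / mu_k) v_k`` over the selected modes
    (the first ``n_modes`` in descending-eigenvalue order unless explicit
    ``mode_indices`` are given).  Returns ``(Q_term, q)`` where ``q`` holds
    the signed coefficients of *all* available modes.
    """
    if decomposition.operator != "maury":
        raise ValueError("decomposition is not a Maury spectrum")
    dP_terminal = np.asarray(dP_terminal, dtype=float)
    coeff = (decomposition.eigenvectors.T @ dP_terminal) / decomposition.eigenvalues
    if mode_indices is None:
        if n_modes is None:
            n_modes = decomposition.n_modes
        if n_modes > decomposition.n_modes:
            raise ValueError(
                f"n_modes={n_modes} exceeds available {decomposition.n_modes}"
            )
        mode_indices = np.arange(n_modes)
    q_term = -(decomposition.eigenvectors[:, mode_indices] @ coeff[mode_indices])
    return q_term, coeff


def delta_R(eigenvalues: np.ndarray, M: int) -> float:
    """Truncation discrepancy of the inverse Maury operator.

    ``eigenvalues`` is the complete spectrum in descending order; the ``M``
    *smallest*-eigenvalue modes are kept (they carry the largest inverse
    weights).  Equals ``sqrt(sum_excluded mu^-2 / sum_all mu^-2)``.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    nt = len(eigenvalues)
    if not 0 <= M <= nt:
        raise ValueError(f"M={M} out of range [0, {nt}]")
    kept = eigenvalues[nt - M:]
    return inverse_truncation_discrepancy(kept, eigenvalues)


def min_modes_for_accuracy(
    tree: AirwayTree,
    dP_terminal: np.ndarray,
    accuracy: float,
    rank_by: str = "auto",
    operator: str = "maury",
    metric: str = "power",
    config: RunConfig | None = None,
) -> int:
    """Smallest number of modes reconstructing the flow to a given accuracy.

    Two accuracy metrics are available:

    * ``"power"`` (default) — accuracy is the captured fraction of the total
      dissipated power.  Mode contributions are orthogonal in the operator's
      energy norm, so mode ``k`` of the Maury operator carries power
      ``(dP_term^T v_k)^2 / mu_k`` (for uniform unit pressure drop, exactly
      its share of the root flow) and a Laplacian mode carries
      ``(u_k^T B Gamma dP_term)^2 / lambda_k``.
    * ``"l2"`` — accuracy is ``1 -`` the relative Euclidean error of the
      reconstructed ``Q_term`` against the direct sparse solve.

    ``rank_by="auto"`` uses the greedy-optimal ranking for the chosen metric
    (power contribution, or coefficient magnitude for "l2"), which makes the
    result the true minimum subset size; ``"coefficient"`` and
    ``"eigenvalue"`` force |q_k| (resp. |p_k|) ranking or plain eigenvalue
    order.  Ties are broken stably toward the conventional eigenvalue order.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must be in (0, 1]")
    if rank_by not in ("auto", "coefficient", "power", "eigenvalue"):
        raise ValueError("rank_by must be auto|coefficient|power|eigenvalue")
    if metric not in ("power", "l2"):
        raise ValueError("metric must be 'power' or 'l2'")
    dP_terminal = np.asarray(dP_terminal, dtype=float)
    system = build_laplacian(tree, config=config)
    sol = solve_fixed_pressure(system, dP_terminal, config=config)
    q_ref = sol.Q_terminal

    if operator == "maury":
        dec = maury_spectrum(tree, config=config)
        proj = dec.eigenvectors.T @ dP_terminal
        coeff = proj / dec.eigenvalues
        power = proj**2 / dec.eigenvalues
        contrib = -dec.eigenvectors * coeff  # column k = mode k's flux term
        baseline = np.zeros_like(q_ref)
        total_power = float(-dP_terminal @ q_ref)
    elif operator == "laplacian":
        from .laplacian import laplacian_spectrum

        dec = laplacian_spectrum(system, config=config)
        gamma = system.terminal_conductances
        f = system.coupling @ (gamma * dP_terminal)
        proj = dec.eigenvectors.T @ f
        coeff = proj / dec.eigenvalues
        power = proj**2 / dec.eigenvalues
        contrib = (system.coupling.T @ dec.eigenvectors) * gamma[:, None] * coeff
        # the -Gamma dP_term boundary term is exact, never truncated
        baseline = -gamma * dP_terminal
        total_power = float(f @ sol.dP_internal)
    else:
        raise ValueError("operator must be 'maury' or 'laplacian'")

    if rank_by == "eigenvalue":
        ranked = np.arange(len(coeff))
    elif rank_by == "coefficient" or (rank_by == "auto" and metric == "l2"):
        ranked = np.argsort(-np.abs(coeff), kind="stable")
    else:
        ranked = np.argsort(-power, kind="stable")

    if metric == "power":
        if total_power <= 0:
            return 0
        captured = np.cumsum(power[ranked]) / total_power
        hit = np.flatnonzero(captured >= accuracy * (1.0 - 1e-12))
        if hit.size == 0:
            raise RuntimeError(
                "full spectrum failed to reach the requested accuracy; "
                "modal and direct routes disagree beyond tolerance"
            )
        return int(hit[0]) + 1

    tol = (1.0 - accuracy) * np.linalg.norm(q_ref)
    recon = baseline
    if np.linalg.norm(recon - q_ref) <= tol:
        return 0
    for m, k in enumerate(ranked, start=1):
        recon = recon + contrib[:, k]
        if np.linalg.norm(recon - q_ref) <= tol:
            return m
    raise RuntimeError(
        "full spectrum failed to reach the requested accuracy; "
        "direct and modal routes disagree beyond tolerance"
    )
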