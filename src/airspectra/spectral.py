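"""Shared spectral containers and truncation diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralDecomposition", "inverse_truncation_discrepancy"]


@dataclass
class SpectralDecomposition:
    """Ordered eigenvalue/eigenvector set of one of the tree operators.

    ``operator`` tags the source ("laplacian" or "maury").  Laplacian modes
    are stored ascending in eigenvalue, Maury modes descending (the
    conventional orderings for each).  Eigenvector columns are orthonormal.
    """

    operator: str
    eigenvalues: np.ndarray  # (k,)
    eigenvectors: np.ndarray  # (dim, k), orthonormal columns
    n_total: int  # full dimension of the operator

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def is_complete(self) -> bool:
        return self.n_modes == self.n_total

    def require_complete(self) -> None:
        if not self.is_complete:
            raise ValueError(
                f"operation requires the full spectrum "
                f"({self.n_modes}/{self.n_total} modes available)"
            )


def inverse_truncation_discrepancy(
    kept: np.ndarray, all_eigenvalues: np.ndarray
) -> float:
    """Normalized Frobenius distance between an SPD operator's inverse and its
    truncated spectral reconstruction.

    For kept eigenvalues K out of the full set E this is
    ``|| A^-1 - sum_{k in K} 1/k v v^T ||_F / || A^-1 ||_F``
    which by orthonormality reduces to
    ``sqrt(1 - sum_K lambda^-2 / sum_E lambda^-2)``.
    """
    total = float(np.sum(np.asarray(all_eigenvalues, dtype=float) ** -2))
    part = float(np.sum(np.asarray(kept, dtype=float) ** -2))
    return float(np.sqrt(max(0.0, 1.0 - part / total)))
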