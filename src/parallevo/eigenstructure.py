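"""Eigenanalysis of the inter-lineage correlation and inter-trait matrices.

Two dual decompositions of the same standardized data Z (n unit rows in p
trait dimensions):

* C = Z Z^T = U L U^T — the n x n inter-lineage correlation matrix, whose
  eigenvalues l_i measure concentration of the lineages' directions;
* A = Z^T Z = V K V^T — the p x p inter-trait cross-product matrix, whose
  eigenvectors V live in trait space and whose row projections Z V ordinate
  the change vectors.

The nonzero eigenvalues of C and A coincide, both traces equal n, and the
eigenvalue dispersion obeys the identity

    sum_i (l_i - lbar)^2 = sum_i (k_i - kbar)^2 + n^2/p - n
                         = 2 * sum_{i<j} r_ij^2,

linking spectral dispersion to the sum of squared pairwise vector
correlations — the statistic of the high-dimensional uniformity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectories import CorrelationMatrix, UnitTrajectorySet

__all__ = [
    "EigenResult",
    "eigen_C",
    "eigen_A",
    "eigenvalue_dispersion",
    "sum_squared_correlations",
]


@dataclass
class EigenResult:
    """Sorted eigendecomposition of C (lineage side) or A (trait side).

    ``scores`` (trait side only) are the projections Z V of the unit change
    vectors onto the trait-space eigenvectors, i.e. the PC scores used for
    ordination.
    """

    source: str  # "lineage_correlation_C" | "trait_crossproduct_A"
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns
    labels: list  # lineage ids (C) or trait names (A)
    scores: np.ndarray | None = None
    score_labels: list | None = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("eigenvalues must be sorted nonincreasing")
        if np.any(lam < -1e-10):
            raise ValueError("matrix not PSD: negative eigenvalue beyond tolerance")
        self.eigenvalues = np.clip(lam, 0.0, None)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _sorted_eigh(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    # polarity convention: largest-|element| entry of each eigenvector positive
    idx = np.argmax(np.abs(vec), axis=0)
    signs = np.sign(vec[idx, np.arange(vec.shape[1])])
    signs[signs == 0] = 1.0
    return lam, vec * signs


def eigen_C(cm: CorrelationMatrix) -> EigenResult:
    """Spectral decomposition of the inter-lineage correlation matrix."""
    lam, vec = _sorted_eigh(cm.C)
    return EigenResult(source="lineage_correlation_C", eigenvalues=lam,
                       eigenvectors=vec, labels=list(cm.lineage_ids))


def eigen_A(uz: UnitTrajectorySet) -> EigenResult:
    """Decomposition of the inter-trait cross-product A = Z^T Z, with scores.

    At most min(n, p) eigenvalues are nonzero; they equal the nonzero
    eigenvalues of C.  Scores Z V place the n change vectors in the
    trait-space principal axes for ordination.
    """
    A = uz.Z.T @ uz.Z
    lam, vec = _sorted_eigh(A)
    return EigenResult(source="trait_crossproduct_A", eigenvalues=lam,
                       eigenvectors=vec, labels=list(uz.trait_names),
                       scores=uz.Z @ vec, score_labels=list(uz.lineage_ids))


def eigenvalue_dispersion(er: EigenResult) -> float:
    """Sum of squared deviations of the eigenvalues from their mean.

    The mean is over all n (lineage side) or p (trait side) eigenvalues,
    zeros included.  Zero for C = I (perfect uniformity of eigenvalues);
    maximal when all change vectors align.
    """
    lam = er.eigenvalues
    return float(np.sum((lam - lam.mean()) ** 2))


def sum_squared_correlations(cm: CorrelationMatrix) -> float:
    """Sum of squared off-diagonal correlations over unordered pairs.

    Equals half the eigenvalue dispersion of C; the Schott test statistic.
    """
    C = cm.C
    return float((np.sum(C * C) - cm.n) / 2.0)
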