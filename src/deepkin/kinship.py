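"""Genetic relationship matrix and moment-based relatedness scores.

The relatedness score ``theta`` between two individuals is twice the
kinship coefficient: 1 for monozygotic twins, 0.5 for first-degree
relatives, (1/2)^t for t-th-degree relatives, ~0 for unrelated pairs.

Two moment estimators are provided:

* ``deepkin_theta`` — per-locus standardized squared difference,
  theta_D = 1 - (1/(2m)) * sum_l (x~_il - x~_jl)^2, which decomposes
  into GRM elements as 1 - (g_ii + g_jj - 2 g_ij)/2 and is therefore
  computed in a single O(n^2 m) GRM pass.
* ``king_homo_theta`` — the homogeneous-population estimator that pools
  the 2pq scaling across loci instead of scaling per locus.

When all loci share the same allele frequency the two coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .genio import StandardizedMatrix

__all__ = [
    "GRM",
    "PairEstimate",
    "compute_grm",
    "deepkin_theta",
    "king_homo_theta",
    "pairwise_scan",
    "pair_thetas",
]


@dataclass
class GRM:
    """Symmetric n x n genetic relationship matrix g_ij = (1/m) x~_i . x~_j."""

    values: np.ndarray
    m: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """The n(n-1)/2 upper-triangle entries in row-major (i<j) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class PairEstimate:
    """Relatedness estimate for one sample pair (annotated downstream)."""

    i: str
    j: str
    theta_D: float
    theta_K: float | None = None
    Z: float | None = None
    p: float | None = None
    degree: int | str | None = None


def compute_grm(X: StandardizedMatrix, chunk_size: int | None = None) -> GRM:
    """GRM from standardized genotypes; optionally accumulated in locus chunks.

    Chunked accumulation gives the same result as the one-shot product up
    to floating-point reordering (<= 1e-10 relative) and bounds peak
    memory when m is large.
    """
    A = X.X
    if not np.all(np.isfinite(A)):
        raise ValueError("standardized genotypes contain non-finite entries")
    n, m = A.shape
    if m < 1:
        raise ValueError("need at least one locus")
    if chunk_size is None or chunk_size >= m:
        K = A @ A.T
    else:
        K = np.zeros((n, n))
        for start in range(0, m, chunk_size):
            B = A[:, start : start + chunk_size]
            K += B @ B.T
    K /= m
    # enforce exact symmetry against BLAS rounding asymmetries
    K = (K + K.T) / 2.0
    return GRM(values=K, m=m)


def deepkin_theta(gii: float, gjj: float, gij: float) -> float:
    """Relatedness score from three GRM elements of the same matrix.

    May be negative: sampling variance, but possibly also diversity
    between the two samples relative to the cohort.
    """
    return 1.0 - (gii + gjj - 2.0 * gij) / 2.0


def king_homo_theta(
    xi: np.ndarray, xj: np.ndarray, p: np.ndarray
) -> float:
    """Homogeneous-population moment estimator on raw genotype counts.

    theta_K = 1 - (1/2) * sum_l (x_il - x_jl)^2 / sum_l 2 p_l (1 - p_l).
    """
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if not (xi.shape == xj.shape == p.shape):
        raise ValueError("xi, xj and p must have equal length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic locus: p must lie strictly in (0, 1)")
    denom = np.sum(2.0 * p * (1.0 - p))
    return 1.0 - 0.5 * np.sum((xi - xj) ** 2) / denom


def pair_thetas(grm: GRM) -> np.ndarray:
    """theta_D for all n(n-1)/2 pairs in row-major (i<j) order."""
    d = np.diag(grm.values)
    iu = np.triu_indices(grm.n, k=1)
    return 1.0 - (d[iu[0]] + d[iu[1]] - 2.0 * grm.values[iu]) / 2.0


def pairwise_scan(
    X: StandardizedMatrix,
    samples: list[str] | None = None,
    threshold: float = -np.inf,
    block_size: int = 1024,
) -> Iterator[PairEstimate]:
    """Stream theta_D for all pairs i<j in deterministic row-major order.

    Pairs with ``theta_D <= threshold`` are suppressed so biobank-style
    scans need not materialize every pair.  Rows are processed in blocks
    against the full matrix, so memory stays O(block_size * n).
    """
    A = X.X
    n, m = A.shape
    if n < 2:
        raise ValueError("need at least two samples")
    ids = samples if samples is not None else [str(k) for k in range(n)]
    diag = np.einsum("ij,ij->i", A, A) / m
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = A[start:stop] @ A.T / m
        for bi, i in enumerate(range(start, stop)):
            row = 1.0 - (diag[i] + diag[i + 1 :] - 2.0 * block[bi, i + 1 :]) / 2.0
            for off in np.flatnonzero(row > threshold):
                j = i + 1 + off
                yield PairEstimate(i=ids[i], j=ids[j], theta_D=float(row[off]))
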