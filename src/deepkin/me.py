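"""Effective number of markers (me) under linkage disequilibrium.

``me = m^2 / sum_{l1,l2} rho^2`` summarizes the panel's global LD as the
equivalent number of independent markers; it controls the sampling
variance of the relatedness score, var(theta) = 2 (1 - theta)^2 / me.

Three estimators:

* ``me_direct``     — the definition, summing all squared locus-pair
                      correlations; O(n m^2), used mainly as an oracle.
* ``me_grm``        — 1 / var(off-diagonal GRM) on unrelated samples;
                      O(n^2 m).
* ``me_randomized`` — Girard-Hutchinson randomized trace of GRM^2,
                      matrix-free; O(n m B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import StandardizedMatrix
from .kinship import GRM

__all__ = ["MeEstimate", "me_direct", "me_grm", "me_randomized"]


@dataclass
class MeEstimate:
    """Effective marker count with method tag and sampling SD."""

    value: float
    method: str
    sd: float | None = None
    m: int | None = None
    n: int | None = None
    B: int | None = None
    sigma_LB: float | None = None


def me_direct(
    X: StandardizedMatrix, bias_correct: bool = True, max_m: int = 20_000
) -> MeEstimate:
    """me from all pairwise squared correlations of the genotype columns.

    With ``bias_correct`` each off-diagonal r^2 is replaced by
    ``r^2 - (1 - r^2)/(n - 2)``, the usual finite-sample correction;
    without it the ~1/n inflation of every r-hat^2 visibly understates
    me once m^2/n is large.
    """
    n, m = X.n, X.m
    if m > max_m:
        raise ValueError(
            f"m={m} exceeds the O(n m^2) guard ({max_m}); "
            "use me_randomized or me_grm instead"
        )
    R2 = np.corrcoef(X.X, rowvar=False) ** 2
    if bias_correct and n > 2:
        off = ~np.eye(m, dtype=bool)
        R2[off] = R2[off] - (1.0 - R2[off]) / (n - 2)
    total = float(R2.sum())
    return MeEstimate(value=m * m / total, method="direct", m=m, n=n)


def me_grm(grm: GRM) -> MeEstimate:
    """me = 1 / var(G_off) from off-diagonal GRM entries.

    Assumes the samples are unrelated; related pairs inflate the
    off-diagonal variance and bias me downward.  The variance uses the
    population divisor (the number of off-diagonal entries), which is
    indistinguishable from the sample divisor at the n(n-1)/2 sizes
    involved.  Sampling SD of the estimate is 2 me / n.
    """
    if grm.n < 3:
        raise ValueError("need n >= 3 samples (at least 3 off-diagonals)")
    off = grm.off_diagonal()
    if np.all(off == off[0]):
        raise ValueError("off-diagonal GRM variance is zero (degenerate input)")
    var = float(np.var(off))
    value = 1.0 / var
    return MeEstimate(
        value=value, method="grm", sd=2.0 * value / grm.n, m=grm.m, n=grm.n
    )


def me_randomized(
    X: StandardizedMatrix,
    B: int = 100,
    seed: int | np.random.Generator | None = None,
) -> MeEstimate:
    """Randomized-trace me estimate, never forming the n x n GRM.

    Draws B standard-normal n-vectors z_b and averages
    L_b = || (X X^T / m) z_b ||^2, an unbiased estimate of tr(GRM^2);
    since E[tr(GRM^2)] = n + n(n+1)/me for unrelated samples, the
    estimate is me = n(n+1)/(L_B - n).  B > 100 is practically
    sufficient.  Cost O(n m B).

    ``sigma_LB`` is the replicate SD of L_b; the reported sampling SD is
    the delta-method value me^2 * sigma_LB / (n^2 sqrt(B)).
    """
    if B < 2:
        raise ValueError("need B >= 2 replicates")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    A = X.X
    n, m = A.shape
    L = np.empty(B)
    for b in range(B):
        z = rng.standard_normal(n)
        w = A @ (A.T @ z) / m  # (X X^T / m) z without forming the GRM
        L[b] = w @ w
    L_B = float(L.mean())
    sigma_LB = float(L.std(ddof=1))
    if L_B <= n:
        raise ValueError(
            "trace estimate L_B <= n: insufficient LD signal or B too small"
        )
    value = n * (n + 1) / (L_B - n)
    sd = value * value * sigma_LB / (n * n * np.sqrt(B))
    return MeEstimate(
        value=value, method="randomized", sd=sd, m=m, n=n, B=B,
        sigma_LB=sigma_LB,
    )
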