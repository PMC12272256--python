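"""Theoretical variances and study-design guidelines.

Two sampling-variance models for the relatedness score:

* single-locus (exact, binomial genotypes, independent loci):
  var per locus = (1-theta)^2/2 + (1-theta)/(4 p q);
* multiple-loci (asymptotic, LD-aware):
  var = 2 (1-theta)^2 / me.

Two design guidelines follow from the multiple-loci model:

* Guideline I (``minimum_me``): the smallest effective number of markers
  able to separate t-th-degree relatives from unrelated pairs at error
  rates (alpha, beta);
* Guideline II (``power``): the detection power achieved by a given me.

The two are exact inverses of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "single_locus_table",
    "variance_single_locus",
    "variance_multi",
    "minimum_me",
    "minimum_me_exact",
    "markers_for_target",
    "power",
]


@dataclass
class DesignSpec:
    """Error rates and target degree for a relatedness scan.

    ``alpha`` is the per-test rate; with ``n_comparisons`` set, the
    Bonferroni experiment-wise rate alpha/N is used throughout.
    """

    alpha: float = 0.05
    beta: float = 0.1
    n_comparisons: int | None = None
    t: float = 3.0

    @property
    def alpha_effective(self) -> float:
        if self.n_comparisons:
            return self.alpha / self.n_comparisons
        return self.alpha

    @property
    def theta_t(self) -> float:
        return 2.0 ** (-self.t)


def single_locus_table(
    theta: float, p: float
) -> tuple[np.ndarray, np.ndarray]:
    """Six genotype-pair classes under the single-locus allele-sharing model.

    Each allele of the second individual copies the first individual's
    corresponding allele with probability theta, otherwise it is an
    independent Bernoulli(p) draw.  Returns (probabilities f_i, scores
    X_i) for the unordered genotype pairs {2,2},{1,1},{0,0},{2,1},{1,0},
    {2,0}; sum f_i = 1 and sum f_i X_i = theta.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    q = 1.0 - p
    f = np.array(
        [
            (theta * p + (1 - theta) * p * p) ** 2,
            4 * (1 - theta) ** 2 * p * p * q * q + 2 * theta * p * q,
            (theta * q + (1 - theta) * q * q) ** 2,
            4 * theta * (1 - theta) * p * p * q + 4 * (1 - theta) ** 2 * p**3 * q,
            4 * theta * (1 - theta) * p * q * q + 4 * (1 - theta) ** 2 * p * q**3,
            2 * (1 - theta) ** 2 * p * p * q * q,
        ]
    )
    x = np.array(
        [
            1.0,
            1.0,
            1.0,
            (4 * p * q - 1) / (4 * p * q),
            (4 * p * q - 1) / (4 * p * q),
            (p * q - 1) / (p * q),
        ]
    )
    return f, x


def variance_single_locus(theta: float, p: float) -> float:
    """Exact per-locus sampling variance (1-theta)^2/2 + (1-theta)/(4pq)."""
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    q = 1.0 - p
    return 0.5 * (1 - theta) ** 2 + (1 - theta) / (4 * p * q)


def variance_multi(theta: float, me: float) -> float:
    """Asymptotic LD-aware sampling variance 2 (1-theta)^2 / me."""
    if me <= 0:
        raise ValueError("me must be positive")
    return 2.0 * (1.0 - theta) ** 2 / me


def minimum_me_exact(alpha: float, beta: float, t: float) -> float:
    """Unrounded Guideline-I minimum: 2 [(z_{1-a} + z_{1-b}(1-th))/th]^2.

    z_{1-beta} is the (1-beta) standard-normal quantile (1.2816 for
    beta = 0.1), the value consistent with the guideline's inversion by
    the power formula.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    theta = 2.0 ** (-t)
    z_a = float(norm.isf(alpha))
    z_b = float(norm.isf(beta))
    return 2.0 * ((z_a + z_b * (1.0 - theta)) / theta) ** 2


def minimum_me(alpha: float, beta: float, t: float) -> int:
    """Guideline I: minimum effective marker count, as an integer ceiling."""
    return math.ceil(minimum_me_exact(alpha, beta, t))


def markers_for_target(alpha: float, beta: float, t: float) -> int:
    """Simulated-marker budget 3x the Guideline-I minimum, as an integer.

    Low-LD panels realize me/m just below 1, so a 3x margin comfortably
    guarantees the realized me of a simulated panel meets the minimum.
    """
    return round(3.0 * minimum_me_exact(alpha, beta, t))


def power(me: float, alpha: float, t: float) -> float:
    """Guideline II: power to detect t-th-degree relatives.

    pi = Phi( (sqrt(me/2) theta_t - z_{1-alpha}) / (1 - theta_t) ),
    i.e. the probability that theta_hat ~ N(theta_t, 2(1-theta_t)^2/me)
    exceeds the critical score z_{1-alpha} sqrt(2/me).  Inverse of
    Guideline I: power(minimum_me_exact(a, b, t), a, t) = 1 - b.
    """
    if me <= 0:
        raise ValueError("me must be positive")
    theta = 2.0 ** (-t)
    z_a = float(norm.isf(alpha))
    if theta == 1.0:
        # duplicates: zero variance under the alternative, so detection is
        # certain iff theta = 1 exceeds the critical score
        return 1.0 if math.sqrt(me / 2.0) > z_a else 0.0
    return float(norm.cdf((math.sqrt(me / 2.0) * theta - z_a) / (1.0 - theta)))
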