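"""Statistical inference on relatedness scores.

Given an estimated relatedness theta and the panel's effective number of
markers me, the null (unrelated) distribution of theta is N(0, 2/me), so
each pair gets a Z score and an upper-tail p-value; the data-specific
critical score theta_delta = z_{1-alpha} sqrt(2/me) is the *deepest
significant relatedness*, and delta = log_{1/2}(theta_delta) the deepest
degree the data can distinguish from unrelatedness.

Significant pairs are classified into discrete degrees by the crossover
boundaries where the two adjacent-degree z-tests (null
N(theta_t, 2(1-theta_t)^2/me)) give equal p-values; the boundary is
independent of me.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "DeepestResult",
    "DegreeAssignment",
    "relatedness_pvalue",
    "deepest_significant",
    "degree_boundary",
    "classification_pvalues",
    "classify",
]

#: Pseudo-degree used for the duplicate/first-degree split: the crossover
#: is undefined at theta = 1 (zero variance), so the boundary is taken at
#: t = 0.1, giving 0.881.
DEGREE_ZERO_T = 0.1


@dataclass
class DeepestResult:
    """Deepest significant relatedness supported by the data."""

    theta_delta: float
    delta: float
    alpha: float
    me: float
    delta_ci: tuple[float, float] | None = None


@dataclass
class DegreeAssignment:
    """Degree call for one pair (``degree`` is int or 'insignificant')."""

    degree: int | str
    p_upper: float
    p_t: float | None = None
    p_t1: float | None = None
    boundary_used: float | None = None


def relatedness_pvalue(theta_hat: float, me: float) -> tuple[float, float]:
    """Z score and upper-tail p-value against the unrelated null.

    Z = theta_hat * sqrt(me/2) ~ N(0,1) under unrelatedness; the p-value
    uses the survival function, accurate into the far tail (~1e-300).
    """
    if me <= 0:
        raise ValueError("me must be positive")
    Z = theta_hat * math.sqrt(me / 2.0)
    return Z, float(norm.sf(Z))


def deepest_significant(
    me: float, alpha: float, me_sd: float | None = None
) -> DeepestResult:
    """Critical relatedness theta_delta and deepest degree delta.

    theta_delta = z_{1-alpha} sqrt(2/me); delta = log_{1/2}(theta_delta).
    When ``me_sd`` is given, a 95% CI for delta is propagated through
    delta's derivative in log me (d delta/d ln me = 1/(2 ln 2)).
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if me <= 0:
        raise ValueError("me must be positive")
    z = float(norm.isf(alpha))
    theta_delta = z * math.sqrt(2.0 / me)
    delta = math.log(theta_delta) / math.log(0.5)
    ci = None
    if me_sd is not None:
        half = 1.96 * me_sd / me / (2.0 * math.log(2.0))
        ci = (delta - half, delta + half)
    return DeepestResult(
        theta_delta=theta_delta, delta=delta, alpha=alpha, me=me, delta_ci=ci
    )


def degree_boundary(t: float) -> float:
    """Variance-based crossover boundary between degrees t and t+1.

    With a = 2^(-t) the two adjacent-degree z-tests are equal at
    a (3 - 2a) / (4 - 3a); strictly decreasing in t.  For the degree-0
    versus degree-1 split call with t = DEGREE_ZERO_T (0.881).
    """
    if t <= 0:
        raise ValueError("t must be positive (use DEGREE_ZERO_T for the 0/1 split)")
    a = 2.0 ** (-t)
    return a * (3.0 - 2.0 * a) / (4.0 - 3.0 * a)


def classification_pvalues(
    theta_x: float, t: float, me: float
) -> tuple[float, float]:
    """One-sided p-values of theta_x against degrees t and t+1.

    Each null is N(theta_t, 2 (1 - theta_t)^2 / me) with
    theta_t = 2^(-t); the statistic uses the absolute deviation, as for
    significant pairs lying between the two expectations both readings
    agree.  Degree t = 0 (theta_t = 1, zero variance) is handled by the
    t = DEGREE_ZERO_T convention.
    """
    if me <= 0:
        raise ValueError("me must be positive")

    def one(t_eff: float) -> float:
        theta_t = 2.0 ** (-t_eff)
        sd = (1.0 - theta_t) * math.sqrt(2.0 / me)
        return float(norm.sf(abs(theta_x - theta_t) / sd))

    t_eff = DEGREE_ZERO_T if t == 0 else t
    return one(t_eff), one(t + 1)


def classify(theta_hat: float, me: float, alpha: float) -> DegreeAssignment:
    """Assign a pair to a discrete degree of relatedness.

    A pair is 'insignificant' unless its upper-tail p-value beats alpha
    (a negative theta_hat can therefore never be significant).  A
    significant pair is assigned the degree whose boundary interval
    contains theta_hat: degree 0 above 0.881, else the smallest t >= 1
    with degree_boundary(t) < theta_hat.  Degrees are unbounded above;
    callers may flag degrees beyond floor(delta) as deeper than the
    data's supported depth.
    """
    Z, p_upper = relatedness_pvalue(theta_hat, me)
    if not p_upper < alpha:
        return DegreeAssignment(degree="insignificant", p_upper=p_upper)
    if theta_hat > degree_boundary(DEGREE_ZERO_T):
        p_t, p_t1 = classification_pvalues(theta_hat, 0, me)
        return DegreeAssignment(
            degree=0, p_upper=p_upper, p_t=p_t, p_t1=p_t1,
            boundary_used=degree_boundary(DEGREE_ZERO_T),
        )
    t = 1
    while theta_hat <= degree_boundary(t):
        t += 1
    p_t, p_t1 = classification_pvalues(theta_hat, t, me)
    return DegreeAssignment(
        degree=t, p_upper=p_upper, p_t=p_t, p_t1=p_t1,
        boundary_used=degree_boundary(t),
    )
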