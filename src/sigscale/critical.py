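"""Critical-point analysis of partition transitions on community-loop networks.

A community-loop configuration places ``r`` equal communities of ``n_c``
vertices on a ring; vertex pairs inside a community link with probability
``p_i`` and pairs spanning ring-adjacent communities with probability ``p_o``.
Merging ``x`` adjacent communities yields expectation-level Significance

    S_x = (r/x) * C(x*n_c, 2) * D(p_x || p),   p_x = (p_i*x + 2(x-1)*p_o)/x^2,

with global density p = (p_i + 2 p_o)/r.  Solving the x=1 -> x=2 transition
gives the closed-form critical community number

    r* = gamma * (p_i + 2 p_o) * exp[(2 H(p_2) - H(p_1)) / (2 p_2 - p_1)],

with p_1 = p_i and p_2 = (p_i + p_o)/2; the Modularity analogue is
r* = gamma * (p_i + 2 p_o)/p_o = gamma=1 -> p_i/p_o + 2.  Above r* merging
adjacent pairs raises the measure (resolution limit); below it the planted
partition is preferred.  Both critical numbers scale exactly linearly in the
resolution parameter gamma.

:func:`numeric_critical_r` locates the transition without the closed form's
large-r / large-n_c approximations: it uses the exact expected edge counts of
the finite generator model (C(n_c,2) internal Bernoulli pairs per community,
n_c^2 spanning pairs per adjacent community pair) and root-finds the exact
merge condition

    C(2 n_c, 2) D(p_2 || gamma p(r)) - 2 C(n_c, 2) D(p_1 || gamma p(r)) = 0.

:func:`potential_well_profile` evaluates the score along the merge path with k
pairs merged; for Significance it is affine in k (no potential well), so greedy
merging is never trapped between the two end partitions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quality import ResolutionError, bernoulli_kl, binary_entropy

__all__ = [
    "LoopParams",
    "CriticalResult",
    "loop_significance",
    "critical_r_significance",
    "critical_r_modularity",
    "numeric_critical_r",
    "potential_well_profile",
    "phase_diagram",
]


@dataclass(frozen=True)
class LoopParams:
    """Community-loop configuration (r communities of n_c vertices on a ring)."""

    r: int
    n_c: int
    p_i: float
    p_o: float

    def __post_init__(self) -> None:
        if self.r < 3:
            raise ValueError("a loop needs r >= 3 communities")
        if self.n_c < 2:
            raise ValueError("communities need n_c >= 2 vertices")
        if not 0.0 < self.p_i <= 1.0:
            raise ValueError("p_i must lie in (0, 1]")
        if not 0.0 <= self.p_o <= 1.0:
            raise ValueError("p_o must lie in [0, 1]")
        if not 0.0 < self.global_density < 1.0:
            raise ValueError("global density (p_i + 2 p_o)/r must lie in (0, 1)")

    @property
    def global_density(self) -> float:
        return (self.p_i + 2.0 * self.p_o) / self.r


@dataclass(frozen=True)
class CriticalResult:
    """Critical community number for one measure at one resolution."""

    r_star: float
    measure: str
    gamma: float
    regime: str | None = None  # 'below'/'above' for a queried r, if any


def loop_significance(params: LoopParams, x: float = 1.0, gamma: float = 1.0) -> float:
    """Expectation-level Significance of the x-merged loop partition, in nats.

    Real-valued ``x`` is accepted for smooth curves; integer ``x`` corresponds
    to actual merge partitions.  ``x = 1`` scores the planted partition.
    """
    if x < 1:
        raise ValueError("merge factor x must be >= 1")
    p = params.global_density
    ptilde = gamma * p
    if ptilde >= 1.0:
        raise ResolutionError(f"gamma*p = {ptilde:.6g} >= 1")
    p_x = (params.p_i * x + 2.0 * (x - 1.0) * params.p_o) / (x * x)
    if not 0.0 <= p_x <= 1.0:
        raise ValueError(f"merged-block density p_x = {p_x:.6g} outside [0, 1]")
    nx_ = x * params.n_c
    pairs = nx_ * (nx_ - 1.0) / 2.0
    return (params.r / x) * pairs * bernoulli_kl(p_x, ptilde)


def critical_r_significance(p_i: float, p_o: float, gamma: float = 1.0) -> CriticalResult:
    """Closed-form critical community number of Significance.

    r*(gamma) = gamma (p_i + 2 p_o) exp[(2H(p_2) - H(p_1)) / (2 p_2 - p_1)]
    with p_1 = p_i, p_2 = (p_i + p_o)/2; note 2 p_2 - p_1 = p_o.
    """
    if not 0.0 < p_i <= 1.0:
        raise ValueError("p_i must lie in (0, 1]")
    if p_o < 0.0 or p_o > 1.0:
        raise ValueError("p_o must lie in [0, 1]")
    p1 = p_i
    p2 = (p_i + p_o) / 2.0
    denom = 2.0 * p2 - p1
    if denom == 0.0:
        raise ZeroDivisionError("2*p_2 - p_1 = p_o = 0: no finite transition")
    r_star = gamma * (p_i + 2.0 * p_o) * math.exp(
        (2.0 * binary_entropy(p2) - binary_entropy(p1)) / denom
    )
    return CriticalResult(r_star, "significance", gamma)


def critical_r_modularity(p_i: float, p_o: float, gamma: float = 1.0) -> CriticalResult:
    """Critical community number of Modularity: gamma (p_i + 2 p_o)/p_o.

    At gamma = 1 this equals the classic p_i/p_o + 2.
    """
    if p_o <= 0.0:
        raise ZeroDivisionError("p_o = 0 gives Modularity infinite resolution")
    return CriticalResult(gamma * (p_i + 2.0 * p_o) / p_o, "modularity", gamma)


def _loop_expectations(p_i: float, p_o: float, n_c: int):
    """Exact expected edge counts of the finite community-loop generator."""
    pairs1 = n_c * (n_c - 1) / 2.0
    pairs2 = 2 * n_c * (2 * n_c - 1) / 2.0
    m_in = p_i * pairs1
    m_btw = p_o * n_c * n_c  # n_c^2 spanning Bernoulli pairs per adjacent pair
    p1 = p_i
    p2 = (2.0 * m_in + m_btw) / pairs2
    return pairs1, pairs2, m_in, m_btw, p1, p2


def numeric_critical_r(
    measure: str,
    p_i: float,
    p_o: float,
    n_c: int,
    gamma: float = 1.0,
    r_max: float = 1e15,
) -> float:
    """Root-find the smallest r > 2 where merging adjacent pairs breaks even.

    Uses exact binomial pair counts (no n_c - 1 ~ n_c or 1 - p ~ 1
    approximations) within the loop model's expectation bookkeeping; the
    closed forms are asymptotic approximations of this root.
    Raises ``LookupError`` if no sign change exists in (2, r_max].
    """
    if measure not in ("significance", "modularity"):
        raise ValueError(f"unknown measure {measure!r}")
    if n_c < 2:
        raise ValueError("n_c must be >= 2")
    pairs1, pairs2, m_in, m_btw, p1, p2 = _loop_expectations(p_i, p_o, n_c)
    if m_btw == 0.0 and measure == "modularity":
        raise ZeroDivisionError("p_o = 0 gives Modularity infinite resolution")

    def p_global(r: float) -> float:
        return r * (m_in + m_btw) / (r * n_c * (r * n_c - 1) / 2.0)

    if measure == "significance":

        def f(r: float) -> float:
            pt = gamma * p_global(r)
            return pairs2 * bernoulli_kl(p2, pt) - 2.0 * pairs1 * bernoulli_kl(p1, pt)

    else:
        d_tot = 2.0 * (m_in + m_btw)  # expected degree sum per community

        def f(r: float) -> float:
            m = r * (m_in + m_btw)
            return m_btw / m - gamma * 2.0 * (d_tot / (2.0 * m)) ** 2

    # start where the rescaled null density is valid
    r_lo = 2.0 + 1e-9
    while r_lo < r_max and gamma * p_global(r_lo) >= 1.0:
        r_lo *= 1.2
    if r_lo >= r_max:
        raise LookupError("no valid r range: gamma*p(r) >= 1 everywhere searched")
    # locate the negative-to-positive crossing: below the transition the
    # planted partition wins (f < 0), above it merging wins (f > 0); at very
    # small r the global density approaches the block densities and f can be
    # positive without describing a merge transition, so skip that region
    from scipy.optimize import brentq

    prev_r, prev_f = r_lo, f(r_lo)
    seen_negative = prev_f < 0.0
    r = r_lo
    while r < r_max:
        r *= 1.3
        fr = f(r)
        if seen_negative and prev_f < 0.0 <= fr:
            return float(brentq(f, prev_r, r, xtol=1e-9, rtol=1e-12))
        seen_negative = seen_negative or fr < 0.0
        prev_r, prev_f = r, fr
    raise LookupError(
        f"no merge transition found in ({r_lo:.3g}, {r_max:.3g}] for {measure}"
    )


def potential_well_profile(
    params: LoopParams, k_values, gamma: float = 1.0
) -> np.ndarray:
    """Score S_2(k) along the merge path with k adjacent pairs merged.

    S_2(k) = (r - 2k) C(n_c,2) D(p_1||p~) + k C(2n_c,2) D(p_2||p~); affine in
    k, so Significance has no potential well between the end partitions.
    """
    ks = np.asarray(k_values, dtype=float)
    if np.any(ks < 0) or np.any(ks > params.r / 2.0):
        raise ValueError("k must lie in [0, r/2]")
    p = params.global_density
    ptilde = gamma * p
    if ptilde >= 1.0:
        raise ResolutionError(f"gamma*p = {ptilde:.6g} >= 1")
    n_c = params.n_c
    pairs1 = n_c * (n_c - 1) / 2.0
    pairs2 = 2 * n_c * (2 * n_c - 1) / 2.0
    p1 = params.p_i
    p2 = (params.p_i + params.p_o) / 2.0
    d1 = bernoulli_kl(p1, ptilde)
    d2 = bernoulli_kl(p2, ptilde)
    return (params.r - 2.0 * ks) * pairs1 * d1 + ks * pairs2 * d2


def phase_diagram(
    ratio_grid,
    p_i: float,
    n_c: int | None = None,
    gamma: float = 1.0,
) -> pd.DataFrame:
    """Critical curves r*(p_o/p_i) for both measures over a ratio grid.

    Returns a DataFrame with columns ``ratio``, ``r_star_significance``,
    ``r_star_modularity`` and, when ``n_c`` is given, numeric transition
    columns from :func:`numeric_critical_r`.
    """
    rows = []
    for ratio in ratio_grid:
        if not 0.0 < ratio <= 1.0:
            raise ValueError("ratios must lie in (0, 1]")
        p_o = ratio * p_i
        row = {
            "ratio": ratio,
            "r_star_significance": critical_r_significance(p_i, p_o, gamma).r_star,
            "r_star_modularity": critical_r_modularity(p_i, p_o, gamma).r_star,
        }
        if n_c is not None:
            row["r_numeric_significance"] = numeric_critical_r(
                "significance", p_i, p_o, n_c, gamma
            )
            row["r_numeric_modularity"] = numeric_critical_r(
                "modularity", p_i, p_o, n_c, gamma
            )
        rows.append(row)
    return pd.DataFrame(rows)
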