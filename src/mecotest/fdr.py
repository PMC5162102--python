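"""False discovery rate control for discrete test statistics.

P-values from a discrete statistic such as a Poisson-binomial tail are not
uniform under the null: each test can only attain a finite set of values,
and pooling many tests with different parameters skews the distribution
towards 1.  Standard step-up procedures remain valid on such p-values but
become needlessly conservative.

The discrete variant implemented here replaces the Benjamini-Hochberg
null-mass estimate ``count * t`` at a candidate threshold ``t`` by the sum
over tests of the *exact* null probability of rejection,

    N(t) = sum_i max{ s in support_i : s <= t }   (0 when no such s),

where ``support_i`` is the set of p-values test ``i`` can attain.  For a
discrete test the null probability of observing a p-value at most ``t`` is
precisely the largest attainable value not exceeding ``t``, so ``N(t)``
never overstates the expected number of null rejections, and because
``N(t) <= count * t`` the resulting q-values are bounded above by the
plain BH q-values (dominance).

Plain BH is also exposed, both as a baseline and for callers who do not
track supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .poibin import PoissonBinomial, pmf_vector

__all__ = [
    "DiscreteSupport",
    "attainable_pvalues",
    "bh_fdr",
    "discrete_fdr",
]


@dataclass(frozen=True)
class DiscreteSupport:
    """Sorted attainable p-values of one discrete test under its null."""

    attainable: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.attainable)
        if not vals:
            raise ValueError("support must be non-empty")
        if any(not 0.0 < v <= 1.0 for v in vals):
            raise ValueError("support values must lie in (0, 1]")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("support must be strictly increasing")
        if vals[-1] != 1.0:
            raise ValueError("largest attainable p-value must be 1.0")
        object.__setattr__(self, "attainable", vals)

    def null_rejection_mass(self, t: float) -> float:
        """Exact null probability of a p-value <= ``t``."""
        arr = np.asarray(self.attainable)
        idx = int(np.searchsorted(arr, t, side="right")) - 1
        return float(arr[idx]) if idx >= 0 else 0.0


def attainable_pvalues(d: PoissonBinomial, direction: str) -> DiscreteSupport:
    """Support of the Poisson-binomial tail test: ``{tail(d, k) : k}``.

    Equivalent to deduplicated cumulative sums of the pmf (lower tail) or
    reverse cumulative sums (upper tail); the value 1 is always attainable
    (at ``k = 0`` for the upper tail, ``k = n`` for the lower).
    """
    if direction not in ("upper", "lower"):
        raise ValueError(f"direction must be 'upper' or 'lower', got {direction!r}")
    pmf = pmf_vector(d)
    if direction == "lower":
        tails = np.cumsum(pmf)
    else:
        tails = np.cumsum(pmf[::-1])
    tails = np.minimum(tails, 1.0)
    tails[-1] = 1.0
    # deduplicate and drop numerically-zero entries (unattainable in double)
    vals = sorted({float(t) for t in tails if t > 0.0})
    return DiscreteSupport(tuple(vals))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Standard Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def discrete_fdr(
    pvalues: Sequence[float], supports: Sequence[DiscreteSupport]
) -> np.ndarray:
    """Step-up q-values using exact discrete null rejection probabilities.

    ``supports[i]`` must be the attainable p-value set of the test that
    produced ``pvalues[i]``.  The q-value of test ``i`` is

        q_i = min over thresholds t >= p_i of  N(t) / #{ j : p_j <= t }

    evaluated at the observed p-values as candidate thresholds, clipped to
    1 and made monotone.  Element-wise ``q <= bh_fdr(pvalues)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(supports) != p.size:
        raise ValueError(
            f"{p.size} p-values but {len(supports)} supports; they must align"
        )
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")

    thresholds = np.unique(p)  # candidate rejection thresholds, ascending
    n_reject = np.searchsorted(np.sort(p), thresholds, side="right").astype(float)

    # accumulate N(t) across tests; supports are often shared between tests
    # (parameter sharing upstream), so group identical supports first
    null_mass = np.zeros(thresholds.size)
    groups: dict[tuple[float, ...], int] = {}
    for s in supports:
        groups[s.attainable] = groups.get(s.attainable, 0) + 1
    for vals, count in groups.items():
        arr = np.asarray(vals)
        idx = np.searchsorted(arr, thresholds, side="right") - 1
        mass = np.where(idx >= 0, arr[np.clip(idx, 0, None)], 0.0)
        null_mass += count * mass

    fdr_at_t = np.minimum(null_mass / n_reject, 1.0)
    # step-up: running minimum from the largest threshold downwards
    step_up = np.minimum.accumulate(fdr_at_t[::-1])[::-1]
    qi = np.searchsorted(thresholds, p, side="left")
    return step_up[qi]
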