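"""Activity-balanced subsetting of a compound pool.

Large bioactivity collections are heavily skewed toward moderate potency.
To obtain a working library with a balanced representation of weak,
moderate and strong hERG blockers, a fixed-size subset is drawn whose
pIC50 histogram follows a normal curve over a stated activity range
(default [2.07, 9.85] log units):

1. records outside the range are excluded;
2. the pool pIC50 mean and standard deviation parameterise a Gaussian;
3. the range is cut into bins (default width 0.5 log units) and each bin
   receives a quota proportional to the Gaussian density at its centre,
   rounded by the largest-remainder method;
4. members are drawn uniformly without replacement within each bin with a
   seeded generator; quota overflow in sparse bins is redistributed to the
   nearest bins that still have spare capacity (with a warning).

The procedure is deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .chem import CompoundRecord

__all__ = ["SubsetSpec", "BalancedSubsetSelector", "balanced_subset", "largest_remainder"]


@dataclass(frozen=True)
class SubsetSpec:
    """Parameters of the Gaussian-balanced subset draw."""

    target_size: int
    bin_width: float = 0.5
    lo: float = 2.07
    hi: float = 9.85
    seed: int = 0

    def __post_init__(self):
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if not self.lo < self.hi:
            raise ValueError("range must satisfy lo < hi")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer seats proportionally to ``weights``.

    Floors of the exact quotas are assigned first; remaining seats go to the
    largest fractional remainders (ties broken by lower bin index).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = total - int(base.sum())
    # stable argsort => ties go to the lower index
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


class BalancedSubsetSelector(BaseEstimator):
    """Draw an activity-balanced subset of compound records.

    Parameters
    ----------
    target_size : int
        Number of records to select.
    bin_width : float
        pIC50 bin width in log units.
    lo, hi : float
        Admissible pIC50 range; records outside are dropped before sampling.
    seed : int
        Seed for the within-bin uniform draws.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_, sd_ : float
        Gaussian parameters estimated from the in-range pool.
    bin_edges_ : ndarray
        Bin boundaries covering [lo, hi].
    quotas_ : ndarray
        Final per-bin quotas after largest-remainder rounding and overflow
        redistribution.
    selected_ : list[CompoundRecord]
        The drawn subset (in pool order).
    """

    def __init__(self, target_size: int = 508, bin_width: float = 0.5,
                 lo: float = 2.07, hi: float = 9.85, seed: int = 0):
        self.target_size = target_size
        self.bin_width = bin_width
        self.lo = lo
        self.hi = hi
        self.seed = seed

    # -- internals ---------------------------------------------------------
    def _edges(self) -> np.ndarray:
        n_bins = max(1, int(math.ceil((self.hi - self.lo) / self.bin_width - 1e-12)))
        edges = self.lo + self.bin_width * np.arange(n_bins + 1)
        edges[-1] = self.hi  # last bin may be narrower
        return edges

    def fit(self, pool: Sequence[CompoundRecord]):
        spec = SubsetSpec(self.target_size, self.bin_width, self.lo, self.hi, self.seed)
        in_range = [r for r in pool if spec.lo <= r.pic50 <= spec.hi]
        if len(in_range) < spec.target_size:
            raise ValueError(
                f"pool too small: {len(in_range)} in-range records for "
                f"target_size {spec.target_size}"
            )
        vals = np.array([r.pic50 for r in in_range])
        self.mean_ = float(vals.mean())
        self.sd_ = float(vals.std(ddof=0)) or (spec.hi - spec.lo) / 4.0
        self.bin_edges_ = self._edges()
        centers = 0.5 * (self.bin_edges_[:-1] + self.bin_edges_[1:])
        density = np.exp(-0.5 * ((centers - self.mean_) / self.sd_) ** 2)

        # right-closed final bin so hi itself is kept
        idx = np.clip(np.searchsorted(self.bin_edges_, vals, side="right") - 1,
                      0, len(centers) - 1)
        capacity = np.bincount(idx, minlength=len(centers))
        quotas = largest_remainder(density, spec.target_size)
        self.quotas_ = _redistribute(quotas, capacity)

        rng = np.random.default_rng(spec.seed)
        chosen: list[int] = []
        # records sorted by id within each bin => draw independent of pool order
        for b in range(len(centers)):
            members = sorted(np.flatnonzero(idx == b),
                             key=lambda i: in_range[i].id)
            take = rng.choice(len(members), size=self.quotas_[b], replace=False)
            chosen.extend(members[t] for t in take)
        chosen_set = set(chosen)
        self.selected_ = [r for i, r in enumerate(in_range) if i in chosen_set]
        return self

    def fit_select(self, pool: Sequence[CompoundRecord]) -> list[CompoundRecord]:
        return self.fit(pool).selected_


def _redistribute(quotas: np.ndarray, capacity: np.ndarray) -> np.ndarray:
    """Cap quotas at bin capacity, pushing overflow to the nearest bins."""
    quotas = quotas.copy()
    overflow = int(np.maximum(quotas - capacity, 0).sum())
    if overflow:
        warnings.warn(
            f"{overflow} quota seats redistributed from under-populated bins",
            stacklevel=2,
        )
    quotas = np.minimum(quotas, capacity)
    while quotas.sum() < capacity.sum() and overflow > 0:
        spare = np.flatnonzero(capacity - quotas > 0)
        if spare.size == 0:
            break
        full = np.flatnonzero(quotas >= capacity)
        # nearest spare bin to any overfull bin; fall back to densest spare
        ref = full if full.size else spare
        dist = np.min(np.abs(spare[:, None] - ref[None, :]), axis=1)
        b = spare[np.argmin(dist, ) ]
        room = int(capacity[b] - quotas[b])
        add = min(room, overflow)
        quotas[b] += add
        overflow -= add
    return quotas


def balanced_subset(pool: Sequence[CompoundRecord], spec: SubsetSpec) -> list[CompoundRecord]:
    """Functional wrapper over :class:`BalancedSubsetSelector`."""
    sel = BalancedSubsetSelector(spec.target_size, spec.bin_width, spec.lo, spec.hi, spec.seed)
    return sel.fit_select(pool)
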