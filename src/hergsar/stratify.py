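"""Heteroatom-stratified activity analysis and representative pair selection.

Compounds are grouped into *strata*: sets sharing the count of one focal
heteroatom (N, O, S or Cl) at a fixed total heteroatom count.  Comparing
strata that differ only in the focal count isolates the association between
that element and potency.  Strata with fewer than five members are dropped
for statistical reliability; when the central pIC50 of two comparable strata
differs by at least ~1 log unit, the pair is flagged and two representative
compounds are pulled out — the weakest blocker of the weaker stratum and the
strongest blocker of the stronger stratum — giving an auditable
matched-pair table of heteroatom effects.

Two comparison modes exist because "comparable" can mean either *same total
heteroatom count* (the default) or *same count of the other heteroatoms*
(total minus focal).  Both median and mean are computed for every stratum;
detection defaults to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .chem import CompoundRecord

__all__ = [
    "Stratum",
    "EffectPair",
    "TrendSummary",
    "HeteroatomEffectAnalysis",
    "build_strata",
    "filter_strata",
    "detect_effects",
    "select_pair",
    "trend_summary",
]

FOCAL_ELEMENTS = ("N", "O", "S", "Cl")


@dataclass
class Stratum:
    """Compounds sharing (focal-element count, total heteroatom count)."""

    focal_element: str
    focal_count: int
    total_heteroatoms: int
    member_ids: list[str]
    member_pic50s: list[float]
    median_pic50: float = field(init=False)
    mean_pic50: float = field(init=False)

    def __post_init__(self):
        if not self.member_ids:
            raise ValueError("stratum must have at least one member")
        if len(self.member_ids) != len(self.member_pic50s):
            raise ValueError("ids and pIC50s must align")
        vals = np.asarray(self.member_pic50s, dtype=float)
        self.median_pic50 = float(np.median(vals))
        self.mean_pic50 = float(vals.mean())

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def other_heteroatoms(self) -> int:
        return self.total_heteroatoms - self.focal_count

    def central(self, statistic: Literal["mean", "median"] = "mean") -> float:
        return self.mean_pic50 if statistic == "mean" else self.median_pic50


@dataclass
class EffectPair:
    """A flagged weak-stratum/strong-stratum comparison plus its extremes."""

    focal_element: str
    total_heteroatoms: int
    weak_stratum: Stratum
    strong_stratum: Stratum
    delta: float
    weak_compound: tuple[str, float]
    strong_compound: tuple[str, float]

    def __post_init__(self):
        if self.strong_compound[1] < self.weak_compound[1]:
            raise ValueError("strong representative is weaker than weak representative")


@dataclass
class TrendSummary:
    """Central pIC50 as a function of focal-element count, with a verdict."""

    focal_element: str
    counts: list[int]
    centrals: list[float]
    spearman_rho: float
    verdict: Literal["increasing", "decreasing", "flat", "non-monotone"]
    turning_point: int | None = None  # focal count at the minimum/maximum


def build_strata(
    compounds: Sequence[CompoundRecord], focal: str
) -> list[Stratum]:
    """Partition compounds by (focal count, total heteroatoms).

    Every compound must carry a heteroatom census and a pIC50.  Strata are
    returned sorted by (total, focal count) for determinism.
    """
    groups: dict[tuple[int, int], list[CompoundRecord]] = {}
    for rec in compounds:
        if rec.census is None:
            raise ValueError(f"{rec.id}: compound has no heteroatom census")
        key = (rec.census.get(focal), rec.census.total)
        groups.setdefault(key, []).append(rec)
    strata = []
    for (fc, tot) in sorted(groups):
        members = sorted(groups[(fc, tot)], key=lambda r: r.id)
        strata.append(
            Stratum(
                focal_element=focal,
                focal_count=fc,
                total_heteroatoms=tot,
                member_ids=[r.id for r in members],
                member_pic50s=[r.pic50 for r in members],
            )
        )
    return strata


def filter_strata(strata: Sequence[Stratum], min_size: int = 5) -> list[Stratum]:
    """Keep only strata with at least ``min_size`` members (order preserved)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [s for s in strata if s.size >= min_size]


def select_pair(weak: Stratum, strong: Stratum) -> tuple[tuple[str, float], tuple[str, float]]:
    """Representative compounds of a flagged stratum pair.

    The weakest blocker (minimum pIC50) is taken from the weaker stratum and
    the strongest blocker (maximum pIC50) from the stronger stratum; ties on
    pIC50 are broken by the lexicographically smallest id.
    """
    for s in (weak, strong):
        if s.size == 0:
            raise ValueError("empty stratum")

    def _argext(s: Stratum, sign: int) -> tuple[str, float]:
        best = min(
            zip(s.member_ids, s.member_pic50s),
            key=lambda iv: (sign * iv[1], iv[0]),
        )
        return best

    return _argext(weak, +1), _argext(strong, -1)


def detect_effects(
    strata: Sequence[Stratum],
    threshold: float = 0.9,
    central: Literal["mean", "median"] = "mean",
    mode: Literal["total", "other"] = "total",
) -> list[EffectPair]:
    """Flag stratum pairs whose central pIC50 differs by >= ``threshold``.

    Strata are compared within groups sharing the same total heteroatom
    count (``mode="total"``, the default) or the same count of non-focal
    heteroatoms (``mode="other"``).  All ordered pairs with differing focal
    counts are examined; for each flagged pair the representative weak and
    strong compounds are selected via :func:`select_pair`.
    """
    elements = {s.focal_element for s in strata}
    if len(elements) > 1:
        raise ValueError(f"strata mix focal elements: {sorted(elements)}")
    groups: dict[int, list[Stratum]] = {}
    for s in strata:
        key = s.total_heteroatoms if mode == "total" else s.other_heteroatoms
        groups.setdefault(key, []).append(s)

    pairs: list[EffectPair] = []
    for key in sorted(groups):
        members = groups[key]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if a.focal_count == b.focal_count:
                    continue
                lo, hi = (a, b) if a.central(central) <= b.central(central) else (b, a)
                delta = hi.central(central) - lo.central(central)
                if delta >= threshold:
                    weak_c, strong_c = select_pair(lo, hi)
                    pairs.append(
                        EffectPair(
                            focal_element=lo.focal_element,
                            total_heteroatoms=key if mode == "total" else lo.total_heteroatoms,
                            weak_stratum=lo,
                            strong_stratum=hi,
                            delta=delta,
                            weak_compound=weak_c,
                            strong_compound=strong_c,
                        )
                    )
    pairs.sort(
        key=lambda p: (
            p.total_heteroatoms,
            p.weak_stratum.focal_count,
            p.strong_stratum.focal_count,
        )
    )
    return pairs


def trend_summary(
    compounds: Sequence[CompoundRecord],
    focal: str,
    min_size: int = 5,
    central: Literal["mean", "median"] = "mean",
    reversal_tol: float = 0.2,
    flat_tol: float = 0.05,
) -> TrendSummary:
    """Central pIC50 per focal-element count, with a monotonicity verdict.

    Members of all qualifying strata (>= ``min_size``) are pooled per focal
    count.  The verdict is "non-monotone" when the curve both falls and
    rises by at least ``reversal_tol`` log units around an interior
    extremum (the turning point is reported); otherwise the sign of the
    Spearman rank correlation between count and central value decides
    between "increasing", "decreasing" and "flat" ("flat" covers a curve
    whose full span is below ``flat_tol``).
    """
    strata = filter_strata(build_strata(compounds, focal), min_size)
    pooled: dict[int, list[float]] = {}
    for s in strata:
        pooled.setdefault(s.focal_count, []).extend(s.member_pic50s)
    if len(pooled) < 2:
        raise ValueError(
            f"need >=2 distinct {focal} counts with qualifying strata, got {len(pooled)}"
        )
    counts = sorted(pooled)
    centrals = [
        float(np.mean(pooled[c]) if central == "mean" else np.median(pooled[c]))
        for c in counts
    ]
    curve = np.asarray(centrals)

    if len(counts) > 1 and curve.max() > curve.min():
        rho = float(spearmanr(counts, centrals).statistic)
    else:
        rho = 0.0
    if np.isnan(rho):
        rho = 0.0

    # U-shape: fall of >= tol before the minimum and rise of >= tol after it
    i_min = int(np.argmin(curve))
    u_amp = min(curve[: i_min + 1].max() - curve[i_min],
                curve[i_min:].max() - curve[i_min])
    # inverted U around the maximum
    i_max = int(np.argmax(curve))
    n_amp = min(curve[i_max] - curve[: i_max + 1].min(),
                curve[i_max] - curve[i_max:].min())

    if max(u_amp, n_amp) >= reversal_tol:
        turning = counts[i_min] if u_amp >= n_amp else counts[i_max]
        verdict = "non-monotone"
    elif curve.max() - curve.min() < flat_tol or rho == 0.0:
        verdict, turning = "flat", None
    else:
        verdict, turning = ("increasing" if rho > 0 else "decreasing"), None

    return TrendSummary(
        focal_element=focal,
        counts=counts,
        centrals=centrals,
        spearman_rho=rho,
        verdict=verdict,
        turning_point=turning,
    )


class HeteroatomEffectAnalysis(BaseEstimator):
    """Full stratified heteroatom-effect analysis over several focal elements.

    Parameters
    ----------
    focal_elements : tuple of str
        Elements whose counts are stratified on (default N, O, S, Cl).
    min_size : int
        Minimum stratum size to enter comparisons.
    threshold : float
        Central-value difference (log units) that flags an effect.
    central : "mean" | "median"
        Central statistic used in detection and trends.
    mode : "total" | "other"
        Quantity held constant when comparing strata.

    Attributes (after :meth:`fit`)
    ------------------------------
    strata_ : dict element -> list[Stratum]         (all strata)
    qualifying_strata_ : dict element -> list[Stratum]  (size-filtered)
    effect_pairs_ : dict element -> list[EffectPair]
    trends_ : dict element -> TrendSummary | None   (None if too few counts)
    """

    def __init__(
        self,
        focal_elements: tuple[str, ...] = FOCAL_ELEMENTS,
        min_size: int = 5,
        threshold: float = 0.9,
        central: Literal["mean", "median"] = "mean",
        mode: Literal["total", "other"] = "total",
        reversal_tol: float = 0.2,
        flat_tol: float = 0.05,
    ):
        self.focal_elements = focal_elements
        self.min_size = min_size
        self.threshold = threshold
        self.central = central
        self.mode = mode
        self.reversal_tol = reversal_tol
        self.flat_tol = flat_tol

    def fit(self, compounds: Sequence[CompoundRecord], y=None):
        self.strata_ = {}
        self.qualifying_strata_ = {}
        self.effect_pairs_ = {}
        self.trends_ = {}
        for el in self.focal_elements:
            strata = build_strata(compounds, el)
            kept = filter_strata(strata, self.min_size)
            self.strata_[el] = strata
            self.qualifying_strata_[el] = kept
            self.effect_pairs_[el] = detect_effects(
                kept, self.threshold, self.central, self.mode
            )
            try:
                self.trends_[el] = trend_summary(
                    compounds, el, self.min_size, self.central,
                    self.reversal_tol, self.flat_tol,
                )
            except ValueError:
                self.trends_[el] = None
        return self
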