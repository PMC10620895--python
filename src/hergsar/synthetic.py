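"""Synthetic hERG-blocker libraries with known, planted heteroatom effects.

Real curated activity sets for this analysis are not redistributable, so
every pipeline stage is exercised on generated libraries in which the
ground truth is known by construction.  Each compound is a heteroatom
composition over {N, O, S, Cl, F} on a saturated acyclic C/H scaffold, and
its mean pIC50 follows an additive planted model:

    pIC50 = base + βO·nO + βS·nS + βCl·nCl + g(nN) + ε,   ε ~ N(0, σ²)

clipped to the activity range [2.07, 9.85].  The defaults plant the
qualitative structure–activity trends the analysis is meant to recover:
oxygen lowers potency (βO = −0.30/atom), chlorine slightly lowers it
(βCl = −0.15), sulfur raises it (βS = +0.35), and nitrogen acts
non-monotonically through g — decreasing from 1 to 3 N, recovering from
3 to 5 N — with unstable behaviour above 5 N modelled as inflated noise.
Fluorine is activity-neutral and serves as composition filler.

The composition law guarantees that the stratum cells the analysis needs
(each focal count at a fixed heteroatom total) hold at least five
compounds; the remainder of the library is sampled uniformly over the
composition ranges observed in practice (totals 4–11, N 0–5, O 0–4,
S 0–1, Cl 0–1, F 0–3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .chem import CompoundRecord, HeteroatomCensus, format_formula, heteroatom_census

__all__ = [
    "EffectParams",
    "planted_response",
    "gen_smiles",
    "gen_library",
    "DesignedComposition",
    "UniformComposition",
    "ELEMENTS",
]

ELEMENTS = ("N", "O", "S", "Cl", "F")

_DEFAULT_G_N = {
    0: 0.0, 1: 0.0, 2: -0.4, 3: -0.8, 4: -0.5, 5: -0.2,
    6: -0.2, 7: -0.2, 8: -0.2,
}


@dataclass(frozen=True)
class EffectParams:
    """Parameters of the planted additive activity model."""

    base: float = 6.0
    beta_O: float = -0.30
    beta_S: float = 0.35
    beta_Cl: float = -0.15
    g_N: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_G_N))
    sigma: float = 0.4
    unstable_n_threshold: int = 5     # nN above this gets inflated noise
    unstable_sigma_factor: float = 3.0
    bounds: tuple[float, float] = (2.07, 9.85)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be ordered")

    def sigma_for(self, n_nitrogen: int) -> float:
        if n_nitrogen > self.unstable_n_threshold:
            return self.sigma * self.unstable_sigma_factor
        return self.sigma


def planted_response(census: HeteroatomCensus, params: EffectParams) -> float:
    """Noise-free mean pIC50 of a composition under the planted model."""
    n_n = census.get("N")
    if n_n not in params.g_N:
        raise ValueError(f"nitrogen count {n_n} outside the g_N domain")
    value = (
        params.base
        + params.beta_O * census.get("O")
        + params.beta_S * census.get("S")
        + params.beta_Cl * census.get("Cl")
        + params.g_N[n_n]
    )
    return float(np.clip(value, *params.bounds))


# ---------------------------------------------------------------------------
# composition laws
# ---------------------------------------------------------------------------

# designed cells: composition {element: count} and member quota at n_ref=1000.
# They populate the stratum contrasts the analysis is meant to detect:
#  - an oxygen series O=0..4 at total 6 (N fixed at 2; F/Cl fill the total),
#  - a nitrogen series N=1..5 at F=3 (plus two unstable high-N cells),
#  - sulfur and chlorine presence/absence cells at matched composition.
_DEFAULT_CELLS: tuple[tuple[dict, int], ...] = (
    ({"N": 2, "O": 0, "F": 3, "Cl": 1}, 50),
    ({"N": 2, "O": 1, "F": 3}, 20),
    ({"N": 2, "O": 2, "F": 2}, 20),
    ({"N": 2, "O": 3, "F": 1}, 20),
    ({"N": 2, "O": 4}, 50),
    ({"N": 1, "F": 3}, 30),
    ({"N": 2, "F": 3}, 30),
    ({"N": 3, "F": 3}, 30),
    ({"N": 4, "F": 3}, 30),
    ({"N": 5, "F": 3}, 30),
    ({"N": 2, "S": 0, "F": 2}, 30),
    ({"N": 2, "S": 1, "F": 2}, 30),
    ({"N": 2, "Cl": 0, "F": 2}, 50),
    ({"N": 2, "Cl": 1, "F": 2}, 50),
)

_RANGES = {"N": 5, "O": 4, "S": 1, "Cl": 1, "F": 3}
_TOTAL_RANGE = (4, 11)


class UniformComposition:
    """Uniform rejection sampling over the composition ranges."""

    def __init__(self, ranges: Mapping[str, int] = _RANGES,
                 total_range: tuple[int, int] = _TOTAL_RANGE):
        self.ranges = dict(ranges)
        self.total_range = total_range

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.total_range
        out = np.empty((0, len(ELEMENTS)), dtype=int)
        while len(out) < n:
            draw = np.column_stack(
                [rng.integers(0, self.ranges[e] + 1, size=4 * n) for e in ELEMENTS]
            )
            totals = draw.sum(axis=1)
            out = np.vstack([out, draw[(totals >= lo) & (totals <= hi)]])
        return out[:n]


class DesignedComposition:
    """Designed stratum cells plus uniform background.

    Cell quotas are stated at a reference library size (default 1000) and
    scaled proportionally for other sizes, never below five members per
    cell; the remaining budget is uniform background.
    """

    def __init__(self, cells=_DEFAULT_CELLS, n_ref: int = 1000,
                 ranges: Mapping[str, int] = _RANGES,
                 total_range: tuple[int, int] = _TOTAL_RANGE):
        self.cells = tuple(cells)
        self.n_ref = n_ref
        self.background = UniformComposition(ranges, total_range)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        scale = min(1.0, n / self.n_ref)
        quotas = [max(5, int(round(m * scale))) for _, m in self.cells]
        if sum(quotas) > n:
            raise ValueError(
                f"composition law infeasible: designed cells need "
                f"{sum(quotas)} compounds but n={n}"
            )
        rows = []
        for (cell, _), q in zip(self.cells, quotas):
            comp = [cell.get(e, 0) for e in ELEMENTS]
            rows.extend([comp] * q)
        designed = np.asarray(rows, dtype=int)
        bg = self.background.sample(n - len(designed), rng)
        comps = np.vstack([designed, bg]) if len(bg) else designed
        return comps[rng.permutation(len(comps))]


# ---------------------------------------------------------------------------
# structural realisation
# ---------------------------------------------------------------------------

def gen_smiles(
    census: HeteroatomCensus | Mapping[str, int],
    n_carbons: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Acyclic, valence-valid SMILES realising a heteroatom census.

    N, O and S are placed as amine / ether / thioether links in an alkyl
    backbone; F and Cl are attached as substituents.  The parsed census of
    the result equals the input census exactly.
    """
    counts = dict(census.counts) if isinstance(census, HeteroatomCensus) else {
        k: v for k, v in census.items() if v > 0
    }
    unsupported = set(counts) - set(ELEMENTS)
    if unsupported:
        raise ValueError(f"census not realisable: unsupported elements {sorted(unsupported)}")
    n_n, n_o, n_s = counts.get("N", 0), counts.get("O", 0), counts.get("S", 0)
    n_cl, n_f = counts.get("Cl", 0), counts.get("F", 0)
    inserts = ["N"] * n_n + ["O"] * n_o + ["S"] * n_s
    if n_carbons is None:
        n_carbons = max(len(inserts) + 1, n_cl + n_f, 4)
    if n_carbons < max(len(inserts) + 1, n_cl + n_f, 1):
        raise ValueError(
            f"census not realisable with {n_carbons} carbons: "
            f"{len(inserts)} chain heteroatoms and {n_cl + n_f} substituents"
        )
    if rng is not None:
        slots = sorted(rng.choice(n_carbons - 1, size=len(inserts), replace=False)) if inserts else []
        rng.shuffle(inserts)
    else:
        step = max(1, (n_carbons - 1) // max(1, len(inserts)))
        slots = [min(i * step, n_carbons - 2) for i in range(len(inserts))]
        # fall back to consecutive slots if the spread collides
        if len(set(slots)) != len(slots):
            slots = list(range(len(inserts)))
    halogens = ["F"] * n_f + ["Cl"] * n_cl
    insert_at = dict(zip(slots, inserts))

    parts = []
    for c in range(n_carbons):
        parts.append("C")
        if c < len(halogens):
            parts.append(f"({halogens[c]})")
        if c in insert_at:
            parts.append(insert_at[c])
    return "".join(parts)


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def gen_library(
    n: int,
    params: Optional[EffectParams] = None,
    seed: int = 0,
    composition=None,
    with_structures: bool = False,
    return_truth: bool = False,
):
    """Generate a synthetic compound library with planted heteroatom effects.

    Returns a list of :class:`CompoundRecord` (with molecular formulas, and
    SMILES graphs when ``with_structures`` is set).  With ``return_truth``
    the noise-free planted response per compound is returned alongside, for
    test harnesses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or EffectParams()
    composition = composition or DesignedComposition()
    rng = np.random.default_rng(seed)

    comps = composition.sample(n, rng)
    idx = {e: i for i, e in enumerate(ELEMENTS)}
    n_arr = comps[:, idx["N"]]
    missing = set(np.unique(n_arr)) - set(params.g_N)
    if missing:
        raise ValueError(f"nitrogen counts {sorted(missing)} outside the g_N domain")
    g = np.array([params.g_N[k] for k in n_arr])
    mean = (
        params.base
        + params.beta_O * comps[:, idx["O"]]
        + params.beta_S * comps[:, idx["S"]]
        + params.beta_Cl * comps[:, idx["Cl"]]
        + g
    )
    lo, hi = params.bounds
    mean = np.clip(mean, lo, hi)
    sigma = np.where(
        n_arr > params.unstable_n_threshold,
        params.sigma * params.unstable_sigma_factor,
        params.sigma,
    )
    pic50 = np.clip(mean + rng.normal(0.0, 1.0, size=n) * sigma, lo, hi)

    totals = comps.sum(axis=1)
    n_carbons = totals + 4 + rng.integers(0, 12, size=n)

    records: list[CompoundRecord] = []
    for i in range(n):
        counts = {e: int(comps[i, idx[e]]) for e in ELEMENTS if comps[i, idx[e]] > 0}
        nc = int(n_carbons[i])
        nh = 2 * nc + counts.get("N", 0) - counts.get("F", 0) - counts.get("Cl", 0) + 2
        formula_counts = {"C": nc, "H": nh, **counts}
        smiles = None
        if with_structures:
            smiles = gen_smiles(heteroatom_census(counts), n_carbons=nc, rng=rng)
        records.append(
            CompoundRecord(
                id=f"SYN{i:05d}",
                pic50=float(pic50[i]),
                formula=format_formula(formula_counts),
                smiles=smiles,
                ic50=10.0 ** (-float(pic50[i])),
                ic50_unit="M",
            )
        )
    if return_truth:
        truth = {
            "params": params,
            "noiseless": mean.tolist(),
            "compositions": comps.tolist(),
        }
        return records, truth
    return records
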