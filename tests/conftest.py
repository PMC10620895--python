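import numpy as np
import pytest

from hergsar.chem import CompoundRecord
from hergsar.stratify import Stratum


def make_stratum(focal, count, total, mean, size=5, extreme=None, prefix="CPD"):
    """Build a stratum whose member mean is exactly ``mean``.

    ``extreme`` optionally plants a named compound as the minimum (if below
    the mean) or maximum member; the remaining members are placed
    symmetrically so the set mean stays at ``mean``.
    """
    if extreme is None:
        vals = [mean - 0.5, mean - 0.25, mean, mean + 0.25, mean + 0.5]
        ids = [f"{prefix}{i}" for i in range(len(vals))]
    else:
        eid, ev = extreme
        # balance the extreme against four members placed around the mean
        rest_sum = size * mean - ev
        base = rest_sum / (size - 1)
        offsets = [-0.3, -0.1, 0.1, 0.3]
        vals = [ev] + [base + o for o in offsets]
        ids = [eid] + [f"{prefix}{i}" for i in range(size - 1)]
    return Stratum(
        focal_element=focal,
        focal_count=count,
        total_heteroatoms=total,
        member_ids=ids,
        member_pic50s=vals,
    )


@pytest.fixture
def pair1_strata():
    """Two nitrogen strata at total 4 with set means 4.89 / 5.92 and the
    documented extreme compounds planted as min and max."""
    weak = make_stratum("N", 1, 4, 4.89, extreme=("CHEMBL70", 3.00), prefix="W")
    strong = make_stratum("N", 2, 4, 5.92, extreme=("CHEMBL1257821", 9.85), prefix="S")
    return weak, strong


def records_from_compositions(comps, pic50s, prefix="R"):
    """CompoundRecords from (N, O, S, Cl, F) composition tuples."""
    recs = []
    for i, ((n, o, s, cl, f), p) in enumerate(zip(comps, pic50s)):
        nc = 10 + (n + o + s + cl + f)
        nh = 2 * nc + n - f - cl + 2
        parts = [f"C{nc}", f"H{nh}"]
        for sym, cnt in (("Cl", cl), ("F", f), ("N", n), ("O", o), ("S", s)):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        recs.append(
            CompoundRecord(id=f"{prefix}{i:04d}", pic50=float(p), formula="".join(parts))
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
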