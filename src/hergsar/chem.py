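"""Molecular formulas, heteroatom censuses and activity conversions.

The unit of analysis throughout the package is the :class:`CompoundRecord`:
one ligand with an identifier, a structure (a linear molecular formula and/or
an RDKit molecular graph) and a potency given as IC50 against the hERG
channel, standardised to pIC50 = -log10(IC50 in molar).

A *heteroatom census* is the per-element count of every atom that is neither
carbon nor hydrogen (N, O, S, Cl, F, Br, I, P, ...) plus their total; it is
the quantity the stratified activity analysis conditions on.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from rdkit import Chem
from rdkit.rdBase import DisableLog

DisableLog("rdApp.*")  # RDKit warnings go through python warnings instead

__all__ = [
    "FormulaError",
    "HeteroatomCensus",
    "CompoundRecord",
    "parse_formula",
    "format_formula",
    "heteroatom_census",
    "census_from_mol",
    "ic50_to_pic50",
    "mol_from_smiles",
    "read_activity_csv",
]

_PT = Chem.GetPeriodicTable()
_VALID_SYMBOLS = frozenset(_PT.GetElementSymbol(z) for z in range(1, 119))
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# characters that signal a formula dialect we deliberately do not support
_REJECTED = re.compile(r"[()\[\]{}+\-·.*^]")


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a linear Hill-style molecular formula into element counts.

    Only plain element-symbol/count runs are accepted ("C17H19NO3");
    parentheses, hydrate dots, isotope prefixes and charges are rejected
    with an error naming the offending position.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    s = formula.strip()
    bad = _REJECTED.search(s)
    if bad:
        raise FormulaError(
            f"unsupported character {bad.group()!r} at position {bad.start()} "
            f"in {formula!r} (only linear Hill formulas are accepted)"
        )
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed token at position {pos} in {formula!r}")
        sym, num = m.group(1), m.group(2)
        # the token regex only takes a lowercase second letter, so "NO3"
        # tokenises as N, O3 — never as the (invalid) symbol "No"
        if sym not in _VALID_SYMBOLS:
            raise FormulaError(
                f"unknown element symbol {sym!r} at position {pos} in {formula!r}"
            )
        pos = m.end()
        n = int(num) if num else 1
        if n < 1:
            raise FormulaError(f"zero count for {sym} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a Hill-ordered formula (C, H, then alphabetic)."""
    parts = []
    order = [s for s in ("C", "H") if counts.get(s)]
    order += sorted(s for s in counts if s not in ("C", "H") and counts[s])
    for sym in order:
        n = counts[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


@dataclass(frozen=True)
class HeteroatomCensus:
    """Per-element counts of all non-C, non-H atoms plus their total."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self):
        if any(k in ("C", "H") for k in self.counts):
            raise ValueError("census must not contain C or H")
        if self.total != sum(self.counts.values()):
            raise ValueError("census total does not equal sum of counts")

    def get(self, element: str) -> int:
        return self.counts.get(element, 0)


def heteroatom_census(counts: Mapping[str, int]) -> HeteroatomCensus:
    """Census of every non-carbon, non-hydrogen element in ``counts``.

    All heteroatoms count toward the total — including F, Br, I and P —
    even though only N, O, S and Cl are focal elements in the stratified
    analysis.
    """
    het = {k: int(v) for k, v in counts.items() if k not in ("C", "H") and v > 0}
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative element count")
    return HeteroatomCensus(counts=het, total=sum(het.values()))


def census_from_mol(mol: Chem.Mol) -> HeteroatomCensus:
    """Heteroatom census computed from a molecular graph (implicit H)."""
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    return heteroatom_census(counts)


_UNIT_FACTORS = {"nm": 1e-9, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "m": 1.0}


def ic50_to_pic50(value: float, unit: str = "nM") -> float:
    """pIC50 = -log10(IC50 in molar). Units: nM, µM (uM) or M."""
    if not value > 0:
        raise ValueError(f"IC50 must be positive, got {value!r}")
    factor = _UNIT_FACTORS.get(str(unit).strip().lower())
    if factor is None:
        raise ValueError(f"unknown concentration unit {unit!r} (expected nM, µM or M)")
    return -math.log10(value * factor)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule (heavy atoms only)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass
class CompoundRecord:
    """One ligand: identifier, structure and hERG-blocking potency."""

    id: str
    pic50: float
    formula: Optional[str] = None
    smiles: Optional[str] = None
    mol: Optional[Chem.Mol] = field(default=None, repr=False)
    ic50: Optional[float] = None
    ic50_unit: str = "M"
    census: Optional[HeteroatomCensus] = None

    def __post_init__(self):
        if self.ic50 is not None:
            if self.ic50 <= 0:
                raise ValueError(f"{self.id}: IC50 must be positive")
            expected = ic50_to_pic50(self.ic50, self.ic50_unit)
            if abs(expected - self.pic50) > 1e-9:
                raise ValueError(
                    f"{self.id}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50} {self.ic50_unit} (expected {expected})"
                )
        if self.mol is None and self.smiles is not None:
            self.mol = mol_from_smiles(self.smiles)
        if self.census is None:
            self.census = self._compute_census()

    def _compute_census(self) -> Optional[HeteroatomCensus]:
        # graph wins when both are present, but must agree with the formula
        if self.mol is not None:
            cg = census_from_mol(self.mol)
            if self.formula:
                cf = heteroatom_census(parse_formula(self.formula))
                if cg != cf:
                    raise ValueError(
                        f"{self.id}: census from graph {dict(cg.counts)} does not "
                        f"match formula {self.formula!r} ({dict(cf.counts)})"
                    )
            return cg
        if self.formula:
            return heteroatom_census(parse_formula(self.formula))
        return None


_DEDUP_FUNCS = {"median": "median", "mean": "mean", "first": "first"}


def read_activity_csv(
    path,
    dedup: str = "median",
    require_structure: bool = False,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Read a ChEMBL-style activity CSV into compound records.

    Expected columns: ``id``, ``standard_value``, ``standard_units`` and at
    least one of ``smiles`` / ``formula`` (``standard_type`` is carried
    through but not interpreted).  Replicate activities for one id are
    collapsed according to ``dedup`` (median of replicate pIC50s by default).
    Unlabelled units are taken as nM — the ChEMBL standard_value convention —
    with a warning.

    Returns the parsed records and a DataFrame of rejected rows with reasons.
    """
    df = pd.read_csv(path, dtype={"id": str}, comment="#")
    missing = [c for c in ("id", "standard_value") if c not in df.columns]
    if missing:
        raise ValueError(f"activity CSV is missing required columns: {missing}")
    if dedup not in _DEDUP_FUNCS:
        raise ValueError(f"unknown dedup policy {dedup!r}")

    rejects: list[dict] = []
    rows: list[dict] = []
    for _, row in df.iterrows():
        try:
            value = float(row["standard_value"])
            unit = row.get("standard_units")
            if unit is None or (isinstance(unit, float) and math.isnan(unit)) or str(unit).strip() == "":
                warnings.warn(
                    f"{row['id']}: no unit on standard_value; assuming nM", stacklevel=2
                )
                unit = "nM"
            pic50 = ic50_to_pic50(value, str(unit))
            rows.append(
                {
                    "id": str(row["id"]),
                    "pic50": pic50,
                    "smiles": row.get("smiles") if isinstance(row.get("smiles"), str) else None,
                    "formula": row.get("formula") if isinstance(row.get("formula"), str) else None,
                }
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"id": row.get("id"), "reason": str(exc)})

    grouped: dict[str, list[dict]] = {}
    for r in rows:
        grouped.setdefault(r["id"], []).append(r)

    records: list[CompoundRecord] = []
    for cid, reps in grouped.items():
        vals = [r["pic50"] for r in reps]
        if dedup == "median":
            pic50 = float(pd.Series(vals).median())
        elif dedup == "mean":
            pic50 = float(pd.Series(vals).mean())
        else:
            pic50 = vals[0]
        first = reps[0]
        try:
            rec = CompoundRecord(
                id=cid, pic50=pic50, formula=first["formula"], smiles=first["smiles"]
            )
            if require_structure and rec.mol is None and rec.formula is None:
                raise ValueError("no structure (smiles or formula)")
            records.append(rec)
        except ValueError as exc:
            rejects.append({"id": cid, "reason": str(exc)})

    return records, pd.DataFrame(rejects, columns=["id", "reason"])
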