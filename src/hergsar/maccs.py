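"""Public 166-key structural-key fingerprint (MACCS convention).

Each key is a binary indicator that a structural pattern occurs (at least a
stated number of times) in the molecule.  The definitions below follow the
published public MACCS key set; patterns are expressed as SMARTS and matched
with RDKit's substructure engine with unique-atom-set counting.  Three keys
need special handling: 125 (more than one aromatic ring), 101 (a ring of
eight or more members) and 166 (more than one fragment).  Keys 1 (isotope)
and 44 (atom of an "other" element class) are not settable here and always
read 0, matching common open-source renditions of the set.

Keys describing a CH2 chain that may close into a ring (90, 91, 116, 118,
128, 129, 147) are matched in their chain form, and key 101 counts explicit
rings of the smallest-ring set (not fused-ring envelopes); those corner
cases may differ from other toolkits.
"""

from __future__ import annotations

from typing import Optional

from rdkit import Chem

from .fingerprints import Fingerprint

__all__ = ["fp_maccs", "MACCS_DEFS", "N_KEYS"]

N_KEYS = 166

# key number -> (SMARTS or None, minimum match count)
MACCS_DEFS: dict[int, tuple[Optional[str], int]] = {
    1: (None, 0),  # isotope: not settable
    2: ("[#104]", 1),
    3: ("[#32,#33,#34,#50,#51,#52,#82,#83,#84]", 1),
    4: ("[#89,#90,#91,#92,#93,#94,#95,#96,#97,#98,#99,#100,#101,#102,#103]", 1),
    5: ("[Sc,Ti,Y,Zr,Hf]", 1),
    6: ("[La,Ce,Pr,Nd,Pm,Sm,Eu,Gd,Tb,Dy,Ho,Er,Tm,Yb,Lu]", 1),
    7: ("[V,Cr,Mn,Nb,Mo,Tc,Ta,W,Re]", 1),
    8: ("[!#6;!#1]1~*~*~*~1", 1),
    9: ("[Fe,Co,Ni,Ru,Rh,Pd,Os,Ir,Pt]", 1),
    10: ("[Be,Mg,Ca,Sr,Ba,Ra]", 1),
    11: ("*1~*~*~*1", 1),
    12: ("[Cu,Zn,Ag,Cd,Au,Hg]", 1),
    13: ("[#8]~[#7](~[#6])~[#6]", 1),
    14: ("[#16]-[#16]", 1),
    15: ("[#8]~[#6](~[#8])~[#8]", 1),
    16: ("[!#6;!#1]1~*~*1", 1),
    17: ("[#6]#[#6]", 1),
    18: ("[#5,#13,#31,#49,#81]", 1),
    19: ("*1~*~*~*~*~*~*1", 1),
    20: ("[#14]", 1),
    21: ("[#6]=[#6](~[!#6;!#1])~[!#6;!#1]", 1),
    22: ("*1~*~*1", 1),
    23: ("[#7]~[#6](~[#8])~[#8]", 1),
    24: ("[#7]-[#8]", 1),
    25: ("[#7]~[#6](~[#7])~[#7]", 1),
    26: ("[#6]=;@[#6](@*)@*", 1),
    27: ("[#53]", 1),
    28: ("[!#6;!#1]~[CH2]~[!#6;!#1]", 1),
    29: ("[#15]", 1),
    30: ("[#6]~[!#6;!#1](~[#6])(~[#6])~*", 1),
    31: ("[!#6;!#1]~[F,Cl,Br,I]", 1),
    32: ("[#6]~[#16]~[#7]", 1),
    33: ("[#7]~[#16]", 1),
    34: ("[CH2]=*", 1),
    35: ("[Li,Na,K,Rb,Cs,Fr]", 1),
    36: ("[#16;R]", 1),
    37: ("[#7]~[#6](~[#8])~[#7]", 1),
    38: ("[#7]~[#6](~[#6])~[#7]", 1),
    39: ("[#8]~[#16](~[#8])~[#8]", 1),
    40: ("[#16]-[#8]", 1),
    41: ("[#6]#[#7]", 1),
    42: ("[#9]", 1),
    43: ("[!#6;!#1;!H0]~*~[!#6;!#1;!H0]", 1),
    44: (None, 0),  # "other" element class: not settable
    45: ("[#6]=[#6]~[#7]", 1),
    46: ("[#35]", 1),
    47: ("[#16]~*~[#7]", 1),
    48: ("[#8]~[!#6;!#1](~[#8])~[#8]", 1),
    49: ("[!+0]", 1),
    50: ("[#6]=[#6](~[#6])~[#6]", 1),
    51: ("[#6]~[#16]~[#8]", 1),
    52: ("[#7]~[#7]", 1),
    53: ("[!#6;!#1;!H0]~*~*~*~[!#6;!#1;!H0]", 1),
    54: ("[!#6;!#1;!H0]~*~*~[!#6;!#1;!H0]", 1),
    55: ("[#8]~[#16]~[#8]", 1),
    56: ("[#8]~[#7](~[#8])~[#6]", 1),
    57: ("[#8;R]", 1),
    58: ("[!#6;!#1]~[#16]~[!#6;!#1]", 1),
    59: ("[#16]!:*:*", 1),
    60: ("[#16]=[#8]", 1),
    61: ("*~[#16](~*)~*", 1),
    62: ("*@*!@*@*", 1),
    63: ("[#7]=[#8]", 1),
    64: ("*@*!@[#16]", 1),
    65: ("c:n", 1),
    66: ("[#6]~[#6](~[#6])(~[#6])~[!#6;!#1]", 1),
    67: ("[!#6;!#1]~[#16]", 1),
    68: ("[!#6;!#1;!H0]~[!#6;!#1;!H0]", 1),
    69: ("[!#6;!#1]~[!#6;!#1;!H0]", 1),
    70: ("[!#6;!#1]~[#7]~[!#6;!#1]", 1),
    71: ("[#7]~[#8]", 1),
    72: ("[#8]~*~*~[#8]", 1),
    73: ("[#16]=*", 1),
    74: ("[CH3]~*~[CH3]", 1),
    75: ("*!@[#7]@*", 1),
    76: ("[#6]=[#6](~*)~*", 1),
    77: ("[#7]~*~[#7]", 1),
    78: ("[#6]=[#7]", 1),
    79: ("[#7]~*~*~[#7]", 1),
    80: ("[#7]~*~*~*~[#7]", 1),
    81: ("[#16]~*(~*)~*", 1),
    82: ("*~[CH2]~[!#6;!#1;!H0]", 1),
    83: ("[!#6;!#1]1~*~*~*~*1", 1),
    84: ("[NH2]", 1),
    85: ("[#6]~[#7](~[#6])~[#6]", 1),
    86: ("[C;H2,H3][!#6;!#1][C;H2,H3]", 1),
    87: ("[F,Cl,Br,I]!@*@*", 1),
    88: ("[#16]", 1),
    89: ("[#8]~*~*~*~[#8]", 1),
    90: ("[!#6;!#1;!H0]~*~*~[CH2]~*", 1),
    91: ("[!#6;!#1;!H0]~*~*~*~[CH2]~*", 1),
    92: ("[#8]~[#6](~[#7])~[#6]", 1),
    93: ("[!#6;!#1]~[CH3]", 1),
    94: ("[!#6;!#1]~[#7]", 1),
    95: ("[#7]~*~*~[#8]", 1),
    96: ("*1~*~*~*~*1", 1),
    97: ("[#7]~*~*~*~[#8]", 1),
    98: ("[!#6;!#1]1~*~*~*~*~*1", 1),
    99: ("[#6]=[#6]", 1),
    100: ("*~[CH2]~[#7]", 1),
    101: (None, 0),  # ring of >= 8 members: handled in code
    102: ("[!#6;!#1]~[#8]", 1),
    103: ("[#17]", 1),
    104: ("[!#6;!#1;!H0]~*~[CH2]~*", 1),
    105: ("*@*(@*)@*", 1),
    106: ("[!#6;!#1]~*(~[!#6;!#1])~[!#6;!#1]", 1),
    107: ("[F,Cl,Br,I]~*(~*)~*", 1),
    108: ("[CH3]~*~*~*~[CH2]~*", 1),
    109: ("*~[CH2]~[#8]", 1),
    110: ("[#7]~[#6]~[#8]", 1),
    111: ("[#7]~*~[CH2]~*", 1),
    112: ("*~*(~*)(~*)~*", 1),
    113: ("[#8]!:*:*", 1),
    114: ("[CH3]~[CH2]~*", 1),
    115: ("[CH3]~*~[CH2]~*", 1),
    116: ("[CH3]~*~*~[CH2]~*", 1),
    117: ("[#7]~*~[#8]", 1),
    118: ("*~[CH2]~[CH2]~*", 2),
    119: ("[#7]=*", 1),
    120: ("[!#6;R]", 2),
    121: ("[#7;R]", 1),
    122: ("*~[#7](~*)~*", 1),
    123: ("[#8]~[#6]~[#8]", 1),
    124: ("[!#6;!#1]~[!#6;!#1]", 1),
    125: (None, 0),  # more than one aromatic ring: handled in code
    126: ("*!@[#8]!@*", 1),
    127: ("*@*!@[#8]", 2),
    128: ("*~[CH2]~*~*~*~[CH2]~*", 1),
    129: ("*~[CH2]~*~*~[CH2]~*", 1),
    130: ("[!#6;!#1]~[!#6;!#1]", 2),
    131: ("[!#6;!#1;!H0]", 2),
    132: ("[#8]~*~[CH2]~*", 1),
    133: ("*@*!@[#7]", 1),
    134: ("[F,Cl,Br,I]", 1),
    135: ("[#7]!:*:*", 1),
    136: ("[#8]=*", 2),
    137: ("[!C;!c;R]", 1),
    138: ("[!#6;!#1]~[CH2]~*", 2),
    139: ("[O;!H0]", 1),
    140: ("[#8]", 4),
    141: ("[C;H3,H4]", 3),
    142: ("[#7]", 2),
    143: ("*@*!@[#8]", 1),
    144: ("*!:*:*!:*", 1),
    145: ("*1~*~*~*~*~*1", 2),
    146: ("[#8]", 3),
    147: ("*~[CH2]~[CH2]~*", 1),
    148: ("*~[!#6;!#1](~*)~*", 1),
    149: ("[C;H3,H4]", 2),
    150: ("*!@*@*!@*", 1),
    151: ("[#7;!H0]", 1),
    152: ("[#8]~[#6](~[#6])~[#6]", 1),
    153: ("[!#6;!#1]~[CH2]~*", 1),
    154: ("[#6]=[#8]", 1),
    155: ("*!@[CH2]!@*", 1),
    156: ("[#7]~*(~*)~*", 1),
    157: ("[#6]-[#8]", 1),
    158: ("[#6]-[#7]", 1),
    159: ("[#8]", 2),
    160: ("[C;H3,H4]", 1),
    161: ("[#7]", 1),
    162: ("a", 1),
    163: ("*1~*~*~*~*~*1", 1),
    164: ("[#8]", 1),
    165: ("[R]", 1),
    166: (None, 0),  # more than one fragment: handled in code
}

_PATTERNS: dict[int, tuple[Chem.Mol, int]] = {}
for _k, (_smarts, _min) in MACCS_DEFS.items():
    if _smarts is not None:
        _patt = Chem.MolFromSmarts(_smarts)
        if _patt is None:  # pragma: no cover - table is static
            raise RuntimeError(f"invalid SMARTS for key {_k}: {_smarts!r}")
        _PATTERNS[_k] = (_patt, _min)


def _aromatic_ring_count(mol: Chem.Mol) -> int:
    ri = mol.GetRingInfo()
    count = 0
    for ring in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            count += 1
    return count


def fp_maccs(
    mol: Chem.Mol, mol_id: Optional[str] = None, track_atoms: bool = False
) -> Fingerprint:
    """166-key structural-key fingerprint (binary; key k -> feature ``M|k``)."""
    feats: dict[str, int] = {}
    atoms: Optional[dict] = {} if track_atoms else None

    for k, (patt, min_count) in _PATTERNS.items():
        matches = mol.GetSubstructMatches(patt, uniquify=True)
        if len(matches) >= min_count:
            key = f"M|{k:03d}"
            feats[key] = 1
            if atoms is not None:
                atoms[key] = [frozenset(m) for m in matches]

    ri = mol.GetRingInfo()
    if any(len(ring) >= 8 for ring in ri.AtomRings()):
        feats["M|101"] = 1
        if atoms is not None:
            atoms["M|101"] = [
                frozenset(r) for r in ri.AtomRings() if len(r) >= 8
            ]
    if _aromatic_ring_count(mol) > 1:
        feats["M|125"] = 1
        if atoms is not None:
            atoms["M|125"] = [frozenset(range(mol.GetNumAtoms()))]
    if len(Chem.GetMolFrags(mol)) > 1:
        feats["M|166"] = 1
        if atoms is not None:
            atoms["M|166"] = [frozenset(range(mol.GetNumAtoms()))]

    return Fingerprint("maccs", feats, mol_id, atoms)
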