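"""Sparse topological molecular fingerprints built from the molecular graph.

Four substructure-feature families are implemented from scratch on top of
the RDKit graph (heavy atoms only, hydrogens implicit):

- ``atom_pairs``  — one feature per unordered heavy-atom pair, keyed by the
  two atom types and their topological (shortest-path) bond distance;
- ``linear``      — one feature per simple path of 1..max_length bonds,
  keyed by the atom-type/bond-order string read in its lexicographically
  smaller direction;
- ``radial``      — circular environments per atom per radius, built by
  iterated order-independent neighbour-hash combination (Morgan style);
- ``torsions``    — linear paths of exactly four atoms (three bonds).

plus ``maccs`` (166 public structural keys, :mod:`hergsar.maccs`).

Features are kept sparse as key -> count maps; the binary view is the
support.  Keys are canonical strings digested with a fixed-seed BLAKE2b
hash, so fingerprints are stable across runs and platforms.  Atom typing is
``(element, heavy degree, aromatic flag)`` by default; an ``element``-only
mode exists for hand-checkable tests.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import CompoundRecord, mol_from_smiles

__all__ = [
    "Fingerprint",
    "fp_atom_pairs",
    "fp_linear",
    "fp_radial",
    "fp_torsions",
    "fingerprint",
    "fold",
    "FingerprintFeaturizer",
    "SCHEMES",
]

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}

_HASH_SALT = b"hergsar-fp-v1"  # fixed: hash stability across runs/platforms

Typing = Literal["full", "element"]


def _stable_hash(key: str) -> str:
    return hashlib.blake2b(key.encode(), digest_size=8, salt=_HASH_SALT).hexdigest()


def _atom_type(atom: Chem.Atom, typing: Typing) -> str:
    if typing == "element":
        return atom.GetSymbol()
    return f"{atom.GetSymbol()}.{atom.GetDegree()}.{int(atom.GetIsAromatic())}"


def _bond_symbol(bond: Chem.Bond) -> str:
    return _BOND_SYMBOL.get(bond.GetBondType(), "~")


@dataclass
class Fingerprint:
    """Sparse substructure-feature vector of one molecule."""

    scheme: str
    features: dict[str, int]
    mol_id: Optional[str] = None
    # per feature, the atom-index sets of its occurrences (for contributions)
    feature_atoms: Optional[dict[str, list[frozenset[int]]]] = field(
        default=None, repr=False
    )

    def __post_init__(self):
        if any(v < 1 for v in self.features.values()):
            raise ValueError("feature counts must be >= 1")

    @property
    def support(self) -> frozenset[str]:
        """Binary view: the set of present feature keys."""
        return frozenset(self.features)

    def without_atom(self, atom_idx: int) -> "Fingerprint":
        """Drop every feature occurrence whose substructure contains the atom."""
        if self.feature_atoms is None:
            raise ValueError("fingerprint was computed without atom tracking")
        feats: dict[str, int] = {}
        for key, count in self.features.items():
            occs = self.feature_atoms[key]
            kept = sum(1 for occ in occs if atom_idx not in occ)
            if kept:
                feats[key] = kept
        return Fingerprint(self.scheme, feats, self.mol_id)


def _record(feats, atoms, key, occ_atoms):
    feats[key] = feats.get(key, 0) + 1
    if atoms is not None:
        atoms.setdefault(key, []).append(frozenset(occ_atoms))


def fp_atom_pairs(
    mol: Chem.Mol,
    typing: Typing = "full",
    mol_id: Optional[str] = None,
    track_atoms: bool = False,
) -> Fingerprint:
    """Atom-pair fingerprint: (type_i, type_j, topological distance)."""
    n = mol.GetNumAtoms()
    feats: dict[str, int] = {}
    atoms: Optional[dict] = {} if track_atoms else None
    if n > 1:
        dm = Chem.GetDistanceMatrix(mol)
        types = [_atom_type(a, typing) for a in mol.GetAtoms()]
        disconnected = False
        for i in range(n):
            for j in range(i + 1, n):
                d = dm[i, j]
                if not np.isfinite(d) or d > 1e7:  # RDKit uses 1e8 for unreachable
                    disconnected = True
                    continue
                t1, t2 = sorted((types[i], types[j]))
                _record(feats, atoms, f"AP|{t1}|{t2}|{int(d)}", (i, j))
        if disconnected:
            warnings.warn(
                "disconnected molecular graph: atom pairs computed per component",
                stacklevel=2,
            )
    return Fingerprint("atom_pairs", feats, mol_id, atoms)


def _simple_paths(mol: Chem.Mol, max_bonds: int) -> Iterable[list[int]]:
    """All simple paths of 1..max_bonds bonds, each undirected path once."""
    for start in range(mol.GetNumAtoms()):
        stack = [[start]]
        while stack:
            path = stack.pop()
            if len(path) > 1 and path[0] < path[-1]:
                yield path
            if len(path) <= max_bonds:
                for nbr in mol.GetAtomWithIdx(path[-1]).GetNeighbors():
                    idx = nbr.GetIdx()
                    if idx not in path:
                        stack.append(path + [idx])


def _path_key(mol: Chem.Mol, path: list[int], typing: Typing) -> str:
    def render(seq: list[int]) -> str:
        out = [_atom_type(mol.GetAtomWithIdx(seq[0]), typing)]
        for a, b in zip(seq, seq[1:]):
            bond = mol.GetBondBetweenAtoms(a, b)
            out.append(_bond_symbol(bond))
            out.append(_atom_type(mol.GetAtomWithIdx(b), typing))
        return "".join(out)

    return min(render(path), render(path[::-1]))


def fp_linear(
    mol: Chem.Mol,
    max_length: int = 7,
    typing: Typing = "full",
    mol_id: Optional[str] = None,
    track_atoms: bool = False,
) -> Fingerprint:
    """Linear-path fingerprint: canonical simple paths up to max_length bonds."""
    feats: dict[str, int] = {}
    atoms: Optional[dict] = {} if track_atoms else None
    for path in _simple_paths(mol, max_length):
        _record(feats, atoms, f"L|{_path_key(mol, path, typing)}", path)
    return Fingerprint("linear", feats, mol_id, atoms)


def fp_torsions(
    mol: Chem.Mol,
    typing: Typing = "full",
    mol_id: Optional[str] = None,
    track_atoms: bool = False,
) -> Fingerprint:
    """Topological-torsion fingerprint: canonical four-atom linear paths."""
    feats: dict[str, int] = {}
    atoms: Optional[dict] = {} if track_atoms else None
    for path in _simple_paths(mol, 3):
        if len(path) == 4:
            _record(feats, atoms, f"T|{_path_key(mol, path, typing)}", path)
    return Fingerprint("torsions", feats, mol_id, atoms)


def fp_radial(
    mol: Chem.Mol,
    max_radius: int = 3,
    typing: Typing = "full",
    mol_id: Optional[str] = None,
    track_atoms: bool = False,
) -> Fingerprint:
    """Radial (circular-environment) fingerprint, radii 0..max_radius.

    Atom identifiers are combined order-independently from sorted
    (bond symbol, neighbour identifier) lists, so the result is invariant
    under graph relabelling.  Atoms whose environment at a radius is
    identical map to the same feature key; the count is the multiplicity.
    An atom stops emitting once its environment no longer grows (an
    isolated atom contributes exactly one radius-0 feature).
    """
    n = mol.GetNumAtoms()
    feats: dict[str, int] = {}
    atoms: Optional[dict] = {} if track_atoms else None
    ids = [_stable_hash(_atom_type(a, typing)) for a in mol.GetAtoms()]
    # atoms covered by each centre's environment, per radius
    env = [{i} for i in range(n)]
    grown = [True] * n
    for r in range(max_radius + 1):
        for i in range(n):
            if grown[i]:
                _record(feats, atoms, f"R{r}|{ids[i]}", env[i])
        if r == max_radius:
            break
        new_ids, new_env = [], []
        for i in range(n):
            nbrs = []
            cover = set(env[i])
            for nbr in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nbr.GetIdx()
                bond = mol.GetBondBetweenAtoms(i, j)
                nbrs.append(f"{_bond_symbol(bond)}{ids[j]}")
                cover |= env[j]
            new_ids.append(_stable_hash(ids[i] + "|" + ",".join(sorted(nbrs))))
            new_env.append(cover)
        grown = [ne != e for ne, e in zip(new_env, env)]
        ids, env = new_ids, new_env
    return Fingerprint("radial", feats, mol_id, atoms)


def fingerprint(
    mol: Chem.Mol,
    scheme: str,
    typing: Typing = "full",
    max_length: int = 7,
    max_radius: int = 3,
    mol_id: Optional[str] = None,
    track_atoms: bool = False,
) -> Fingerprint:
    """Dispatch to one of the fingerprint schemes by name."""
    if scheme == "atom_pairs":
        return fp_atom_pairs(mol, typing, mol_id, track_atoms)
    if scheme == "linear":
        return fp_linear(mol, max_length, typing, mol_id, track_atoms)
    if scheme == "radial":
        return fp_radial(mol, max_radius, typing, mol_id, track_atoms)
    if scheme == "torsions":
        return fp_torsions(mol, typing, mol_id, track_atoms)
    if scheme == "maccs":
        from .maccs import fp_maccs

        return fp_maccs(mol, mol_id, track_atoms)
    raise ValueError(f"unknown fingerprint scheme {scheme!r}")


SCHEMES = ("atom_pairs", "linear", "radial", "torsions", "maccs")


def fold(fp: Fingerprint, n_bits: int = 2048, binary: bool = False) -> np.ndarray:
    """Fold a sparse fingerprint into a fixed-length dense count vector."""
    vec = np.zeros(n_bits)
    for key, count in fp.features.items():
        vec[int(_stable_hash(key), 16) % n_bits] += count
    return (vec > 0).astype(float) if binary else vec


class FingerprintFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping molecules to fingerprints (or folded vectors).

    Accepts SMILES strings, RDKit molecules or :class:`CompoundRecord`
    objects.  ``transform`` returns a list of :class:`Fingerprint` unless
    ``n_bits`` is set, in which case a dense (n_samples, n_bits) count
    matrix is returned for use in ordinary sklearn pipelines.
    """

    def __init__(
        self,
        scheme: str = "radial",
        typing: Typing = "full",
        max_length: int = 7,
        max_radius: int = 3,
        n_bits: Optional[int] = None,
        track_atoms: bool = False,
    ):
        self.scheme = scheme
        self.typing = typing
        self.max_length = max_length
        self.max_radius = max_radius
        self.n_bits = n_bits
        self.track_atoms = track_atoms

    def fit(self, X: Sequence, y=None):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown fingerprint scheme {self.scheme!r}")
        return self

    def _coerce(self, item) -> tuple[Chem.Mol, Optional[str]]:
        if isinstance(item, CompoundRecord):
            if item.mol is None:
                raise ValueError(f"{item.id}: record has no molecular graph")
            return item.mol, item.id
        if isinstance(item, str):
            return mol_from_smiles(item), item
        return item, None

    def transform(self, X: Sequence):
        self.fit(X)
        fps = []
        for item in X:
            mol, mid = self._coerce(item)
            fps.append(
                fingerprint(
                    mol,
                    self.scheme,
                    typing=self.typing,
                    max_length=self.max_length,
                    max_radius=self.max_radius,
                    mol_id=mid,
                    track_atoms=self.track_atoms,
                )
            )
        if self.n_bits is not None:
            return np.vstack([fold(fp, self.n_bits) for fp in fps])
        return fps
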