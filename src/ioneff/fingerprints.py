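"""Molecular fingerprint families used for structure-based logIE models.

Implemented families:

* ``pubchem`` — 881-bit PubChem-style substructure fingerprint, built here
  from explicit element-count / ring-count / bond-pair / SMARTS rules
  (see :mod:`ioneff._pubchem_bits`); this is the family behind the final
  structure-based model.
* ``pubchem-ringblock`` — only the 148 ring-count bits of ``pubchem``,
  used as the cyclicity add-on for atom-pair fingerprints.
* ``maccs`` — 166-bit MACCS keys (RDKit).
* ``morgan`` — 1024-bit Morgan fingerprint, radius 2 (RDKit).
* ``apc2d`` — 2D atom-pair counts: occurrences of (element, element,
  topological distance) triples for the common organic elements at
  distances 1-10 (450 count features).
* ``apc2d+ringblock`` — concatenation of ``apc2d`` and the ring block.

Other families of the original sixteen-variant comparison (CDK, EState,
Klekota-Roth, substructure, ...) are registered but unimplemented; asking
for one raises :class:`UnimplementedFamilyError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, MACCSkeys, rdmolops

from . import _pubchem_bits as pcb
from .compounds import IEEntry

__all__ = [
    "FingerprintVector",
    "SmilesParseError",
    "UnimplementedFamilyError",
    "available_families",
    "family_length",
    "feature_names",
    "compute_fingerprint",
    "compute_combined",
    "build_feature_matrix",
    "pubchem_bit_description",
]


class SmilesParseError(ValueError):
    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class UnimplementedFamilyError(NotImplementedError):
    pass


@dataclass(frozen=True)
class FingerprintVector:
    family: str
    bits: np.ndarray  # non-negative ints; 0/1 for binary families

    def __len__(self) -> int:
        return len(self.bits)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


# ---------------------------------------------------------------------------
# PubChem-style fingerprint

_SMARTS_CACHE: dict[str, Chem.Mol] = {}


def _smarts(pattern: str) -> Chem.Mol:
    if pattern not in _SMARTS_CACHE:
        q = Chem.MolFromSmarts(pattern)
        if q is None:  # pragma: no cover - table is static
            raise ValueError(f"bad SMARTS in bit table: {pattern}")
        _SMARTS_CACHE[pattern] = q
    return _SMARTS_CACHE[pattern]


def _ring_properties(mol: Chem.Mol):
    """Classify every SSSR ring; returns list of dicts per ring."""
    info = mol.GetRingInfo()
    rings = []
    for atom_ids, bond_ids in zip(info.AtomRings(), info.BondRings()):
        atoms = [mol.GetAtomWithIdx(i) for i in atom_ids]
        bonds = [mol.GetBondWithIdx(i) for i in bond_ids]
        aromatic = all(b.GetIsAromatic() for b in bonds)
        saturated = all(
            b.GetBondType() == Chem.BondType.SINGLE and not b.GetIsAromatic()
            for b in bonds
        )
        rings.append(
            {
                "size": len(atom_ids),
                "aromatic": aromatic,
                "saturated": saturated,
                "carbon_only": all(a.GetSymbol() == "C" for a in atoms),
                "has_nitrogen": any(a.GetSymbol() == "N" for a in atoms),
                "has_hetero": any(a.GetSymbol() != "C" for a in atoms),
            }
        )
    return rings


def _ring_block(mol: Chem.Mol) -> np.ndarray:
    """The 148 ring-count bits (section 2 of the PubChem-style layout)."""
    rings = _ring_properties(mol)
    bits = np.zeros(148, dtype=np.int64)
    pos = 0
    for size, counts in pcb.RING_SIZE_COUNTS:
        of_size = [r for r in rings if r["size"] == size]
        # predicate tallies, in RING_PREDICATES order
        tallies = [
            len(of_size),
            sum(r["carbon_only"] and (r["saturated"] or r["aromatic"]) for r in of_size),
            sum(r["has_nitrogen"] and (r["saturated"] or r["aromatic"]) for r in of_size),
            sum(r["has_hetero"] and (r["saturated"] or r["aromatic"]) for r in of_size),
            sum(r["carbon_only"] and not r["saturated"] and not r["aromatic"] for r in of_size),
            sum(r["has_nitrogen"] and not r["saturated"] and not r["aromatic"] for r in of_size),
            sum(r["has_hetero"] and not r["saturated"] and not r["aromatic"] for r in of_size),
        ]
        for k in counts:
            for t in tallies:
                bits[pos] = int(t >= k)
                pos += 1
    n_aromatic = sum(r["aromatic"] for r in rings)
    n_hetero_aromatic = sum(r["aromatic"] and r["has_hetero"] for r in rings)
    for k, hetero in pcb.AROMATIC_RING_BITS:
        bits[pos] = int((n_hetero_aromatic if hetero else n_aromatic) >= k)
        pos += 1
    assert pos == 148
    return bits


def _pubchem_fingerprint(mol: Chem.Mol) -> np.ndarray:
    bits = np.zeros(pcb.N_BITS, dtype=np.int64)

    counts: dict[str, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            n_h += 1
        else:
            counts[sym] = counts.get(sym, 0) + 1
            n_h += atom.GetTotalNumHs()
    counts["H"] = n_h
    for i, (k, sym) in enumerate(pcb.ELEMENT_COUNT_BITS):
        bits[i] = int(counts.get(sym, 0) >= k)

    bits[pcb.SECTION2_START : pcb.SECTION3_START] = _ring_block(mol)

    for j, (a, b) in enumerate(pcb.SIMPLE_PAIR_BITS):
        idx = pcb.SECTION3_START + j
        if "H" in (a, b):
            heavy = a if b == "H" else b
            bits[idx] = int(
                any(
                    at.GetSymbol() == heavy and at.GetTotalNumHs() >= 1
                    for at in mol.GetAtoms()
                )
            )
        else:
            target = {a, b}  # collapses to one element when a == b
            bits[idx] = int(
                any(
                    {bd.GetBeginAtom().GetSymbol(), bd.GetEndAtom().GetSymbol()}
                    == target
                    for bd in mol.GetBonds()
                )
            )

    for idx, (pattern, _desc) in pcb.SMARTS_BITS.items():
        bits[idx] = int(mol.HasSubstructMatch(_smarts(pattern)))
    return bits


def pubchem_bit_description(index: int) -> str:
    return pcb.bit_description(index)


# ---------------------------------------------------------------------------
# other families

_APC2D_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]
_APC2D_PAIRS = [
    (a, b)
    for i, a in enumerate(_APC2D_ELEMENTS)
    for b in _APC2D_ELEMENTS[i:]
]
_APC2D_MAX_DIST = 10


def _apc2d_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """Counts of (element, element, topological distance) atom pairs."""
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    keep = [i for i, s in enumerate(symbols) if s in _APC2D_ELEMENTS]
    counts = np.zeros(len(_APC2D_PAIRS) * _APC2D_MAX_DIST, dtype=np.int64)
    if len(keep) >= 2:
        dm = rdmolops.GetDistanceMatrix(mol)
        pair_index = {p: i for i, p in enumerate(_APC2D_PAIRS)}
        for ii, i in enumerate(keep):
            for j in keep[ii + 1 :]:
                d = int(dm[i, j])
                if 1 <= d <= _APC2D_MAX_DIST:
                    pair = tuple(sorted((symbols[i], symbols[j]),
                                        key=_APC2D_ELEMENTS.index))
                    counts[(d - 1) * len(_APC2D_PAIRS) + pair_index[pair]] += 1
    return counts


def _maccs_fingerprint(mol: Chem.Mol) -> np.ndarray:
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    return np.array(list(fp.ToBitString()[1:]), dtype=np.int64)


def _morgan_fingerprint(mol: Chem.Mol) -> np.ndarray:
    fp = AllChem.GetMorganFingerprintAsBitVect(mol, radius=2, nBits=1024)
    return np.array(list(fp.ToBitString()), dtype=np.int64)


_FAMILIES = {
    "pubchem": (pcb.N_BITS, _pubchem_fingerprint),
    "pubchem-ringblock": (148, _ring_block),
    "maccs": (166, _maccs_fingerprint),
    "morgan": (1024, _morgan_fingerprint),
    "apc2d": (len(_APC2D_PAIRS) * _APC2D_MAX_DIST, _apc2d_fingerprint),
}
# placeholders for the remaining families of the original comparison
_UNIMPLEMENTED = {
    "cdk", "cdk-extended", "cdk-graphonly", "estate", "klekota-roth",
    "klekota-roth-count", "substructure", "substructure-count", "ap2d",
    "padel-toxicity-optimized",
}
_COMBINED_ALIASES = {"apc2d+ringblock": ["apc2d", "pubchem-ringblock"]}


def available_families() -> list[str]:
    return sorted(_FAMILIES) + sorted(_COMBINED_ALIASES)


def _resolve(family: str):
    if family in _UNIMPLEMENTED:
        raise UnimplementedFamilyError(
            f"fingerprint family {family!r} is registered but not implemented"
        )
    if family not in _FAMILIES:
        raise KeyError(
            f"unknown fingerprint family {family!r}; "
            f"available: {available_families()}"
        )
    return _FAMILIES[family]


def family_length(family: str) -> int:
    if family in _COMBINED_ALIASES:
        return sum(family_length(f) for f in _COMBINED_ALIASES[family])
    return _resolve(family)[0]


def feature_names(family: str) -> list[str]:
    if family in _COMBINED_ALIASES:
        return [
            n for f in _COMBINED_ALIASES[family] for n in feature_names(f)
        ]
    prefix = family.replace("-", "_")
    return [f"{prefix}_{i}" for i in range(family_length(family))]


@lru_cache(maxsize=200_000)
def _cached_bits(smiles: str, family: str) -> tuple[int, ...]:
    length, fn = _resolve(family)
    bits = fn(_mol_from_smiles(smiles))
    assert len(bits) == length
    return tuple(int(b) for b in bits)


def compute_fingerprint(smiles: str, family: str) -> FingerprintVector:
    """Compute one fingerprint; deterministic for a given SMILES."""
    if family in _COMBINED_ALIASES:
        return compute_combined(smiles, _COMBINED_ALIASES[family], name=family)
    return FingerprintVector(
        family=family, bits=np.array(_cached_bits(smiles, family), dtype=np.int64)
    )


def compute_combined(
    smiles: str, spec: Sequence[str], name: str | None = None
) -> FingerprintVector:
    """Concatenate several families in the declared order."""
    if not spec:
        raise ValueError("empty fingerprint combination spec")
    parts = [compute_fingerprint(smiles, f).bits for f in spec]
    return FingerprintVector(
        family=name or "+".join(spec), bits=np.concatenate(parts)
    )


def build_feature_matrix(
    entries: Sequence[IEEntry], family: str = "pubchem"
) -> pd.DataFrame:
    """Fingerprint columns followed by one ``ph`` column, rows = entries.

    Raises ``ValueError`` listing the InChIKeys of entries whose SMILES
    cannot be parsed (or that carry no SMILES at all).
    """
    bad = []
    rows = []
    for e in entries:
        if not e.compound.smiles:
            bad.append(e.compound.key)
            continue
        try:
            rows.append(compute_fingerprint(e.compound.smiles, family).bits)
        except SmilesParseError:
            bad.append(e.compound.key)
    if bad:
        raise ValueError(f"unparseable compounds for family {family!r}: {bad}")
    X = pd.DataFrame(np.vstack(rows), columns=feature_names(family))
    X["ph"] = [e.ph for e in entries]
    return X
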