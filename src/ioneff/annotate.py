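"""Molecular-formula suggestion for CNL feature masses.

The most important CNL features of the structure-free model are plain
mass values; to interpret them chemically, every CHNOSP formula within
given element bounds is enumerated and kept when its neutral mass — or
its protonated mass, for the [M+H]+ species — matches the query within a
20 mDa window. Candidate plausibility ranking against a particular
dataset's chemistry is left to the user; the annotator reports exact
mass deltas for every candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

__all__ = [
    "FormulaCandidate",
    "ISOTOPE_MASSES",
    "PROTON_MASS",
    "monoisotopic_mass",
    "suggest_formulas",
    "format_formula",
    "candidates_to_frame",
]

# most-abundant-isotope masses (Da), IUPAC/CODATA values
ISOTOPE_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}
PROTON_MASS = 1.007276466

DEFAULT_BOUNDS: dict[str, int] = {"C": 20, "H": 40, "N": 5, "O": 10, "S": 3, "P": 2}

_ELEMENT_ORDER = ["C", "H", "N", "O", "S", "P"]  # Hill-ish display order


@dataclass(frozen=True)
class FormulaCandidate:
    formula: dict[str, int]
    monoisotopic_mass: float
    delta_mda: float  # signed: candidate (as species) minus query, in mDa
    species: str  # "neutral" ([M]+ treated as M) or "protonated" ([M+H]+)

    def __str__(self) -> str:
        return f"{format_formula(self.formula)} ({self.species}, {self.delta_mda:+.1f} mDa)"


def monoisotopic_mass(formula: dict[str, int]) -> float:
    """Sum of count x most-abundant-isotope mass; empty formula -> 0."""
    mass = 0.0
    for element, count in formula.items():
        if element not in ISOTOPE_MASSES:
            raise ValueError(f"unsupported element {element!r}")
        if count < 0:
            raise ValueError(f"negative count for {element}")
        mass += count * ISOTOPE_MASSES[element]
    return mass


def format_formula(formula: dict[str, int]) -> str:
    parts = []
    for el in _ELEMENT_ORDER:
        c = formula.get(el, 0)
        if c == 1:
            parts.append(el)
        elif c > 1:
            parts.append(f"{el}{c}")
    return "".join(parts) or "(empty)"


def suggest_formulas(
    mz: float,
    tol_mda: float = 20.0,
    element_bounds: dict[str, int] | None = None,
) -> list[FormulaCandidate]:
    """Enumerate CHNOSP formulas matching ``mz`` within ``tol_mda``.

    A formula M is kept when |mass(M) − mz| <= tol (neutral/[M]+ species,
    the electron mass being far below the tolerance) or
    |mass(M) + proton − mz| <= tol ([M+H]+ species); a formula matching
    both ways yields two candidates. Sorted by |delta|, ties by formula.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    bounds = dict(DEFAULT_BOUNDS if element_bounds is None else element_bounds)
    if unknown := set(bounds) - set(ISOTOPE_MASSES):
        raise ValueError(f"unsupported elements in bounds: {sorted(unknown)}")
    n_combos = 1
    for b in bounds.values():
        n_combos *= b + 1
    if n_combos > 10_000_000:
        raise ValueError(
            f"element bounds produce {n_combos} combinations; tighten them"
        )

    tol = tol_mda / 1000.0
    elements = [e for e in _ELEMENT_ORDER if e in bounds]
    # no formula heavier than the query (plus tolerance) can match either
    # species, so cap each element count by the query mass
    eff_bounds = {
        e: min(bounds[e], int((mz + tol) / ISOTOPE_MASSES[e])) for e in elements
    }
    candidates: list[FormulaCandidate] = []
    masses = [ISOTOPE_MASSES[e] for e in elements]
    for counts in product(*(range(eff_bounds[e] + 1) for e in elements)):
        mass = sum(c * m for c, m in zip(counts, masses))
        if mass > mz + tol:
            continue
        formula = {e: c for e, c in zip(elements, counts) if c > 0}
        if abs(mass - mz) <= tol:
            candidates.append(
                FormulaCandidate(formula, mass, (mass - mz) * 1000.0, "neutral")
            )
        if abs(mass + PROTON_MASS - mz) <= tol:
            candidates.append(
                FormulaCandidate(
                    formula,
                    mass,
                    (mass + PROTON_MASS - mz) * 1000.0,
                    "protonated",
                )
            )
    candidates.sort(key=lambda c: (abs(c.delta_mda), format_formula(c.formula)))
    return candidates


def candidates_to_frame(
    mz: float, candidates: list[FormulaCandidate]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_mz": [mz] * len(candidates),
            "formula": [format_formula(c.formula) for c in candidates],
            "species": [c.species for c in candidates],
            "mass": [c.monoisotopic_mass for c in candidates],
            "delta_mda": [c.delta_mda for c in candidates],
        }
    )
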