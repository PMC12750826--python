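"""Bit tables for the PubChem-style 881-bit substructure fingerprint.

The layout follows the public CACTVS section structure:

* section 1, bits 0-114:   element counts ("at least k atoms of element E")
* section 2, bits 115-262: ring counts by size / composition / saturation,
                           plus aromatic-ring counts
* section 3, bits 263-326: simple bonded element pairs
* sections 4-7, bits 327-880: atom-neighbourhood and SMARTS substructure
                           bits; a curated subset of common organic
                           patterns is implemented at documented indices,
                           the remaining bits are always 0.

Bit-level parity with PubChem's own implementation is not promised; the
definitions here are explicit and self-consistent, and each implemented
bit carries a human-readable description used when reporting feature
importance. Ring perception uses RDKit's SSSR rather than CACTVS ESSSR.
"""

from __future__ import annotations

N_BITS = 881

# --- section 1: element counts (bit index -> (min count, element symbol)) ---
# H counts include implicit hydrogens.
ELEMENT_COUNT_BITS: list[tuple[int, str]] = [
    (4, "H"), (8, "H"), (16, "H"), (32, "H"),
    (1, "Li"), (2, "Li"),
    (1, "B"), (2, "B"), (4, "B"),
    (2, "C"), (4, "C"), (8, "C"), (16, "C"), (32, "C"),
    (1, "N"), (2, "N"), (4, "N"), (8, "N"),
    (1, "O"), (2, "O"), (4, "O"), (8, "O"), (16, "O"),
    (1, "F"), (2, "F"), (4, "F"),
    (1, "Na"), (2, "Na"),
    (1, "Si"), (2, "Si"),
    (1, "P"), (2, "P"), (4, "P"),
    (1, "S"), (2, "S"), (4, "S"), (8, "S"),
    (1, "Cl"), (2, "Cl"), (4, "Cl"), (8, "Cl"),
    (1, "K"), (2, "K"),
    (1, "Br"), (2, "Br"), (4, "Br"),
    (1, "I"), (2, "I"), (4, "I"),
] + [
    (1, sym)
    for sym in (
        "Be Mg Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Kr Rb Sr Y Zr "
        "Nb Mo Ru Rh Pd Ag Cd In Sn Sb Te Xe Cs Ba Lu Hf Ta W Re Os Ir Pt "
        "Au Hg Tl Pb Bi La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Tc U"
    ).split()
]
assert len(ELEMENT_COUNT_BITS) == 114
# pad section 1 to 115 bits with a rare-element singleton
ELEMENT_COUNT_BITS += [(1, "He")]

SECTION2_START = 115

# ring-size block layout: (ring size, list of min-counts per predicate)
RING_SIZE_COUNTS: list[tuple[int, list[int]]] = [
    (3, [1, 2]),
    (4, [1, 2]),
    (5, [1, 2, 3, 4, 5]),
    (6, [1, 2, 3, 4, 5]),
    (7, [1, 2]),
    (8, [1, 2]),
    (9, [1]),
    (10, [1]),
]
# per (size, min-count): 7 predicates, in this order
RING_PREDICATES = [
    "any ring",
    "saturated or aromatic carbon-only ring",
    "saturated or aromatic nitrogen-containing ring",
    "saturated or aromatic heteroatom-containing ring",
    "unsaturated non-aromatic carbon-only ring",
    "unsaturated non-aromatic nitrogen-containing ring",
    "unsaturated non-aromatic heteroatom-containing ring",
]
# aromatic tail of section 2: (min count, hetero-only?)
AROMATIC_RING_BITS = [(1, False), (1, True), (2, False), (2, True),
                      (3, False), (3, True), (4, False), (4, True)]

_n_ring_bits = sum(len(c) for _, c in RING_SIZE_COUNTS) * 7 + len(AROMATIC_RING_BITS)
assert _n_ring_bits == 148
SECTION3_START = SECTION2_START + _n_ring_bits  # 263

# --- section 3: simple element-pair bonds ("E1 bonded to E2") ---
SIMPLE_PAIR_BITS: list[tuple[str, str]] = [
    ("Li", "H"), ("Li", "Li"), ("B", "H"), ("B", "B"), ("B", "C"),
    ("B", "N"), ("B", "O"), ("B", "F"), ("B", "Si"), ("B", "P"),
    ("B", "S"), ("B", "Cl"), ("B", "Br"), ("C", "H"), ("C", "C"),
    ("C", "N"), ("C", "O"), ("C", "F"), ("C", "Na"), ("C", "Mg"),
    ("C", "Al"), ("C", "Si"), ("C", "P"), ("C", "S"), ("C", "Cl"),
    ("C", "As"), ("C", "Se"), ("C", "Br"), ("C", "I"), ("N", "H"),
    ("N", "N"), ("N", "O"), ("N", "F"), ("N", "Si"), ("N", "P"),
    ("N", "S"), ("N", "Cl"), ("N", "Br"), ("O", "H"), ("O", "O"),
    ("O", "Mg"), ("O", "Na"), ("O", "Al"), ("O", "Si"), ("O", "P"),
    ("O", "K"), ("F", "P"), ("F", "S"), ("Al", "H"), ("Al", "Cl"),
    ("Si", "H"), ("Si", "Si"), ("Si", "Cl"), ("P", "H"), ("P", "P"),
    ("As", "H"), ("As", "As"), ("S", "H"), ("S", "S"), ("Sn", "H"),
    ("Ge", "H"), ("Se", "H"), ("Te", "H"), ("Cl", "O"),
]
assert len(SIMPLE_PAIR_BITS) == 64
SECTION4_START = SECTION3_START + 64  # 327

# --- sections 4-7: curated SMARTS bits at fixed indices -------------------
# index -> (SMARTS, description). Indices live in [327, 880]; unlisted
# indices in that range are always 0.
SMARTS_BITS: dict[int, tuple[str, str]] = {
    # atom-neighbourhood style patterns
    327: ("[CX4H3]", "methyl carbon"),
    328: ("[CX4H2]", "methylene carbon"),
    329: ("[CX4H1]", "methine carbon"),
    330: ("[CX4H0]", "quaternary sp3 carbon"),
    331: ("[CX3]=[CX3]", "C=C double bond"),
    332: ("C#C", "C#C triple bond"),
    333: ("[NX3;H2]", "primary amine N"),
    334: ("[NX3;H1]([#6])[#6]", "secondary amine N"),
    335: ("[NX3;H0]([#6])([#6])[#6]", "tertiary amine N"),
    336: ("N(~C)~C", "N with two carbon neighbours N(~C)(~C)"),
    337: ("[nX2]", "aromatic N, pyridine-like"),
    338: ("[nH]", "aromatic NH, pyrrole-like"),
    339: ("[OX2H]", "hydroxyl O"),
    340: ("[OX2]([#6])[#6]", "ether O"),
    341: ("[SX2H]", "thiol S"),
    342: ("[SX2]([#6])[#6]", "thioether S"),
    # functional groups
    350: ("[CX3]=[OX1]", "carbonyl C=O"),
    351: ("[CX3](=O)[OX2H1]", "carboxylic acid"),
    352: ("[CX3](=O)[OX2][#6]", "ester"),
    353: ("[CX3](=O)[NX3]", "amide"),
    354: ("[CX3H1]=O", "aldehyde"),
    355: ("[CX3](=O)[#6]", "ketone/acyl carbon"),
    356: ("C#N", "nitrile"),
    357: ("[NX3](=O)=O", "nitro group (charge-separated form matched too)"),
    358: ("[N+](=O)[O-]", "nitro group, charged depiction"),
    359: ("[NX3][CX3](=O)", "N-acyl nitrogen"),
    360: ("[SX4](=O)(=O)[OX2H1]", "sulfonic acid"),
    361: ("[SX4](=O)(=O)[NX3]", "sulfonamide"),
    362: ("[PX4](=O)([OX2])[OX2]", "phosphate-like P"),
    363: ("[OX2H][cX3]", "phenolic OH"),
    364: ("[NX3][cX3]", "aniline-like N"),
    365: ("[F,Cl,Br,I][#6]", "halogen on carbon"),
    366: ("[CX4]([F])([F])[F]", "trifluoromethyl"),
    367: ("[OX2H][CX4]", "aliphatic alcohol"),
    368: ("[#6]=[#7]", "C=N imine"),
    369: ("[NX3][NX3]", "hydrazine N-N"),
    370: ("[#7]~[#7]~[#7]", "azide-like N chain"),
    # short chain/topology patterns (paper-style path features)
    380: ("C-N", "C-N single bond"),
    381: ("C-N-C", "C-N-C path"),
    382: ("C-N-C-C", "C-N-C-C path"),
    383: ("C-N-C-C-C", "C-N-C-C-C path"),
    384: ("C-C-C-C", "butyl path"),
    385: ("C-C-C-C-C-C", "hexyl path"),
    386: ("C-O-C", "C-O-C path"),
    387: ("O=C-C-N", "beta-amino carbonyl path"),
    388: ("O=C-O", "carboxyl-type O=C-O path"),
    389: ("N-C-C-O", "aminoethanol-type path"),
    # aromatic substitution patterns
    400: ("c1ccccc1", "benzene ring"),
    401: ("[#6]c1ccccc1", "carbon-substituted benzene"),
    402: ("[#7]c1ccccc1", "nitrogen-substituted benzene"),
    403: ("[#8]c1ccccc1", "oxygen-substituted benzene"),
    404: ("[F,Cl,Br,I]c1ccccc1", "halogen-substituted benzene"),
    405: ("c1ccc2ccccc2c1", "fused bicyclic aromatic (naphthalene-like)"),
    406: ("c1ccncc1", "pyridine ring"),
    407: ("c1cc[nH]c1", "pyrrole ring"),
    408: ("c1ccoc1", "furan ring"),
    409: ("c1ccsc1", "thiophene ring"),
    410: ("c1cncnc1", "pyrimidine-type ring"),
    # saturated heterocycles
    420: ("C1CCNCC1", "piperidine-type ring"),
    421: ("C1CCOCC1", "tetrahydropyran-type ring"),
    422: ("C1CCNC1", "pyrrolidine-type ring"),
    423: ("N1CCNCC1", "piperazine-type ring"),
    424: ("C1CCOC1", "tetrahydrofuran-type ring"),
}


def bit_description(index: int) -> str:
    """Human-readable meaning of one fingerprint bit."""
    if index < SECTION2_START:
        k, sym = ELEMENT_COUNT_BITS[index]
        return f">= {k} {sym} atoms" if sym == "H" or k > 1 else f">= 1 {sym} atom"
    if index < SECTION3_START:
        i = index - SECTION2_START
        n_size_bits = sum(len(c) for _, c in RING_SIZE_COUNTS) * 7
        if i < n_size_bits:
            for size, counts in RING_SIZE_COUNTS:
                block = len(counts) * 7
                if i < block:
                    k = counts[i // 7]
                    pred = RING_PREDICATES[i % 7]
                    return f">= {k} size-{size} {pred}"
                i -= block
        k, hetero = AROMATIC_RING_BITS[i - n_size_bits]
        return f">= {k} {'hetero-' if hetero else ''}aromatic rings"
    if index < SECTION4_START:
        a, b = SIMPLE_PAIR_BITS[index - SECTION3_START]
        return f"{a} bonded to {b}"
    if index in SMARTS_BITS:
        return SMARTS_BITS[index][1]
    return f"bit {index} (unimplemented, always 0)"
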