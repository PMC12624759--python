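"""Element and residue reference tables shared across the package.

All radii are in Å, masses in amu (monoisotopic for residues, standard
atomic weights for elements).
"""

from __future__ import annotations

import warnings

# Bondi-style van der Waals radii; unknown elements fall back to carbon.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW = 1.70

# Standard atomic weights for mass-weighted fits and centers of mass.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}
DEFAULT_WEIGHT = 12.011

# Monoisotopic residue masses of the 20 standard amino acids.
RESIDUE_MONO_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MONO = 18.010565
HYDROGEN_ATOM_MONO = 1.007825
#: C-terminal amidation replaces -OH by -NH2.
AMIDE_DELTA = -0.984016
CARBAMIDOMETHYL = 57.02146
MET_OXIDATION = 15.99491

THREE_TO_ONE: dict[str, str] = {
    "GLY": "G", "ALA": "A", "SER": "S", "PRO": "P", "VAL": "V",
    "THR": "T", "CYS": "C", "LEU": "L", "ILE": "I", "ASN": "N",
    "ASP": "D", "GLN": "Q", "LYS": "K", "GLU": "E", "MET": "M",
    "HIS": "H", "PHE": "F", "ARG": "R", "TYR": "Y", "TRP": "W",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Residues counted as hydrophobic by the pocket-ranking surrogate.
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWP")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

_warned: set[str] = set()


def vdw_radius(element: str) -> float:
    el = element.capitalize()
    if el in VDW_RADII:
        return VDW_RADII[el]
    if el not in _warned:
        _warned.add(el)
        warnings.warn(
            f"no van der Waals radius for element {element!r}; "
            f"defaulting to {DEFAULT_VDW} Å"
        )
    return DEFAULT_VDW


def atomic_weight(element: str) -> float:
    return ATOMIC_WEIGHTS.get(element.capitalize(), DEFAULT_WEIGHT)


def element_from_atom_name(name: str) -> str:
    """Best-effort element inference from a PDB atom name."""
    stripped = name.strip()
    if not stripped:
        return "C"
    if stripped[0].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Na"):
        return stripped[:2].capitalize()
    return stripped[0].upper()
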