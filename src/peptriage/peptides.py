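"""Tripeptide library enumeration and per-peptide descriptors.

The design library is every length-L combination over a chosen residue
alphabet — by default the 19 standard amino acids excluding cysteine,
amidated at the C-terminus with a free N-terminus (protease-stable
species carrying an extra positive charge). D-configuration is metadata:
mass and charge are stereochemistry-independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .elements import HYDROPHOBIC_RESIDUES, RESIDUE_MONO_MASS
from .xlink import AlphabetError, PeptideSpecies, monoisotopic_mass

#: 20 standard residues minus cysteine, the default design alphabet.
DEFAULT_ALPHABET = tuple(sorted(set(RESIDUE_MONO_MASS) - {"C"}))

AROMATIC = frozenset("FWY")


def enumerate_tripeptides(
    alphabet=DEFAULT_ALPHABET, length: int = 3
) -> list[PeptideSpecies]:
    """All |alphabet|^length sequences in lexicographic order, amidated."""
    if not alphabet:
        raise AlphabetError("alphabet must be non-empty")
    if length < 1:
        raise ValueError("length must be >= 1")
    letters = sorted(alphabet)
    for letter in letters:
        if letter not in RESIDUE_MONO_MASS:
            raise AlphabetError(f"unknown residue letter {letter!r}")
    return [
        PeptideSpecies(sequence="".join(combo), c_terminal_amide=True)
        for combo in itertools.product(letters, repeat=length)
    ]


def select_synthesis_set(
    ranked_per_cavity: dict[str, list], top_k: int = 8
) -> list[tuple[str, object, bool]]:
    """Take the top-k candidates of each cavity's ranked list.

    Returns ``(cavity, peptide, is_duplicate)`` triples, cavity order
    preserved; lists shorter than ``top_k`` are taken whole; duplicates
    across cavities are retained and flagged.
    """
    out: list[tuple[str, object, bool]] = []
    seen: set[str] = set()
    for cavity, ranked in ranked_per_cavity.items():
        for peptide in ranked[:top_k]:
            seq = peptide.sequence if isinstance(peptide, PeptideSpecies) else str(peptide)
            out.append((cavity, peptide, seq in seen))
            seen.add(seq)
    return out


@dataclass
class PeptideDescriptors:
    sequence: str
    monoisotopic_mass: float
    net_charge_pH7: int
    aromatic_count: int
    hydrophobic_fraction: float


def peptide_descriptors(p: PeptideSpecies | str) -> PeptideDescriptors:
    """Mass plus integer-heuristic charge and simple composition counts.

    Net charge at pH 7 ≈ (+1 free N-terminus) + #(R,K) + round(0.1·#H)
    − #(D,E) − (1 for a free-acid C-terminus). This is a bookkeeping
    heuristic, not a titration.
    """
    if isinstance(p, str):
        p = PeptideSpecies(sequence=p, c_terminal_amide=True)
    seq = p.sequence
    for letter in seq:
        if letter not in RESIDUE_MONO_MASS:
            raise AlphabetError(f"unknown residue letter {letter!r}")
    charge = 0
    if p.n_terminal_free:
        charge += 1
    charge += sum(seq.count(r) for r in "RK")
    charge += round(0.1 * seq.count("H"))
    charge -= sum(seq.count(r) for r in "DE")
    if not p.c_terminal_amide:
        charge -= 1
    return PeptideDescriptors(
        sequence=seq,
        monoisotopic_mass=monoisotopic_mass(p),
        net_charge_pH7=charge,
        aromatic_count=sum(seq.count(a) for a in AROMATIC),
        hydrophobic_fraction=sum(1 for l in seq if l in HYDROPHOBIC_RESIDUES) / len(seq),
    )


def library_table(peptides: list[PeptideSpecies]) -> pd.DataFrame:
    """Descriptor table for a peptide list (CSV-ready)."""
    rows = []
    for p in peptides:
        d = peptide_descriptors(p)
        rows.append(
            {
                "sequence": d.sequence,
                "c_terminal_amide": p.c_terminal_amide,
                "monoisotopic_mass": d.monoisotopic_mass,
                "net_charge_pH7": d.net_charge_pH7,
                "aromatic_count": d.aromatic_count,
                "hydrophobic_fraction": d.hydrophobic_fraction,
            }
        )
    return pd.DataFrame(rows)
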