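"""Shared fixtures: small synthetic structures built programmatically."""

import numpy as np
import pytest

from peptriage.core_io import MolecularStructure


def build_chain(
    n_residues: int,
    atoms_per_residue=("N", "CA", "C", "O"),
    chain_id: str = "A",
    residue_name: str = "ALA",
    spacing: float = 3.5,
    seed: int = 0,
) -> MolecularStructure:
    """A linear pseudo-chain with the requested backbone atoms per residue."""
    rng = np.random.default_rng(seed)
    names, resnames, resids, chains, coords = [], [], [], [], []
    elements = []
    for r in range(1, n_residues + 1):
        base = np.array([spacing * r, 0.0, 0.0])
        for k, atom in enumerate(atoms_per_residue):
            names.append(atom)
            elements.append(atom[0])
            resnames.append(residue_name)
            resids.append(r)
            chains.append(chain_id)
            coords.append(base + np.array([0.8 * k, 0.4 * (k % 2), 0.0])
                          + rng.normal(0, 0.05, 3))
    n = len(names)
    return MolecularStructure(
        serials=np.arange(1, n + 1),
        names=names,
        elements=elements,
        residue_names=resnames,
        residue_indices=resids,
        chain_ids=chains,
        coordinates=np.array(coords),
    )


@pytest.fixture(scope="session")
def chain160() -> MolecularStructure:
    """160-residue chain with the 4 backbone heavy atoms per residue."""
    return build_chain(160)


@pytest.fixture(scope="session")
def tripeptide() -> tuple[MolecularStructure, dict]:
    """3-residue peptide plus a manifest of its construction counts."""
    s = build_chain(3, atoms_per_residue=("N", "CA", "C", "O", "CB"), seed=7)
    manifest = {"n_residues": 3, "n_atoms": 15, "atoms_per_residue": 5}
    return s, manifest
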