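"""Trajectory statistics for protein–peptide complexes.

Implements the metrics used to adjudicate binding poses: ligand RMSD
after receptor-only superposition, CAPRI-style interface RMSD, per-residue
RMSF, peptide-to-site center-of-mass distance and bound fraction,
residue–residue contact frequencies with a persistence filter, occupancy
grids, and average structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import (
    AtomSelection,
    MolecularStructure,
    SelectionError,
    StructuralMismatchError,
    Trajectory,
    center_of_mass,
    rmsd,
    select_atoms,
    superpose,
)
from .elements import BACKBONE_ATOMS

DEFAULT_SITE_RADIUS = 5.0
DEFAULT_UNBOUND_CUTOFF = 6.0
DEFAULT_FREQUENCY_CUTOFF = 0.25
DEFAULT_INTERFACE_RADIUS = 10.0


def _indices(sel) -> np.ndarray:
    if isinstance(sel, AtomSelection):
        return sel.resolved_indices
    return np.asarray(sel, dtype=int)


# ---------------------------------------------------------------------------
# RMSD-family metrics
# ---------------------------------------------------------------------------

def ligand_rmsd_series(
    traj: Trajectory,
    fit_selection,
    ligand_selection,
    reference_frame: int = 0,
) -> np.ndarray:
    """Ligand RMSD per frame after receptor-only superposition.

    Each frame is rigidly fitted to the reference frame on
    ``fit_selection`` (mass-weighted); the RMSD is then taken over the
    ligand selection *without* further fitting, so ligand drift relative
    to the receptor is preserved.
    """
    fit_idx = _indices(fit_selection)
    lig_idx = _indices(ligand_selection)
    if len(fit_idx) == 0 or len(lig_idx) == 0:
        raise SelectionError("fit and ligand selections must be non-empty")
    ref = traj.frames[reference_frame]
    masses = traj.topology.masses
    series = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        _, _, fitted = superpose(frame, ref, fit_idx, weights=masses)
        series[k] = rmsd(fitted, ref, lig_idx)
    return series


def interface_rmsd(
    model: MolecularStructure,
    reference: MolecularStructure,
    partner_a_selection,
    partner_b_selection,
    interface_radius: float = DEFAULT_INTERFACE_RADIUS,
) -> float:
    """CAPRI-style interface RMSD.

    Interface residues are those of either partner with a heavy atom
    within ``interface_radius`` of the other partner in the *reference*
    complex; the model is superposed on the interface backbone atoms and
    the RMSD is reported over those same atoms.
    """
    if model.n_atoms != reference.n_atoms:
        raise StructuralMismatchError("model and reference topologies differ")
    a_idx = _indices(partner_a_selection)
    b_idx = _indices(partner_b_selection)
    heavy = reference.elements.astype(str) != "H"
    ra = reference.coordinates[a_idx]
    rb = reference.coordinates[b_idx]
    tree_a = cKDTree(ra)
    tree_b = cKDTree(rb)
    iface_res: set[tuple[str, int]] = set()
    for local, i in enumerate(a_idx):
        if heavy[i] and tree_b.query(reference.coordinates[i])[0] <= interface_radius:
            iface_res.add((str(reference.chain_ids[i]), int(reference.residue_indices[i])))
    for local, i in enumerate(b_idx):
        if heavy[i] and tree_a.query(reference.coordinates[i])[0] <= interface_radius:
            iface_res.add((str(reference.chain_ids[i]), int(reference.residue_indices[i])))
    bb = [
        i
        for i in range(reference.n_atoms)
        if (str(reference.chain_ids[i]), int(reference.residue_indices[i])) in iface_res
        and str(reference.names[i]) in BACKBONE_ATOMS
    ]
    if len(bb) < 3:
        raise SelectionError(
            "interface is empty or too small for a fit (no residues within "
            f"{interface_radius} Å); I-RMSD undefined"
        )
    _, _, fitted = superpose(model.coordinates, reference.coordinates, bb)
    return rmsd(fitted, reference.coordinates, bb)


def rmsf(traj: Trajectory, selection, align_selection=None) -> dict:
    """Per-residue RMSF after per-frame alignment to the first frame.

    Per-atom RMSF is sqrt(<|x - <x>|^2>) over frames; residues report
    the mass-weighted mean over their selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel_idx = _indices(selection)
    if len(sel_idx) == 0:
        raise SelectionError("empty selection for RMSF")
    align_idx = _indices(align_selection) if align_selection is not None else sel_idx
    masses = traj.topology.masses
    ref = traj.frames[0]
    fitted = np.empty((traj.n_frames, traj.topology.n_atoms, 3))
    for k, frame in enumerate(traj.frames):
        _, _, fitted[k] = superpose(frame, ref, align_idx, weights=masses)
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
    out: dict = {}
    for chain, resid, idx in traj.topology.residue_groups():
        keep = np.intersect1d(idx, sel_idx)
        if len(keep) == 0:
            continue
        w = masses[keep]
        out[(chain, resid)] = float((per_atom[keep] * w).sum() / w.sum())
    return out


# ---------------------------------------------------------------------------
# Bound fraction
# ---------------------------------------------------------------------------

@dataclass
class BindingSiteDefinition:
    """Receptor residues near the peptide in a fixed reference structure."""

    site_residues: list                # [(chain, resid), ...]
    com_atom_name: str = "CA"
    site_radius: float = DEFAULT_SITE_RADIUS

    @classmethod
    def from_reference(
        cls,
        reference: MolecularStructure,
        peptide_selection,
        receptor_selection,
        site_radius: float = DEFAULT_SITE_RADIUS,
        com_atom_name: str = "CA",
    ) -> "BindingSiteDefinition":
        pep_idx = _indices(peptide_selection)
        rec_idx = _indices(receptor_selection)
        if len(pep_idx) == 0 or len(rec_idx) == 0:
            raise SelectionError("peptide and receptor selections must be non-empty")
        tree = cKDTree(reference.coordinates[pep_idx])
        residues: list = []
        seen = set()
        for i in rec_idx:
            if tree.query(reference.coordinates[i])[0] <= site_radius:
                key = (str(reference.chain_ids[i]), int(reference.residue_indices[i]))
                if key not in seen:
                    seen.add(key)
                    residues.append(key)
        if not residues:
            raise SelectionError(
                f"no receptor residues within {site_radius} Å of the peptide"
            )
        return cls(site_residues=residues, com_atom_name=com_atom_name, site_radius=site_radius)

    def com_indices(self, structure: MolecularStructure) -> np.ndarray:
        wanted = set(self.site_residues)
        idx = [
            i
            for i in range(structure.n_atoms)
            if (str(structure.chain_ids[i]), int(structure.residue_indices[i])) in wanted
            and str(structure.names[i]) == self.com_atom_name
        ]
        if not idx:
            raise SelectionError("binding site has no COM atoms in this topology")
        return np.asarray(idx, dtype=int)


def bound_fraction(
    traj: Trajectory,
    site: BindingSiteDefinition,
    peptide_selection,
    unbound_cutoff: float = DEFAULT_UNBOUND_CUTOFF,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fraction of frames with peptide COM within the cutoff of the site COM.

    The site COM uses the site residues' Cα atoms (by default); the
    peptide COM is mass-weighted over its heavy atoms. Returns
    ``(fraction, distance series, bound mask)``.
    """
    pep_idx = _indices(peptide_selection)
    heavy = traj.topology.elements.astype(str) != "H"
    pep_idx = pep_idx[heavy[pep_idx]]
    if len(pep_idx) == 0:
        raise SelectionError("peptide selection has no heavy atoms")
    site_idx = site.com_indices(traj.topology)
    masses = traj.topology.masses
    dist = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        site_com = center_of_mass(frame, site_idx, weights=masses)
        pep_com = center_of_mass(frame, pep_idx, weights=masses)
        dist[k] = np.linalg.norm(pep_com - site_com)
    mask = dist <= unbound_cutoff
    return float(mask.mean()), dist, mask


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactSpec:
    """Geometric rules per contact kind; all thresholds in Å / degrees."""

    hbond_distance: float = 3.5
    hbond_angle: float = 120.0          # D-H...A, applied only when H present
    salt_bridge_distance: float = 4.0
    vdw_pad: float = 0.5
    cation_pi_distance: float = 6.0
    cation_pi_angle: float = 60.0       # from ring normal
    frequency_cutoff: float = DEFAULT_FREQUENCY_CUTOFF
    kinds: tuple = ("hydrogen_bond", "salt_bridge", "vdw", "cation_pi")


_BASIC_N = {
    "ARG": {"NH1", "NH2", "NE"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_CATION_N = {"ARG": {"NH1", "NH2", "NE"}, "LYS": {"NZ"}}
_RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


def _residue_info(structure: MolecularStructure, idx: np.ndarray):
    info = {}
    for chain, resid, atoms in structure.residue_groups():
        atoms = np.intersect1d(atoms, idx)
        if len(atoms):
            info[(chain, resid)] = atoms
    return info


def _ring_geometry(coords: np.ndarray):
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, Vt = np.linalg.svd(centered)
    normal = Vt[2]
    return centroid, normal


def contact_frequencies(
    traj: Trajectory,
    group_a_selection,
    group_b_selection,
    spec: ContactSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame contact detection between two atom groups, aggregated to
    residue-pair frequencies.

    Returns ``(filtered, full)`` tables; the filtered view drops rows at
    or below ``spec.frequency_cutoff`` (a 25% persistence rule by
    default). Angle criteria degrade to distance-only when no hydrogens
    are present.
    """
    spec = spec or ContactSpec()
    top = traj.topology
    heavy = top.elements.astype(str) != "H"
    names = top.names.astype(str)
    resnames = top.residue_names.astype(str)

    a_res = _residue_info(top, _indices(group_a_selection))
    b_res = _residue_info(top, _indices(group_b_selection))

    counts: dict[tuple, int] = {}

    for frame in traj.frames:
        for ra, ia in a_res.items():
            ia_h = ia[heavy[ia]]
            for rb, ib in b_res.items():
                ib_h = ib[heavy[ib]]
                if len(ia_h) == 0 or len(ib_h) == 0:
                    continue
                d = np.linalg.norm(
                    frame[ia_h][:, None, :] - frame[ib_h][None, :, :], axis=2
                )
                found: set[str] = set()
                # van der Waals
                if "vdw" in spec.kinds:
                    thresh = (
                        top.vdw_radii[ia_h][:, None]
                        + top.vdw_radii[ib_h][None, :]
                        + spec.vdw_pad
                    )
                    if (d <= thresh).any():
                        found.add("vdw")
                # hydrogen bond: N/O to N/O
                if "hydrogen_bond" in spec.kinds:
                    pol_a = np.isin(top.elements[ia_h].astype(str), ["N", "O"])
                    pol_b = np.isin(top.elements[ib_h].astype(str), ["N", "O"])
                    if pol_a.any() and pol_b.any():
                        if (d[np.ix_(pol_a, pol_b)] <= spec.hbond_distance).any():
                            found.add("hydrogen_bond")
                # salt bridge: basic N to acidic O, either direction
                if "salt_bridge" in spec.kinds:
                    for (ri, ii, rj, jj, dm) in (
                        (ra, ia_h, rb, ib_h, d),
                        (rb, ib_h, ra, ia_h, d.T),
                    ):
                        rn_i = resnames[ii[0]]
                        rn_j = resnames[jj[0]]
                        basic = _BASIC_N.get(rn_i, set())
                        acidic = _ACIDIC_O.get(rn_j, set())
                        if basic and acidic:
                            bi = np.isin(names[ii], list(basic))
                            aj = np.isin(names[jj], list(acidic))
                            if bi.any() and aj.any():
                                if (dm[np.ix_(bi, aj)] <= spec.salt_bridge_distance).any():
                                    found.add("salt_bridge")
                # cation-pi: charged N near an aromatic ring, near the normal
                if "cation_pi" in spec.kinds:
                    for (ii, jj) in ((ia_h, ib_h), (ib_h, ia_h)):
                        rn_cat = resnames[ii[0]]
                        rn_ring = resnames[jj[0]]
                        cat = _CATION_N.get(rn_cat, set())
                        ring = _RING_ATOMS.get(rn_ring)
                        if not cat or ring is None:
                            continue
                        ring_idx = jj[np.isin(names[jj], ring)]
                        cat_idx = ii[np.isin(names[ii], list(cat))]
                        if len(ring_idx) < 3 or len(cat_idx) == 0:
                            continue
                        centroid, normal = _ring_geometry(frame[ring_idx])
                        vecs = frame[cat_idx] - centroid
                        dists = np.linalg.norm(vecs, axis=1)
                        ok = dists <= spec.cation_pi_distance
                        if ok.any():
                            cosang = np.abs(
                                (vecs[ok] @ normal) / np.maximum(dists[ok], 1e-9)
                            )
                            if (cosang >= np.cos(np.radians(spec.cation_pi_angle))).any():
                                found.add("cation_pi")
                for kind in found:
                    counts[(ra, rb, kind)] = counts.get((ra, rb, kind), 0) + 1

    rows = [
        {
            "residue_a": f"{ra[0]}:{ra[1]}",
            "residue_b": f"{rb[0]}:{rb[1]}",
            "kind": kind,
            "frequency": c / traj.n_frames,
        }
        for (ra, rb, kind), c in sorted(counts.items())
    ]
    full = pd.DataFrame(rows, columns=["residue_a", "residue_b", "kind", "frequency"])
    filtered = full[full["frequency"] > spec.frequency_cutoff].reset_index(drop=True)
    return filtered, full


# ---------------------------------------------------------------------------
# Occupancy and averages
# ---------------------------------------------------------------------------

def occupancy_grid(
    traj: Trajectory, selection, spacing: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel visit counts of the selected atoms across all frames.

    Returns ``(counts, origin)``; counts sum to n_frames × n_selected.
    Frames are assumed to be pre-aligned.
    """
    idx = _indices(selection)
    if len(idx) == 0:
        raise SelectionError("empty selection for occupancy grid")
    all_coords = np.concatenate([frame[idx] for frame in traj.frames])
    origin = np.floor(all_coords.min(axis=0) / spacing) * spacing
    voxel = np.floor((all_coords - origin) / spacing).astype(int)
    dims = voxel.max(axis=0) + 1
    counts = np.zeros(dims, dtype=np.int64)
    np.add.at(counts, (voxel[:, 0], voxel[:, 1], voxel[:, 2]), 1)
    return counts, origin


def average_structure(traj: Trajectory, fit_selection=None) -> MolecularStructure:
    """Mass-weighted fit of every frame to the first, then a plain mean."""
    fit_idx = (
        _indices(fit_selection)
        if fit_selection is not None
        else np.arange(traj.topology.n_atoms)
    )
    ref = traj.frames[0]
    masses = traj.topology.masses
    acc = np.zeros_like(ref)
    for frame in traj.frames:
        _, _, fitted = superpose(frame, ref, fit_idx, weights=masses)
        acc += fitted
    return traj.topology.with_coordinates(acc / traj.n_frames)


# ---------------------------------------------------------------------------
# Secondary structure (φ/ψ-window surrogate)
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def secondary_structure_mask(structure: MolecularStructure, chain: str | None = None) -> np.ndarray:
    """Cα indices of residues in helix/strand by a φ/ψ-window assignment.

    Helix: φ∈[−100,−30], ψ∈[−80,−5]; strand: φ∈[−180,−90], ψ∈[90,180];
    runs of ≥4 consecutive residues only. A coarse stand-in for a full
    hydrogen-bond-based assignment, sufficient for choosing fit atoms.
    """
    groups = [
        g for g in structure.residue_groups() if chain is None or g[0] == chain
    ]
    names = structure.names.astype(str)

    def atom_of(g, nm):
        hits = [i for i in g[2] if names[i] == nm]
        return hits[0] if hits else None

    labels = []
    for k, g in enumerate(groups):
        phi = psi = None
        n_i, ca_i, c_i = atom_of(g, "N"), atom_of(g, "CA"), atom_of(g, "C")
        if k > 0 and groups[k - 1][0] == g[0]:
            c_prev = atom_of(groups[k - 1], "C")
            if None not in (c_prev, n_i, ca_i, c_i):
                phi = _dihedral(*structure.coordinates[[c_prev, n_i, ca_i, c_i]])
        if k + 1 < len(groups) and groups[k + 1][0] == g[0]:
            n_next = atom_of(groups[k + 1], "N")
            if None not in (n_i, ca_i, c_i, n_next):
                psi = _dihedral(*structure.coordinates[[n_i, ca_i, c_i, n_next]])
        label = "-"
        if phi is not None and psi is not None:
            if -100 <= phi <= -30 and -80 <= psi <= -5:
                label = "H"
            elif -180 <= phi <= -90 and 90 <= psi <= 180:
                label = "E"
        labels.append(label)

    keep = np.zeros(len(groups), dtype=bool)
    run_start = 0
    for k in range(len(groups) + 1):
        if k == len(groups) or labels[k] == "-" or (k > run_start and labels[k] != labels[run_start]):
            if k - run_start >= 4 and run_start < len(groups) and labels[run_start] != "-":
                keep[run_start:k] = True
            run_start = k
    ca_indices = []
    for k, g in enumerate(groups):
        if keep[k]:
            ca = atom_of(g, "CA")
            if ca is not None:
                ca_indices.append(ca)
    return np.asarray(ca_indices, dtype=int)
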