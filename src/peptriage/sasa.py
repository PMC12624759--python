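"""Solvent-accessible surface area: Shrake–Rupley and the LCPO approximation.

Shrake–Rupley places a deterministic golden-section spiral of test points
on each atom's solvent-expanded sphere and counts the points not occluded
by any neighbor; the LCPO route approximates per-atom exposed area from
pairwise sphere-overlap (cap) areas and is what the nonpolar solvation
term of the rescoring module consumes.

Hydrogens are excluded by default (united-atom convention); pass
``include_hydrogens=True`` to keep them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import MolecularStructure
from .elements import BACKBONE_ATOMS

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


class SasaError(ValueError):
    pass


@dataclass
class SasaResult:
    per_atom: np.ndarray              # Å², aligned with the structure's atoms
    per_residue: dict                 # (chain, resid) -> Å²
    sidechain_per_residue: dict       # (chain, resid) -> Å²
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    structure: MolecularStructure,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Per-atom, per-residue, and side-chain SASA by test-point counting.

    Per-atom area = (exposed points / n_points) * 4π(r_i + probe)².
    """
    if n_points < 96:
        raise SasaError("n_points must be >= 96")
    coords = structure.coordinates
    radii = structure.vdw_radii
    heavy = structure.elements.astype(str) != "H"
    active = np.ones(structure.n_atoms, bool) if include_hydrogens else heavy

    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    per_atom = np.zeros(structure.n_atoms)

    act_idx = np.flatnonzero(active)
    if len(act_idx):
        tree = cKDTree(coords[act_idx])
        max_r = expanded[act_idx].max()
        for i in act_idx:
            ri = expanded[i]
            pts = coords[i] + ri * unit
            neighbors = act_idx[tree.query_ball_point(coords[i], ri + max_r)]
            neighbors = neighbors[neighbors != i]
            if len(neighbors):
                d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(-1)
                buried = (d2 < (expanded[neighbors][None, :] ** 2)).any(axis=1)
                exposed = int((~buried).sum())
            else:
                exposed = n_points
            per_atom[i] = exposed / n_points * 4.0 * np.pi * ri * ri

    per_residue: dict = {}
    sidechain: dict = {}
    for chain, resid, idx in structure.residue_groups():
        key = (chain, resid)
        per_residue[key] = float(per_atom[idx].sum())
        names = structure.names[idx].astype(str)
        sc = idx[(~np.isin(names, list(BACKBONE_ATOMS))) & heavy[idx]]
        sidechain[key] = float(per_atom[sc].sum()) if len(sc) else 0.0
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        sidechain_per_residue=sidechain,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


def sidechain_sasa(
    structure: MolecularStructure,
    residue_id: tuple[str, int],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> float:
    """SASA summed over the non-backbone heavy atoms of one residue.

    ``residue_id`` is ``(chain_id, residue_index)``. Backbone is N, CA,
    C, O; glycine therefore reports 0.
    """
    result = shrake_rupley(structure, probe_radius=probe_radius, n_points=n_points)
    if residue_id not in result.sidechain_per_residue:
        raise KeyError(f"residue {residue_id} not found in structure")
    return result.sidechain_per_residue[residue_id]


def _pair_overlap_area(r1: float, r2: float, d: float) -> float:
    """Area of sphere 1 buried by overlapping sphere 2 (both solvent-expanded)."""
    if d >= r1 + r2:
        return 0.0
    if d + r1 <= r2:          # sphere 1 fully inside sphere 2
        return 4.0 * np.pi * r1 * r1
    if d + r2 <= r1:          # sphere 2 fully inside sphere 1: no cap on 1's surface
        return 0.0
    return 2.0 * np.pi * r1 * (r1 - d / 2.0 - (r1 * r1 - r2 * r2) / (2.0 * d))


def lcpo_sasa(
    structure: MolecularStructure,
    lcpo_params: np.ndarray,
    probe_radius: float = DEFAULT_PROBE,
) -> tuple[np.ndarray, float]:
    """Linear Combination of Pairwise Overlaps surface area.

    ``lcpo_params`` is an (n_atoms, 4) array of the P1..P4 weights. For
    atom i with solvent-expanded radius R_i = r_vdw + probe and neighbor
    set N(i) = {j : d_ij < R_i + R_j}:

        A_i = P1·4πR_i² + P2·Σ_j A_ij + P3·Σ_j Σ_k A_jk
              + P4·Σ_j [A_ij · Σ_k A_jk]

    where A_ij is the cap area of sphere i buried by j, and k runs over
    N(i) ∩ N(j), k ≠ j. Negative per-atom areas are clamped to zero.
    Hydrogens are skipped (their P rows are ignored).
    """
    P = np.asarray(lcpo_params, dtype=float)
    if P.shape != (structure.n_atoms, 4):
        raise SasaError(
            f"lcpo_params shape {P.shape} != ({structure.n_atoms}, 4)"
        )
    heavy = np.flatnonzero(structure.elements.astype(str) != "H")
    coords = structure.coordinates[heavy]
    R = structure.vdw_radii[heavy] + probe_radius
    n = len(heavy)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.0 * R.max(), output_type="ndarray")
    # neighbor lists restricted to actual sphere overlap
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d < R[a] + R[b]:
            nbrs[a].append(b)
            nbrs[b].append(a)

    def A(i: int, j: int) -> float:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        return _pair_overlap_area(R[i], R[j], d)

    per_atom = np.zeros(structure.n_atoms)
    for ii in range(n):
        i = heavy[ii]
        p1, p2, p3, p4 = P[i]
        S1 = 4.0 * np.pi * R[ii] * R[ii]
        term2 = 0.0
        term3 = 0.0
        term4 = 0.0
        ni = set(nbrs[ii])
        for j in nbrs[ii]:
            a_ij = A(ii, j)
            term2 += a_ij
            inner = 0.0
            for k in nbrs[j]:
                if k != ii and k in ni:
                    inner += A(j, k)
            term3 += inner
            term4 += a_ij * inner
        per_atom[i] = max(0.0, p1 * S1 + p2 * term2 + p3 * term3 + p4 * term4)
    return per_atom, float(per_atom.sum())
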