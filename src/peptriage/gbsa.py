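"""Single-trajectory MM/GBSA-style rescoring.

ΔG_bind = G(complex) − G(receptor) − G(ligand), all three species
evaluated on the same frame (single-trajectory protocol) and the solute
entropy neglected, so the result is a *relative* binding energy:

    G = E_coulomb + E_LJ + G_GB + γ·SASA_LCPO + β

The polar solvation term is a generalized-Born model with
pairwise-descreening effective radii and OBC-style tanh rescaling
(α=1.0, β=0.8, γ=4.85); the dielectric offset is zero so that an
isolated ion's effective radius equals its intrinsic radius and the
Born limit is exact. The nonpolar term is surface tension γ (default
0.0072 kcal/mol/Å²) times the LCPO surface area. No cutoffs, no salt.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MolecularStructure, Trajectory
from .sasa import lcpo_sasa

COULOMB_CONST = 332.0637  # kcal·Å/(mol·e²)
GB_CONST = 166.0319       # conventional GB prefactor, kcal·Å/(mol·e²)

OBC_ALPHA = 1.0
OBC_BETA = 0.8
OBC_GAMMA = 4.85

#: mbondi-style intrinsic GB radii by element (Å).
DEFAULT_GB_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "S": 1.8, "P": 1.85}
#: HCT descreening scale factors by element.
DEFAULT_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96, "P": 0.86}


class EnergyError(ValueError):
    pass


@dataclass
class TopologyParams:
    """Per-atom energy parameters plus global solvation constants."""

    charge: np.ndarray                  # e
    gb_radius: np.ndarray               # Å
    screen: np.ndarray                  # dimensionless descreening scale
    lj_sigma: np.ndarray                # Å
    lj_epsilon: np.ndarray              # kcal/mol
    lcpo: np.ndarray                    # (n, 4) P1..P4
    interior_dielectric: float = 1.0
    solvent_dielectric: float = 78.5
    surface_tension: float = 0.0072     # kcal/mol/Å²
    surface_offset: float = 0.0         # kcal/mol

    def __post_init__(self):
        self.charge = np.asarray(self.charge, float)
        self.gb_radius = np.asarray(self.gb_radius, float)
        self.screen = np.asarray(self.screen, float)
        self.lj_sigma = np.asarray(self.lj_sigma, float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, float)
        self.lcpo = np.asarray(self.lcpo, float).reshape(len(self.charge), 4)
        if np.any(self.gb_radius <= 0):
            raise EnergyError("gb_radius must be positive")
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise EnergyError("dielectrics must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    def subset(self, indices: np.ndarray) -> "TopologyParams":
        idx = np.asarray(indices, int)
        return TopologyParams(
            charge=self.charge[idx],
            gb_radius=self.gb_radius[idx],
            screen=self.screen[idx],
            lj_sigma=self.lj_sigma[idx],
            lj_epsilon=self.lj_epsilon[idx],
            lcpo=self.lcpo[idx],
            interior_dielectric=self.interior_dielectric,
            solvent_dielectric=self.solvent_dielectric,
            surface_tension=self.surface_tension,
            surface_offset=self.surface_offset,
        )

    @classmethod
    def from_structure(
        cls,
        structure: MolecularStructure,
        charges: np.ndarray | None = None,
        **kwargs,
    ) -> "TopologyParams":
        """Element-table defaults (mbondi radii, generic LJ, two-body LCPO)."""
        els = structure.elements.astype(str)
        n = structure.n_atoms
        return cls(
            charge=np.zeros(n) if charges is None else charges,
            gb_radius=np.array([DEFAULT_GB_RADII.get(e, 1.7) for e in els]),
            screen=np.array([DEFAULT_SCREEN.get(e, 0.8) for e in els]),
            lj_sigma=np.full(n, 3.4),
            lj_epsilon=np.full(n, 0.1),
            lcpo=np.tile([1.0, -1.0, 0.0, 0.0], (n, 1)),
            **kwargs,
        )

    def to_csv(self) -> str:
        df = pd.DataFrame(
            {
                "serial": np.arange(1, self.n_atoms + 1),
                "charge": self.charge,
                "gb_radius": self.gb_radius,
                "screen": self.screen,
                "lj_sigma": self.lj_sigma,
                "lj_epsilon": self.lj_epsilon,
                "lcpo_p1": self.lcpo[:, 0],
                "lcpo_p2": self.lcpo[:, 1],
                "lcpo_p3": self.lcpo[:, 2],
                "lcpo_p4": self.lcpo[:, 3],
            }
        )
        return df.to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str, **kwargs) -> "TopologyParams":
        df = pd.read_csv(io.StringIO(text)).sort_values("serial")
        return cls(
            charge=df["charge"].to_numpy(),
            gb_radius=df["gb_radius"].to_numpy(),
            screen=df["screen"].to_numpy(),
            lj_sigma=df["lj_sigma"].to_numpy(),
            lj_epsilon=df["lj_epsilon"].to_numpy(),
            lcpo=df[["lcpo_p1", "lcpo_p2", "lcpo_p3", "lcpo_p4"]].to_numpy(),
            **kwargs,
        )


@dataclass
class EnergyDecomposition:
    E_coulomb: float
    E_lj: float
    G_gb: float
    G_np: float
    sem: float | None = None
    per_frame: pd.DataFrame | None = None

    @property
    def G_total(self) -> float:
        return self.E_coulomb + self.E_lj + self.G_gb + self.G_np


# ---------------------------------------------------------------------------
# Molecular mechanics terms
# ---------------------------------------------------------------------------

def coulomb_lj_energy(
    coords: np.ndarray,
    topology: TopologyParams,
    pairs: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pairwise Coulomb and Lennard-Jones energies (no cutoff).

    ``pairs`` is an (m, 2) array of atom index pairs; by default all
    unique intramolecular pairs. Lorentz–Berthelot combination rules.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if pairs is None:
        iu, ju = np.triu_indices(n, k=1)
        pairs = np.column_stack([iu, ju])
    if len(pairs) == 0:
        return 0.0, 0.0
    i = pairs[:, 0]
    j = pairs[:, 1]
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    if np.any(r < 1e-6):
        raise EnergyError("overlapping atoms (r < 1e-6 Å)")
    e_coul = float(
        (COULOMB_CONST * topology.charge[i] * topology.charge[j] / r).sum()
        / topology.interior_dielectric
    )
    sigma = 0.5 * (topology.lj_sigma[i] + topology.lj_sigma[j])
    eps = np.sqrt(topology.lj_epsilon[i] * topology.lj_epsilon[j])
    sr6 = (sigma / r) ** 6
    e_lj = float((4.0 * eps * (sr6 * sr6 - sr6)).sum())
    return e_coul, e_lj


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

def effective_born_radii(coords: np.ndarray, topology: TopologyParams) -> np.ndarray:
    """OBC-rescaled pairwise-descreening effective radii."""
    coords = np.asarray(coords, float)
    n = len(coords)
    rho = topology.gb_radius          # zero dielectric offset
    s = topology.screen * rho
    I = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            sj = s[j]
            if r + sj <= rho[i]:
                continue  # j's descreening sphere buried inside i
            U = r + sj
            L = max(rho[i], abs(r - sj))
            term = 0.5 * (
                1.0 / L
                - 1.0 / U
                + 0.25 * (r - sj * sj / r) * (1.0 / (U * U) - 1.0 / (L * L))
                + 0.5 * np.log(L / U) / r
            )
            if sj - r > rho[i]:  # atom i inside j's descreening sphere
                term += 1.0 / rho[i] - 1.0 / L
            I[i] += term
    psi = I * rho
    inv_b = 1.0 / rho - np.tanh(OBC_ALPHA * psi - OBC_BETA * psi**2 + OBC_GAMMA * psi**3) / rho
    if np.any(inv_b <= 0):
        bad = int(np.argmax(inv_b <= 0))
        raise EnergyError(f"non-positive effective Born radius for atom {bad}")
    return 1.0 / inv_b


def gb_polar(coords: np.ndarray, topology: TopologyParams) -> float:
    """GB polar solvation energy (Still's f_GB, self terms included)."""
    coords = np.asarray(coords, float)
    q = topology.charge
    B = effective_born_radii(coords, topology)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff * diff).sum(-1)
    BB = B[:, None] * B[None, :]
    f = np.sqrt(r2 + BB * np.exp(-r2 / (4.0 * BB)))
    pref = -GB_CONST * (1.0 / topology.interior_dielectric - 1.0 / topology.solvent_dielectric)
    return float(pref * (q[:, None] * q[None, :] / f).sum())


# ---------------------------------------------------------------------------
# MM/GBSA assembly
# ---------------------------------------------------------------------------

def _species_energy(
    structure: MolecularStructure, coords: np.ndarray, topology: TopologyParams
) -> EnergyDecomposition:
    e_coul, e_lj = coulomb_lj_energy(coords, topology)
    g_gb = gb_polar(coords, topology)
    _, sasa_total = lcpo_sasa(structure.with_coordinates(coords), topology.lcpo)
    g_np = topology.surface_tension * sasa_total + topology.surface_offset
    return EnergyDecomposition(E_coulomb=e_coul, E_lj=e_lj, G_gb=g_gb, G_np=g_np)


def gbsa_frame(
    structure: MolecularStructure,
    coords: np.ndarray,
    topology: TopologyParams,
    receptor_indices: np.ndarray,
    ligand_indices: np.ndarray,
) -> EnergyDecomposition:
    """ΔG for one frame: G(complex) − G(receptor) − G(ligand).

    The receptor/ligand partition must be disjoint and cover all atoms;
    all three species are evaluated on the same coordinates.
    """
    rec = np.asarray(receptor_indices, int)
    lig = np.asarray(ligand_indices, int)
    if np.intersect1d(rec, lig).size:
        raise EnergyError("receptor/ligand partition overlaps")
    if len(rec) + len(lig) != topology.n_atoms:
        raise EnergyError("partition does not cover all atoms")
    coords = np.asarray(coords, float)

    def sub_structure(idx):
        return MolecularStructure(
            structure.serials[idx], structure.names[idx], structure.elements[idx],
            structure.residue_names[idx], structure.residue_indices[idx],
            structure.chain_ids[idx], coords[idx],
        )

    g_cplx = _species_energy(structure, coords, topology)
    g_rec = _species_energy(sub_structure(rec), coords[rec], topology.subset(rec))
    g_lig = _species_energy(sub_structure(lig), coords[lig], topology.subset(lig))
    return EnergyDecomposition(
        E_coulomb=g_cplx.E_coulomb - g_rec.E_coulomb - g_lig.E_coulomb,
        E_lj=g_cplx.E_lj - g_rec.E_lj - g_lig.E_lj,
        G_gb=g_cplx.G_gb - g_rec.G_gb - g_lig.G_gb,
        G_np=g_cplx.G_np - g_rec.G_np - g_lig.G_np,
    )


def gbsa_trajectory(
    traj: Trajectory,
    topology: TopologyParams,
    receptor_indices: np.ndarray,
    ligand_indices: np.ndarray,
    frame_stride: int = 1,
) -> EnergyDecomposition:
    """Frame-averaged ΔG with the standard error of the mean over frames."""
    frames = traj.frames[::frame_stride]
    rows = []
    for k, coords in enumerate(frames):
        d = gbsa_frame(traj.topology, coords, topology, receptor_indices, ligand_indices)
        rows.append(
            {
                "frame": k * frame_stride,
                "E_coulomb": d.E_coulomb,
                "E_lj": d.E_lj,
                "G_gb": d.G_gb,
                "G_np": d.G_np,
                "G_total": d.G_total,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    sem = float(table["G_total"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return EnergyDecomposition(
        E_coulomb=float(table["E_coulomb"].mean()),
        E_lj=float(table["E_lj"].mean()),
        G_gb=float(table["G_gb"].mean()),
        G_np=float(table["G_np"].mean()),
        sem=sem,
        per_frame=table,
    )
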