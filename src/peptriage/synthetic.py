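"""Synthetic inputs with planted ground truth.

Every generator is a pure function of its arguments (seed included) and
returns, next to the structures, a :class:`GeneratorManifest` whose
planted values are re-derivable from the emitted coordinates alone:

* a pseudo-protein shell enclosing a spherical cavity of known volume
  (cavity detection substrate);
* a rigid toy receptor + tripeptide trajectory whose per-frame
  center-of-mass distance follows a scripted bound/unbound mask, with a
  planted salt bridge, hydrogen bond, and cation–π contact present in
  exactly the bound frames;
* pose ensembles of a Tyr tripeptide in a spherical cage whose aperture
  is tuned until the measured aromatic side-chain SASA hits a requested
  burial;
* a charged host–guest pair where complementary charges mark the true
  binder and like charges the decoy.

The toys use dummy atoms with explicit per-atom parameters; nothing here
aims at physical realism — the point is unambiguous, recomputable truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import MolecularStructure, Trajectory
from .gbsa import TopologyParams
from .sasa import sphere_points

CARBON_VDW = 1.70
POCKET_PROBE = 1.2


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorManifest:
    seed: int
    planted_truth: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(
            {
                "seed": self.seed,
                "planted_truth": self.planted_truth,
                "parameters": self.parameters,
            },
            indent=2,
            sort_keys=True,
            default=default,
        )


def _fibonacci_shell(n: int, radius: float) -> np.ndarray:
    return radius * sphere_points(n)


def _make_structure(
    names, residue_names, residue_indices, chain_ids, coords
) -> MolecularStructure:
    n = len(names)
    return MolecularStructure(
        serials=np.arange(1, n + 1),
        names=names,
        elements=["C" if nm[0] == "C" else nm[0] for nm in names],
        residue_names=residue_names,
        residue_indices=residue_indices,
        chain_ids=chain_ids,
        coordinates=np.asarray(coords, float),
    )


# ---------------------------------------------------------------------------
# Cavity protein
# ---------------------------------------------------------------------------

def gen_cavity_protein(
    sphere_radius: float = 4.0,
    shell_atoms: int | None = None,
    jitter: float = 0.05,
    seed: int = 0,
    n_layers: int = 3,
    layer_gap: float = 1.2,
    mouth_half_width: float = 1.0,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[MolecularStructure, GeneratorManifest]:
    """Thick carbon shell enclosing an empty sphere with one narrow mouth.

    The innermost atom layer sits at ``sphere_radius + vdW + probe`` so
    the voxel-occupancy cavity has radius ≈ ``sphere_radius``. Atom
    spacing on each layer is ≈0.9 Å: for spacing g, the voxelized cavity
    radius overshoots by 2.9 − sqrt(2.9² − (g/2)²), which keeps the
    volume bias within a few percent. The mouth (atoms removed inside a
    narrow cone about +z) has an aperture below 2×probe, so grid
    occupancy seals it and the cavity stays topologically enclosed; the
    generator verifies enclosure by flood fill and refuses otherwise.

    The manifest records the ideal cavity volume (4/3)πr³, the center,
    and the mouth direction.
    """
    if sphere_radius < 2.0:
        raise GeneratorError("sphere_radius must be >= 2 Å")
    if 2.0 * mouth_half_width >= 2.0 * POCKET_PROBE:
        raise GeneratorError("mouth aperture must be narrower than 2×probe")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, float)
    inflate = CARBON_VDW + POCKET_PROBE
    r0 = sphere_radius + inflate
    target_spacing = 0.9
    coords_list = []
    for layer in range(n_layers):
        radius = r0 + layer * layer_gap
        n = shell_atoms if (shell_atoms and layer == 0) else int(
            np.ceil(4.0 * np.pi * radius**2 / target_spacing**2)
        )
        pts = _fibonacci_shell(n, radius)
        # carve the mouth: a cone about +z with the requested half-width
        cos_theta = np.sqrt(max(0.0, 1.0 - (mouth_half_width / radius) ** 2))
        keep = (pts[:, 2] / radius) < cos_theta
        pts = pts[keep]
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
        coords_list.append(pts)
    coords = np.vstack(coords_list) + center
    n_atoms = len(coords)
    names = [f"C{i % 8 + 1}" for i in range(n_atoms)]
    resids = [i // 8 + 1 for i in range(n_atoms)]
    structure = _make_structure(
        names=names,
        residue_names=["DUM"] * n_atoms,
        residue_indices=resids,
        chain_ids=["A"] * n_atoms,
        coords=coords,
    )

    # enclosure check: flood fill from the cavity center must not escape
    filled = flood_fill_cavity(structure, center, spacing=1.0)
    if filled is None:
        raise GeneratorError(
            "shell does not enclose the cavity (flood fill escapes); "
            "increase shell density or reduce jitter/mouth width"
        )
    manifest = GeneratorManifest(
        seed=seed,
        planted_truth={
            "cavity_volume": 4.0 / 3.0 * np.pi * sphere_radius**3,
            "cavity_center": center.tolist(),
            "mouth_direction": [0.0, 0.0, 1.0],
        },
        parameters={
            "sphere_radius": sphere_radius,
            "shell_atoms": shell_atoms,
            "jitter": jitter,
            "n_layers": n_layers,
            "layer_gap": layer_gap,
            "mouth_half_width": mouth_half_width,
            "n_atoms": n_atoms,
        },
    )
    return structure, manifest


def flood_fill_cavity(
    structure: MolecularStructure,
    start: np.ndarray,
    spacing: float = 1.0,
    probe_radius: float = POCKET_PROBE,
) -> float | None:
    """Voxel volume of the empty region containing ``start``.

    Independent of the pocket-detection pipeline: voxelizes by
    per-atom vdW + probe inflation and flood-fills 6-connected empty
    voxels. Returns None when the region touches the grid boundary
    (i.e. is not enclosed).
    """
    coords = structure.coordinates
    radii = structure.vdw_radii
    pad = 3.0
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
    axes = [lo[k] + (np.arange(dims[k]) + 0.5) * spacing for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    tree = cKDTree(centers)
    occupied = np.zeros(len(centers), bool)
    for r in np.unique(radii):
        for hits in tree.query_ball_point(coords[radii == r], r + probe_radius):
            occupied[hits] = True
    empty = ~occupied.reshape(dims)
    labels, _ = ndimage.label(empty, structure=ndimage.generate_binary_structure(3, 1))
    start_voxel = tuple(int((np.asarray(start)[k] - lo[k]) / spacing) for k in range(3))
    if any(not (0 <= start_voxel[k] < dims[k]) for k in range(3)):
        return None  # start lies outside the grid: trivially not enclosed
    lab = labels[start_voxel]
    if lab == 0:
        return None
    mask = labels == lab
    # enclosed iff the component never reaches the grid faces
    if (
        mask[0, :, :].any() or mask[-1, :, :].any()
        or mask[:, 0, :].any() or mask[:, -1, :].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    ):
        return None
    return float(mask.sum()) * spacing**3


def gen_convex_ball(radius: float = 8.0, spacing: float = 1.8) -> MolecularStructure:
    """A solid convex ball of carbons — the zero-cavity control."""
    grid = np.arange(-radius, radius + spacing, spacing)
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    n = len(pts)
    return _make_structure(
        names=[f"C{i % 8 + 1}" for i in range(n)],
        residue_names=["DUM"] * n,
        residue_indices=[i // 8 + 1 for i in range(n)],
        chain_ids=["A"] * n,
        coords=pts,
    )


# ---------------------------------------------------------------------------
# Binding trajectory
# ---------------------------------------------------------------------------

# peptide template: Arg-Tyr-Arg with the atoms the contact rules need;
# z spans roughly [-2, +1] so the Tyr ring faces the receptor below
_PEPTIDE_ATOMS: list[tuple[str, str, int, tuple[float, float, float]]] = [
    # (atom name, residue name, residue index, local coordinates)
    ("N", "ARG", 1, (-4.0, 0.0, 0.0)),
    ("CA", "ARG", 1, (-2.9, 0.6, 0.2)),
    ("C", "ARG", 1, (-1.8, -0.1, 0.6)),
    ("O", "ARG", 1, (-1.8, -1.3, 0.6)),
    ("CB", "ARG", 1, (-2.9, 1.8, -0.8)),
    ("NH1", "ARG", 1, (-3.4, 3.0, -1.5)),
    ("N", "TYR", 2, (-0.7, 0.5, 0.8)),
    ("CA", "TYR", 2, (0.5, -0.1, 1.0)),
    ("C", "TYR", 2, (1.7, 0.7, 0.9)),
    ("O", "TYR", 2, (1.8, 1.9, 1.0)),
    ("CB", "TYR", 2, (0.5, -1.2, 0.0)),
    ("N", "ARG", 3, (2.6, 0.0, 0.6)),
    ("CA", "ARG", 3, (3.8, 0.6, 0.4)),
    ("C", "ARG", 3, (5.0, -0.2, 0.4)),
    ("O", "ARG", 3, (5.1, -1.4, 0.5)),
    ("CB", "ARG", 3, (3.8, 1.6, -0.7)),
    ("NH1", "ARG", 3, (4.4, 2.9, -1.1)),
]
_RING_CENTER = np.array([0.5, -1.5, -2.0])
_RING_RADIUS = 1.39
_RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]


def _peptide_template() -> tuple[list, np.ndarray]:
    rows = list(_PEPTIDE_ATOMS)
    coords = [np.array(c) for (_n, _r, _i, c) in rows]
    for k, name in enumerate(_RING_NAMES):
        ang = np.radians(60.0 * k)
        pos = _RING_CENTER + _RING_RADIUS * np.array([np.cos(ang), np.sin(ang), 0.0])
        rows.append((name, "TYR", 2, tuple(pos)))
        coords.append(pos)
    # hydroxyl para to CG (bonded to CZ at 180°)
    oh = _RING_CENTER + (2.75) * np.array([np.cos(np.pi), np.sin(np.pi), 0.0])
    rows.append(("OH", "TYR", 2, tuple(oh)))
    coords.append(oh)
    return rows, np.array(coords)


def gen_binding_trajectory(
    n_frames: int = 1000,
    bound_mask: np.ndarray | None = None,
    bound_com_distance: float = 4.0,
    unbound_com_distance: float = 9.0,
    noise_sigma: float = 0.2,
    seed: int = 0,
) -> tuple[Trajectory, TopologyParams, GeneratorManifest]:
    """Rigid receptor + tripeptide trajectory with a scripted bound mask.

    The peptide rigidly translates between a bound placement (COM at
    ``bound_com_distance`` above the receptor-site Cα COM) and an
    unbound one, with isotropic Gaussian COM jitter truncated at 3σ so
    the scripted mask is exactly recoverable whenever
    ``bound + 3σ < 6 < unbound − 3σ``. A salt bridge (Arg1 NH1 – Glu
    OE1), a hydrogen bond (Tyr OH – Ser OG), and a cation–π pair (Lys
    NZ under the Tyr ring) hold in exactly the bound frames.
    """
    if bound_mask is None:
        rng_mask = np.random.default_rng(seed + 1)
        bound_mask = rng_mask.random(n_frames) < 0.6
    bound_mask = np.asarray(bound_mask, bool)
    n_frames = len(bound_mask)
    cutoff = 6.0
    if not (
        bound_com_distance + 3 * noise_sigma < cutoff
        and unbound_com_distance - 3 * noise_sigma > cutoff
    ):
        raise GeneratorError(
            "separability violated: need bound+3σ < 6 Å < unbound−3σ"
        )
    rng = np.random.default_rng(seed)

    pep_rows, pep_local = _peptide_template()
    # mass-weighted COM of the (all heavy) template at the origin
    from .elements import atomic_weight

    masses = np.array([atomic_weight(nm[0]) for (nm, _r, _i, _c) in pep_rows])
    com = (masses[:, None] * pep_local).sum(0) / masses.sum()
    pep_local = pep_local - com

    bound_shift = np.array([0.0, 0.0, bound_com_distance])
    pep_bound = pep_local + bound_shift

    def pep_atom(name, resid):
        for k, (nm, _r, ri, _c) in enumerate(pep_rows):
            if nm == name and ri == resid:
                return k
        raise KeyError((name, resid))

    ring_idx = [pep_atom(nm, 2) for nm in _RING_NAMES]
    ring_centroid = pep_bound[ring_idx].mean(axis=0)

    # receptor: 8 Cα on a circle (COM at the origin) + contact side chains
    rec_rows: list[tuple[str, str, int, np.ndarray]] = []
    rec_resnames = ["GLU", "SER", "LYS", "ALA", "ALA", "ALA", "ALA", "ALA"]
    for k, resname in enumerate(rec_resnames):
        ang = 2.0 * np.pi * k / 8.0
        rec_rows.append(
            ("CA", resname, k + 1, np.array([2.0 * np.cos(ang), 2.0 * np.sin(ang), 0.0]))
        )
    rec_rows.append(("OE1", "GLU", 1, pep_bound[pep_atom("NH1", 1)] + [0, 0, -3.2]))
    rec_rows.append(("OG", "SER", 2, pep_bound[pep_atom("OH", 2)] + [0, 0, -2.8]))
    rec_rows.append(("NZ", "LYS", 3, ring_centroid + [0, 0, -4.5]))

    names = [r[0] for r in rec_rows] + [r[0] for r in pep_rows]
    resnames = [r[1] for r in rec_rows] + [r[1] for r in pep_rows]
    resids = [r[2] for r in rec_rows] + [r[2] for r in pep_rows]
    chains = ["A"] * len(rec_rows) + ["B"] * len(pep_rows)
    rec_coords = np.array([r[3] for r in rec_rows])
    base = np.vstack([rec_coords, pep_bound])
    topology_structure = _make_structure(
        names=names,
        residue_names=resnames,
        residue_indices=resids,
        chain_ids=chains,
        coords=base,
    )
    # every receptor residue must fall inside the 5 Å site definition
    tree = cKDTree(pep_bound)
    for r in rec_rows:
        if tree.query(r[3])[0] > 5.0:
            raise GeneratorError("receptor residue outside the 5 Å site shell")

    n_rec = len(rec_rows)
    frames = []
    distances = []
    for k in range(n_frames):
        d = bound_com_distance if bound_mask[k] else unbound_com_distance
        jit = np.clip(
            rng.normal(0.0, noise_sigma, size=3), -3 * noise_sigma, 3 * noise_sigma
        )
        shift = np.array([0.0, 0.0, d]) + jit
        frame = base.copy()
        frame[n_rec:] = pep_local + shift
        frames.append(frame)
        distances.append(float(np.linalg.norm(shift)))

    traj = Trajectory(
        topology=topology_structure,
        frames=frames,
        frame_times=[0.01 * k for k in range(n_frames)],
    )

    charge = np.zeros(len(names))
    charge[names.index("OE1")] = -1.0
    charge[n_rec + pep_atom("NH1", 1)] = 1.0
    charge[[i for i, nm in enumerate(names) if nm == "NZ"][0]] = 1.0
    topo = TopologyParams.from_structure(topology_structure, charges=charge)

    manifest = GeneratorManifest(
        seed=seed,
        planted_truth={
            "bound_mask": bound_mask.astype(int).tolist(),
            "bound_fraction": float(bound_mask.mean()),
            "com_distances": distances,
            "site_residues": [["A", k + 1] for k in range(8)],
            "contacts": [
                {"residue_a": "A:1", "residue_b": "B:1", "kind": "salt_bridge"},
                {"residue_a": "A:2", "residue_b": "B:2", "kind": "hydrogen_bond"},
                {"residue_a": "A:3", "residue_b": "B:2", "kind": "cation_pi"},
            ],
            "contact_frequency": float(bound_mask.mean()),
        },
        parameters={
            "n_frames": n_frames,
            "bound_com_distance": bound_com_distance,
            "unbound_com_distance": unbound_com_distance,
            "noise_sigma": noise_sigma,
        },
    )
    return traj, topo, manifest


# ---------------------------------------------------------------------------
# Pose sets with controlled aromatic burial
# ---------------------------------------------------------------------------

_GYG_ATOMS: list[tuple[str, str, int, tuple[float, float, float]]] = [
    ("N", "GLY", 1, (-3.6, 0.3, 0.1)),
    ("CA", "GLY", 1, (-2.5, 0.9, 0.4)),
    ("C", "GLY", 1, (-1.3, 0.1, 0.2)),
    ("O", "GLY", 1, (-1.3, -1.1, 0.3)),
    ("N", "TYR", 2, (-0.2, 0.7, 0.0)),
    ("CA", "TYR", 2, (1.0, 0.1, -0.2)),
    ("C", "TYR", 2, (2.2, 0.9, 0.1)),
    ("O", "TYR", 2, (2.2, 2.1, 0.2)),
    ("N", "GLY", 3, (3.4, 0.2, 0.1)),
    ("CA", "GLY", 3, (4.6, 0.8, 0.3)),
    ("C", "GLY", 3, (5.8, 0.0, 0.1)),
    ("O", "GLY", 3, (5.9, -1.2, 0.1)),
]
_TYR_SC_CENTER = np.array([1.0, -1.6, -1.6])


def _pose_peptide() -> tuple[list, np.ndarray]:
    rows = list(_GYG_ATOMS)
    coords = [np.array(c) for (_n, _r, _i, c) in rows]
    cb = np.array([1.0, -1.2, -0.4])
    rows.append(("CB", "TYR", 2, tuple(cb)))
    coords.append(cb)
    for k, name in enumerate(_RING_NAMES):
        ang = np.radians(60.0 * k)
        pos = _TYR_SC_CENTER + _RING_RADIUS * np.array(
            [np.cos(ang), 0.38 * np.sin(ang), 0.925 * np.sin(ang)]
        )
        rows.append((name, "TYR", 2, tuple(pos)))
        coords.append(pos)
    oh = _TYR_SC_CENTER + 2.75 * np.array([-1.0, 0.0, 0.0])
    rows.append(("OH", "TYR", 2, tuple(oh)))
    coords.append(oh)
    return rows, np.array(coords)


def _measure_sidechain_sasa(coords, radii, sc_idx, n_points=960, probe=1.4) -> float:
    unit = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    total = 0.0
    for i in sc_idx:
        ri = expanded[i]
        pts = coords[i] + ri * unit
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + expanded.max()) if j != i]
        if nbrs:
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(-1)
            buried = (d2 < expanded[np.asarray(nbrs)][None, :] ** 2).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        total += exposed / n_points * 4.0 * np.pi * ri * ri
    return total


@dataclass
class PoseSet:
    poses: list                      # list of (pose_id, MolecularStructure)
    scores: dict                     # pose_id -> {vina, cnn_score, cnn_affinity}
    manifest: GeneratorManifest


def gen_pose_set(
    target_sasa: list[float],
    score_triples: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
    sasa_cutoff: float = 20.0,
    tolerance: float = 2.0,
) -> PoseSet:
    """Poses of a Tyr tripeptide in a carbon cage with tuned aromatic burial.

    For each requested side-chain SASA a spherical cage around the Tyr
    side chain is opened by an aperture found by bisection until the
    Shrake–Rupley side-chain SASA is within ``tolerance`` of the
    request. The manifest records each pose's measured SASA and which
    poses survive the ``sasa_cutoff`` (≤ cutoff retained).
    """
    rng = np.random.default_rng(seed)
    pep_rows, pep_coords = _pose_peptide()
    sc_names = {"CB", "OH"} | set(_RING_NAMES)
    sc_idx = [
        k for k, (nm, _r, ri, _c) in enumerate(pep_rows) if ri == 2 and nm in sc_names
    ]
    center = pep_coords[sc_idx].mean(axis=0)
    extent = max(
        np.linalg.norm(pep_coords[i] - center) + CARBON_VDW + 1.4 for i in sc_idx
    )
    # concentric cage layers so inner test points can be buried too
    layer_radii = np.arange(extent + 0.2, 1.6, -1.2)
    layers = []
    for radius in layer_radii:
        n = int(np.ceil(4.0 * np.pi * radius**2 / 1.1**2))
        layers.append(center + _fibonacci_shell(n, radius))
    cage_full = np.vstack(layers)
    # drop cage atoms sitting on top of peptide atoms
    ptree = cKDTree(pep_coords)
    cage_full = cage_full[ptree.query(cage_full)[0] > 2.0]
    # aperture opens about the direction away from the backbone
    axis = center - pep_coords[[k for k, r in enumerate(pep_rows) if r[0] == "CA" and r[2] == 2][0]]
    axis = axis / np.linalg.norm(axis)
    rad = np.linalg.norm(cage_full - center, axis=1)
    proj = (cage_full - center) @ axis / np.maximum(rad, 1e-9)

    def build(aperture_cos: float):
        cage = cage_full[proj < aperture_cos]
        coords = np.vstack([cage, pep_coords])
        radii = np.full(len(coords), CARBON_VDW)
        for off, (nm, _r, _i, _c) in enumerate(pep_rows):
            el = nm[0]
            radii[len(cage) + off] = {"N": 1.55, "O": 1.52}.get(el, CARBON_VDW)
        sc_global = [len(cage) + k for k in sc_idx]
        return cage, coords, radii, sc_global

    # aperture parameter t: cage atoms kept where proj < t, so t=-1 means
    # no cage (free side chain) and t=+1 a fully closed shell
    _, coords_free, radii_free, sc_free = build(-1.0)
    free_sasa = _measure_sidechain_sasa(coords_free, radii_free, sc_free)

    poses = []
    scores: dict = {}
    measured_list = []
    for p, target in enumerate(target_sasa):
        if not (0.0 <= target <= free_sasa):
            raise GeneratorError(
                f"requested SASA {target} Å² outside feasible range [0, {free_sasa:.1f}]"
            )
        lo, hi = -1.0, 1.0   # SASA decreases monotonically from lo to hi
        best = None
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            cage, coords, radii, sc_global = build(mid)
            measured = _measure_sidechain_sasa(coords, radii, sc_global)
            if best is None or abs(measured - target) < abs(best[1] - target):
                best = (mid, measured, cage, coords)
            if abs(measured - target) <= 0.25 * tolerance:
                break
            if measured < target:   # too buried: open the cage
                hi = mid
            else:
                lo = mid
        mid, measured, cage, coords = best
        if abs(measured - target) > tolerance:
            raise GeneratorError(
                f"could not reach requested SASA {target} Å² "
                f"(closest {measured:.2f}; feasible range [0, {free_sasa:.1f}])"
            )
        pose_id = f"pose_{p:03d}"
        n_cage_atoms = len(cage)
        names = [f"C{i % 8 + 1}" for i in range(n_cage_atoms)] + [
            r[0] for r in pep_rows
        ]
        resnames = ["DUM"] * n_cage_atoms + [r[1] for r in pep_rows]
        resids = [i // 8 + 1 for i in range(n_cage_atoms)] + [r[2] for r in pep_rows]
        chains = ["A"] * n_cage_atoms + ["B"] * len(pep_rows)
        structure = _make_structure(names, resnames, resids, chains, coords)
        poses.append((pose_id, structure))
        measured_list.append(measured)
        if score_triples is not None:
            vina, cnn_s, cnn_a = score_triples[p]
        else:
            vina = float(-5.0 - 3.0 * rng.random())
            cnn_s = float(rng.random())
            cnn_a = float(3.0 + 3.0 * rng.random())
        scores[pose_id] = {"vina": vina, "cnn_score": cnn_s, "cnn_affinity": cnn_a}

    survivors = [
        pid for (pid, _s), m in zip(poses, measured_list) if m <= sasa_cutoff
    ]
    manifest = GeneratorManifest(
        seed=seed,
        planted_truth={
            "measured_sasa": {pid: m for (pid, _s), m in zip(poses, measured_list)},
            "survivors": survivors,
            "free_sidechain_sasa": free_sasa,
        },
        parameters={
            "target_sasa": list(target_sasa),
            "sasa_cutoff": sasa_cutoff,
            "tolerance": tolerance,
        },
    )
    return PoseSet(poses=poses, scores=scores, manifest=manifest)


# ---------------------------------------------------------------------------
# Energy toy systems
# ---------------------------------------------------------------------------

@dataclass
class EnergySystem:
    strong: tuple[MolecularStructure, TopologyParams]
    decoy: tuple[MolecularStructure, TopologyParams]
    receptor_indices: np.ndarray
    ligand_indices: np.ndarray
    manifest: GeneratorManifest


def gen_energy_system(
    strong_separation: float | None = None,
    decoy_separation: float | None = None,
    host_charge: float = -0.5,
    guest_charge: float = 1.0,
    lj_sigma: float = 3.4,
    lj_epsilon: float = 0.1,
    jitter: float = 0.0,
    seed: int = 0,
) -> EnergySystem:
    """Charged host–guest toy: complementary charges vs a like-charge decoy.

    The host is two carbons carrying ``host_charge`` each; the guest is
    one carbon at the Lennard-Jones contact distance (2^(1/6)σ by
    default) carrying ``guest_charge`` in the strong complex and
    ``−guest_charge`` in the decoy. The manifest records the expected
    binding-energy ordering.
    """
    contact = 2.0 ** (1.0 / 6.0) * lj_sigma
    strong_separation = contact if strong_separation is None else strong_separation
    decoy_separation = contact if decoy_separation is None else decoy_separation
    if strong_separation < contact - 1e-9 or decoy_separation < contact - 1e-9:
        raise GeneratorError("separations must be at least the LJ contact distance")
    rng = np.random.default_rng(seed)

    def complex_structure(sep: float) -> MolecularStructure:
        host = np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        guest = np.array([[1.0 + sep, 0.0, 0.0]])
        coords = np.vstack([host, guest])
        if jitter > 0:
            coords = coords + rng.normal(0.0, jitter, coords.shape)
        return _make_structure(
            names=["C1", "C2", "C1"],
            residue_names=["HST", "HST", "GST"],
            residue_indices=[1, 1, 2],
            chain_ids=["A", "A", "B"],
            coords=coords,
        )

    def topology(gq: float) -> TopologyParams:
        return TopologyParams(
            charge=np.array([host_charge, host_charge, gq]),
            gb_radius=np.array([1.7, 1.7, 1.7]),
            screen=np.array([0.72, 0.72, 0.72]),
            lj_sigma=np.full(3, lj_sigma),
            lj_epsilon=np.full(3, lj_epsilon),
            lcpo=np.tile([1.0, -1.0, 0.0, 0.0], (3, 1)),
        )

    expected = "strong<decoy" if host_charge * guest_charge < 0 else "decoy<strong"
    manifest = GeneratorManifest(
        seed=seed,
        planted_truth={"energy_ordering": expected},
        parameters={
            "strong_separation": strong_separation,
            "decoy_separation": decoy_separation,
            "host_charge": host_charge,
            "guest_charge": guest_charge,
        },
    )
    return EnergySystem(
        strong=(complex_structure(strong_separation), topology(guest_charge)),
        decoy=(complex_structure(decoy_separation), topology(-guest_charge)),
        receptor_indices=np.array([0, 1]),
        ligand_indices=np.array([2]),
        manifest=manifest,
    )
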