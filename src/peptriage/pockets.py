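"""Grid-based cavity detection: occupancy, buriedness scan, morphological
cleanup, connected-component labeling, and hydrophobicity ranking.

The structure is embedded in a regular grid (default 1.0 Å). Voxels
within (vdW + probe) of an atom are *protein*; the rest are *candidate*
pocket points. Each candidate's buriedness counts how many of a fixed
set of scan directions (6 axes + 8 cube diagonals by default) hit
protein within a range; weakly buried points are discarded, a binary
opening removes speckle and reconnects areas, and 6-connected
components above a volume floor become ranked pockets.

The buriedness threshold, probe radius, and scan range are conventions
(exposed as parameters) — the geometric construction, not any
particular force-field probe, defines the cavity here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import MolecularStructure
from .elements import HYDROPHOBIC_RESIDUES, THREE_TO_ONE

DEFAULT_SPACING = 1.0
DEFAULT_PROBE = 1.2
DEFAULT_BURIAL_THRESHOLD = 9
DEFAULT_MAX_RANGE = 10.0
DEFAULT_MIN_VOLUME = 30.0

#: 6 axis + 8 diagonal scan directions.
DIRECTIONS_14 = np.array(
    [
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
        [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1],
    ],
    dtype=int,
)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


@dataclass
class PocketGrid:
    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    protein: np.ndarray                  # bool, protein-occupied voxels
    candidate: np.ndarray                # bool, surviving pocket candidates
    buriedness: np.ndarray | None = None # int per voxel (0 where not scanned)
    n_rays: int = 14

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.spacing


@dataclass
class Pocket:
    label: int
    voxels: np.ndarray                   # (n, 3) integer voxel indices
    volume: float                        # ų
    centroid: np.ndarray                 # Å
    lining_residues: set = field(default_factory=set)
    hydrophobic_score: float = 0.0


def build_grid(
    structure: MolecularStructure,
    spacing: float = DEFAULT_SPACING,
    probe_radius: float = DEFAULT_PROBE,
    padding: float | None = None,
) -> PocketGrid:
    """Voxelize a structure: protein within (vdW + probe) of any atom."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = structure.coordinates
    radii = structure.vdw_radii
    pad = padding if padding is not None else 2.0 * radii.max() + probe_radius
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
    # voxel centers, marked per atom with that atom's inflated radius
    axes = [lo[k] + (np.arange(dims[k]) + 0.5) * spacing for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    center_tree = cKDTree(centers)
    occupied = np.zeros(len(centers), dtype=bool)
    for r in np.unique(radii):
        sub = coords[radii == r]
        for hits in center_tree.query_ball_point(sub, r + probe_radius):
            occupied[hits] = True
    protein = occupied.reshape(dims)
    return PocketGrid(
        origin=lo,
        spacing=spacing,
        dims=dims,
        protein=protein,
        candidate=~protein,
    )


def buriedness_scan(
    grid: PocketGrid,
    n_rays: int = 14,
    max_range: float = DEFAULT_MAX_RANGE,
    threshold: int = DEFAULT_BURIAL_THRESHOLD,
) -> PocketGrid:
    """Count, per candidate voxel, scan directions hitting protein.

    Directions are the 6 grid axes for ``n_rays=6``, plus the 8 cube
    diagonals for 14, plus the 12 edge diagonals for 26. Candidates with
    buriedness below ``threshold`` are excluded.
    """
    if n_rays == 6:
        dirs = DIRECTIONS_14[:6]
    elif n_rays == 14:
        dirs = DIRECTIONS_14
    elif n_rays == 26:
        edge = [
            [a, b, c]
            for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0) and abs(a) + abs(b) + abs(c) == 2
        ]
        dirs = np.vstack([DIRECTIONS_14, np.array(edge, int)])
    else:
        raise ValueError("n_rays must be one of 6, 14, 26")

    protein = grid.protein
    dims = protein.shape
    buried = np.zeros(dims, dtype=np.int32)
    for d in dirs:
        step_len = np.linalg.norm(d) * grid.spacing
        max_steps = int(np.floor(max_range / step_len))
        hit = np.zeros(dims, dtype=bool)
        for s in range(1, max_steps + 1):
            shift = d * s
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            ok = True
            for ax in range(3):
                if shift[ax] > 0:
                    if shift[ax] >= dims[ax]:
                        ok = False
                        break
                    dst[ax] = slice(0, dims[ax] - shift[ax])
                    src[ax] = slice(shift[ax], dims[ax])
                elif shift[ax] < 0:
                    if -shift[ax] >= dims[ax]:
                        ok = False
                        break
                    dst[ax] = slice(-shift[ax], dims[ax])
                    src[ax] = slice(0, dims[ax] + shift[ax])
            if not ok:
                break
            hit[tuple(dst)] |= protein[tuple(src)]
        buried += hit.astype(np.int32)

    candidate = grid.candidate & (buried >= threshold)
    return PocketGrid(
        origin=grid.origin,
        spacing=grid.spacing,
        dims=grid.dims,
        protein=protein,
        candidate=candidate,
        buriedness=buried,
        n_rays=len(dirs),
    )


def morph_clean(grid: PocketGrid, erode_steps: int = 1, dilate_steps: int = 1) -> PocketGrid:
    """Binary erosion then dilation (opening) on the candidate set."""
    cand = grid.candidate
    if erode_steps > 0:
        cand = ndimage.binary_erosion(cand, structure=_STRUCT6, iterations=erode_steps)
    if dilate_steps > 0:
        cand = ndimage.binary_dilation(cand, structure=_STRUCT6, iterations=dilate_steps)
        cand &= ~grid.protein  # dilation must not grow into the protein
    return PocketGrid(
        origin=grid.origin,
        spacing=grid.spacing,
        dims=grid.dims,
        protein=grid.protein,
        candidate=cand,
        buriedness=grid.buriedness,
        n_rays=grid.n_rays,
    )


def label_pockets(
    grid: PocketGrid,
    structure: MolecularStructure,
    min_volume: float = DEFAULT_MIN_VOLUME,
    probe_radius: float = DEFAULT_PROBE,
) -> list[Pocket]:
    """6-connected components of surviving candidates, largest first.

    Volume = voxel count × spacing³. Lining residues are those with any
    atom within (vdW + probe + spacing) of a pocket voxel center.
    """
    labels, n = ndimage.label(grid.candidate, structure=_STRUCT6)
    pockets: list[Pocket] = []
    tree = cKDTree(structure.coordinates)
    reach = structure.vdw_radii.max() + probe_radius + grid.spacing
    for lab in range(1, n + 1):
        mask = labels == lab
        count = int(mask.sum())
        volume = count * grid.spacing**3
        if volume < min_volume:
            continue
        centers = grid.voxel_centers(mask)
        centroid = centers.mean(axis=0)
        lining: set = set()
        for center in centers:
            for ai in tree.query_ball_point(center, reach):
                d = np.linalg.norm(structure.coordinates[ai] - center)
                if d <= structure.vdw_radii[ai] + probe_radius + grid.spacing:
                    lining.add(
                        (
                            str(structure.chain_ids[ai]),
                            int(structure.residue_indices[ai]),
                            str(structure.residue_names[ai]),
                        )
                    )
        pockets.append(
            Pocket(
                label=lab,
                voxels=np.argwhere(mask),
                volume=volume,
                centroid=centroid,
                lining_residues=lining,
            )
        )
    pockets.sort(key=lambda p: -p.volume)
    return pockets


def rank_pockets(
    pockets: list[Pocket],
    volume_weight: float = 1.0,
    hydrophobic_weight: float = 0.0,
) -> list[Pocket]:
    """Score lining hydrophobicity and re-rank pockets.

    hydrophobic_score = fraction of lining residues in {A,V,L,I,M,F,W,P}
    (a residue-class surrogate for a hydrophobic-probe field). The final
    order is by ``volume_weight·(volume/max_volume) +
    hydrophobic_weight·score``, descending.
    """
    if not pockets:
        return []
    for p in pockets:
        if p.lining_residues:
            hydro = sum(
                1
                for (_c, _i, res3) in p.lining_residues
                if THREE_TO_ONE.get(res3, "X") in HYDROPHOBIC_RESIDUES
            )
            p.hydrophobic_score = hydro / len(p.lining_residues)
        else:
            p.hydrophobic_score = 0.0
    vmax = max(p.volume for p in pockets)
    return sorted(
        pockets,
        key=lambda p: -(volume_weight * p.volume / vmax + hydrophobic_weight * p.hydrophobic_score),
    )


def find_pockets(
    structure: MolecularStructure,
    spacing: float = DEFAULT_SPACING,
    probe_radius: float = DEFAULT_PROBE,
    n_rays: int = 14,
    max_range: float = DEFAULT_MAX_RANGE,
    threshold: int = DEFAULT_BURIAL_THRESHOLD,
    erode_steps: int = 1,
    dilate_steps: int = 1,
    min_volume: float = DEFAULT_MIN_VOLUME,
) -> list[Pocket]:
    """Full pipeline: grid → buriedness → opening → labeled, ranked pockets."""
    grid = build_grid(structure, spacing=spacing, probe_radius=probe_radius)
    grid = buriedness_scan(grid, n_rays=n_rays, max_range=max_range, threshold=threshold)
    grid = morph_clean(grid, erode_steps=erode_steps, dilate_steps=dilate_steps)
    pockets = label_pockets(grid, structure, min_volume=min_volume, probe_radius=probe_radius)
    return rank_pockets(pockets)
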