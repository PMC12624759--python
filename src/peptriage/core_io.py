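"""Molecular data model, PDB I/O, atom selections, and rigid-body geometry.

Coordinates are Å throughout, residue numbering is 1-based as in the PDB
format, and residue ranges in selections are closed intervals.

The in-memory model is structure-of-arrays: a :class:`MolecularStructure`
holds parallel numpy/object arrays over atoms, and a :class:`Trajectory`
shares one topology across an ordered list of coordinate frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .elements import (
    BACKBONE_ATOMS,
    atomic_weight,
    element_from_atom_name,
    vdw_radius,
)


class PDBParseError(ValueError):
    """Malformed or empty PDB content."""


class StructuralMismatchError(ValueError):
    """Coordinate sets or model blocks that do not share a topology."""


class SelectionError(ValueError):
    """Bad selection grammar or an empty selection where one is required."""


class DegenerateFitError(ValueError):
    """Too few or collinear atoms for a rigid-body fit."""


@dataclass
class AtomRecord:
    """One atom: identifiers, coordinates, and an assigned vdW radius."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    coordinates: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    vdw_radius: float = 1.70


class MolecularStructure:
    """An ordered collection of atoms with vectorized per-atom columns."""

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_indices: Sequence[int],
        chain_ids: Sequence[str],
        coordinates: np.ndarray,
        occupancy: Sequence[float] | None = None,
        bfactor: Sequence[float] | None = None,
        metadata: dict | None = None,
    ):
        n = len(names)
        if n == 0:
            raise PDBParseError("structure contains no atoms")
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coordinates = np.asarray(coordinates, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coordinates)):
            raise PDBParseError("non-finite coordinates")
        self.occupancy = (
            np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=float)
        )
        self.bfactor = (
            np.zeros(n) if bfactor is None else np.asarray(bfactor, dtype=float)
        )
        self.vdw_radii = np.array([vdw_radius(e) for e in self.elements])
        self.masses = np.array([atomic_weight(e) for e in self.elements])
        self.metadata: dict = metadata or {}

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.residue_names[i]),
            residue_index=int(self.residue_indices[i]),
            chain_id=str(self.chain_ids[i]),
            coordinates=self.coordinates[i].copy(),
            occupancy=float(self.occupancy[i]),
            bfactor=float(self.bfactor[i]),
            vdw_radius=float(self.vdw_radii[i]),
        )

    def __len__(self) -> int:
        return self.n_atoms

    def residue_groups(self) -> list[tuple[str, int, np.ndarray]]:
        """(chain_id, residue_index, atom indices) in order of appearance."""
        groups: list[tuple[str, int, np.ndarray]] = []
        seen: dict[tuple[str, int], list[int]] = {}
        order: list[tuple[str, int]] = []
        for i in range(self.n_atoms):
            key = (str(self.chain_ids[i]), int(self.residue_indices[i]))
            if key not in seen:
                seen[key] = []
                order.append(key)
            seen[key].append(i)
        for key in order:
            groups.append((key[0], key[1], np.asarray(seen[key], dtype=int)))
        return groups

    def validate(self) -> None:
        keys = list(zip(self.chain_ids, self.residue_indices, self.names))
        if len(set(keys)) != len(keys):
            raise PDBParseError("duplicate (chain, residue, atom name) records")

    def with_coordinates(self, coords: np.ndarray) -> "MolecularStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coordinates.shape:
            raise StructuralMismatchError(
                f"coordinate shape {coords.shape} does not match "
                f"{self.coordinates.shape}"
            )
        s = MolecularStructure(
            self.serials, self.names, self.elements, self.residue_names,
            self.residue_indices, self.chain_ids, coords,
            self.occupancy, self.bfactor, dict(self.metadata),
        )
        return s


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one atom table."""

    topology: MolecularStructure
    frames: list[np.ndarray]
    frame_times: list[float] | None = None

    def __post_init__(self):
        if not self.frames:
            raise StructuralMismatchError("trajectory needs at least one frame")
        n = self.topology.n_atoms
        checked = []
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise StructuralMismatchError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)"
                )
            checked.append(f)
        self.frames = checked

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, k: int) -> MolecularStructure:
        return self.topology.with_coordinates(self.frames[k])

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)


@dataclass
class AtomSelection:
    """A selection expression together with its resolved atom indices."""

    expression: str
    resolved_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        idx = np.asarray(self.resolved_indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0)):
            idx = np.unique(idx)
        self.resolved_indices = idx

    def __len__(self) -> int:
        return len(self.resolved_indices)


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_idx = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bf = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}")
    if not element:
        element = element_from_atom_name(name)
    return serial, name, element.capitalize(), res_name, res_idx, chain, (x, y, z), occ, bf


def parse_structure(text: str) -> MolecularStructure:
    """Parse PDB-format content into a single structure.

    MODEL/ENDMDL records, if present, are ignored and every ATOM/HETATM
    line contributes one atom; use :func:`parse_trajectory` for
    multi-model files meant as frames.
    """
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            rows.append(_parse_atom_line(line, lineno))
    if not rows:
        raise PDBParseError("no ATOM/HETATM records found")
    cols = list(zip(*rows))
    return MolecularStructure(
        serials=cols[0], names=cols[1], elements=cols[2],
        residue_names=cols[3], residue_indices=cols[4], chain_ids=cols[5],
        coordinates=np.array(cols[6]), occupancy=cols[7], bfactor=cols[8],
    )


def parse_trajectory(text: str) -> Trajectory:
    """Parse a multi-MODEL PDB file into a trajectory.

    The topology is taken from the first model; all models must have the
    same atom count and ordering. A file without MODEL records yields a
    one-frame trajectory.
    """
    blocks: list[list[str]] = []
    current: list[str] = []
    in_model = False
    saw_model = False
    lineno_of: list[list[int]] = []
    cur_nos: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("MODEL"):
            saw_model = True
            in_model = True
            current, cur_nos = [], []
        elif line.startswith("ENDMDL"):
            in_model = False
            blocks.append(current)
            lineno_of.append(cur_nos)
        elif line.startswith(("ATOM  ", "HETATM")):
            if not saw_model:
                if not blocks:
                    blocks.append([])
                    lineno_of.append([])
                blocks[0].append(line)
                lineno_of[0].append(lineno)
            elif in_model:
                current.append(line)
                cur_nos.append(lineno)
    blocks = [b for b in blocks if b]
    if not blocks:
        raise PDBParseError("no ATOM/HETATM records found")

    first = [_parse_atom_line(l, n) for l, n in zip(blocks[0], lineno_of[0])]
    cols = list(zip(*first))
    topology = MolecularStructure(
        serials=cols[0], names=cols[1], elements=cols[2],
        residue_names=cols[3], residue_indices=cols[4], chain_ids=cols[5],
        coordinates=np.array(cols[6]), occupancy=cols[7], bfactor=cols[8],
    )
    frames = [np.array(cols[6], dtype=float)]
    for bi, (block, nos) in enumerate(zip(blocks[1:], lineno_of[1:]), start=2):
        if len(block) != topology.n_atoms:
            raise StructuralMismatchError(
                f"MODEL {bi} has {len(block)} atoms, expected {topology.n_atoms}"
            )
        rows = [_parse_atom_line(l, n) for l, n in zip(block, nos)]
        for r, expected_name in zip(rows, topology.names):
            if r[1] != expected_name:
                raise StructuralMismatchError(
                    f"MODEL {bi} atom ordering differs from MODEL 1 "
                    f"({r[1]!r} vs {expected_name!r})"
                )
        frames.append(np.array([r[6] for r in rows], dtype=float))
    return Trajectory(topology=topology, frames=frames)


def _format_atom_line(s: MolecularStructure, i: int, serial: int) -> str:
    name = str(s.names[i])
    # PDB convention: 4-char names start in column 13, shorter in column 14
    if len(name) >= 4:
        name_f = name[:4]
    else:
        name_f = f" {name:<3s}"
    x, y, z = s.coordinates[i]
    return (
        f"ATOM  {serial:5d} {name_f}{'':1s}{str(s.residue_names[i])[:3]:>3s} "
        f"{str(s.chain_ids[i])[:1]:1s}{int(s.residue_indices[i]):4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{s.occupancy[i]:6.2f}{s.bfactor[i]:6.2f}"
        f"          {str(s.elements[i]):>2s}"
    )


def write_structure(structure: MolecularStructure) -> str:
    """Render a structure as PDB text (ATOM records plus TER/END)."""
    lines = []
    for i in range(structure.n_atoms):
        lines.append(_format_atom_line(structure, i, i + 1))
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory) -> str:
    """Render a trajectory as multi-MODEL PDB text."""
    lines = []
    for k, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {k:4d}")
        s = traj.topology.with_coordinates(frame)
        for i in range(s.n_atoms):
            lines.append(_format_atom_line(s, i, i + 1))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords):
#   expr     := term (("and" | "or") term)*    -- left-associative, "and" binds
#   term     := "not" term | "(" expr ")" | primitive
#   primitive:= "chain" ID | "resid" N | "resid" N-M | "name" NAME+
#             | "backbone" | "sidechain" | "heavy" | "hydrogen" | "all"

class _Tokens:
    def __init__(self, expression: str):
        self.expression = expression
        self.tokens: list[tuple[str, int]] = []
        i = 0
        while i < len(expression):
            if expression[i].isspace():
                i += 1
                continue
            if expression[i] in "()":
                self.tokens.append((expression[i], i))
                i += 1
                continue
            j = i
            while j < len(expression) and not expression[j].isspace() and expression[j] not in "()":
                j += 1
            self.tokens.append((expression[i:j], i))
            i = j
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expression))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok


def _resolve_primitive(tokens: _Tokens, s: MolecularStructure) -> np.ndarray:
    tok, at = tokens.next()
    if tok is None:
        raise SelectionError(f"unexpected end of selection at position {at}")
    low = tok.lower()
    if low == "(":
        mask = _resolve_expr(tokens, s)
        closing, cat = tokens.next()
        if closing != ")":
            raise SelectionError(f"expected ')' at position {cat}")
        return mask
    if low == "not":
        return ~_resolve_primitive(tokens, s)
    if low == "all":
        return np.ones(s.n_atoms, dtype=bool)
    if low == "backbone":
        return np.isin(s.names.astype(str), list(BACKBONE_ATOMS))
    if low == "sidechain":
        return ~np.isin(s.names.astype(str), list(BACKBONE_ATOMS))
    if low == "heavy":
        return s.elements.astype(str) != "H"
    if low == "hydrogen":
        return s.elements.astype(str) == "H"
    if low == "chain":
        val, vat = tokens.next()
        if val is None:
            raise SelectionError(f"'chain' needs an argument at position {vat}")
        return s.chain_ids.astype(str) == val
    if low == "resid":
        val, vat = tokens.next()
        if val is None:
            raise SelectionError(f"'resid' needs an argument at position {vat}")
        try:
            if "-" in val and not val.startswith("-"):
                lo_s, hi_s = val.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(val)
        except ValueError:
            raise SelectionError(f"bad residue range {val!r} at position {vat}")
        return (s.residue_indices >= lo) & (s.residue_indices <= hi)
    if low == "name":
        names = []
        while True:
            nxt, _ = tokens.peek()
            if nxt is None or nxt.lower() in ("and", "or", "not") or nxt in "()":
                break
            names.append(tokens.next()[0])
        if not names:
            raise SelectionError(f"'name' needs at least one atom name at position {at}")
        return np.isin(s.names.astype(str), names)
    raise SelectionError(f"unknown selection keyword {tok!r} at position {at}")


def _resolve_expr(tokens: _Tokens, s: MolecularStructure) -> np.ndarray:
    # "and" binds tighter than "or"
    def and_chain():
        mask = _resolve_primitive(tokens, s)
        while tokens.peek()[0] is not None and tokens.peek()[0].lower() == "and":
            tokens.next()
            mask = mask & _resolve_primitive(tokens, s)
        return mask

    mask = and_chain()
    while tokens.peek()[0] is not None and tokens.peek()[0].lower() == "or":
        tokens.next()
        mask = mask | and_chain()
    return mask


def select_atoms(structure: MolecularStructure, expression: str) -> AtomSelection:
    """Resolve a selection expression against a structure.

    An expression matching nothing yields an empty (valid) selection;
    only grammar errors raise.
    """
    tokens = _Tokens(expression)
    if not tokens.tokens:
        raise SelectionError("empty selection expression")
    mask = _resolve_expr(tokens, structure)
    leftover, at = tokens.peek()
    if leftover is not None:
        raise SelectionError(f"unexpected token {leftover!r} at position {at}")
    return AtomSelection(expression=expression, resolved_indices=np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------

def _as_indices(sel, n: int) -> np.ndarray:
    if sel is None:
        return np.arange(n)
    if isinstance(sel, AtomSelection):
        return sel.resolved_indices
    return np.asarray(sel, dtype=int)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices=None,
    weights: np.ndarray | None = None,
):
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The optionally mass-weighted Kabsch fit is computed over
    ``fit_indices`` and the resulting proper rotation + translation is
    applied to all atoms of ``mobile``.

    Returns ``(rotation, translation, fitted_coordinates)`` such that
    ``fitted = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise StructuralMismatchError(
            f"mobile {mobile.shape} vs reference {reference.shape}"
        )
    idx = _as_indices(fit_indices, len(mobile))
    if len(idx) < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    m = mobile[idx]
    r = reference[idx]
    if weights is None:
        w = np.ones(len(idx))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) == len(mobile):
            w = w[idx]
        elif len(w) != len(idx):
            raise StructuralMismatchError("weights length mismatch")
    w = w / w.sum()
    mc = (w[:, None] * m).sum(axis=0)
    rc = (w[:, None] * r).sum(axis=0)
    m0 = m - mc
    r0 = r - rc
    # collinearity check: centered cloud must span >= 2 dimensions
    if np.linalg.matrix_rank(m0 * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    H = (m0 * w[:, None]).T @ r0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rotation = Vt.T @ D @ U.T
    translation = rc - rotation @ mc
    fitted = mobile @ rotation.T + translation
    return rotation, translation, fitted


def rmsd(a: np.ndarray, b: np.ndarray, indices=None) -> float:
    """Root-mean-square deviation over ``indices`` (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ia = _as_indices(indices, len(a))
    if a.shape != b.shape:
        raise StructuralMismatchError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if len(ia) == 0:
        raise SelectionError("empty selection for RMSD")
    d = a[ia] - b[ia]
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def center_of_mass(coords: np.ndarray, indices=None, weights=None) -> np.ndarray:
    """Weighted mean position; unweighted defaults to the arithmetic mean."""
    coords = np.asarray(coords, dtype=float)
    idx = _as_indices(indices, len(coords))
    if len(idx) == 0:
        raise SelectionError("empty selection for center of mass")
    c = coords[idx]
    if weights is None:
        return c.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    if len(w) == len(coords):
        w = w[idx]
    elif len(w) != len(idx):
        raise StructuralMismatchError("weights length mismatch")
    return (w[:, None] * c).sum(axis=0) / w.sum()
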