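"""Pose triage: NMR-informed aromatic-burial SASA filter and per-score
top-pose selection.

Docked pose ensembles carry three black-box score annotations — a
Vina-style energy (lower is better), a CNN pose score in [0, 1]
(higher better), and a CNN affinity (higher better). The filter removes
poses whose designated aromatic side chain is too solvent-exposed to be
consistent with the saturation-transfer NMR epitope; the selector then
picks one top pose per scoring function (pose #1/#2/#3), deliberately
without consensus ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import MolecularStructure
from .sasa import DEFAULT_POINTS, DEFAULT_PROBE, shrake_rupley

DEFAULT_SASA_CUTOFF = 20.0

SCORE_KEYS = ("vina", "cnn_score", "cnn_affinity")


class PoseDataError(ValueError):
    pass


@dataclass
class PoseRecord:
    pose_id: str
    complex_structure: MolecularStructure
    peptide_chain: str
    scores: dict = field(default_factory=dict)
    aromatic_residue: tuple[str, int] | None = None  # (chain, resid)
    aromatic_sasa: float | None = None

    def require_scores(self) -> None:
        for key in SCORE_KEYS:
            if key not in self.scores:
                raise PoseDataError(f"pose {self.pose_id!r} missing score {key!r}")


def compute_aromatic_sasa(
    pose: PoseRecord,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> float:
    """Side-chain SASA of the pose's designated aromatic residue, cached."""
    if pose.aromatic_residue is None:
        raise PoseDataError(f"pose {pose.pose_id!r} has no aromatic residue designated")
    result = shrake_rupley(
        pose.complex_structure, probe_radius=probe_radius, n_points=n_points
    )
    if pose.aromatic_residue not in result.sidechain_per_residue:
        raise PoseDataError(
            f"pose {pose.pose_id!r}: residue {pose.aromatic_residue} absent from complex"
        )
    pose.aromatic_sasa = result.sidechain_per_residue[pose.aromatic_residue]
    return pose.aromatic_sasa


def sasa_filter(
    poses: list[PoseRecord],
    sasa_cutoff: float = DEFAULT_SASA_CUTOFF,
    strict_less: bool = False,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> tuple[list[PoseRecord], pd.DataFrame]:
    """Exclude poses whose aromatic side-chain SASA exceeds the cutoff.

    Default boundary semantics retain a pose *at* the cutoff (only
    strictly-greater values are excluded); ``strict_less=True`` flips
    the boundary. Returns the retained poses and an audit table with
    every pose's measured value and decision.
    """
    retained: list[PoseRecord] = []
    rows = []
    for pose in poses:
        value = pose.aromatic_sasa
        if value is None:
            value = compute_aromatic_sasa(pose, probe_radius, n_points)
        keep = value < sasa_cutoff if strict_less else value <= sasa_cutoff
        rows.append(
            {
                "pose_id": pose.pose_id,
                "aromatic_sasa": value,
                "cutoff": sasa_cutoff,
                "retained": keep,
            }
        )
        if keep:
            retained.append(pose)
    return retained, pd.DataFrame(rows)


def select_top_poses(poses: list[PoseRecord]) -> tuple[PoseRecord, PoseRecord, PoseRecord]:
    """One top pose per scoring function.

    pose #1 = lowest Vina score, pose #2 = highest CNN score, pose #3 =
    highest CNN affinity. The same pose may fill several slots. Ties are
    broken by lexicographic pose_id.
    """
    if not poses:
        raise PoseDataError("no poses to select from")
    for p in poses:
        p.require_scores()
    by_id = sorted(poses, key=lambda p: p.pose_id)
    # min/max keep the first (lexicographically smallest id) on ties
    pose1 = min(by_id, key=lambda p: p.scores["vina"])
    pose2 = max(by_id, key=lambda p: p.scores["cnn_score"])
    pose3 = max(by_id, key=lambda p: p.scores["cnn_affinity"])
    return pose1, pose2, pose3
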