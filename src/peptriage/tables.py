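"""Experiment-table summaries: SPR kinetics averages and STD-NMR group
epitope mapping (GEM) percentages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class KineticsSummary:
    mean_ka: float          # 1/(M s)
    mean_kd: float          # 1/s
    mean_KD: float          # M
    diagnostics: list = field(default_factory=list)


def kinetics_summary(table: pd.DataFrame, rel_tol: float = 0.10) -> KineticsSummary:
    """Unweighted column means of per-concentration kinetic fits.

    Expects columns ``ka``, ``kd``, ``KD`` (one row per analyte
    concentration). Rows where the printed KD disagrees with kd/ka by
    more than ``rel_tol`` are listed in ``diagnostics`` — reported, not
    corrected, since such inconsistencies usually trace back to the
    source table itself.
    """
    if len(table) == 0:
        raise ValueError("empty kinetics table")
    for col in ("ka", "kd", "KD"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    diags = []
    for _, row in table.iterrows():
        implied = row["kd"] / row["ka"]
        if abs(implied - row["KD"]) / row["KD"] > rel_tol:
            diags.append(
                {
                    "row": dict(row),
                    "implied_KD": implied,
                    "relative_deviation": abs(implied - row["KD"]) / row["KD"],
                }
            )
    return KineticsSummary(
        mean_ka=float(table["ka"].mean()),
        mean_kd=float(table["kd"].mean()),
        mean_KD=float(table["KD"].mean()),
        diagnostics=diags,
    )


def gem_map(integrals: dict[str, float]) -> dict[str, float]:
    """Group epitope mapping: normalize STD integrals to the strongest proton.

    The proton with the largest integral defines 100%; every other label
    is reported as a percentage of it. Ties all report 100.
    """
    if not integrals:
        raise ValueError("empty STD series")
    values = np.array(list(integrals.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("STD integrals must be non-negative")
    top = values.max()
    if top <= 0:
        raise ValueError("all STD integrals are zero")
    # divide first so the strongest proton maps to exactly 100.0
    return {label: 100.0 * (v / top) for label, v in integrals.items()}
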