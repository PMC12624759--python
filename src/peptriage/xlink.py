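"""In-silico protease digestion, peptide mass / m/z arithmetic, and
crosslink Δmass candidate search.

The workflow mirrors a chemical-crosslinking identification: digest the
target protein with trypsin-like rules, add the crosslinker+ligand mass
shift to every fragment (including variable-modification states), and
match the resulting charge-state m/z values against an observed peak
list within a ppm tolerance.

m/z uses the hydrogen-*atom* mass (1.007825 amu) per charge rather than
the bare proton (1.007276): the convention is configurable but the atom
convention is the default because it is the one consistent with
TOF-calibrated peak tables reported to four decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .elements import (
    AMIDE_DELTA,
    CARBAMIDOMETHYL,
    HYDROGEN_ATOM_MONO,
    MET_OXIDATION,
    RESIDUE_MONO_MASS,
    WATER_MONO,
)

PROTON_MASS = 1.007276
HYDROGEN_MASS = HYDROGEN_ATOM_MONO


class AlphabetError(ValueError):
    pass


@dataclass
class PeptideSpecies:
    """A peptide with terminal chemistry and modification bookkeeping."""

    sequence: str
    c_terminal_amide: bool = False
    n_terminal_free: bool = True
    fixed_mods: list = field(default_factory=list)     # (position 1-based, Δamu, name)
    variable_mods: list = field(default_factory=list)  # (position 1-based, Δamu, name)
    span: tuple | None = None                          # (start, end) 1-based inclusive
    missed_cleavages: int = 0

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(p: PeptideSpecies | str) -> float:
    """Monoisotopic mass: residue sum + water, amide correction, and mods."""
    if isinstance(p, str):
        p = PeptideSpecies(sequence=p)
    total = WATER_MONO
    for letter in p.sequence:
        try:
            total += RESIDUE_MONO_MASS[letter]
        except KeyError:
            raise AlphabetError(f"unknown residue letter {letter!r}")
    if p.c_terminal_amide:
        total += AMIDE_DELTA
    for pos, delta, _name in list(p.fixed_mods) + list(p.variable_mods):
        if not (1 <= pos <= len(p.sequence)):
            raise ValueError(f"modification position {pos} outside sequence")
        total += delta
    return total


def mz(total_mass: float, charge: int, convention: str = "hydrogen") -> float:
    """m/z of ``[M + zH]^(z+)``.

    ``convention`` is ``"hydrogen"`` (atom mass per charge, default) or
    ``"proton"``.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    adduct = HYDROGEN_MASS if convention == "hydrogen" else PROTON_MASS
    return (total_mass + charge * adduct) / charge


@dataclass
class DigestSettings:
    """Trypsin-style cleavage rules with per-residue missed-cleavage caps."""

    cleavage_residues: frozenset = frozenset({"K", "R"})
    max_missed: dict = field(default_factory=lambda: {"K": 3, "R": 2})
    global_max_missed: int = 3
    proline_rule: bool = True
    fixed_mods: list = field(default_factory=lambda: [("C", CARBAMIDOMETHYL, "carbamidomethyl")])
    variable_mods: list = field(default_factory=lambda: [("M", MET_OXIDATION, "oxidation", 1)])


def digest(sequence: str, settings: DigestSettings | None = None) -> list[PeptideSpecies]:
    """Enumerate tryptic fragments of a sequence.

    Cleavage happens C-terminal to each residue in
    ``settings.cleavage_residues`` (suppressed before Pro when the
    proline rule is on). Fragments combine adjacent zero-missed pieces
    up to the per-residue and global missed-cleavage caps. Spans are
    1-based inclusive; fixed modifications are attached, variable ones
    are left to :func:`expand_variable_mods`.
    """
    settings = settings or DigestSettings()
    for letter in sequence:
        if letter not in RESIDUE_MONO_MASS:
            raise AlphabetError(f"unknown residue letter {letter!r}")
    n = len(sequence)
    cuts = []  # cut after position i (1-based)
    for i in range(1, n):
        if sequence[i - 1] in settings.cleavage_residues:
            if settings.proline_rule and sequence[i] == "P":
                continue
            cuts.append(i)
    boundaries = [0] + cuts + [n]
    pieces = [
        (boundaries[k] + 1, boundaries[k + 1])
        for k in range(len(boundaries) - 1)
    ]
    fragments: list[PeptideSpecies] = []
    for a in range(len(pieces)):
        for b in range(a, len(pieces)):
            start = pieces[a][0]
            end = pieces[b][1]
            missed_by = {
                r: sum(
                    1
                    for i in range(start, end)
                    if sequence[i - 1] == r
                    and i in cuts
                )
                for r in settings.cleavage_residues
            }
            total_missed = sum(missed_by.values())
            if total_missed > settings.global_max_missed:
                continue
            if any(
                missed_by.get(r, 0) > settings.max_missed.get(r, 0)
                for r in settings.cleavage_residues
            ):
                continue
            sub = sequence[start - 1:end]
            fixed = [
                (pos + 1, delta, name)
                for pos, letter in enumerate(sub)
                for res, delta, name in settings.fixed_mods
                if letter == res
            ]
            fragments.append(
                PeptideSpecies(
                    sequence=sub,
                    span=(start, end),
                    missed_cleavages=total_missed,
                    fixed_mods=fixed,
                )
            )
    return fragments


def expand_variable_mods(
    fragment: PeptideSpecies, settings: DigestSettings
) -> list[PeptideSpecies]:
    """All variable-modification states of a fragment (including none)."""
    states = [fragment]
    for res, delta, name, max_count in settings.variable_mods:
        positions = [i + 1 for i, l in enumerate(fragment.sequence) if l == res]
        new_states = list(states)
        for state in states:
            used = len(state.variable_mods)
            for pos in positions:
                if used < max_count and all(p != pos for p, _, _ in state.variable_mods):
                    new_states.append(
                        PeptideSpecies(
                            sequence=state.sequence,
                            span=state.span,
                            missed_cleavages=state.missed_cleavages,
                            fixed_mods=list(state.fixed_mods),
                            variable_mods=state.variable_mods + [(pos, delta, name)],
                        )
                    )
        states = new_states
    return states


@dataclass
class CrosslinkCandidate:
    fragment: PeptideSpecies
    delta_mass: float
    total_mass: float
    charge: int
    mz: float
    observed_mz: float
    ppm_error: float


def crosslink_search(
    fragments: list[PeptideSpecies],
    delta_mass: float,
    observed_peaks: list[tuple[float, int]],
    ppm_tolerance: float = 10.0,
    settings: DigestSettings | None = None,
    convention: str = "hydrogen",
) -> list[CrosslinkCandidate]:
    """Match Δmass-shifted fragments against observed (m/z, charge) peaks.

    Every fragment is expanded over its variable-modification states,
    shifted by ``delta_mass``, converted to the peak's charge state, and
    reported when within ``ppm_tolerance``. Results are sorted by
    absolute ppm error.
    """
    settings = settings or DigestSettings()
    candidates: list[CrosslinkCandidate] = []
    for frag in fragments:
        for state in expand_variable_mods(frag, settings):
            total = monoisotopic_mass(state) + delta_mass
            for obs_mz, charge in observed_peaks:
                calc = mz(total, charge, convention=convention)
                ppm = 1e6 * (calc - obs_mz) / obs_mz
                if abs(ppm) <= ppm_tolerance:
                    candidates.append(
                        CrosslinkCandidate(
                            fragment=state,
                            delta_mass=delta_mass,
                            total_mass=total,
                            charge=charge,
                            mz=calc,
                            observed_mz=obs_mz,
                            ppm_error=ppm,
                        )
                    )
    candidates.sort(key=lambda c: abs(c.ppm_error))
    return candidates


def candidates_table(candidates: list[CrosslinkCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "sequence": c.fragment.sequence,
                "span": f"{c.fragment.span[0]}-{c.fragment.span[1]}" if c.fragment.span else "",
                "missed": c.fragment.missed_cleavages,
                "variable_mods": ";".join(n for _, _, n in c.fragment.variable_mods),
                "total_mass": c.total_mass,
                "charge": c.charge,
                "mz_calc": c.mz,
                "mz_obs": c.observed_mz,
                "ppm_error": c.ppm_error,
            }
        )
    return pd.DataFrame(rows)
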