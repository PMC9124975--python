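"""Nernst potentials for the H2 couple and electron-shuttle feasibility.

Potentials are reported in mV vs the standard hydrogen electrode (SHE),
reduction convention: a more negative potential marks a stronger electron
donor when reduced.  The 2H+/H2 couple at pH 7, 25 C and unit H2 activity
evaluates to -414 mV, the usual biochemical anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import pandas as pd

from .constants import FARADAY, LN10, R_J
from .thermo import Conditions

__all__ = [
    "RedoxCouple",
    "ShuttleVerdict",
    "h2_couple_potential",
    "potential_from_delta_g",
    "shuttle_feasible",
    "load_couple_table",
    "builtin_couple_table",
]


@dataclass(frozen=True)
class RedoxCouple:
    """A redox couple: standard (or formal) potential in mV vs SHE and the
    number of electrons transferred."""

    name: str
    e0_mv: float
    n: int = 2
    reference_state: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n (electrons) must be >= 1")
        if not math.isfinite(self.e0_mv):
            raise ValueError("e0_mv must be finite")


class ShuttleVerdict(NamedTuple):
    feasible: bool
    margin_mv: float
    at_boundary: bool


def h2_couple_potential(
    cond: Conditions, h2: float, state_flag: str = "aqueous"
) -> float:
    """Non-standard-state potential of the 2H+ + 2e- -> H2 couple, mV vs SHE.

        E = -(2.303 R T / F) pH - (2.303 R T / 2F) log10(a_H2)

    ``h2`` is the aqueous concentration in mol L^-1 (``state_flag='aqueous'``,
    1 M reference, unit coefficient for the neutral molecule) or the partial
    pressure in bar (``state_flag='gas'``, 1 bar reference).  Reduces to 0 mV
    at pH 0 / unit activity (the SHE definition) and to -414 mV at pH 7,
    25 C, unit activity.
    """
    if h2 <= 0:
        raise ValueError("H2 concentration/pressure must be positive")
    if state_flag not in ("aqueous", "gas"):
        raise ValueError(f"state_flag must be 'aqueous' or 'gas', got {state_flag!r}")
    slope_mv = LN10 * R_J * cond.temperature / FARADAY * 1e3  # mV per pH unit
    return -slope_mv * cond.pH - (slope_mv / 2.0) * math.log10(h2)


def potential_from_delta_g(dg_kj_mol: float, n: int) -> float:
    """Electrode potential (mV) equivalent to a half-reaction free energy.

    ``E = -dG / (n F)``; the bridge used for cross-module oracle checks
    against the Gibbs-energy module.
    """
    if n < 1:
        raise ValueError("n (electrons) must be >= 1")
    return -dg_kj_mol * 1e6 / (n * FARADAY)


def shuttle_feasible(shuttle: RedoxCouple, required_mv: float) -> ShuttleVerdict:
    """Can ``shuttle`` deliver electrons at or below ``required_mv``?

    Feasible iff the shuttle potential is <= the required potential (lower =
    stronger reductant); the margin is ``required - shuttle`` in mV.  Exact
    ties sit on the thermodynamic boundary and count as feasible, flagged
    via ``at_boundary``.
    """
    margin = required_mv - shuttle.e0_mv
    return ShuttleVerdict(
        feasible=margin >= 0.0,
        margin_mv=margin,
        at_boundary=margin == 0.0,
    )


def load_couple_table(path) -> dict[str, RedoxCouple]:
    """Read a couple TSV (`name  e0_mv  n  reference_state  source`)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "e0_mv", "n"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"couple table {path} missing columns: {sorted(missing)}")
    table: dict[str, RedoxCouple] = {}
    for _, row in frame.iterrows():
        name = str(row["name"])
        table[name] = RedoxCouple(
            name=name,
            e0_mv=float(row["e0_mv"]),
            n=int(row["n"]),
            reference_state=str(row.get("reference_state", "")),
            source=str(row.get("source", "")) if "source" in frame.columns else "",
        )
    return table


def builtin_couple_table() -> dict[str, RedoxCouple]:
    """Packaged couples: H2 (-414 mV), AH2QDS (-184 mV), methanophenazine (-165 mV)."""
    ref = resources.files("fes2red") / "data" / "redox_couples.tsv"
    with resources.as_file(ref) as path:
        return load_couple_table(path)
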