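"""Henry's-law gas/aqueous conversions and closed-reactor mass balance.

Serum-bottle reactors hold a liquid phase and a sealed headspace; analytes
measured in one phase (dissolved sulfide by colorimetry, H2 and CH4 by
headspace gas chromatography) are converted to total moles in the vessel
assuming ideal gas behaviour and Henry's-law equilibrium.

Following the study's own data-reduction convention, total dissolved sulfide
partitions with the headspace as if it were all volatile H2S (no HS-/H2S
acid-base split); :func:`speciated_total_sulfide` provides the chemically
rigorous alternative for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .constants import R_LBAR

__all__ = [
    "HenryEntry",
    "ReactorGeometry",
    "aqueous_from_headspace",
    "total_amount_closed",
    "speciated_total_sulfide",
    "gc_ppm_to_total",
    "load_henry_table",
    "builtin_henry_table",
    "PAPER_GEOMETRY",
    "SULFIDE_DETECTION_LIMIT_M",
    "H2_DETECTION_LIMIT_M",
]

#: Aqueous detection limit of the methylene-blue sulfide assay, mol L^-1.
SULFIDE_DETECTION_LIMIT_M = 1.5e-6
#: Aqueous-equivalent detection limit of headspace H2 by GC, mol L^-1.
H2_DETECTION_LIMIT_M = 1.0e-7


@dataclass(frozen=True)
class HenryEntry:
    """Henry solubility constant for one gas species.

    ``kh`` is in mol L^-1 bar^-1 at the stated temperature.
    """

    species: str
    kh: float
    temperature: float = 311.15
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.kh > 0 and math.isfinite(self.kh)):
            raise ValueError(f"kh must be positive, got {self.kh}")


@dataclass(frozen=True)
class ReactorGeometry:
    """Closed-vessel geometry: liquid and headspace volumes (L), total
    pressure (bar) and temperature (K)."""

    v_liquid: float
    v_headspace: float
    total_pressure: float = 2.5
    temperature: float = 311.15

    def __post_init__(self) -> None:
        if self.v_liquid < 0 or self.v_headspace < 0:
            raise ValueError("volumes must be nonnegative")
        if self.v_liquid == 0 and self.v_headspace == 0:
            raise ValueError("at least one phase volume must be positive")
        if self.total_pressure <= 0:
            raise ValueError("total pressure must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


#: 165 mL serum bottle with 75 mL medium at 2.5 bar and 38 C.
PAPER_GEOMETRY = ReactorGeometry(
    v_liquid=0.075, v_headspace=0.090, total_pressure=2.5, temperature=311.15
)


def aqueous_from_headspace(
    mole_fraction: float, geom: ReactorGeometry, kh: HenryEntry
) -> float:
    """Dissolved concentration (mol L^-1) in equilibrium with a headspace.

    ``kh * (mole_fraction * total_pressure)``; strictly linear in both the
    mole fraction and the total pressure.
    """
    if not 0.0 <= mole_fraction <= 1.0:
        raise ValueError(f"mole fraction {mole_fraction} outside [0, 1]")
    return kh.kh * mole_fraction * geom.total_pressure


def total_amount_closed(
    c_aq: float, geom: ReactorGeometry, kh: HenryEntry
) -> float:
    """Total moles in the vessel from a measured aqueous concentration.

    The dissolved analyte is treated as entirely volatile (the study's
    convention for total sulfide):

        n = c_aq * (V_liq + V_head / (kh R T))

    with R T in L bar mol^-1 so the headspace term is the equilibrium
    gas-phase moles per unit aqueous concentration.
    """
    if c_aq < 0:
        raise ValueError("aqueous concentration must be nonnegative")
    rt = R_LBAR * geom.temperature
    return c_aq * (geom.v_liquid + geom.v_headspace / (kh.kh * rt))


def speciated_total_sulfide(
    c_aq_total: float,
    pH: float,
    pka1: float,
    geom: ReactorGeometry,
    kh: HenryEntry,
) -> float:
    """Closed-vessel sulfide total with H2S/HS- speciation.

    Only the neutral H2S fraction ``f = 1 / (1 + 10^(pH - pKa1))`` of the
    dissolved pool exchanges with the headspace; the rigorous alternative to
    :func:`total_amount_closed`.
    """
    if not 5.0 < pka1 < 9.0:
        raise ValueError(f"pKa1 {pka1} outside the plausible (5, 9) range")
    if c_aq_total < 0:
        raise ValueError("aqueous concentration must be nonnegative")
    f = 1.0 / (1.0 + 10.0 ** (pH - pka1))
    rt = R_LBAR * geom.temperature
    return c_aq_total * (
        geom.v_liquid + f * geom.v_headspace / (kh.kh * rt)
    )


def gc_ppm_to_total(
    ppm: float, geom: ReactorGeometry, kh: HenryEntry
) -> float:
    """Total moles from a GC headspace reading in ppm (by mole).

    The partial pressure is ``ppm * 1e-6 * P_total``; the gas-phase moles
    follow from the ideal-gas law and the dissolved moles from Henry's law.
    """
    if ppm < 0:
        raise ValueError("ppm must be nonnegative")
    p_partial = ppm * 1e-6 * geom.total_pressure
    rt = R_LBAR * geom.temperature
    n_gas = p_partial * geom.v_headspace / rt
    n_aq = kh.kh * p_partial * geom.v_liquid
    return n_gas + n_aq


def load_henry_table(path) -> dict[str, HenryEntry]:
    """Read a Henry-constant TSV (`species  kh_m_per_bar  temperature_k  source`)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"species", "kh_m_per_bar"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(
            f"Henry table {path} missing columns: {sorted(missing)}"
        )
    table: dict[str, HenryEntry] = {}
    for _, row in frame.iterrows():
        name = str(row["species"])
        table[name] = HenryEntry(
            species=name,
            kh=float(row["kh_m_per_bar"]),
            temperature=float(row.get("temperature_k", 311.15)),
            source=str(row.get("source", "")) if "source" in frame.columns else "",
        )
    return table


def builtin_henry_table() -> dict[str, HenryEntry]:
    """The packaged 38 C Henry constants (H2 calibrated, H2S, CH4)."""
    ref = resources.files("fes2red") / "data" / "henry_38c.tsv"
    with resources.as_file(ref) as path:
        return load_henry_table(path)
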