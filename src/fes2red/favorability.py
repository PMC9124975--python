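"""Favorability analysis: dG grids over H2 x HS- and threshold reports.

Builds the Gibbs-energy surface for pyrite reduction over aqueous H2 and
HS- concentration axes (decade-spaced by default: H2 1e-12..1e-2 M, HS-
1e-7..1e-2 M, at pH 7, I = 0.05 M, 38 C), finds the minimum H2 at which
the reaction turns favorable (strict dG < 0) per HS- level, compares the
pyrrhotite and mackinawite product phases, and reports the gap between the
thermodynamic minimum and the experimentally detectable threshold
(1.98e-4 M aqueous H2, the 10 % headspace condition).

Both stoichiometric conventions (literal / balanced) and both H2 standard
states (aqueous / gas, bridged by Henry's law) are first-class and emitted
side by side in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .partition import builtin_henry_table
from .thermo import (
    Conditions,
    ReactionSpec,
    SpeciesEntry,
    delta_g,
    pyrrhotite_reaction,
)

__all__ = [
    "DGGrid",
    "decade_axis",
    "build_grid",
    "min_favorable_h2",
    "threshold_report",
    "dual_convention_report",
    "grid_to_frame",
    "plot_grid",
    "DEFAULT_H2_RANGE",
    "DEFAULT_HS_RANGE",
    "EXPERIMENTAL_MIN_H2_M",
]

#: Default aqueous H2 axis bounds, mol L^-1 (decade spacing).
DEFAULT_H2_RANGE = (1e-12, 1e-2)
#: Default HS- axis bounds, mol L^-1 (decade spacing).
DEFAULT_HS_RANGE = (1e-7, 1e-2)
#: Lowest aqueous H2 at which reduction was detectable experimentally.
EXPERIMENTAL_MIN_H2_M = 1.98e-4


@dataclass(frozen=True)
class DGGrid:
    """dG surface (kJ mol^-1) indexed [hs][h2] with its provenance."""

    h2_axis: np.ndarray
    hs_axis: np.ndarray
    dg: np.ndarray
    reaction: ReactionSpec
    conditions: Conditions
    h2_phase: str = "aqueous"

    def __post_init__(self) -> None:
        if self.dg.shape != (len(self.hs_axis), len(self.h2_axis)):
            raise ValueError("dg matrix shape does not match the axes")


def decade_axis(lo: float, hi: float) -> np.ndarray:
    """Decade-spaced axis from ``lo`` to ``hi`` inclusive."""
    if not (lo > 0 and hi > lo):
        raise ValueError("axis bounds must satisfy 0 < lo < hi")
    n = int(round(math.log10(hi / lo))) + 1
    return np.logspace(math.log10(lo), math.log10(hi), n)


def build_grid(
    rxn: ReactionSpec,
    table: Mapping[str, SpeciesEntry],
    cond: Conditions,
    h2_axis: Sequence[float] | None = None,
    hs_axis: Sequence[float] | None = None,
    h2_phase: str = "aqueous",
    kh_h2: float | None = None,
) -> DGGrid:
    """Evaluate dG at every (HS-, H2) pair.

    Axes are aqueous molar concentrations; when the reaction references
    gas-phase H2 the axis values are converted to partial pressures through
    the Henry constant ``kh_h2`` (default: the packaged calibrated value).
    """
    h2_ax = (
        decade_axis(*DEFAULT_H2_RANGE)
        if h2_axis is None
        else np.asarray(h2_axis, dtype=float)
    )
    hs_ax = (
        decade_axis(*DEFAULT_HS_RANGE)
        if hs_axis is None
        else np.asarray(hs_axis, dtype=float)
    )
    if len(h2_ax) < 1 or len(hs_ax) < 1:
        raise ValueError("axes must contain at least one point")
    if np.any(h2_ax <= 0) or np.any(hs_ax <= 0):
        raise ValueError("axis concentrations must be positive")
    h2_name = "H2(aq)" if h2_phase == "aqueous" else "H2(g)"
    if h2_name not in rxn.coefficients:
        raise ValueError(
            f"reaction does not contain {h2_name!r}; build it with "
            f"h2_phase={h2_phase!r}"
        )
    if h2_phase == "gas":
        kh = builtin_henry_table()["h2"].kh if kh_h2 is None else kh_h2
    dg = np.empty((len(hs_ax), len(h2_ax)))
    for i, hs in enumerate(hs_ax):
        for j, h2 in enumerate(h2_ax):
            h2_value = h2 if h2_phase == "aqueous" else h2 / kh
            dg[i, j] = delta_g(
                rxn, table, cond, {h2_name: h2_value, "HS-": hs}
            )
    return DGGrid(
        h2_axis=h2_ax,
        hs_axis=hs_ax,
        dg=dg,
        reaction=rxn,
        conditions=cond,
        h2_phase=h2_phase,
    )


def _hs_row(grid: DGGrid, hs: float) -> int:
    rel = np.abs(np.log10(grid.hs_axis / hs))
    i = int(np.argmin(rel))
    if rel[i] > 1e-9:
        raise ValueError(f"HS- = {hs} M is not on the grid's HS- axis")
    return i


def min_favorable_h2(grid: DGGrid, hs: float) -> float | None:
    """Smallest H2 axis value with dG strictly < 0 at the given HS- level.

    Returns ``None`` when no grid point on that row is favorable
    (dG = 0 exactly does not count as favorable).
    """
    i = _hs_row(grid, hs)
    for j in range(len(grid.h2_axis)):
        if grid.dg[i, j] < 0.0:
            return float(grid.h2_axis[j])
    return None


def threshold_report(
    grid: DGGrid, experimental_min: float = EXPERIMENTAL_MIN_H2_M
) -> dict:
    """Thermodynamic minimum per HS- row vs the experimental H2 threshold.

    The gap is reported in decades, ``log10(experimental / thermodynamic)``.
    """
    if experimental_min <= 0:
        raise ValueError("experimental_min must be positive")
    rows = []
    for hs in grid.hs_axis:
        tmin = min_favorable_h2(grid, float(hs))
        rows.append(
            {
                "hs_molar": float(hs),
                "thermodynamic_min_h2_molar": tmin,
                "gap_decades": (
                    None if tmin is None else math.log10(experimental_min / tmin)
                ),
            }
        )
    return {
        "experimental_min_h2_molar": experimental_min,
        "convention": grid.reaction.convention,
        "h2_phase": grid.h2_phase,
        "x": grid.reaction.x,
        "rows": rows,
    }


def dual_convention_report(
    table: Mapping[str, SpeciesEntry],
    cond: Conditions,
    x: float = 0.14,
    h2_axis: Sequence[float] | None = None,
    hs_axis: Sequence[float] | None = None,
    experimental_min: float = EXPERIMENTAL_MIN_H2_M,
) -> dict:
    """Threshold reports for every (convention, H2 standard state) pairing.

    Emitting all four keeps the choice of convention transparent: none is
    singled out as "the" published one.
    """
    out: dict = {"x": x, "reports": []}
    for convention in ("literal", "balanced"):
        for h2_phase in ("aqueous", "gas"):
            rxn = pyrrhotite_reaction(x, convention, h2_phase)
            grid = build_grid(
                rxn, table, cond, h2_axis, hs_axis, h2_phase=h2_phase
            )
            out["reports"].append(threshold_report(grid, experimental_min))
    return out


def grid_to_frame(grid: DGGrid):
    """Long-format table: hs_molar, h2_molar, dg_kj_mol, favorable."""
    import pandas as pd

    records = []
    for i, hs in enumerate(grid.hs_axis):
        for j, h2 in enumerate(grid.h2_axis):
            records.append(
                {
                    "hs_molar": float(hs),
                    "h2_molar": float(h2),
                    "dg_kj_mol": float(grid.dg[i, j]),
                    "favorable": bool(grid.dg[i, j] < 0.0),
                }
            )
    return pd.DataFrame.from_records(records)


def plot_grid(grid: DGGrid, path) -> None:
    """dG vs log10[H2], one curve per HS- level, favorability line at 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for i, hs in enumerate(grid.hs_axis):
        ax.plot(
            np.log10(grid.h2_axis),
            grid.dg[i],
            marker="o",
            label=f"[HS-] = 1e{math.log10(hs):+.0f} M".replace("+", ""),
        )
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("log10 [H2] (M, aqueous)")
    ax.set_ylabel("dG (kJ per mol FeS2)")
    ax.set_title(
        f"FeS2 reduction, x={grid.reaction.x}, {grid.reaction.convention}, "
        f"H2 {grid.h2_phase}"
    )
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
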