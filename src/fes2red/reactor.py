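"""Reactor time-series data reduction.

Turns raw per-bottle measurements (aqueous assay concentrations; headspace
GC ppm) into total-amount trajectories with replicate mean/SD and censoring
bookkeeping.  Aqueous-mode volatile analytes go through the closed-vessel
Henry balance, headspace-mode analytes through the GC ppm conversion, and
nonvolatile analytes (ferrous iron) count the liquid phase only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .partition import (
    HenryEntry,
    ReactorGeometry,
    gc_ppm_to_total,
    total_amount_closed,
)

__all__ = [
    "ANALYTE_MODES",
    "ANALYTE_HENRY_SPECIES",
    "Measurement",
    "ReducedSeries",
    "reduce_measurements",
    "read_measurements_csv",
    "series_to_frame",
]

#: Measurement mode each analyte's assay produces.
ANALYTE_MODES = {
    "sulfide": "aqueous_molar",
    "fe2": "aqueous_molar",
    "h2": "headspace_ppm",
    "ch4": "headspace_ppm",
}

#: Henry-table species backing each analyte (None = nonvolatile).
ANALYTE_HENRY_SPECIES = {
    "sulfide": "h2s",
    "fe2": None,
    "h2": "h2",
    "ch4": "ch4",
}


@dataclass(frozen=True)
class Measurement:
    """One raw observation from one reactor at one time point."""

    reactor_id: str
    condition: str
    time: float  # days
    analyte: str
    mode: str
    value: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTE_MODES:
            raise ValueError(
                f"unknown analyte {self.analyte!r}; expected one of "
                f"{sorted(ANALYTE_MODES)}"
            )
        if self.mode != ANALYTE_MODES[self.analyte]:
            raise ValueError(
                f"analyte {self.analyte!r} is assayed as "
                f"{ANALYTE_MODES[self.analyte]!r}, got mode {self.mode!r}"
            )
        if self.value < 0:
            raise ValueError("measurement value must be nonnegative")


@dataclass(frozen=True)
class ReducedSeries:
    """Replicate-aggregated total amount for one (condition, time, analyte).

    ``total_mol``/``sd_mol`` are computed over detected replicates only
    (sample SD, n-1 denominator); censored replicates are excluded from the
    statistics and reported through ``censored_fraction``.  ``n`` is the
    number of detected replicates; when every replicate is censored the
    statistics are NaN and ``n`` is 0.
    """

    condition: str
    time: float
    analyte: str
    total_mol: float
    sd_mol: float
    n: int
    censored_fraction: float


def _to_total(m: Measurement, geom: ReactorGeometry,
              henry: Mapping[str, HenryEntry]) -> float:
    species = ANALYTE_HENRY_SPECIES[m.analyte]
    if m.mode == "aqueous_molar":
        if species is None:
            return m.value * geom.v_liquid
        if species not in henry:
            raise KeyError(
                f"no Henry entry {species!r} for analyte {m.analyte!r}"
            )
        return total_amount_closed(m.value, geom, henry[species])
    # headspace_ppm
    if species is None or species not in henry:
        raise KeyError(f"no Henry entry {species!r} for analyte {m.analyte!r}")
    return gc_ppm_to_total(m.value, geom, henry[species])


def reduce_measurements(
    measurements: Iterable[Measurement],
    geom: ReactorGeometry,
    henry: Mapping[str, HenryEntry],
) -> list[ReducedSeries]:
    """Reduce raw measurements to total-amount replicate statistics.

    Grouping key is (condition, time, analyte); the output order is the
    sorted key order, so the reduction is invariant to input permutation.
    """
    groups: dict[tuple[str, float, str], list[Measurement]] = {}
    for m in measurements:
        groups.setdefault((m.condition, m.time, m.analyte), []).append(m)
    out: list[ReducedSeries] = []
    for (condition, time, analyte) in sorted(groups):
        members = groups[(condition, time, analyte)]
        detected = [
            _to_total(m, geom, henry) for m in members if not m.below_detection
        ]
        n_cens = sum(1 for m in members if m.below_detection)
        if detected:
            mean = float(np.mean(detected))
            sd = float(np.std(detected, ddof=1)) if len(detected) > 1 else 0.0
        else:
            mean = math.nan
            sd = math.nan
        out.append(
            ReducedSeries(
                condition=condition,
                time=time,
                analyte=analyte,
                total_mol=mean,
                sd_mol=sd,
                n=len(detected),
                censored_fraction=n_cens / len(members),
            )
        )
    return out


def read_measurements_csv(path) -> list[Measurement]:
    """Read the raw-measurement CSV
    (`reactor_id,condition,time_d,analyte,mode,value,below_detection`)."""
    frame = pd.read_csv(path, comment="#")
    required = {
        "reactor_id", "condition", "time_d", "analyte", "mode", "value",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            Measurement(
                reactor_id=str(row["reactor_id"]),
                condition=str(row["condition"]),
                time=float(row["time_d"]),
                analyte=str(row["analyte"]),
                mode=str(row["mode"]),
                value=float(row["value"]),
                below_detection=bool(row["below_detection"])
                if "below_detection" in frame.columns
                else False,
            )
        )
    return out


def series_to_frame(series: Sequence[ReducedSeries]) -> pd.DataFrame:
    """Reduced series as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "condition": s.condition,
                "time_d": s.time,
                "analyte": s.analyte,
                "total_mol": s.total_mol,
                "sd_mol": s.sd_mol,
                "n": s.n,
                "censored_fraction": s.censored_fraction,
            }
            for s in series
        ]
    )
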