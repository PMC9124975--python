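"""Species/reaction data model and non-standard-state Gibbs energies.

The central computation is the Gibbs free energy of the pyrite-reduction
reaction

    FeS2 + (1-x) H2  <->  Fe(1-x)S + (1-x) HS- + (1-x) H+        (literal)

with pyrrhotite nonstoichiometry ``x`` in [0, 0.17].  As printed, that
stoichiometry does not conserve Fe or S for x > 0, so an element-balanced
variant (per mole FeS2)

    FeS2 + (1-2x)/(1-x) H2  <->  1/(1-x) Fe(1-x)S
                                 + (1-2x)/(1-x) HS- + (1-2x)/(1-x) H+

is provided alongside; both conventions are first-class and reported side
by side throughout the package.

Activities follow geochemical conventions: pure solids and water are unity,
the proton activity is 10^-pH, gases are referenced to 1 bar, and aqueous
ions carry a Davies-equation activity coefficient.  Formation energies are
25 C tabulated values used unchanged at the evaluation temperature (no
enthalpy correction); see docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .constants import DAVIES_A_25C, R_KJ

__all__ = [
    "PHASES",
    "SpeciesEntry",
    "Conditions",
    "ReactionSpec",
    "davies_log_gamma",
    "activity",
    "delta_g_standard",
    "delta_g",
    "pyrrhotite_reaction",
    "reaction_compositions",
    "element_imbalance",
    "charge_imbalance",
    "load_species_table",
    "builtin_species_table",
    "X_MAX",
]

#: Recognized activity conventions.  ``electron`` is a pseudo-phase (unit
#: activity, zero formation energy) so half-reactions can be expressed for
#: cross-checks against the Nernst module.
PHASES = frozenset(
    {"aqueous", "gas", "solid", "water", "proton-reference", "electron"}
)

#: Upper bound of pyrrhotite nonstoichiometry.
X_MAX = 0.17


@dataclass(frozen=True)
class SpeciesEntry:
    """One chemical species with phase, charge and standard formation energy.

    Parameters
    ----------
    name : str
        Identifier, unique within a species table.
    phase : str
        One of :data:`PHASES`.
    charge : int
        Signed charge in elementary units.  Solids and water must be neutral.
    dgf0 : float
        Standard Gibbs free energy of formation, kJ mol^-1 at 25 C.
    source : str
        Free-text provenance of ``dgf0``.
    """

    name: str
    phase: str
    charge: int
    dgf0: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"unknown phase {self.phase!r} for species {self.name!r}; "
                f"expected one of {sorted(PHASES)}"
            )
        if self.phase in ("solid", "water") and self.charge != 0:
            raise ValueError(
                f"{self.phase} species {self.name!r} must have charge 0"
            )
        if not math.isfinite(self.dgf0):
            raise ValueError(f"non-finite dgf0 for species {self.name!r}")


@dataclass(frozen=True)
class Conditions:
    """Solution conditions governing activity and free-energy evaluation.

    ``davies_A`` defaults to the 25 C value 0.509; pass
    :func:`fes2red.constants.davies_a_for_temperature` output (0.520 at 38 C)
    for the temperature-adjusted alternative.
    """

    temperature: float = 311.15  # K
    pH: float = 7.0
    ionic_strength: float = 0.05  # mol L^-1
    davies_A: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be nonnegative")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH must lie in [0, 14]")

    @property
    def A(self) -> float:
        return DAVIES_A_25C if self.davies_A is None else self.davies_A


@dataclass(frozen=True)
class ReactionSpec:
    """Signed stoichiometric map (negative = reactant, positive = product).

    ``x`` carries the pyrrhotite nonstoichiometry the coefficients were built
    with, and ``convention`` records whether they follow the literal printed
    stoichiometry or the element-balanced variant.
    """

    coefficients: Mapping[str, float] = field(default_factory=dict)
    x: float = 0.0
    convention: str = "balanced"

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= X_MAX:
            raise ValueError(f"x={self.x} outside [0, {X_MAX}]")
        if self.convention not in ("literal", "balanced"):
            raise ValueError(f"unknown convention {self.convention!r}")
        coeffs = dict(self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if coeffs:
            has_reactant = any(v < 0 for v in coeffs.values())
            has_product = any(v > 0 for v in coeffs.values())
            if not (has_reactant and has_product):
                raise ValueError(
                    "a non-empty reaction needs at least one reactant and "
                    "one product"
                )

    @classmethod
    def from_json(cls, text: str) -> "ReactionSpec":
        obj = json.loads(text)
        return cls(
            coefficients=obj["coefficients"],
            x=obj.get("x", 0.0),
            convention=obj.get("convention", "balanced"),
        )


def davies_log_gamma(z: int, ionic_strength: float, A: float = DAVIES_A_25C) -> float:
    """log10 single-ion activity coefficient from the Davies equation.

    ``log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)``; zero for
    uncharged species or at zero ionic strength.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be nonnegative")
    if z == 0 or ionic_strength == 0:
        return 0.0
    root = math.sqrt(ionic_strength)
    return -A * z * z * (root / (1.0 + root) - 0.3 * ionic_strength)


def activity(species: SpeciesEntry, value: float | None, cond: Conditions) -> float:
    """Dimensionless activity of ``species`` at ``value`` under ``cond``.

    Aqueous: gamma * c / (1 M); gas: p / (1 bar); solid, water and electron:
    unity; proton-reference: 10^-pH (``value`` ignored for the latter three).
    """
    if species.phase in ("solid", "water", "electron"):
        return 1.0
    if species.phase == "proton-reference":
        return 10.0 ** (-cond.pH)
    if value is None or value <= 0:
        raise ValueError(
            f"positive concentration/pressure required for {species.name!r}"
        )
    if species.phase == "aqueous":
        lg = davies_log_gamma(species.charge, cond.ionic_strength, cond.A)
        return (10.0**lg) * value
    if species.phase == "gas":
        return value
    raise AssertionError(f"unhandled phase {species.phase!r}")


def delta_g_standard(
    rxn: ReactionSpec,
    table: Mapping[str, SpeciesEntry],
    cond: Conditions | None = None,
) -> float:
    """Standard-state reaction free energy, sum(nu_i dGf0_i), kJ mol^-1.

    Tabulated 25 C formation energies are used unchanged at the evaluation
    temperature (isothermal-dGf assumption).  ``cond`` is accepted for
    interface symmetry with :func:`delta_g` but does not enter the sum.
    """
    total = 0.0
    for name, nu in rxn.coefficients.items():
        try:
            entry = table[name]
        except KeyError:
            raise KeyError(
                f"species {name!r} missing from the species table"
            ) from None
        total += nu * entry.dgf0
    return total


def delta_g(
    rxn: ReactionSpec,
    table: Mapping[str, SpeciesEntry],
    cond: Conditions,
    conc: Mapping[str, float],
) -> float:
    """Non-standard-state reaction free energy, dG0 + RT ln Q, kJ mol^-1.

    ``conc`` maps aqueous species to mol L^-1 and gas species to bar; solids,
    water and electrons are skipped (unit activity) and the proton activity is
    taken from ``cond.pH``, never from ``conc``.
    """
    rt = R_KJ * cond.temperature
    ln_q = 0.0
    for name, nu in rxn.coefficients.items():
        try:
            entry = table[name]
        except KeyError:
            raise KeyError(
                f"species {name!r} missing from the species table"
            ) from None
        if entry.phase in ("solid", "water", "electron"):
            continue
        value = None if entry.phase == "proton-reference" else conc.get(name)
        a = activity(entry, value, cond)
        ln_q += nu * math.log(a)
    return delta_g_standard(rxn, table) + rt * ln_q


def pyrrhotite_reaction(
    x: float,
    convention: str = "balanced",
    h2_phase: str = "aqueous",
    product: str | None = None,
) -> ReactionSpec:
    """Pyrite-reduction reaction for nonstoichiometry ``x``.

    ``convention='literal'`` reproduces the printed stoichiometry
    (1, 1-x, 1, 1-x, 1-x), which leaves an Fe and S deficit of ``x`` per
    formula unit for x > 0; ``'balanced'`` uses (1, (1-2x)/(1-x), 1/(1-x),
    (1-2x)/(1-x), (1-2x)/(1-x)), conserving Fe, S, H and charge.

    The solid product defaults to ``"mackinawite"`` (stoichiometric FeS) at
    x = 0 and ``"pyrrhotite"`` otherwise, matching the fixture species table;
    pass ``product`` to override.  ``h2_phase`` selects the H2 standard
    state: ``"aqueous"`` (1 M reference) or ``"gas"`` (1 bar reference).
    """
    if not 0.0 <= x <= X_MAX:
        raise ValueError(f"x={x} outside [0, {X_MAX}]")
    if h2_phase not in ("aqueous", "gas"):
        raise ValueError(f"h2_phase must be 'aqueous' or 'gas', got {h2_phase!r}")
    h2_name = "H2(aq)" if h2_phase == "aqueous" else "H2(g)"
    if product is None:
        product = "mackinawite" if x == 0 else "pyrrhotite"
    if convention == "literal":
        nu_h2 = 1.0 - x
        nu_solid = 1.0
        nu_hs = 1.0 - x
    elif convention == "balanced":
        nu_h2 = (1.0 - 2.0 * x) / (1.0 - x)
        nu_solid = 1.0 / (1.0 - x)
        nu_hs = (1.0 - 2.0 * x) / (1.0 - x)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return ReactionSpec(
        coefficients={
            "FeS2": -1.0,
            h2_name: -nu_h2,
            product: nu_solid,
            "HS-": nu_hs,
            "H+": nu_hs,
        },
        x=x,
        convention=convention,
    )


def reaction_compositions(x: float) -> dict[str, dict[str, float]]:
    """Elemental compositions of the pyrite-reduction species at ``x``."""
    return {
        "FeS2": {"Fe": 1.0, "S": 2.0},
        "pyrrhotite": {"Fe": 1.0 - x, "S": 1.0},
        "mackinawite": {"Fe": 1.0, "S": 1.0},
        "HS-": {"H": 1.0, "S": 1.0},
        "H+": {"H": 1.0},
        "H2(aq)": {"H": 2.0},
        "H2(g)": {"H": 2.0},
        "H2O": {"H": 2.0, "O": 1.0},
    }


def element_imbalance(
    rxn: ReactionSpec,
    compositions: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, float]:
    """Net element count (products minus reactants) per formula unit.

    Zero for every element means the reaction is element-balanced; the
    literal printed stoichiometry shows an Fe and S deficit of ``-x``.
    """
    comps = (
        reaction_compositions(rxn.x) if compositions is None else compositions
    )
    net: dict[str, float] = {}
    for name, nu in rxn.coefficients.items():
        if name not in comps:
            raise KeyError(f"no elemental composition known for {name!r}")
        for element, count in comps[name].items():
            net[element] = net.get(element, 0.0) + nu * count
    return net


def charge_imbalance(
    rxn: ReactionSpec, table: Mapping[str, SpeciesEntry]
) -> float:
    """Net charge carried by products minus reactants (0 if conserved)."""
    return sum(
        nu * table[name].charge for name, nu in rxn.coefficients.items()
    )


def load_species_table(path) -> dict[str, SpeciesEntry]:
    """Read a species table from TSV (or JSON) into a name-keyed dict.

    TSV columns: ``name  phase  charge  dgf0_kj_mol  source``.  JSON is a
    list of objects with the same keys.
    """
    text = str(path)
    if text.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "phase", "charge", "dgf0_kj_mol"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(
            f"species table {path} missing columns: {sorted(missing)}"
        )
    table: dict[str, SpeciesEntry] = {}
    for _, row in frame.iterrows():
        name = str(row["name"])
        if name in table:
            raise ValueError(f"duplicate species name {name!r} in {path}")
        table[name] = SpeciesEntry(
            name=name,
            phase=str(row["phase"]),
            charge=int(row["charge"]),
            dgf0=float(row["dgf0_kj_mol"]),
            source=str(row.get("source", "")) if "source" in frame.columns else "",
        )
    return table


def builtin_species_table() -> dict[str, SpeciesEntry]:
    """The packaged species table (printed mineral dGf0 plus supplements)."""
    ref = resources.files("fes2red") / "data" / "species_paper.tsv"
    with resources.as_file(ref) as path:
        return load_species_table(path)
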