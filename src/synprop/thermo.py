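"""Gibbs free energy bookkeeping for anaerobic digester reactions.

The central question in syntrophic propionate degradation is which of the
competing hydrogen-producing and hydrogen-consuming reactions are exergonic
at a given hydrogen partial pressure.  This module evaluates

    dG' = dG0' + R*T*ln Q

for reactions written over dissolved species (mol/L against a 1 mol/L
standard state), gases (atm against 1 atm), water (activity 1) and protons
(activity referenced to 1e-7, the "prime" convention, so the proton term
vanishes at pH 7).  Activity coefficients are taken as 1 and dG0' is not
temperature-corrected: temperature enters only through the R*T*ln Q term.

Stoichiometric coefficients are exact rationals so that linear combinations
of reactions (e.g. propionate oxidation + 0.75 x hydrogenotrophic
methanogenesis) cancel without floating-point residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "R_KJ",
    "ChemSpecies",
    "Reaction",
    "Conditions",
    "ThermoError",
    "delta_g_prime",
    "combine_reactions",
    "h2_crossover",
    "free_energy_table",
    "h2_window",
    "load_registry",
    "registry",
    "digester_conditions",
    "round_half_away",
]

#: Gas constant in kJ mol-1 K-1.
R_KJ = 8.314e-3

#: Species name used for molecular hydrogen throughout the registry.
H2 = "H2"
WATER = "H2O"
PROTON = "H+"

PHASES = ("solute", "gas", "water", "proton")


class ThermoError(ValueError):
    """Raised for ill-posed thermodynamic evaluations."""


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical species participating in a reaction.

    The phase determines how its activity is interpreted: ``solute`` in
    mol/L, ``gas`` in atm, ``water`` fixed at activity 1 and ``proton``
    derived from pH.  Water and the proton are singletons identified by
    the names ``H2O`` and ``H+``.
    """

    name: str
    phase: str = "solute"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ThermoError(f"unknown phase {self.phase!r} for {self.name}")
        if self.phase == "water" and self.name != WATER:
            raise ThermoError("water must be named H2O")
        if self.phase == "proton" and self.name != PROTON:
            raise ThermoError("the proton must be named H+")


def _as_fraction(x) -> Fraction:
    # Floats convert exactly (every float is a binary rational): rounding
    # them to "nice" fractions would silently break linear-combination
    # exactness for small multipliers.
    return Fraction(x)


@dataclass(frozen=True)
class Reaction:
    """A chemical reaction with exact stoichiometry and a dG0' constant.

    ``stoichiometry`` maps species names to signed rational coefficients,
    negative for consumed species.  ``dg0_prime`` is the standard-condition
    free energy in kJ per reaction as written.  Element/charge balance is
    deliberately not checked: coefficients are taken as published.
    """

    name: str
    stoichiometry: Mapping[str, Fraction]
    dg0_prime: float

    def __post_init__(self) -> None:
        stoich = {
            sp: _as_fraction(c) for sp, c in self.stoichiometry.items() if c != 0
        }
        if not stoich:
            raise ThermoError(f"reaction {self.name!r} has no nonzero coefficient")
        object.__setattr__(self, "stoichiometry", stoich)

    def coefficient(self, species: str) -> Fraction:
        return self.stoichiometry.get(species, Fraction(0))

    def reversed(self) -> "Reaction":
        return Reaction(
            name=f"-({self.name})",
            stoichiometry={sp: -c for sp, c in self.stoichiometry.items()},
            dg0_prime=-self.dg0_prime,
        )


@dataclass(frozen=True)
class Conditions:
    """Physico-chemical conditions defining a reaction quotient.

    activities holds solute concentrations (mol/L) and gas partial
    pressures (atm) keyed by species name.  Water is fixed at activity 1
    and the proton activity is derived from pH; neither may appear in
    ``activities``.
    """

    temperature: float
    activities: Mapping[str, float]
    pH: float = 7.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ThermoError("temperature must be positive (kelvin)")
        acts = dict(self.activities)
        for special in (WATER, PROTON):
            if special in acts:
                raise ThermoError(
                    f"{special} activity is fixed by convention; do not supply it"
                )
        for sp, a in acts.items():
            if a <= 0:
                raise ThermoError(f"non-positive activity for {sp}: {a}")
        object.__setattr__(self, "activities", acts)

    def with_activity(self, species: str, value: float) -> "Conditions":
        acts = dict(self.activities)
        acts[species] = value
        return replace(self, activities=acts)

    def with_h2(self, ph2: float) -> "Conditions":
        return self.with_activity(H2, ph2)

    def ln_activity(self, species: str) -> float:
        """ln of the effective activity under the prime convention."""
        if species == WATER:
            return 0.0
        if species == PROTON:
            # 10**-pH referenced to the 1e-7 standard state.
            return (7.0 - self.pH) * math.log(10.0)
        try:
            a = self.activities[species]
        except KeyError:
            raise ThermoError(f"no activity supplied for species {species!r}")
        return math.log(a)


def delta_g_prime(reaction: Reaction, conditions: Conditions) -> float:
    """dG' in kJ per reaction: dG0' + R*T*ln Q.

    Q is the product of activities raised to their signed stoichiometric
    coefficients, with water at activity 1 and the proton activity divided
    by 1e-7 so the proton term vanishes at pH 7.
    """
    ln_q = 0.0
    for sp, coeff in reaction.stoichiometry.items():
        ln_q += float(coeff) * conditions.ln_activity(sp)
    return reaction.dg0_prime + R_KJ * conditions.temperature * ln_q


def combine_reactions(terms: Sequence[tuple[Reaction, float]], name: str | None = None) -> Reaction:
    """Linear combination of reactions with exact stoichiometric cancellation.

    ``terms`` is a non-empty list of (reaction, multiplier) pairs.  The
    combined stoichiometry is the coefficient-wise weighted sum (species
    with zero net coefficient are dropped exactly) and the combined dG0'
    is the same weighted sum of the constituents' dG0' values.

    Free energies are linear, so for every condition set
    ``delta_g_prime(combine_reactions(ts), c)`` equals the weighted sum of
    the individual ``delta_g_prime`` values.
    """
    if not terms:
        raise ThermoError("combine_reactions requires at least one term")
    stoich: dict[str, Fraction] = {}
    dg0 = 0.0
    parts = []
    for rxn, mult in terms:
        m = _as_fraction(mult)
        for sp, coeff in rxn.stoichiometry.items():
            stoich[sp] = stoich.get(sp, Fraction(0)) + m * coeff
        dg0 += float(m) * rxn.dg0_prime
        parts.append(f"{m}*{rxn.name}")
    stoich = {sp: c for sp, c in stoich.items() if c != 0}
    if not stoich:
        # Fully cancelling combination (e.g. r + (-1)*r): represent as a
        # null reaction without tripping the nonzero-coefficient check.
        null = Reaction(name or " + ".join(parts), {"_null": 1}, dg0)
        object.__setattr__(null, "stoichiometry", {})
        return null
    return Reaction(name or " + ".join(parts), stoich, dg0)


def h2_crossover(reaction: Reaction, conditions: Conditions) -> float:
    """Hydrogen partial pressure (atm) at which dG' of the reaction is zero.

    With all non-H2 activities fixed, dG'(pH2) = a + nu*R*T*ln(pH2) where
    nu is the H2 coefficient and ``a`` collects every H2-independent term;
    the unique root is pH2 = exp(-a / (nu*R*T)), solved in closed form.
    """
    nu = reaction.coefficient(H2)
    if nu == 0:
        raise ThermoError(
            f"reaction {reaction.name!r} has no H2 term; dG' does not depend on pH2"
        )
    a = delta_g_prime(reaction, conditions.with_h2(1.0))
    return math.exp(-a / (float(nu) * R_KJ * conditions.temperature))


def free_energy_table(
    reactions: Sequence[Reaction],
    conditions: Conditions,
    ph2_values: Sequence[float],
) -> pd.DataFrame:
    """dG' (kJ per reaction) for every reaction across a pH2 sweep.

    Rows are the pH2 values in the order given, columns the reaction names.
    """
    if len(ph2_values) == 0:
        raise ThermoError("ph2_values must be non-empty")
    if any(p <= 0 for p in ph2_values):
        raise ThermoError("ph2_values must be positive")
    data = {
        rxn.name: [delta_g_prime(rxn, conditions.with_h2(p)) for p in ph2_values]
        for rxn in reactions
    }
    table = pd.DataFrame(data, index=list(ph2_values))
    table.index.name = "pH2_atm"
    return table


def h2_window(
    producing: Reaction, consuming: Reaction, conditions: Conditions
) -> tuple[float, float]:
    """The open pH2 interval in which both reactions are exergonic.

    ``producing`` must form H2 (positive H2 coefficient; its dG' rises with
    pH2, so it is feasible below its crossover) and ``consuming`` must take
    H2 up (negative coefficient; feasible above its crossover).  Returns
    (lower, upper) = (consuming crossover, producing crossover); a result
    with lower >= upper means the window is empty.
    """
    if producing.coefficient(H2) <= 0:
        raise ThermoError(
            f"{producing.name!r} does not produce H2 (coefficient must be > 0)"
        )
    if consuming.coefficient(H2) >= 0:
        raise ThermoError(
            f"{consuming.name!r} does not consume H2 (coefficient must be < 0)"
        )
    lower = h2_crossover(consuming, conditions)
    upper = h2_crossover(producing, conditions)
    return lower, upper


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties away from zero (table display)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Packaged registry and reference conditions


def _load_yaml(name: str):
    ref = resources.files("synprop.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def reaction_from_dict(doc: Mapping) -> Reaction:
    stoich = {sp: Fraction(str(c)) for sp, c in doc["stoichiometry"].items()}
    return Reaction(doc["name"], stoich, float(doc["dg0_prime"]))


def conditions_from_dict(doc: Mapping) -> Conditions:
    return Conditions(
        temperature=float(doc["temperature"]),
        activities={sp: float(a) for sp, a in doc.get("activities", {}).items()},
        pH=float(doc.get("pH", 7.0)),
    )


def load_registry(path=None) -> dict[str, Reaction]:
    """The five-reaction registry (packaged default, or a user YAML file).

    Registry invariants are asserted on load: autotrophic homoacetogenesis
    is the exact negation of syntrophic acetate oxidation, and SAO plus
    hydrogenotrophic methanogenesis is stoichiometrically and energetically
    identical to acetoclastic methanogenesis.
    """
    if path is None:
        docs = _load_yaml("reactions.yaml")
    else:
        with open(path) as fh:
            docs = yaml.safe_load(fh)
    reg = {}
    for doc in docs["reactions"]:
        rxn = reaction_from_dict(doc)
        if rxn.name in reg:
            raise ThermoError(f"duplicate reaction name {rxn.name!r}")
        reg[rxn.name] = rxn
    if set(reg) >= {
        "propionate_oxidation",
        "hydrogenotrophic_methanogenesis",
        "acetoclastic_methanogenesis",
        "syntrophic_acetate_oxidation",
        "autotrophic_homoacetogenesis",
    }:
        sao = reg["syntrophic_acetate_oxidation"]
        aha = reg["autotrophic_homoacetogenesis"]
        hm = reg["hydrogenotrophic_methanogenesis"]
        am = reg["acetoclastic_methanogenesis"]
        neg = sao.reversed()
        if aha.stoichiometry != neg.stoichiometry or aha.dg0_prime != neg.dg0_prime:
            raise ThermoError("registry: AHA must be the exact negation of SAO")
        summed = combine_reactions([(sao, 1), (hm, 1)])
        if summed.stoichiometry != am.stoichiometry:
            raise ThermoError("registry: SAO + HM must equal acetoclastic stoichiometry")
        if abs(summed.dg0_prime - am.dg0_prime) > 1e-9:
            raise ThermoError("registry: SAO + HM dG0' must equal acetoclastic dG0'")
    return reg


def registry() -> dict[str, Reaction]:
    """Packaged five-reaction registry, loaded fresh."""
    return load_registry()


#: Canonical registry order used for tables (matches the published layout).
REGISTRY_ORDER = [
    "propionate_oxidation",
    "hydrogenotrophic_methanogenesis",
    "acetoclastic_methanogenesis",
    "syntrophic_acetate_oxidation",
    "autotrophic_homoacetogenesis",
]

#: The eight hydrogen partial pressures (atm) of the reference sweep.
REFERENCE_PH2 = [1e-1, 1e-2, 1e-3, 1e-4, 5e-5, 1e-5, 1e-6, 1e-7]


def digester_conditions(ph2: float | None = None) -> Conditions:
    """Mesophilic digester reference conditions.

    37 degC, 1 mmol/L acetate and propionate, 20 mmol/L bicarbonate,
    0.6 atm CH4, pH 7.  ``ph2`` optionally fixes the hydrogen partial
    pressure (atm); leave None when sweeping.
    """
    cond = conditions_from_dict(_load_yaml("conditions_digester.yaml"))
    if ph2 is not None:
        cond = cond.with_h2(ph2)
    return cond
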