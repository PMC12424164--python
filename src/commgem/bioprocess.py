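"""Chemostat and physico-chemical bookkeeping for gas fermentations.

Dilution rate / hydraulic retention time, ideal-gas conversion of gas
flows to molar rates, substrate-consumption percentages, steady-state
production rates from liquid mass balances, Henderson-Hasselbalch
undissociated-acid fractions, degrees of reduction, and carbon/electron
balance recoveries.

The gas molar-volume convention is explicit: temperature and pressure are
required arguments of :func:`gas_flow_to_molar` — there is no hidden STP
default, because percentage-level results depend on the convention chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import parse_formula

__all__ = [
    "R_KPA_L",
    "CompoundInfo",
    "ChemostatRecord",
    "COMPOUNDS",
    "PKA",
    "PKA_AVERAGE",
    "dilution_rate",
    "hrt_from_dilution",
    "gas_flow_to_molar",
    "consumption_percent",
    "undissociated_fraction",
    "undissociated_concentration",
    "degree_of_reduction",
    "balance_recovery",
    "steady_state_rate",
]

#: Gas constant in kPa L mol^-1 K^-1.
R_KPA_L = 8.31446
_ABS_ZERO_C = -273.15

#: Acid dissociation constants of the fermentation acids; the mean of the
#: C2-C6 set is close to the 4.83 "average pKa" convention.
PKA = {
    "acetate": 4.76,
    "propionate": 4.87,
    "butyrate": 4.82,
    "valerate": 4.84,
    "caproate": 4.88,
}
PKA_AVERAGE = 4.83

#: Neutral-species formulas used for balances (biomass = CH1.8O0.5N0.2).
COMPOUNDS: dict[str, dict[str, float]] = {
    "co": parse_formula("CO"),
    "h2": parse_formula("H2"),
    "co2": parse_formula("CO2"),
    "acetate": parse_formula("C2H4O2"),
    "ethanol": parse_formula("C2H6O"),
    "propionate": parse_formula("C3H6O2"),
    "propanol": parse_formula("C3H8O"),
    "butyrate": parse_formula("C4H8O2"),
    "butanol": parse_formula("C4H10O"),
    "valerate": parse_formula("C5H10O2"),
    "pentanol": parse_formula("C5H12O"),
    "caproate": parse_formula("C6H12O2"),
    "hexanol": parse_formula("C6H14O"),
    "heptanoate": parse_formula("C7H14O2"),
    "biomass": {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2},
}


@dataclass
class CompoundInfo:
    formula: dict[str, float]
    pKa: float | None = None

    @property
    def carbons(self) -> float:
        return self.formula.get("C", 0.0)

    @property
    def gamma(self) -> float:
        return degree_of_reduction(self.formula)


@dataclass
class ChemostatRecord:
    """One steady-state observation of a chemostat bioreactor."""

    volume: float  # L
    dilution_rate: float  # h^-1
    concentrations: dict[str, float] = field(default_factory=dict)  # mM (outflow)
    inflow_concentrations: dict[str, float] = field(default_factory=dict)  # mM
    gas_inflow_ml_min: float = 0.0
    gas_fractions: dict[str, float] = field(default_factory=dict)  # v/v in [0, 1]
    gas_partial_pressures: dict[str, float] = field(default_factory=dict)  # kPa

    def validate(self) -> None:
        if self.volume <= 0 or self.dilution_rate <= 0:
            raise ValueError("volume and dilution rate must be positive")
        if self.gas_inflow_ml_min < 0:
            raise ValueError("gas inflow must be nonnegative")
        if sum(self.gas_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("gas fractions sum above 1")
        if any(f < 0 for f in self.gas_fractions.values()):
            raise ValueError("negative gas fraction")


def dilution_rate(hrt_hours: float) -> float:
    """D = 1 / HRT (h^-1); e.g. a 48 h retention time gives 0.021 h^-1."""
    if hrt_hours <= 0:
        raise ValueError(f"HRT must be positive, got {hrt_hours}")
    return 1.0 / hrt_hours


def hrt_from_dilution(d: float) -> float:
    if d <= 0:
        raise ValueError(f"dilution rate must be positive, got {d}")
    return 1.0 / d


def gas_flow_to_molar(
    flow_ml_min: float,
    fraction: float,
    temperature_C: float,
    pressure_kPa: float,
) -> float:
    """Convert a volumetric gas flow to mmol h^-1 via the ideal-gas law at
    the stated temperature and pressure (n = P V / R T)."""
    if flow_ml_min < 0:
        raise ValueError("flow must be nonnegative")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if temperature_C < _ABS_ZERO_C:
        raise ValueError(f"temperature below absolute zero: {temperature_C} C")
    if pressure_kPa <= 0:
        raise ValueError("pressure must be positive")
    liters_per_hour = flow_ml_min * fraction * 60.0 / 1000.0
    mol_per_hour = pressure_kPa * liters_per_hour / (R_KPA_L * (temperature_C - _ABS_ZERO_C))
    return mol_per_hour * 1000.0


def consumption_percent(uptake_rate: float, inflow_rate: float) -> float:
    """100 * uptake / inflow (both as magnitudes in the same unit)."""
    if inflow_rate <= 0:
        raise ValueError("inflow rate must be positive")
    return 100.0 * abs(uptake_rate) / inflow_rate


def undissociated_fraction(pH: float, pKa: float = PKA_AVERAGE) -> float:
    """Henderson-Hasselbalch: fraction of acid in the undissociated (HA)
    form, 1 / (1 + 10^(pH - pKa)); strictly decreasing in pH."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def undissociated_concentration(
    total_mM: float, pH: float, pKa: float = PKA_AVERAGE
) -> float:
    if total_mM < 0:
        raise ValueError("total concentration must be nonnegative")
    return total_mM * undissociated_fraction(pH, pKa)


def degree_of_reduction(
    formula: dict[str, float] | str, nitrogen_source: str = "ammonia"
) -> float:
    """Available electrons per molecule, gamma = 4 C + H - 2 O (CO2/H2O
    reference), with N counted at the ammonia reference state (-3) by
    default.  Unsupported elements (beyond C, H, O, N, P) raise."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    weights = {"C": 4.0, "H": 1.0, "O": -2.0, "P": 0.0}
    if nitrogen_source == "ammonia":
        weights["N"] = -3.0
    elif nitrogen_source == "n2":
        weights["N"] = 0.0
    else:
        raise ValueError(f"unknown nitrogen reference state {nitrogen_source!r}")
    gamma = 0.0
    for el, n in formula.items():
        if el not in weights:
            raise ValueError(f"no reference state for element {el!r}")
        gamma += weights[el] * n
    return gamma


def _lookup_formula(compound: str, formulas: dict[str, dict[str, float]]) -> dict[str, float]:
    if compound in formulas:
        return formulas[compound]
    raise KeyError(f"no formula known for compound {compound!r}")


def balance_recovery(
    inputs: dict[str, float],
    outputs: dict[str, float],
    basis: str = "carbon",
    formulas: dict[str, dict[str, float]] | None = None,
) -> float:
    """Recovery percentage 100 * sum(outputs) / sum(inputs) on a carbon or
    electron (degree-of-reduction) basis; amounts in mmol.

    Compounds with zero weight on the chosen basis (e.g. H2 for carbon,
    CO2 for electrons) contribute nothing; scale-invariant by construction.
    """
    formulas = {**COMPOUNDS, **(formulas or {})}

    def weight(compound: str) -> float:
        f = _lookup_formula(compound, formulas)
        if basis == "carbon":
            return f.get("C", 0.0)
        if basis == "electrons":
            return degree_of_reduction(f)
        raise ValueError(f"basis must be 'carbon' or 'electrons', got {basis!r}")

    total_in = sum(weight(c) * amount for c, amount in inputs.items())
    total_out = sum(weight(c) * amount for c, amount in outputs.items())
    if total_in <= 0:
        raise ValueError("inputs carry no material on the chosen basis")
    return 100.0 * total_out / total_in


def steady_state_rate(record: ChemostatRecord, compound: str) -> float:
    """Liquid-phase steady-state production rate, D * V * (c_out - c_in) in
    mmol h^-1 (negative = net consumption).  Gas-phase terms, when partial
    pressures and flows are recorded, are the caller's to add via
    :func:`gas_flow_to_molar`."""
    record.validate()
    if compound not in record.concentrations:
        raise KeyError(f"no outflow concentration recorded for {compound!r}")
    c_out = record.concentrations[compound]
    c_in = record.inflow_concentrations.get(compound, 0.0)
    return record.dilution_rate * record.volume * (c_out - c_in)
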