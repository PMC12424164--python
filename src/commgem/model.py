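"""Core stoichiometric-network data types.

A :class:`MetabolicModel` is a plain in-memory representation of a
constraint-based (FBA-ready) metabolic network: compartments, metabolites
with optional elemental formulas, reactions with flux bounds, and the ids
of the objective / biomass / maintenance reactions.  It is deliberately
minimal — enough to carry SBML-FBC models and the bundled toy community
through community assembly, linear programming, and flux sampling.

Sign convention: negative stoichiometric coefficients are substrates,
positive are products.  An *exchange* reaction touches exactly one
metabolite, which lives in the extracellular compartment; positive flux
through an exchange is export (production), negative flux is uptake.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "UNBOUNDED",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "parse_formula",
    "format_formula",
    "check_elemental_balance",
]

#: Magnitude treated as the "no constraint" sentinel for flux bounds
#: (the conventional +/-1000 mmol gCDW^-1 h^-1 of genome-scale models).
UNBOUNDED = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


def parse_formula(text: str) -> dict[str, float]:
    """Parse a chemical formula string like ``"C2H4O2"`` into element counts.

    Fractional counts (e.g. biomass ``CH1.8O0.5N0.2``) are accepted.
    """
    if text is None:
        raise ValueError("formula text is None")
    text = text.strip()
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {text!r}")
        pos = m.end()
        n = float(m.group(2)) if m.group(2) else 1.0
        counts[m.group(1)] = counts.get(m.group(1), 0.0) + n
    if pos != len(text):
        raise ValueError(f"unparseable formula {text!r}")
    return counts


def format_formula(counts: dict[str, float]) -> str:
    """Inverse of :func:`parse_formula`; Hill-ish deterministic ordering."""

    def fmt(n: float) -> str:
        if n == 1:
            return ""
        if float(n).is_integer():
            return str(int(n))
        return repr(round(float(n), 6))

    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{el}{fmt(counts[el])}" for el in order)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, float] | None = None
    charge: int | None = None
    compartment: str = "c"

    def copy(self) -> "Metabolite":
        return replace(self, formula=None if self.formula is None else dict(self.formula))


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -UNBOUNDED
    upper_bound: float = UNBOUNDED
    name: str = ""
    gene_rule: str | None = None

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """Stoichiometric network with flux bounds and an FBA objective."""

    id: str
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_id: str | None = None
    biomass_id: str | None = None
    ngam_id: str | None = None
    extracellular_id: str = "e"

    # -- construction helpers -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites={k: m.copy() for k, m in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            objective_id=self.objective_id,
            biomass_id=self.biomass_id,
            ngam_id=self.ngam_id,
            extracellular_id=self.extracellular_id,
        )

    # -- classification -------------------------------------------------------

    def is_exchange(self, rxn_id: str) -> bool:
        """True iff the reaction touches exactly one metabolite and that
        metabolite lives in the extracellular compartment."""
        rxn = self.reactions[rxn_id]
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        met = self.metabolites.get(met_id)
        return met is not None and met.compartment == self.extracellular_id

    def exchange_ids(self) -> list[str]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def exchange_for(self, met_id: str) -> str | None:
        """Exchange reaction id draining/feeding ``met_id``, if any."""
        for rid in self.reactions:
            rxn = self.reactions[rid]
            if len(rxn.stoichiometry) == 1 and met_id in rxn.stoichiometry and self.is_exchange(rid):
                return rid
        return None

    # -- linear-algebra view --------------------------------------------------

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Sparse S (metabolites x reactions) plus row/column id orderings."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                data.append(coef)
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions.values()], dtype=float)
        return lb, ub

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r} references undeclared compartment "
                    f"{met.compartment!r}"
                )
            if met.formula is not None and any(v < 0 for v in met.formula.values()):
                raise ModelValidationError(f"negative element count in {met.id!r}")
        for rxn in self.reactions.values():
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            if not rxn.lower_bound <= rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
        for attr in ("objective_id", "biomass_id", "ngam_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self.reactions:
                raise ModelValidationError(f"{attr} {rid!r} is not a reaction in the model")

    def equal_to(self, other: "MetabolicModel", tol: float = 1e-9) -> bool:
        """Field-wise equality up to numeric tolerance (round-trip checks)."""
        if set(self.metabolites) != set(other.metabolites):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        if self.compartments != other.compartments:
            return False
        for mid, m in self.metabolites.items():
            o = other.metabolites[mid]
            if (m.formula is None) != (o.formula is None):
                return False
            if m.formula is not None:
                keys = set(m.formula) | set(o.formula)
                if any(
                    abs(m.formula.get(k, 0.0) - o.formula.get(k, 0.0)) > tol for k in keys
                ):
                    return False
            if m.charge != o.charge or m.compartment != o.compartment:
                return False
        for rid, r in self.reactions.items():
            o = other.reactions[rid]
            keys = set(r.stoichiometry) | set(o.stoichiometry)
            if any(
                abs(r.stoichiometry.get(k, 0.0) - o.stoichiometry.get(k, 0.0)) > tol
                for k in keys
            ):
                return False
            if (
                abs(r.lower_bound - o.lower_bound) > tol
                or abs(r.upper_bound - o.upper_bound) > tol
            ):
                return False
        return (
            self.objective_id == other.objective_id
            and self.biomass_id == other.biomass_id
            and self.ngam_id == other.ngam_id
        )


@dataclass
class BalanceReport:
    """Outcome of an elemental-balance audit."""

    imbalanced: dict[str, dict[str, float]]  # reaction id -> element -> net
    unchecked: list[str]  # reactions skipped for missing formulas
    checked: list[str]

    @property
    def ok(self) -> bool:
        return not self.imbalanced


def check_elemental_balance(
    model: MetabolicModel,
    tol: float = 1e-9,
    exclude: set[str] | None = None,
) -> BalanceReport:
    """Audit per-reaction elemental balance.

    Exchange reactions and the biomass reaction(s) are excluded (they are
    boundary/lumped by construction).  Reactions containing a metabolite
    with no formula are reported as *unchecked* rather than imbalanced.
    """
    exclude = set(exclude or ())
    if model.biomass_id:
        exclude.add(model.biomass_id)
    exclude.update(rid for rid in model.reactions if rid.startswith("Biomass"))
    imbalanced: dict[str, dict[str, float]] = {}
    unchecked: list[str] = []
    checked: list[str] = []
    for rid, rxn in model.reactions.items():
        if rid in exclude or model.is_exchange(rid):
            continue
        if any(model.metabolites[m].formula is None for m in rxn.stoichiometry):
            unchecked.append(rid)
            continue
        net: dict[str, float] = {}
        for met_id, coef in rxn.stoichiometry.items():
            for el, n in model.metabolites[met_id].formula.items():
                net[el] = net.get(el, 0.0) + coef * n
        bad = {el: v for el, v in net.items() if abs(v) > tol}
        if bad:
            imbalanced[rid] = bad
        else:
            checked.append(rid)
    return BalanceReport(imbalanced=imbalanced, unchecked=unchecked, checked=checked)


def is_bounded(value: float) -> bool:
    """False for the +/-UNBOUNDED sentinel and infinities."""
    return math.isfinite(value) and abs(value) < UNBOUNDED - 1e-9
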