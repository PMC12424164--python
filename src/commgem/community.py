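"""Assembly of multi-species community models.

The merging procedure follows the standard compartment-per-species
construction for community FBA (cFBA): each species keeps a private,
tag-suffixed cytosol, all species share one extracellular compartment,
duplicate exchange reactions are unified, and a pseudo-reaction
(``EX_Biomass_e``) consumes the species biomass metabolites with
stoichiometric coefficients equal to the biomass abundance fractions.

Under chemostat-style balanced growth every species grows at the common
dilution rate mu while keeping its abundance fraction f_i of the total
community biomass X, so the species biomass flux is pinned to
``f_i * X * mu`` (g h^-1) and the community biomass flux to ``X * mu``.
Per-species flux bounds stated per gram of cell dry weight are converted
to "environmental" whole-culture bounds (mmol h^-1) by multiplying with
the species biomass amount ``f_i * X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    is_bounded,
)

__all__ = [
    "SpeciesSpec",
    "CommunityModel",
    "CommunityCondition",
    "tag_species",
    "untag_species",
    "merge_models",
    "add_community_biomass",
    "apply_condition",
    "constrain_monoculture",
    "COMMUNITY_BIOMASS_ID",
]

COMMUNITY_BIOMASS_ID = "EX_Biomass_e"
FRACTION_TOL = 1e-9


@dataclass
class SpeciesSpec:
    model: MetabolicModel
    tag: str
    biomass_fraction: float = 1.0


@dataclass
class CommunityModel:
    model: MetabolicModel
    species: dict[str, str]  # tag -> species biomass reaction id
    community_biomass_id: str = COMMUNITY_BIOMASS_ID
    extracellular_id: str = "e"

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            model=self.model.copy(),
            species=dict(self.species),
            community_biomass_id=self.community_biomass_id,
            extracellular_id=self.extracellular_id,
        )


@dataclass
class CommunityCondition:
    """One cFBA scenario: growth rate, total biomass, ratios, feed bounds."""

    growth_rate: float  # mu, h^-1
    total_biomass: float  # X, g
    fractions: dict[str, float]
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective_id: str | None = None

    def validate(self) -> None:
        if self.growth_rate < 0:
            raise ValueError(f"growth rate must be >= 0, got {self.growth_rate}")
        if self.total_biomass <= 0:
            raise ValueError(f"total biomass must be > 0, got {self.total_biomass}")
        if not self.fractions:
            raise ValueError("fractions mapping is empty")
        _check_fractions(self.fractions)
        for rid, (lo, hi) in self.exchange_bounds.items():
            if lo > hi:
                raise ValueError(f"exchange bound for {rid!r} has lower {lo} > upper {hi}")


def _check_fractions(fractions: dict[str, float]) -> None:
    total = sum(fractions.values())
    if abs(total - 1.0) > FRACTION_TOL:
        raise ValueError(f"species fractions sum to {total!r}, expected 1")
    for tag, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction for {tag!r} out of [0, 1]: {f}")


def tag_species(model: MetabolicModel, tag: str) -> MetabolicModel:
    """Suffix every non-extracellular compartment, metabolite and reaction
    id with ``_tag``; extracellular ids are left untouched."""
    suffix = f"_{tag}"
    ext = model.extracellular_id
    for cid in model.compartments:
        if cid != ext and cid.endswith(suffix):
            raise ModelValidationError(
                f"compartment {cid!r} already carries the tag {tag!r}"
            )

    out = MetabolicModel(id=f"{model.id}{suffix}", extracellular_id=ext)
    comp_map = {
        cid: cid if cid == ext else cid + suffix for cid in model.compartments
    }
    out.compartments = {comp_map[c]: n for c, n in model.compartments.items()}

    met_map: dict[str, str] = {}
    for met in model.metabolites.values():
        new_id = met.id if met.compartment == ext else met.id + suffix
        met_map[met.id] = new_id
        new = met.copy()
        new.id = new_id
        new.compartment = comp_map[met.compartment]
        out.add_metabolite(new)

    rxn_map: dict[str, str] = {}
    for rxn in model.reactions.values():
        extracellular_only = all(
            model.metabolites[m].compartment == ext for m in rxn.stoichiometry
        )
        new_id = rxn.id if extracellular_only else rxn.id + suffix
        rxn_map[rxn.id] = new_id
        new = rxn.copy()
        new.id = new_id
        new.stoichiometry = {met_map[m]: c for m, c in rxn.stoichiometry.items()}
        out.add_reaction(new)

    for attr in ("objective_id", "biomass_id", "ngam_id"):
        rid = getattr(model, attr)
        setattr(out, attr, rxn_map.get(rid) if rid else None)
    out.validate()
    return out


def untag_species(model: MetabolicModel, tag: str) -> MetabolicModel:
    """Strip a species tag applied by :func:`tag_species`."""
    suffix = f"_{tag}"

    def strip(s: str | None) -> str | None:
        if s is None:
            return None
        return s[: -len(suffix)] if s.endswith(suffix) else s

    out = MetabolicModel(
        id=strip(model.id), extracellular_id=model.extracellular_id
    )
    out.compartments = {strip(c): n for c, n in model.compartments.items()}
    for met in model.metabolites.values():
        new = met.copy()
        new.id = strip(met.id)
        new.compartment = strip(met.compartment)
        out.add_metabolite(new)
    for rxn in model.reactions.values():
        new = rxn.copy()
        new.id = strip(rxn.id)
        new.stoichiometry = {strip(m): c for m, c in rxn.stoichiometry.items()}
        out.add_reaction(new)
    out.objective_id = strip(model.objective_id)
    out.biomass_id = strip(model.biomass_id)
    out.ngam_id = strip(model.ngam_id)
    return out


def merge_models(species: list[SpeciesSpec]) -> CommunityModel:
    """Merge tagged single-species models into one community model.

    Extracellular metabolites present in several inputs appear once;
    duplicate exchange reactions collapse to a single reaction whose bound
    interval is the componentwise union (min of lowers, max of uppers), so
    the community is never more restricted than any member.
    """
    if len(species) < 2:
        raise ValueError("a community needs at least two species")
    tags = [s.tag for s in species]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate species tags: {tags}")
    ext_ids = {s.model.extracellular_id for s in species}
    if len(ext_ids) != 1:
        raise ValueError(f"species disagree on the extracellular compartment id: {ext_ids}")
    ext = ext_ids.pop()

    merged = MetabolicModel(id="community_" + "_".join(tags), extracellular_id=ext)
    biomass_by_tag: dict[str, str] = {}
    for spec in species:
        m = spec.model
        if m.biomass_id is None:
            raise ModelValidationError(f"species {spec.tag!r} has no biomass reaction")
        if not m.biomass_id.endswith(f"_{spec.tag}"):
            raise ModelValidationError(
                f"species {spec.tag!r} does not look tagged "
                f"(biomass reaction {m.biomass_id!r}); call tag_species first"
            )
        biomass_by_tag[spec.tag] = m.biomass_id

        for cid, name in m.compartments.items():
            merged.compartments.setdefault(cid, name)
        for met in m.metabolites.values():
            if met.id in merged.metabolites:
                existing = merged.metabolites[met.id]
                if met.compartment != ext:
                    raise ModelValidationError(
                        f"intracellular metabolite id collision: {met.id!r}"
                    )
                if (
                    existing.formula is not None
                    and met.formula is not None
                    and existing.formula != met.formula
                ):
                    raise ModelValidationError(
                        f"conflicting formulas for shared metabolite {met.id!r}"
                    )
                if existing.formula is None:
                    existing.formula = None if met.formula is None else dict(met.formula)
            else:
                merged.add_metabolite(met.copy())
        for rxn in m.reactions.values():
            if rxn.id in merged.reactions:
                existing = merged.reactions[rxn.id]
                if not m.is_exchange(rxn.id):
                    raise ModelValidationError(f"reaction id collision: {rxn.id!r}")
                if existing.stoichiometry != rxn.stoichiometry:
                    raise ModelValidationError(
                        f"duplicate exchange {rxn.id!r} with differing stoichiometry"
                    )
                existing.lower_bound = min(existing.lower_bound, rxn.lower_bound)
                existing.upper_bound = max(existing.upper_bound, rxn.upper_bound)
            else:
                merged.add_reaction(rxn.copy())

    merged.validate()
    cm = CommunityModel(model=merged, species=biomass_by_tag, extracellular_id=ext)
    fractions = {s.tag: s.biomass_fraction for s in species}
    if abs(sum(fractions.values()) - 1.0) <= FRACTION_TOL:
        add_community_biomass(cm, fractions)
    return cm


def _species_biomass_metabolite(model: MetabolicModel, biomass_rxn_id: str) -> str:
    """The (sole) metabolite produced by a species biomass reaction."""
    products = [
        m for m, c in model.reactions[biomass_rxn_id].stoichiometry.items() if c > 0
    ]
    named = [m for m in products if "biomass" in m.lower()]
    if len(named) == 1:
        return named[0]
    candidates = [
        m for m in products
        if not (m.startswith("h2o") or m.startswith("adp") or m.startswith("atp"))
    ]
    if len(candidates) != 1:
        raise ModelValidationError(
            f"biomass reaction {biomass_rxn_id!r} must produce exactly one "
            f"species-biomass metabolite, found {candidates}"
        )
    return candidates[0]


def add_community_biomass(cm: CommunityModel, fractions: dict[str, float]) -> CommunityModel:
    """Create or re-parametrize ``EX_Biomass_e``: one unit of community
    biomass flux drains ``fraction_i`` units of each species biomass
    metabolite.  Mutates ``cm`` in place and returns it."""
    _check_fractions(fractions)
    if set(fractions) != set(cm.species):
        raise ValueError(
            f"fractions keys {sorted(fractions)} do not match species {sorted(cm.species)}"
        )
    stoich = {}
    for tag, biomass_rxn in cm.species.items():
        met = _species_biomass_metabolite(cm.model, biomass_rxn)
        stoich[met] = -fractions[tag]
    rid = cm.community_biomass_id
    if rid in cm.model.reactions:
        cm.model.reactions[rid].stoichiometry = stoich
    else:
        cm.model.add_reaction(
            Reaction(
                id=rid,
                name="community biomass",
                stoichiometry=stoich,
                lower_bound=0.0,
            )
        )
    cm.model.objective_id = rid
    cm.model.biomass_id = rid
    return cm


def apply_condition(cm: CommunityModel, cond: CommunityCondition) -> CommunityModel:
    """Return a constrained copy of the community model for one scenario.

    Steps, in order, on a fresh copy (the input is never mutated):

    1. rebuild the community biomass stoichiometry from ``cond.fractions``;
    2. scale every *finite* per-species reaction bound by ``f_i * X``
       (specific mmol gCDW^-1 h^-1 -> environmental mmol h^-1), leaving the
       +/-1000 "unbounded" sentinels alone;
    3. fix each species biomass flux to ``f_i * X * mu`` and the community
       biomass flux to ``X * mu`` (g h^-1);
    4. apply the exchange-bound overrides from ``cond`` (mmol h^-1).
    """
    cond.validate()
    if set(cond.fractions) != set(cm.species):
        raise ValueError(
            f"condition fractions {sorted(cond.fractions)} do not match "
            f"community species {sorted(cm.species)}"
        )
    out = cm.copy()
    add_community_biomass(out, cond.fractions)
    X, mu = cond.total_biomass, cond.growth_rate

    for tag in out.species:
        scale = cond.fractions[tag] * X
        suffix = f"_{tag}"
        for rxn in out.model.reactions.values():
            if not rxn.id.endswith(suffix):
                continue
            if scale == 0.0:
                # an absent species carries no flux at all
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
            else:
                if is_bounded(rxn.lower_bound):
                    rxn.lower_bound *= scale
                if is_bounded(rxn.upper_bound):
                    rxn.upper_bound *= scale

    for tag, biomass_rxn in out.species.items():
        v = cond.fractions[tag] * X * mu
        out.model.reactions[biomass_rxn].lower_bound = v
        out.model.reactions[biomass_rxn].upper_bound = v
    comm = out.model.reactions[out.community_biomass_id]
    comm.lower_bound = X * mu
    comm.upper_bound = X * mu

    for rid, (lo, hi) in cond.exchange_bounds.items():
        if rid not in out.model.reactions:
            raise KeyError(f"exchange bound for unknown reaction {rid!r}")
        out.model.reactions[rid].lower_bound = lo
        out.model.reactions[rid].upper_bound = hi

    if cond.objective_id is not None:
        out.model.objective_id = cond.objective_id
    out.model.validate()
    return out


def constrain_monoculture(
    model: MetabolicModel,
    growth_rate: float,
    total_biomass: float,
    exchange_bounds: dict[str, tuple[float, float]] | None = None,
) -> MetabolicModel:
    """Monoculture analogue of :func:`apply_condition` for a single species
    model: scale finite non-exchange bounds by X, fix the biomass flux to
    ``X * mu`` (g h^-1), then apply exchange-bound overrides."""
    if growth_rate < 0 or total_biomass <= 0:
        raise ValueError("growth rate must be >= 0 and biomass > 0")
    out = model.copy()
    for rxn in out.reactions.values():
        if out.is_exchange(rxn.id):
            continue
        if is_bounded(rxn.lower_bound):
            rxn.lower_bound *= total_biomass
        if is_bounded(rxn.upper_bound):
            rxn.upper_bound *= total_biomass
    if out.biomass_id is None:
        raise ModelValidationError("model has no biomass reaction")
    v = total_biomass * growth_rate
    out.reactions[out.biomass_id].lower_bound = v
    out.reactions[out.biomass_id].upper_bound = v
    for rid, (lo, hi) in (exchange_bounds or {}).items():
        out.reactions[rid].lower_bound = lo
        out.reactions[rid].upper_bound = hi
    out.validate()
    return out
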