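"""Scenario analyses: feed media, ratio scans, H2 supplementation scans,
and qualitative growth-phenotype screens.

All flux-level results in the scan tables are sampling means +/- sd over
the feasible polytope (never single LP optima); feasibility per scenario
is decided by FBA first, and infeasible scenarios are recorded as such
while the scan continues.
"""

from __future__ import annotations

import pandas as pd

from .community import (
    CommunityCondition,
    CommunityModel,
    apply_condition,
    constrain_monoculture,
)
from .fba import solve_fba
from .model import MetabolicModel, UNBOUNDED
from .sampling import product_profile, sample_fluxes

__all__ = [
    "make_feed_bounds",
    "catabolic_mode",
    "scan_ratios",
    "scan_h2",
    "phenotype_screen",
    "DEFAULT_PRODUCTS",
]

#: Extracellular metabolites reported as products by default (water and
#: the inorganic N source are element-balancing, not products).
DEFAULT_PRODUCTS = [
    "ac", "etoh", "prop", "poh", "but", "boh", "val", "peoh",
    "cap", "hoh", "hep", "co2", "h2",
]


def make_feed_bounds(
    model: MetabolicModel,
    co: tuple[float, float] | None = None,
    h2: tuple[float, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Chemostat-style feed: CO (and optionally H2) may be taken up within
    the given interval; every other exchange is export-only except water
    and ammonium, which stay free."""
    free = {"EX_h2o_e", "EX_nh3_e"}
    bounds: dict[str, tuple[float, float]] = {}
    for rid in model.exchange_ids():
        if rid in free:
            bounds[rid] = (-UNBOUNDED, UNBOUNDED)
        elif rid == "EX_co_e" and co is not None:
            bounds[rid] = co
        elif rid == "EX_h2_e" and h2 is not None:
            bounds[rid] = h2
        else:
            bounds[rid] = (0.0, UNBOUNDED)
    return bounds


def catabolic_mode(model: MetabolicModel) -> MetabolicModel:
    """Copy of a species model with growth and maintenance switched off
    (biomass flux fixed at zero, NGAM lower bound zero): pure catabolism,
    useful for stoichiometric limit cases."""
    out = model.copy()
    if out.biomass_id:
        out.reactions[out.biomass_id].lower_bound = 0.0
        out.reactions[out.biomass_id].upper_bound = 0.0
    if out.ngam_id:
        out.reactions[out.ngam_id].lower_bound = 0.0
    return out


def _product_exchange_map(model: MetabolicModel, products=None) -> dict[str, str]:
    products = products or DEFAULT_PRODUCTS
    mapping = {}
    for met in products:
        rid = f"EX_{met}_e"
        if rid in model.reactions:
            mapping[met] = rid
    return mapping


def _sample_profile(model, products, n, seed, thinning, extra_reactions=()):
    sr = sample_fluxes(model, n=n, seed=seed, thinning=thinning)
    table = product_profile(sr, _product_exchange_map(model, products))
    extras = []
    for rid in extra_reactions:
        if rid in sr.reaction_ids:
            col = sr.column(rid)
            extras.append({
                "product": rid, "reaction": rid,
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                "n": len(col),
            })
    if extras:
        table = pd.concat([table, pd.DataFrame(extras)], ignore_index=True)
    return table


def scan_ratios(
    cm: CommunityModel,
    ratio_list: list[dict[str, float]],
    growth_rate: float,
    total_biomass: float,
    co_bounds: tuple[float, float],
    n: int = 1000,
    seed: int | None = None,
    thinning: int = 25,
    products: list[str] | None = None,
) -> pd.DataFrame:
    """Sampled product profile per species-ratio combination (tidy table:
    one row per ratio x product).  Infeasible ratios are kept in the table
    with ``feasible = False``."""
    rows = []
    feed = make_feed_bounds(cm.model, co=co_bounds)
    for k, fractions in enumerate(ratio_list):
        cond = CommunityCondition(
            growth_rate=growth_rate,
            total_biomass=total_biomass,
            fractions=fractions,
            exchange_bounds=dict(feed),
        )
        constrained = apply_condition(cm, cond)
        sol = solve_fba(constrained.model)
        tags = {f"fraction_{t}": f for t, f in fractions.items()}
        if not sol.optimal:
            rows.append({**tags, "feasible": False, "product": None,
                         "mean": None, "sd": None, "n": 0})
            continue
        run_seed = None if seed is None else seed + k
        table = _sample_profile(constrained.model, products, n, run_seed, thinning)
        for rec in table.to_dict("records"):
            rows.append({**tags, "feasible": True, **rec})
    return pd.DataFrame(rows)


def scan_h2(
    model_or_cm: MetabolicModel | CommunityModel,
    co_bounds: tuple[float, float],
    h2_levels: list[float],
    growth_rate: float,
    total_biomass: float,
    fractions: dict[str, float] | None = None,
    n: int = 1000,
    seed: int | None = None,
    thinning: int = 25,
    products: list[str] | None = None,
) -> pd.DataFrame:
    """Sampled product profile per H2 uptake level (mmol h^-1, negative =
    uptake; 0 means no supplementation, i.e. the CO-only feed).

    Works on a community model (``fractions`` required) or a single
    species model (monoculture).  Alongside the exchange products the table
    reports the Wood-Ljungdahl carbon flux when the model carries a
    ``WLP``/``WLP_aw`` reaction.
    """
    rows = []
    for k, h2 in enumerate(h2_levels):
        if h2 > 0:
            raise ValueError(f"H2 level must be an uptake rate (<= 0), got {h2}")
        h2_bounds = (h2, h2) if h2 < 0 else None
        if isinstance(model_or_cm, CommunityModel):
            if fractions is None:
                raise ValueError("fractions required for a community model")
            feed = make_feed_bounds(model_or_cm.model, co=co_bounds, h2=h2_bounds)
            cond = CommunityCondition(
                growth_rate=growth_rate,
                total_biomass=total_biomass,
                fractions=fractions,
                exchange_bounds=feed,
            )
            constrained = apply_condition(model_or_cm, cond).model
        else:
            feed = make_feed_bounds(model_or_cm, co=co_bounds, h2=h2_bounds)
            constrained = constrain_monoculture(
                model_or_cm, growth_rate, total_biomass, exchange_bounds=feed
            )
        sol = solve_fba(constrained)
        if not sol.optimal:
            rows.append({"h2_level": h2, "feasible": False, "product": None,
                         "mean": None, "sd": None, "n": 0})
            continue
        run_seed = None if seed is None else seed + k
        table = _sample_profile(
            constrained, products, n, run_seed, thinning,
            extra_reactions=("WLP", "WLP_aw"),
        )
        for rec in table.to_dict("records"):
            rows.append({"h2_level": h2, "feasible": True, **rec})
    return pd.DataFrame(rows)


def phenotype_screen(
    model: MetabolicModel,
    substrates: dict[str, str | list[str]],
    medium: dict[str, tuple[float, float]] | None = None,
    uptake_bound: float = 10.0,
    threshold: float = 1e-6,
) -> dict[str, bool | None]:
    """Qualitative growth phenotypes: for each substrate, open only its
    uptake (at ``-uptake_bound``), keep the mineral medium open, close all
    other uptakes, and maximize biomass.

    Returns ``True`` (growth), ``False`` (no growth), or ``None`` when the
    substrate has no exchange reaction in the model (not representable).
    The NGAM floor is relaxed for the screen so that "cannot even pay
    maintenance" reads as no growth rather than LP infeasibility.
    """
    if medium is None:
        medium = {
            rid: (-UNBOUNDED, UNBOUNDED)
            for rid in ("EX_h2o_e", "EX_nh3_e")
            if rid in model.reactions
        }
    base = model.copy()
    if base.biomass_id is None:
        raise ValueError("model has no biomass reaction to screen")
    base.reactions[base.biomass_id].lower_bound = 0.0
    base.reactions[base.biomass_id].upper_bound = UNBOUNDED
    if base.ngam_id:
        base.reactions[base.ngam_id].lower_bound = 0.0
    for rid in base.exchange_ids():
        if rid in medium:
            base.reactions[rid].lower_bound, base.reactions[rid].upper_bound = medium[rid]
        else:
            base.reactions[rid].lower_bound = 0.0

    results: dict[str, bool | None] = {}
    for name, spec in substrates.items():
        exchanges = [spec] if isinstance(spec, str) else list(spec)
        if any(rid not in base.reactions for rid in exchanges):
            results[name] = None
            continue
        trial = base.copy()
        for rid in exchanges:
            trial.reactions[rid].lower_bound = -uptake_bound
        sol = solve_fba(trial, objective_id=trial.biomass_id)
        results[name] = bool(sol.optimal and sol.objective_value > threshold)
    return results
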