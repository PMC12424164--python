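"""Synthetic three-species community for syngas chain elongation.

Three small, elementally balanced lumped-pathway models emulate the
metabolic division of labour of a CO-fed triculture:

* **acetogen** — Wood-Ljungdahl CO/H2 fixation to an acetyl unit, with an
  acetate-kinase branch (ATP-yielding), an ethanol branch, and CO-driven
  reduction of C2-C6 carboxylates to their alcohols;
* **propionigen** — ethanol + CO2 via an acrylate-pathway lump to
  propionate + acetate (2:1), plus ethanol oxidation to acetate + H2;
* **chain elongator** — ethanol-driven reverse beta-oxidation extending
  acetate -> butyrate -> caproate and propionate -> valerate -> heptanoate,
  with H2-evolving ethanol oxidation.

Electron carriers are collapsed into a single reduced-equivalent pool
``red`` worth 2 e- (chemical formula H2), so elemental balance doubles as
electron balance.  ATP is an explicit ``atp``/``adp`` moiety pair (formula
"P"): every catabolic lump carries a configurable ATP coefficient, the
biomass reaction a growth-associated maintenance (GAM) demand, and a
non-growth maintenance (NGAM) reaction hydrolyses ATP at a fixed minimum
rate.  Biomass has the standard composition CH1.8O0.5N0.2 (24.6 g per
C-mol); biomass reaction flux is expressed in g h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import CommunityModel, SpeciesSpec, merge_models, tag_species
from .model import MetabolicModel, Metabolite, Reaction, UNBOUNDED

__all__ = [
    "ToyConfig",
    "make_toy_acetogen",
    "make_toy_propionigen",
    "make_toy_chain_elongator",
    "make_toy_triculture",
    "simulate_chemostat_observations",
    "FORMULAS",
]

#: Neutral (acid-form) elemental formulas of the shared metabolite pool.
FORMULAS: dict[str, dict[str, float]] = {
    "co": {"C": 1, "O": 1},
    "h2": {"H": 2},
    "co2": {"C": 1, "O": 2},
    "h2o": {"H": 2, "O": 1},
    "nh3": {"N": 1, "H": 3},
    "ac": {"C": 2, "H": 4, "O": 2},
    "etoh": {"C": 2, "H": 6, "O": 1},
    "prop": {"C": 3, "H": 6, "O": 2},
    "poh": {"C": 3, "H": 8, "O": 1},
    "but": {"C": 4, "H": 8, "O": 2},
    "boh": {"C": 4, "H": 10, "O": 1},
    "val": {"C": 5, "H": 10, "O": 2},
    "peoh": {"C": 5, "H": 12, "O": 1},
    "cap": {"C": 6, "H": 12, "O": 2},
    "hoh": {"C": 6, "H": 14, "O": 1},
    "hep": {"C": 7, "H": 14, "O": 2},
    "red": {"H": 2},  # reduced carrier, 2 e- (ferredoxin/NADH pool lumped)
    "accoa": {"C": 2, "H": 4, "O": 2},  # acetyl unit (CoA moiety collapsed)
    "atp": {"P": 1},  # phosphoryl moiety carrier
    "adp": {"P": 1},
}

_ELEMENT_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


@dataclass
class ToyConfig:
    """Tunable stoichiometric parameters of the toy species.

    ATP coefficients are toy parameters chosen so that each species grows
    on its native substrate and fails without it; rates are specific
    (mmol gCDW^-1 h^-1) before environmental conversion.
    """

    include_reduction_pathways: bool = True
    atp_per_acetate: float = 1.0  # acetate kinase (substrate-level)
    atp_per_ethanol: float = 0.25  # chemiosmotic share of the ethanol branch
    atp_per_acrylate: float = 1.0  # per acrylate lump turn (3 ethanol)
    # Ethanol oxidation supplies electrons/acetate, not ATP: a nonzero yield
    # here combined with acid-to-alcohol reduction and H2 recapture would
    # close a perpetual ATP-generating loop across species.
    atp_per_oxidation: float = 0.0
    atp_per_elongation: float = 0.4  # per two-carbon elongation cycle
    ngam_rate: float = 0.3  # mmol ATP gCDW^-1 h^-1, fixed lower bound
    gam_per_biomass: float = 40.0  # mmol ATP per g biomass
    biomass_formula: dict[str, float] = field(
        default_factory=lambda: {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2}
    )
    bounds_default: float = UNBOUNDED

    def validate(self) -> None:
        for name in ("atp_per_acetate", "atp_per_ethanol", "atp_per_acrylate",
                     "atp_per_oxidation", "atp_per_elongation", "ngam_rate",
                     "gam_per_biomass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.biomass_formula.get("C", 0) < 1:
            raise ValueError("biomass formula must contain at least one carbon")

    @property
    def biomass_molar_mass(self) -> float:
        """g per C-mol of biomass (approx. 24.6 for CH1.8O0.5N0.2)."""
        return sum(_ELEMENT_MASS[e] * n for e, n in self.biomass_formula.items())

    @property
    def mmol_biomass_per_g(self) -> float:
        return 1000.0 / self.biomass_molar_mass


def _base_model(model_id: str, cfg: ToyConfig, ext_mets: list[str]) -> MetabolicModel:
    """Skeleton with compartments, internal/external metabolites, transports
    and exchanges for the given extracellular metabolite set."""
    m = MetabolicModel(
        id=model_id,
        compartments={"c": "cytosol", "e": "extracellular"},
        extracellular_id="e",
    )
    bd = cfg.bounds_default
    for met in ext_mets:
        m.add_metabolite(Metabolite(id=f"{met}_e", formula=dict(FORMULAS[met]), compartment="e"))
        m.add_metabolite(Metabolite(id=met, formula=dict(FORMULAS[met]), compartment="c"))
        m.add_reaction(
            Reaction(
                id=f"T_{met}",
                name=f"{met} transport",
                stoichiometry={f"{met}_e": -1.0, met: 1.0},
                lower_bound=-bd,
                upper_bound=bd,
            )
        )
        m.add_reaction(
            Reaction(
                id=f"EX_{met}_e",
                name=f"{met} exchange",
                stoichiometry={f"{met}_e": -1.0},
                lower_bound=-bd,
                upper_bound=bd,
            )
        )
    for met in ("red", "accoa", "atp", "adp"):
        if met not in m.metabolites:
            m.add_metabolite(
                Metabolite(id=met, formula=dict(FORMULAS[met]), compartment="c")
            )
    m.add_metabolite(Metabolite(id="biomass", formula=None, compartment="c"))
    return m


def _add_energy_and_growth(m: MetabolicModel, cfg: ToyConfig, precursor: str,
                           reductant: str) -> None:
    """NGAM, biomass synthesis (per gram, GAM included) and biomass drain.

    Per C-mol: 0.5 precursor (C2 unit) + 0.2 NH3 + 0.1 red -> biomass
    + 0.5 H2O, element-balanced for CH1.8O0.5N0.2; scaled to 1 g.
    """
    bd = cfg.bounds_default
    n = cfg.mmol_biomass_per_g
    gam = cfg.gam_per_biomass
    m.add_reaction(
        Reaction(
            id="NGAM",
            name="non-growth maintenance (ATP hydrolysis)",
            stoichiometry={"atp": -1.0, "adp": 1.0},
            lower_bound=cfg.ngam_rate,
            upper_bound=bd,
        )
    )
    m.add_reaction(
        Reaction(
            id="Biomass",
            name="biomass synthesis (flux in g h^-1)",
            stoichiometry={
                precursor: -0.5 * n,
                "nh3": -0.2 * n,
                reductant: -0.1 * n,
                "atp": -gam,
                "adp": gam,
                "h2o": 0.5 * n,
                "biomass": 1.0,
            },
            lower_bound=0.0,
            upper_bound=bd,
        )
    )
    m.add_reaction(
        Reaction(
            id="DM_biomass",
            name="biomass drain",
            stoichiometry={"biomass": -1.0},
            lower_bound=0.0,
            upper_bound=bd,
        )
    )
    m.objective_id = "Biomass"
    m.biomass_id = "Biomass"
    m.ngam_id = "NGAM"


def make_toy_acetogen(cfg: ToyConfig | None = None) -> MetabolicModel:
    """CO/H2 acetogen: Wood-Ljungdahl fixation, acetate/ethanol branches,
    and CO-driven carboxylate-to-alcohol reductions (C2-C6)."""
    cfg = cfg or ToyConfig()
    cfg.validate()
    bd = cfg.bounds_default
    ext = ["co", "h2", "co2", "h2o", "nh3", "ac", "etoh"]
    reductions = [("ac", "etoh"), ("prop", "poh"), ("but", "boh"),
                  ("val", "peoh"), ("cap", "hoh")]
    if cfg.include_reduction_pathways:
        ext += ["prop", "poh", "but", "boh", "val", "peoh", "cap", "hoh"]
    m = _base_model("toy_acetogen", cfg, ext)

    m.add_reaction(Reaction(
        id="CODH", name="CO dehydrogenase",
        stoichiometry={"co": -1.0, "h2o": -1.0, "co2": 1.0, "red": 1.0},
        lower_bound=0.0, upper_bound=bd))
    m.add_reaction(Reaction(
        id="HYD", name="uptake hydrogenase",
        stoichiometry={"h2": -1.0, "red": 1.0},
        lower_bound=0.0, upper_bound=bd))
    m.add_reaction(Reaction(
        id="WLP", name="Wood-Ljungdahl pathway (lumped)",
        stoichiometry={"co2": -2.0, "red": -4.0, "accoa": 1.0, "h2o": 2.0},
        lower_bound=0.0, upper_bound=bd))
    m.add_reaction(Reaction(
        id="ACK", name="acetate kinase branch",
        stoichiometry={"accoa": -1.0, "adp": -cfg.atp_per_acetate,
                       "ac": 1.0, "atp": cfg.atp_per_acetate},
        lower_bound=0.0, upper_bound=bd))
    m.add_reaction(Reaction(
        id="ETB", name="ethanol branch",
        stoichiometry={"accoa": -1.0, "red": -2.0, "adp": -cfg.atp_per_ethanol,
                       "etoh": 1.0, "h2o": 1.0, "atp": cfg.atp_per_ethanol},
        lower_bound=0.0, upper_bound=bd))
    if cfg.include_reduction_pathways:
        for acid, alcohol in reductions:
            m.add_reaction(Reaction(
                id=f"RED_{acid}", name=f"{acid} reduction to {alcohol}",
                stoichiometry={acid: -1.0, "red": -2.0, alcohol: 1.0, "h2o": 1.0},
                lower_bound=0.0, upper_bound=bd))
    _add_energy_and_growth(m, cfg, precursor="accoa", reductant="red")
    m.validate()
    return m


def make_toy_propionigen(cfg: ToyConfig | None = None) -> MetabolicModel:
    """Ethanol + CO2 propionigen (acrylate-pathway lump, 2 propionate :
    1 acetate) with H2-evolving ethanol oxidation."""
    cfg = cfg or ToyConfig()
    cfg.validate()
    bd = cfg.bounds_default
    m = _base_model("toy_propionigen", cfg,
                    ["etoh", "co2", "prop", "ac", "h2", "h2o", "nh3"])
    m.add_reaction(Reaction(
        id="ACR", name="acrylate pathway (lumped)",
        stoichiometry={"etoh": -3.0, "co2": -2.0, "adp": -cfg.atp_per_acrylate,
                       "prop": 2.0, "ac": 1.0, "h2o": 1.0,
                       "atp": cfg.atp_per_acrylate},
        lower_bound=0.0, upper_bound=bd))
    m.add_reaction(Reaction(
        id="OXE", name="ethanol oxidation",
        stoichiometry={"etoh": -1.0, "h2o": -1.0, "adp": -cfg.atp_per_oxidation,
                       "ac": 1.0, "h2": 2.0, "atp": cfg.atp_per_oxidation},
        lower_bound=0.0, upper_bound=bd))
    _add_energy_and_growth(m, cfg, precursor="ac", reductant="h2")
    m.validate()
    return m


def make_toy_chain_elongator(cfg: ToyConfig | None = None) -> MetabolicModel:
    """Ethanol-driven chain elongator: even (C4, C6) and odd (C5, C7)
    elongation cycles plus H2-evolving ethanol oxidation."""
    cfg = cfg or ToyConfig()
    cfg.validate()
    bd = cfg.bounds_default
    m = _base_model("toy_elongator", cfg,
                    ["etoh", "ac", "prop", "but", "val", "cap", "hep",
                     "h2", "h2o", "nh3"])
    cycles = [("ELC4", "ac", "but"), ("ELC6", "but", "cap"),
              ("ELC5", "prop", "val"), ("ELC7", "val", "hep")]
    for rid, donor, product in cycles:
        m.add_reaction(Reaction(
            id=rid, name=f"elongation {donor} -> {product}",
            stoichiometry={"etoh": -1.0, donor: -1.0,
                           "adp": -cfg.atp_per_elongation,
                           product: 1.0, "h2o": 1.0,
                           "atp": cfg.atp_per_elongation},
            lower_bound=0.0, upper_bound=bd))
    m.add_reaction(Reaction(
        id="OXE", name="ethanol oxidation",
        stoichiometry={"etoh": -1.0, "h2o": -1.0, "adp": -cfg.atp_per_oxidation,
                       "ac": 1.0, "h2": 2.0, "atp": cfg.atp_per_oxidation},
        lower_bound=0.0, upper_bound=bd))
    _add_energy_and_growth(m, cfg, precursor="ac", reductant="h2")
    m.validate()
    return m


def make_toy_triculture(
    cfg: ToyConfig | None = None,
    fractions: dict[str, float] | None = None,
) -> CommunityModel:
    """Tag, merge, and ratio-parametrize the three toy species into a
    community model with tags ``aw`` (acetogen), ``an`` (propionigen) and
    ``ck`` (chain elongator)."""
    cfg = cfg or ToyConfig()
    fractions = fractions or {"aw": 0.5, "an": 0.3, "ck": 0.2}
    from .community import _check_fractions

    _check_fractions(fractions)
    species = [
        SpeciesSpec(tag_species(make_toy_acetogen(cfg), "aw"), "aw",
                    fractions.get("aw", 0.0)),
        SpeciesSpec(tag_species(make_toy_propionigen(cfg), "an"), "an",
                    fractions.get("an", 0.0)),
        SpeciesSpec(tag_species(make_toy_chain_elongator(cfg), "ck"), "ck",
                    fractions.get("ck", 0.0)),
    ]
    cm = merge_models(species)
    # the community biomass reaction is the sole biomass drain
    for tag in cm.species:
        dm = cm.model.reactions.get(f"DM_biomass_{tag}")
        if dm is not None:
            dm.lower_bound = 0.0
            dm.upper_bound = 0.0
    return cm


def simulate_chemostat_observations(
    true_rates: dict[str, float],
    dilution_rate: float,
    volume: float,
    noise_sd: float,
    seed: int | None = None,
    n_obs: int = 20,
):
    """Steady-state chemostat concentration series for known production
    rates: c = rate / (D * V), perturbed with multiplicative Gaussian noise.

    Returns a list of :class:`~commgem.bioprocess.ChemostatRecord`, one per
    observation, suitable for :func:`~commgem.bioprocess.steady_state_rate`.
    """
    from .bioprocess import ChemostatRecord

    if dilution_rate <= 0 or volume <= 0:
        raise ValueError("dilution rate and volume must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_obs):
        conc = {
            compound: (rate / (dilution_rate * volume))
            * (1.0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            for compound, rate in true_rates.items()
        }
        records.append(
            ChemostatRecord(
                volume=volume,
                dilution_rate=dilution_rate,
                concentrations=conc,
            )
        )
    return records
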