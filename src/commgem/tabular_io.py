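"""Simple tabular model dialect: one JSON document or a TSV table pair.

The JSON form is a single document::

    {"id": ..., "extracellular_id": "e",
     "compartments": {"c": "cytosol", "e": "extracellular"},
     "metabolites": [{"id", "name", "formula", "charge", "compartment"}, ...],
     "reactions":   [{"id", "equation", "lower_bound", "upper_bound", ...}, ...],
     "objective_id": ..., "biomass_id": ..., "ngam_id": ...}

The TSV form is a directory containing ``metabolites.tsv``,
``reactions.tsv`` and ``model.json`` (header fields).  Reaction equations
use the conventional arrow syntax, e.g.::

    1 co_e + 1 h2o_aw -> 1 co2_aw + 2 fdred_aw
    co_e ->                      # exchange (export direction)
    a <-> b                      # reversibility is carried by the bounds
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import pandas as pd

from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    UNBOUNDED,
    format_formula,
    parse_formula,
)

__all__ = ["read_tabular", "write_tabular", "parse_equation", "format_equation", "EquationError"]


class EquationError(ValueError):
    pass


def parse_equation(text: str, known_metabolites=None) -> dict[str, float]:
    """Parse a reaction equation string into a stoichiometry mapping.

    ``known_metabolites`` (optional) is used to reject unknown ids early.
    """
    for arrow in ("<->", "<=>", "->", "=>"):
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise EquationError(f"no reaction arrow in equation {text!r}")

    stoich: dict[str, float] = {}

    def consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            tokens = term.split()
            if not tokens:
                raise EquationError(f"empty term in equation {text!r}")
            if len(tokens) == 1:
                coef, met = 1.0, tokens[0]
            elif len(tokens) == 2:
                try:
                    coef = float(tokens[0])
                except ValueError as exc:
                    raise EquationError(
                        f"bad coefficient {tokens[0]!r} in equation {text!r}"
                    ) from exc
                met = tokens[1]
            else:
                raise EquationError(f"unparseable term {term.strip()!r} in {text!r}")
            if known_metabolites is not None and met not in known_metabolites:
                raise EquationError(f"unknown metabolite id {met!r} in equation {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    consume(left, -1.0)
    consume(right, +1.0)
    if not stoich:
        raise EquationError(f"equation {text!r} has no metabolites")
    return {m: c for m, c in stoich.items() if c != 0.0} or stoich


def format_equation(stoich: dict[str, float], reversible: bool = False) -> str:
    def side(items):
        # repr keeps full double precision so round-trips are exact
        return " + ".join(f"{repr(abs(c))} {m}" for m, c in items)

    subs = [(m, c) for m, c in stoich.items() if c < 0]
    prods = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "extracellular_id": model.extracellular_id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": None if m.formula is None else format_formula(m.formula),
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry, r.reversible),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
            }
            for r in model.reactions.values()
        ],
        "objective_id": model.objective_id,
        "biomass_id": model.biomass_id,
        "ngam_id": model.ngam_id,
    }


def _clean(value):
    """Normalize pandas NaN and empty cells to None."""
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    return value


def _model_from_dict(doc: dict) -> MetabolicModel:
    model = MetabolicModel(
        id=doc.get("id", "model"),
        compartments=dict(doc.get("compartments", {})),
        extracellular_id=doc.get("extracellular_id", "e"),
    )
    for row in doc.get("metabolites", []):
        formula = _clean(row.get("formula"))
        if formula is None:
            parsed = None
        elif formula == "":
            parsed = {}
        else:
            parsed = parse_formula(str(formula))
        charge = _clean(row.get("charge"))
        model.add_metabolite(
            Metabolite(
                id=row["id"],
                name=_clean(row.get("name")) or "",
                formula=parsed,
                charge=None if charge is None else int(charge),
                compartment=row.get("compartment", "c"),
            )
        )
    for lineno, row in enumerate(doc.get("reactions", []), start=1):
        try:
            stoich = parse_equation(row["equation"], known_metabolites=model.metabolites)
        except EquationError as exc:
            raise EquationError(f"reaction entry {lineno} ({row.get('id')}): {exc}") from exc
        lb = _clean(row.get("lower_bound"))
        ub = _clean(row.get("upper_bound"))
        model.add_reaction(
            Reaction(
                id=row["id"],
                name=_clean(row.get("name")) or "",
                stoichiometry=stoich,
                lower_bound=-UNBOUNDED if lb is None else float(lb),
                upper_bound=UNBOUNDED if ub is None else float(ub),
                gene_rule=_clean(row.get("gene_rule")),
            )
        )
    model.objective_id = doc.get("objective_id")
    model.biomass_id = doc.get("biomass_id")
    model.ngam_id = doc.get("ngam_id")
    model.validate()
    return model


def write_tabular(model: MetabolicModel, path: str | os.PathLike) -> None:
    """Write the model as JSON (``*.json``) or a TSV directory otherwise."""
    path = Path(path)
    doc = _model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")
        return
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(doc["metabolites"]).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(doc["reactions"]).to_csv(path / "reactions.tsv", sep="\t", index=False)
    header = {k: doc[k] for k in ("id", "extracellular_id", "compartments",
                                  "objective_id", "biomass_id", "ngam_id")}
    (path / "model.json").write_text(json.dumps(header, indent=1) + "\n")


def read_tabular(path: str | os.PathLike) -> MetabolicModel:
    """Inverse of :func:`write_tabular`."""
    path = Path(path)
    if path.is_dir():
        header = json.loads((path / "model.json").read_text())
        mets = pd.read_csv(path / "metabolites.tsv", sep="\t").where(
            lambda df: df.notna(), None
        )
        rxns = pd.read_csv(path / "reactions.tsv", sep="\t").where(
            lambda df: df.notna(), None
        )
        doc = dict(header)
        doc["metabolites"] = mets.to_dict("records")
        doc["reactions"] = rxns.to_dict("records")
        return _model_from_dict(doc)
    return _model_from_dict(json.loads(Path(path).read_text()))
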