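"""Flux balance analysis: LP formulation, feasibility, and grid scans.

The linear program is the textbook one:

    max / min  c^T v
    s.t.       S v = 0
               lb <= v <= ub

solved with HiGHS through :func:`scipy.optimize.linprog`.  Solutions are
revalidated against the steady-state and bound constraints before being
returned; a numerical failure is reported as an explicit status, never a
silent zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .community import CommunityCondition, CommunityModel, apply_condition
from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "FeasibilityGrid",
    "solve_fba",
    "check_feasibility",
    "scan_feasibility",
    "FEASIBILITY_TOL",
]

FEASIBILITY_TOL = 1e-6

_STATUS = {0: "optimal", 1: "solver_failure", 2: "infeasible", 3: "unbounded", 4: "solver_failure"}


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | solver_failure
    objective_value: float | None
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
    tol: float = FEASIBILITY_TOL,
) -> FluxSolution:
    """Solve the FBA linear program for ``model``.

    ``objective_id`` defaults to the model's configured objective.  The
    returned solution is checked to satisfy ``S v = 0`` and the bounds
    within ``tol``; a violating solver answer is downgraded to
    ``solver_failure``.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None or objective_id not in model.reactions:
        raise ValueError(f"objective reaction {objective_id!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")

    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0 if direction == "max" else 1.0

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "solver_failure")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None, fluxes={})

    v = np.asarray(res.x)
    residual = np.abs(S @ v).max() if S.shape[0] else 0.0
    if residual > tol or np.any(v < lb - tol) or np.any(v > ub + tol):
        return FluxSolution(status="solver_failure", objective_value=None, fluxes={})
    obj = float(v[rxn_ids.index(objective_id)])
    return FluxSolution(
        status="optimal",
        objective_value=obj,
        fluxes=dict(zip(rxn_ids, map(float, v))),
    )


def check_feasibility(cm: CommunityModel, cond: CommunityCondition) -> bool:
    """True iff FBA on the condition-constrained community model reaches an
    optimum.  A solver failure propagates as an exception — it is a
    distinct outcome, not "infeasible"."""
    constrained = apply_condition(cm, cond)
    sol = solve_fba(constrained.model, objective_id=cond.objective_id)
    if sol.status == "solver_failure":
        raise RuntimeError("LP solver failed; feasibility undetermined")
    return sol.optimal


@dataclass
class FeasibilityGrid:
    ratio_combinations: list[dict[str, float]]
    growth_rates: list[float]
    feasible: np.ndarray  # bool, |combinations| x |growth rates|

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (ratio combination, mu) cell."""
        rows = []
        for i, combo in enumerate(self.ratio_combinations):
            for j, mu in enumerate(self.growth_rates):
                row = {f"fraction_{tag}": f for tag, f in combo.items()}
                row["growth_rate"] = mu
                row["feasible"] = bool(self.feasible[i, j])
                rows.append(row)
        return pd.DataFrame(rows)


def scan_feasibility(
    cm: CommunityModel,
    ratio_grid: list[dict[str, float]],
    mu_grid: list[float],
    total_biomass: float,
    exchange_bounds: dict[str, tuple[float, float]] | None = None,
) -> FeasibilityGrid:
    """Feasibility over the species-ratio x growth-rate grid at fixed total
    biomass and feed bounds (the heatmap-style scan)."""
    if not ratio_grid or not mu_grid:
        raise ValueError("ratio and growth-rate grids must be nonempty")
    feas = np.zeros((len(ratio_grid), len(mu_grid)), dtype=bool)
    for i, fractions in enumerate(ratio_grid):
        for j, mu in enumerate(mu_grid):
            cond = CommunityCondition(
                growth_rate=mu,
                total_biomass=total_biomass,
                fractions=fractions,
                exchange_bounds=dict(exchange_bounds or {}),
            )
            feas[i, j] = check_feasibility(cm, cond)
    return FeasibilityGrid(
        ratio_combinations=list(ratio_grid), growth_rates=list(mu_grid), feasible=feas
    )


def ratio_lattice(tags: list[str], step: float = 0.1, min_fraction: float = 0.1) -> list[dict[str, float]]:
    """All species-fraction combinations on a ``step`` lattice with every
    fraction in [min_fraction, 1] and summing to 1."""
    n_steps = round(1.0 / step)
    lo = round(min_fraction / step)
    combos = []

    def rec(prefix: list[int], remaining: int, k: int) -> None:
        if k == 1:
            if remaining >= lo:
                combos.append(prefix + [remaining])
            return
        for v in range(lo, remaining - lo * (k - 1) + 1):
            rec(prefix + [v], remaining - v, k - 1)

    rec([], n_steps, len(tags))
    return [
        {tag: v * step for tag, v in zip(tags, combo)} for combo in combos
    ]
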