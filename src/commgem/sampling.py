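"""Uniform sampling of the steady-state flux polytope.

Artificial-centering hit-and-run (ACHR) over ``{v : S v = 0, lb <= v <= ub}``.
Warm-up points are LP vertices obtained by optimizing randomized objectives
(plus per-reaction min/max for small models); chord directions are drawn
as (stored point - running center), which keeps every direction inside the
null space of S because all stored points satisfy the same equality system.
Every returned sample is revalidated against the constraints.

Single FBA optima of degenerate LPs are arbitrary among alternate optima;
flux-level statements in this package are therefore made on sampling means
and standard deviations, never on one LP solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .fba import FEASIBILITY_TOL, solve_fba
from .model import MetabolicModel

__all__ = ["SamplingResult", "sample_fluxes", "product_profile", "validate_samples"]

_DIR_TOL = 1e-9


@dataclass
class SamplingResult:
    samples: np.ndarray  # n_samples x n_reactions
    reaction_ids: list[str]
    seed: int | None
    n_kept: int
    thinning: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def column(self, rxn_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rxn_id)]


def _warmup_points(
    S, lb: np.ndarray, ub: np.ndarray, rng: np.random.Generator, n_rxns: int, n_random: int
) -> np.ndarray:
    """LP vertices spanning the polytope: per-coordinate min/max for small
    models plus randomized-objective vertices."""
    points = []
    bounds = np.column_stack([lb, ub])
    b_eq = np.zeros(S.shape[0])

    objectives = []
    if n_rxns <= 80:  # coordinate sweeps are cheap on toy-sized models
        for j in range(n_rxns):
            for sign in (+1.0, -1.0):
                c = np.zeros(n_rxns)
                c[j] = sign
                objectives.append(c)
    for _ in range(n_random):
        objectives.append(rng.standard_normal(n_rxns))

    for c in objectives:
        res = linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status == 0:
            points.append(np.asarray(res.x))
    if not points:
        raise RuntimeError("no warm-up vertices found; model is infeasible")
    return np.array(points)


def sample_fluxes(
    model: MetabolicModel,
    n: int,
    seed: int | None = None,
    thinning: int = 100,
    n_warmup_random: int = 20,
    tol: float = FEASIBILITY_TOL,
) -> SamplingResult:
    """Draw ``n`` (approximately uniform) flux vectors from the feasible
    polytope of ``model`` by artificial-centering hit-and-run.

    Deterministic for a given ``seed``; every returned row satisfies
    ``S v = 0`` and the flux bounds within ``tol`` (checked, not assumed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    check = solve_fba(model, objective_id=model.objective_id or next(iter(model.reactions)))
    if not check.optimal:
        raise RuntimeError(f"model is not feasible (status {check.status}); cannot sample")

    S, _mets, rxn_ids = model.stoichiometric_matrix()
    S = S.toarray()
    lb, ub = model.bounds_arrays()
    rng = np.random.default_rng(seed)
    n_rxns = len(rxn_ids)

    # The walk lives on the affine subspace {S v = 0, v_i = lb_i for every
    # bound-fixed coordinate}: its orthonormal basis N comes from the
    # augmented equality system, so chord directions automatically vanish
    # on fixed fluxes and rounding noise outside the subspace is projected
    # away before it can be amplified by normalization.
    from scipy.linalg import lstsq, null_space

    fixed = ub - lb <= _DIR_TOL
    A = np.vstack([S, np.eye(n_rxns)[fixed]]) if fixed.any() else S
    b = np.concatenate([np.zeros(S.shape[0]), lb[fixed]])

    warmup = _warmup_points(S, lb, ub, rng, n_rxns, n_warmup_random)
    # anchor point satisfying A x = b to machine precision
    anchor = warmup[0] - lstsq(A, A @ warmup[0] - b)[0]

    N = null_space(A)

    def to_subspace(vec: np.ndarray) -> np.ndarray:
        return anchor + N @ (N.T @ (vec - anchor)) if N.size else anchor.copy()

    if N.size == 0:
        # fully determined system: the polytope is the single point `anchor`
        samples = np.tile(anchor, (n, 1))
        validate_samples(samples, S, lb, ub, tol=tol)
        return SamplingResult(
            samples=samples, reaction_ids=rxn_ids, seed=seed, n_kept=n, thinning=thinning
        )

    warmup = np.array([to_subspace(w) for w in warmup])
    pool = list(warmup)
    center = warmup.mean(axis=0)
    x = center.copy()
    n_total_steps = 0

    samples = np.empty((n, n_rxns))
    kept = 0
    while kept < n:
        ref = pool[rng.integers(len(pool))]
        d = N @ (N.T @ (ref - center))
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            # degenerate chord (all points coincide); polytope is a point
            samples[kept] = x
            kept += 1
            continue
        d = d / norm
        active = np.abs(d) > _DIR_TOL
        if not np.any(active):
            samples[kept] = x
            kept += 1
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lb[active] - x[active]) / d[active]
            t_hi = (ub[active] - x[active]) / d[active]
        t_min = np.minimum(t_lo, t_hi).max()
        t_max = np.maximum(t_lo, t_hi).min()
        if t_max < t_min:  # numerically stuck at a face; re-center
            x = center.copy()
            continue
        theta = rng.uniform(t_min, t_max)
        x = x + theta * d
        n_total_steps += 1
        if n_total_steps % 256 == 0:  # guard against slow rounding drift
            x = to_subspace(x)
        center = center + (x - center) / (len(pool) + n_total_steps)
        if n_total_steps % thinning == 0:
            samples[kept] = x
            pool.append(x.copy())
            kept += 1

    validate_samples(samples, S, lb, ub, tol=tol)
    return SamplingResult(
        samples=samples, reaction_ids=rxn_ids, seed=seed, n_kept=kept, thinning=thinning
    )


def validate_samples(samples: np.ndarray, S, lb, ub, tol: float = FEASIBILITY_TOL) -> None:
    """Raise if any sample violates steady state or bounds beyond ``tol``."""
    residual = np.abs(samples @ S.T).max() if S.shape[0] else 0.0
    if residual > tol:
        raise RuntimeError(f"sample steady-state residual {residual:.2e} exceeds {tol}")
    if np.any(samples < lb - tol) or np.any(samples > ub + tol):
        raise RuntimeError("sample violates flux bounds")


def product_profile(
    sr: SamplingResult, exchange_ids: list[str] | dict[str, str]
) -> pd.DataFrame:
    """Mean +/- sd of exchange fluxes over the samples.

    ``exchange_ids`` is either a list of exchange reaction ids or a mapping
    ``label -> reaction id``.  Sign convention is production-positive
    (exchanges are written ``met_e ->``, so positive flux is export).
    """
    if isinstance(exchange_ids, dict):
        items = list(exchange_ids.items())
    else:
        items = [(rid, rid) for rid in exchange_ids]
    rows = []
    for label, rid in items:
        if rid not in sr.reaction_ids:
            raise KeyError(f"unknown exchange reaction {rid!r}")
        col = sr.column(rid)
        rows.append(
            {
                "product": label,
                "reaction": rid,
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                "n": len(col),
            }
        )
    return pd.DataFrame(rows)
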