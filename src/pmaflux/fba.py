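"""Flux balance analysis: maximize a linear objective over S·v = 0 with box bounds.

The production solver is linear programming (HiGHS via scipy); for small
networks the module also provides an independent brute-force oracle that
enumerates the vertices of the flux polytope, used to cross-check the LP
path.  Only the optimal objective value is contractually unique — flux
vectors at degenerate optima are returned as found, flagged with
``degenerate_warning``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .model_core import FluxSolution, MetabolicModel

__all__ = ["FbaProblem", "solve_fba", "fix_flux", "set_bounds", "brute_force_optimum"]

#: feasibility tolerance on S·v = 0 and bounds (relative to largest coefficient)
FEASIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class FbaProblem:
    """An FBA instance: model + objective + optional bound overrides.

    ``extra_constraints`` maps reaction id to a ``(lower, upper)`` pair that
    *replaces* the model's declared bounds for that reaction (replacement, not
    intersection, is the documented behavior — a route scan fixes fluxes to
    values that may lie outside a reaction's default range).
    """

    model: MetabolicModel
    objective_id: str | None = None
    sense: str = "maximize"
    extra_constraints: tuple[tuple[str, tuple[float, float]], ...] = ()

    def resolved_objective(self) -> str:
        return self.objective_id or self.model.objective_id

    def bounds_for(self, rxn_id: str) -> tuple[float, float]:
        overrides = dict(self.extra_constraints)
        if rxn_id in overrides:
            return overrides[rxn_id]
        rxn = self.model.reaction(rxn_id)
        return (rxn.lower_bound, rxn.upper_bound)


def _check_override_ids(problem: FbaProblem) -> None:
    for rxn_id, _ in problem.extra_constraints:
        if not problem.model.has_reaction(rxn_id):
            raise KeyError(f"override references unknown reaction {rxn_id!r}")


def fix_flux(problem: FbaProblem, rxn_id: str, value: float) -> FbaProblem:
    """Return a new problem with ``rxn_id`` fixed to ``value`` (lb = ub = value).

    The original problem is unchanged; an existing override for the same
    reaction is replaced.
    """
    if not problem.model.has_reaction(rxn_id):
        raise KeyError(f"cannot fix unknown reaction {rxn_id!r}")
    kept = tuple((r, b) for r, b in problem.extra_constraints if r != rxn_id)
    return replace(
        problem, extra_constraints=kept + ((rxn_id, (float(value), float(value))),)
    )


def set_bounds(problem: FbaProblem, rxn_id: str, lower: float, upper: float) -> FbaProblem:
    """Return a new problem with the bounds of ``rxn_id`` replaced by
    ``(lower, upper)``."""
    if not problem.model.has_reaction(rxn_id):
        raise KeyError(f"cannot bound unknown reaction {rxn_id!r}")
    if lower > upper:
        raise ValueError(f"bounds for {rxn_id!r} inverted: {lower} > {upper}")
    kept = tuple((r, b) for r, b in problem.extra_constraints if r != rxn_id)
    return replace(
        problem, extra_constraints=kept + ((rxn_id, (float(lower), float(upper))),)
    )


def solve_fba(problem: FbaProblem) -> FluxSolution:
    """Solve the linear program and report status faithfully.

    On ``optimal``, S·v = 0 and all bounds hold to :data:`FEASIBILITY_TOL`
    (relative to the largest stoichiometric coefficient) and
    ``objective_value`` equals the flux of the objective reaction.
    """
    _check_override_ids(problem)
    model = problem.model
    if not model.reactions:
        return FluxSolution(status="optimal", objective_value=0.0, fluxes={})
    objective = problem.resolved_objective()
    if not model.has_reaction(objective):
        raise KeyError(f"objective reaction {objective!r} not in model")
    if problem.sense not in ("maximize", "minimize"):
        raise ValueError(f"unknown sense {problem.sense!r}")

    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = -1.0 if problem.sense == "maximize" else 1.0
    bounds = [problem.bounds_for(r) for r in rxn_ids]
    for (lo, hi), rid in zip(bounds, rxn_ids):
        if lo > hi:
            raise ValueError(f"bounds for {rid!r} inverted: {lo} > {hi}")

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=None, fluxes={})
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=None, fluxes={})
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")

    fluxes = dict(zip(rxn_ids, map(float, res.x)))
    obj = fluxes[objective]
    # degeneracy heuristic: more basic-like (strictly interior) variables than
    # equality constraints implies alternate optima may exist
    interior = sum(
        1
        for (lo, hi), v in zip(bounds, res.x)
        if v - lo > 1e-7 and hi - v > 1e-7
    )
    return FluxSolution(
        status="optimal",
        objective_value=obj,
        fluxes=fluxes,
        degenerate_warning=bool(interior > np.linalg.matrix_rank(S)),
    )


# ---------------------------------------------------------------------------
# brute-force oracle (independent of the LP path)


def brute_force_optimum(problem: FbaProblem) -> float | None:
    """Optimal objective value by enumerating vertices of the flux polytope.

    Exhaustive and exponential — intended for networks of at most ~8
    reactions as an independent check on :func:`solve_fba`.  Returns ``None``
    when no feasible vertex exists (with finite bounds and 0 inside the box
    the polytope is never empty, so ``None`` signals a genuinely infeasible
    instance, e.g. after overrides exclude 0).
    """
    _check_override_ids(problem)
    model = problem.model
    if not model.reactions:
        return 0.0
    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    if n > 12:
        raise ValueError("brute-force oracle is restricted to small networks")
    objective = problem.resolved_objective()
    j_obj = rxn_ids.index(objective)
    lo = np.array([problem.bounds_for(r)[0] for r in rxn_ids])
    hi = np.array([problem.bounds_for(r)[1] for r in rxn_ids])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("oracle requires finite bounds")

    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_free = n - rank
    sign = 1.0 if problem.sense == "maximize" else -1.0
    tol = 1e-7 * max(1.0, np.max(np.abs(np.concatenate([lo, hi]))))

    best: float | None = None

    def consider(v: np.ndarray) -> None:
        nonlocal best
        if np.any(v < lo - tol) or np.any(v > hi + tol):
            return
        if S.size and np.max(np.abs(S @ v)) > tol:
            return
        val = sign * v[j_obj]
        if best is None or val > best:
            best = val

    # a vertex has at least n_free coordinates at a bound; enumerate every
    # choice of fixed set and bound side, solve the rest by least squares
    for fixed in itertools.combinations(range(n), n_free):
        fixed_l = list(fixed)
        free = [j for j in range(n) if j not in fixed]
        for sides in itertools.product((0, 1), repeat=n_free):
            v = np.zeros(n)
            for j, s in zip(fixed_l, sides):
                v[j] = lo[j] if s == 0 else hi[j]
            if free:
                A = S[:, free]
                b = -S[:, fixed_l] @ v[fixed_l] if fixed_l else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            consider(v)
    # the origin-like interior point (all-zero flux) is a safety net for
    # degenerate rank cases
    consider(np.zeros(n))
    if best is None:
        return None
    return sign * best  # undo sign flip: return actual objective value
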