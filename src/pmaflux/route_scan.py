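"""Robustness scan of malate-synthesis routes for polymalate production.

The in-silico experiment: three routes can supply the cytosolic malate that
polymalic acid (PMA) synthesis consumes —

* **oxidative TCA**: the classical cycle through oxoglutarate dehydrogenase,
  aconitate hydratase, fumarase, succinate dehydrogenase and succinate-CoA
  ligase;
* **reductive TCA**: CO2-fixing pyruvate carboxylase followed by cytosolic
  malate dehydrogenase (the constrained reaction);
* **glyoxylate shunt**: isocitrate lyase + malate synthase (with fumarase).

For one route at a time, every reaction of that route is fixed to a common
imposed flux, the reactions of the other two routes are fixed to 0 (a
reaction shared with the scanned route keeps the scanned value), the
mitochondrial malate dehydrogenase is fixed to 0, growth is fixed per grid
point, and the PMA synthesis rate is maximized by FBA.  The resulting
(route flux × growth) surface shows how much PMA each route can sustain and
where it collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import FbaProblem, fix_flux, set_bounds, solve_fba
from .model_core import MetabolicModel

__all__ = [
    "RouteDefinition",
    "ScanGrid",
    "ScanSummary",
    "RouteSummary",
    "ROUTES",
    "apply_route_constraints",
    "scan_surface",
    "summarize",
    "INFEASIBLE",
]

#: marker for scan cells with no feasible flux state (distinct from PMA = 0)
INFEASIBLE = float("nan")

#: default uptake bounds, mmol/gDW/h (sucrose at the hexose equivalent of
#: glucose 10)
SUBSTRATE_UPTAKE = {"glucose": 10.0, "sucrose": 5.0}

_SUBSTRATE_EXCHANGE = {"glucose": "EX_glc", "sucrose": "EX_suc"}

#: reaction always silenced during scans: the mitochondrial malate
#: dehydrogenase (the reductive branch is taken to be purely cytosolic)
MDH_MITOCHONDRIAL = "MDH_m"

_BIOMASS_REACTION = "BIOMASS"


@dataclass(frozen=True)
class RouteDefinition:
    """A named malate-synthesis route and the reaction ids it constrains."""

    name: str
    constrained_reaction_ids: tuple[str, ...]

    def validate_against(self, model: MetabolicModel) -> None:
        for rid in self.constrained_reaction_ids:
            if not model.has_reaction(rid):
                raise KeyError(
                    f"route {self.name!r}: reaction {rid!r} missing from model"
                )


#: the three packaged route definitions (reaction ids of the packaged model)
ROUTES: dict[str, RouteDefinition] = {
    "oxidative_tca": RouteDefinition(
        "oxidative_tca", ("AKGDH", "ACO_m", "FUM_m", "SDH", "SCS")
    ),
    "reductive_tca": RouteDefinition("reductive_tca", ("MDH_c",)),
    "glyoxylate_shunt": RouteDefinition(
        "glyoxylate_shunt", ("FUM_m", "ICL", "MAS")
    ),
}


@dataclass
class ScanGrid:
    """Optimal PMA synthesis rate over (imposed route flux × imposed growth)."""

    route: RouteDefinition
    route_flux_values: np.ndarray
    growth_values: np.ndarray
    pma_optimum: np.ndarray  # shape (n_flux, n_growth); NaN = infeasible
    carbon_source: str

    def __post_init__(self) -> None:
        self.route_flux_values = np.asarray(self.route_flux_values, dtype=float)
        self.growth_values = np.asarray(self.growth_values, dtype=float)
        self.pma_optimum = np.asarray(self.pma_optimum, dtype=float)
        expected = (len(self.route_flux_values), len(self.growth_values))
        if self.pma_optimum.shape != expected:
            raise ValueError(
                f"grid shape {self.pma_optimum.shape} does not match "
                f"axes {expected}"
            )

    def column_optimum(self) -> np.ndarray:
        """Best PMA over growth for each route flux (NaN where no cell is
        feasible)."""
        with np.errstate(all="ignore"):
            out = np.full(len(self.route_flux_values), np.nan)
            any_finite = np.isfinite(self.pma_optimum).any(axis=1)
            out[any_finite] = np.nanmax(self.pma_optimum[any_finite], axis=1)
        return out


@dataclass(frozen=True)
class RouteSummary:
    route_name: str
    optimum: float
    argmax_flux: float
    cutoff_flux: float | None
    optimum_at_zero_growth: float


@dataclass
class ScanSummary:
    per_route: dict[str, RouteSummary] = field(default_factory=dict)


def apply_route_constraints(
    model: MetabolicModel,
    route: RouteDefinition,
    route_flux: float,
    growth: float,
    carbon_source: str = "glucose",
    routes: dict[str, RouteDefinition] | None = None,
) -> FbaProblem:
    """Build the FBA problem for one scan cell.

    Every reaction of the scanned route is fixed to ``route_flux``; every
    reaction of the other two routes is fixed to 0 unless it is shared with
    the scanned route, in which case the scanned constraint wins.  The
    mitochondrial malate dehydrogenase is fixed to 0, the biomass flux to
    ``growth``, and the substrate exchange opened at its documented uptake
    rate (all other substrate exchanges closed).  The objective is PMA
    synthesis, maximized.
    """
    if route_flux < 0 or growth < 0:
        raise ValueError("route_flux and growth must be non-negative")
    if carbon_source not in _SUBSTRATE_EXCHANGE:
        raise KeyError(f"unknown carbon source {carbon_source!r}")
    routes = routes if routes is not None else ROUTES
    route.validate_against(model)
    for other in routes.values():
        other.validate_against(model)

    problem = FbaProblem(model=model, objective_id=model.objective_id,
                         sense="maximize")
    scanned = set(route.constrained_reaction_ids)
    for other in routes.values():
        if other.name == route.name:
            continue
        for rid in other.constrained_reaction_ids:
            if rid not in scanned:  # scanned constraint wins on shared reactions
                problem = fix_flux(problem, rid, 0.0)
    for rid in route.constrained_reaction_ids:
        problem = fix_flux(problem, rid, float(route_flux))
    if model.has_reaction(MDH_MITOCHONDRIAL) and MDH_MITOCHONDRIAL not in scanned:
        problem = fix_flux(problem, MDH_MITOCHONDRIAL, 0.0)
    if model.has_reaction(_BIOMASS_REACTION):
        problem = fix_flux(problem, _BIOMASS_REACTION, float(growth))
    # substrate entry: open the requested source, close the others
    for source, exchange in _SUBSTRATE_EXCHANGE.items():
        if not model.has_reaction(exchange):
            if source == carbon_source:
                raise KeyError(
                    f"carbon source {carbon_source!r}: exchange {exchange!r} "
                    "missing from model"
                )
            continue
        if source == carbon_source:
            problem = set_bounds(problem, exchange, -SUBSTRATE_UPTAKE[source], 0.0)
        else:
            problem = set_bounds(problem, exchange, 0.0, 0.0)
    return problem


def scan_surface(
    model: MetabolicModel,
    route: RouteDefinition,
    flux_max: float = 140.0,
    flux_steps: int = 71,
    growth_max: float = 1.0,
    growth_steps: int = 21,
    carbon_source: str = "glucose",
    routes: dict[str, RouteDefinition] | None = None,
) -> ScanGrid:
    """Populate the full (route flux × growth) surface for one route.

    Deterministic for a fixed model and grid.  Infeasible cells carry the
    NaN marker, never 0.
    """
    if flux_steps < 2 or growth_steps < 2:
        raise ValueError("need at least 2 steps on each axis")
    flux_values = np.linspace(0.0, flux_max, flux_steps)
    growth_values = np.linspace(0.0, growth_max, growth_steps)
    grid = np.full((flux_steps, growth_steps), np.nan)
    for i, v in enumerate(flux_values):
        for j, g in enumerate(growth_values):
            try:
                problem = apply_route_constraints(
                    model, route, v, g, carbon_source, routes=routes
                )
                solution = solve_fba(problem)
            except Exception as exc:
                raise RuntimeError(
                    f"scan aborted at route_flux={v}, growth={g}: {exc}"
                ) from exc
            if solution.optimal:
                grid[i, j] = max(solution.objective_value, 0.0)
    return ScanGrid(
        route=route,
        route_flux_values=flux_values,
        growth_values=growth_values,
        pma_optimum=grid,
        carbon_source=carbon_source,
    )


def summarize(grids: list[ScanGrid], zero_tol: float = 1e-9) -> ScanSummary:
    """Per-route optimum, arg-max flux and cutoff flux, read off the grids.

    The arg-max breaks ties toward the smallest flux.  The cutoff is the
    smallest scanned flux at or above the arg-max whose best-over-growth
    optimum is 0 (within ``zero_tol``) or infeasible; ``None`` if the route
    never collapses inside the scanned range.
    """
    if not grids:
        raise ValueError("summarize needs at least one grid")
    summary = ScanSummary()
    for grid in grids:
        col = grid.column_optimum()
        finite = np.isfinite(col)
        if not finite.any():
            raise ValueError(
                f"route {grid.route.name!r}: every scanned cell is infeasible"
            )
        best = float(np.nanmax(col))
        argmax_idx = int(np.nanargmax(np.where(finite, col, -np.inf)))
        argmax_flux = float(grid.route_flux_values[argmax_idx])
        cutoff: float | None = None
        for idx in range(argmax_idx, len(col)):
            if not finite[idx] or col[idx] <= zero_tol:
                cutoff = float(grid.route_flux_values[idx])
                break
        zero_col = grid.pma_optimum[:, np.argmin(np.abs(grid.growth_values))]
        zero_growth_opt = (
            float(np.nanmax(zero_col)) if np.isfinite(zero_col).any() else 0.0
        )
        summary.per_route[grid.route.name] = RouteSummary(
            route_name=grid.route.name,
            optimum=best,
            argmax_flux=argmax_flux,
            cutoff_flux=cutoff,
            optimum_at_zero_growth=zero_growth_opt,
        )
    return summary
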