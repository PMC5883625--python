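"""Scan the three malate-synthesis routes of the packaged reduced model.

For each route the scan fixes the route's reactions to an imposed flux,
silences the other two routes and the mitochondrial malate dehydrogenase,
fixes growth per grid point, and maximizes the polymalate synthesis rate.
The summary shows which route sustains the highest PMA flux and where each
route collapses.
"""

from pmaflux.model_core import build_reduced_model
from pmaflux.route_scan import ROUTES, scan_surface, summarize

model = build_reduced_model()
grids = [
    scan_surface(model, route, flux_max=60, flux_steps=31, growth_steps=11)
    for route in ROUTES.values()
]
summary = summarize(grids)

print("route              optimum  arg-max  cutoff   (mmol/gDW/h)")
for name, rs in summary.per_route.items():
    print(f"{name:18s} {rs.optimum:7.2f} {rs.argmax_flux:8.1f} "
          f"{rs.cutoff_flux:7.1f}")
print()
print("The reductive route (pyruvate carboxylase + cytosolic MDH) reaches the")
print("highest PMA optimum and tolerates by far the largest imposed flux")
print("before PMA collapses; the oxidative TCA and glyoxylate routes collapse")
print("at the same, much smaller flux — the qualitative signature that makes")
print("pyruvate carboxylase the engineering target.")
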