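"""Fermentation quantitation: residue-mass conversion and endpoint metrics.

Reproduces the published arithmetic for a fed-batch run (94.2 g/L malic acid
in 140 h) and summarizes a synthetic noise-free batch time course.
"""

from pmaflux.fermentation import (
    percent_change,
    pma_from_ma,
    productivity,
    residue_mass_ratio,
    round_half_up,
    summarize_run,
)
from pmaflux.synth import TimecourseSpec, gen_timecourse

factor = residue_mass_ratio()
print(f"residue mass ratio  : {factor:.5f} (rounds to {round_half_up(factor, 2)})")
print(f"94.2 g/L MA as PMA  : {round_half_up(pma_from_ma(94.2, factor), 1)} g/L")
print(f"fed-batch prod.     : {round_half_up(productivity(94.2, 140), 2)} g/L/h")
print(f"sucrose vs glucose  : +{round_half_up(percent_change(33.91, 24.10), 1)} %")
print()

records = gen_timecourse(TimecourseSpec(noise_sd=0.0, yield_biomass_g_g=None,
                                        yield_product_g_g=0.62))
summary = summarize_run(records)
print("synthetic batch (planted product yield 0.62 g/g):")
print(f"  final MA {summary.final_ma_g_L:.2f} g/L in {summary.elapsed_h:.0f} h, "
      f"productivity {summary.productivity_g_L_h:.3f} g/L/h, "
      f"yield {summary.yield_g_g:.2f} g/g")
print()
print("The recovered yield equals the planted coefficient exactly because the")
print("generator draws substrate down by product/yield and noise is off.")
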