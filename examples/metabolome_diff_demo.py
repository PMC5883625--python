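"""Differential analysis of a synthetic sucrose-vs-glucose metabolome.

Generates a 2-condition × 2-timepoint × 6-replicate table of 81 metabolites
with 24 planted two-fold effects, then runs the full pipeline: internal-
standard normalization, log-scale t tests with BH-FDR, PLS-DA VIP scores,
and the triple selection rule (p < 0.05, VIP > 1, q ≤ 0.05).
"""

from pmaflux.metabolomics import run_differential_analysis
from pmaflux.synth import MetabolomeSpec, gen_metabolome

spec = MetabolomeSpec(seed=7).with_planted(24, 2.0)
table, truth = gen_metabolome(spec)
result = run_differential_analysis(table, control_group="glucose_48",
                                   treated_group="sucrose_48")

planted = set(truth[truth.group == "sucrose_48"].metabolite)
selected = set(result.table.index[result.table.selected])
print(f"{result.n_selected} of {len(result.table)} metabolites selected; "
      f"{len(selected & planted)} of {len(planted)} planted effects recovered, "
      f"{len(selected - planted)} false positives")
print()
top = result.table[result.table.selected].sort_values("q_value").head(5)
print(top[["fold_change_log2", "t_statistic", "q_value", "vip"]].round(3))
print()
print("A selected metabolite passes all three criteria at once; the log2 fold")
print("changes of the recovered metabolites cluster near the planted ±2.")
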