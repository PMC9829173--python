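"""Parameter sensitivity of population suppression.

Varies one parameter at a time around the baseline (all others fixed)
under the low- and high-EJR scenarios and reports the minimum relative
population size, the summary used throughout the sensitivity analysis.
"""

from doubledrive import parameter_sensitivity_scan

for scenario in ("low", "high"):
    table = parameter_sensitivity_scan("epsilon_edit", [0.0, 0.5, 0.8, 0.9, 0.95],
                                       ejr_scenario=scenario)
    print(f"-- editing efficiency, {scenario} EJR")
    for _, r in table.iterrows():
        print(f"   eps_edit={r['value']:<5g} min relative F = {r['min_relative_F']:.3e}")

table = parameter_sensitivity_scan("r_x", [0.0, 0.25, 0.5], "low")
print("-- X-locus recombination fraction (no effect under dominant lethality)")
for _, r in table.iterrows():
    print(f"   r_x={r['value']:<5g} min relative F = {r['min_relative_F']:.3e}")

# Editing efficiency is the most stringent requirement (high-EJR species
# need roughly >80% for strong suppression); with zero editing the
# X-shredder alone yields only mild suppression.  Recombination between
# the two X-linked target loci is irrelevant because a single edited
# allele is already lethal in females.
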