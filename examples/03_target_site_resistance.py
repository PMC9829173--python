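"""Functional target-site resistance at the three cut sites.

Sweeps the probability that a cleavage event creates a functional
resistant allele at the homing, shredding or editing site, and reports
the minimum population size reached over the run.  The homing sweep
varies the end-joining rate itself (at a neutral insertion site every
end-joined allele is functionally resistant).
"""

from doubledrive import resistance_probability_sweep

for site, grid in [
    ("homing", [0.05, 0.30, 0.60, 0.75]),
    ("shredding", [0.0, 0.05, 0.30]),
    ("editing", [0.0, 0.001, 0.01, 0.05]),
]:
    table = resistance_probability_sweep(site, grid, "low")
    print(f"-- {site} site")
    for _, r in table.iterrows():
        print(f"   P(resistance)={r['probability']:<6g} min relative F = {r['min_relative_F']:.3e}")

# Suppression tolerates high end-joining rates at the homing site and
# moderate shredding resistance, but is most sensitive to resistance at
# the editing site: the editor, not the distorter, carries the load, so
# even editing-resistance probabilities of order 1e-3 raise the
# population minimum by orders of magnitude.
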