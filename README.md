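# doubledrive

Deterministic population-genetic and population-dynamic modelling of a
**Y-linked editor (YLE) + autosomal sex distorter (ASD) "double drive"**
for genetic pest-population suppression, together with a
**PAM-polymorphism screen** for restricting such a drive to a target
population by exploiting standing sequence differences.

## The system

Two CRISPR constructs are released in the same (or different) males:

* **YLE** — on the Y chromosome: a germline-expressed Cas9 and a
  ubiquitous gRNA that edit a target gene on the X chromosome, so that
  daughters inheriting the edited X die (dominant lethality, baseline
  `s = h = 1`). Because the Y never passes through those females, the
  editor is shielded from the cost it imposes.
* **ASD** — on an autosome: an X-shredder nuclease expressed during male
  meiosis (destroying a fraction `epsilon_shred` of X-bearing sperm, so
  carrier males sire mostly sons) plus a ubiquitous gRNA targeting the
  construct's own insertion site, so that in males that also carry the
  Y-linked Cas9 the ASD **homes** into the wildtype homologue.

Each construct boosts the other's transmission — the shredder drives the
Y it sits with, and the Cas9 lets the ASD home — so both can spread from
arbitrarily small releases (no invasion threshold), unlike the
self-limiting designs they extend.

The model is an exact discrete-generation genotype-frequency recursion.
Allele classes track per-component loss of function (Cas9, edit-gRNA,
shredder, homing-gRNA) and functional cleavage resistance at all three
cut sites, giving 441 female and 630 male genotype classes. Ecology is
Beverton–Holt: each female produces `2*R_m` juveniles, density-dependent
juvenile survival `1/(1 + gamma*J)` with `gamma = (R_m-1)/(2*R_m)` fixes
the wildtype equilibrium at `F = 1`, and genotype viability (edited-female
lethality, unintended costs) applies after density dependence, before
censusing. The reproductive load is
`L = 1 - (surviving daughters per female at low density) / R_m`.

Pre-existing cleavage-resistant alleles at the homing (or shredding) site
suppress the drive's ability to take off; because the outcome is
exquisitely sensitive to that standing frequency, a drive can be aimed at
populations where the cleavable sequence is common and spare those where
it is rare. The `pam` module implements the corresponding genomic
screen: find polymorphic GG/CC dinucleotides (Cas9 NGG PAMs) in a
reference, compute per-population intact-PAM frequencies from a VCF
(dropping sites with >5% missing data in any population), count sites
passing target/non-target frequency thresholds in both directions, and
report Hudson F_ST per population pair.

## Worked example

```python
from doubledrive import Params, run_timecourse, summarize

tc = run_timecourse(Params.idealised(), generations=100)
s = summarize(tc)
print(f"max load {s['max_load']:.4f}, "
      f"min F {s['min_relative_F']:.2e} at generation {s['generation_of_min']}")
```

prints

```
max load 0.9903, min F 2.99e-103 at generation 100
```

i.e. after a combined release of heterozygous males equal to 0.1% of the
adult population, the reproductive load climbs to 0.99 (females produce
1% of the offspring a wildtype population would) and the female
population collapses — below 1% of its pre-release size within about 18
generations. `examples/` contains one short script per capability:
idealised release, loss-of-function dynamics, target-site resistance
sweeps, parameter sensitivity, standing-resistance restriction windows,
the synthetic PAM screen, and the stochastic individual-based
cross-check. Scenario tables are plain pandas DataFrames;
`doubledrive.io` reads flat key=value parameter files and round-trips
timecourses through CSV.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities of the analysis from scratch by
running the model: the idealised maximum load; the population minimum
under 5% editing resistance; the minima under 84% and 87% standing
homing-site resistance (low end-joining scenario); and the
population-restriction window edges on a 1% standing-frequency grid (the
largest frequencies compatible with 99% suppression within 50 generations
under the low- and high-EJR scenarios, and the smallest frequency leaving
the population at least 95% intact under high EJR). The model is fully
deterministic; `--seed` only feeds the synthetic-fixture machinery.

## Scope notes

The model is non-spatial with non-overlapping generations; landscape
dynamics, chasing/recolonisation and finite-population extensions (beyond
the verification oracle in `doubledrive.fixtures`) are out of scope, as
is re-deriving published mosquito population-resequencing results — the
PAM screen runs on any reference+VCF input, and the package generates
synthetic multi-population datasets for testing.
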