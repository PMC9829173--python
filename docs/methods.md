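# Methods

## State space

Alleles are enumerated with per-component functionality:

* **Y** (5 classes): wildtype, or editor construct with Cas9 and
  edit-gRNA each functional/nonfunctional.
* **X haplotype** (6): shred target {susceptible, resistant} × edit
  target {wildtype, edited, resistant}; the two loci are distinct sites
  with recombination fraction `r_x` in females (default 0.5).
* **Autosome** (6): wildtype (the only allele cleavable for homing),
  resistant (cleavage-proof, wildtype fitness), or sex-distorter
  construct with shredder and homing-gRNA each functional/nonfunctional.

Chromosome pairs are unordered (no imprinting or parental deposition), so
females occupy 21×21 = 441 classes (X pairs × autosome pairs) and males
6×5×21 = 630 (X × Y × autosome pair).

## Gametogenesis (males)

Processes apply in germline order; all are exact branch enumerations, so
returned distributions are analytic, not sampled.

1. **Editing** (pre-meiotic, diploid germline): requires functional Cas9
   *and* edit-gRNA and a wildtype edit target. The X is attacked with
   probability `epsilon_edit` (0.95); an attack yields the edited allele
   with probability `1 − rho_edit_res`, else a functional resistant
   allele.
2. **Homing** (pre-meiotic): only in {wildtype, construct} heterozygotes
   whose construct carries a functional homing-gRNA and whose Y carries
   functional Cas9. Cleavage with probability `cleave_home` (0.95)
   resolves to end-joining (probability `ejr`; 0.05 low scenario, 0.60
   high), producing a functional resistant allele — the insertion site is
   neutral — or to a copy of the template construct whose components each
   acquire loss-of-function with probability `mu_homing` (1e-3).
3. **Meiosis**: sex chromosome and autosome assort independently.
4. **Shredding** (meiotic, in trans): if either autosomal allele carries
   a functional shredder, every X-bearing product with a susceptible
   shred target is destroyed with probability
   `epsilon_shred·(1 − rho_shred_res)` (0.9 baseline) or converted to a
   retained shred-resistant haplotype with `epsilon_shred·rho_shred_res`.
   No dose effect: one functional copy attacks all X products.
5. The gamete pool renormalises to mass 1 (sperm are not limiting), then
   **background mutation** flips each transmitted functional component
   with probability `mu_background` (1e-6).

Females perform only recombination, Mendelian segregation and background
mutation. Two structural consequences are tested as invariants: homing
is impossible without Cas9, a wildtype target and a functional gRNA; and
shredding never alters the autosomal marginal among a male's gametes.

## Population dynamics

Random mating with all females mated makes the juvenile genotype
distribution the outer product of the population egg pool and sperm pool
(frequency-weighted means of per-genotype gamete distributions); the
sperm class (X- or Y-bearing, post-shredding) sets offspring sex. Each
female produces `2·R_m` juveniles (`R_m` = 6 daughters per female at low
density; alternatives 2 and 12 supported). Density-dependent juvenile
survival is Beverton–Holt, `sigma = 1/(1 + gamma·J)` on total juveniles
`J`, with `gamma = (R_m − 1)/(2·R_m)` chosen so the wildtype equilibrium
is `F = M = 1`; a wildtype population then follows
`F' = R_m·F/(1 + (R_m − 1)·F)` exactly. Viability — dominant edited-
allele lethality in females and the six unintended cost multipliers —
applies after density dependence and before censusing, matching the
stated timing for edited-female mortality. All adults compete equally as
juveniles regardless of genotype.

The reproductive load of a censused adult population is
`L = 1 − 2·Σ_{o female} O(o)·v(o)` with `O` the per-female offspring
distribution — equivalently one minus surviving daughters per female at
low density over `R_m`. Releases add males sized as a fraction of the
pre-release total adult population (F*+M* = 2 normalised units, so the
0.1% default adds 0.002); repeated and split (separate-cohort) schedules
are supported. The engine precomputes gamete tables and offspring
scatter matrices per parameter set, so a 1000-generation run costs a few
hundred milliseconds and full 1%-grid scans stay around a minute.

### Unintended costs

Six multiplicative zygote-to-adult viability costs (all baseline 0):
Cas9 expression, per-functional-gRNA expression, per-active
Cas9–gRNA-pair activity, shredder expression, shredder activity, and the
edited-allele cost in males. Expression/activity costs act where the
component is expressed (gRNAs ubiquitously, hence both sexes; Cas9 and
shredder in males). Their exact placement only matters when nonzero, and
the sensitivity scan treats them like any other parameter.

## Scan experiments

* **Resistance sweeps**: for the homing site the swept quantity is the
  end-joining rate itself (at a neutral insertion every end-joined allele
  is functionally resistant); for shredding/editing it is the per-event
  conversion probability under the low/high EJR scenario.
* **Standing resistance**: the resistant allele is seeded at
  Hardy–Weinberg proportions (linkage equilibrium) before release; the
  default grid is 1%, the resolution at which thresholds are quoted.
  Window edges: *lower* = largest frequency with 1000-generation minimum
  < 1e-6; *upper* = smallest with minimum > 0.95; *practicable* =
  smallest frequency at which suppression to ≤1% of the pre-release size
  within 50 generations fails.
* **Design comparison** uses a 50-generation horizon: the self-limiting
  reference designs act within tens of generations, and with a perfect
  trans-acting shredder (`epsilon_shred = 1`, the published setting for
  those designs) the editor sits exactly at the self-sustaining knife
  edge and accumulates linearly over much longer horizons, which would
  misrepresent those designs as self-sustaining.

## PAM screen

Candidate sites are all GG (+) and CC (−) dinucleotides, overlapping runs
included; coordinates are 0-based half-open. Any SNP allele at either
motif base disrupts the PAM (alternate alleles at a G/C reference base
can never be the required base), so intact-PAM frequency is the
reference-allele frequency over called chromosomes; when both bases are
polymorphic the per-base intact frequencies multiply (linkage-equilibrium
assumption) and the site's missing fraction is the larger of the two
bases'. Indels are ignored. Sites exceeding 5% missing data in any
population are dropped. Threshold counting uses strict inequalities and
presets (intact > 0.36 in the target and < 0.13 in the non-target
population for low-EJR species; 0.88/0.33 for high-EJR), counted in both
directions and averaged. F_ST is the Hudson estimator as a
ratio-of-averages over sites, clipped to [−0.05, 1]; for real analyses of
published cohorts one would typically plot against the consortium's own
F_ST values.

## Synthetic data

`generate_pam_dataset` emulates the statistical structure the screen
consumes: planted motifs in an AT filler (no spurious GG/CC), one
disrupting SNP per site, per-population intact frequencies and
missing-genotype rates realised as exact counts (largest-remainder
rounding) in the default deterministic mode, so threshold tests are
exact. It does not emulate linkage disequilibrium, demography, indels,
multi-SNP motifs or accessibility masks — a green screen test therefore
establishes the counting/filtering logic, not robustness to those
real-data features.

`individual_based_oracle` is a finite-N stochastic counterpart of the
recursion: multinomial juvenile genotypes from the same offspring
distribution, binomial density-dependent survival and viability. It
deliberately reuses the gamete tables — it verifies the
population-dynamic assembly independently, while the gamete mathematics
is verified separately against hand-computed probability trees. Oracle
agreement is asserted generation-conditionally (one stochastic transition
from each deterministic state, 3 binomial standard errors): trajectory-
level comparisons are not binomial, because early fluctuations are
amplified by drive growth.

## Numerical choices and degenerate inputs

* Distributions are renormalised after shredding; the pool cannot vanish
  (Y gametes survive shredding).
* A population with `F ≤ 0` or `M ≤ 0` stays extinct; frequencies are
  carried unchanged to avoid 0/0. The deterministic female count can
  underflow to exactly 0 under sustained load — minima below ~1e-300
  are reported as 0.
* The construct–construct correlation among males is defined as 0 when
  either indicator has zero variance.
* Timecourse CSVs are written at 15 significant digits and re-read with
  exact float parsing (`float_precision="round_trip"`).
* Threshold extraction warns, but still answers from the definitions, if
  a scan table is not monotone.

## Known limitations

Single panmictic population, non-overlapping generations, no stochastic
extinction (the deterministic recursion never loses the last female), no
spatial or temporal heterogeneity, no paternal deposition or somatic
expression, SNP-only PAM disruption. Published restriction-window values
for this design depend on model constants documented only in the original
supplementary material; with the forms committed here the windows
reproduce qualitatively (sharp low-EJR transition, broader high-EJR one)
but sit several percentage points higher, and the acceptance suite
records the corresponding checks as failing rather than adjusting the
model toward them.
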