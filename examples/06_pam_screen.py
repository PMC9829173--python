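"""Differentiated-PAM-site screen on a synthetic two-population dataset.

Builds a small reference with polymorphic GG/CC dinucleotides, a VCF with
per-sample genotypes at chosen per-population intact-PAM frequencies, and
a sample-to-population map; then runs the screen: per-population intact
frequencies, missing-data filtering, threshold counts in both directions,
and the Hudson F_ST for the pair.
"""

import tempfile

from doubledrive import (
    HIGH_EJR_THRESHOLDS,
    LOW_EJR_THRESHOLDS,
    PamSiteSpec,
    count_differentiated_sites,
    find_pam_sites_in_fasta,
    generate_pam_dataset,
    load_population_map,
    pairwise_fst,
    site_frequency_table,
)

spec = [
    PamSiteSpec((0.45, 0.08)),                      # suitable, low-EJR sense
    PamSiteSpec((0.92, 0.10), strand="-"),          # suitable even for high EJR
    PamSiteSpec((0.55, 0.50)),                      # undifferentiated
    PamSiteSpec((0.30, 0.70), missing_rate=0.02),   # differentiated the other way
]

with tempfile.TemporaryDirectory() as tmp:
    fasta, vcf, popmap, truth = generate_pam_dataset(
        seed=2024, n_populations=2, samples_per_pop=40,
        sequence_length=600, site_spec=spec, outdir=tmp)
    sites = find_pam_sites_in_fasta(fasta)
    table = site_frequency_table(sites, vcf, load_population_map(popmap))

    print(f"candidate GG/CC sites in reference: {len(sites)}")
    print(f"polymorphic sites passing the 5% missing-data filter: "
          f"{table.groupby(['start']).ngroups}")
    for name, thr in (("low-EJR", LOW_EJR_THRESHOLDS),
                      ("high-EJR", HIGH_EJR_THRESHOLDS)):
        c = count_differentiated_sites(table, "pop1", "pop2", *thr)
        print(f"{name} thresholds {thr}: pop1-target={c['a_as_target']} "
              f"pop2-target={c['b_as_target']} average={c['average']}")
    print(f"Hudson F_ST(pop1, pop2) over polymorphic PAMs: "
          f"{pairwise_fst(table, 'pop1', 'pop2'):.3f}")

# A site counts for a population pair when the cleavable (intact) PAM is
# common in the intended target population and rare in the non-target
# one; the averaged two-direction count is what rises with overall
# differentiation (F_ST) between the populations.
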