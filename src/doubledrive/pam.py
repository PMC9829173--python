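"""Differentiated-PAM-site screen for sequence-based population restriction.

Cas9 requires an NGG protospacer-adjacent motif, so a target site can be
chosen whose PAM dinucleotide (GG on the plus strand, CC on the minus
strand) is polymorphic and differentiated between target and non-target
populations: the cleavable (intact) motif must be common where suppression
is wanted and rare where it is not.  This module finds candidate GG/CC
dinucleotides in a reference, computes per-population intact-PAM allele
frequencies from a multi-sample VCF, filters on missing data, counts
sites passing frequency thresholds in either direction between a
population pair, and computes the Hudson F_ST for the pair.

Threshold presets correspond to the modelled restriction windows for the
homing site: a low-EJR species needs the intact motif >36% in the target
and <13% in the non-target population; a high-EJR species >88% and <33%.

Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "PamSite",
    "find_pam_sites",
    "find_pam_sites_in_fasta",
    "load_population_map",
    "site_frequency_table",
    "count_differentiated_sites",
    "pairwise_fst",
    "LOW_EJR_THRESHOLDS",
    "HIGH_EJR_THRESHOLDS",
]

#: (target_min, nontarget_max) intact-PAM frequency thresholds.
LOW_EJR_THRESHOLDS = (0.36, 0.13)
HIGH_EJR_THRESHOLDS = (0.88, 0.33)


@dataclass(frozen=True)
class PamSite:
    """A GG (+) or CC (-) dinucleotide at [start, start+2) on ``chromosome``."""

    chromosome: str
    start: int
    strand: str  # '+' for GG, '-' for CC

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 0:
            raise ValueError("negative start")


def find_pam_sites(sequence: str, chromosome: str = "ref") -> list[PamSite]:
    """All GG/CC dinucleotides, including overlapping runs (GGG -> 2 sites).

    Ambiguous bases never match.  The empty sequence yields an empty list.
    """
    seq = sequence.upper()
    sites = []
    for i in range(len(seq) - 1):
        dinuc = seq[i:i + 2]
        if dinuc == "GG":
            sites.append(PamSite(chromosome, i, "+"))
        elif dinuc == "CC":
            sites.append(PamSite(chromosome, i, "-"))
    return sites


def find_pam_sites_in_fasta(fasta_path) -> list[PamSite]:
    """Scan every record of a FASTA file (via Biopython)."""
    from Bio import SeqIO

    sites: list[PamSite] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sites.extend(find_pam_sites(str(rec.seq), rec.id))
    return sites


def load_population_map(path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> {sample: population}."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sample, pop = line.split("\t")[:2]
        out[sample] = pop
    return out


def _genotype_alleles(variant) -> np.ndarray:
    """Per-sample allele calls as an (n_samples, 2) int array, -1 missing."""
    gts = np.asarray(variant.genotypes, dtype=np.int64)  # allele1, allele2, phased
    return gts[:, :2]


def site_frequency_table(sites, vcf_path, population_map,
                         max_missing: float = 0.05) -> pd.DataFrame:
    """Per-population intact-PAM frequencies at polymorphic motif sites.

    A site is polymorphic iff at least one SNP overlaps either motif base
    (any substitution there disrupts the GG/CC, so every alternate allele
    is motif-disrupting).  Intact frequencies are computed from called
    alleles only; when both bases are polymorphic, the intact frequency is
    the product of per-base reference-allele frequencies (linkage
    equilibrium across the dinucleotide) and the missing fraction is the
    larger of the two bases'.  Sites whose missing fraction exceeds
    ``max_missing`` in ANY population are dropped.

    Returns a tidy frame: chromosome, start, strand, population,
    intact_freq, missing_frac, n_called (called chromosomes; the minimum
    across the site's polymorphic bases), n_intact.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in population_map]
    if missing_samples:
        raise KeyError(f"samples absent from population map: {missing_samples}")
    pops = sorted(set(population_map[s] for s in samples))
    pop_cols = {p: np.array([population_map[s] == p for s in samples]) for p in pops}

    # collect SNPs by (chrom, 0-based position)
    snp_calls: dict[tuple[str, int], list[np.ndarray]] = {}
    wanted: set[tuple[str, int]] = set()
    for site in sites:
        wanted.add((site.chromosome, site.start))
        wanted.add((site.chromosome, site.start + 1))
    for v in vcf:
        if len(v.REF) != 1 or not v.ALT or any(len(a) != 1 for a in v.ALT):
            continue  # SNPs only; indels over the motif are ignored
        key = (v.CHROM, v.POS - 1)
        if key in wanted:
            snp_calls.setdefault(key, []).append(_genotype_alleles(v))

    rows = []
    for site in sites:
        per_base: list[np.ndarray] = []
        for pos in (site.start, site.start + 1):
            calls = snp_calls.get((site.chromosome, pos))
            if calls:
                per_base.extend(calls)
        if not per_base:
            continue  # motif not polymorphic
        site_rows = []
        keep = True
        for pop in pops:
            mask = pop_cols[pop]
            intact = 1.0
            n_called_min = None
            n_chrom = int(mask.sum()) * 2
            missing_max = 0.0
            for calls in per_base:
                alleles = calls[mask].reshape(-1)
                called = alleles >= 0
                n_called = int(called.sum())
                if n_called == 0:
                    intact = np.nan
                    missing_max = 1.0
                    n_called_min = 0
                    continue
                missing_max = max(missing_max, 1.0 - n_called / n_chrom)
                ref_freq = float((alleles[called] == 0).mean())
                intact *= ref_freq
                n_called_min = (n_called if n_called_min is None
                                else min(n_called_min, n_called))
            if missing_max > max_missing:
                keep = False
                break
            site_rows.append({
                "chromosome": site.chromosome,
                "start": site.start,
                "strand": site.strand,
                "population": pop,
                "intact_freq": intact,
                "missing_frac": missing_max,
                "n_called": n_called_min,
                "n_intact": (round(intact * n_called_min)
                             if np.isfinite(intact) else 0),
            })
        if keep:
            rows.extend(site_rows)
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start", "strand", "population",
                 "intact_freq", "missing_frac", "n_called", "n_intact"],
    )


def count_differentiated_sites(table: pd.DataFrame, pop_a: str, pop_b: str,
                               target_min: float, nontarget_max: float) -> dict[str, float]:
    """Sites whose intact-PAM frequency exceeds ``target_min`` in the
    target population and is below ``nontarget_max`` in the other
    (strict inequalities), counted in both directions and averaged.
    """
    for pop in (pop_a, pop_b):
        if len(table) and pop not in set(table["population"]):
            raise KeyError(f"unknown population {pop!r}")
    if len(table) == 0:
        return {"a_as_target": 0, "b_as_target": 0, "average": 0.0}
    wide = table.pivot_table(index=["chromosome", "start", "strand"],
                             columns="population", values="intact_freq")
    fa = wide[pop_a].to_numpy()
    fb = wide[pop_b].to_numpy()
    ok = np.isfinite(fa) & np.isfinite(fb)
    a_target = int(((fa > target_min) & (fb < nontarget_max) & ok).sum())
    b_target = int(((fb > target_min) & (fa < nontarget_max) & ok).sum())
    return {"a_as_target": a_target, "b_as_target": b_target,
            "average": (a_target + b_target) / 2.0}


def pairwise_fst(table: pd.DataFrame, pop_a: str, pop_b: str) -> float:
    """Hudson F_ST between two populations, averaged over sites as a
    ratio of averages and clipped to [-0.05, 1].

    Per site, with sample allele frequencies p1, p2 from n1, n2 called
    chromosomes::

        num = (p1 - p2)^2 - p1 (1-p1)/(n1-1) - p2 (1-p2)/(n2-1)
        den = p1 (1-p2) + p2 (1-p1)

    Sites with fewer than 2 called chromosomes in either population are
    skipped; if no site is usable the estimator is undefined.
    """
    sub = table[table["population"].isin([pop_a, pop_b])]
    wide_p = sub.pivot_table(index=["chromosome", "start", "strand"],
                             columns="population", values="intact_freq")
    wide_n = sub.pivot_table(index=["chromosome", "start", "strand"],
                             columns="population", values="n_called")
    for pop in (pop_a, pop_b):
        if pop not in wide_p.columns:
            raise KeyError(f"unknown population {pop!r}")
    p1 = wide_p[pop_a].to_numpy(dtype=float)
    p2 = wide_p[pop_b].to_numpy(dtype=float)
    n1 = wide_n[pop_a].to_numpy(dtype=float)
    n2 = wide_n[pop_b].to_numpy(dtype=float)
    ok = np.isfinite(p1) & np.isfinite(p2) & (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise ValueError("F_ST undefined: no site with >=2 called "
                         "chromosomes in both populations")
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total_den = den.sum()
    if total_den == 0.0:
        return 0.0
    return float(np.clip(num.sum() / total_den, -0.05, 1.0))
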