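"""Synthetic inputs: multi-population PAM datasets and a stochastic
individual-based oracle for the deterministic recursion.

``generate_pam_dataset`` writes a small reference FASTA with planted GG/CC
motifs (plus non-polymorphic decoys), a multi-sample VCF whose SNPs
disrupt the planted motifs at specified per-population frequencies and
missing-data rates, and a sample-to-population map.  In the default
deterministic mode allele and missing counts are placed exactly (rounded
to whole chromosomes), so screen outputs can be predicted exactly from
the returned ground truth.

``individual_based_oracle`` runs a finite-population stochastic version
of the population model with the identical genetic rules — gamete pools
are taken from the same per-genotype distributions as the deterministic
engine — so at large N it converges on the deterministic recursion.  It
exists to verify the population-dynamic assembly; the gamete mathematics
itself is verified separately against hand-computed probability trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alleles import Params, STATE, StateSpace
from .dynamics import (
    Engine,
    PopulationState,
    ReleaseEvent,
    combined_release,
    wildtype_equilibrium,
)

__all__ = [
    "PamSiteSpec",
    "generate_pam_dataset",
    "individual_based_oracle",
    "stochastic_step",
]


@dataclass(frozen=True)
class PamSiteSpec:
    """One planted polymorphic motif: intact-PAM frequency per population,
    missing-genotype rate per population (scalar broadcast), strand."""

    intact_freq: tuple[float, ...]
    missing_rate: tuple[float, ...] | float = 0.0
    strand: str = "+"


def _filler(n: int) -> str:
    return ("AT" * (n // 2 + 1))[:n]


def generate_pam_dataset(seed: int, n_populations: int, samples_per_pop: int,
                         sequence_length: int, site_spec, outdir,
                         deterministic: bool = True):
    """Write FASTA + VCF + population map; return paths and ground truth.

    ``site_spec`` is a list of ``PamSiteSpec`` (or bare per-population
    frequency tuples).  Planted motifs are spaced along an AT filler that
    contains no GG/CC; one decoy (non-polymorphic) motif is added when
    space allows.  Each polymorphic motif gets a single disrupting SNP at
    its second base.  In deterministic mode the number of disrupting
    alleles among called chromosomes is ``round(freq * called)`` exactly;
    otherwise genotypes are sampled binomially.

    Returns ``(fasta_path, vcf_path, popmap_path, truth)`` where ``truth``
    is a tidy DataFrame with the realised per-population intact
    frequencies, called counts and missing fractions per site.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for s in site_spec:
        if not isinstance(s, PamSiteSpec):
            s = PamSiteSpec(tuple(float(v) for v in s))
        if len(s.intact_freq) != n_populations:
            raise ValueError("site spec frequency length != n_populations")
        miss = s.missing_rate
        if np.isscalar(miss):
            miss = tuple(float(miss) for _ in range(n_populations))
        elif len(miss) != n_populations:
            raise ValueError("site spec missing-rate length != n_populations")
        specs.append((tuple(float(v) for v in s.intact_freq), miss, s.strand))

    n_sites = len(specs)
    spacing = max(8, sequence_length // (n_sites + 2)) if n_sites else sequence_length
    if n_sites and spacing * n_sites + 4 > sequence_length:
        raise ValueError("sequence_length too short for the requested sites")

    seq = list(_filler(sequence_length))
    positions = []
    for k, (_, _, strand) in enumerate(specs):
        start = (k + 1) * spacing
        motif = "GG" if strand == "+" else "CC"
        seq[start:start + 2] = motif
        positions.append(start)
    if n_sites and positions[-1] + spacing + 2 < sequence_length:
        seq[positions[-1] + spacing:positions[-1] + spacing + 2] = "GG"  # decoy
    ref = "".join(seq)

    pops = [f"pop{i + 1}" for i in range(n_populations)]
    samples = [f"{p}_s{j + 1}" for p in pops for j in range(samples_per_pop)]

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(ref), 60):
            fh.write(ref[i:i + 60] + "\n")
    popmap_path = outdir / "populations.tsv"
    popmap_path.write_text(
        "".join(f"{s}\t{p}\n" for p in pops for s in samples if s.startswith(p + "_"))
    )

    truth_rows = []
    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chr1,length={sequence_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for (freqs, miss, strand), start in zip(specs, positions):
        snp_pos0 = start + 1  # disrupt the second motif base
        ref_base = ref[snp_pos0]
        alt_base = "A" if ref_base == "G" else "T"
        gts = []
        for pi, pop in enumerate(pops):
            n = samples_per_pop
            if deterministic:
                n_missing = int(round(miss[pi] * n))
            else:
                n_missing = int(rng.binomial(n, miss[pi]))
            called = n - n_missing
            chroms = 2 * called
            disrupt_freq = 1.0 - freqs[pi]
            if deterministic:
                n_disrupt = int(round(disrupt_freq * chroms))
            else:
                n_disrupt = int(rng.binomial(chroms, disrupt_freq))
            sample_gts = ["./."] * n_missing
            n_hom = n_disrupt // 2
            n_het = n_disrupt % 2
            sample_gts += ["1/1"] * n_hom + ["0/1"] * n_het
            sample_gts += ["0/0"] * (called - n_hom - n_het)
            order = rng.permutation(len(sample_gts))
            gts.extend(sample_gts[i] for i in order)
            truth_rows.append({
                "chromosome": "chr1",
                "start": start,
                "strand": strand,
                "population": pop,
                "intact_freq": (1.0 - n_disrupt / chroms) if chroms else np.nan,
                "missing_frac": n_missing / n,
                "n_called": chroms,
            })
        vcf_lines.append(
            f"chr1\t{snp_pos0 + 1}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    vcf_path = outdir / "variants.vcf"
    vcf_path.write_text("\n".join(vcf_lines) + "\n")
    truth = pd.DataFrame(
        truth_rows,
        columns=["chromosome", "start", "strand", "population",
                 "intact_freq", "missing_frac", "n_called"],
    )
    return fasta_path, vcf_path, popmap_path, truth


# ---------------------------------------------------------------------------
# Individual-based stochastic oracle
# ---------------------------------------------------------------------------


def integerize_counts(freqs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of ``n * freqs`` to integers summing to n."""
    raw = freqs * n
    base = np.floor(raw).astype(np.int64)
    short = n - int(base.sum())
    if short > 0:
        order = np.argsort(raw - base)[::-1]
        base[order[:short]] += 1
    return base


def stochastic_step(eng: Engine, f_counts: np.ndarray, m_counts: np.ndarray,
                    half: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic generation from integer adult genotype counts.

    ``half`` is the equilibrium female count (N/2), which sets the scale of
    density dependence.  Juvenile genotypes are multinomial draws from the
    deterministic offspring distribution; survival (density-dependent times
    viability) is binomial per genotype.
    """
    p = eng.params
    space = eng.space
    nF = int(f_counts.sum())
    nM = int(m_counts.sum())
    if nF == 0 or nM == 0:
        return np.zeros_like(f_counts), np.zeros_like(m_counts)
    state = PopulationState(0, nF / half, nM / half, f_counts / nF, m_counts / nM)
    Of, Om = eng.offspring_distribution(state)
    J = 2.0 * p.R_m * nF
    sigma = 1.0 / (1.0 + eng.gamma * (J / half))
    probs = np.clip(np.concatenate([Of, Om]), 0.0, None)
    probs = probs / probs.sum()
    juveniles = rng.multinomial(int(round(J)), probs)
    jf = juveniles[: space.n_female]
    jm = juveniles[space.n_female:]
    f_next = rng.binomial(jf, np.clip(sigma * eng.vf, 0.0, 1.0))
    m_next = rng.binomial(jm, np.clip(sigma * eng.vm, 0.0, 1.0))
    return f_next, m_next


def individual_based_oracle(p: Params, N: int, seed: int, generations: int,
                            releases: list[ReleaseEvent] | None = None,
                            space: StateSpace = STATE) -> pd.DataFrame:
    """Finite-population stochastic counterpart of the deterministic model.

    ``N`` is the total adult population at the wildtype equilibrium (N/2
    females).  Each generation, juvenile genotypes are drawn multinomially
    from the population offspring distribution (built from the same gamete
    tables as the deterministic engine), and survival (density-dependent
    times viability) is binomial per genotype.  Releases add
    ``round(fraction * N)`` males.  Fixed seeds give bit-identical runs.

    Returns per-generation F and M (relative to the pre-release
    equilibrium), construct frequencies, and raw counts for standard-error
    computations.
    """
    if N < 2:
        raise ValueError("N too small")
    rng = np.random.default_rng(seed)
    eng = Engine(p, space)
    eq = wildtype_equilibrium(p, space)
    half = N // 2
    f_counts = rng.multinomial(half, eq.female_freqs)
    m_counts = rng.multinomial(N - half, eq.male_freqs)
    if releases is None:
        releases = combined_release(p.release_fraction)
    ind_y, ind_a_construct = _male_indicators(space)

    rows = []
    for gen in range(generations + 1):
        for r in releases:
            if r.generation == gen:
                m_counts[r.male_genotype] += int(round(r.fraction * N))
        nF = int(f_counts.sum())
        nM = int(m_counts.sum())
        rows.append({
            "generation": gen,
            "F": nF / half,
            "M": nM / half,
            "n_females": nF,
            "n_males": nM,
            "freq_Y_construct": float(m_counts @ ind_y) / nM if nM else 0.0,
            "freq_A_construct_males": float(m_counts @ ind_a_construct) / nM
            if nM else 0.0,
        })
        if gen == generations or nF == 0 or nM == 0:
            if gen < generations:
                for g2 in range(gen + 1, generations + 1):
                    rows.append({"generation": g2, "F": 0.0, "M": 0.0,
                                 "n_females": 0, "n_males": 0,
                                 "freq_Y_construct": 0.0,
                                 "freq_A_construct_males": 0.0})
                break
            continue
        f_counts, m_counts = stochastic_step(eng, f_counts, m_counts, half, rng)
    return pd.DataFrame(rows)


def _male_indicators(space: StateSpace) -> tuple[np.ndarray, np.ndarray]:
    ind_y = np.zeros(space.n_male)
    ind_a = np.zeros(space.n_male)
    for j in range(space.n_male):
        g = space.male_genotype(j)
        ind_y[j] = 1.0 if g.y.is_construct else 0.0
        ind_a[j] = 1.0 if any(a.kind == "construct" for a in (g.a1, g.a2)) else 0.0
    return ind_y, ind_a
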