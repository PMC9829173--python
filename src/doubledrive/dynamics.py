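"""One-generation population recursion and timecourse summaries.

The model tracks a randomly mating population with non-overlapping
generations and two life stages.  Adult counts are in units of the
pre-release equilibrium female count (wildtype equilibrium F = M = 1).
Each generation:

1. the population egg and sperm pools are the frequency-weighted means of
   the per-genotype gamete distributions; random mating makes the juvenile
   genotype distribution their outer product, with offspring sex set by
   the sperm class (X- or Y-bearing) after shredding;
2. each female produces ``2 * R_m`` juveniles, so ``J = 2 * R_m * F``;
3. juveniles pass density-dependent (Beverton-Holt) survival
   ``sigma = 1 / (1 + gamma * J)`` with ``gamma = (R_m - 1) / (2 * R_m)``,
   which fixes the wildtype equilibrium at F = 1 and reduces, for a
   wildtype population, to ``F' = R_m * F / (1 + (R_m - 1) * F)``;
4. genotype-dependent viability (dominant edited-allele female lethality
   and any unintended costs) applies after density-dependent mortality and
   before censusing.

The reproductive load is the proportionate reduction in reproductive
output relative to wildtype: ``L = 1 - 2 * sum_female O(o) * v(o)`` where
``O`` is the per-female offspring distribution (density-independent),
i.e. one minus surviving daughters per female at low density over R_m.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .alleles import (
    EDIT_EDITED,
    EDIT_RESISTANT,
    SHRED_RESISTANT,
    STATE,
    Params,
    StateSpace,
)
from .gametes import gamete_tables
from .alleles import viability_vectors

__all__ = [
    "PopulationState",
    "ReleaseEvent",
    "Engine",
    "wildtype_equilibrium",
    "apply_release",
    "next_generation",
    "reproductive_load",
    "run_timecourse",
    "summarize",
    "construct_correlation",
    "combined_release",
    "separate_release",
    "repeated_release",
    "TIMECOURSE_COLUMNS",
]

TIMECOURSE_COLUMNS = [
    "generation",
    "F",
    "M",
    "sex_ratio",
    "load",
    "freq_Y_construct",
    "freq_Y_intact",
    "freq_A_construct",
    "freq_A_intact",
    "freq_A_resistant",
    "freq_X_edited",
    "freq_X_shred_res",
    "freq_X_edit_res",
    "correlation",
]


@dataclass(frozen=True)
class PopulationState:
    """Adult census: absolute sizes plus genotype frequency vectors."""

    generation: int
    F: float
    M: float
    female_freqs: np.ndarray  # (441,)
    male_freqs: np.ndarray  # (630,)

    def __post_init__(self) -> None:
        if self.F < 0 or self.M < 0:
            raise ValueError("negative population size")


@dataclass(frozen=True)
class ReleaseEvent:
    """A cohort of males added to the adult population.

    ``fraction`` is measured relative to the *pre-release* total adult
    population (F* + M* = 2 in normalised units), so the default 0.1%
    release adds 0.002 males.
    """

    generation: int
    male_genotype: int  # index into the male genotype space
    fraction: float


def _release_male_index(space: StateSpace, *, yle: bool, asd: str) -> int:
    """Male genotype index for standard release cohorts.

    ``asd`` is one of 'none', 'het', 'hom' (intact construct), or
    'het_nodrive'/'hom_nodrive' (construct lacking the homing gRNA, i.e. a
    non-driving sex distorter).
    """
    y = 1 if yle else 0  # intact construct or wildtype Y
    x = 0  # fully wildtype X
    intact = 2  # construct (shredder+, gRNA+)
    nodrive = 3  # construct (shredder+, gRNA-)
    pair = {
        "none": (0, 0),
        "het": (0, intact),
        "hom": (intact, intact),
        "het_nodrive": (0, nodrive),
        "hom_nodrive": (nodrive, nodrive),
    }[asd]
    return space.male_index(x, y, int(space.a_pair_index[pair[0], pair[1]]))


def combined_release(fraction: float = 0.001, generation: int = 0,
                     *, asd: str = "het", space: StateSpace = STATE) -> list[ReleaseEvent]:
    """Heterozygous males carrying both constructs (the default release)."""
    return [ReleaseEvent(generation, _release_male_index(space, yle=True, asd=asd), fraction)]


def separate_release(fraction: float = 0.001, generation: int = 0,
                     *, space: StateSpace = STATE) -> list[ReleaseEvent]:
    """Two cohorts: YLE-only males and intact-ASD heterozygote males."""
    return [
        ReleaseEvent(generation, _release_male_index(space, yle=True, asd="none"), fraction),
        ReleaseEvent(generation, _release_male_index(space, yle=False, asd="het"), fraction),
    ]


def repeated_release(fraction: float, every: int = 1, until: int = 1000,
                     *, yle: bool = True, asd: str = "none",
                     space: StateSpace = STATE) -> list[ReleaseEvent]:
    """The same cohort released every ``every`` generations through ``until``."""
    idx = _release_male_index(space, yle=yle, asd=asd)
    return [ReleaseEvent(g, idx, fraction) for g in range(0, until + 1, every)]


# ---------------------------------------------------------------------------
# Initial state
# ---------------------------------------------------------------------------


def _hwe_pair_freqs(allele_freqs: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        out[k] = allele_freqs[i] ** 2 if i == j else 2.0 * allele_freqs[i] * allele_freqs[j]
    return out


def wildtype_equilibrium(p: Params, space: StateSpace = STATE) -> PopulationState:
    """Pre-release equilibrium: F = M = 1, wildtype genotypes.

    ``p.standing_resistance`` seeds pre-existing cleavage-resistant
    alleles: frequency ``q`` at the homing site puts the resistant
    autosomal allele at Hardy-Weinberg proportions; frequency at the shred
    site does the same for shred-resistant X haplotypes.  The two are in
    linkage equilibrium.
    """
    if not p.R_m > 1.0:
        raise ValueError("no positive equilibrium for R_m <= 1")
    q_home = float(dict(p.standing_resistance).get("homing_site", 0.0))
    q_shred = float(dict(p.standing_resistance).get("shred_site", 0.0))

    a_freqs = np.zeros(space.n_a)
    a_freqs[0] = 1.0 - q_home
    a_freqs[1] = q_home
    x_freqs = np.zeros(space.n_x)
    x_freqs[space.x_index[space.x_haplotypes[0]]] = 1.0 - q_shred  # (sus, wt)
    x_freqs[3] = q_shred  # (res, wt): shred index 1, edit index 0

    ap = _hwe_pair_freqs(a_freqs, space.a_pairs)
    xp = _hwe_pair_freqs(x_freqs, space.x_pairs)
    f = np.outer(xp, ap).ravel()  # female index = xpair * 21 + apair

    m = np.zeros(space.n_male)
    for xi in range(space.n_x):
        if x_freqs[xi] == 0.0:
            continue
        for k, w in enumerate(ap):
            if w > 0.0:
                m[space.male_index(xi, 0, k)] = x_freqs[xi] * w
    return PopulationState(0, 1.0, 1.0, f, m)


def apply_release(s: PopulationState, releases: list[ReleaseEvent],
                  space: StateSpace = STATE) -> PopulationState:
    """Add released male cohorts due at ``s.generation`` to the census."""
    due = [r for r in releases if r.generation == s.generation]
    if not due:
        return s
    M = s.M
    m = s.male_freqs * M
    for r in due:
        if not 0 <= r.male_genotype < space.n_male:
            raise ValueError("release genotype must be a male genotype index")
        count = r.fraction * 2.0  # fraction of pre-release total adults (=2)
        m[r.male_genotype] += count
        M += count
    if M > 0:
        m = m / M
    return _dc_replace(s, M=M, male_freqs=m)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


class Engine:
    """Precomputed recursion operator for a fixed parameter set.

    Builds the per-genotype gamete tables, viability vectors and the
    offspring scatter matrices once; ``step`` then advances a state in a
    handful of small dense matrix products.  The engine is reusable across
    initial states (e.g. standing-resistance scans).
    """

    def __init__(self, p: Params, space: StateSpace = STATE) -> None:
        self.params = p
        self.space = space
        self.Gf, self.Gm = gamete_tables(p, space)
        self.vf, self.vm = viability_vectors(p, space)
        self.gamma = (p.R_m - 1.0) / (2.0 * p.R_m)
        nx, ny, na = space.n_x, space.n_y, space.n_a

        # scatter: ordered egg (x,a) x X-sperm (x',a') -> unordered female idx
        idx_f = np.empty(nx * na * nx * na, dtype=np.intp)
        t = 0
        for xe in range(nx):
            for ae in range(na):
                for xs in range(nx):
                    for asp in range(na):
                        idx_f[t] = space.female_index(
                            int(space.x_pair_index[xe, xs]),
                            int(space.a_pair_index[ae, asp]),
                        )
                        t += 1
        Wf = np.zeros((idx_f.size, space.n_female))
        Wf[np.arange(idx_f.size), idx_f] = 1.0
        self._Wf = Wf

        # scatter: egg (x,a) x Y-sperm (y,a') -> male idx
        idx_m = np.empty(nx * na * ny * na, dtype=np.intp)
        t = 0
        for xe in range(nx):
            for ae in range(na):
                for y in range(ny):
                    for asp in range(na):
                        idx_m[t] = space.male_index(
                            xe, y, int(space.a_pair_index[ae, asp])
                        )
                        t += 1
        Wm = np.zeros((idx_m.size, space.n_male))
        Wm[np.arange(idx_m.size), idx_m] = 1.0
        self._Wm = Wm

        self._summary = _SummaryTables(space)

    # -- offspring distribution -----------------------------------------

    def offspring_distribution(self, s: PopulationState) -> tuple[np.ndarray, np.ndarray]:
        """Juvenile genotype distribution ``(Of, Om)`` summing to 1.

        ``Of[i]``/``Om[j]`` is the probability that a random juvenile is a
        female/male of genotype i/j, given the current adult gene pools.
        """
        space = self.space
        nx, na = space.n_x, space.n_a
        E = (s.female_freqs @ self.Gf).reshape(nx, na)
        S = (s.male_freqs @ self.Gm).reshape(nx + space.n_y, na)
        SX, SY = S[:nx], S[nx:]
        Of = np.multiply.outer(E, SX).ravel() @ self._Wf
        Om = np.multiply.outer(E, SY).ravel() @ self._Wm
        return Of, Om

    def step(self, s: PopulationState) -> tuple[PopulationState, float]:
        """Advance one generation; returns (next state, load of ``s``)."""
        if s.F <= 0.0 or s.M <= 0.0:
            return _dc_replace(s, generation=s.generation + 1, F=0.0 if s.F <= 0 else s.F,
                               M=0.0 if s.M <= 0 else s.M), 1.0
        p = self.params
        Of, Om = self.offspring_distribution(s)
        wf = float(Of @ self.vf)
        wm = float(Om @ self.vm)
        load = 1.0 - 2.0 * wf
        J = 2.0 * p.R_m * s.F
        sigma = 1.0 / (1.0 + self.gamma * J)
        F1 = J * sigma * wf
        M1 = J * sigma * wm
        f1 = Of * self.vf
        m1 = Om * self.vm
        f1 = f1 / f1.sum() if F1 > 0 else s.female_freqs
        m1 = m1 / m1.sum() if M1 > 0 else s.male_freqs
        return PopulationState(s.generation + 1, F1, M1, f1, m1), load

    def load(self, s: PopulationState) -> float:
        """Reproductive load imposed by the current adult population."""
        if s.F <= 0.0 or s.M <= 0.0:
            return 1.0
        Of, _ = self.offspring_distribution(s)
        return 1.0 - 2.0 * float(Of @ self.vf)

    # -- timecourse ------------------------------------------------------

    def run(self, initial: PopulationState | None = None,
            releases: list[ReleaseEvent] | None = None,
            generations: int | None = None) -> pd.DataFrame:
        """Equilibrate, release, iterate; one row per censused generation."""
        p = self.params
        if generations is None:
            generations = p.generations
        if releases is None:
            releases = combined_release(p.release_fraction)
        s = initial if initial is not None else wildtype_equilibrium(p, self.space)
        s = apply_release(s, releases, self.space)
        rows = []
        for _ in range(generations):
            nxt, load = self.step(s)
            rows.append(self._record(s, load))
            nxt = apply_release(nxt, releases, self.space)
            s = nxt
        rows.append(self._record(s, self.load(s)))
        return pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)

    def _record(self, s: PopulationState, load: float) -> list[float]:
        sm = self._summary.metrics(s)
        total = s.F + s.M
        sex_ratio = s.F / total if total > 0 else 0.0
        return [
            s.generation, s.F, s.M, sex_ratio, load,
            sm["freq_Y_construct"], sm["freq_Y_intact"],
            sm["freq_A_construct"], sm["freq_A_intact"], sm["freq_A_resistant"],
            sm["freq_X_edited"], sm["freq_X_shred_res"], sm["freq_X_edit_res"],
            construct_correlation(s, self.space),
        ]


class _SummaryTables:
    """Per-genotype allele-class counting vectors for census summaries."""

    def __init__(self, space: StateSpace) -> None:
        self.space = space
        # male-genotype counts
        n_m = space.n_male
        self.m_y_construct = np.zeros(n_m)
        self.m_y_intact = np.zeros(n_m)
        self.m_a_construct = np.zeros(n_m)  # 0..2 copies
        self.m_a_intact = np.zeros(n_m)
        self.m_a_resistant = np.zeros(n_m)
        self.m_x_edited = np.zeros(n_m)  # 0/1 (single X)
        self.m_x_shred_res = np.zeros(n_m)
        self.m_x_edit_res = np.zeros(n_m)
        for j in range(n_m):
            g = space.male_genotype(j)
            self.m_y_construct[j] = 1.0 if g.y.is_construct else 0.0
            self.m_y_intact[j] = (
                1.0 if g.y.is_construct and g.y.cas9_functional and g.y.grna_edit_functional
                else 0.0
            )
            for a in (g.a1, g.a2):
                if a.kind == "construct":
                    self.m_a_construct[j] += 1.0
                    if a.shredder_functional and a.grna_home_functional:
                        self.m_a_intact[j] += 1.0
                elif a.kind == "resistant":
                    self.m_a_resistant[j] += 1.0
            self.m_x_edited[j] = 1.0 if g.x1.edit_target == EDIT_EDITED else 0.0
            self.m_x_edit_res[j] = 1.0 if g.x1.edit_target == EDIT_RESISTANT else 0.0
            self.m_x_shred_res[j] = 1.0 if g.x1.shred_target == SHRED_RESISTANT else 0.0

        n_f = space.n_female
        self.f_a_construct = np.zeros(n_f)
        self.f_a_intact = np.zeros(n_f)
        self.f_a_resistant = np.zeros(n_f)
        self.f_x_edited = np.zeros(n_f)  # 0..2
        self.f_x_shred_res = np.zeros(n_f)
        self.f_x_edit_res = np.zeros(n_f)
        for i in range(n_f):
            g = space.female_genotype(i)
            for a in (g.a1, g.a2):
                if a.kind == "construct":
                    self.f_a_construct[i] += 1.0
                    if a.shredder_functional and a.grna_home_functional:
                        self.f_a_intact[i] += 1.0
                elif a.kind == "resistant":
                    self.f_a_resistant[i] += 1.0
            for x in (g.x1, g.x2):
                if x.edit_target == EDIT_EDITED:
                    self.f_x_edited[i] += 1.0
                elif x.edit_target == EDIT_RESISTANT:
                    self.f_x_edit_res[i] += 1.0
                if x.shred_target == SHRED_RESISTANT:
                    self.f_x_shred_res[i] += 1.0

    def metrics(self, s: PopulationState) -> dict[str, float]:
        F, M = s.F, s.M
        f, m = s.female_freqs, s.male_freqs
        # Y frequencies among males
        out = {
            "freq_Y_construct": float(m @ self.m_y_construct),
            "freq_Y_intact": float(m @ self.m_y_intact),
        }
        # autosomal allele frequencies among all adult autosomes
        tot_a = 2.0 * (F + M)
        if tot_a > 0:
            out["freq_A_construct"] = (F * float(f @ self.f_a_construct)
                                       + M * float(m @ self.m_a_construct)) / tot_a
            out["freq_A_intact"] = (F * float(f @ self.f_a_intact)
                                    + M * float(m @ self.m_a_intact)) / tot_a
            out["freq_A_resistant"] = (F * float(f @ self.f_a_resistant)
                                       + M * float(m @ self.m_a_resistant)) / tot_a
        else:
            out["freq_A_construct"] = out["freq_A_intact"] = out["freq_A_resistant"] = 0.0
        # X-linked frequencies among all adult X chromosomes
        tot_x = 2.0 * F + M
        if tot_x > 0:
            out["freq_X_edited"] = (F * float(f @ self.f_x_edited)
                                    + M * float(m @ self.m_x_edited)) / tot_x
            out["freq_X_shred_res"] = (F * float(f @ self.f_x_shred_res)
                                       + M * float(m @ self.m_x_shred_res)) / tot_x
            out["freq_X_edit_res"] = (F * float(f @ self.f_x_edit_res)
                                      + M * float(m @ self.m_x_edit_res)) / tot_x
        else:
            out["freq_X_edited"] = out["freq_X_shred_res"] = out["freq_X_edit_res"] = 0.0
        return out


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def next_generation(s: PopulationState, p: Params,
                    space: StateSpace = STATE) -> PopulationState:
    return Engine(p, space).step(s)[0]


def reproductive_load(s: PopulationState, p: Params,
                      space: StateSpace = STATE) -> float:
    if s.F <= 0:
        raise ValueError("load undefined with no females")
    return Engine(p, space).load(s)


def run_timecourse(p: Params, releases: list[ReleaseEvent] | None = None,
                   generations: int | None = None,
                   space: StateSpace = STATE) -> pd.DataFrame:
    """Equilibrate, release, iterate ``generations`` steps; see ``Engine.run``."""
    return Engine(p, space).run(releases=releases, generations=generations)


_CORR_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _correlation_indicators(space: StateSpace) -> tuple[np.ndarray, np.ndarray]:
    key = id(space)
    if key not in _CORR_CACHE:
        ind_y = np.zeros(space.n_male)
        ind_a = np.zeros(space.n_male)
        for j in range(space.n_male):
            g = space.male_genotype(j)
            ind_y[j] = 1.0 if g.y.is_construct else 0.0
            ind_a[j] = 1.0 if any(a.kind == "construct" for a in (g.a1, g.a2)) else 0.0
        _CORR_CACHE[key] = (ind_y, ind_a)
    return _CORR_CACHE[key]


def construct_correlation(s: PopulationState, space: StateSpace = STATE) -> float:
    """Pearson correlation among adult males between carrying the Y-linked
    construct and carrying at least one autosomal construct allele.

    Defined as 0 when either indicator has zero variance.
    """
    m = s.male_freqs
    ind_y, ind_a = _correlation_indicators(space)
    py = float(m @ ind_y)
    pa = float(m @ ind_a)
    vy = py * (1.0 - py)
    va = pa * (1.0 - pa)
    if vy <= 1e-300 or va <= 1e-300:
        return 0.0
    cov = float(m @ (ind_y * ind_a)) - py * pa
    return cov / np.sqrt(vy * va)


def summarize(tc: pd.DataFrame) -> dict[str, float]:
    """Whole-run summary: population minimum and peak allele frequencies."""
    if len(tc) == 0:
        raise ValueError("empty timecourse")
    i_min = int(tc["F"].idxmin())
    return {
        "min_relative_F": float(tc["F"].min()),
        "generation_of_min": int(tc.loc[i_min, "generation"]),
        "max_load": float(tc["load"].max()),
        "max_freq_Y_construct": float(tc["freq_Y_construct"].max()),
        "max_freq_Y_intact": float(tc["freq_Y_intact"].max()),
        "max_freq_A_construct": float(tc["freq_A_construct"].max()),
        "max_freq_A_intact": float(tc["freq_A_intact"].max()),
        "max_freq_A_resistant": float(tc["freq_A_resistant"].max()),
        "max_freq_X_edited": float(tc["freq_X_edited"].max()),
        "final_F": float(tc["F"].iloc[-1]),
        "final_freq_Y_construct": float(tc["freq_Y_construct"].iloc[-1]),
        "final_freq_A_construct": float(tc["freq_A_construct"].iloc[-1]),
    }
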