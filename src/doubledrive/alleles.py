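"""Allele and genotype state spaces for the double-drive suppression model.

The system has two transgenic constructs:

* a Y-linked editor (YLE): germline-expressed Cas9 plus a ubiquitous gRNA
  that edits an X-linked target so that daughters inheriting the edited X
  die (or are sterile);
* an autosomal sex distorter (ASD): a meiotic X-shredder plus a ubiquitous
  gRNA targeting the construct's own insertion site, so that in the
  presence of the Y-linked Cas9 the ASD can home.

Each construct component can independently lose function by mutation, and
each of the three cut sites (editing target, shredding target, homing /
insertion site) can carry a functionally resistant sequence.  This module
enumerates the resulting allele classes, the sexed diploid genotypes, and
the viability (fitness) model.

Allele classes
--------------
Y chromosome (5 classes): wildtype, or construct with Cas9 and edit-gRNA
each functional or not (4 combinations).

X haplotype (6 classes): two linked loci — the shred target
(susceptible/resistant) and the edit target (wildtype/edited/resistant).
The two loci are distinct sites on the X.

Autosome (6 classes): wildtype (cleavable by the homing reaction),
resistant (cleavage-proof, wildtype fitness), or construct with shredder
and homing-gRNA each functional or not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

__all__ = [
    "YAllele",
    "XHaplotype",
    "AutosomalAllele",
    "Genotype",
    "Params",
    "StateSpace",
    "STATE",
    "EJR_LOW",
    "EJR_HIGH",
    "viability",
]

EJR_LOW = 0.05
EJR_HIGH = 0.60

SHRED_SUSCEPTIBLE = "susceptible"
SHRED_RESISTANT = "resistant"
EDIT_WILDTYPE = "wildtype"
EDIT_EDITED = "edited"
EDIT_RESISTANT = "resistant"


@dataclass(frozen=True)
class YAllele:
    """Y chromosome class: wildtype, or the editor construct.

    ``cas9_functional`` / ``grna_edit_functional`` are meaningful only when
    ``is_construct`` is True; a wildtype Y carries neither component.
    """

    is_construct: bool
    cas9_functional: bool = False
    grna_edit_functional: bool = False

    def __post_init__(self) -> None:
        if not self.is_construct and (self.cas9_functional or self.grna_edit_functional):
            raise ValueError("wildtype Y carries no functional components")


@dataclass(frozen=True)
class XHaplotype:
    """X chromosome haplotype over the two target loci (shred, edit)."""

    shred_target: str  # susceptible | resistant
    edit_target: str  # wildtype | edited | resistant

    def __post_init__(self) -> None:
        if self.shred_target not in (SHRED_SUSCEPTIBLE, SHRED_RESISTANT):
            raise ValueError(f"bad shred_target {self.shred_target!r}")
        if self.edit_target not in (EDIT_WILDTYPE, EDIT_EDITED, EDIT_RESISTANT):
            raise ValueError(f"bad edit_target {self.edit_target!r}")


@dataclass(frozen=True)
class AutosomalAllele:
    """Autosomal allele at the ASD insertion site.

    ``wildtype`` is the only class cleavable by the homing reaction;
    ``resistant`` is cleavage-proof with wildtype fitness.
    """

    kind: str  # wildtype | construct | resistant
    shredder_functional: bool = False
    grna_home_functional: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("wildtype", "construct", "resistant"):
            raise ValueError(f"bad autosomal kind {self.kind!r}")
        if self.kind != "construct" and (self.shredder_functional or self.grna_home_functional):
            raise ValueError("only construct alleles carry components")


@dataclass(frozen=True)
class Genotype:
    """Sexed diploid genotype.

    Females carry an unordered X pair; males a single X and a Y.  The
    autosomal pair is unordered in both sexes (no parent-of-origin
    effects).  Indices into the canonical orderings are stored alongside
    the allele objects for fast table lookups.
    """

    sex: str  # "female" | "male"
    x1: XHaplotype
    x2: XHaplotype | None
    y: YAllele | None
    a1: AutosomalAllele
    a2: AutosomalAllele

    def __post_init__(self) -> None:
        if self.sex == "female":
            if self.x2 is None or self.y is not None:
                raise ValueError("female genotypes carry two X and no Y")
        elif self.sex == "male":
            if self.x2 is not None or self.y is None:
                raise ValueError("male genotypes carry one X and one Y")
        else:
            raise ValueError(f"bad sex {self.sex!r}")


def _unordered_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i, n)]


class StateSpace:
    """Canonical orderings and index tables for alleles and genotypes.

    Orderings are deterministic: wildtype first, then (for constructs) the
    four functionality combinations with fully intact first.  Female
    genotypes are indexed by (X-pair, A-pair), males by (X, Y, A-pair).
    """

    def __init__(self) -> None:
        flag_combos = [(True, True), (True, False), (False, True), (False, False)]
        self.y_alleles: list[YAllele] = [YAllele(False)] + [
            YAllele(True, c, g) for c, g in flag_combos
        ]
        self.x_haplotypes: list[XHaplotype] = [
            XHaplotype(s, e)
            for s in (SHRED_SUSCEPTIBLE, SHRED_RESISTANT)
            for e in (EDIT_WILDTYPE, EDIT_EDITED, EDIT_RESISTANT)
        ]
        self.a_alleles: list[AutosomalAllele] = [
            AutosomalAllele("wildtype"),
            AutosomalAllele("resistant"),
        ] + [AutosomalAllele("construct", s, g) for s, g in flag_combos]

        self.n_y = len(self.y_alleles)  # 5
        self.n_x = len(self.x_haplotypes)  # 6
        self.n_a = len(self.a_alleles)  # 6

        self.y_index = {a: i for i, a in enumerate(self.y_alleles)}
        self.x_index = {a: i for i, a in enumerate(self.x_haplotypes)}
        self.a_index = {a: i for i, a in enumerate(self.a_alleles)}

        # Unordered pairs of X haplotypes / autosomal alleles (21 each).
        self.x_pairs = _unordered_pairs(self.n_x)
        self.a_pairs = _unordered_pairs(self.n_a)
        self.n_xp = len(self.x_pairs)
        self.n_ap = len(self.a_pairs)
        self.x_pair_index = np.empty((self.n_x, self.n_x), dtype=np.intp)
        for k, (i, j) in enumerate(self.x_pairs):
            self.x_pair_index[i, j] = self.x_pair_index[j, i] = k
        self.a_pair_index = np.empty((self.n_a, self.n_a), dtype=np.intp)
        for k, (i, j) in enumerate(self.a_pairs):
            self.a_pair_index[i, j] = self.a_pair_index[j, i] = k

        self.n_female = self.n_xp * self.n_ap  # 441
        self.n_male = self.n_x * self.n_y * self.n_ap  # 630

    # --- genotype index arithmetic -------------------------------------

    def female_index(self, xpair: int, apair: int) -> int:
        return xpair * self.n_ap + apair

    def male_index(self, x: int, y: int, apair: int) -> int:
        return (x * self.n_y + y) * self.n_ap + apair

    def female_genotype(self, idx: int) -> Genotype:
        xp, ap = divmod(idx, self.n_ap)
        i, j = self.x_pairs[xp]
        k, l = self.a_pairs[ap]
        return Genotype(
            "female",
            self.x_haplotypes[i],
            self.x_haplotypes[j],
            None,
            self.a_alleles[k],
            self.a_alleles[l],
        )

    def male_genotype(self, idx: int) -> Genotype:
        xy, ap = divmod(idx, self.n_ap)
        x, y = divmod(xy, self.n_y)
        k, l = self.a_pairs[ap]
        return Genotype(
            "male",
            self.x_haplotypes[x],
            None,
            self.y_alleles[y],
            self.a_alleles[k],
            self.a_alleles[l],
        )

    def genotype_index(self, g: Genotype) -> int:
        ak = self.a_index[g.a1]
        al = self.a_index[g.a2]
        ap = int(self.a_pair_index[ak, al])
        if g.sex == "female":
            xi = self.x_index[g.x1]
            xj = self.x_index[g.x2]
            return self.female_index(int(self.x_pair_index[xi, xj]), ap)
        return self.male_index(self.x_index[g.x1], self.y_index[g.y], ap)


#: Shared immutable state space (the orderings never change).
STATE = StateSpace()


def enumerate_state_space() -> StateSpace:
    """Return the canonical allele registry and genotype index tables."""
    return STATE


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

_PROBS = (
    "epsilon_edit",
    "rho_edit_res",
    "epsilon_shred",
    "rho_shred_res",
    "cleave_home",
    "ejr",
    "mu_background",
    "mu_homing",
    "r_x",
    "s_edit_female",
    "h_edit_female",
    "c_edit_male",
    "cost_cas9_expression",
    "cost_grna_expression",
    "cost_cas9_activity",
    "cost_shredder_expression",
    "cost_shredder_activity",
    "release_fraction",
)


@dataclass(frozen=True)
class Params:
    """All molecular, fitness, mutation, ecological and release parameters.

    Baseline values follow the published parameterisation: high but
    imperfect molecular efficiencies (editing 0.95, shredding 0.9, homing
    cleavage 0.95), low-EJR end-joining (0.05; the high-EJR scenario is
    0.60), loss-of-function rates of 1e-6 per component per generation and
    1e-3 per component per homing event, dominant-lethal edited allele in
    females, all unintended costs zero, intrinsic rate of increase R_m = 6
    daughters per female at low density, and a single release of
    heterozygous males equal to 0.1% of the pre-release adult population.

    The realised homing rate is ``cleave_home * (1 - ejr)``.
    """

    epsilon_edit: float = 0.95
    rho_edit_res: float = 0.0
    epsilon_shred: float = 0.9
    rho_shred_res: float = 0.0
    cleave_home: float = 0.95
    ejr: float = EJR_LOW
    mu_background: float = 1e-6
    mu_homing: float = 1e-3
    r_x: float = 0.5
    s_edit_female: float = 1.0
    h_edit_female: float = 1.0
    c_edit_male: float = 0.0
    cost_cas9_expression: float = 0.0
    cost_grna_expression: float = 0.0
    cost_cas9_activity: float = 0.0
    cost_shredder_expression: float = 0.0
    cost_shredder_activity: float = 0.0
    R_m: float = 6.0
    release_fraction: float = 0.001
    generations: int = 1000
    standing_resistance: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _PROBS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if not self.R_m > 1.0:
            raise ValueError(f"R_m={self.R_m!r} must exceed 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for site, q in dict(self.standing_resistance).items():
            if site not in ("homing_site", "shred_site"):
                raise ValueError(f"unknown standing-resistance site {site!r}")
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"standing resistance {q!r} outside [0, 1]")

    @property
    def homing_rate(self) -> float:
        return self.cleave_home * (1.0 - self.ejr)

    @classmethod
    def idealised(cls, **overrides) -> "Params":
        """No mutation, no resistance formation, no unintended costs."""
        base = dict(ejr=0.0, mu_background=0.0, mu_homing=0.0)
        base.update(overrides)
        return cls(**base)

    def with_ejr(self, scenario: str) -> "Params":
        """Return a copy under the 'low' (5%) or 'high' (60%) EJR scenario."""
        try:
            ejr = {"low": EJR_LOW, "high": EJR_HIGH}[scenario]
        except KeyError:
            raise ValueError(f"unknown EJR scenario {scenario!r}") from None
        return replace(self, ejr=ejr)

    def replace(self, **changes) -> "Params":
        return replace(self, **changes)

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return tuple(f.name for f in fields(Params))


# ---------------------------------------------------------------------------
# Viability
# ---------------------------------------------------------------------------


def _n_functional_grnas(g: Genotype) -> int:
    n = 0
    if g.y is not None and g.y.is_construct and g.y.grna_edit_functional:
        n += 1
    for a in (g.a1, g.a2):
        if a.kind == "construct" and a.grna_home_functional:
            n += 1
    return n


def viability(g: Genotype, p: Params) -> float:
    """Zygote-to-adult survival multiplier in [0, 1].

    The intended effect is the dominant edited-allele lethality in females
    (applied after density-dependent mortality, before censusing):
    heterozygotes survive at ``1 - h*s``, homozygotes at ``1 - s``.  On top
    of that, six unintended costs multiply in: Cas9 expression, per
    functional gRNA expression, per active Cas9-gRNA pair, shredder
    expression and activity (expression/activity costs act in males, where
    the components are expressed), and the edited-allele cost in males.
    Resistant alleles at any of the three sites carry wildtype fitness.
    """
    v = 1.0
    if g.sex == "female":
        n_edit = sum(
            1 for x in (g.x1, g.x2) if x.edit_target == EDIT_EDITED
        )
        if n_edit == 1:
            v *= 1.0 - p.h_edit_female * p.s_edit_female
        elif n_edit == 2:
            v *= 1.0 - p.s_edit_female
        # ubiquitous gRNA expression also costs females
        for a in (g.a1, g.a2):
            if a.kind == "construct" and a.grna_home_functional:
                v *= 1.0 - p.cost_grna_expression
        return v

    # males
    if g.x1.edit_target == EDIT_EDITED:
        v *= 1.0 - p.c_edit_male
    n_grna = _n_functional_grnas(g)
    v *= (1.0 - p.cost_grna_expression) ** n_grna
    cas9 = g.y.is_construct and g.y.cas9_functional
    if cas9:
        v *= 1.0 - p.cost_cas9_expression
        v *= (1.0 - p.cost_cas9_activity) ** n_grna
    n_shred = sum(
        1 for a in (g.a1, g.a2) if a.kind == "construct" and a.shredder_functional
    )
    v *= (1.0 - p.cost_shredder_expression) ** n_shred
    v *= (1.0 - p.cost_shredder_activity) ** n_shred
    return v


def viability_vectors(p: Params, space: StateSpace = STATE) -> tuple[np.ndarray, np.ndarray]:
    """Viability per female (441,) and male (630,) genotype index."""
    vf = np.array(
        [viability(space.female_genotype(i), p) for i in range(space.n_female)]
    )
    vm = np.array(
        [viability(space.male_genotype(i), p) for i in range(space.n_male)]
    )
    return vf, vm
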