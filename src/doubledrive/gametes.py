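"""Exact gamete distributions per parent genotype.

Males run the full molecular cascade, in germline order:

1. **editing** — if the Y carries functional Cas9 *and* a functional
   edit-gRNA and the X edit target is wildtype, the X is attacked with
   probability ``epsilon_edit``; an attack yields the edited allele with
   probability ``1 - rho_edit_res`` or a functional resistant allele with
   probability ``rho_edit_res``.  Editing acts on the single X in the
   diploid germline, so the outcome is shared by all X-bearing products of
   that branch.
2. **homing** — only in {wildtype, construct-with-functional-homing-gRNA}
   autosomal heterozygotes whose Y carries functional Cas9: the wildtype
   allele is cleaved with probability ``cleave_home``; a cleavage resolves
   by end joining to the resistant allele (probability ``ejr``) or to a
   copy of the construct, each functional component of the copy
   independently lost with probability ``mu_homing``.
3. **meiosis** — sex chromosome and autosome assort independently.
4. **shredding** — if at least one autosomal allele carries a functional
   shredder it acts in trans: every X-bearing product with a susceptible
   shred target is destroyed with probability
   ``epsilon_shred * (1 - rho_shred_res)`` or converted to shred-resistant
   and retained with probability ``epsilon_shred * rho_shred_res``.
5. the surviving pool is renormalised (sperm are not limiting), and
6. background loss-of-function mutation at ``mu_background`` per component
   is applied to the transmitted gametes.

Females do none of the above: X haplotypes recombine between the shred and
edit loci at fraction ``r_x``, autosomes segregate Mendelian, background
mutation applies to transmitted construct components.

Distributions are dense arrays over the canonical gamete spaces:
``(6 X-haplotypes, 6 autosomal alleles)`` for eggs and
``(11 sex classes = 6 X + 5 Y, 6 autosomal alleles)`` for sperm.
"""

from __future__ import annotations

import numpy as np

from .alleles import (
    EDIT_EDITED,
    EDIT_RESISTANT,
    EDIT_WILDTYPE,
    SHRED_RESISTANT,
    SHRED_SUSCEPTIBLE,
    STATE,
    Genotype,
    Params,
    StateSpace,
)

__all__ = [
    "male_gamete_distribution",
    "female_gamete_distribution",
    "apply_background_mutation",
    "component_loss_matrices",
    "gamete_tables",
]


def _component_loss_vector(functional: tuple[bool, ...], mu: float,
                           variants: list[tuple[bool, ...]]) -> np.ndarray:
    """P(variant) when each functional component is lost independently w.p. mu."""
    out = np.zeros(len(variants))
    for k, target in enumerate(variants):
        p = 1.0
        ok = True
        for f, t in zip(functional, target):
            if not f:
                if t:  # cannot regain function
                    ok = False
                    break
                continue
            p *= mu if not t else 1.0 - mu
        if ok:
            out[k] = p
    return out


def component_loss_matrices(mu: float, space: StateSpace = STATE) -> tuple[np.ndarray, np.ndarray]:
    """Markov matrices for per-component loss-of-function at rate ``mu``.

    Returns ``(D_y, D_a)`` with ``D[i, j] = P(allele i -> allele j)``.
    Wildtype and resistant alleles carry no components and are fixed
    points; construct alleles can only lose function.
    """
    combos = [(True, True), (True, False), (False, True), (False, False)]
    D_y = np.eye(space.n_y)
    D_a = np.eye(space.n_a)
    if mu > 0.0:
        for i, y in enumerate(space.y_alleles):
            if y.is_construct:
                row = _component_loss_vector(
                    (y.cas9_functional, y.grna_edit_functional), mu, combos
                )
                D_y[i, :] = 0.0
                D_y[i, 1:] = row
        for i, a in enumerate(space.a_alleles):
            if a.kind == "construct":
                row = _component_loss_vector(
                    (a.shredder_functional, a.grna_home_functional), mu, combos
                )
                D_a[i, :] = 0.0
                D_a[i, 2:] = row
    return D_y, D_a


def apply_background_mutation(dist: np.ndarray, p: Params,
                              space: StateSpace = STATE) -> np.ndarray:
    """Apply per-component background loss-of-function to a gamete array.

    ``dist`` is ``(6, 6)`` (eggs: X x A) or ``(11, 6)`` (sperm: sex class x
    A).  X haplotypes carry no construct components; transmitted Y and
    autosomal construct components each mutate independently at
    ``mu_background``.  Mass is conserved.
    """
    D_y, D_a = component_loss_matrices(p.mu_background, space)
    out = dist @ D_a
    if out.shape[0] == space.n_x + space.n_y:  # sperm: mutate the Y block
        out[space.n_x:, :] = D_y.T @ out[space.n_x:, :]
    return out


# ---------------------------------------------------------------------------
# Males
# ---------------------------------------------------------------------------


def _edit_branches(g: Genotype, p: Params, space: StateSpace) -> list[tuple[int, float]]:
    """Post-editing X haplotype of the male germline: [(x_index, prob)]."""
    x = g.x1
    xi = space.x_index[x]
    y = g.y
    active = (
        y.is_construct
        and y.cas9_functional
        and y.grna_edit_functional
        and x.edit_target == EDIT_WILDTYPE
    )
    if not active or p.epsilon_edit == 0.0:
        return [(xi, 1.0)]
    edited = space.x_index[type(x)(x.shred_target, EDIT_EDITED)]
    resist = space.x_index[type(x)(x.shred_target, EDIT_RESISTANT)]
    e = p.epsilon_edit
    branches = [
        (xi, 1.0 - e),
        (edited, e * (1.0 - p.rho_edit_res)),
        (resist, e * p.rho_edit_res),
    ]
    return [(i, pr) for i, pr in branches if pr > 0.0]


def _homing_branches(g: Genotype, p: Params, space: StateSpace) -> list[tuple[tuple[int, int], float]]:
    """Post-homing autosomal pair of the male germline: [((a, b), prob)]."""
    ai = space.a_index[g.a1]
    bi = space.a_index[g.a2]
    kinds = {g.a1.kind, g.a2.kind}
    template = None
    if kinds == {"wildtype", "construct"}:
        c = g.a1 if g.a1.kind == "construct" else g.a2
        if c.grna_home_functional:
            template = c
    eligible = (
        template is not None
        and g.y.is_construct
        and g.y.cas9_functional
        and p.cleave_home > 0.0
    )
    if not eligible:
        return [((ai, bi), 1.0)]
    ti = space.a_index[template]
    ch, ejr = p.cleave_home, p.ejr
    branches: list[tuple[tuple[int, int], float]] = [((0, ti), 1.0 - ch)]
    if ejr > 0.0:
        branches.append(((1, ti), ch * ejr))  # resistant end-joining product
    # homed copy: template functionality degraded at mu_homing per component
    combos = [(True, True), (True, False), (False, True), (False, False)]
    copy_probs = _component_loss_vector(
        (template.shredder_functional, template.grna_home_functional),
        p.mu_homing,
        combos,
    )
    for k, pr in enumerate(copy_probs):
        if pr > 0.0:
            branches.append(((2 + k, ti), ch * (1.0 - ejr) * pr))
    return branches


def male_gamete_distribution(g: Genotype, p: Params,
                             space: StateSpace = STATE) -> np.ndarray:
    """Sperm distribution ``(11, 6)`` over (sex class, autosomal allele).

    Rows 0-5 are X-bearing sperm by X haplotype; rows 6-10 Y-bearing sperm
    by Y class.  Masses sum to 1.
    """
    if g.sex != "male":
        raise ValueError("male_gamete_distribution requires a male genotype")
    nx, ny, na = space.n_x, space.n_y, space.n_a
    yi = space.y_index[g.y]
    shred_active = any(
        a.kind == "construct" and a.shredder_functional for a in (g.a1, g.a2)
    )
    out = np.zeros((nx + ny, na))
    for (ai, bi), pa in _homing_branches(g, p, space):
        a_dist = np.zeros(na)
        a_dist[ai] += 0.5
        a_dist[bi] += 0.5
        for xi, px in _edit_branches(g, p, space):
            # meiosis: half X-bearing, half Y-bearing, A assorts independently
            w = pa * px * 0.5
            x_row = np.zeros(nx)
            x_row[xi] = 1.0
            if shred_active and space.x_haplotypes[xi].shred_target == SHRED_SUSCEPTIBLE:
                surv = 1.0 - p.epsilon_shred
                conv = p.epsilon_shred * p.rho_shred_res
                res = space.x_index[
                    type(space.x_haplotypes[xi])(
                        SHRED_RESISTANT, space.x_haplotypes[xi].edit_target
                    )
                ]
                x_row = np.zeros(nx)
                x_row[xi] = surv
                x_row[res] += conv
            out[:nx] += w * np.outer(x_row, a_dist)
            out[nx + yi] += w * a_dist
    total = out.sum()
    if total <= 0.0:
        raise ValueError("gamete pool annihilated (epsilon_shred=1 with no Y?)")
    out /= total
    return apply_background_mutation(out, p, space)


# ---------------------------------------------------------------------------
# Females
# ---------------------------------------------------------------------------


def female_gamete_distribution(g: Genotype, p: Params,
                               space: StateSpace = STATE) -> np.ndarray:
    """Egg distribution ``(6, 6)`` over (X haplotype, autosomal allele).

    No editing, homing or shredding occurs in females; the two X-linked
    loci recombine at fraction ``r_x`` and autosomes are Mendelian.
    """
    if g.sex != "female":
        raise ValueError("female_gamete_distribution requires a female genotype")
    nx, na = space.n_x, space.n_a
    x_dist = np.zeros(nx)
    h1, h2 = g.x1, g.x2
    r = p.r_x
    for hap, pr in (
        (h1, (1.0 - r) / 2.0),
        (h2, (1.0 - r) / 2.0),
        (type(h1)(h1.shred_target, h2.edit_target), r / 2.0),
        (type(h1)(h2.shred_target, h1.edit_target), r / 2.0),
    ):
        x_dist[space.x_index[hap]] += pr
    a_dist = np.zeros(na)
    a_dist[space.a_index[g.a1]] += 0.5
    a_dist[space.a_index[g.a2]] += 0.5
    return apply_background_mutation(np.outer(x_dist, a_dist), p, space)


# ---------------------------------------------------------------------------
# Dense per-genotype tables for the population recursion
# ---------------------------------------------------------------------------


def gamete_tables(p: Params, space: StateSpace = STATE) -> tuple[np.ndarray, np.ndarray]:
    """Gamete distributions for every genotype.

    Returns ``(Gf, Gm)``: ``Gf[i]`` is the flattened ``(36,)`` egg
    distribution of female genotype ``i`` and ``Gm[j]`` the flattened
    ``(66,)`` sperm distribution of male genotype ``j``.
    """
    Gf = np.empty((space.n_female, space.n_x * space.n_a))
    for i in range(space.n_female):
        Gf[i] = female_gamete_distribution(space.female_genotype(i), p, space).ravel()
    Gm = np.empty((space.n_male, (space.n_x + space.n_y) * space.n_a))
    for j in range(space.n_male):
        Gm[j] = male_gamete_distribution(space.male_genotype(j), p, space).ravel()
    return Gf, Gm
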