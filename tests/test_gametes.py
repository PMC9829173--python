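"""Gamete distributions against hand-computed probability trees.

The frozen expected values below were derived by enumerating the branch
trees by hand: editing (attack / outcome), homing (cleave / repair
pathway), independent meiotic assortment, trans-acting shredding of
susceptible X products, renormalisation, then per-component background
mutation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doubledrive.alleles import Params, STATE
from doubledrive.gametes import (
    apply_background_mutation,
    component_loss_matrices,
    female_gamete_distribution,
    gamete_tables,
    male_gamete_distribution,
)

from conftest import make_female, make_male

NX = STATE.n_x


def male_dist(space, p, **kw):
    return male_gamete_distribution(space.male_genotype(make_male(space, **kw)), p, space)


def female_dist(space, p, **kw):
    return female_gamete_distribution(space.female_genotype(make_female(space, **kw)), p, space)


def test_wildtype_male_mendelian(space, baseline_low):
    d = male_dist(space, baseline_low)
    assert d[0, 0] == pytest.approx(0.5, abs=1e-15)       # (sus, wt) X, wt A
    assert d[NX + 0, 0] == pytest.approx(0.5, abs=1e-15)  # wt Y, wt A
    assert d.sum() == pytest.approx(1.0, abs=1e-12)


def test_intact_double_drive_male_tree(space):
    """Full probability-tree oracle for the release genotype (ejr = 0.05)."""
    p = Params.idealised(ejr=0.05)
    d = male_dist(space, p, y=1, a=(0, 2))
    # sex margin: Y-bearing 0.5 / (0.5 + 0.5*0.1) = 10/11
    assert d[NX:].sum() == pytest.approx(0.5 / 0.55, abs=1e-12)
    # among X gametes: 0.95 edited, 0.05 wildtype
    x = d[:NX].sum(axis=1)
    assert x[1] / x.sum() == pytest.approx(0.95, abs=1e-12)
    assert x[0] / x.sum() == pytest.approx(0.05, abs=1e-12)
    # autosome margin: construct 0.95125, resistant 0.02375, wildtype 0.025
    a = d.sum(axis=0)
    assert a[2] == pytest.approx(0.95125, abs=1e-12)
    assert a[1] == pytest.approx(0.02375, abs=1e-12)
    assert a[0] == pytest.approx(0.025, abs=1e-12)


def test_wildtype_y_with_asd_shreds_but_cannot_home(space):
    """Without Cas9 there is no editing and no homing, but shredding acts."""
    p = Params.idealised(ejr=0.05)
    d = male_dist(space, p, y=0, a=(0, 2))
    assert d[NX:].sum() == pytest.approx(10 / 11, abs=1e-12)
    a = d.sum(axis=0)
    assert a[0] == pytest.approx(0.5, abs=1e-12)  # Mendelian autosome
    assert a[2] == pytest.approx(0.5, abs=1e-12)
    x = d[:NX].sum(axis=1)
    assert x[1] == 0.0  # no edited X


@pytest.mark.parametrize("r", [0.5, 0.0])
def test_female_recombination(space, r):
    """X pair {(sus, edited), (res, wildtype)} recombining at fraction r.

    Parental haplotypes are indices 1=(sus, edited) and 3=(res, wt);
    recombinants are 0=(sus, wt) and 4=(res, edited).
    """
    p = Params.idealised(r_x=r)
    d = female_dist(space, p, x=(1, 3))
    x = d.sum(axis=1)
    if r == 0.5:
        assert np.allclose(x[[0, 1, 3, 4]], 0.25, atol=1e-12)
    else:
        assert np.allclose(x[[1, 3]], 0.5, atol=1e-12)
        assert np.allclose(x[[0, 4]], 0.0, atol=1e-12)


def test_homozygous_wildtype_female(space, idealised):
    d = female_dist(space, idealised)
    assert d[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_background_mutation_identity_and_products(space):
    p0 = Params(mu_background=0.0)
    d = np.zeros((NX, 6))
    d[0, 2] = 1.0  # intact-ASD gamete
    assert np.array_equal(apply_background_mutation(d, p0, space), d)

    p = Params(mu_background=1e-3)
    out = apply_background_mutation(d, p, space)
    assert out[0, 2] == pytest.approx(0.999 ** 2, abs=1e-15)   # 0.998001
    assert out[0, 3] == pytest.approx(0.999e-3, abs=1e-15)     # gRNA kept, shredder lost? see order
    assert out[0, 4] == pytest.approx(0.999e-3, abs=1e-15)
    assert out[0, 5] == pytest.approx(1e-6, abs=1e-18)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)

    d_wt = np.zeros((NX, 6))
    d_wt[0, 0] = 1.0
    assert np.array_equal(apply_background_mutation(d_wt, p, space), d_wt)


def test_loss_matrices_are_stochastic(space):
    D_y, D_a = component_loss_matrices(0.02, space)
    assert np.allclose(D_y.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(D_a.sum(axis=1), 1.0, atol=1e-12)
    # function is never regained
    assert D_a[5, 2] == D_a[5, 3] == D_a[5, 4] == 0.0


@settings(max_examples=80, derandomize=True, deadline=None)
@given(j=st.integers(min_value=0, max_value=629),
       ee=st.floats(0, 1), es=st.floats(0, 1), chp=st.floats(0, 1),
       ejr=st.floats(0, 1), rs=st.floats(0, 1), re=st.floats(0, 1))
def test_male_distribution_normalised(space, j, ee, es, chp, ejr, rs, re):
    p = Params(epsilon_edit=ee, epsilon_shred=es, cleave_home=chp, ejr=ejr,
               rho_shred_res=rs, rho_edit_res=re)
    d = male_gamete_distribution(space.male_genotype(j), p, space)
    assert d.min() >= 0.0
    assert d.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(idx=st.integers(min_value=0, max_value=440), r=st.floats(0, 1))
def test_female_distribution_normalised(space, idx, r):
    d = female_gamete_distribution(
        space.female_genotype(idx), Params(r_x=r), space
    )
    assert d.min() >= 0.0
    assert d.sum() == pytest.approx(1.0, abs=1e-12)


def test_all_processes_off_is_mendelian(space):
    p = Params(epsilon_edit=0, epsilon_shred=0, cleave_home=0,
               mu_background=0, mu_homing=0)
    for j in (0, 17, 101, 333, 629):
        g = space.male_genotype(j)
        d = male_gamete_distribution(g, p, space)
        xi = space.x_index[g.x1]
        yi = space.y_index[g.y]
        want = np.zeros((11, 6))
        for a in (g.a1, g.a2):
            want[xi, space.a_index[a]] += 0.25
            want[NX + yi, space.a_index[a]] += 0.25
        assert np.allclose(d, want, atol=1e-15)


def test_shredding_preserves_autosomal_marginal(space):
    """Shredding acts on the sex-chromosome margin only."""
    rng = np.random.default_rng(7)
    p_on = Params.idealised(ejr=0.05)
    p_off = p_on.replace(epsilon_shred=0.0)
    for j in rng.integers(0, space.n_male, size=25):
        g = space.male_genotype(int(j))
        a_on = male_gamete_distribution(g, p_on, space).sum(axis=0)
        a_off = male_gamete_distribution(g, p_off, space).sum(axis=0)
        assert np.allclose(a_on, a_off, atol=1e-12)


@pytest.mark.parametrize("y, a", [
    (0, (0, 2)),   # no Cas9
    (3, (0, 2)),   # Cas9 nonfunctional on construct Y
    (1, (2, 2)),   # no wildtype allele to convert
    (1, (1, 2)),   # resistant/construct pair
    (1, (0, 3)),   # construct lacks the homing gRNA
])
def test_homing_requires_cas9_wildtype_and_grna(space, y, a):
    p = Params.idealised(ejr=0.05)
    d = male_gamete_distribution(space.male_genotype(make_male(space, y=y, a=a)), p, space)
    a_marg = d.sum(axis=0)
    want = np.zeros(6)
    want[a[0]] += 0.5
    want[a[1]] += 0.5
    assert np.allclose(a_marg, want, atol=1e-12)


def test_defective_yle_grna_still_homes(space):
    """A Y with working Cas9 but broken edit-gRNA still drives the ASD."""
    p = Params.idealised(ejr=0.05)
    d = male_gamete_distribution(space.male_genotype(make_male(space, y=2, a=(0, 2))), p, space)
    a_marg = d.sum(axis=0)
    assert a_marg[2] == pytest.approx(0.95125, abs=1e-12)
    x = d[:NX].sum(axis=1)
    assert x[1] == 0.0  # but no editing


def test_sex_mismatch_raises(space, baseline_low):
    with pytest.raises(ValueError):
        male_gamete_distribution(space.female_genotype(0), baseline_low, space)
    with pytest.raises(ValueError):
        female_gamete_distribution(space.male_genotype(0), baseline_low, space)


def test_gamete_tables_rows_normalised(baseline_low, space):
    Gf, Gm = gamete_tables(baseline_low, space)
    assert np.allclose(Gf.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(Gm.sum(axis=1), 1.0, atol=1e-10)
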