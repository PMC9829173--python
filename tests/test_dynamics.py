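"""Population recursion: fixed points, releases, load, correlation, and the
stochastic individual-based cross-check."""

import numpy as np
import pandas as pd
import pytest

from doubledrive.alleles import Params
from doubledrive.dynamics import (
    Engine,
    apply_release,
    combined_release,
    construct_correlation,
    next_generation,
    reproductive_load,
    run_timecourse,
    separate_release,
    summarize,
    wildtype_equilibrium,
)
from doubledrive.fixtures import individual_based_oracle

from conftest import make_male


def test_wildtype_fixed_point_100_generations(baseline_low):
    eng = Engine(baseline_low)
    s = wildtype_equilibrium(baseline_low)
    for _ in range(100):
        s, _ = eng.step(s)
    assert s.F == pytest.approx(1.0, abs=1e-12)
    assert s.M == pytest.approx(1.0, abs=1e-12)


def test_beverton_holt_closed_form(baseline_low):
    """Wildtype females obey F' = R_m F / (1 + (R_m - 1) F)."""
    eng = Engine(baseline_low)
    eq = wildtype_equilibrium(baseline_low)
    for F0 in (0.5, 0.1, 2.0):
        s = eq.__class__(0, F0, F0, eq.female_freqs, eq.male_freqs)
        nxt, _ = eng.step(s)
        assert nxt.F == pytest.approx(6 * F0 / (1 + 5 * F0), rel=1e-12)
    s = eq.__class__(0, 0.5, 0.5, eq.female_freqs, eq.male_freqs)
    nxt, _ = eng.step(s)
    assert nxt.F == pytest.approx(0.857142857142857, rel=1e-12)


def test_release_arithmetic(baseline_low, space):
    s = wildtype_equilibrium(baseline_low)
    out = apply_release(s, combined_release(0.001))
    assert out.M == pytest.approx(1.002, rel=1e-12)
    g = combined_release(0.001)[0].male_genotype
    assert out.male_freqs[g] == pytest.approx(0.002 / 1.002, rel=1e-12)
    # zero-size release leaves the state unchanged
    out0 = apply_release(s, combined_release(0.0))
    assert out0.M == s.M
    assert np.array_equal(out0.male_freqs, s.male_freqs)


def test_separate_release_is_two_cohorts(baseline_low, space):
    s = apply_release(wildtype_equilibrium(baseline_low), separate_release(0.001))
    assert s.M == pytest.approx(1.004, rel=1e-12)
    carriers = [j for j in np.nonzero(s.male_freqs)[0]
                if space.male_genotype(j).y.is_construct
                or any(a.kind == "construct"
                       for a in (space.male_genotype(j).a1, space.male_genotype(j).a2))]
    kinds = set()
    for j in carriers:
        g = space.male_genotype(j)
        kinds.add((g.y.is_construct,
                   any(a.kind == "construct" for a in (g.a1, g.a2))))
    assert kinds == {(True, False), (False, True)}


def test_nonmale_release_rejected(baseline_low, space):
    s = wildtype_equilibrium(baseline_low)
    from doubledrive.dynamics import ReleaseEvent
    with pytest.raises(ValueError):
        apply_release(s, [ReleaseEvent(0, space.n_male + 5, 0.001)])


def test_neutral_alleles_have_constant_frequencies(space):
    """With every molecular process off, allele frequencies never change."""
    p = Params(epsilon_edit=0, epsilon_shred=0, cleave_home=0,
               mu_background=0, mu_homing=0)
    eng = Engine(p)
    s = apply_release(wildtype_equilibrium(p), combined_release(0.05))
    tc = eng.run(initial=s, releases=[], generations=40)
    for col in ("freq_Y_construct", "freq_A_construct"):
        vals = tc[col].to_numpy()
        # one generation mixes the release males into both sexes, then freezes
        assert np.allclose(vals[2:], vals[1], atol=1e-12)
    assert np.allclose(tc["F"].iloc[-1], 1.0, atol=1e-6)


def test_no_census_female_carries_edited_x(space, idealised):
    eng = Engine(idealised)
    s = apply_release(wildtype_equilibrium(idealised), combined_release(0.001))
    edited_female = np.array(
        [any(x.edit_target == "edited"
             for x in (space.female_genotype(i).x1, space.female_genotype(i).x2))
         for i in range(space.n_female)]
    )
    for _ in range(30):
        s, _ = eng.step(s)
        assert float(s.female_freqs @ edited_female) == 0.0


def test_load_wildtype_zero(baseline_low):
    s = wildtype_equilibrium(baseline_low)
    assert reproductive_load(s, baseline_low) == pytest.approx(0.0, abs=1e-12)


def test_load_all_fathers_shredding(space):
    """All fathers carry one intact shredder, no editing: the probability a
    juvenile is a daughter is 0.05/0.55, so L = 1 - 2/11."""
    p = Params.idealised()
    eq = wildtype_equilibrium(p)
    m = np.zeros(space.n_male)
    m[make_male(space, y=0, a=(0, 2))] = 1.0
    s = eq.__class__(0, 1.0, 1.0, eq.female_freqs, m)
    assert reproductive_load(s, p) == pytest.approx(1 - 2 / 11, abs=1e-12)


def test_correlation_release_modes(baseline_low, space):
    eq = wildtype_equilibrium(baseline_low)
    assert construct_correlation(eq) == 0.0  # zero variance convention
    comb = apply_release(eq, combined_release(0.001))
    assert construct_correlation(comb) == pytest.approx(1.0, abs=1e-12)
    sep = apply_release(eq, separate_release(0.001))
    assert construct_correlation(sep) < 0.0


def test_run_timecourse_zero_generations(baseline_low):
    tc = run_timecourse(baseline_low, generations=0)
    assert len(tc) == 1
    assert tc["generation"].iloc[0] == 0


def test_summarize(baseline_low):
    tc = run_timecourse(baseline_low, releases=[], generations=5)
    s = summarize(tc)
    assert s["min_relative_F"] == pytest.approx(1.0, abs=1e-12)
    toy = tc.iloc[:3].copy()
    toy["F"] = [1.0, 0.5, 0.1]
    toy["generation"] = [0, 1, 2]
    s2 = summarize(toy)
    assert s2["min_relative_F"] == 0.1
    assert s2["generation_of_min"] == 2
    with pytest.raises(ValueError):
        summarize(tc.iloc[:0])


def test_standing_resistance_seeding(space):
    p = Params(standing_resistance={"homing_site": 0.5})
    s = wildtype_equilibrium(p)
    pair_freq = {}
    for k, (i, j) in enumerate(space.a_pairs):
        w = s.female_freqs.reshape(space.n_xp, space.n_ap)[0, k] / \
            s.female_freqs.reshape(space.n_xp, space.n_ap)[0].sum()
        if w > 0:
            pair_freq[(i, j)] = w
    assert pair_freq[(0, 0)] == pytest.approx(0.25, abs=1e-12)
    assert pair_freq[(0, 1)] == pytest.approx(0.5, abs=1e-12)
    assert pair_freq[(1, 1)] == pytest.approx(0.25, abs=1e-12)

    p1 = Params(standing_resistance={"homing_site": 1.0})
    s1 = wildtype_equilibrium(p1)
    resistant_pair = int(space.a_pair_index[1, 1])
    assert s1.female_freqs.reshape(space.n_xp, space.n_ap)[0, resistant_pair] == 1.0


def test_equilibrium_requires_growth():
    with pytest.raises(ValueError):
        Params(R_m=0.5)


def test_next_generation_functional_wrapper(baseline_low):
    s = wildtype_equilibrium(baseline_low)
    nxt = next_generation(s, baseline_low)
    assert nxt.generation == 1
    assert nxt.F == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Individual-based stochastic oracle
# ---------------------------------------------------------------------------


def test_oracle_wildtype_neutral_fluctuation(baseline_low):
    tc = individual_based_oracle(baseline_low, N=1_000_000, seed=11,
                                 generations=10, releases=[])
    se = 3.0 / np.sqrt(500_000)
    assert np.all(np.abs(tc["F"].to_numpy() - 1.0) < 5 * se)


def test_oracle_tracks_deterministic_drive(idealised, space):
    """One stochastic generation from each deterministic state agrees with
    the deterministic recursion within binomial sampling error."""
    from doubledrive.fixtures import integerize_counts, stochastic_step

    N = 1_000_000
    half = N // 2
    rng = np.random.default_rng(3)
    eng = Engine(idealised)
    s = apply_release(wildtype_equilibrium(idealised), combined_release(0.001))
    ind_y = np.array([space.male_genotype(j).y.is_construct
                      for j in range(space.n_male)], dtype=float)
    for g in range(10):
        det_next, _ = eng.step(s)
        f_counts = integerize_counts(s.female_freqs, int(round(s.F * half)))
        m_counts = integerize_counts(s.male_freqs, int(round(s.M * half)))
        f1, m1 = stochastic_step(eng, f_counts, m_counts, half, rng)
        p_det = float(det_next.male_freqs @ ind_y)
        p_st = float(m1 @ ind_y) / m1.sum()
        se = np.sqrt(max(p_det * (1 - p_det), 1e-12) / m1.sum())
        assert abs(p_st - p_det) <= 3 * se + 1e-9, g
        assert f1.sum() / half == pytest.approx(det_next.F, abs=15 / np.sqrt(half))
        s = det_next


def test_oracle_seed_determinism(baseline_low):
    a = individual_based_oracle(baseline_low, N=20_000, seed=5, generations=5)
    b = individual_based_oracle(baseline_low, N=20_000, seed=5, generations=5)
    pd.testing.assert_frame_equal(a, b)
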