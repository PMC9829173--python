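"""Scan experiments: resistance sweeps, sensitivity analysis, standing
resistance and design comparisons.

All scans are fully deterministic: each grid point is one run of the
deterministic recursion, and repeated runs are bit-identical.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .alleles import Params, STATE
from .dynamics import (
    Engine,
    combined_release,
    repeated_release,
    summarize,
    wildtype_equilibrium,
)

__all__ = [
    "resistance_probability_sweep",
    "parameter_sensitivity_scan",
    "standing_resistance_scan",
    "extract_thresholds",
    "compare_designs",
]

_EJR = {"low": 0.05, "high": 0.60}


def _baseline(ejr_scenario: str, **overrides) -> Params:
    return Params(ejr=_EJR[ejr_scenario], **overrides)


def resistance_probability_sweep(site: str, grid, ejr_scenario: str = "low",
                                 generations: int | None = None) -> pd.DataFrame:
    """Minimum relative population size vs probability of resistance forming.

    ``site`` is one of 'homing', 'shredding', 'editing'.  For the homing
    site the swept probability is the end-joining rate itself (functional
    resistance at a neutral insertion site is just end-joining repair), so
    ``ejr_scenario`` is ignored there; for shredding and editing the swept
    quantity is the per-event resistant-conversion probability under the
    chosen EJR scenario.
    """
    if site not in ("homing", "shredding", "editing"):
        raise ValueError(f"unknown resistance site {site!r}")
    rows = []
    for prob in grid:
        prob = float(prob)
        if site == "homing":
            p = Params(ejr=prob)
        elif site == "shredding":
            p = _baseline(ejr_scenario, rho_shred_res=prob)
        else:
            p = _baseline(ejr_scenario, rho_edit_res=prob)
        tc = Engine(p).run(generations=generations)
        rows.append({"site": site, "probability": prob,
                     "min_relative_F": float(tc["F"].min())})
    return pd.DataFrame(rows)


def parameter_sensitivity_scan(param_name: str, grid, ejr_scenario: str = "low",
                               R_m: float = 6.0,
                               generations: int | None = None) -> pd.DataFrame:
    """Minimum relative population size as one parameter varies.

    All other parameters stay at baseline for the chosen EJR scenario and
    intrinsic rate of increase (supported alternatives: 2, 6, 12).
    """
    if param_name not in Params.field_names():
        raise ValueError(f"unknown parameter {param_name!r}")
    rows = []
    for value in grid:
        p = _baseline(ejr_scenario, R_m=R_m).replace(**{param_name: value})
        tc = Engine(p).run(generations=generations)
        rows.append({"parameter": param_name, "value": value,
                     "ejr_scenario": ejr_scenario, "R_m": R_m,
                     "min_relative_F": float(tc["F"].min())})
    return pd.DataFrame(rows)


def standing_resistance_scan(site: str, freq_grid=None, ejr_scenario: str = "low",
                             generations: int = 1000,
                             release_fraction: float = 0.001,
                             timecourse_dir=None) -> pd.DataFrame:
    """Outcomes of releases into populations with pre-existing resistance.

    For each initial resistant-allele frequency at the homing or shredding
    site: seed the equilibrium, release 0.1% combined heterozygous males,
    run ``generations`` steps, and record the minimum relative population
    size, peak construct frequencies (any-variant and intact-only), and
    the first generation at which the population is suppressed to 1% of
    its pre-release size (NaN if never).

    The default grid is 0..100% in 1% steps — the resolution at which
    restriction thresholds are quoted.
    """
    if site not in ("homing_site", "shred_site"):
        raise ValueError(f"unknown standing-resistance site {site!r}")
    if freq_grid is None:
        freq_grid = np.arange(0, 101) / 100.0
    base = _baseline(ejr_scenario)
    engine = Engine(base)  # gamete tables do not depend on the initial state
    releases = combined_release(release_fraction)
    rows = []
    for q in freq_grid:
        q = float(q)
        p = base.replace(standing_resistance={site: q})
        init = wildtype_equilibrium(p)
        tc = engine.run(initial=init, releases=releases, generations=generations)
        below = tc.loc[tc["F"] <= 0.01, "generation"]
        rows.append({
            "site": site,
            "ejr_scenario": ejr_scenario,
            "frequency": q,
            "min_relative_F": float(tc["F"].min()),
            "max_freq_Y_construct": float(tc["freq_Y_construct"].max()),
            "max_freq_A_construct": float(tc["freq_A_construct"].max()),
            "max_freq_Y_intact": float(tc["freq_Y_intact"].max()),
            "max_freq_A_intact": float(tc["freq_A_intact"].max()),
            "first_gen_below_1pct": float(below.iloc[0]) if len(below) else np.nan,
        })
        if timecourse_dir is not None:
            from pathlib import Path
            d = Path(timecourse_dir)
            d.mkdir(parents=True, exist_ok=True)
            tc.to_csv(d / f"{site}_{ejr_scenario}_q{q:.2f}.csv", index=False)
    return pd.DataFrame(rows)


def extract_thresholds(table: pd.DataFrame, horizon: int = 50,
                       lower_cut: float = 1e-6,
                       upper_cut: float = 0.95) -> dict[str, float]:
    """Transition-window edges from a standing-resistance scan table.

    * ``lower_edge``: largest scanned frequency whose minimum relative
      population size is still below 1e-6 (near-elimination regime, as
      appropriate for a target population);
    * ``upper_edge``: smallest frequency whose minimum stays above 0.95
      (negligible suppression, as appropriate for a non-target
      population);
    * ``practicable_edge``: smallest frequency at which the population is
      *not* suppressed by >=99% within ``horizon`` generations — the
      frequency the standing allele must stay below for practicable
      control.

    Frequencies are returned as fractions (NaN when no grid point
    qualifies).
    """
    t = table.sort_values("frequency")
    mins = t["min_relative_F"].to_numpy()
    freqs = t["frequency"].to_numpy()
    if not np.all(np.diff(mins) >= -1e-9):
        warnings.warn("min_relative_F not monotone in standing frequency; "
                      "edges computed from the definitions anyway")
    low = freqs[mins < lower_cut]
    high = freqs[mins > upper_cut]
    out = {
        "lower_edge": float(low.max()) if low.size else float("nan"),
        "upper_edge": float(high.min()) if high.size else float("nan"),
    }
    if "first_gen_below_1pct" in t.columns:
        ok = t["first_gen_below_1pct"].to_numpy() <= horizon
        fail = freqs[~ok]
        out["practicable_edge"] = float(fail.min()) if fail.size else float("nan")
    else:
        out["practicable_edge"] = float("nan")
    return out


def compare_designs(generations: int = 50) -> pd.DataFrame:
    """Compare five release strategies built on Y-linked editors.

    The default 50-generation horizon is the timescale on which the
    self-limiting designs act; over much longer horizons a perfect
    trans-acting shredder sits exactly at the self-sustaining knife edge
    and slowly accumulates the editor.

    Strategies (i)-(iv) mirror the earlier self-limiting designs, with
    perfect editing/shredding efficiencies and ASD-homozygous released
    males where an ASD is used; strategy (v) is the double drive analysed
    here (efficiencies 0.95/0.9, heterozygous males):

    i.   YLE alone, repeated 10% releases every generation;
    ii.  YLE alone, single 10% release;
    iii. YLE + non-driving ASD (no homing gRNA), single 10% release;
    iv.  YLE + non-driving ASD, single 0.1% release;
    v.   double drive, single 0.1% release.
    """
    prior = Params.idealised(epsilon_edit=1.0, epsilon_shred=1.0)
    ideal = Params.idealised()
    runs = [
        ("yle_repeated_10pct", prior, repeated_release(0.10, until=generations)),
        ("yle_single_10pct", prior, repeated_release(0.10, until=0)),
        ("yle_nondriving_asd_10pct", prior,
         [r for r in combined_release(0.10, asd="hom_nodrive")]),
        ("yle_nondriving_asd_0.1pct", prior,
         [r for r in combined_release(0.001, asd="hom_nodrive")]),
        ("double_drive_0.1pct", ideal, combined_release(0.001)),
    ]
    rows = []
    for name, p, releases in runs:
        tc = Engine(p).run(releases=releases, generations=generations)
        s = summarize(tc)
        rows.append({"strategy": name,
                     "min_relative_F": s["min_relative_F"],
                     "generation_of_min": s["generation_of_min"],
                     "max_load": s["max_load"]})
    return pd.DataFrame(rows)
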