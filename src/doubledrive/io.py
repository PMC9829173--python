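"""Configuration files and tabular input/output.

Configs are flat ``key = value`` text files whose keys mirror the
``Params`` field names exactly (``#`` comments and blank lines allowed).
``ejr`` additionally accepts the scenario names ``low``/``high`` (0.05 /
0.60).  Standing resistance is given as ``standing_resistance.homing_site``
/ ``standing_resistance.shred_site`` keys.

Timecourses round-trip through CSV at 15 significant digits with a stable
column order.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .alleles import EJR_HIGH, EJR_LOW, Params
from .dynamics import TIMECOURSE_COLUMNS

__all__ = [
    "load_config",
    "params_from_config",
    "load_params",
    "write_timecourse",
    "read_timecourse",
]

_EJR_NAMES = {"low": EJR_LOW, "high": EJR_HIGH}


def load_config(path) -> dict[str, str]:
    """Parse a flat key = value file into a string mapping."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def params_from_config(config: dict[str, str]) -> Params:
    """Build a validated ``Params`` from a string mapping.

    Unknown keys and out-of-range values raise ``ValueError`` naming the
    offending key.
    """
    kwargs: dict = {}
    standing: dict[str, float] = {}
    valid = set(Params.field_names())
    for key, value in config.items():
        if key.startswith("standing_resistance."):
            site = key.split(".", 1)[1]
            if site not in ("homing_site", "shred_site"):
                raise ValueError(f"unknown config key {key!r}")
            standing[site] = float(value)
            continue
        if key not in valid or key == "standing_resistance":
            raise ValueError(f"unknown config key {key!r}")
        if key == "generations":
            kwargs[key] = int(value)
        elif key == "ejr" and value in _EJR_NAMES:
            kwargs[key] = _EJR_NAMES[value]
        else:
            kwargs[key] = float(value)
    if standing:
        kwargs["standing_resistance"] = standing
    try:
        return Params(**kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def load_params(path) -> Params:
    return params_from_config(load_config(path))


def write_timecourse(tc: pd.DataFrame, path) -> None:
    """Write a timecourse CSV (15 significant digits, stable columns)."""
    cols = [c for c in TIMECOURSE_COLUMNS if c in tc.columns]
    tc.loc[:, cols].to_csv(path, index=False, float_format="%.15g")


def read_timecourse(path) -> pd.DataFrame:
    # the default C-parser float conversion is lossy; ask for exact parsing
    return pd.read_csv(path, float_precision="round_trip")
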