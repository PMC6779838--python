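"""Access to the packaged reference tables.

The package ships four small CSV fixtures transcribing published reference
values for the Olympic taekwondo corpus: the 9-category alphabet, the per-sex
adjusted-residual (z-score) matrices, the per-sex significant-pattern table
(pair, observed count, within-block rank), and the per-sex marginal action
counts.  The raw coded sequences themselves are not public, so these tables
are the ground truth the rest of the package is checked against.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .event_data import ActionCode, Alphabet, SEXES, TKDOT

__all__ = [
    "FIXTURE_FILES",
    "fixture_path",
    "load_alphabet",
    "load_marginals",
    "load_zscores",
    "load_patterns",
]

FIXTURE_FILES = (
    "table1_alphabet.csv",
    "table2_zscores.csv",
    "table3_patterns.csv",
    "results_marginals.csv",
)


def fixture_path(name: str):
    """Traversable path of a packaged fixture file."""
    if name not in FIXTURE_FILES:
        raise FileNotFoundError(f"unknown fixture {name!r}; have {FIXTURE_FILES}")
    return resources.files("tkdseq.fixtures").joinpath(name)


def _read(name: str) -> pd.DataFrame:
    with fixture_path(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_alphabet() -> Alphabet:
    """The 9-code alphabet with labels and tactical classes."""
    df = _read("table1_alphabet.csv")
    return Alphabet(
        ActionCode(r.code, r.label, r.tactical_class) for r in df.itertuples()
    )


def load_marginals(sex: str) -> pd.Series:
    """Per-code action counts for one sex group, in canonical code order."""
    _check_sex(sex)
    df = _read("results_marginals.csv")
    s = df[df["sex"] == sex].set_index("code")["count"]
    return s.reindex(list(TKDOT.codes)).astype(int)


def load_zscores(sex: str) -> pd.DataFrame:
    """The 9x9 adjusted-residual matrix for one sex (rows focal, cols conditioned)."""
    _check_sex(sex)
    df = _read("table2_zscores.csv")
    mat = (
        df[df["sex"] == sex]
        .pivot(index="focal", columns="conditioned", values="z")
        .reindex(index=list(TKDOT.codes), columns=list(TKDOT.codes))
    )
    if mat.isna().any().any():
        raise ValueError(f"z-score fixture incomplete for sex {sex!r}")
    return mat


def load_patterns(sex: str | None = None) -> pd.DataFrame:
    """The significant-pattern table; optionally restricted to one sex.

    Restricted form has columns ``pattern, focal, conditioned, count, order``
    with absent-for-this-sex rows dropped; counts and orders are integers.
    """
    df = _read("table3_patterns.csv")
    if sex is None:
        return df
    _check_sex(sex)
    out = df[["pattern", "focal", "conditioned", f"{sex}_count", f"{sex}_order"]]
    out = out.rename(columns={f"{sex}_count": "count", f"{sex}_order": "order"})
    out = out.dropna(subset=["count"]).copy()
    out["count"] = out["count"].astype(int)
    out["order"] = out["order"].astype(int)
    return out.reset_index(drop=True)


def _check_sex(sex: str) -> None:
    if sex not in SEXES:
        raise ValueError(f"sex {sex!r} not in {list(SEXES)}")
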