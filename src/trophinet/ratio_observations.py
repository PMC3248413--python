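"""Treatment-ratio observations from paired half-field counts.

Each species/site pair carries a year-total count under each of the two
herbicide treatments of a split field.  Counts are log-transformed as
``L = log10(count + 1)``; the geometric treatment ratio ``R = 10**(L2 - L1)``
compares the GMHT half-field (treatment 2) with the conventional one
(treatment 1).  Ratios beyond a +/-50% band become the directional
observations ``abundance(X, S, up)`` / ``abundance(X, S, down)`` that the
abduction engine explains.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple, Union

import numpy as np
import pandas as pd

from .config import AnalysisConfig

CONVENTIONAL = "conventional"
GMHT = "gmht"
TREATMENTS = (CONVENTIONAL, GMHT)

UP = "up"
DOWN = "down"
NONE = "none"

COUNT_COLUMNS = ["species_id", "site_id", "treatment", "count"]


class CountRecord(NamedTuple):
    """One year-total count for a species in one half-field."""

    species_id: str
    site_id: str
    treatment: str
    count: int


class DirectionObservation(NamedTuple):
    """The observable predicate ``abundance(species, site, up|down)``."""

    species_id: str
    site_id: str
    direction: str


def log_count(count: int) -> float:
    """Log-transform a count as ``log10(count + 1)``.

    The +1 offset keeps zero counts finite: ``log_count(0) == 0.0``.
    """
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return math.log10(count + 1)


def filter_site(c1: int, c2: int, cfg: AnalysisConfig) -> bool:
    """Return True when a species/site pair is retained for learning.

    Pairs whose two half-field counts sum to at most ``cfg.site_filter_sum``
    (default 1) are too sparse to carry a meaningful ratio and are removed.
    """
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    return (c1 + c2) > cfg.site_filter_sum


def treatment_ratio(L1: float, L2: float) -> float:
    """Geometric treatment ratio ``R = 10**(L2 - L1)``."""
    return 10.0 ** (L2 - L1)


def classify_direction(R: float, cfg: AnalysisConfig) -> str:
    """Classify a ratio as ``up``, ``down`` or ``none``.

    The inequalities are strict: a ratio exactly at a threshold is ``none``.
    """
    if R <= 0:
        raise ValueError("ratio must be positive")
    if R > cfg.up_threshold:
        return UP
    if R < cfg.down_threshold:
        return DOWN
    return NONE


def _normalise_counts(counts: Union[pd.DataFrame, Iterable[CountRecord]]) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        df = counts.loc[:, COUNT_COLUMNS].copy()
    else:
        df = pd.DataFrame(list(counts), columns=COUNT_COLUMNS)
    if len(df) == 0:
        return df
    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        raise ValueError(
            f"unknown treatment values: {sorted(df.loc[bad_treat, 'treatment'].unique())}"
        )
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    dup = df.duplicated(subset=["species_id", "site_id", "treatment"])
    if dup.any():
        rows = df.loc[dup, ["species_id", "site_id", "treatment"]].iloc[0]
        raise ValueError(
            "duplicate count row for "
            f"({rows['species_id']}, {rows['site_id']}, {rows['treatment']})"
        )
    return df


def build_ratio_table(
    counts: Union[pd.DataFrame, Iterable[CountRecord]],
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Compute per species/site log counts, ratio and direction.

    A treatment row absent for a species/site pair is imputed as count 0: a
    species missing from one half-field is itself an observation of absence,
    not missing data.  Pairs failing the site filter are dropped.  The result
    is sorted lexicographically by (site_id, species_id) — the canonical
    observation order that permutations reshuffle.

    Returns a DataFrame with columns
    ``species_id, site_id, count_conventional, count_gmht, L1, L2, d, R,
    direction``.
    """
    df = _normalise_counts(counts)
    if len(df) == 0:
        return pd.DataFrame(
            columns=[
                "species_id", "site_id", "count_conventional", "count_gmht",
                "L1", "L2", "d", "R", "direction",
            ]
        )
    wide = df.pivot(index=["species_id", "site_id"], columns="treatment", values="count")
    for t in TREATMENTS:
        if t not in wide.columns:
            wide[t] = np.nan
    wide = wide[list(TREATMENTS)].fillna(0).astype(np.int64).reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={CONVENTIONAL: "count_conventional", GMHT: "count_gmht"})

    c1 = wide["count_conventional"].to_numpy()
    c2 = wide["count_gmht"].to_numpy()
    retained = (c1 + c2) > cfg.site_filter_sum
    wide = wide.loc[retained].copy()

    wide["L1"] = np.log10(wide["count_conventional"] + 1.0)
    wide["L2"] = np.log10(wide["count_gmht"] + 1.0)
    wide["d"] = wide["L2"] - wide["L1"]
    wide["R"] = 10.0 ** wide["d"]
    wide["direction"] = np.select(
        [wide["R"] > cfg.up_threshold, wide["R"] < cfg.down_threshold],
        [UP, DOWN],
        default=NONE,
    )
    wide = wide.sort_values(["site_id", "species_id"], kind="mergesort").reset_index(drop=True)
    return wide


def build_observations(
    counts: Union[pd.DataFrame, Iterable[CountRecord]],
    cfg: AnalysisConfig,
) -> list[DirectionObservation]:
    """Turn a count table into the directional observation list.

    Composition of the site filter, log transform, ratio and direction
    classification; pairs classed ``none`` are dropped.  Output order is
    lexicographic by (site_id, species_id).
    """
    table = build_ratio_table(counts, cfg)
    keep = table[table["direction"] != NONE]
    return [
        DirectionObservation(r.species_id, r.site_id, r.direction)
        for r in keep.itertuples(index=False)
    ]


def canonical_order(observations: Iterable[DirectionObservation]) -> list[DirectionObservation]:
    """Sort observations into the canonical (site_id, species_id) order."""
    return sorted(observations, key=lambda o: (o.site_id, o.species_id))
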