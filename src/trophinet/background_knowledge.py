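"""Background predicates constraining the search for trophic links.

Three relations filter which predator/prey pairs may ever be linked:

* ``predator(X)`` — consumer/non-consumer status from a trait table;
* ``bigger_than(X, Y)`` — strict body-size ordering on a 1-4 class scale
  ("big things eat small things"), which caps any food chain at four levels;
* ``co_occurs(S, X, Y)`` — the pair was jointly present at one or more
  suction-sample points of site S.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Union

import pandas as pd

SIZE_CLASSES = (1, 2, 3, 4)

POINT_COLUMNS = ["site_id", "point_id", "species_id", "count"]
TRAIT_COLUMNS = ["species_id", "name", "is_predator", "size_class"]


@dataclass(frozen=True)
class SpeciesTaxon:
    """Trait record for one species or higher-order taxon."""

    species_id: str
    name: str
    is_predator: bool
    size_class: int

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(
                f"size_class must be in {SIZE_CLASSES}, got {self.size_class} "
                f"for {self.species_id}"
            )


TraitTable = Mapping[str, SpeciesTaxon]


def traits_from_records(records: Iterable[SpeciesTaxon]) -> dict[str, SpeciesTaxon]:
    out: dict[str, SpeciesTaxon] = {}
    for rec in records:
        if rec.species_id in out:
            raise ValueError(f"duplicate trait record for {rec.species_id}")
        out[rec.species_id] = rec
    return out


def co_occurs_at_point(count_x: int, count_y: int) -> bool:
    """Both species present (count >= 1) in the same suction sample."""
    if count_x < 0 or count_y < 0:
        raise ValueError("counts must be non-negative")
    return count_x >= 1 and count_y >= 1


def bigger_than(x: SpeciesTaxon, y: SpeciesTaxon) -> bool:
    """Strict size ordering: X can only eat strictly smaller classes.

    Equal-size pairs are never comparable, which also rules out cannibalism
    and makes every admissible link set acyclic.
    """
    return x.size_class > y.size_class


class CoOccurrenceTable:
    """Site-level co-occurrence scores for unordered species pairs.

    The score of a pair at a site is the number of sample points where both
    species had count >= 1.  The predicate ``co_occurs(S, X, Y)`` is true
    when the score is at least 1 and X != Y; self-pair scores are retained
    for diagnostics but excluded from predicate use.
    """

    def __init__(
        self,
        scores: Mapping[tuple[str, frozenset], int],
        n_points_per_site: Mapping[str, int] | None = None,
    ) -> None:
        self._scores = dict(scores)
        self.n_points_per_site = dict(n_points_per_site or {})

    def score(self, site_id: str, x: str, y: str) -> int:
        return self._scores.get((site_id, frozenset((x, y))), 0)

    def co_occurs(self, site_id: str, x: str, y: str) -> bool:
        return x != y and self.score(site_id, x, y) >= 1

    def sites(self) -> set[str]:
        return {site for site, _ in self._scores}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoOccurrenceTable):
            return NotImplemented
        return self._scores == other._scores

    def __len__(self) -> int:
        return len(self._scores)

    @classmethod
    def from_points(cls, points: pd.DataFrame) -> "CoOccurrenceTable":
        """Build the table from per-sample-point counts.

        ``points`` has columns site_id, point_id, species_id, count; a
        (site, point, species) triple must appear at most once.
        """
        missing = [c for c in POINT_COLUMNS if c not in points.columns]
        if missing:
            raise ValueError(f"point table missing columns: {missing}")
        if (points["count"] < 0).any():
            raise ValueError("point counts must be non-negative")
        dup = points.duplicated(subset=["site_id", "point_id", "species_id"])
        if dup.any():
            row = points.loc[dup].iloc[0]
            raise ValueError(
                "duplicate sample-point row for "
                f"({row['site_id']}, {row['point_id']}, {row['species_id']})"
            )
        scores: dict[tuple[str, frozenset], int] = {}
        n_points: dict[str, int] = {}
        present = points[points["count"] >= 1]
        for site, site_df in points.groupby("site_id", sort=False):
            n_points[str(site)] = site_df["point_id"].nunique()
        for (site, _point), grp in present.groupby(["site_id", "point_id"], sort=False):
            species = sorted(grp["species_id"].unique())
            for x, y in combinations_with_replacement(species, 2):
                key = (str(site), frozenset((x, y)))
                scores[key] = scores.get(key, 0) + 1
        return cls(scores, n_points)

    @classmethod
    def from_site_counts(cls, counts: pd.DataFrame) -> "CoOccurrenceTable":
        """Fallback when no sample-point data exist.

        Two species co-occur at a site when both year totals (summed over
        the two half-fields) are >= 1.  This is a superset of the point-level
        predicate: joint presence at a point implies positive site totals.
        """
        totals = (
            counts.groupby(["site_id", "species_id"])["count"].sum().reset_index()
        )
        present = totals[totals["count"] >= 1]
        scores: dict[tuple[str, frozenset], int] = {}
        for site, grp in present.groupby("site_id", sort=False):
            species = sorted(grp["species_id"].unique())
            for x, y in combinations_with_replacement(species, 2):
                scores[(str(site), frozenset((x, y)))] = 1
        return cls(scores, {site: 1 for site in present["site_id"].unique()})


def build_cooccurrence(
    points: Union[pd.DataFrame, None],
    counts: pd.DataFrame | None = None,
) -> CoOccurrenceTable:
    """Point-level co-occurrence when sample points exist, else the
    site-total fallback."""
    if points is not None and len(points) > 0:
        return CoOccurrenceTable.from_points(points)
    if counts is None:
        raise ValueError("need either sample-point data or site counts")
    return CoOccurrenceTable.from_site_counts(counts)
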