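"""Greedy cover-set abduction of ground ``eats(X, Y)`` hypotheses.

The explanatory theory is the rule pair

    abundance(X, S, up)   if  predator(X) and co_occurs(S, X, Y) and
                              bigger_than(X, Y) and abundance(Y, S, up)
                              and eats(X, Y).
    abundance(X, S, down) if  ...same body with down...

``eats`` is the abducible: it is entirely undefined before learning and
ground facts are hypothesised to entail the directional observations.
The engine scans observations in a given order and, for each not yet
explained, adopts the candidate ``eats`` fact that covers the most still
unexplained observations across the whole data set (ties broken
deterministically).  Different scan orders explore different parts of the
hypothesis space, which is what the permutation ensemble exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .background_knowledge import CoOccurrenceTable, SpeciesTaxon, bigger_than
from .ratio_observations import DirectionObservation

Pair = tuple[str, str]  # (predator_id, prey_id)


@dataclass(frozen=True)
class EatsHypothesis:
    """An abduced ground fact ``eats(predator, prey)`` with its support."""

    predator_id: str
    prey_id: str
    support: frozenset[DirectionObservation] = frozenset()
    probability: float | None = None

    @property
    def n_support_up(self) -> int:
        return sum(1 for o in self.support if o.direction == "up")

    @property
    def n_support_down(self) -> int:
        return sum(1 for o in self.support if o.direction == "down")


@dataclass
class TrophicNetwork:
    """One learnt link set plus the observations no link could explain."""

    links: dict[Pair, EatsHypothesis] = field(default_factory=dict)
    uncovered: frozenset[DirectionObservation] = frozenset()

    @property
    def link_pairs(self) -> set[Pair]:
        return set(self.links)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for (pred, prey), hyp in self.links.items():
            g.add_edge(pred, prey, n_support_up=hyp.n_support_up,
                       n_support_down=hyp.n_support_down)
        return g


def _check_traits(species: Iterable[str], traits: Mapping[str, SpeciesTaxon]) -> None:
    missing = sorted({s for s in species if s not in traits})
    if missing:
        raise KeyError(f"species missing from trait table: {missing}")


class ExplanationIndex:
    """Which observations each admissible ``eats`` fact explains.

    Given a fixed observation context, the set of observations a link
    (X, Y) explains does not depend on scan order, so it is precomputed
    once and shared by every permutation of the same training data.
    """

    def __init__(
        self,
        observations: Iterable[DirectionObservation],
        traits: Mapping[str, SpeciesTaxon],
        cooccurrence: CoOccurrenceTable,
    ) -> None:
        self.observations = tuple(observations)
        obs_set = frozenset(self.observations)
        _check_traits((o.species_id for o in self.observations), traits)

        by_species: dict[str, list[DirectionObservation]] = {}
        for o in self.observations:
            by_species.setdefault(o.species_id, []).append(o)
        species = sorted(by_species)

        self.explained: dict[Pair, frozenset[DirectionObservation]] = {}
        self._candidates: dict[DirectionObservation, set[Pair]] = {}
        for x in species:
            tx = traits[x]
            if not tx.is_predator:
                continue
            for y in species:
                if y == x or not bigger_than(tx, traits[y]):
                    continue
                ex = frozenset(
                    o
                    for o in by_species[x]
                    if DirectionObservation(y, o.site_id, o.direction) in obs_set
                    and cooccurrence.co_occurs(o.site_id, x, y)
                )
                if ex:
                    self.explained[(x, y)] = ex
                    for o in ex:
                        self._candidates.setdefault(o, set()).add((x, y))

    def candidates_for(self, obs: DirectionObservation) -> set[Pair]:
        return set(self._candidates.get(obs, set()))


def candidate_explanations(
    obs: DirectionObservation,
    traits: Mapping[str, SpeciesTaxon],
    cooccurrence: CoOccurrenceTable,
    all_observations: Iterable[DirectionObservation],
) -> set[Pair]:
    """All ground ``eats(obs.species, Y)`` facts that would explain ``obs``.

    A pair qualifies when the full rule body holds at ``obs.site_id`` with
    ``obs.direction``: the observed species is a predator, strictly bigger
    than Y, co-occurring with Y at the site, and Y itself has a
    matching-direction observation there.  Empty when the species is not a
    predator.
    """
    all_obs = list(all_observations)
    _check_traits([obs.species_id] + [o.species_id for o in all_obs], traits)
    tx = traits[obs.species_id]
    if not tx.is_predator:
        return set()
    out: set[Pair] = set()
    for other in all_obs:
        y = other.species_id
        if (
            y != obs.species_id
            and other.site_id == obs.site_id
            and other.direction == obs.direction
            and bigger_than(tx, traits[y])
            and cooccurrence.co_occurs(obs.site_id, obs.species_id, y)
        ):
            out.add((obs.species_id, y))
    return out


def learn_network(
    observations: Sequence[DirectionObservation],
    traits: Mapping[str, SpeciesTaxon],
    cooccurrence: CoOccurrenceTable,
    *,
    index: ExplanationIndex | None = None,
) -> TrophicNetwork:
    """Greedy cover-set abduction over the observations in the given order.

    For each observation not yet covered, every candidate ``eats`` fact is
    scored by the number of currently unexplained observations (over the
    whole data set) it would explain; the best is adopted and all the
    observations it explains — past and future in the scan — are marked
    covered.  Ties break by smaller prey size class, then prey id, then
    predator id, so a given order fully determines the network.
    Observations with no candidate under the rule body stay ``uncovered``.
    """
    if index is None:
        index = ExplanationIndex(observations, traits, cooccurrence)
    covered: set[DirectionObservation] = set()
    links: dict[Pair, EatsHypothesis] = {}
    for obs in observations:
        if obs in covered:
            continue
        cands = index.candidates_for(obs)
        if not cands:
            continue

        def sort_key(pair: Pair) -> tuple:
            x, y = pair
            gain = len(index.explained[pair] - covered)
            return (-gain, traits[y].size_class, y, x)

        best = min(cands, key=sort_key)
        covered |= index.explained[best]
        links[best] = EatsHypothesis(best[0], best[1], support=index.explained[best])
    uncovered = frozenset(o for o in observations if o not in covered)
    return TrophicNetwork(links=links, uncovered=uncovered)


def entailing_links(
    link_pairs: Iterable[Pair],
    species_id: str,
    site_id: str,
    direction: str,
    context: Iterable[DirectionObservation],
    traits: Mapping[str, SpeciesTaxon],
    cooccurrence: CoOccurrenceTable,
) -> list[Pair]:
    """Links that imply ``abundance(species, site, direction)`` given context."""
    ctx = frozenset(context)
    tx = traits.get(species_id)
    if tx is None:
        raise KeyError(f"species missing from trait table: ['{species_id}']")
    if not tx.is_predator:
        return []
    out = []
    for x, y in link_pairs:
        if x != species_id or y not in traits:
            continue
        if (
            bigger_than(tx, traits[y])
            and cooccurrence.co_occurs(site_id, x, y)
            and DirectionObservation(y, site_id, direction) in ctx
        ):
            out.append((x, y))
    return out


def entails(
    network: TrophicNetwork,
    obs: DirectionObservation,
    context: Iterable[DirectionObservation],
    traits: Mapping[str, SpeciesTaxon],
    cooccurrence: CoOccurrenceTable,
) -> bool:
    """True when some network link explains ``obs`` under the rule body."""
    return bool(
        entailing_links(
            network.links, obs.species_id, obs.site_id, obs.direction,
            context, traits, cooccurrence,
        )
    )


def max_path_nodes(network: TrophicNetwork) -> int:
    """Node count of the longest directed path (the trophic-chain length).

    Links point predator -> prey with strictly decreasing size classes, so
    the learnt graph is a DAG and this is well defined; 0 for an empty
    network.
    """
    g = network.to_digraph()
    if g.number_of_nodes() == 0:
        return 0
    return len(nx.dag_longest_path(g))
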