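"""Independent brute-force oracles for the abduction rule body.

These enumerate the explanatory rule directly from its logical definition,
without using the package's candidate index or greedy engine, so they can
certify candidate enumeration, entailment and cover soundness on small
instances.
"""

from __future__ import annotations

import numpy as np

from trophinet import CoOccurrenceTable, DirectionObservation, SpeciesTaxon


def oracle_candidates(obs, traits, cooc, all_observations):
    """Exhaustive enumeration of the rule body for one observation."""
    x = obs.species_id
    if not traits[x].is_predator:
        return set()
    out = set()
    for other in all_observations:
        y = other.species_id
        if y == x:
            continue
        if other.site_id != obs.site_id or other.direction != obs.direction:
            continue
        if traits[x].size_class <= traits[y].size_class:
            continue
        if not cooc.co_occurs(obs.site_id, x, y):
            continue
        out.add((x, y))
    return out


def oracle_entails(link_pairs, obs, context, traits, cooc):
    """Direct quantifier loop over the rule body for a fixed link set."""
    ctx = set(context)
    for x, y in link_pairs:
        if (
            x == obs.species_id
            and traits[x].is_predator
            and traits[x].size_class > traits[y].size_class
            and cooc.co_occurs(obs.site_id, x, y)
            and DirectionObservation(y, obs.site_id, obs.direction) in ctx
        ):
            return True
    return False


def random_instance(rng: np.random.Generator):
    """A random small world: traits, observations and co-occurrence truth."""
    n_species = int(rng.integers(2, 7))
    n_sites = int(rng.integers(1, 9))
    species = [f"x{i}" for i in range(n_species)]
    sites = [f"s{j}" for j in range(n_sites)]
    traits = {
        s: SpeciesTaxon(s, s, bool(rng.random() < 0.5), int(rng.integers(1, 5)))
        for s in species
    }
    observations = [
        DirectionObservation(s, site, "up" if rng.random() < 0.5 else "down")
        for site in sites
        for s in species
        if rng.random() < 0.5
    ]
    scores = {}
    for site in sites:
        for i, x in enumerate(species):
            for y in species[i:]:
                if rng.random() < 0.6:
                    scores[(site, frozenset((x, y)))] = int(rng.integers(1, 4))
    return traits, observations, CoOccurrenceTable(scores)


def random_link_set(rng: np.random.Generator, traits):
    """A random subset of the admissible (predator, smaller prey) pairs."""
    pairs = [
        (x, y)
        for x in traits
        for y in traits
        if x != y
        and traits[x].is_predator
        and traits[x].size_class > traits[y].size_class
    ]
    return {p for p in pairs if rng.random() < 0.4}
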