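"""Link probabilities as relative frequency across permutation runs.

The greedy abduction engine is order-dependent: scanning the training
observations in a different order seeds a different part of the hypothesis
space and can yield a different network.  Learning one network per random
permutation of the data and scoring each distinct ``eats`` fact by the
fraction of networks that contain it gives a probability per link —
stable links appear under every ordering, order artefacts only rarely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .abduction_engine import (
    EatsHypothesis,
    ExplanationIndex,
    Pair,
    TrophicNetwork,
    learn_network,
)
from .background_knowledge import CoOccurrenceTable, SpeciesTaxon
from .config import AnalysisConfig
from .ratio_observations import DirectionObservation, canonical_order


@dataclass
class PermutationEnsemble:
    """N networks learnt from reordered training data, with per-link counts."""

    networks: list[TrophicNetwork] = field(default_factory=list)
    link_frequency: dict[Pair, int] = field(default_factory=dict)
    n_permutations: int = 0
    rng_seed: int = 0

    def probability(self, pair: Pair) -> float:
        """Relative frequency of the link; 0.0 when it was never learnt."""
        return self.link_frequency.get(pair, 0) / self.n_permutations

    def probabilistic_links(self) -> list[EatsHypothesis]:
        """Distinct links with probabilities, pooling support across networks."""
        support: dict[Pair, set[DirectionObservation]] = {}
        for net in self.networks:
            for pair, hyp in net.links.items():
                support.setdefault(pair, set()).update(hyp.support)
        return [
            EatsHypothesis(
                pair[0], pair[1],
                support=frozenset(support[pair]),
                probability=count / self.n_permutations,
            )
            for pair, count in sorted(self.link_frequency.items())
        ]


def permute_observations(
    observations: Iterable[DirectionObservation],
    seed: int,
    k: int,
) -> list[DirectionObservation]:
    """Reproducible random order of the observations for permutation ``k``.

    ``k = 0`` is the canonical lexicographic (site, species) order itself;
    ``k >= 1`` draws a uniform permutation from an RNG stream keyed by
    ``(seed, k)``, so permutations are independent across k and identical
    across repeated calls.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if k < 0:
        raise ValueError("permutation index must be non-negative")
    canonical = canonical_order(observations)
    if k == 0:
        return canonical
    rng = np.random.default_rng([seed, k])
    idx = rng.permutation(len(canonical))
    return [canonical[i] for i in idx]


def build_ensemble(
    observations: Sequence[DirectionObservation],
    traits: Mapping[str, SpeciesTaxon],
    cooccurrence: CoOccurrenceTable,
    cfg: AnalysisConfig,
) -> PermutationEnsemble:
    """Learn one network per permutation and aggregate link frequencies.

    With ``cfg.n_permutations == 1`` this is exactly one ``learn_network``
    call on the canonical order.  Permutations are sampled with replacement
    from the permutation space (duplicates possible), with permutation 0
    always the canonical order.
    """
    canonical = canonical_order(observations)
    index = ExplanationIndex(canonical, traits, cooccurrence)
    networks: list[TrophicNetwork] = []
    freq: Counter = Counter()
    for k in range(cfg.n_permutations):
        order = permute_observations(canonical, cfg.rng_seed, k)
        net = learn_network(order, traits, cooccurrence, index=index)
        networks.append(net)
        freq.update(net.links.keys())
    return PermutationEnsemble(
        networks=networks,
        link_frequency=dict(freq),
        n_permutations=cfg.n_permutations,
        rng_seed=cfg.rng_seed,
    )
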