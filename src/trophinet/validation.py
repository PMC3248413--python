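"""Leave-one-out cross-validation of direction predictions.

Each directional observation of a predator species is held out in turn;
the network (or ensemble) is relearnt from the remaining observations and
asked whether the held-out abundance went up or down.  Three prediction
modes are compared:

* ``probabilistic`` — sum the ensemble probabilities of links entailing
  *up* vs *down* and take the larger;
* ``nonprobabilistic`` — a single network learnt from the canonical order,
  comparing the raw counts of entailing links;
* ``majority`` — always predict the training data's majority direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abduction_engine import entailing_links, learn_network
from .background_knowledge import CoOccurrenceTable, SpeciesTaxon
from .config import AnalysisConfig
from .probability_ensemble import PermutationEnsemble, build_ensemble
from .ratio_observations import DOWN, UP, DirectionObservation, canonical_order

MODES = ("probabilistic", "nonprobabilistic", "majority")


@dataclass
class CVResult:
    n_folds: int
    n_correct: int
    accuracy: float  # percent
    se: float  # percent
    mode: str
    per_fold: list[tuple[DirectionObservation, str, bool]] = field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "mode": self.mode,
            "accuracy": self.accuracy,
            "se": self.se,
            "n_folds": self.n_folds,
        }

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species_id": o.species_id,
                    "site_id": o.site_id,
                    "observed": o.direction,
                    "predicted": pred,
                    "correct": ok,
                }
                for o, pred, ok in self.per_fold
            ]
        )


def accuracy_se(n_correct: int, n_folds: int) -> float:
    """Binomial standard error of the accuracy, in percent."""
    if n_folds <= 0:
        raise ValueError("n_folds must be positive")
    if not 0 <= n_correct <= n_folds:
        raise ValueError("n_correct must lie in [0, n_folds]")
    p = n_correct / n_folds
    return 100.0 * math.sqrt(p * (1.0 - p) / n_folds)


def majority_direction(observations: Iterable[DirectionObservation]) -> str:
    """Most common direction in the training data; ties break to ``down``."""
    n_up = sum(1 for o in observations if o.direction == UP)
    n_down = sum(1 for o in observations if o.direction == DOWN)
    return UP if n_up > n_down else DOWN


def predict_direction(
    test_key: tuple[str, str],
    ensemble: PermutationEnsemble,
    context: Iterable[DirectionObservation],
    traits: Mapping[str, SpeciesTaxon],
    cooccurrence: CoOccurrenceTable,
    majority: str,
) -> str:
    """Probabilistic direction prediction for a held-out (species, site).

    Sums link probabilities over the distinct ensemble links that would
    entail an *up* observation given the context, likewise for *down*, and
    predicts the larger side; when both scores tie (including both zero)
    the majority class is returned.
    """
    species_id, site_id = test_key
    ctx = list(context)
    scores = {}
    for direction in (UP, DOWN):
        links = entailing_links(
            ensemble.link_frequency, species_id, site_id, direction,
            ctx, traits, cooccurrence,
        )
        scores[direction] = sum(ensemble.probability(p) for p in links)
    if scores[UP] > scores[DOWN]:
        return UP
    if scores[DOWN] > scores[UP]:
        return DOWN
    return majority


def _fold_seed(master_seed: int, fold: int) -> int:
    """Fold-indexed seed derived from the master seed, below 2**31."""
    state = np.random.SeedSequence([master_seed, fold]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def loo_crossvalidate(
    observations: Sequence[DirectionObservation],
    traits: Mapping[str, SpeciesTaxon],
    cooccurrence: CoOccurrenceTable,
    cfg: AnalysisConfig,
    mode: str = "probabilistic",
) -> CVResult:
    """Leave-one-out cross-validation over predator observations.

    Every observation whose species is flagged a predator becomes one fold;
    non-predator observations are never test cases but always remain in the
    training data (they are the prey evidence).  The held-out observation is
    removed from training and from the entailment context of its own
    prediction.  In probabilistic mode the ensemble is rebuilt per fold with
    a fold-indexed seed derived from ``cfg.rng_seed``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    obs = canonical_order(observations)
    folds = [o for o in obs if traits[o.species_id].is_predator]
    if len(folds) < 2:
        raise ValueError(
            f"need at least 2 predator observations for cross-validation, "
            f"got {len(folds)}"
        )
    per_fold: list[tuple[DirectionObservation, str, bool]] = []
    for i, held in enumerate(folds):
        training = [o for o in obs if o != held]
        majority = majority_direction(training)
        if mode == "majority":
            predicted = majority
        elif mode == "nonprobabilistic":
            net = learn_network(training, traits, cooccurrence)
            n_up = len(entailing_links(
                net.links, held.species_id, held.site_id, UP,
                training, traits, cooccurrence))
            n_down = len(entailing_links(
                net.links, held.species_id, held.site_id, DOWN,
                training, traits, cooccurrence))
            if n_up > n_down:
                predicted = UP
            elif n_down > n_up:
                predicted = DOWN
            else:
                predicted = majority
        else:
            fold_cfg = replace(cfg, rng_seed=_fold_seed(cfg.rng_seed, i))
            ensemble = build_ensemble(training, traits, cooccurrence, fold_cfg)
            predicted = predict_direction(
                (held.species_id, held.site_id), ensemble, training,
                traits, cooccurrence, majority,
            )
        per_fold.append((held, predicted, predicted == held.direction))
    n_correct = sum(1 for _, _, ok in per_fold if ok)
    n_folds = len(per_fold)
    return CVResult(
        n_folds=n_folds,
        n_correct=n_correct,
        accuracy=100.0 * n_correct / n_folds,
        se=accuracy_se(n_correct, n_folds),
        mode=mode,
        per_fold=per_fold,
    )
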