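"""Synthetic split-field ecosystems with a known food web.

The generator emulates the conceptual model behind the learning task: a
management perturbation hits basal (prey-less) species independently at
each site, and the treatment response of a consumer tracks the mean
response of its prey, so that log treatment ratios of trophically linked
species are positively correlated across sites.  Because the ground-truth
web is known, link recovery and cross-validation behaviour can be measured
exactly — something the undeposited field data never allow.

All effects live on the log10 scale, so simulated ``d`` values compose
exactly with the ratio pipeline (``R = 10**d``).  Consumer responses use a
variance-stabilised propagation: the residual standard deviation is
``sqrt(noise_sd**2 + (1 - rho**2) * basal_effect_sd**2)`` where ``rho`` is
``propagation_correlation``.  This keeps the marginal scale of every
species' response roughly independent of ``rho``, so ``rho = 0`` is a true
no-signal null in which consumers are statistically indistinguishable from
basal species, rather than merely quieter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

from .background_knowledge import SpeciesTaxon, bigger_than
from .probability_ensemble import PermutationEnsemble
from .ratio_observations import CONVENTIONAL, GMHT

Pair = tuple[str, str]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic ecosystem.

    Defaults describe a mid-sized arable invertebrate community: 20 species
    over 50 split-field sites, 12 suction-sample points per site, size
    classes skewed toward small taxa, half the taxa consumers, and a strong
    (0.9) propagation of prey responses to their consumers.  The baseline
    abundance scale (log10 mean 0.8, i.e. ~6 individuals per species per
    half-field) matches the per-taxon totals typical of national-scale
    suction sampling of epigeal invertebrates; at this sparsity
    co-occurrence genuinely filters candidate pairs instead of being
    trivially true everywhere.
    """

    n_species: int = 20
    n_sites: int = 50
    n_points_per_site: int = 12
    size_class_probs: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    predator_fraction: float = 0.5
    link_density: float = 0.3
    propagation_correlation: float = 0.9
    basal_effect_sd: float = 0.6
    noise_sd: float = 0.15
    baseline_log_mean: float = 0.8
    baseline_log_sd: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be at least 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")
        if self.n_points_per_site < 1:
            raise ValueError("n_points_per_site must be at least 1")
        probs = np.asarray(self.size_class_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("size_class_probs must be 4 non-negative reals summing to 1")
        for name in ("predator_fraction", "link_density", "propagation_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("basal_effect_sd", "noise_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be non-negative")


@dataclass
class SyntheticEcosystem:
    """Ground truth plus (once simulated) the observable data tables."""

    traits: dict[str, SpeciesTaxon]
    true_links: frozenset[Pair]
    counts: pd.DataFrame | None = None
    points: pd.DataFrame | None = None
    config: SyntheticConfig = field(default_factory=SyntheticConfig)


def _residual_sd(cfg: SyntheticConfig) -> float:
    rho = cfg.propagation_correlation
    return float(np.sqrt(cfg.noise_sd**2 + (1.0 - rho**2) * cfg.basal_effect_sd**2))


def generate_ecosystem(cfg: SyntheticConfig) -> SyntheticEcosystem:
    """Draw traits and a ground-truth web consistent with the constraints.

    Size classes come from ``size_class_probs``, predator flags from
    ``predator_fraction``; every admissible pair (predator strictly bigger
    than prey) becomes a true link with probability ``link_density``.  True
    links therefore always lie inside the learner's hypothesis space.
    """
    rng = np.random.default_rng([cfg.rng_seed, 0])
    ids = [f"sp{i:03d}" for i in range(1, cfg.n_species + 1)]
    sizes = rng.choice([1, 2, 3, 4], size=cfg.n_species, p=cfg.size_class_probs)
    predators = rng.random(cfg.n_species) < cfg.predator_fraction
    traits = {
        sid: SpeciesTaxon(sid, f"taxon {sid}", bool(pred), int(size))
        for sid, pred, size in zip(ids, predators, sizes)
    }
    admissible = [
        (x, y)
        for x, y in product(ids, ids)
        if x != y and traits[x].is_predator and bigger_than(traits[x], traits[y])
    ]
    if not admissible and cfg.link_density > 0:
        warnings.warn("no admissible predator/prey pairs; true web is empty")
    links = frozenset(p for p in admissible if rng.random() < cfg.link_density)
    return SyntheticEcosystem(traits=traits, true_links=links, config=cfg)


def simulate_counts(
    eco: SyntheticEcosystem, cfg: SyntheticConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate half-field year totals and sample-point counts.

    Per site, each species gets a conventional log10 abundance
    ``L1 ~ Normal(baseline_log_mean, baseline_log_sd)`` and a treatment
    effect ``d``: for basal species ``d ~ Normal(0, basal_effect_sd)``; for
    consumers ``d = rho * mean(prey d) + Normal(0, residual_sd)`` with the
    variance-stabilised residual.  Counts are the rounded back-transforms
    ``max(0, round(10**L - 1))``.  The pooled site total of each species is
    multinomially thinned over the sample points, so species abundant at
    the same site genuinely co-occur.
    """
    cfg = cfg or eco.config
    rng = np.random.default_rng([cfg.rng_seed, 1])
    traits = eco.traits
    prey_of: dict[str, list[str]] = {sid: [] for sid in traits}
    for pred, prey in sorted(eco.true_links):
        prey_of[pred].append(prey)
    # prey are strictly smaller, so ascending size class is a topological order
    order = sorted(traits, key=lambda s: (traits[s].size_class, s))
    resid_sd = _residual_sd(cfg)
    rho = cfg.propagation_correlation

    count_rows = []
    point_rows = []
    for j in range(1, cfg.n_sites + 1):
        site = f"s{j:03d}"
        d: dict[str, float] = {}
        for sid in order:
            L1 = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd)
            if prey_of[sid]:
                prey_mean = float(np.mean([d[p] for p in prey_of[sid]]))
                d[sid] = rho * prey_mean + rng.normal(0.0, resid_sd)
            else:
                d[sid] = rng.normal(0.0, cfg.basal_effect_sd)
            c1 = max(0, int(round(10.0**L1 - 1.0)))
            c2 = max(0, int(round(10.0 ** (L1 + d[sid]) - 1.0)))
            count_rows.append((sid, site, CONVENTIONAL, c1))
            count_rows.append((sid, site, GMHT, c2))
            total = c1 + c2
            if total > 0:
                alloc = rng.multinomial(
                    total, np.full(cfg.n_points_per_site, 1.0 / cfg.n_points_per_site)
                )
                for p, n in enumerate(alloc, start=1):
                    if n > 0:
                        point_rows.append((site, f"p{p:02d}", sid, int(n)))
    counts = pd.DataFrame(
        count_rows, columns=["species_id", "site_id", "treatment", "count"]
    )
    points = pd.DataFrame(
        point_rows, columns=["site_id", "point_id", "species_id", "count"]
    )
    return counts, points


def generate(cfg: SyntheticConfig) -> SyntheticEcosystem:
    """Generate a complete ecosystem: traits, true web, counts and points."""
    eco = generate_ecosystem(cfg)
    eco.counts, eco.points = simulate_counts(eco, cfg)
    return eco


def admissible_pairs(traits: Mapping[str, SpeciesTaxon]) -> list[Pair]:
    """Every (predator, strictly smaller prey) pair the rule body allows."""
    return [
        (x, y)
        for x, y in product(sorted(traits), sorted(traits))
        if x != y and traits[x].is_predator and bigger_than(traits[x], traits[y])
    ]


def recovery_score(
    ensemble: PermutationEnsemble,
    true_links: frozenset[Pair] | set[Pair],
    traits: Mapping[str, SpeciesTaxon],
) -> float:
    """Probability-ranking score of true links against admissible non-links.

    The fraction of (true link, admissible non-link) pairs in which the true
    link received the higher estimated probability, counting ties as 1/2 —
    the AUC of the probability ranking.  1.0 is perfect recovery, 0.5 is
    chance.  Undefined (error) when there are no true links; trivially 1.0
    when every admissible pair is a true link.
    """
    if not true_links:
        raise ValueError("recovery score undefined for an empty true web")
    admissible = admissible_pairs(traits)
    truths = [p for p in admissible if p in true_links]
    negatives = [p for p in admissible if p not in true_links]
    if not truths:
        raise ValueError("no true link is admissible under the trait table")
    if not negatives:
        return 1.0
    p_true = np.array([ensemble.probability(p) for p in truths])
    p_neg = np.array([ensemble.probability(p) for p in negatives])
    wins = (p_true[:, None] > p_neg[None, :]).sum()
    ties = (p_true[:, None] == p_neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(truths) * len(negatives)))
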