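# Methods

## Observational model

The unit of observation is a species/site pair under a split-field design:
one half-field under conventional management, the other under the contrasted
(GMHT) management. Counts are year totals per half-field. The pipeline
log-transforms (`L = log10(C + 1)`), removes pairs with `C1 + C2 ≤ 1`
(a single individual cannot carry directional information), and forms the
geometric treatment ratio `R = 10^(L2 − L1)`. Changes of more than 50% in
either direction are treated as signal: `R > 1.5` → *up*, `R < 0.67` →
*down*, anything else → no observation. Both inequalities are strict, so a
ratio exactly at a threshold yields nothing. The default 0.67 is kept as the
literal decimal rather than 2/3; the reciprocal-mirror symmetry
(`direction(1/R)` is the mirror of `direction(R)`) holds exactly only for
thresholds (2/3, 3/2), and the test suite asserts it there.

A species absent from one half-field but present in the other is a real
observation of absence, so a missing treatment row is imputed as count 0
rather than rejected; the site filter still removes the pair when the
remaining count is ≤ 1.

## Background knowledge

Three predicates restrict which `eats(X, Y)` facts are ever considered:

* `predator(X)` — a boolean consumer flag from the trait table (an input;
  the package does not derive diet from taxonomy).
* `bigger_than(X, Y)` — strict ordering of 4-level body-size classes.
  Strictness has two structural consequences: equal-size pairs (and hence
  cannibalism) can never be linked, and every directed chain has strictly
  decreasing classes, so no learnt web can exceed four trophic levels.
* `co_occurs(S, X, Y)` — the pair was jointly present (both counts ≥ 1) at
  ≥ 1 sample point of site S. The raw per-site scores are retained, but the
  predicate uses the minimal cut-off of one point because no stricter
  cut-off is obviously defensible; self-pairs are scored but excluded from
  predicate use. Sample points are pooled across the two half-fields of a
  site, since the predicate is indexed by site only. When no point-level
  data exist, a site-level fallback (both year totals ≥ 1) is used; it is a
  strict superset of the point-level predicate, and a test asserts that.

## Abduction engine

The engine emulates abductive cover-set learning for the fixed rule pair
(the *up* rule and its *down* mirror, both active simultaneously; one
link's support may mix directions). "Choose the explanation that best
generalises" is operationalised as **maximal incremental cover**: scanning
observations in a given order, each unexplained observation's candidate
`eats` facts are scored by how many currently unexplained observations
(anywhere in the data) they would explain, and the best is adopted. This is
the central modelling assumption of the package — the original abductive
system's internal compression measure is not publicly specified, and a
greedy maximal-cover rule is the canonical reading of cover-set abduction.

Determinism requires a total tie-break: ties resolve by smaller prey size
class, then lexicographic prey id, then predator id. The hierarchy is
arbitrary but fixed, so (data order, seed) fully determines the network. An
adopted link explains *all* matching observations, past and future in the
scan; several adopted links may cover the same observation. Observations
with no candidate under the rule body are reported as `uncovered` — and
since candidacy depends only on the full data context, the uncovered set is
provably order-invariant (tested against random scan orders).

Because the explained-observation set of each admissible pair depends only
on the training context, it is precomputed once (`ExplanationIndex`) and
shared across all permutations of the same data; the greedy scan itself is
the only order-dependent part.

## Permutation ensemble

N random orders of the training data (default N = 10) are drawn with
replacement from the permutation space, with permutation 0 defined as the
canonical lexicographic (site, species) order. One network is learnt per
order; each distinct link's probability is its relative frequency, so
probabilities are multiples of 1/N in (0, 1]. With N = 1 the ensemble is
exactly the canonical single network. Permutation streams are keyed by
(seed, k) so each index is reproducible and independent.

## Cross-validation

One fold per (predator species, site) observation; non-predator
observations are never test cases but always remain in training — they are
the prey evidence. The held-out observation is removed from training *and*
from the entailment context of its own prediction. Probabilistic mode sums
link probabilities entailing *up* versus *down* (tie → majority class);
non-probabilistic mode learns one canonical-order network and compares
counts of entailing links; the majority mode always predicts the training
majority (tie → *down*, alphabetical — the data never tie in practice).
Fold-level ensembles are rebuilt from the remaining data with fold-indexed
seeds derived from the master seed via `SeedSequence([master, fold])`. The
standard error attached to an accuracy is binomial,
`100·sqrt(p(1−p)/n)`.

Note a known artefact of leave-one-out with a near-balanced label
distribution: removing the held-out label tips the training majority
against it, so the majority baseline can fall below the raw majority
proportion (even below 50%). The baseline is reported as measured.

## Synthetic ecosystems

The generator emulates the conceptual perturbation model: management
perturbs basal resources; consumers redistribute in response to their prey,
so log ratios of linked species are positively correlated across sites.
Concretely, per site, every species draws a conventional log10 abundance
`L1 ~ N(baseline_log_mean, baseline_log_sd)`; basal (prey-less) species
draw a treatment effect `d ~ N(0, basal_effect_sd)`; a consumer with true
prey draws `d = ρ·mean(prey d) + ε`. Counts are rounded back-transforms,
and sample-point counts are multinomial thinnings of the site total across
12 points, which guarantees point-level co-occurrence statistics consistent
with the totals.

The residual is **variance-stabilised**:
`sd(ε) = sqrt(noise_sd² + (1 − ρ²)·basal_effect_sd²)`. A naive
`ε ~ N(0, noise_sd)` would make consumers' marginal response variance
collapse as ρ → 0, so consumers would simply stop producing directional
observations and any "null" comparison would measure a variance artefact
rather than absence of trophic signal. With the stabilised form, ρ = 0
makes consumers statistically identical to basal species (a true null),
and the degenerate limits are exact: ρ = 1 with `noise_sd = 0` copies the
mean prey effect; all sds zero gives `R = 1` everywhere and no
observations.

Default study conditions: 20 species, 50 sites, 12 points/site, size-class
probabilities (0.4, 0.3, 0.2, 0.1), predator fraction 0.5, link density 0.3
over admissible pairs, ρ = 0.9, `basal_effect_sd = 0.6`, `noise_sd = 0.15`.
The abundance scale (`baseline_log_mean = 0.8`, sd 0.6, i.e. ~6 individuals
per species per half-field) reflects per-taxon totals typical of
national-scale suction sampling of epigeal invertebrates; it matters
because at unrealistically high abundance every pair co-occurs at every
point and the co-occurrence constraint stops doing any work.

What the generator does **not** emulate: crop types, sampling dates,
insecticide disturbance, taxon-specific sampling efficiency, aggregation
behaviour, or interactions other than predation (competition, reproduction)
that can also correlate treatment ratios. Passing tests therefore show that
the pipeline recovers trophic structure *when the perturbation-propagation
model holds and the background knowledge is correct* — not that real
communities satisfy those assumptions.

## Evaluation quantities

* **Recovery score**: probability-ranking AUC of true links against
  admissible non-links (ties ½). Chance = 0.5. Undefined for an empty true
  web (error); trivially 1.0 if every admissible pair is linked. Replicates
  whose random web came out empty are skipped and redrawn in the acceptance
  experiments.
* **CV accuracies** are pooled over replicates before comparison: the
  property of interest (probabilistic ≥ non-probabilistic ≥ majority on
  strong-signal data, non-strict) concerns the modes' expected behaviour,
  and single desk-scale replicates are dominated by fold noise. The null
  comparison (ρ = 0) uses a pooled two-proportion z-test at α = 0.05; by
  construction such a test will occasionally reject under the null at the
  5% level.

## Problem sizes

Recovery experiments run at the default 20 × 50 scale (5 strong replicates,
20 null replicates). Cross-validation experiments use a 15-species,
25-site community — leave-one-out with per-fold ensemble rebuilds is
quadratic in the data, and the scaled community reproduces the same
qualitative behaviour. Oracle-equivalence checks run on 200 random
instances of ≤ 6 species and ≤ 8 sites, where exhaustive enumeration of the
rule body is feasible. The chain-length bound is checked analytically over
all strictly decreasing size-class chains and empirically on 100 seeded
learnt networks.

## Known limitations

* The greedy maximal-cover rule is an emulation; other operationalisations
  of "best generalising explanation" (e.g. penalising hypothesis count)
  could yield different networks from identical data.
* Probabilities are relative frequencies over N = 10 permutations, so they
  are coarse (multiples of 0.1) and not calibrated posteriors.
* The size-order constraint forbids links within a size class and larger
  prey; real systems (web-building spiders being the classic case) violate
  it, producing false negatives the method cannot recover.
* With near-balanced directions the LOO majority baseline is pessimistic
  (see above), which flatters both model-based modes in absolute — though
  not relative — terms.
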