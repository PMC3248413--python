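# trophinet

Logic-based discovery of food webs from paired-treatment abundance data.

Field ecologists rarely get to observe who eats whom. What they do get,
from experiments like national split-field trials, are paired abundance
counts: each species' year-total count under two contrasting management
treatments at each site. `trophinet` turns such counts into a testable,
probabilistic trophic network, on the reasoning that a management
perturbation propagates along trophic links — when a prey species' abundance
shifts between treatments, its predators' abundances tend to shift the same
way.

## The method

For species *i* at site *j*, counts are log-transformed,
`L_ij = log10(C_ij + 1)`, and compared across treatments by the geometric
ratio `R = 10^d` with `d = L_2j − L_1j`. Species/site pairs whose counts sum
to ≤ 1 are dropped; ratios `R > 1.5` and `R < 0.67` become the directional
observations `abundance(X, S, up)` / `abundance(X, S, down)`.

A ground fact `eats(X, Y)` — the abducible hypothesis, entirely undefined
before learning — can explain an observation through the rule

```
abundance(X, S, up)  if  predator(X) and co_occurs(S, X, Y) and
                         bigger_than(X, Y) and abundance(Y, S, up) and
                         eats(X, Y).
```

(and its mirror-image rule for `down`). The background predicates come from
a trait table (consumer status, body-size class 1–4) and from co-occurrence
of the two species at the individual sample points of a site. A greedy
cover-set engine scans the observations in order and adopts, for each
unexplained one, the candidate `eats` fact that explains the most still
unexplained observations.

Because the scan is order-dependent, the data are randomly permuted N times
(default 10) and one network is learnt per permutation; the probability of
each link is its relative frequency across the N networks. Predictive value
is measured by leave-one-out cross-validation: each predator observation is
held out, the network relearnt, and the held-out direction predicted by
comparing the summed probabilities of links entailing *up* versus *down* —
against a single-network (non-probabilistic) predictor and a majority-class
baseline.

A synthetic-ecosystem generator provides ground truth: basal species receive
independent log-scale treatment effects, consumers track the mean effect of
their true prey with correlation ρ, and sample-point counts are multinomial
thinnings of site totals. Link recovery is scored by the probability-ranking
(AUC) of true links against admissible non-links.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
20-species, 50-site community (seed 1) and print:

```
$ python analysis/01_simulate_ecosystem.py
ecosystem: 20 species (8 predators), 50 sites, 12 true links
$ python analysis/02_build_observations.py
1000 species/site pairs -> 822 retained after the site filter
  -> 615 directional observations (327 up, 288 down)
$ python analysis/03_learn_food_web.py
29 distinct links learnt from 10 permutations of 615 observations
  (12 with probability 1.0)
longest trophic chain in the canonical network: 3 levels (bound: 4)
recovery score (true links ranked above non-links): 0.617
$ python analysis/04_crossvalidate.py
probabilistic     accuracy  61.65% +/- 4.22 (82/133)
nonprobabilistic  accuracy  60.15% +/- 4.25 (80/133)
majority          accuracy  50.38% +/- 4.34 (67/133)
```

Reading the output: of the 1000 species/site pairs, 615 moved by more than
50% between treatments and entered the learning; the ensemble proposes 29
`eats` hypotheses of which 12 are stable under every permutation; true links
rank above non-links (0.617 > 0.5 chance); and probabilistic prediction of
held-out directions beats the single-network predictor, which beats the
majority baseline — the qualitative ordering this method is designed to
produce. The strict 4-class size order caps every learnt chain at four
trophic levels. `analysis/05_signal_sweep.py` shows recovery rising from
chance (0.516 at ρ = 0) to 0.684 at ρ = 0.9.

The same pipeline runs from the shell on any CSV inputs:

```
trophinet simulate --out-dir data --seed 1
trophinet learn --counts data/counts.csv --traits data/traits.csv \
    --points data/points.csv --out-dir net --seed 1 --permutations 10
trophinet crossval --counts data/counts.csv --traits data/traits.csv \
    --points data/points.csv --mode probabilistic --out cv.json
```

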