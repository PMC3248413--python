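import numpy as np
import pytest

from oracles import oracle_candidates, oracle_entails, random_instance, random_link_set
from trophinet import (
    CoOccurrenceTable,
    DirectionObservation,
    SpeciesTaxon,
    candidate_explanations,
    entails,
    learn_network,
    max_path_nodes,
)


class TestCandidateExplanations:
    def test_predator_with_two_smaller_up_prey(self, triple_world):
        traits, obs, cooc = triple_world
        cands = candidate_explanations(obs[0], traits, cooc, obs)
        assert cands == {("A", "B"), ("A", "C")}

    def test_non_predator_has_no_candidates(self, triple_world):
        traits, obs, cooc = triple_world
        assert candidate_explanations(obs[2], traits, cooc, obs) == set()

    def test_direction_mismatch_excluded(self):
        traits = {
            "A": SpeciesTaxon("A", "A", True, 3),
            "B": SpeciesTaxon("B", "B", False, 1),
        }
        obs = [
            DirectionObservation("A", "s1", "up"),
            DirectionObservation("B", "s1", "down"),
        ]
        cooc = CoOccurrenceTable({("s1", frozenset(("A", "B"))): 1})
        assert candidate_explanations(obs[0], traits, cooc, obs) == set()

    def test_missing_species_raises_named_error(self, triple_world):
        traits, obs, cooc = triple_world
        ghost = DirectionObservation("Z", "s1", "up")
        with pytest.raises(KeyError, match="Z"):
            candidate_explanations(ghost, traits, cooc, obs + [ghost])


class TestLearnNetwork:
    def test_greedy_trace_with_prey_size_tiebreak(self, triple_world):
        traits, obs, cooc = triple_world
        net = learn_network(obs, traits, cooc)
        assert net.link_pairs == {("A", "C"), ("B", "C")}
        assert net.uncovered == {DirectionObservation("C", "s1", "up")}

    def test_empty_observations_give_empty_network(self, triple_world):
        traits, _, cooc = triple_world
        net = learn_network([], traits, cooc)
        assert net.links == {} and net.uncovered == frozenset()

    def test_single_explanation_adopted(self):
        traits = {
            "A": SpeciesTaxon("A", "A", True, 2),
            "B": SpeciesTaxon("B", "B", False, 1),
        }
        obs = [
            DirectionObservation("A", "s1", "up"),
            DirectionObservation("B", "s1", "up"),
        ]
        cooc = CoOccurrenceTable({("s1", frozenset(("A", "B"))): 1})
        net = learn_network(obs, traits, cooc)
        assert net.link_pairs == {("A", "B")}
        assert net.links[("A", "B")].n_support_up == 1

    def test_adopted_link_covers_future_observations(self):
        # A up at two sites; one link (A,B) must cover both A observations
        traits = {
            "A": SpeciesTaxon("A", "A", True, 2),
            "B": SpeciesTaxon("B", "B", False, 1),
        }
        obs = [
            DirectionObservation("A", "s1", "up"),
            DirectionObservation("A", "s2", "down"),
            DirectionObservation("B", "s1", "up"),
            DirectionObservation("B", "s2", "down"),
        ]
        cooc = CoOccurrenceTable(
            {(s, frozenset(("A", "B"))): 1 for s in ("s1", "s2")}
        )
        net = learn_network(obs, traits, cooc)
        assert net.link_pairs == {("A", "B")}
        hyp = net.links[("A", "B")]
        assert hyp.n_support_up == 1 and hyp.n_support_down == 1


class TestEntails:
    def test_direct_rule_application(self, triple_world):
        traits, obs, cooc = triple_world
        net = learn_network(obs, traits, cooc)
        assert entails(net, obs[0], obs, traits, cooc)

    def test_direction_must_match_context(self, triple_world):
        traits, obs, cooc = triple_world
        net = learn_network(obs, traits, cooc)
        flipped = DirectionObservation("A", "s1", "down")
        assert not entails(net, flipped, obs, traits, cooc)

    def test_empty_network_entails_nothing(self, triple_world):
        traits, obs, cooc = triple_world
        net = learn_network([], traits, cooc)
        assert not entails(net, obs[0], obs, traits, cooc)


class TestOracleEquivalence:
    """The engine must agree with brute-force enumeration of the rule body."""

    def test_candidates_match_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            traits, obs, cooc = random_instance(rng)
            for o in obs:
                assert candidate_explanations(o, traits, cooc, obs) == oracle_candidates(
                    o, traits, cooc, obs
                )

    def test_entailment_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(43)
        for _ in range(40):
            traits, obs, cooc = random_instance(rng)
            links = random_link_set(rng, traits)
            net = learn_network([], traits, cooc)
            net.links = {p: None for p in links}  # only keys are consulted
            for o in obs:
                assert entails(net, o, obs, traits, cooc) == oracle_entails(
                    links, o, obs, traits, cooc
                )

    def test_every_covered_observation_is_entailed(self):
        rng = np.random.default_rng(44)
        for _ in range(40):
            traits, obs, cooc = random_instance(rng)
            net = learn_network(obs, traits, cooc)
            for o in obs:
                if o not in net.uncovered:
                    assert oracle_entails(net.link_pairs, o, obs, traits, cooc)

    def test_uncovered_set_is_order_invariant(self):
        rng = np.random.default_rng(45)
        for _ in range(20):
            traits, obs, cooc = random_instance(rng)
            baseline = learn_network(obs, traits, cooc).uncovered
            for _ in range(3):
                order = [obs[i] for i in rng.permutation(len(obs))]
                assert learn_network(order, traits, cooc).uncovered == baseline


def test_learnt_networks_are_acyclic_and_at_most_four_levels():
    rng = np.random.default_rng(46)
    import networkx as nx

    for _ in range(30):
        traits, obs, cooc = random_instance(rng)
        net = learn_network(obs, traits, cooc)
        g = net.to_digraph()
        assert nx.is_directed_acyclic_graph(g)
        assert max_path_nodes(net) <= 4
        for pred, prey in net.link_pairs:
            assert traits[pred].size_class > traits[prey].size_class
            assert traits[pred].is_predator
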