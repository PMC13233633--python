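"""Transition graphs, longest-walk scoring, and FSM extraction."""

import numpy as np
import pytest

from isnkit.attractors import enumerate_attractors
from isnkit.automaton import (StateMachine, apply_and_settle,
                              build_transition_graph, extract_fsm,
                              homogeneous_longest_path,
                              longest_itinerant_path, transition_closure)
from isnkit.dynamics import StimulusSpec
from isnkit.network import assemble_isn, fiducial_cross_spec, make_cue_vector


class TestWalkLength:
    def test_identity_map_scores_zero(self):
        assert longest_itinerant_path(np.array([0, 1, 2])) == 0

    def test_chain_closing_on_visited_state(self):
        # a->b->c->d->c : 4 transitions from a (the closing edge counts)
        dest = np.array([1, 2, 3, 2])
        assert longest_itinerant_path(dest) == 4

    def test_terminal_self_loop_not_counted(self):
        dest = np.array([1, 1])  # a->b, b->b
        assert longest_itinerant_path(dest) == 1

    def test_nonconverged_edge_terminates_walk(self):
        # walks stop at the failed edge without counting it: 2->0->1 is longest
        dest = np.array([1, -1, 0])
        assert longest_itinerant_path(dest) == 2

    def test_matches_brute_force_walks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            dest = rng.integers(0, n, size=n)

            def walk(s):
                seen, cur, L = {s}, s, 0
                while True:
                    nxt = int(dest[cur])
                    if nxt == cur:
                        return L
                    if nxt in seen:
                        return L + 1
                    seen.add(nxt)
                    cur, L = nxt, L + 1

            assert longest_itinerant_path(dest) == max(walk(s) for s in range(n))


class TestTransitions:
    def test_zero_amplitude_is_identity(self, ref_net):
        cat = enumerate_attractors(ref_net)
        stim = StimulusSpec(amplitude=0.0, duration=0.01)
        g = build_transition_graph(ref_net, cat, stim)
        np.testing.assert_array_equal(g.dest, np.arange(cat.n_states))
        assert longest_itinerant_path(g) == 0

    def test_reference_stimulus_swaps_up_and_down(self, ref_net):
        cat = enumerate_attractors(ref_net)
        stim = StimulusSpec(amplitude=52.15, duration=0.001)
        g = build_transition_graph(ref_net, cat, stim)
        by_nup = {cat.states[i].n_up: int(g.dest[i]) for i in range(2)}
        assert cat.states[by_nup[0]].n_up == 1  # DOWN -> UP
        assert cat.states[by_nup[1]].n_up == 0  # UP -> DOWN

    def test_overwhelming_stimulus_erases_history(self, ref_pair):
        # far above both thresholds every start converges to one final state
        net = assemble_isn(ref_pair, 2, fiducial_cross_spec(ref_pair, seed=8),
                           seed=8)
        cat = enumerate_attractors(net)
        stim = StimulusSpec(amplitude=5000.0, duration=0.05)
        g = build_transition_graph(net, cat, stim)
        finals = set(int(v) for v in g.dest if v >= 0)
        assert len(finals) == 1

    def test_edge_caching_consistency(self, ref_net):
        cat = enumerate_attractors(ref_net)
        stim = StimulusSpec(amplitude=52.15, duration=0.001)
        first = apply_and_settle(ref_net, cat, cat.states[0], stim)
        again = apply_and_settle(ref_net, cat, cat.states[0], stim)
        assert first == again


class TestHomogeneousBound:
    def test_uniform_stimuli_capped_at_four(self, ref_pair):
        net = assemble_isn(ref_pair, 5, fiducial_cross_spec(ref_pair, cv=0.0))
        for amp in (8.0, 20.0, 60.0):
            for dur in (0.003, 0.02):
                L = homogeneous_longest_path(
                    net, StimulusSpec(amplitude=amp, duration=dur),
                    pulse_dt=1e-4)
                assert L <= 4

    def test_agrees_with_explicit_graph(self, ref_pair):
        # full 2^N graph on a small homogeneous network gives the same L
        net = assemble_isn(ref_pair, 3, fiducial_cross_spec(ref_pair, cv=0.0))
        for amp, dur in ((10.0, 0.01), (30.0, 0.005)):
            stim = StimulusSpec(amplitude=amp, duration=dur)
            cat = enumerate_attractors(net)
            g = build_transition_graph(net, cat, stim)
            assert longest_itinerant_path(g) == homogeneous_longest_path(net, stim)


class TestClosure:
    def test_recovers_injected_table(self):
        table = {  # hand-specified mock dynamical system
            ("q", 0): "a", ("q", 1): "q",
            ("a", 0): "b", ("a", 1): "q",
            ("b", 0): "b", ("b", 1): "c",
            ("c", 0): "a", ("c", 1): "c",
        }
        calls = []

        def step(s, sym):
            calls.append((s, sym))
            return table[(s, sym)]

        order, delta = transition_closure("q", 2, step)
        assert order == ["q", "a", "b", "c"]
        want = np.array([[1, 0], [2, 0], [2, 3], [1, 3]])
        np.testing.assert_array_equal(delta, want)
        assert len(calls) == len(set(calls))  # each edge simulated once

    def test_failed_edges_marked(self):
        order, delta = transition_closure(0, 1, lambda s, a: None)
        assert delta.tolist() == [[-1]]


class TestStateMachine:
    def test_trace_and_partial_flags(self):
        m = StateMachine(delta=np.array([[1, 0], [1, 1]]))
        assert not m.partial
        assert m.trace([0, 1, 0]) == 1
        bad = StateMachine(delta=np.array([[-1, 0]]))
        assert bad.partial
        with pytest.raises(ValueError, match="partial"):
            bad.trace([0])

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        m = StateMachine(delta=np.array([[1, 0], [1, 1]]),
                         signatures=[(0,), (1,)])
        path = tmp_path / "m.graphml"
        m.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 3  # 0-L->1, 0-R->0, 1-(L,R)->1
        assert g.edges[("0", "1")]["cue"] == "L"
        assert g.edges[("1", "1")]["cue"] == "L,R"

    def test_dot_export_mentions_all_states(self, tmp_path):
        m = StateMachine(delta=np.array([[1, 0], [1, 1]]))
        path = tmp_path / "m.dot"
        m.write_dot(path)
        text = path.read_text()
        assert text.startswith("digraph")
        assert "0 -> 1" in text


class TestExtraction:
    def test_inert_cues_give_single_state_machine(self, ref_pair):
        net = assemble_isn(ref_pair, 2, fiducial_cross_spec(ref_pair, seed=2),
                           seed=2)
        cues = (make_cue_vector(2, 0, "L"), make_cue_vector(2, 1, "R"))
        m = extract_fsm(net, cues, amplitude=0.5, duration=0.005)
        assert m.n_states == 1
        assert not m.partial

    def test_single_pair_machine_toggles(self, ref_net):
        from isnkit.network import CueVector

        # uniform cues at the state-dependent pulse: both cues toggle the pair
        cues = (CueVector(weights=np.ones(2), label="L"),
                CueVector(weights=np.ones(2), label="R"))
        m = extract_fsm(net=ref_net, cues=cues, amplitude=52.15, duration=0.001)
        assert m.n_states == 2
        np.testing.assert_array_equal(m.delta, [[1, 1], [0, 0]])
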