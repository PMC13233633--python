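"""Stimulus-evoked transition graphs and finite-state-machine extraction.

A fixed stimulus turns the attractor catalogue into a functional graph: each
attractor maps deterministically to the attractor reached after the pulse
plus equilibration.  The length of the longest walk through that graph
measures the network's itinerancy.  With an alphabet of cue stimuli, the
same machinery extracts the finite-state machine the network implements: a
breadth-first search from the quiescent state where traversing an edge costs
one simulation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .attractors import (AttractorCatalogue, AttractorState, settle,
                         refine_fixed_point, _check_stationary)
from .dynamics import StimulusSpec, simulate
from .network import CueVector, ISNetwork

__all__ = [
    "TransitionGraph",
    "StateMachine",
    "apply_and_settle",
    "build_transition_graph",
    "longest_itinerant_path",
    "itinerancy_sweep",
    "homogeneous_longest_path",
    "extract_fsm",
    "transition_closure",
]


@dataclass
class TransitionGraph:
    """Per-stimulus functional map over an attractor catalogue.

    ``dest[i]`` is the catalogue id reached from state i; -1 marks a
    non-converged transition.
    """

    dest: np.ndarray
    stimulus: StimulusSpec
    catalogue: AttractorCatalogue

    @property
    def n_nodes(self) -> int:
        return self.dest.size

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for st in self.catalogue.states:
            g.add_node(st.id, signature="".join(map(str, st.key())),
                       n_up=st.n_up)
        for i, j in enumerate(self.dest):
            if j >= 0:
                g.add_edge(int(i), int(j))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def edge_list(self):
        """Edge list (source, dest, converged) as a DataFrame, CSV-ready."""
        import pandas as pd

        return pd.DataFrame([
            {"source": int(i), "dest": int(j), "converged": bool(j >= 0)}
            for i, j in enumerate(self.dest)
        ])

    def components(self) -> list:
        """Weakly connected components (sets of node ids), largest first."""
        import networkx as nx

        comps = nx.weakly_connected_components(self.to_networkx())
        return sorted((set(c) for c in comps), key=len, reverse=True)


@dataclass
class StateMachine:
    """Deterministic finite-state machine read out of the network.

    ``delta[s, a]`` is the successor of state s under symbol a (-1 when the
    underlying simulation failed to equilibrate: the machine is *partial*
    and task metrics refuse it unless forced).  State 0 is always the
    initial (quiescent) state in extraction order.
    """

    delta: np.ndarray
    q0: int = 0
    alphabet: tuple = ("L", "R")
    signatures: Optional[list] = None
    rates: Optional[list] = None
    labeling: Optional[dict] = None  # state -> "L" | "R" | None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, int)
        if self.delta.ndim != 2 or self.delta.shape[1] != len(self.alphabet):
            raise ValueError("delta must be (n_states, n_symbols)")
        if not (0 <= self.q0 < self.delta.shape[0]):
            raise ValueError("q0 out of range")

    @property
    def n_states(self) -> int:
        return self.delta.shape[0]

    @property
    def partial(self) -> bool:
        return bool((self.delta < 0).any())

    def trace(self, symbols: Sequence[int]) -> int:
        """Final state after consuming a symbol-index sequence."""
        s = self.q0
        for a in symbols:
            s = self.delta[s, a]
            if s < 0:
                raise ValueError("trace hit a non-converged edge (partial machine)")
        return int(s)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for s in range(self.n_states):
            attrs = {"initial": s == self.q0}
            if self.signatures is not None:
                attrs["signature"] = "".join(map(str, self.signatures[s]))
            if self.labeling is not None:
                attrs["label"] = str(self.labeling.get(s))
            g.add_node(s, **attrs)
        for s in range(self.n_states):
            for a, sym in enumerate(self.alphabet):
                if self.delta[s, a] >= 0:
                    t = int(self.delta[s, a])
                    if g.has_edge(s, t):
                        g[s][t]["cue"] += "," + sym
                    else:
                        g.add_edge(s, t, cue=sym)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path) -> None:
        g = self.to_networkx()
        lines = ["digraph fsm {"]
        for n, d in g.nodes(data=True):
            label = d.get("label", "")
            shape = "doublecircle" if d.get("initial") else "circle"
            lines.append(f'  {n} [label="{n}:{label}" shape={shape}];')
        for u, v, d in g.edges(data=True):
            lines.append(f'  {u} -> {v} [label="{d.get("cue", "")}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def apply_and_settle(net: ISNetwork, catalogue: AttractorCatalogue,
                     state: AttractorState, stim: StimulusSpec,
                     settle_time: float = 12.0, pulse_dt: float = 1e-5,
                     settle_dt: float = 1e-4,
                     allow_append: bool = True) -> int:
    """Apply one pulse from a catalogued state; return the destination id.

    The settled state is matched against the catalogue (signature, then a
    0.5 Hz rate check); a genuinely new stationary state is appended when
    ``allow_append``.  Returns -1 when equilibration fails.
    """
    t_pulse = stim.onset + stim.duration
    n_steps = max(1, int(round(t_pulse / pulse_dt)))
    traj = simulate(net, state.rates, [stim], t_end=t_pulse, dt=pulse_dt,
                    sample_every=n_steps)
    res = settle(net, traj.final_rates, settle_time=settle_time, dt=settle_dt)
    if not res.converged:
        return -1
    match = catalogue.match(res.state.rates)
    if match is not None:
        return match
    if not allow_append:
        return -1
    _check_stationary(net, res.state)
    return catalogue.add(res.state)


def build_transition_graph(net: ISNetwork, catalogue: AttractorCatalogue,
                           stim: StimulusSpec, **kwargs) -> TransitionGraph:
    """Complete functional graph of one stimulus over the catalogue.

    States discovered mid-build get their own outgoing edge too, so the
    returned graph is complete over the final catalogue.
    """
    dest: List[int] = []
    i = 0
    while i < len(catalogue.states):
        dest.append(apply_and_settle(net, catalogue, catalogue.states[i],
                                     stim, **kwargs))
        i += 1
    return TransitionGraph(dest=np.asarray(dest, int), stimulus=stim,
                           catalogue=catalogue)


def _walk_length(dest: np.ndarray, start: int) -> int:
    """Transitions taken from ``start`` until a state repeats.

    A terminal self-loop edge is not counted; a closing edge onto a
    previously visited *different* state is.
    """
    visited = {start}
    cur = start
    length = 0
    while True:
        nxt = int(dest[cur])
        if nxt < 0 or nxt == cur:
            return length
        if nxt in visited:
            return length + 1
        length += 1
        visited.add(nxt)
        cur = nxt


def longest_itinerant_path(graph) -> int:
    """Longest functional walk over all start nodes (see :func:`_walk_length`)."""
    dest = graph.dest if isinstance(graph, TransitionGraph) else np.asarray(graph, int)
    if dest.size == 0:
        return 0
    return max(_walk_length(dest, s) for s in range(dest.size))


# ---------------------------------------------------------------------------
# homogeneous-network fast path
# ---------------------------------------------------------------------------

def _representative_state(net: ISNetwork, k: int) -> Optional[np.ndarray]:
    """Exact *stable* fixed point with the first k pairs UP, if it exists."""
    from .pair import up_fixed_point

    if k == 0:
        return np.zeros(net.n_units)
    guess = np.zeros(net.n_units)
    for j in range(k):
        fp = up_fixed_point(net.pair_params(j))
        guess[2 * j] = fp.r_e
        guess[2 * j + 1] = fp.r_i
    rep = refine_fixed_point(net, guess, active_tol=0.25)
    if rep is None:
        return None
    active = rep > 0
    jac = (net.weights[np.ix_(active, active)] - np.eye(int(active.sum()))) / net.tau
    if np.max(np.linalg.eigvals(jac).real) >= 0:
        return None
    return rep


def homogeneous_longest_path(net: ISNetwork, stim: StimulusSpec,
                             settle_time: float = 12.0,
                             pulse_dt: float = 1e-5,
                             settle_dt: float = 1e-4) -> int:
    """Longest itinerant path for a homogeneous network and uniform stimulus.

    Permutation symmetry means a transition from any state with j pairs UP
    either keeps or silences all its UP pairs and either keeps or activates
    all its DOWN pairs, so one representative simulation per UP-count j
    determines the whole 2^N-node graph.  Walks are then evaluated
    symbolically on {start set, its complement, all-UP, all-DOWN}.
    """
    N = net.n_pairs
    outcome = {}
    for j in range(N + 1):
        rep = _representative_state(net, j)
        if rep is None:
            continue
        if j > 0 and (rep[: 2 * j : 2] <= 0.5).any():
            continue  # no such attractor
        t_pulse = stim.onset + stim.duration
        n_steps = max(1, int(round(t_pulse / pulse_dt)))
        traj = simulate(net, rep, [stim], t_end=t_pulse, dt=pulse_dt,
                        sample_every=n_steps)
        res = settle(net, traj.final_rates, settle_time=settle_time, dt=settle_dt)
        if not res.converged:
            outcome[j] = None
            continue
        sig = res.state.signature
        u_up = int(sig[:j].sum())  # initially-UP pairs still UP
        u_dn = int(sig[j:].sum())  # initially-DOWN pairs now UP
        if u_up not in (0, j) or u_dn not in (0, N - j):
            outcome[j] = None  # asymmetric settle: treat as non-converged
            continue
        outcome[j] = (u_up == j, u_dn == N - j)  # (keep UP set, flip DOWN set)

    full = frozenset({"S", "Sc"})

    def canon(token: frozenset, k: int) -> frozenset:
        # drop members denoting the empty set so token identity equals
        # subset identity (S is empty at k=0, its complement at k=N)
        if k == 0:
            token = token - {"S"}
        if k == N:
            token = token - {"Sc"}
        return token

    def size(token: frozenset, k: int) -> int:
        return (k if "S" in token else 0) + (N - k if "Sc" in token else 0)

    best = 0
    for k in range(N + 1):
        if k not in outcome:
            continue
        cur = canon(frozenset({"S"}), k)
        visited = {cur}
        length = 0
        while True:
            j = size(cur, k)
            out = outcome.get(j)
            if out is None:
                break
            keep, flip = out
            nxt = canon(frozenset(
                (cur if keep else frozenset())
                | ((full - cur) if flip else frozenset())), k)
            if nxt == cur:
                break  # terminal self-loop: not counted
            if nxt in visited:
                length += 1
                break
            length += 1
            visited.add(nxt)
            cur = nxt
        best = max(best, length)
    return best


def itinerancy_sweep(net: ISNetwork, catalogue: Optional[AttractorCatalogue],
                     amp_grid: Sequence[float], dur_grid: Sequence[float],
                     homogeneous: Optional[bool] = None,
                     **kwargs) -> np.ndarray:
    """Longest itinerant path per (amplitude, duration) grid cell.

    Pass the network's catalogue for the general per-state construction, or
    set ``homogeneous=True`` (auto-detected when None) to use the
    symmetry-reduced representative construction.
    """
    from .attractors import _is_homogeneous

    amps = np.asarray(amp_grid, float)
    durs = np.asarray(dur_grid, float)
    if (amps <= 0).any() or (durs <= 0).any():
        raise ValueError("grids must be positive")
    if homogeneous is None:
        homogeneous = _is_homogeneous(net)
    L = np.zeros((amps.size, durs.size), int)
    for i, a in enumerate(amps):
        for j, d in enumerate(durs):
            stim = StimulusSpec(amplitude=a, duration=d)
            if homogeneous:
                L[i, j] = homogeneous_longest_path(net, stim, **kwargs)
            else:
                cat = copy.deepcopy(catalogue)
                g = build_transition_graph(net, cat, stim, **kwargs)
                L[i, j] = longest_itinerant_path(g)
    return L


# ---------------------------------------------------------------------------
# finite-state-machine extraction
# ---------------------------------------------------------------------------

def transition_closure(q0, n_symbols: int, step: Callable):
    """Breadth-first closure of a transition function from ``q0``.

    ``step(state, symbol_index)`` returns the successor state (hashable) or
    None for a failed edge.  Returns the discovery-ordered state list and
    the relabelled delta array (-1 for failed edges).  Results of ``step``
    are cached so each edge is simulated exactly once.
    """
    order = [q0]
    index = {q0: 0}
    rows: List[List[int]] = []
    cache = {}
    qi = 0
    while qi < len(order):
        s = order[qi]
        row = []
        for a in range(n_symbols):
            if (s, a) not in cache:
                cache[(s, a)] = step(s, a)
            t = cache[(s, a)]
            if t is None:
                row.append(-1)
            else:
                if t not in index:
                    index[t] = len(order)
                    order.append(t)
                row.append(index[t])
        rows.append(row)
        qi += 1
    return order, np.asarray(rows, int)


def extract_fsm(net: ISNetwork, cues: Sequence[CueVector],
                amplitude: float, duration: float,
                settle_time: float = 12.0, pulse_dt: float = 1e-5,
                settle_dt: float = 1e-4) -> StateMachine:
    """Read out the FSM induced by a cue alphabet at one pulse shape.

    Starts from the quiescent (all-DOWN) state — always stable here since
    both thresholds are positive — and breadth-first expands (state, cue)
    edges by simulation until no new attractor appears.
    """
    quiescent = refine_fixed_point(net, np.zeros(net.n_units))
    if quiescent is None or (quiescent != 0).any():
        raise ValueError("quiescent state is not a stable fixed point of this network")
    cat = AttractorCatalogue(states=[], method="bfs", n_pairs=net.n_pairs)
    cat.add(AttractorState(rates=np.zeros(net.n_units),
                           signature=np.zeros(net.n_pairs, np.uint8),
                           settled_by="proximity"))

    def step(state_id: int, a: int):
        stim = StimulusSpec(amplitude=amplitude, duration=duration,
                            weights=cues[a].weights)
        dest = apply_and_settle(net, cat, cat.states[state_id], stim,
                                settle_time=settle_time, pulse_dt=pulse_dt,
                                settle_dt=settle_dt)
        return None if dest < 0 else dest

    order, delta = transition_closure(0, len(cues), step)
    return StateMachine(
        delta=delta, q0=0,
        alphabet=tuple(c.label for c in cues),
        signatures=[cat.states[s].key() for s in order],
        rates=[cat.states[s].rates for s in order],
    )
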