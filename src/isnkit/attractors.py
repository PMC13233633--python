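"""Attractor discovery: equilibration criteria and state enumeration.

Every attractor of the clamped threshold-linear network is a fixed point
whose active (nonzero-rate) units satisfy a linear system; once the active
set is known the exact fixed point is one linear solve away.  Settling
therefore integrates the autonomous dynamics in chunks, proposes the exact
candidate point implied by the current active set, and accepts it when
either (1) the trajectory stays within 0.5 Hz of the candidate for 0.5 s
(proximity), or (2) the oscillation envelope around the candidate decays
monotonically over the final 2 s of a 12 s equilibration (decay-envelope —
damped spirals too slow to meet proximity are extrapolated to their focus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .dynamics import simulate
from .network import ISNetwork
from .pair import up_fixed_point

__all__ = [
    "AttractorState",
    "AttractorCatalogue",
    "SettleResult",
    "settle",
    "refine_fixed_point",
    "enumerate_attractors",
]

RATE_TOL = 0.5  # Hz: convergence tolerance, UP threshold, and state-merge radius
STATIONARITY_TOL = 1e-6  # Hz/s: max |dr/dt| allowed at a catalogued state


@dataclass
class AttractorState:
    """A settled rate vector with its per-pair UP/DOWN signature."""

    rates: np.ndarray
    signature: np.ndarray  # length N, 1 where the pair's E rate > RATE_TOL
    settled_by: str  # proximity | decay-envelope
    id: int = -1

    @property
    def n_up(self) -> int:
        return int(self.signature.sum())

    def key(self) -> tuple:
        return tuple(int(b) for b in self.signature)


@dataclass
class SettleResult:
    converged: bool
    state: Optional[AttractorState]
    t_elapsed: float


@dataclass
class AttractorCatalogue:
    """Unique attractors of one network, with the discovery method."""

    states: List[AttractorState]
    method: str  # exhaustive | symmetry-reduced
    n_nonconverged: int = 0
    #: for symmetry-reduced runs: stable UP-counts k, each contributing C(N,k)
    stable_counts: Optional[list] = None
    n_pairs: int = 0

    @property
    def n_states(self) -> int:
        if self.method == "symmetry-reduced":
            return int(sum(math.comb(self.n_pairs, k) for k in self.stable_counts))
        return len(self.states)

    def match(self, rates: np.ndarray) -> Optional[int]:
        """Index of the catalogued state matching ``rates``, or None.

        Signature first, then a RATE_TOL max-norm rate comparison, mirroring
        the uniqueness rule used during enumeration.
        """
        sig = signature_of(rates)
        for st in self.states:
            if np.array_equal(st.signature, sig) and \
                    np.max(np.abs(st.rates - rates)) < RATE_TOL:
                return st.id
        return None

    def add(self, state: AttractorState) -> int:
        state.id = len(self.states)
        self.states.append(state)
        return state.id

    def to_signature_table(self):
        """Signature table (one row per state) as a DataFrame, CSV-ready."""
        import pandas as pd

        return pd.DataFrame([
            {"id": s.id, "signature": "".join(map(str, s.key())),
             "n_up": s.n_up, "settled_by": s.settled_by}
            for s in self.states
        ])

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "n_pairs": self.n_pairs,
            "n_states": self.n_states,
            "n_nonconverged": self.n_nonconverged,
            "stable_counts": self.stable_counts,
            "states": [
                {"id": s.id, "signature": s.key(), "rates": s.rates.tolist(),
                 "settled_by": s.settled_by}
                for s in self.states
            ],
        }


def signature_of(rates: np.ndarray) -> np.ndarray:
    """Per-pair binary UP/DOWN signature (E rate above RATE_TOL)."""
    return (np.asarray(rates)[0::2] > RATE_TOL).astype(np.uint8)


def refine_fixed_point(net: ISNetwork, rates: np.ndarray,
                       active_tol: float = 0.25) -> Optional[np.ndarray]:
    """Exact fixed point implied by the active set of ``rates``.

    Units above ``active_tol`` Hz are taken active; the active subsystem
    solves (I - W_AA) r_A = -theta_A.  Returns None when the solve is
    singular, yields a negative active rate, or an inactive unit would
    receive net positive drive (the proposed point is not a fixed point of
    the clamped dynamics).
    """
    rates = np.asarray(rates, float)
    active = rates > active_tol
    n = net.n_units
    r_star = np.zeros(n)
    if active.any():
        A = np.ix_(active, active)
        try:
            r_a = np.linalg.solve(np.eye(int(active.sum())) - net.weights[A],
                                  -net.thresholds[active])
        except np.linalg.LinAlgError:
            return None
        if (r_a <= 0).any():
            return None
        r_star[active] = r_a
    inactive = ~active
    if inactive.any():
        drive = net.weights[inactive] @ r_star - net.thresholds[inactive]
        if (drive > 0).any():
            return None
    return r_star


def _stationarity(net: ISNetwork, rates: np.ndarray) -> float:
    from .dynamics import rate_derivative

    return float(np.max(np.abs(rate_derivative(rates, net, np.zeros(net.n_units)))))


def _envelope_decays(dist: np.ndarray) -> bool:
    """True when successive local maxima of the distance signal shrink."""
    peaks = []
    for i in range(1, dist.size - 1):
        if dist[i] >= dist[i - 1] and dist[i] > dist[i + 1]:
            peaks.append(dist[i])
    if len(peaks) < 2:
        # no oscillation left to speak of: accept if the signal shrinks overall
        return dist[-1] < dist[0]
    return all(b < a for a, b in zip(peaks, peaks[1:]))


def settle(net: ISNetwork, r0: np.ndarray, settle_time: float = 12.0,
           dt: float = 1e-4, chunk: float = 0.5,
           sample_interval: float = 1e-3) -> SettleResult:
    """Equilibrate autonomously and classify convergence.

    Integrates in ``chunk``-second pieces.  After each chunk the exact fixed
    point implied by the current active set is proposed; the run converges by
    proximity when the final 0.5 s stays within 0.5 Hz of it.  If the full
    ``settle_time`` elapses, the decay-envelope criterion is checked over the
    final 2 s.  Accepted states carry the linear-solve point (stationary to
    machine precision), not the raw integrator sample.
    """
    r = np.array(r0, float)
    sample_every = max(1, int(round(sample_interval / dt)))
    window = []  # (t, rates) samples of the trailing 2 s
    keep = int(round(2.0 / (sample_every * dt))) + 1
    t = 0.0
    n_chunks = int(math.ceil(settle_time / chunk))
    prox_n = int(round(0.5 / (sample_every * dt)))  # samples in 0.5 s

    for _ in range(n_chunks):
        traj = simulate(net, r, t_end=chunk, dt=dt, sample_every=sample_every,
                        t_start=t)
        r = traj.final_rates.copy()
        t += chunk
        for row in traj.rates[1:]:
            window.append(row)
        window = window[-keep:]

        cand = refine_fixed_point(net, r)
        if cand is not None and len(window) >= prox_n:
            recent = np.asarray(window[-prox_n:])
            if np.max(np.abs(recent - cand)) < RATE_TOL:
                state = AttractorState(rates=cand, signature=signature_of(cand),
                                       settled_by="proximity")
                return SettleResult(True, state, t)

    cand = refine_fixed_point(net, r)
    if cand is not None and len(window) >= 2:
        dist = np.max(np.abs(np.asarray(window) - cand), axis=1)
        if _envelope_decays(dist):
            state = AttractorState(rates=cand, signature=signature_of(cand),
                                   settled_by="decay-envelope")
            return SettleResult(True, state, t)
    return SettleResult(False, None, t)


def _is_homogeneous(net: ISNetwork, tol: float = 1e-12) -> bool:
    """All pair blocks identical and, per class, all cross weights identical."""
    N = net.n_pairs
    if N == 1:
        return True
    b0 = net.weights[0:2, 0:2]
    for k in range(1, N):
        if not np.allclose(net.weights[2 * k:2 * k + 2, 2 * k:2 * k + 2], b0,
                           atol=tol, rtol=0):
            return False
    for a in range(2):  # post offset
        for b in range(2):  # pre offset
            vals = [net.weights[2 * p + a, 2 * q + b]
                    for p in range(N) for q in range(N) if p != q]
            if np.ptp(vals) > tol:
                return False
    if np.ptp(net.thresholds[0::2]) > tol or np.ptp(net.thresholds[1::2]) > tol:
        return False
    return True


def _initial_conditions(net: ISNetwork, up_mask: np.ndarray, scale: float) -> np.ndarray:
    """Start with the masked pairs at ``scale`` times their isolated UP rates."""
    r0 = np.zeros(net.n_units)
    for k in np.flatnonzero(up_mask):
        fp = up_fixed_point(net.pair_params(k))
        r0[2 * k] = scale * fp.r_e
        r0[2 * k + 1] = scale * fp.r_i
    return r0


UP_GUESS_SCALES = (0.5, 1.0, 2.0)


def enumerate_attractors(net: ISNetwork, method: str = "exhaustive",
                         settle_time: float = 12.0, dt: float = 1e-4,
                         max_pairs_exhaustive: int = 12) -> AttractorCatalogue:
    """Catalogue attractors from the standard grid of initial conditions.

    ``exhaustive`` settles 3 * 2^N starts (every UP-subset, three UP-rate
    guesses bracketing the isolated-pair UP point at 0.5x/1x/2x).
    ``symmetry-reduced`` (homogeneous networks only) settles 3 starts per
    UP-count k and credits C(N, k) permutations for each stable k, reducing
    the cost from O(2^N) to O(N).
    """
    N = net.n_pairs
    if method == "exhaustive":
        if N > max_pairs_exhaustive:
            raise ValueError(
                f"exhaustive enumeration capped at N={max_pairs_exhaustive} "
                f"(3*2^N settles); use symmetry-reduced for homogeneous networks")
        cat = AttractorCatalogue(states=[], method="exhaustive", n_pairs=N)
        for mask_bits in range(2 ** N):
            up_mask = np.array([(mask_bits >> k) & 1 for k in range(N)], bool)
            for scale in UP_GUESS_SCALES:
                res = settle(net, _initial_conditions(net, up_mask, scale),
                             settle_time=settle_time, dt=dt)
                if not res.converged:
                    cat.n_nonconverged += 1
                    continue
                if cat.match(res.state.rates) is None:
                    _check_stationary(net, res.state)
                    cat.add(res.state)
        return cat

    if method == "symmetry-reduced":
        if not _is_homogeneous(net):
            raise ValueError("symmetry-reduced enumeration requires a homogeneous network")
        cat = AttractorCatalogue(states=[], method="symmetry-reduced",
                                 n_pairs=N, stable_counts=[])
        for k in range(N + 1):
            up_mask = np.zeros(N, bool)
            up_mask[:k] = True
            found = None
            for scale in UP_GUESS_SCALES:
                res = settle(net, _initial_conditions(net, up_mask, scale),
                             settle_time=settle_time, dt=dt)
                if not res.converged:
                    cat.n_nonconverged += 1
                    continue
                if res.state.n_up == k:
                    found = res.state
                    break
            if found is not None and k not in cat.stable_counts:
                _check_stationary(net, found)
                cat.stable_counts.append(k)
                cat.add(found)
        return cat

    raise ValueError(f"unknown method {method!r}")


def _check_stationary(net: ISNetwork, state: AttractorState) -> None:
    resid = _stationarity(net, state.rates)
    if resid >= STATIONARITY_TOL:
        raise RuntimeError(
            f"catalogued state {state.key()} is not stationary "
            f"(max |dr/dt| = {resid:.3g} Hz/s)")
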