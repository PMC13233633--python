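"""Scoring state machines on the six-cue left/right accumulation task.

The task presents six cues, each "L" or "R"; the correct decision is the
majority side.  Machines are scored by *reliability*: trace all 64
sequences to their final states, label each final state by the majority
class of the non-tie sequences that reach it, and count the correctly
classified non-tie sequences,

    reliability = sum_i max(|S_i ∩ L|, |S_i ∩ R|) / (|L| + |R|),

where S_i collects the sequences ending in state i and L, R are the
strict-majority sequence sets (|L| = |R| = 22; the 20 tied 3-3 sequences are
excluded).  Chance performance scores 0.50; deciding by any single fixed cue
position scores 8/11; perfect separation scores 1.00.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .automaton import StateMachine, extract_fsm
from .network import (CueVector, ISPParams, assemble_isn, fiducial_cross_spec,
                      make_cue_vector)

__all__ = [
    "SEQUENCE_LENGTH",
    "all_sequences",
    "majority_label",
    "reliability",
    "primacy_recency",
    "psychometric",
    "reliability_stimulus_sweep",
    "heterogeneity_experiment",
    "fit_exponential_growth",
    "constant_machine",
    "last_cue_machine",
    "fixed_position_machine",
    "counter_machine",
    "search_machines",
]

SEQUENCE_LENGTH = 6
BASELINE_RELIABILITY = 8.0 / 11.0
_SYMBOLS = ("L", "R")


def all_sequences(length: int = SEQUENCE_LENGTH) -> np.ndarray:
    """All 2^length cue sequences as symbol-index rows (0 = L, 1 = R)."""
    return np.array(list(itertools.product((0, 1), repeat=length)), int)


def majority_label(seq: Sequence[int]) -> Optional[str]:
    """'L', 'R', or None for a tied sequence."""
    n_l = len(seq) - int(np.sum(seq))
    n_r = int(np.sum(seq))
    if n_l > n_r:
        return "L"
    if n_r > n_l:
        return "R"
    return None


def _final_states(m: StateMachine, seqs: np.ndarray) -> np.ndarray:
    return np.array([m.trace(s) for s in seqs], int)


def reliability(m: StateMachine, force: bool = False) -> tuple:
    """Eq-style reliability in [0.5, 1] plus the optimal per-state labeling.

    Every final state is labelled by whichever majority class (L or R)
    dominates among the non-tie sequences reaching it (None on an exact
    tie, including states reached only by tied sequences); this per-state
    majority labeling is the globally optimal output function.  Partial
    machines are refused unless ``force``.
    """
    if m.partial and not force:
        raise ValueError("machine is partial (has non-converged edges)")
    seqs = all_sequences()
    finals = _final_states(m, seqs)
    labels = [majority_label(s) for s in seqs]
    counts = {}
    for st, lab in zip(finals, labels):
        if lab is None:
            continue
        c = counts.setdefault(int(st), [0, 0])
        c[0 if lab == "L" else 1] += 1
    n_correct = sum(max(c) for c in counts.values())
    n_total = sum(c[0] + c[1] for c in counts.values())  # = |L| + |R| = 44
    labeling = {}
    for st in set(int(s) for s in finals):
        c = counts.get(st, [0, 0])
        if c[0] > c[1]:
            labeling[st] = "L"
        elif c[1] > c[0]:
            labeling[st] = "R"
        else:
            labeling[st] = None
    return n_correct / n_total, labeling


def primacy_recency(m: StateMachine, labeling: Optional[dict] = None,
                    force: bool = False) -> tuple:
    """P(decision == first cue), P(decision == last cue).

    The decision for a sequence is the label of its final state; sequences
    ending in an unlabelled state are excluded.  Tied 3-3 sequences still
    produce decisions and are included (the congruence question is
    well-posed for them).
    """
    if labeling is None:
        _, labeling = reliability(m, force=force)
    seqs = all_sequences()
    finals = _final_states(m, seqs)
    first_hits = last_hits = n = 0
    for seq, st in zip(seqs, finals):
        lab = labeling.get(int(st))
        if lab is None:
            continue
        decision = 0 if lab == "L" else 1
        n += 1
        first_hits += int(decision == seq[0])
        last_hits += int(decision == seq[-1])
    if n == 0:
        return math.nan, math.nan
    return first_hits / n, last_hits / n


def _decision_table(m: StateMachine, labeling: dict) -> pd.DataFrame:
    seqs = all_sequences()
    finals = _final_states(m, seqs)
    rows = []
    for seq, st in zip(seqs, finals):
        rows.append({
            "n_left": SEQUENCE_LENGTH - int(seq.sum()),
            "label": labeling.get(int(st)),
        })
    return pd.DataFrame(rows)


def psychometric(machines, baseline: float = BASELINE_RELIABILITY) -> dict:
    """P(left decision | k left cues) pooled over above-baseline machines.

    Decisions from unlabelled final states contribute half a left vote
    (their count is also reported separately).  Binary decisions are fitted
    with a logistic regression and, for comparison, a linear probability
    model; both are scored by binomial log-likelihood.
    """
    if isinstance(machines, StateMachine):
        machines = [machines]
    used = []
    for m in machines:
        rel, labeling = reliability(m)
        if rel > baseline:
            used.append((m, rel, labeling))
    if not used:
        raise ValueError(f"no machine above the baseline reliability {baseline:.3f}")

    frames = [_decision_table(m, lab) for m, _, lab in used]
    table = pd.concat(frames, ignore_index=True)
    ks = np.arange(SEQUENCE_LENGTH + 1)
    p_left = np.empty(ks.size)
    n_none = np.zeros(ks.size, int)
    for k in ks:
        sub = table[table.n_left == k]
        left = (sub.label == "L").sum()
        none = sub.label.isna().sum()
        n_none[k] = none
        p_left[k] = (left + 0.5 * none) / len(sub)

    # model comparison on the labelled binary decisions
    lab = table.dropna(subset=["label"])
    y = (lab.label == "L").to_numpy(int)
    x = lab.n_left.to_numpy(float)
    import statsmodels.api as sm

    X = sm.add_constant(x)
    # lbfgs handles perfectly separated decisions (likelihood sup -> 0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ll_logistic = float(sm.Logit(y, X).fit(disp=0, method="lbfgs",
                                               maxiter=500).llf)
    linfit = sm.OLS(y, X).fit()
    p_lin = np.clip(linfit.predict(X), 1e-9, 1 - 1e-9)
    ll_linear = float(np.sum(y * np.log(p_lin) + (1 - y) * np.log(1 - p_lin)))

    return {
        "k": ks, "p_left": p_left, "n_none": n_none,
        "n_machines": len(used),
        "reliabilities": [r for _, r, _ in used],
        "ll_logistic": ll_logistic, "ll_linear": ll_linear,
    }


def reliability_stimulus_sweep(net, cue_pair: Sequence[CueVector],
                               amp_grid, dur_grid, **fsm_kwargs) -> pd.DataFrame:
    """Extract the FSM and score it at every (amplitude, duration) cell."""
    rows = []
    for a in np.asarray(amp_grid, float):
        for d in np.asarray(dur_grid, float):
            m = extract_fsm(net, cue_pair, amplitude=a, duration=d, **fsm_kwargs)
            if m.partial:
                rows.append({"amplitude": a, "duration": d, "n_states": m.n_states,
                             "reliability": math.nan, "primacy": math.nan,
                             "recency": math.nan, "partial": True})
                continue
            rel, labeling = reliability(m)
            pri, rec = primacy_recency(m, labeling)
            rows.append({"amplitude": a, "duration": d, "n_states": m.n_states,
                         "reliability": rel, "primacy": pri, "recency": rec,
                         "partial": False})
    return pd.DataFrame(rows)


def heterogeneity_experiment(p: ISPParams, cv_levels: Sequence[float],
                             n_matrices: int = 10, n_pairs: int = 5,
                             amp_grid=None, dur_grid=None,
                             cue_pair: Optional[Sequence[CueVector]] = None,
                             seed: int = 0, beta: float = 1.0,
                             settle_time: float = 12.0,
                             score_task: bool = False) -> pd.DataFrame:
    """Vary cross-connectivity heterogeneity at fixed mean; record capacity,
    itinerancy and (optionally) task performance per matrix.

    Weights are gamma-distributed (Dale's law is then automatic) with the
    coefficient of variation set per level; CV = 0 is the homogeneous limit.
    Returns one row per (cv, matrix): attractor count, mean/max longest
    itinerant path over the stimulus grid, and task reliability statistics
    when ``score_task``.
    """
    from .attractors import enumerate_attractors
    from .automaton import itinerancy_sweep

    if amp_grid is None:
        amp_grid = np.geomspace(2 * p.theta_e, 40 * p.theta_e, 6)
    if dur_grid is None:
        dur_grid = np.geomspace(0.003, 0.3, 5)
    rows = []
    ss = np.random.SeedSequence(seed)
    for cv in cv_levels:
        if cv < 0:
            raise ValueError("cv levels must be >= 0")
        for mi in range(n_matrices):
            child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            spec = fiducial_cross_spec(p, beta=beta, cv=cv, family="gamma",
                                       seed=child)
            # small rows at high CV accept rarely; a larger resample cap
            # keeps the prescribed 5%/10% moment tolerances attainable
            net = assemble_isn(p, n_pairs, spec, seed=child,
                               max_attempts=400_000)
            cat = enumerate_attractors(net, method="exhaustive",
                                       settle_time=settle_time)
            L = itinerancy_sweep(net, cat, amp_grid, dur_grid,
                                 homogeneous=(cv == 0.0),
                                 settle_time=settle_time)
            row = {"cv": cv, "matrix_seed": child, "n_states": cat.n_states,
                   "mean_L": float(L.mean()), "max_L": int(L.max())}
            if score_task:
                cues = cue_pair or (make_cue_vector(n_pairs, child + 1, "L"),
                                    make_cue_vector(n_pairs, child + 2, "R"))
                sweep = reliability_stimulus_sweep(
                    net, cues, amp_grid, dur_grid, settle_time=settle_time)
                ok = sweep.dropna(subset=["reliability"])
                row.update({
                    "max_reliability": float(ok.reliability.max()) if len(ok) else math.nan,
                    "mean_reliability": float(ok.reliability.mean()) if len(ok) else math.nan,
                    "frac_above_baseline": float(
                        (ok.reliability > BASELINE_RELIABILITY).mean()) if len(ok) else math.nan,
                })
            rows.append(row)
    return pd.DataFrame(rows)


def fit_exponential_growth(sizes, counts) -> tuple:
    """Least-squares fit of state counts vs network size to y = a * b^x + c."""
    x = np.asarray(sizes, float)
    y = np.asarray(counts, float)
    if x.size < 4:
        raise ValueError("need at least 4 size points")

    def model(x, a, b, c):
        return a * np.power(b, x) + c

    # initial guess from successive ratios
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = y[1:] / np.where(y[:-1] == 0, np.nan, y[:-1])
    b0 = float(np.nanmedian(ratios)) if np.isfinite(np.nanmedian(ratios)) else 2.0
    b0 = max(b0, 1.01)
    a0 = max(y[-1] / b0 ** x[-1], 1e-6)
    popt, _ = optimize.curve_fit(model, x, y, p0=[a0, b0, 0.0], maxfev=20000)
    a, b, c = (float(v) for v in popt)
    degenerate = abs(b - 1.0) < 1e-3 or abs(a) < 1e-9
    return a, b, c, degenerate


# ---------------------------------------------------------------------------
# reference machines and exhaustive machine search
# ---------------------------------------------------------------------------

def constant_machine() -> StateMachine:
    """One state; every sequence ends in it (no discrimination)."""
    return StateMachine(delta=np.zeros((1, 2), int))


def last_cue_machine() -> StateMachine:
    """Two states remembering only the most recent cue."""
    # state 0: start/"last was L"; state 1: "last was R"
    return StateMachine(delta=np.array([[0, 1], [0, 1]]))


def fixed_position_machine(position: int,
                           length: int = SEQUENCE_LENGTH) -> StateMachine:
    """Decide by the cue at one fixed position (0-based), ignoring the rest."""
    if not 0 <= position < length:
        raise ValueError("position out of range")
    if position == length - 1:
        return last_cue_machine()
    # states 0..position count cues blindly; then latch into L or R absorbers
    n = position + 3
    delta = np.empty((n, 2), int)
    for s in range(position):
        delta[s] = (s + 1, s + 1)
    delta[position] = (position + 1, position + 2)  # branch on the watched cue
    delta[position + 1] = (position + 1, position + 1)  # L absorber
    delta[position + 2] = (position + 2, position + 2)  # R absorber
    return StateMachine(delta=delta)


def counter_machine(length: int = SEQUENCE_LENGTH,
                    limit: Optional[int] = None) -> StateMachine:
    """Track the signed cue difference #L - #R, saturating at ``limit``.

    The default limit equals the sequence length, so counting is exact and
    the machine separates the majority classes perfectly.  Smaller limits
    give imperfect but above-baseline accumulators.
    """
    if limit is None:
        limit = length
    offsets = list(range(-limit, limit + 1))
    index = {v: i for i, v in enumerate(offsets)}
    delta = np.empty((len(offsets), 2), int)
    for v in offsets:
        delta[index[v], 0] = index[min(v + 1, limit)]
        delta[index[v], 1] = index[max(v - 1, -limit)]
    return StateMachine(delta=delta, q0=index[0])


def search_machines(n_states: int, length: int = SEQUENCE_LENGTH):
    """Exhaustively score every deterministic 2-symbol machine on ``n_states``.

    Enumerates all n_states^(2 n_states) transition functions with fixed
    initial state 0 and evaluates the optimally-labelled reliability of
    each, fully vectorized.  Returns (best reliability, best delta).
    """
    seqs = all_sequences(length)
    n_seq = seqs.shape[0]
    maj = np.array([{"L": 0, "R": 1, None: 2}[majority_label(s)] for s in seqs])
    n_trans = 2 * n_states
    n_machines = n_states**n_trans
    # delta_flat[m, s*2 + a] = successor; enumerate via mixed radix
    idx = np.arange(n_machines)
    delta_flat = np.empty((n_machines, n_trans), np.int8)
    for pos in range(n_trans):
        delta_flat[:, pos] = (idx // n_states**pos) % n_states

    state = np.zeros((n_machines, n_seq), np.int8)
    for t in range(length):
        cols = state.astype(np.int64) * 2 + seqs[:, t][None, :]
        state = np.take_along_axis(delta_flat, cols, axis=1)

    # per-machine, per-final-state counts of L- and R-majority sequences
    key = (np.arange(n_machines)[:, None] * (n_states * 3)
           + state.astype(np.int64) * 3 + maj[None, :])
    counts = np.bincount(key.ravel(), minlength=n_machines * n_states * 3)
    counts = counts.reshape(n_machines, n_states, 3)
    correct = np.maximum(counts[:, :, 0], counts[:, :, 1]).sum(axis=1)
    rel = correct / counts[:, :, :2].sum(axis=(1, 2))  # denominator = |L| + |R|
    best = int(np.argmax(rel))
    return float(rel[best]), delta_flat[best].reshape(n_states, 2).astype(int)
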