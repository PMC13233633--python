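# isnkit

Simulation and analysis of **inhibition-stabilized attractor networks**:
circuits built from bistable excitatory–inhibitory rate-unit pairs whose
stimulus-evoked movement between attractor states implements
history-dependent computation — up to and including finite-state machines
that solve an evidence-accumulation task.

The package is aimed at computational neuroscientists studying attractor
dynamics, working memory, and the automata-theoretic view of cortical
computation.

## The model

Each unit is a threshold-linear (ReLU) rate unit. A network of N
excitatory–inhibitory pairs (2N units, interleaved E1, I1, E2, I2, …) obeys

    τ dr/dt = −r + W·r − θ + Σ_α ω_α I_α(t),    r ≥ 0,

where the rate of any unit at zero is never driven negative (projected,
clamped dynamics), τ = 10 ms, W is the signed 2N×2N weight matrix, θ the
per-unit thresholds, and each stimulus α is a rectangular current pulse
I_α(t) of amplitude I_app and duration τ_dur distributed across units by a
weight vector ω_α.

For a single pair the nonzero ("UP") fixed point is available in closed
form, and its character follows from the Jacobian's trace and determinant:

    Tr = (W_EE + W_II − 2)/τ,
    Δ  = [(W_EE − 1)(W_II − 1) − W_EI·W_IE]/τ²,

stable for Tr < 0, Δ > 0; a **stable spiral** when Tr² < 4Δ. With
θ_I > θ_E > 0 and the inhibitory nullcline gain above the excitatory one,
the pair is bistable (silent DOWN state + inhibition-stabilized UP state).
Spiral dynamics around UP are what allow one excitatory pulse to switch the
pair in *both* directions depending on its current state — the
state-dependent response at the heart of the package.

Key quantities the library computes:

- **Tolerance** — log-scale effective diameter of the stimulus region with
  state-dependent responses, `10^D − 1` for the equal-area circle on log axes.
- **Attractor catalogue** — all stable states, found from 3·2^N initial
  conditions (or 3N for homogeneous networks via permutation symmetry),
  with a 12 s equilibration and 0.5 Hz proximity / decay-envelope criteria.
- **Itinerancy** — the longest walk through the per-stimulus functional
  graph over attractors (provably ≤ 4 for homogeneous networks under
  uniform stimuli).
- **Finite-state machines** — breadth-first extraction of the transition
  function induced by a cue alphabet, and its **reliability** on the
  six-cue left/right majority task:
  `reliability = Σ_i max(|S_i∩L|, |S_i∩R|) / (|L|+|R|)` ∈ [0.5, 1],
  plus primacy/recency scores and psychometric curves.

## Worked example

```python
import numpy as np
import isnkit as ik

# design a pair: UP state at (5, 10) Hz, thresholds 5.34 / 82.43,
# Jacobian trace -50 /s and determinant 1.5e4 /s^2 (a stable spiral)
p = ik.solve_isp_from_spec(-50.0, 1.5e4, theta_e=5.34, theta_i=82.43,
                           r_e_up=5.0, r_i_up=10.0)
print(ik.up_fixed_point(p).location)    # (5.000000000000002, 10.00000000000001)
print(ik.classify_up(p))                # stable spiral

# the same 1 ms, amplitude-52.15 pulse switches the pair both ways
res = ik.state_dependence_test(p, ik.StimulusSpec(amplitude=52.15, duration=0.001))
print(res)  # {'down_to_up': True, 'up_to_down': True,
            #  'state_dependent': True, 'indeterminate': False}

# a nine-pair network with weak identical cross-connections keeps
# every UP/DOWN configuration stable
net = ik.assemble_isn(p, 9, ik.fiducial_cross_spec(p, cv=0.0))
cat = ik.enumerate_attractors(net, method="symmetry-reduced")
print(cat.n_states)                     # 512
```

Scoring hand-built machines on the six-cue task:

```python
from isnkit.task import reliability, last_cue_machine, counter_machine
print(reliability(last_cue_machine())[0])   # 0.7272727272727273  (= 8/11)
print(reliability(counter_machine())[0])    # 1.0
```

A command-line interface mirrors the library
(`isn build`, `isn solve-isp`, `isn sweep`, `isn count-states`,
`isn itinerancy`, `isn fsm`, `isn task`, `isn heterogeneity`,
`isn fixtures`); run `isn --help`.

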