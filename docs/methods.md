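# Methods

## Model

The network state is a vector of 2N nonnegative firing rates, one
excitatory (E) and one inhibitory (I) unit per pair, interleaved
(E1, I1, E2, I2, …) so each pair's strong within-pair coupling forms a 2×2
diagonal block of the weight matrix. Dynamics are threshold-linear with a
single time constant τ (default 10 ms, the only timescale in the model):

τ·dr/dt = −r + W·r − θ + Σ_α ω_α I_α(t), with the projection rule that a
unit at zero rate ignores any negative drive. Stimuli are rectangular
pulses; the leading edge is inclusive and the trailing edge exclusive, so a
pulse of duration τ_dur occupies exactly τ_dur/dt grid points.

Weight sign conventions follow Dale's law by *column* (presynaptic unit):
excitatory columns ≥ 0, inhibitory columns ≤ 0. `W[i, j]` is the connection
from unit j to unit i.

## Single-pair analytics

The UP fixed point, its Jacobian trace/determinant, and the
node/spiral/unstable/saddle classification are closed-form. Bistability
requires θ_I > θ_E > 0, inhibitory nullcline gain W_EI/(1−W_II) above
excitatory gain (W_EE−1)/(−W_IE), and a stable UP point with positive
rates.

The inverse designer takes (Tr, Δ, θ_E, θ_I, r_E*, r_I*, τ) and solves for
the four weights with `scipy.optimize.root` (hybr), starting from the
configuration that fixes W_IE = −1 and satisfies the steady-state and trace
equations, with up to 50 deterministic random restarts. After substituting
the steady-state relations the system is linear in (W_EE−1, W_II−1), so the
solve is effectively exact (residuals ≪ 1e−9); the test suite uses that
closed form as an independent oracle. Converged solutions violating the
sign convention are rejected loudly, never returned.

Targets may be given in physical units (1/s, 1/s²) or, with
`dimensionless=True`, as τ·Tr and τ²·Δ.

## State dependence, sweeps, tolerance

A stimulus is state-dependent when the identical pulse drives DOWN→UP from
the origin and UP→DOWN from the UP point. Final states are identified with
the same criteria as attractor settling (below); non-convergence is
reported as `indeterminate`, never silently counted as a failed
transition. Sweeps default to log-spaced 40×40 grids spanning a 100-fold
amplitude range and a 1000-fold duration range; linear duration grids
expose the near-periodicity of the state-dependent region at the UP
spiral's rotation period 2π/ω, ω = √(4Δ−Tr²)/2. That recurrence is only
visible when the spiral is weakly damped (|Tr| ≪ ω): a strongly damped
transient decays before completing a rotation, and the window does not
recur.

Tolerance converts the state-dependent fraction f_sd into the diameter D of
an equal-area circle on log₁₀ axes spanning the marked stimulus sets and
reports 10^D − 1; it is zero exactly when f_sd is zero.

## Integration

Classic fourth-order Runge–Kutta with the nonnegativity clamp applied after
every combined step *and* to every intermediate stage state (configurable;
stage clamping is the default because it keeps the vector field from being
evaluated at unphysical negative rates — whether the original scheme
clamped stages is ambiguous, and both modes are provided). The inner loop
is compiled with numba; divergence (non-finite state) raises an error
naming the offending time.

Step sizes: 10 µs is the reference resolution for stimulus application; the
autonomous equilibration used in settling and sweeps runs at 100 µs for
speed. Catalogued fixed points are *not* integrator output (see below), so
this choice affects only transition outcomes; the step-halving test and the
homogeneous-bound checks pass at both resolutions, and the worked-example
quantities are identical at 10, 20 and 100 µs.

## Attractor settling and enumeration

Every attractor of the clamped threshold-linear system is a fixed point
whose active set satisfies a linear system, so settling combines
integration with an exact refinement: after each 0.5 s chunk the candidate
fixed point implied by the current active set (units above 0.25 Hz) is
computed by a linear solve and checked for consistency (positive active
rates, nonpositive drive to inactive units). Convergence is declared when

1. **proximity** — the trajectory stays within 0.5 Hz of the candidate for
   the trailing 0.5 s, or
2. **decay envelope** — after the full 12 s budget, the successive local
   maxima of the max-norm distance to the candidate decrease monotonically
   over the final 2 s (slowly damped spirals whose oscillation cannot reach
   the 0.5 Hz tube in 12 s).

Accepted states carry the linear-solve point, stationary to machine
precision (every catalogued state is verified to have max |dr/dt| < 1e−6
Hz/s). The early exit on the proximity criterion makes typical settles cost
well under a second of simulated time.

Enumeration seeds 3·2^N settles: every UP-subset of pairs, with the UP pairs
initialized at 0.5×, 1× and 2× their isolated-pair UP rates (the three
guesses bracket the attractor from below and above). States are merged when
their UP/DOWN signatures match and rates agree within 0.5 Hz (max norm).
For homogeneous networks the symmetry-reduced mode settles 3 starts per
UP-count k and credits C(N, k) permutations per stable k — O(N) instead of
O(2^N); it refuses heterogeneous networks. Exhaustive enumeration is capped
at N = 12.

## Transition graphs, itinerancy, machines

A transition applies the pulse from a catalogued state (10 µs resolution),
equilibrates with the standard criteria, and matches the result against the
catalogue (appending genuinely new stationary states). Walk length counts
transitions until a state repeats; a terminal self-loop edge is not
counted, while a closing edge onto a previously visited *different* state
is — under this convention the homogeneous worked example
(n-UP → (N−n)-UP → all-UP → all-DOWN → all-UP) scores exactly 4.

For homogeneous networks under uniform stimuli, permutation symmetry means
one representative simulation per UP-count determines the entire 2^N-node
graph; walks are then evaluated symbolically over {start set, complement,
all-UP, all-DOWN}. This is what makes 20×20-grid bound checks at N = 9
affordable.

Machine extraction is a breadth-first closure from the quiescent (all-DOWN)
state over a cue alphabet; each (state, cue) edge is simulated once and
cached. Cue vectors are standard log-normal draws rescaled to unit mean.
Machines with any non-convergent edge are marked partial and refused by the
task metrics unless forced. The inter-cue interval equals the equilibration
time (cues are presented at fixed intervals, each from a settled state).

## Task metrics

Reliability traces all 64 six-cue sequences, labels each final state by the
majority class of the non-tie sequences reaching it (the per-state majority
labeling is provably the optimal output function; the suite also verifies
this exhaustively for small machines), and scores the fraction of the 44
strict-majority sequences classified correctly. Tied (3-3) sequences are
excluded from reliability, as the majority sets are defined without them,
but *included* in primacy/recency — they produce decisions, and the
congruence of a decision with the first or last cue is well-posed for them;
only sequences ending in unlabelled states are dropped. Psychometric curves
report P(left | k left cues); unlabelled decisions contribute half a left
vote and are also counted separately. The logistic-vs-linear comparison
fits both models to the binary decisions and reports binomial
log-likelihoods (the logistic fit uses L-BFGS so perfectly separated
decisions converge to their likelihood supremum instead of erroring).

## Network construction

Cross-connection magnitudes are sampled per row and per connection class
(E→E, E→I, I→E, I→I), resampled until the empirical mean is within 5% and
the population standard deviation within 10% of the targets; single-target
rows and zero-sd targets use the mean criterion alone. Log-normal sampling
is parameterized by the desired arithmetic moments; the gamma family used
in the heterogeneity experiment is parameterized by mean and CV (Dale's
law is then automatic), with CV = 0 the homogeneous limit. Targets are
stated before the 1/N scaling applied at assembly, which keeps total input
per unit size-independent.

The fiducial cross-strength multiplier β scales class means set to 10% of
the corresponding within-pair weight magnitude, giving a within-pair to
cross input ratio near 10:1 — comfortably in the pair-dominated regime
(the dominance diagnostic reports ≈ 11:1 at the defaults).

## Reference fixtures and study conditions

- *Reference pair*: inverse-designed at θ_E = 5.34, θ_I = 82.43,
  UP = (5, 10) Hz, Tr = −50 /s, Δ = 1.5e4 /s² — a strongly oscillatory
  spiral, verified state-dependent under a 1 ms amplitude-52.15 pulse.
- *Reference network*: N = 5, log-normal cross-connectivity at CV = 0.5,
  β = 1, seed 3; a uniform pulse (amplitude 5.78, 16.1 ms) drives a
  7-transition itinerant walk, beyond the homogeneous bound of 4.
- *Task regime*: the sequence-discrimination studies use a heavily damped
  spiral (Tr = −150 /s, Δ = 1e4 /s², same thresholds and UP rates). The
  choice is mechanistic: in this regime weak pulses can only recruit pairs
  (early cues latch → primacy) while strong pulses silence and re-pattern
  the network (last cue dominates → recency), and both effects coexist with
  rich machine structure. In the strongly oscillatory regime silencing is
  easy at essentially every duration, which biases every machine toward
  recency. A seeded search in the task regime found cue pairs implementing
  perfect (reliability 1.0) machines; the packaged one has 5 states
  (network seed 0, cue seeds 47832/47833, pulse amplitude 14.53, 7.15 ms).

## Heterogeneity experiment

Gamma cross-connectivity at fixed mean with CV varied; 10 matrices per
level by default, N = 5, attractor counts by exhaustive enumeration and
itinerancy over a stimulus grid concentrated where transitions occur
(amplitudes ≈ 1.5–25, durations 5–200 ms). With only four cross-targets
per class-row, the 5%/10% resampling tolerances become statistically
unreachable above CV ≈ 2 (the acceptance probability of a 4-sample moment
match collapses below 1e−6 by CV = 2.5), so the CV axis tops out at 2.0
and the experiment raises the per-row resample cap to 4×10⁵ there. Within
the reachable range the expected signature holds: capacity decreases
monotonically with CV while mean itinerancy peaks at an intermediate CV
(≈ 1.5) and declines at 2.0.

## What the synthetic conditions do and do not show

All networks are generated by the package's own samplers; there is no
external data. Identical pairs, all-to-all cross-connectivity, noiseless
dynamics, and deterministic transitions are assumptions, not findings:
passing tests demonstrate the internal consistency of the model and the
reproducibility of its qualitative phenomena (spiral-dependent state
dependence, combinatorial capacity, itinerancy beyond the homogeneous
bound, primacy/recency trends), not that cortical circuits realize them.
Statistical claims are seed-averaged orderings over ~6–10 random networks
at desk scale; individual networks vary widely.

## Known limitations

- Fixed-step RK4 only; stiff/adaptive integration, delays, and stochastic
  (noise-driven) dynamics are out of scope, as are learning rules.
- Limit cycles are not catalogued: non-converged settles are reported and
  terminate graph walks, not classified.
- The decay-envelope criterion extrapolates from the final 2 s of a 12 s
  window; a pathological slow modulation of the envelope could in
  principle be misread (the stationarity re-verification of the candidate
  point guards the catalogue itself).
- Exhaustive enumeration cost grows as 3·2^N; beyond N = 12 only the
  homogeneous symmetry reduction is practical.
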