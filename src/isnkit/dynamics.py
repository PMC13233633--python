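"""Clamped threshold-linear rate dynamics.

The network obeys  tau * dr/dt = -r + W r - theta + sum_a omega_a I_a(t),
with each unit's rate clamped at a minimum of zero: whenever a unit sits at
zero and the right-hand side is negative, the decrease is not enacted
(projected dynamics).  Integration uses a classic fourth-order Runge-Kutta
scheme that re-applies the clamp after every update; by default the
intermediate stage states are clamped too, so no stage ever evaluates the
vector field at unphysical negative rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import rk4_run
from .network import ISNetwork

__all__ = [
    "StimulusSpec",
    "Trajectory",
    "IntegrationDivergedError",
    "rate_derivative",
    "step_rk4_clamped",
    "simulate",
]

DEFAULT_DT = 1e-5  # seconds


class IntegrationDivergedError(RuntimeError):
    """State became non-finite during integration."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"integration diverged (non-finite state) at t = {t:.6g} s")


@dataclass(frozen=True)
class StimulusSpec:
    """A rectangular current pulse with a per-unit weight vector.

    The pulse delivers ``amplitude * weights[i]`` to unit i for
    t in [onset, onset + duration).  ``weights=None`` means uniform drive
    (all ones); a cue-identity vector should have unit mean so cues differ
    in pattern, not average strength.
    """

    amplitude: float
    duration: float
    onset: float = 0.0
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if (w < 0).any():
                raise ValueError("stimulus weights must be nonnegative")
            object.__setattr__(self, "weights", w)

    def weight_vector(self, n_units: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(n_units)
        if self.weights.shape != (n_units,):
            raise ValueError(
                f"stimulus weight vector has length {self.weights.shape[0]}, "
                f"network has {n_units} units"
            )
        return self.weights


@dataclass
class Trajectory:
    """Sampled rates on a strictly increasing time grid."""

    times: np.ndarray
    rates: np.ndarray  # (n_samples, n_units)
    config: dict = field(default_factory=dict)

    @property
    def final_rates(self) -> np.ndarray:
        return self.rates[-1]

    def to_dataframe(self) -> pd.DataFrame:
        n_pairs = self.rates.shape[1] // 2
        cols = []
        for k in range(n_pairs):
            cols += [f"e{k + 1}", f"i{k + 1}"]
        df = pd.DataFrame(self.rates, columns=cols)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _stimulus_arrays(stimuli: Sequence[StimulusSpec], n_units: int):
    if not stimuli:
        return (np.zeros(0), np.zeros(0), np.zeros(0), np.zeros((0, n_units)))
    amps = np.array([s.amplitude for s in stimuli], float)
    onsets = np.array([s.onset for s in stimuli], float)
    durs = np.array([s.duration for s in stimuli], float)
    omegas = np.stack([s.weight_vector(n_units) for s in stimuli])
    return amps, onsets, durs, omegas


def rate_derivative(r: np.ndarray, net: ISNetwork, drive: np.ndarray) -> np.ndarray:
    """Projected instantaneous rate change, (-r + W r - theta + drive)/tau.

    Components where the rate is zero and the raw derivative negative are set
    to zero, matching the clamp in the integrator.
    """
    r = np.asarray(r, float)
    drive = np.asarray(drive, float)
    n = net.n_units
    if r.shape != (n,) or drive.shape != (n,):
        raise ValueError(
            f"dimension mismatch: r {r.shape}, drive {drive.shape}, "
            f"network expects length {n}"
        )
    d = (-r + net.weights @ r - net.thresholds + drive) / net.tau
    d[(r <= 0.0) & (d < 0.0)] = 0.0
    return d


def step_rk4_clamped(r: np.ndarray, net: ISNetwork,
                     stimuli: Sequence[StimulusSpec], t: float, dt: float,
                     stage_clamp: bool = True) -> np.ndarray:
    """One clamped RK4 step from time ``t`` to ``t + dt``."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    r = np.array(r, float)
    if r.shape != (net.n_units,):
        raise ValueError("state vector length does not match network")
    amps, onsets, durs, omegas = _stimulus_arrays(stimuli, net.n_units)
    samples = np.empty((2, net.n_units))
    bad = rk4_run(r, net.weights, net.thresholds, net.tau, t, dt, 1,
                  amps, onsets, durs, omegas, stage_clamp, 1, samples)
    if bad >= 0:
        raise IntegrationDivergedError(t + bad * dt)
    return r


def simulate(net: ISNetwork, r0: np.ndarray,
             stimuli: Sequence[StimulusSpec] = (),
             t_end: float = 1.0, dt: float = DEFAULT_DT,
             sample_every: int = 100, t_start: float = 0.0,
             stage_clamp: bool = True) -> Trajectory:
    """Integrate from ``t_start`` to ``t_start + t_end`` and sample rates.

    ``sample_every`` thins the stored trajectory to every k-th step (the
    integration itself always runs at ``dt``).  The final state is always
    included.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if not dt > 0:
        raise ValueError("dt must be positive")
    r = np.array(r0, float)
    if r.shape != (net.n_units,):
        raise ValueError("initial state length does not match network")
    if (r < 0).any():
        raise ValueError("initial rates must be nonnegative")

    n_steps = int(round(t_end / dt))
    amps, onsets, durs, omegas = _stimulus_arrays(stimuli, net.n_units)
    n_samples = n_steps // sample_every + 1
    samples = np.empty((n_samples, net.n_units))
    bad = rk4_run(r, net.weights, net.thresholds, net.tau, t_start, dt, n_steps,
                  amps, onsets, durs, omegas, stage_clamp, sample_every, samples)
    if bad >= 0:
        raise IntegrationDivergedError(t_start + bad * dt)

    times = t_start + np.arange(n_samples) * (sample_every * dt)
    if n_steps % sample_every != 0:
        times = np.append(times, t_start + n_steps * dt)
        samples = np.vstack([samples, r])
    return Trajectory(times=times, rates=samples,
                      config={"dt": dt, "stage_clamp": stage_clamp,
                              "sample_every": sample_every})
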