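"""Numba-compiled inner loops for the clamped threshold-linear integrator."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _drive_at(t, amps, onsets, durs, omegas, out):
    """Total stimulus current per unit at time ``t``.

    Pulses are on for t in [onset, onset + duration): the leading edge is
    inclusive, the trailing edge exclusive, so a pulse covers exactly
    duration/dt grid points.
    """
    n = out.shape[0]
    for i in range(n):
        out[i] = 0.0
    for a in range(amps.shape[0]):
        if t >= onsets[a] and t < onsets[a] + durs[a]:
            for i in range(n):
                out[i] += amps[a] * omegas[a, i]


@njit(cache=True)
def _deriv(r, W, theta, tau, drive, out):
    """Projected rate derivative: components pushing a zero rate negative are
    zeroed (the rate is clamped at a minimum of zero)."""
    n = r.shape[0]
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += W[i, j] * r[j]
        v = (-r[i] + acc - theta[i] + drive[i]) / tau
        if r[i] <= 0.0 and v < 0.0:
            v = 0.0
        out[i] = v


@njit(cache=True)
def rk4_run(r, W, theta, tau, t0, dt, n_steps,
            amps, onsets, durs, omegas,
            stage_clamp, sample_every, samples):
    """Integrate ``n_steps`` classic RK4 steps in place, clamping rates >= 0.

    ``samples`` is preallocated with shape (n_steps // sample_every + 1, n)
    and receives the state at step 0 and after every ``sample_every``-th
    step.  Returns the step index at which the state became non-finite, or
    -1 on success.
    """
    n = r.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    dr = np.empty(n)
    si = 0
    for i in range(n):
        samples[0, i] = r[i]
    for s in range(n_steps):
        t = t0 + s * dt
        _drive_at(t, amps, onsets, durs, omegas, dr)
        _deriv(r, W, theta, tau, dr, k1)

        for i in range(n):
            tmp[i] = r[i] + 0.5 * dt * k1[i]
            if stage_clamp and tmp[i] < 0.0:
                tmp[i] = 0.0
        _drive_at(t + 0.5 * dt, amps, onsets, durs, omegas, dr)
        _deriv(tmp, W, theta, tau, dr, k2)

        for i in range(n):
            tmp[i] = r[i] + 0.5 * dt * k2[i]
            if stage_clamp and tmp[i] < 0.0:
                tmp[i] = 0.0
        _deriv(tmp, W, theta, tau, dr, k3)

        for i in range(n):
            tmp[i] = r[i] + dt * k3[i]
            if stage_clamp and tmp[i] < 0.0:
                tmp[i] = 0.0
        _drive_at(t + dt, amps, onsets, durs, omegas, dr)
        _deriv(tmp, W, theta, tau, dr, k4)

        ok = True
        for i in range(n):
            v = r[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if v < 0.0:
                v = 0.0
            if not np.isfinite(v):
                ok = False
            r[i] = v
        if not ok:
            return s
        if (s + 1) % sample_every == 0:
            si += 1
            for i in range(n):
                samples[si, i] = r[i]
    return -1
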