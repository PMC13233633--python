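"""Analytic treatment of a single inhibition-stabilized pair.

For one E-I pair the dynamics reduce to a planar threshold-linear system
whose nonzero (UP) fixed point is available in closed form.  Local stability
follows from the trace and determinant of the Jacobian: the UP state is
stable when Tr < 0 and Det > 0, a node when Tr^2 > 4 Det, and a spiral when
Tr^2 < 4 Det.  Spiral (damped-oscillatory) UP dynamics are what let a purely
excitatory pulse knock the pair from UP to DOWN, and hence what make the
same stimulus switch the pair in both directions (a state-dependent
response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .dynamics import StimulusSpec, simulate
from .network import ISNetwork, ISPParams

__all__ = [
    "FixedPointReport",
    "SweepResult",
    "DegenerateSystemError",
    "NoSolutionError",
    "DaleSignError",
    "up_fixed_point",
    "classify_up",
    "bistability_check",
    "solve_isp_from_spec",
    "state_dependence_test",
    "stimulus_sweep",
    "tolerance",
    "up_rotation_period",
]


class DegenerateSystemError(ValueError):
    """The steady-state system is singular (zero denominator)."""


class NoSolutionError(RuntimeError):
    """The inverse design solve did not converge."""


class DaleSignError(RuntimeError):
    """A converged inverse solve violates the sign convention."""


@dataclass(frozen=True)
class FixedPointReport:
    """Location and linear classification of the UP fixed point."""

    r_e: float
    r_i: float
    trace: float  # 1/s
    determinant: float  # 1/s^2
    kind: str  # stable node | stable spiral | unstable | saddle | invalid

    @property
    def location(self) -> tuple:
        return (float(self.r_e), float(self.r_i))


def _classify(trace: float, determinant: float) -> str:
    if determinant < 0:
        return "saddle"
    if trace >= 0:
        return "unstable"
    if trace**2 < 4 * determinant:
        return "stable spiral"
    return "stable node"


def trace_determinant(p: ISPParams) -> tuple:
    """Trace (1/s) and determinant (1/s^2) of the UP-state Jacobian."""
    tr = (p.w_ee + p.w_ii - 2.0) / p.tau
    det = ((p.w_ee - 1.0) * (p.w_ii - 1.0) - p.w_ei * p.w_ie) / p.tau**2
    return tr, det


def jacobian(p: ISPParams) -> np.ndarray:
    """Jacobian of the pair dynamics at the UP fixed point (units 1/s)."""
    return (1.0 / p.tau) * np.array(
        [[p.w_ee - 1.0, p.w_ie], [p.w_ei, p.w_ii - 1.0]]
    )


def up_fixed_point(p: ISPParams, I: float = 0.0) -> FixedPointReport:
    """Closed-form nonzero fixed point under constant input ``I``.

    Flags ``kind='invalid'`` when either steady rate is negative (the formal
    solution lies outside the physical quadrant).
    """
    denom = (p.w_ii - 1.0) * (p.w_ee - 1.0) - p.w_ei * p.w_ie
    if denom == 0.0:
        raise DegenerateSystemError("singular steady-state system (zero denominator)")
    r_e = -(p.w_ie * (p.theta_i - I) + (1.0 - p.w_ii) * (p.theta_e - I)) / denom
    r_i = -(p.w_ei * (p.theta_e - I) + (1.0 - p.w_ee) * (p.theta_i - I)) / denom
    tr, det = trace_determinant(p)
    kind = "invalid" if (r_e < 0 or r_i < 0) else _classify(tr, det)
    return FixedPointReport(r_e=r_e, r_i=r_i, trace=tr, determinant=det, kind=kind)


def classify_up(p: ISPParams) -> str:
    """Node/spiral/unstable/saddle classification of the UP point."""
    return up_fixed_point(p).kind


def up_rotation_period(p: ISPParams) -> float:
    """Rotation period 2*pi/omega of a spiral UP point, omega = sqrt(4*Det - Tr^2)/2."""
    tr, det = trace_determinant(p)
    disc = 4.0 * det - tr**2
    if disc <= 0:
        raise ValueError("UP point is not a spiral (Tr^2 >= 4 Det)")
    return 2.0 * math.pi / (math.sqrt(disc) / 2.0)


def bistability_check(p: ISPParams) -> tuple:
    """Whether the pair supports both a stable DOWN and a stable UP state.

    Requires (1) theta_I > theta_E > 0 (the origin is then locally stable),
    (2) the inhibitory nullcline gain W_EI/(1-W_II) exceeds the excitatory
    nullcline gain (W_EE-1)/(-W_IE), and (3) the closed-form UP point is
    stable with both rates positive.  Returns (ok, diagnostic) where the
    diagnostic names the first failed condition.
    """
    if not (p.theta_i > p.theta_e > 0):
        return False, "threshold ordering violated (need theta_I > theta_E > 0)"
    gain_i = p.w_ei / (1.0 - p.w_ii)  # 1 - w_ii >= 1 > 0
    if p.w_ie == 0.0:
        gain_e = math.inf if p.w_ee > 1.0 else -math.inf
    else:
        gain_e = (p.w_ee - 1.0) / (-p.w_ie)
    if not gain_i > gain_e:
        return False, "inhibitory nullcline gain does not exceed excitatory gain"
    try:
        fp = up_fixed_point(p)
    except DegenerateSystemError:
        return False, "degenerate steady-state system"
    if fp.r_e <= 0 or fp.r_i <= 0:
        return False, "UP fixed point has a nonpositive rate"
    if fp.kind not in ("stable node", "stable spiral"):
        return False, "UP unstable"
    return True, "bistable"


def _design_residuals(w, trace, det, theta_e, theta_i, r_e, r_i, tau):
    """Dimensionless residuals of the inverse-design system."""
    w_ee, w_ie, w_ei, w_ii = w
    return np.array([
        (w_ee + w_ii - 2.0) - tau * trace,
        ((w_ee - 1.0) * (w_ii - 1.0) - w_ei * w_ie) - tau**2 * det,
        ((w_ee - 1.0) * r_e + w_ie * r_i - theta_e) / max(theta_e, 1.0),
        (w_ei * r_e + (w_ii - 1.0) * r_i - theta_i) / max(theta_i, 1.0),
    ])


def solve_isp_from_spec(trace: float, determinant: float,
                        theta_e: float, theta_i: float,
                        r_e_up: float, r_i_up: float,
                        tau: float = 0.010,
                        dimensionless: bool = False,
                        max_restarts: int = 50,
                        tol: float = 1e-9) -> ISPParams:
    """Solve for the four weights hitting a prescribed UP point and Jacobian.

    Given thresholds, target UP rates (at zero input) and a target
    (trace, determinant) of the UP-state Jacobian, finds the pair weights by
    a root solve.  ``dimensionless=True`` interprets the targets as tau*Tr
    and tau^2*Det.  The first guess fixes W_IE = -1 and back-substitutes;
    deterministic random restarts perturb it if the solver stalls.
    """
    if dimensionless:
        trace = trace / tau
        determinant = determinant / tau**2
    if not (trace < 0 and determinant > 0):
        raise ValueError("target UP point must be stable: trace < 0, determinant > 0")
    if not (theta_i > theta_e > 0):
        raise ValueError("need theta_I > theta_E > 0 for the bistable regime")
    if not (r_e_up > 0 and r_i_up > 0):
        raise ValueError("target UP rates must be positive")

    # first guess: fix w_ie = -1, satisfy the steady-state and trace equations
    w_ee0 = 1.0 + (theta_e + r_i_up) / r_e_up
    w_ii0 = 2.0 + tau * trace - w_ee0
    w_ei0 = (theta_i - (w_ii0 - 1.0) * r_i_up) / r_e_up
    guess0 = np.array([w_ee0, -1.0, w_ei0, w_ii0])

    rng = np.random.default_rng(0)
    args = (trace, determinant, theta_e, theta_i, r_e_up, r_i_up, tau)
    best_res = np.inf
    for attempt in range(max_restarts + 1):
        guess = guess0 if attempt == 0 else guess0 * (
            1.0 + 0.5 * rng.standard_normal(4))
        sol = optimize.root(_design_residuals, guess, args=args, method="hybr")
        res = np.max(np.abs(_design_residuals(sol.x, *args)))
        best_res = min(best_res, res)
        if res < tol:
            w_ee, w_ie, w_ei, w_ii = sol.x
            if w_ee < 0 or w_ei < 0 or w_ie > 0 or w_ii > 0:
                raise DaleSignError(
                    f"converged solution violates the sign convention: "
                    f"w_ee={w_ee:.4g}, w_ie={w_ie:.4g}, w_ei={w_ei:.4g}, w_ii={w_ii:.4g}"
                )
            return ISPParams(w_ee=w_ee, w_ie=w_ie, w_ei=w_ei, w_ii=w_ii,
                             theta_e=theta_e, theta_i=theta_i, tau=tau)
    raise NoSolutionError(
        f"inverse design failed after {max_restarts} restarts "
        f"(best residual {best_res:.3g})"
    )


# ---------------------------------------------------------------------------
# state dependence and stimulus sweeps
# ---------------------------------------------------------------------------

def _final_state_identity(rates: Optional[np.ndarray], up_location,
                          tol: float = 0.5) -> str:
    if rates is None:
        return "indeterminate"
    if (rates < tol).all():
        return "down"
    if np.max(np.abs(rates - np.asarray(up_location))) < tol:
        return "up"
    return "indeterminate"


def _respond(net: ISNetwork, r0: np.ndarray, stim: StimulusSpec,
             settle_time: float, pulse_dt: float, settle_dt: float):
    """Apply the pulse then equilibrate; return settled rates or None."""
    from .attractors import settle  # deferred: attractors imports network only

    t_pulse = stim.onset + stim.duration
    traj = simulate(net, r0, [stim], t_end=t_pulse, dt=pulse_dt,
                    sample_every=max(1, int(round(t_pulse / pulse_dt))))
    res = settle(net, traj.final_rates, settle_time=settle_time, dt=settle_dt)
    return res.state.rates if res.converged else None


def state_dependence_test(p: ISPParams, stim: StimulusSpec,
                          settle_time: float = 12.0,
                          pulse_dt: float = 1e-5,
                          settle_dt: float = 1e-4) -> dict:
    """Apply one stimulus from DOWN and from UP; report both transitions.

    A response is state-dependent when the same pulse drives DOWN->UP and
    UP->DOWN.  Non-convergence of either equilibration is reported via the
    ``indeterminate`` flag, never silently treated as a failed transition.
    """
    ok, why = bistability_check(p)
    if not ok:
        raise ValueError(f"pair is not bistable: {why}")
    net = ISNetwork.from_pair(p)
    up = up_fixed_point(p)

    from_down = _respond(net, np.zeros(2), stim, settle_time, pulse_dt, settle_dt)
    from_up = _respond(net, np.array(up.location), stim, settle_time,
                       pulse_dt, settle_dt)
    id_down = _final_state_identity(from_down, up.location)
    id_up = _final_state_identity(from_up, up.location)

    indeterminate = "indeterminate" in (id_down, id_up)
    down_to_up = id_down == "up"
    up_to_down = id_up == "down"
    return {
        "down_to_up": down_to_up,
        "up_to_down": up_to_down,
        "state_dependent": down_to_up and up_to_down,
        "indeterminate": indeterminate,
    }


@dataclass
class SweepResult:
    """State-dependence over an amplitude x duration stimulus grid."""

    amplitudes: np.ndarray
    durations: np.ndarray
    down_to_up: np.ndarray  # (n_amp, n_dur) bool
    up_to_down: np.ndarray
    state_dependent: np.ndarray
    indeterminate: np.ndarray
    f_sd: float = field(init=False)
    tolerance: float = field(init=False)

    def __post_init__(self) -> None:
        self.f_sd = float(self.state_dependent.mean())
        mask = self.state_dependent
        if mask.any():
            amp_set = self.amplitudes[mask.any(axis=1)]
            dur_set = self.durations[mask.any(axis=0)]
            self.tolerance = tolerance(self.f_sd, amp_set, dur_set)
        else:
            self.tolerance = 0.0

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, a in enumerate(self.amplitudes):
            for j, d in enumerate(self.durations):
                rows.append({
                    "amplitude": a, "duration": d,
                    "down_to_up": bool(self.down_to_up[i, j]),
                    "up_to_down": bool(self.up_to_down[i, j]),
                    "state_dependent": bool(self.state_dependent[i, j]),
                })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"f_sd": self.f_sd, "tolerance": self.tolerance}


def default_grids(n_amp: int = 40, n_dur: int = 40,
                  amp_lo: float = 6.0, dur_lo: float = 0.001):
    """Log-spaced sweep grids: 100-fold amplitude, 1000-fold duration range."""
    amps = np.geomspace(amp_lo, amp_lo * 100.0, n_amp)
    durs = np.geomspace(dur_lo, dur_lo * 1000.0, n_dur)
    return amps, durs


def stimulus_sweep(p: ISPParams, amp_grid: Sequence[float],
                   dur_grid: Sequence[float],
                   settle_time: float = 12.0,
                   pulse_dt: float = 1e-5,
                   settle_dt: float = 1e-4) -> SweepResult:
    """Run the state-dependence test at every grid cell.

    Grids may be log- or linearly spaced; linear duration spacing exposes the
    near-periodicity of the state-dependent region at the UP spiral's
    rotation period.
    """
    amps = np.asarray(amp_grid, float)
    durs = np.asarray(dur_grid, float)
    if (amps <= 0).any() or (durs <= 0).any():
        raise ValueError("grids must be positive")
    shape = (amps.size, durs.size)
    d2u = np.zeros(shape, bool)
    u2d = np.zeros(shape, bool)
    sd = np.zeros(shape, bool)
    ind = np.zeros(shape, bool)
    for i, a in enumerate(amps):
        for j, d in enumerate(durs):
            res = state_dependence_test(
                p, StimulusSpec(amplitude=a, duration=d),
                settle_time=settle_time, pulse_dt=pulse_dt, settle_dt=settle_dt)
            d2u[i, j] = res["down_to_up"]
            u2d[i, j] = res["up_to_down"]
            sd[i, j] = res["state_dependent"]
            ind[i, j] = res["indeterminate"]
    return SweepResult(amplitudes=amps, durations=durs, down_to_up=d2u,
                       up_to_down=u2d, state_dependent=sd, indeterminate=ind)


def tolerance(f_sd: float, amp_set: Sequence[float],
              dur_set: Sequence[float]) -> float:
    """Log-scale effective stimulus diameter supporting state-dependence.

    Converts the state-dependent fraction f_sd into the diameter D of an
    equal-area circle on log10 axes spanning the marked stimulus sets, and
    returns 10**D - 1 (fold-range divided by the minimum stimulus).  Zero
    when no stimulus was state-dependent.
    """
    if not 0.0 <= f_sd <= 1.0:
        raise ValueError("f_sd must lie in [0, 1]")
    if f_sd == 0.0:
        return 0.0
    amp_set = np.asarray(amp_set, float)
    dur_set = np.asarray(dur_set, float)
    if amp_set.size == 0 or dur_set.size == 0 or (amp_set <= 0).any() or (dur_set <= 0).any():
        raise ValueError("stimulus sets must be nonempty with positive entries")
    area = (f_sd
            * math.log10(amp_set.max() / amp_set.min())
            * math.log10(dur_set.max() / dur_set.min()))
    return 10.0 ** math.sqrt(4.0 * area / math.pi) - 1.0
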