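"""Network containers and constrained random connectivity.

An inhibition-stabilized network (ISN) is built from N identical
excitatory-inhibitory rate-unit pairs (ISPs).  Within-pair coupling is strong
and hand-specified; coupling between pairs is weak, random, all-to-all, and
constrained so that (i) Dale's law holds (a unit's outgoing weights share the
sign of its type), and (ii) every row of the weight matrix carries the same
per-class total input, enforced by resampling rows until their empirical
moments match the targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ISPParams",
    "ISNetwork",
    "CrossConnectivitySpec",
    "CueVector",
    "InfeasibleStatisticsError",
    "sample_cross_row",
    "assemble_isn",
    "make_cue_vector",
    "coupling_dominance",
    "fiducial_cross_spec",
]

#: connection classes, named source-to-target
CONNECTION_CLASSES = ("e_to_e", "e_to_i", "i_to_e", "i_to_i")


class InfeasibleStatisticsError(RuntimeError):
    """Raised when row resampling cannot hit the target moments."""


@dataclass(frozen=True)
class ISPParams:
    """The six scalars of one E-I pair plus the rate time constant.

    Weights are dimensionless multipliers of presynaptic rate.  Inhibitory
    weights (``w_ie``, source I; ``w_ii``) are stored non-positive; excitatory
    weights non-negative.  Thresholds share rate units (Hz); ``tau`` is in
    seconds.
    """

    w_ee: float
    w_ie: float
    w_ei: float
    w_ii: float
    theta_e: float
    theta_i: float
    tau: float = 0.010

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.w_ee < 0 or self.w_ei < 0:
            raise ValueError("excitatory-source weights w_ee, w_ei must be >= 0")
        if self.w_ie > 0 or self.w_ii > 0:
            raise ValueError("inhibitory-source weights w_ie, w_ii must be <= 0")

    def block(self) -> np.ndarray:
        """2x2 within-pair weight block in (E, I) unit order."""
        return np.array([[self.w_ee, self.w_ie], [self.w_ei, self.w_ii]], float)

    def thresholds(self) -> np.ndarray:
        return np.array([self.theta_e, self.theta_i], float)


@dataclass
class ISNetwork:
    """A 2N-unit signed weight matrix with pair bookkeeping.

    Units are interleaved (E1, I1, E2, I2, ...) so that within-pair blocks sit
    on the diagonal.  ``weights[i, j]`` is the connection from unit j to unit
    i, hence Dale's law constrains the *columns*: every entry in the column of
    an excitatory unit is >= 0, of an inhibitory unit <= 0.
    """

    n_pairs: int
    weights: np.ndarray
    thresholds: np.ndarray
    tau: float = 0.010
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = 2 * self.n_pairs
        self.weights = np.asarray(self.weights, float)
        self.thresholds = np.asarray(self.thresholds, float)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights must be {n}x{n}, got {self.weights.shape}")
        if self.thresholds.shape != (n,):
            raise ValueError(f"thresholds must have length {n}")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        exc = self.excitatory_indices
        inh = self.inhibitory_indices
        if (self.weights[:, exc] < 0).any():
            raise ValueError("Dale violation: negative weight in an excitatory column")
        if (self.weights[:, inh] > 0).any():
            raise ValueError("Dale violation: positive weight in an inhibitory column")

    @property
    def n_units(self) -> int:
        return 2 * self.n_pairs

    @property
    def excitatory_indices(self) -> np.ndarray:
        return np.arange(0, self.n_units, 2)

    @property
    def inhibitory_indices(self) -> np.ndarray:
        return np.arange(1, self.n_units, 2)

    def pair_params(self, k: int = 0) -> ISPParams:
        """Within-pair parameters of pair ``k`` read off the diagonal block."""
        i = 2 * k
        b = self.weights[i : i + 2, i : i + 2]
        return ISPParams(
            w_ee=b[0, 0], w_ie=b[0, 1], w_ei=b[1, 0], w_ii=b[1, 1],
            theta_e=self.thresholds[i], theta_i=self.thresholds[i + 1],
            tau=self.tau,
        )

    @classmethod
    def from_pair(cls, p: ISPParams) -> "ISNetwork":
        return cls(
            n_pairs=1, weights=p.block(), thresholds=p.thresholds(), tau=p.tau,
            meta={"source": "single-pair"},
        )

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "n_pairs": self.n_pairs,
            "tau": self.tau,
            "weights": self.weights.ravel().tolist(),  # row-major
            "thresholds": self.thresholds.tolist(),
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ISNetwork":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        n = 2 * payload["n_pairs"]
        return cls(
            n_pairs=payload["n_pairs"],
            weights=np.asarray(payload["weights"], float).reshape(n, n),
            thresholds=np.asarray(payload["thresholds"], float),
            tau=payload.get("tau", 0.010),
            meta=payload.get("meta", {}),
        )


@dataclass(frozen=True)
class CrossConnectivitySpec:
    """Targets for the weak random between-pair connectivity.

    ``means``/``sds`` give per-connection-class arithmetic mean and standard
    deviation of the weight *magnitudes*, stated before the 1/N scaling that
    :func:`assemble_isn` applies.  Accepted rows must land within
    ``mean_tol`` (relative) of the mean target and ``sd_tol`` of the sd
    target.
    """

    family: str = "lognormal"  # lognormal | gamma | homogeneous
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    mean_tol: float = 0.05
    sd_tol: float = 0.10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma", "homogeneous"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (self.mean_tol > 0 and self.sd_tol > 0):
            raise ValueError("tolerances must be strictly positive")
        for c in CONNECTION_CLASSES:
            if c not in self.means:
                raise ValueError(f"missing mean for class {c!r}")
            if self.means[c] < 0:
                raise ValueError("target means are magnitudes; must be >= 0")

    def sd_of(self, cls: str) -> float:
        if self.family == "homogeneous":
            return 0.0
        return float(self.sds.get(cls, 0.0))


@dataclass(frozen=True)
class CueVector:
    """Per-unit input weights identifying one cue (e.g. left vs right).

    Entries are positive and rescaled to unit mean, so cue identity changes
    the spatial pattern of the input but not its average drive.
    """

    weights: np.ndarray
    label: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        object.__setattr__(self, "weights", w)
        if (w <= 0).any():
            raise ValueError("cue weights must be positive")
        if abs(w.mean() - 1.0) > 1e-12:
            raise ValueError("cue weights must have unit mean")


def _draw_magnitudes(family: str, mean: float, sd: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` positive weight magnitudes with the requested moments."""
    if sd == 0.0 or family == "homogeneous":
        return np.full(n, mean)
    if mean <= 0:
        raise ValueError("positive-sd sampling needs a positive mean")
    if family == "lognormal":
        # arithmetic mean m and sd s -> underlying normal mu, sigma
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    if family == "gamma":
        cv = sd / mean
        shape = 1.0 / cv**2
        scale = mean * cv**2
        return rng.gamma(shape, scale, size=n)
    raise ValueError(f"unknown family {family!r}")


def sample_cross_row(spec: CrossConnectivitySpec, cls: str, n_targets: int,
                     rng: np.random.Generator, mean_scale: float = 1.0,
                     max_attempts: int = 10_000) -> np.ndarray:
    """Sample the magnitudes of one row's cross-connections of one class.

    The row is redrawn until its empirical mean is within ``mean_tol``
    (relative) of the target and its standard deviation (population, ddof=0)
    within ``sd_tol`` of the target sd.  A single-entry row or a zero-sd
    target is accepted on the mean criterion alone.  ``mean_scale`` applies
    the network-size scaling (1/N) to both target moments.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    mean = spec.means[cls] * mean_scale
    sd = spec.sd_of(cls) * mean_scale
    if mean == 0.0:
        return np.zeros(n_targets)
    tried = 0
    while tried < max_attempts:
        block = min(1000, max_attempts - tried)
        rows = _draw_magnitudes(spec.family, mean, sd, block * n_targets,
                                rng).reshape(block, n_targets)
        tried += block
        mean_ok = np.abs(rows.mean(axis=1) - mean) <= spec.mean_tol * mean
        if sd == 0.0 or n_targets == 1:
            ok = mean_ok
        else:
            ok = mean_ok & (np.abs(rows.std(axis=1, ddof=0) - sd)
                            <= spec.sd_tol * sd)
        hits = np.flatnonzero(ok)
        if hits.size:
            return rows[hits[0]]
    raise InfeasibleStatisticsError(
        f"row resampling for class {cls!r} failed after {max_attempts} attempts "
        f"(targets mean={mean:.4g}, sd={sd:.4g}; last achieved "
        f"mean={rows[-1].mean():.4g}, sd={rows[-1].std(ddof=0):.4g})"
    )


def assemble_isn(p: ISPParams, n_pairs: int, spec: CrossConnectivitySpec,
                 seed: Optional[int] = None, require_bistable: bool = True,
                 max_attempts: int = 10_000) -> ISNetwork:
    """Build an N-pair ISN: within-pair blocks from ``p``, random cross weights.

    Cross-connection target moments are scaled by 1/N so the mean total input
    per unit is independent of network size and the coefficient of variation
    of the weights is preserved.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if require_bistable:
        from .pair import bistability_check  # local import avoids a cycle

        ok, why = bistability_check(p)
        if not ok:
            raise ValueError(f"pair parameters are not bistable: {why}")

    n = 2 * n_pairs
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    theta = np.tile([p.theta_e, p.theta_i], n_pairs)
    for k in range(n_pairs):
        W[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = p.block()

    scale = 1.0 / n_pairs
    if n_pairs > 1:
        for i in range(n):  # postsynaptic unit = row
            post = "e" if i % 2 == 0 else "i"
            my_pair = i // 2
            others = [q for q in range(n_pairs) if q != my_pair]
            e_cols = [2 * q for q in others]
            i_cols = [2 * q + 1 for q in others]
            row_e = sample_cross_row(spec, f"e_to_{post}", len(e_cols), rng,
                                     scale, max_attempts=max_attempts)
            row_i = sample_cross_row(spec, f"i_to_{post}", len(i_cols), rng,
                                     scale, max_attempts=max_attempts)
            W[i, e_cols] = row_e  # excitatory source: positive
            W[i, i_cols] = -row_i  # inhibitory source: negative

    meta = {
        "seed": int(seed),
        "family": spec.family,
        "means": dict(spec.means),
        "sds": {c: spec.sd_of(c) for c in CONNECTION_CLASSES},
        "n_pairs": n_pairs,
        "pair": {f: getattr(p, f) for f in
                 ("w_ee", "w_ie", "w_ei", "w_ii", "theta_e", "theta_i", "tau")},
    }
    return ISNetwork(n_pairs=n_pairs, weights=W, thresholds=theta, tau=p.tau, meta=meta)


def make_cue_vector(n_pairs: int, seed: int, label: str = "cue") -> CueVector:
    """Draw a cue weight vector: standard log-normal entries, unit mean."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    w = rng.lognormal(0.0, 1.0, size=2 * n_pairs)
    w = w / w.mean()
    return CueVector(weights=w, label=label, seed=seed)


def coupling_dominance(net: ISNetwork) -> np.ndarray:
    """Per-unit ratio of within-pair to summed cross input magnitude.

    Values above 1 indicate the within-pair coupling dominates, the regime
    the architecture assumes.
    """
    n = net.n_units
    ratios = np.empty(n)
    absW = np.abs(net.weights)
    for i in range(n):
        k = i // 2
        within = absW[i, 2 * k] + absW[i, 2 * k + 1]
        cross = absW[i].sum() - within
        ratios[i] = np.inf if cross == 0 else within / cross
    return ratios


def fiducial_cross_spec(p: ISPParams, beta: float = 1.0, cv: float = 0.5,
                        family: str = "lognormal", seed: Optional[int] = None,
                        cross_fraction: float = 0.1) -> CrossConnectivitySpec:
    """Default cross-connectivity targets derived from the within-pair weights.

    Each class's target mean is ``cross_fraction * beta`` times the magnitude
    of the corresponding within-pair weight, so the total cross input per
    unit sits near ``cross_fraction * beta`` of the within-pair input (a
    roughly 10:1 dominance at the defaults).  ``beta`` is the overall
    cross-strength multiplier; ``cv`` the weight coefficient of variation.
    """
    base = {
        "e_to_e": abs(p.w_ee), "e_to_i": abs(p.w_ei),
        "i_to_e": abs(p.w_ie), "i_to_i": abs(p.w_ii),
    }
    means = {c: cross_fraction * beta * v for c, v in base.items()}
    if cv == 0.0:
        family = "homogeneous"
    sds = {c: cv * m for c, m in means.items()}
    return CrossConnectivitySpec(family=family, means=means, sds=sds, seed=seed)
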