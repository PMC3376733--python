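"""Run-off elongation model of position-dependent mRNA persistence.

At heat-shock onset, initiation of RNA polymerase II transcription is
reduced or stops, but polymerases already on the template keep elongating.
A gene at distance d from its initiation site therefore continues to be
transcribed until the last pre-shock polymerase arrives, a journey time of
tau = d / v (about 60 min for d ~ 250 kbp at the mammalian elongation rate
of 4.3 kb/min); any additional pausing stretches tau by a factor >= 1.
With first-order mRNA decay at rate k and pre-shock steady state m0 = p0/k,
the relative abundance stays at 1 while production continues and decays
exponentially once it stops — so distal genes' mRNAs persist longer, and
their *relative* abundance rises as proximal mRNAs fall.

No decay-rate measurements are modelled here: k is a user parameter and the
default (30-min half-life) is a placeholder, not a fitted value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: RNAP II elongation rate, kb per minute (mammalian estimate).
DEFAULT_ELONGATION_RATE = 4.3


@dataclass(frozen=True)
class RunoffParams:
    """Kinetic parameters of the run-off model.

    v: elongation rate, kb/min; k: first-order mRNA decay rate, /min
    (default ln2/30, a 30-min half-life placeholder); p0: pre-shock
    production rate, arbitrary units/min; pause_factor: multiplies the
    journey time (>= 1); initiation_reduction: residual initiation after
    onset as a fraction of p0 (0 = full stop, the default).
    """

    v: float = DEFAULT_ELONGATION_RATE
    k: float = math.log(2) / 30.0
    p0: float = 1.0
    pause_factor: float = 1.0
    initiation_reduction: float = 0.0

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("elongation rate v must be > 0")
        if self.k < 0:
            raise ValueError("decay rate k must be >= 0")
        if self.p0 <= 0:
            raise ValueError("production rate p0 must be > 0")
        if self.pause_factor < 1:
            raise ValueError("pause_factor must be >= 1")
        if not 0 <= self.initiation_reduction <= 1:
            raise ValueError("initiation_reduction must be in [0, 1]")

    @classmethod
    def from_half_life(cls, half_life: float, **kw) -> "RunoffParams":
        return cls(k=math.log(2) / half_life, **kw)


@dataclass(frozen=True)
class AbundanceTrajectory:
    times: tuple[float, ...]  # minutes since heat-shock onset
    relative_abundance: tuple[float, ...]
    distance: int
    tau: float  # production cutoff, minutes
    params: RunoffParams = field(compare=False, default=RunoffParams())


def production_time(distance: float, params: RunoffParams) -> float:
    """Journey time tau = pause_factor * (distance/1000) / v, minutes.

    This is how long after onset the gene keeps being transcribed by
    polymerases that had initiated before heat shock."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return params.pause_factor * (distance / 1000.0) / params.v


def relative_abundance(t: np.ndarray, distance: float, params: RunoffParams) -> np.ndarray:
    """Closed-form relative mRNA abundance m(t)/m0 at minutes ``t``.

    1 for t <= tau; afterwards r + (1 - r) * exp(-k (t - tau)) where r is
    the residual initiation fraction (0 by default)."""
    t = np.asarray(t, dtype=float)
    tau = production_time(distance, params)
    r = params.initiation_reduction
    out = np.ones_like(t)
    late = t > tau
    out[late] = r + (1.0 - r) * np.exp(-params.k * (t[late] - tau))
    return out


def simulate_abundance(
    distance: float, params: RunoffParams, times: list[float] | np.ndarray
) -> AbundanceTrajectory:
    """Relative-abundance trajectory for one gene distance.

    ``times`` must be sorted and start at 0 (heat-shock onset). The
    trajectory is the closed form; :func:`integrate_abundance` provides the
    independent numerical route. With k = 0 there is no pre-shock steady
    state; the no-decay limit (abundance 1 at all finite times) is returned
    with a warning.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0 or np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted and start at 0")
    if params.k == 0:
        logger.warning("k = 0: no steady state; returning the no-decay limit")
        rel = np.ones_like(t)
    else:
        rel = relative_abundance(t, distance, params)
    return AbundanceTrajectory(
        times=tuple(t),
        relative_abundance=tuple(rel),
        distance=int(distance),
        tau=production_time(distance, params),
        params=params,
    )


def integrate_abundance(
    distance: float,
    params: RunoffParams,
    times: list[float] | np.ndarray,
    max_step: float = 0.01,
) -> np.ndarray:
    """Forward RK4 integration of dm/dt = p(t) - k m from m(0) = p0/k,
    with the production cutoff at tau inserted as a step boundary.

    Returns m(t)/m0 at ``times``; agrees with the closed form to high
    accuracy and serves as its independent check.
    """
    if params.k == 0:
        raise ValueError("numerical route requires k > 0 (no steady state at k=0)")
    t_eval = np.asarray(times, dtype=float)
    tau = production_time(distance, params)
    r = params.initiation_reduction

    # breakpoints: every requested time plus tau, so no RK4 step straddles
    # the production discontinuity; production is constant within a segment
    grid = np.unique(np.concatenate([t_eval, [0.0, tau]]))
    grid = grid[grid >= 0]
    m0 = params.p0 / params.k
    m = m0
    out = {0.0: m0}
    for a, b in zip(grid[:-1], grid[1:]):
        p_seg = params.p0 if (a + b) / 2 <= tau else r * params.p0

        def rhs(m: float) -> float:
            return p_seg - params.k * m

        n_steps = max(1, math.ceil((b - a) / max_step))
        h = (b - a) / n_steps
        for _ in range(n_steps):
            k1 = rhs(m)
            k2 = rhs(m + h / 2 * k1)
            k3 = rhs(m + h / 2 * k2)
            k4 = rhs(m + h * k3)
            m += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[b] = m
    return np.array([out[t] / m0 for t in t_eval])


def compare_positions(
    distances: list[float], params: RunoffParams, t: float
) -> list[float]:
    """Relative abundance at time ``t`` for each gene distance; always
    non-decreasing in distance (distal mRNAs persist longer)."""
    if not distances:
        raise ValueError("distances must be nonempty")
    if params.k == 0:
        return [1.0] * len(distances)
    return [
        float(relative_abundance(np.array([t]), d, params)[0]) for d in distances
    ]
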