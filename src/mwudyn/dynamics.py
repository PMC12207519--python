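"""Heterogeneous multiplicative-weights-update (MWU) learning dynamics in
two-strategy nonatomic congestion games.

A population of total mass ``Q`` is split into ``m`` types; a fraction
``mu_i`` of the population has type ``i`` and plays strategy 1 with
probability ``x_i``.  Strategy costs are linear in their loads,

    C1 = alpha * Q * (M . X),        C2 = beta * Q * (1 - M . X),

with ``M . X = sum_i mu_i x_i`` the population-average frequency of
strategy 1 (the *flow*).  Every type updates by MWU with its own learning
rate ``a_i > 0``; after absorbing the cost normalization into ``a_i`` and
the cost asymmetry ``b = beta / (alpha + beta)`` the one-step map is

    x_i' = x_i / (x_i + (1 - x_i) * exp(a_i * (M . X - b))).

In logit coordinates ``z_i = log(x_i / (1 - x_i))`` the same step is the
exact linear shift ``z_i' = z_i - a_i * (M . X - b)``, which is the
representation used throughout (it never overflows and keeps every
coordinate strictly inside (0, 1)).

The module is laid out in the order the method runs:

1.  tolerances and defaults;
2.  game definition, costs, the epsilon <-> a reparametrization;
3.  the one-step map and trajectory iteration;
4.  the invariant-curve splitting and the conjugate one-dimensional map
    ``g(s) = s + M . y(s) - b``, equilibria and linear stability;
5.  ergodic / chaos diagnostics (time averages, normalized social cost,
    Lyapunov exponent, periodic orbits, orbit classification);
6.  the sigma-family (scaling A -> sigma * A): bifurcation scans and the
    critical sigma of the first instability;
7.  experiment fixtures (the two worked examples, seeded random
    populations), config and CSV/JSON readers/writers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "Tolerances",
    "TOL",
    "CongestionGame",
    "PopulationState",
    "Trajectory",
    "CurveContext",
    "PeriodicOrbit",
    "DiagnosticsReport",
    "SigmaScan",
    "ExperimentSpec",
    "BracketError",
    "costs",
    "social_cost",
    "epsilon_to_a",
    "a_to_epsilon",
    "mwu_step",
    "iterate",
    "iterate_to_fixed_point",
    "curve_point",
    "curve_coordinate",
    "reduced_map",
    "reduced_derivative",
    "equilibrium_on_curve",
    "iterate_reduced",
    "curve_coordinates",
    "time_average_flow",
    "time_average_costs",
    "normalized_social_cost",
    "lyapunov_exponent",
    "lyapunov_from_trajectory",
    "find_periodic_orbits",
    "classify_orbit",
    "diagnose",
    "sigma_scan",
    "sigma_critical",
    "example1",
    "example2",
    "random_population",
    "game_from_spec",
    "initial_state",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_json",
    "write_curve_scan_csv",
    "write_sigma_scan_csv",
    "write_sigma_summary_csv",
    "write_config",
    "read_config",
]

# ---------------------------------------------------------------------------
# 1. Tolerances and defaults
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Tolerances:
    """Central numerical tolerances and default horizons.

    All comparisons in the package route through one instance of this class
    so that every threshold is documented and overridable in one place.
    """

    #: simplex-sum slack for the type-weight vector M
    simplex: float = 1e-12
    #: |M.y(s*) - b| at a located equilibrium
    equilibrium_flow: float = 1e-12
    #: root tolerance (in s) for bracketed root finding on the curve
    root_s: float = 1e-14
    #: relative agreement of per-type curve coordinates for membership
    on_curve: float = 1e-8
    #: terminal-increment threshold for classifying a fixed point
    fixed_point: float = 1e-10
    #: recurrence threshold for classifying a periodic orbit
    periodic: float = 1e-8
    #: largest minimal period the classifier searches for
    p_max: int = 64
    #: derivative magnitude below which Lyapunov terms are skipped
    lyapunov_floor: float = 1e-300
    #: default burn-in for trajectory samples (bifurcation diagrams)
    burn_in_samples: int = 10_000
    #: default burn-in for social-cost summaries
    burn_in_social: int = 20_000
    #: default number of retained bifurcation samples per parameter value
    n_samples: int = 1_000


TOL = Tolerances()

#: floats are serialized with 17 significant digits (lossless for float64)
FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# 2. Game definition and costs
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class CongestionGame:
    """Static parameters of the two-strategy nonatomic congestion game.

    Parameters
    ----------
    mu : array of shape (m,)
        Type proportions; strictly positive, summing to one.
    a : array of shape (m,)
        Learning rates (intensities of adaptation), strictly positive.
    b : float
        Cost asymmetry ``beta / (alpha + beta)`` in (0, 1).
    q : float
        Total population mass, > 0.  Default 1.
    alpha, beta : float, optional
        Cost slopes of strategies 1 and 2.  Default to the normalization
        ``alpha + beta = 1`` (so ``alpha = 1 - b`` and ``beta = b``), under
        which the equilibrium cost is ``q * b * (1 - b)``.
    """

    mu: np.ndarray
    a: np.ndarray
    b: float
    q: float = 1.0
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "a", a)
        if mu.ndim != 1 or a.ndim != 1 or mu.size != a.size:
            raise ValueError(
                f"mu and a must be 1-d vectors of equal length, got shapes "
                f"{mu.shape} and {a.shape}"
            )
        if not np.all(np.isfinite(mu)) or not np.all(mu > 0):
            raise ValueError("all type proportions mu_i must be finite and > 0")
        if abs(float(mu.sum()) - 1.0) > TOL.simplex:
            raise ValueError(f"mu must sum to 1 within {TOL.simplex}, got {mu.sum()!r}")
        if not np.all(np.isfinite(a)) or not np.all(a > 0):
            raise ValueError("all learning rates a_i must be finite and > 0")
        if not (0.0 < self.b < 1.0):
            raise ValueError(f"cost asymmetry b must lie in (0,1), got {self.b!r}")
        if not (self.q > 0 and math.isfinite(self.q)):
            raise ValueError(f"population mass q must be > 0, got {self.q!r}")
        if self.alpha is None:
            object.__setattr__(self, "alpha", 1.0 - self.b)
        if self.beta is None:
            object.__setattr__(self, "beta", self.b)
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("cost slopes alpha, beta must be > 0")
        # b is redundant with (alpha, beta); they must agree
        if abs(self.beta / (self.alpha + self.beta) - self.b) > 1e-9:
            raise ValueError(
                "inconsistent parameters: b must equal beta / (alpha + beta)"
            )

    @property
    def m(self) -> int:
        """Number of agent types."""
        return int(self.mu.size)

    def scaled(self, sigma: float) -> "CongestionGame":
        """The game with every learning rate multiplied by ``sigma`` > 0."""
        if not (sigma > 0 and math.isfinite(sigma)):
            raise ValueError(f"sigma must be > 0, got {sigma!r}")
        return replace(self, a=self.a * float(sigma))

    @property
    def equilibrium_cost(self) -> float:
        """Common cost of both strategies at any Nash equilibrium:
        ``q (alpha+beta) b (1-b)`` — ``q b (1-b)`` under the default
        normalization."""
        return self.q * (self.alpha + self.beta) * self.b * (1.0 - self.b)


class PopulationState:
    """State of the population, carried in logit coordinates.

    ``z_i = log(x_i / (1 - x_i))`` is the primary representation; ``x`` is
    derived.  Logits make the MWU step an exact linear shift and guarantee
    every ``x_i`` stays strictly inside (0, 1) for any finite trajectory.
    """

    __slots__ = ("z",)

    def __init__(self, z: Sequence[float] | np.ndarray):
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if z.ndim != 1 or not np.all(np.isfinite(z)):
            raise ValueError("state logits must form a finite 1-d vector")
        self.z = z

    @classmethod
    def from_x(cls, x: Sequence[float] | np.ndarray) -> "PopulationState":
        """Build a state from frequencies ``x`` in the open cube (0,1)^m."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all((x > 0) & (x < 1)):
            raise ValueError("all frequencies x_i must lie strictly in (0,1)")
        return cls(logit(x))

    @property
    def x(self) -> np.ndarray:
        """Per-type frequencies of strategy 1, in (0,1)^m."""
        return expit(self.z)

    @property
    def m(self) -> int:
        return int(self.z.size)

    def flow(self, mu: np.ndarray) -> float:
        """Population-average frequency of strategy 1, ``M . X`` in (0,1)."""
        if np.asarray(mu).size != self.z.size:
            raise ValueError(
                f"dimension mismatch: state has {self.z.size} types, "
                f"mu has {np.asarray(mu).size}"
            )
        return float(self.x @ np.asarray(mu, dtype=float))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PopulationState(x={np.array2string(self.x, precision=6)})"


def costs(game: CongestionGame, state: PopulationState) -> tuple[float, float]:
    """Per-unit costs ``(C1, C2)`` of the two strategies at ``state``.

    ``C1 = alpha q (M.X)`` and ``C2 = beta q (1 - M.X)``; both non-negative,
    equal (to ``q(alpha+beta)b(1-b)``) exactly on the Nash set ``M.X = b``.
    """
    f = state.flow(game.mu)
    return game.alpha * game.q * f, game.beta * game.q * (1.0 - f)


def social_cost(game: CongestionGame, flow: float | np.ndarray):
    """Total (load-weighted) cost at flow ``f``:
    ``q^2 (alpha f^2 + beta (1-f)^2)``."""
    f = np.asarray(flow, dtype=float)
    out = game.q**2 * (game.alpha * f**2 + game.beta * (1.0 - f) ** 2)
    return float(out) if out.ndim == 0 else out


def epsilon_to_a(
    epsilon: float, q: float = 1.0, alpha: float = 0.5, beta: float = 0.5
) -> float:
    """Convert a per-round MWU multiplier ``epsilon`` in (0,1) to the
    learning rate ``a = q (alpha + beta) log(1 / (1 - epsilon))``."""
    if not (0.0 < epsilon < 1.0):
        raise ValueError(f"epsilon must lie in (0,1), got {epsilon!r}")
    return q * (alpha + beta) * math.log(1.0 / (1.0 - epsilon))


def a_to_epsilon(
    a: float, q: float = 1.0, alpha: float = 0.5, beta: float = 0.5
) -> float:
    """Inverse of :func:`epsilon_to_a`: ``epsilon = 1 - exp(-a / (q (alpha+beta)))``."""
    if not (a > 0 and math.isfinite(a)):
        raise ValueError(f"learning rate a must be finite and > 0, got {a!r}")
    return -math.expm1(-a / (q * (alpha + beta)))


# ---------------------------------------------------------------------------
# 3. One step of the map and trajectory iteration
# ---------------------------------------------------------------------------


def mwu_step(game: CongestionGame, state: PopulationState) -> PopulationState:
    """One round of heterogeneous MWU learning.

    Implements ``x_i' = x_i / (x_i + (1-x_i) exp(a_i (M.X - b)))`` as the
    algebraically identical, overflow-free logit shift
    ``z_i' = z_i - a_i (M.X - b)``.  States with ``M.X = b`` are fixed.
    """
    if state.m != game.m:
        raise ValueError(
            f"dimension mismatch: game has {game.m} types, state has {state.m}"
        )
    f = state.flow(game.mu)
    return PopulationState(state.z - game.a * (f - game.b))


@dataclass
class Trajectory:
    """An orbit of the MWU map with its per-step derived series.

    All series (``flows``, ``c1``, ``c2``, ``social``) cover exactly the
    retained post-burn-in steps; ``Z`` holds the retained state logits row
    by row when states were stored.  ``z_final`` is the state one step past
    the last retained one, which closes the telescoping identity
    ``mean(flow) - b = (s_final - s_first) / n``.
    """

    burn_in: int
    flows: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    social: np.ndarray
    z_final: np.ndarray
    Z: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return int(self.flows.size)

    @property
    def states(self) -> list[PopulationState]:
        if self.Z is None:
            raise ValueError(
                "trajectory was run with store_states=False; only the "
                "per-step series are available"
            )
        return [PopulationState(row) for row in self.Z]

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(self.z_final)


def iterate(
    game: CongestionGame,
    x0: PopulationState,
    n_steps: int,
    burn_in: int = 0,
    store_states: bool = True,
) -> Trajectory:
    """Iterate the MWU map and record the post-burn-in orbit.

    The retained steps are ``n = burn_in, ..., burn_in + n_steps - 1``; the
    series hold the flow and costs *at* each retained state (before its
    update).  Deterministic: identical inputs give bit-identical outputs.

    Set ``store_states=False`` to keep only the scalar series (necessary
    for long horizons with many types, where the full state array would
    dominate memory).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if burn_in < 0:
        raise ValueError(f"burn_in must be >= 0, got {burn_in}")
    if x0.m != game.m:
        raise ValueError(
            f"dimension mismatch: game has {game.m} types, state has {x0.m}"
        )
    mu, a, b = game.mu, game.a, game.b
    z = x0.z.copy()
    for _ in range(burn_in):
        z -= a * (float(expit(z) @ mu) - b)
    flows = np.empty(n_steps)
    Z = np.empty((n_steps, game.m)) if store_states else None
    for n in range(n_steps):
        x = expit(z)
        f = float(x @ mu)
        flows[n] = f
        if Z is not None:
            Z[n] = z
        z -= a * (f - b)
    c1 = game.alpha * game.q * flows
    c2 = game.beta * game.q * (1.0 - flows)
    return Trajectory(
        burn_in=burn_in,
        flows=flows,
        c1=c1,
        c2=c2,
        social=social_cost(game, flows),
        z_final=z,
        Z=Z,
    )


def iterate_to_fixed_point(
    game: CongestionGame,
    x0: PopulationState,
    tol: float = 1e-12,
    max_steps: int = 1_000_000,
) -> tuple[PopulationState, int]:
    """Iterate until successive states differ by less than ``tol`` in sup
    norm on ``x``; returns the terminal state and the number of steps.

    Raises if the orbit has not converged after ``max_steps`` (it will not
    converge in the unstable/chaotic regime)."""
    mu, a, b = game.mu, game.a, game.b
    z = x0.z.copy()
    for n in range(max_steps):
        x = expit(z)
        z_new = z - a * (float(x @ mu) - b)
        if np.max(np.abs(expit(z_new) - x)) < tol:
            return PopulationState(z_new), n + 1
        z = z_new
    raise RuntimeError(f"no fixed point reached within {max_steps} steps")


# ---------------------------------------------------------------------------
# 4. Invariant-curve splitting and the conjugate one-dimensional map
# ---------------------------------------------------------------------------


class CurveContext:
    """The invariant curve through a base point ``y``.

    Each point of the curve is ``y(s)_i = y_i / (y_i + (1-y_i) exp(s a_i))``
    — in logits, ``logit(y(s)_i) = logit(y_i) - s a_i``.  The curves for a
    fixed learning-rate vector partition the open cube, each is invariant
    under the MWU map, and the dynamics restricted to a curve is conjugate
    to the real-line map ``g(s) = s + M . y(s) - b``.
    """

    __slots__ = ("y", "a", "zy")

    def __init__(self, y: PopulationState | Sequence[float], a: Sequence[float]):
        if not isinstance(y, PopulationState):
            y = PopulationState.from_x(y)
        a = np.atleast_1d(np.asarray(a, dtype=float))
        if a.size != y.m:
            raise ValueError(
                f"dimension mismatch: base point has {y.m} types, a has {a.size}"
            )
        if not np.all(np.isfinite(a)) or not np.all(a > 0):
            raise ValueError("all learning rates a_i must be finite and > 0")
        self.y = y.x
        self.a = a
        self.zy = y.z.copy()

    @classmethod
    def for_game(
        cls, game: CongestionGame, y: PopulationState | Sequence[float]
    ) -> "CurveContext":
        return cls(y, game.a)


def curve_point(ctx: CurveContext, s: float) -> PopulationState:
    """The point ``y(s)`` on the curve; ``y(0)`` is the base point exactly."""
    if not math.isfinite(s):
        raise ValueError(f"curve parameter s must be finite, got {s!r}")
    return PopulationState(ctx.zy - s * ctx.a)


def curve_coordinate(ctx: CurveContext, x: PopulationState) -> float | None:
    """The parameter ``s`` with ``x = y(s)``, or ``None`` if ``x`` is not on
    the curve.

    The per-type candidates ``s_i = (logit(y_i) - logit(x_i)) / a_i`` must
    agree within the on-curve tolerance (relative, in s units); any
    disagreement means the point lies on a different curve of the
    partition.
    """
    if x.m != ctx.a.size:
        raise ValueError("dimension mismatch between curve and state")
    cand = (ctx.zy - x.z) / ctx.a
    s = float(cand.mean())
    if np.max(np.abs(cand - s)) > TOL.on_curve * (1.0 + abs(s)):
        return None
    return s


def reduced_map(ctx: CurveContext, game: CongestionGame, s: float) -> float:
    """The conjugate one-dimensional map ``g(s) = s + M . y(s) - b``.

    Satisfies ``F(y(s)) = y(g(s))``: in logits the MWU step shifts every
    coordinate by ``-a_i (M.X - b)``, i.e. it moves the curve parameter
    from ``s`` to ``s + M.y(s) - b``.
    """
    return s + curve_point(ctx, s).flow(game.mu) - game.b


def reduced_derivative(ctx: CurveContext, game: CongestionGame, s: float) -> float:
    """``g'(s) = 1 - sum_i mu_i a_i y_i(s) (1 - y_i(s))``."""
    y = curve_point(ctx, s).x
    return 1.0 - float((game.mu * ctx.a * y * (1.0 - y)).sum())


class BracketError(RuntimeError):
    """A bracketed root search found no sign change."""


def equilibrium_on_curve(ctx: CurveContext, game: CongestionGame) -> float:
    """The unique ``s*`` on the curve with ``M . y(s*) = b``.

    ``s -> M.y(s)`` is strictly decreasing from 1 to 0, so the root exists,
    is unique, and a geometrically expanded bracket always captures it.
    """

    def h(s: float) -> float:
        return curve_point(ctx, s).flow(game.mu) - game.b

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if h(lo) >= 0.0 >= h(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:  # pragma: no cover - unreachable for b in (0,1)
        raise BracketError("could not bracket the equilibrium on the curve")
    return float(brentq(h, lo, hi, xtol=TOL.root_s))


def iterate_reduced(
    ctx: CurveContext,
    game: CongestionGame,
    s0: float,
    n_steps: int,
    burn_in: int = 0,
) -> np.ndarray:
    """Orbit of the reduced map: the retained ``s``-values after burn-in."""
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if burn_in < 0:
        raise ValueError(f"burn_in must be >= 0, got {burn_in}")
    mu, a, b = game.mu, ctx.a, game.b
    s = float(s0)
    for _ in range(burn_in):
        s += float(expit(ctx.zy - s * a) @ mu) - b
    out = np.empty(n_steps)
    for n in range(n_steps):
        out[n] = s
        s += float(expit(ctx.zy - s * a) @ mu) - b
    return out


def curve_coordinates(ctx: CurveContext, traj: Trajectory) -> np.ndarray:
    """Curve parameters of every retained state of a trajectory (plus the
    final state), assuming the orbit lies on ``ctx``'s curve."""
    if traj.Z is None:
        raise ValueError("trajectory must be run with store_states=True")
    Z = np.vstack([traj.Z, traj.z_final])
    return (ctx.zy[0] - Z[:, 0]) / ctx.a[0]


# ---------------------------------------------------------------------------
# 5. Ergodic and chaos diagnostics
# ---------------------------------------------------------------------------


def time_average_flow(traj: Trajectory) -> float:
    """Cesàro mean of the flow over the retained steps; converges to ``b``
    for every game and initial state (at rate O(1/n), by telescoping the
    reduced map)."""
    if traj.n_steps == 0:
        raise ValueError("empty trajectory")
    return float(traj.flows.mean())


def time_average_costs(traj: Trajectory, game: CongestionGame) -> tuple[float, float]:
    """Time-averaged per-unit costs of the two strategies; both converge to
    the equilibrium cost ``q (alpha+beta) b (1-b)`` as the horizon grows."""
    if traj.n_steps == 0:
        raise ValueError("empty trajectory")
    return float(traj.c1.mean()), float(traj.c2.mean())


def normalized_social_cost(traj: Trajectory, game: CongestionGame) -> float:
    """Time-average social cost divided by the social cost at Nash
    equilibrium.

    Equals ``1 + mean((f_n - b)^2) / (b (1-b))`` identically, hence is
    always >= 1, with equality exactly for an orbit constant at
    equilibrium.
    """
    if traj.n_steps == 0:
        raise ValueError("empty trajectory")
    denom = game.q**2 * (game.alpha + game.beta) * game.b * (1.0 - game.b)
    if denom <= 0:  # pragma: no cover - unreachable under game validation
        raise ValueError("degenerate game: b must lie strictly in (0,1)")
    return float(traj.social.mean() / denom)


def lyapunov_exponent(
    ctx: CurveContext,
    game: CongestionGame,
    s0: float,
    n_steps: int,
    burn_in: int = 0,
) -> float:
    """Lyapunov exponent of the reduced map along the orbit of ``s0``:
    the mean of ``log |g'(s_k)|`` after burn-in.  Steps where ``g'``
    vanishes to below the floor are skipped."""
    orbit = iterate_reduced(ctx, game, s0, n_steps, burn_in)
    y = expit(ctx.zy[None, :] - orbit[:, None] * ctx.a[None, :])
    deriv = 1.0 - (y * (1.0 - y)) @ (game.mu * ctx.a)
    keep = np.abs(deriv) > TOL.lyapunov_floor
    if not keep.any():
        raise ValueError("derivative vanished along the entire orbit")
    return float(np.mean(np.log(np.abs(deriv[keep]))))


def lyapunov_from_trajectory(traj: Trajectory, game: CongestionGame) -> float:
    """Lyapunov exponent computed directly from stored full states, using
    ``g'(s_n) = 1 - sum_i mu_i a_i x_i (1-x_i)`` at each retained state."""
    if traj.Z is None:
        raise ValueError("trajectory must be run with store_states=True")
    x = expit(traj.Z)
    deriv = 1.0 - (x * (1.0 - x)) @ (game.mu * game.a)
    keep = np.abs(deriv) > TOL.lyapunov_floor
    return float(np.mean(np.log(np.abs(deriv[keep]))))


@dataclass(frozen=True)
class PeriodicOrbit:
    """A periodic orbit of the reduced map: its points in orbit order, its
    minimal period and the stability multiplier ``prod g'(s_k)`` (the orbit
    is linearly stable iff the multiplier lies in (-1, 1))."""

    points: tuple[float, ...]
    period: int
    multiplier: float

    @property
    def stable(self) -> bool:
        return abs(self.multiplier) < 1.0


def find_periodic_orbits(
    ctx: CurveContext,
    game: CongestionGame,
    period: int,
    s_range: tuple[float, float],
    grid: int = 2000,
) -> list[PeriodicOrbit]:
    """All orbits of minimal period ``period`` of the reduced map with a
    point in ``s_range``.

    Roots of ``g^p(s) - s`` are located by a sign-change scan over a
    uniform grid followed by bracketed polishing; roots whose minimal
    period strictly divides ``p`` are discarded, and roots on the same
    orbit are merged.  The scan can miss tangent (even-multiplicity)
    roots; a finer grid narrows that window.
    """
    if period < 1:
        raise ValueError(f"period must be >= 1, got {period}")
    lo, hi = float(s_range[0]), float(s_range[1])
    if not (hi > lo):
        raise ValueError(f"empty s_range {s_range!r}")

    def gp(s: float) -> float:
        for _ in range(period):
            s = reduced_map(ctx, game, s)
        return s

    def h(s: float) -> float:
        return gp(s) - s

    ss = np.linspace(lo, hi, grid + 1)
    hs = np.array([h(s) for s in ss])
    roots: list[float] = []
    for i in range(grid):
        if hs[i] == 0.0:
            roots.append(float(ss[i]))
        elif hs[i] * hs[i + 1] < 0:
            roots.append(float(brentq(h, ss[i], ss[i + 1], xtol=TOL.root_s)))
    if hs[-1] == 0.0:
        roots.append(float(ss[-1]))

    orbits: list[PeriodicOrbit] = []
    seen: list[float] = []
    for s in roots:
        pts = [s]
        for _ in range(period - 1):
            pts.append(reduced_map(ctx, game, pts[-1]))
        # minimal period must be exactly `period`, not a proper divisor
        if any(
            period % d == 0 and abs(pts[d] - s) < TOL.periodic
            for d in range(1, period)
        ):
            continue
        rep = min(pts)
        if any(abs(rep - r) < 10 * TOL.periodic for r in seen):
            continue
        seen.append(rep)
        mult = 1.0
        for p in pts:
            mult *= reduced_derivative(ctx, game, p)
        orbits.append(PeriodicOrbit(tuple(pts), period, mult))
    return sorted(orbits, key=lambda o: min(o.points))


def classify_orbit(
    series: np.ndarray,
    tol_fixed: float = TOL.fixed_point,
    tol_periodic: float = TOL.periodic,
    p_max: int = TOL.p_max,
) -> str:
    """Classify the tail of a scalar orbit series as ``"fixed_point"``,
    ``"periodic(p)"`` (minimal period ``p <= p_max``), or ``"aperiodic"``.

    Works on any scalar series that is a homeomorphic image of the orbit
    (the curve parameter s, or the flow, which is strictly monotone in s).
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least two points to classify an orbit")
    tail = series[-min(series.size, 4 * p_max) :]
    if np.max(np.abs(np.diff(tail))) < tol_fixed:
        return "fixed_point"
    scale = 1.0 + np.max(np.abs(tail))
    for p in range(1, min(p_max, tail.size - 1) + 1):
        if np.max(np.abs(tail[p:] - tail[:-p])) < tol_periodic * scale:
            return f"periodic({p})"
    return "aperiodic"


@dataclass(frozen=True)
class DiagnosticsReport:
    """Summary of one run: ergodic averages, social cost, Lyapunov
    exponent and orbit classification."""

    mean_flow: float
    mean_costs: tuple[float, float]
    normalized_social_cost: float
    lyapunov: float | None
    orbit_class: str
    horizon: int
    burn_in: int

    def to_dict(self) -> dict:
        return {
            "mean_flow": self.mean_flow,
            "mean_c1": self.mean_costs[0],
            "mean_c2": self.mean_costs[1],
            "normalized_social_cost": self.normalized_social_cost,
            "lyapunov": self.lyapunov,
            "orbit_class": self.orbit_class,
            "horizon": self.horizon,
            "burn_in": self.burn_in,
        }


def diagnose(traj: Trajectory, game: CongestionGame) -> DiagnosticsReport:
    """Build the full diagnostics report for a trajectory.  The Lyapunov
    exponent needs the stored states and is reported as None otherwise."""
    lyap = lyapunov_from_trajectory(traj, game) if traj.Z is not None else None
    return DiagnosticsReport(
        mean_flow=time_average_flow(traj),
        mean_costs=time_average_costs(traj, game),
        normalized_social_cost=normalized_social_cost(traj, game),
        lyapunov=lyap,
        orbit_class=classify_orbit(traj.flows),
        horizon=traj.n_steps,
        burn_in=traj.burn_in,
    )


# ---------------------------------------------------------------------------
# 6. The sigma-family: bifurcation scans and the first instability
# ---------------------------------------------------------------------------


@dataclass
class SigmaScan:
    """Results of a scan over the one-parameter family A -> sigma A.

    ``samples[k, t, i]`` is ``x_i`` at retained step ``t`` for
    ``sigmas[k]`` (the data behind a bifurcation diagram); ``flows`` holds
    the corresponding population flows, and ``reports`` the per-sigma
    diagnostics.
    """

    sigmas: np.ndarray
    samples: np.ndarray
    flows: np.ndarray
    reports: list[DiagnosticsReport]

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"sigma": float(s), **r.to_dict()}
            for s, r in zip(self.sigmas, self.reports)
        ]
        return pd.DataFrame(rows).drop(columns=["horizon", "burn_in"])


def sigma_scan(
    game: CongestionGame,
    x0: PopulationState,
    sigmas: Sequence[float] | np.ndarray,
    n_samples: int = TOL.n_samples,
    burn_in: int = TOL.burn_in_samples,
) -> SigmaScan:
    """Iterate every game of the sigma-family from the same initial state
    and retain ``n_samples`` post-burn-in states per sigma.

    All sigma values are advanced in lockstep (one vectorized orbit per
    step), which makes dense bifurcation grids cheap.
    """
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if sigmas.size == 0:
        raise ValueError("sigma grid must be non-empty")
    if np.any(np.diff(sigmas) <= 0) and sigmas.size > 1:
        raise ValueError("sigma grid must be strictly increasing")
    if not np.all(sigmas > 0):
        raise ValueError("all sigma values must be > 0")
    if x0.m != game.m:
        raise ValueError("dimension mismatch between game and initial state")
    K, m = sigmas.size, game.m
    mu, b = game.mu, game.b
    A = sigmas[:, None] * game.a[None, :]  # (K, m) per-sigma learning rates
    Z = np.tile(x0.z, (K, 1))
    for _ in range(burn_in):
        f = expit(Z) @ mu
        Z -= A * (f - b)[:, None]
    samples = np.empty((K, n_samples, m))
    flows = np.empty((K, n_samples))
    for t in range(n_samples):
        X = expit(Z)
        samples[:, t, :] = X
        f = X @ mu
        flows[:, t] = f
        Z -= A * (f - b)[:, None]
    reports = []
    for k in range(K):
        x = samples[k]
        deriv = 1.0 - (x * (1.0 - x)) @ (mu * A[k])
        keep = np.abs(deriv) > TOL.lyapunov_floor
        lyap = float(np.mean(np.log(np.abs(deriv[keep])))) if keep.any() else None
        fk = flows[k]
        gk = game.scaled(float(sigmas[k]))
        reports.append(
            DiagnosticsReport(
                mean_flow=float(fk.mean()),
                mean_costs=(
                    float((gk.alpha * gk.q * fk).mean()),
                    float((gk.beta * gk.q * (1.0 - fk)).mean()),
                ),
                normalized_social_cost=float(
                    1.0 + ((fk - b) ** 2).mean() / (b * (1.0 - b))
                ),
                lyapunov=lyap,
                orbit_class=classify_orbit(fk),
                horizon=n_samples,
                burn_in=burn_in,
            )
        )
    return SigmaScan(sigmas=sigmas, samples=samples, flows=flows, reports=reports)


def sigma_critical(
    game: CongestionGame,
    x0: PopulationState,
    bracket: tuple[float, float] = (1e-3, 50.0),
) -> float:
    """The sigma at which the curve equilibrium first loses linear
    stability: the root of ``sum_i mu_i (sigma a_i) y_i(s*) (1 - y_i(s*)) = 2``
    (i.e. ``g'(s*) = -1``), with ``s*`` the equilibrium on the curve of the
    sigma-scaled family through ``x0``.

    Raises :class:`BracketError` when the stability margin does not change
    sign over the bracket.
    """

    def margin(sigma: float) -> float:
        g = game.scaled(sigma)
        ctx = CurveContext.for_game(g, x0)
        s_star = equilibrium_on_curve(ctx, g)
        y = curve_point(ctx, s_star).x
        return float((g.mu * g.a * y * (1.0 - y)).sum()) - 2.0

    lo, hi = float(bracket[0]), float(bracket[1])
    if margin(lo) * margin(hi) > 0:
        raise BracketError(
            f"stability margin has the same sign at both ends of {bracket!r}"
        )
    return float(brentq(margin, lo, hi, xtol=1e-9))


# ---------------------------------------------------------------------------
# 7. Experiment fixtures, config and file IO
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ExperimentSpec:
    """A fully serializable description of one experiment: the game, the
    initial state, the sigma settings and the horizons."""

    name: str
    mu: np.ndarray
    a: np.ndarray
    b: float
    q: float
    x0: np.ndarray
    sigma: float = 1.0
    sigma_grid: np.ndarray | None = None
    n_steps: int = 100_000
    burn_in: int = TOL.burn_in_samples

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.atleast_1d(np.asarray(self.mu, float)))
        object.__setattr__(self, "a", np.atleast_1d(np.asarray(self.a, float)))
        object.__setattr__(self, "x0", np.atleast_1d(np.asarray(self.x0, float)))
        if self.sigma_grid is not None:
            object.__setattr__(
                self, "sigma_grid", np.atleast_1d(np.asarray(self.sigma_grid, float))
            )
        self.to_game()  # validates mu, a, b, q
        if self.x0.size != self.mu.size or not np.all((self.x0 > 0) & (self.x0 < 1)):
            raise ValueError("x0 must be an m-vector strictly inside (0,1)")
        if self.n_steps < 1 or self.burn_in < 0:
            raise ValueError("n_steps must be >= 1 and burn_in >= 0")

    @property
    def m(self) -> int:
        return int(self.mu.size)

    def to_game(self, sigma: float | None = None) -> CongestionGame:
        """The game of the spec, optionally scaled by sigma (defaults to
        the spec's own sigma; pass ``sigma=1`` for the baseline)."""
        g = CongestionGame(mu=self.mu, a=self.a, b=self.b, q=self.q)
        s = self.sigma if sigma is None else sigma
        return g if s == 1.0 else g.scaled(s)

    def initial_state(self) -> PopulationState:
        return PopulationState.from_x(self.x0)


def game_from_spec(spec: ExperimentSpec, sigma: float | None = None) -> CongestionGame:
    return spec.to_game(sigma)


def initial_state(spec: ExperimentSpec) -> PopulationState:
    return spec.initial_state()


def example1() -> ExperimentSpec:
    """Two-type sigma-family benchmark: equal type weights, learning rates
    (1, 3), cost asymmetry b = 0.3, initial state (0.2, 0.6).

    ``sigma = 12.2`` (deep in the chaotic regime) is the setting of the
    time-average cost experiment; ``sigma_grid`` spans the bifurcation scan
    from near 0 to 14.
    """
    return ExperimentSpec(
        name="example1",
        mu=np.array([0.5, 0.5]),
        a=np.array([1.0, 3.0]),
        b=0.3,
        q=1.0,
        x0=np.array([0.2, 0.6]),
        sigma=12.2,
        sigma_grid=np.linspace(0.01, 14.0, 1400),
        n_steps=100_000,
        burn_in=TOL.burn_in_samples,
    )


def example2() -> ExperimentSpec:
    """Highly heterogeneous benchmark with 999 equal-weight types.

    Learning rates ``a_i = 1.2 (5 + (i mod 31))`` and initial frequencies
    ``x_i = 0.0001 + (i mod 23)/24`` for i = 1..999 (1-based, as printed);
    b = 0.3, burn-in 20000.
    """
    i = np.arange(1, 1000)
    return ExperimentSpec(
        name="example2",
        mu=np.full(999, 1.0 / 999),
        a=1.2 * (5.0 + (i % 31)),
        b=0.3,
        q=1.0,
        x0=0.0001 + (i % 23) / 24.0,
        sigma=1.0,
        sigma_grid=None,
        n_steps=100_000,
        burn_in=TOL.burn_in_social,
    )


def random_population(
    m: int,
    a_range: tuple[float, float] = (0.5, 30.0),
    seed: int = 0,
    b: float | None = None,
    q: float = 1.0,
) -> ExperimentSpec:
    """A seeded random heterogeneous population for property tests.

    Type weights are Dirichlet(1) (uniform on the simplex), learning rates
    uniform in ``a_range``, initial frequencies uniform in (0.01, 0.99).
    ``b`` defaults to a uniform draw in [0.15, 0.85].  Identical seeds give
    identical specs.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0 < a_range[0] < a_range[1]):
        raise ValueError(f"invalid a_range {a_range!r}")
    rng = np.random.default_rng(seed)
    mu = rng.dirichlet(np.ones(m))
    mu = np.clip(mu, 1e-6, None)
    mu = mu / mu.sum()
    a = rng.uniform(a_range[0], a_range[1], size=m)
    x0 = rng.uniform(0.01, 0.99, size=m)
    if b is None:
        b = float(rng.uniform(0.15, 0.85))
    return ExperimentSpec(
        name=f"random-m{m}-seed{seed}",
        mu=mu,
        a=a,
        b=b,
        q=q,
        x0=x0,
        sigma=1.0,
    )


# -- config file (plain key = value; vectors comma-separated) ---------------

_CONFIG_KEYS = ("name", "m", "mu", "a", "b", "q", "x0", "sigma", "sigma_grid",
                "n_steps", "burn_in")


def write_config(spec: ExperimentSpec, path) -> None:
    """Serialize a spec to a plain key-value file, 17 significant digits."""
    lines = [
        f"name = {spec.name}",
        f"m = {spec.m}",
        "mu = " + ",".join(_fmt(v) for v in spec.mu),
        "a = " + ",".join(_fmt(v) for v in spec.a),
        f"b = {_fmt(spec.b)}",
        f"q = {_fmt(spec.q)}",
        "x0 = " + ",".join(_fmt(v) for v in spec.x0),
        f"sigma = {_fmt(spec.sigma)}",
    ]
    if spec.sigma_grid is not None:
        lines.append("sigma_grid = " + ",".join(_fmt(v) for v in spec.sigma_grid))
    lines += [f"n_steps = {spec.n_steps}", f"burn_in = {spec.burn_in}", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_config(path) -> ExperimentSpec:
    """Parse a key-value config file back into an :class:`ExperimentSpec`."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            raw[key] = val.strip()
    missing = {"mu", "a", "b", "x0"} - raw.keys()
    if missing:
        raise ValueError(f"{path}: missing required keys {sorted(missing)}")

    def vec(key: str) -> np.ndarray:
        return np.array([float(v) for v in raw[key].split(",")])

    spec = ExperimentSpec(
        name=raw.get("name", "unnamed"),
        mu=vec("mu"),
        a=vec("a"),
        b=float(raw["b"]),
        q=float(raw.get("q", "1")),
        x0=vec("x0"),
        sigma=float(raw.get("sigma", "1")),
        sigma_grid=vec("sigma_grid") if "sigma_grid" in raw else None,
        n_steps=int(raw.get("n_steps", "100000")),
        burn_in=int(raw.get("burn_in", str(TOL.burn_in_samples))),
    )
    if "m" in raw and int(raw["m"]) != spec.m:
        raise ValueError(f"{path}: declared m={raw['m']} but vectors have {spec.m}")
    return spec


# -- CSV / JSON writers and readers -----------------------------------------


def _trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    if traj.Z is None:
        raise ValueError("trajectory must be run with store_states=True to export")
    x = expit(traj.Z)
    m = x.shape[1]
    data = {"step": np.arange(traj.burn_in, traj.burn_in + traj.n_steps)}
    for i in range(m):
        data[f"x_{i + 1}"] = x[:, i]  # 1-based type labels at the IO boundary
    data["flow"] = traj.flows
    data["c1"] = traj.c1
    data["c2"] = traj.c2
    data["social_cost"] = traj.social
    return pd.DataFrame(data)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Columns: step, x_1..x_m, flow, c1, c2, social_cost; floats written
    with 17 significant digits for bit-level reproducibility."""
    _trajectory_frame(traj).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectory_csv(path) -> pd.DataFrame:
    # round_trip parsing makes the 17-digit serialization bit-lossless
    return pd.read_csv(path, float_precision="round_trip")


def write_trajectory_json(traj: Trajectory, path) -> None:
    """One JSON record per retained step, same fields as the CSV."""
    records = _trajectory_frame(traj).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(records, fh)


def write_curve_scan_csv(
    ctx: CurveContext, game: CongestionGame, s_values: np.ndarray, path
) -> None:
    """Columns: s, y_1..y_m, flow, g, gprime — a tabulation of the curve
    and the reduced map along it."""
    s_values = np.asarray(s_values, dtype=float)
    rows = []
    for s in s_values:
        y = curve_point(ctx, float(s))
        row = {"s": float(s)}
        for i, yi in enumerate(y.x):
            row[f"y_{i + 1}"] = yi
        row["flow"] = y.flow(game.mu)
        row["g"] = reduced_map(ctx, game, float(s))
        row["gprime"] = reduced_derivative(ctx, game, float(s))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_sigma_scan_csv(scan: SigmaScan, path) -> None:
    """Tidy bifurcation table: sigma, step, type (1-based), x_value."""
    K, T, m = scan.samples.shape
    sig = np.repeat(scan.sigmas, T * m)
    step = np.tile(np.repeat(np.arange(T), m), K)
    typ = np.tile(np.arange(1, m + 1), K * T)
    pd.DataFrame(
        {
            "sigma": sig,
            "step": step,
            "type": typ,
            "x_value": scan.samples.reshape(-1),
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_sigma_summary_csv(scan: SigmaScan, path) -> None:
    """Per-sigma summary: mean flow, mean costs, normalized social cost,
    Lyapunov exponent and orbit class."""
    scan.summary_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def plot_bifurcation(scan: SigmaScan, path) -> None:  # pragma: no cover
    """Best-effort bifurcation figure (per-type samples against sigma).
    The CSV exports are the canonical artifacts; this is a convenience."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K, T, m = scan.samples.shape
    fig, axes = plt.subplots(m, 1, figsize=(8, 2.5 * m), sharex=True, squeeze=False)
    for i in range(m):
        ax = axes[i, 0]
        ax.plot(
            np.repeat(scan.sigmas, T),
            scan.samples[:, :, i].reshape(-1),
            ",",
            color="k",
            alpha=0.3,
        )
        ax.set_ylabel(f"x_{i + 1}")
    axes[-1, 0].set_xlabel("sigma")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
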