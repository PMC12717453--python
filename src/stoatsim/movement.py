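"""Stochastic movement mathematics.

Movement is a biased correlated random walk in 30-minute steps.  Step
lengths follow a Weibull distribution with shape 1 (i.e. exponential), whose
scale is the mean displacement per step (50 m by default).  Bearings follow
a von Mises distribution whose mean points at the current centre of
attraction (COA) and whose concentration κ encodes the strength of pull:

* home-range mode: κ = max(0, α·ln d) where d is the distance to the
  home-range centre, so pull strengthens away from the centre and vanishes
  near it (α in [0.01, 0.1]);
* mate-search mode: κ = (1/minK)·exp(−δ·d)·exp(−γ·a) for a candidate COA at
  distance d that has been deployed for a days (a = 0 for live animals), so
  nearby and fresh scents attract most strongly.

Bearings use compass convention: 0 is north, positive angles turn east,
the domain is (−π, π].  A κ of zero degenerates to a uniformly random
bearing (unbiased random walk).

The scalar draws are implemented as numba-jitted helpers shared with the
simulation engine's inner loop; the public functions accept numpy
``Generator`` objects and vectorise where natural.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


class ParameterError(ValueError):
    """A movement parameter is outside its valid domain."""


# ---------------------------------------------------------------------------
# jitted scalar primitives (shared with the engine kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _draw_vonmises(rng, mu, kappa):
    """Best-Fisher rejection sampler for the von Mises distribution.

    Falls back to a uniform bearing for κ ≈ 0.  Returns an angle in
    (−π, π].
    """
    # below ~1e-6 the distribution is numerically uniform and the b term
    # underflows to zero by cancellation
    if kappa < 1e-6:
        return rng.uniform(-math.pi, math.pi)
    a = 1.0 + math.sqrt(1.0 + 4.0 * kappa * kappa)
    b = (a - math.sqrt(2.0 * a)) / (2.0 * kappa)
    r = (1.0 + b * b) / (2.0 * b)
    while True:
        u1 = rng.random()
        z = math.cos(math.pi * u1)
        f = (1.0 + r * z) / (r + z)
        c = kappa * (r - f)
        u2 = rng.random()
        if c * (2.0 - c) - u2 > 0.0 or math.log(c / u2) + 1.0 - c >= 0.0:
            break
    u3 = rng.random()
    theta = math.acos(f)
    if u3 < 0.5:
        theta = -theta
    angle = mu + theta
    # wrap to (-pi, pi]
    while angle > math.pi:
        angle -= 2.0 * math.pi
    while angle <= -math.pi:
        angle += 2.0 * math.pi
    return angle


@njit(cache=True)
def _draw_exponential(rng, scale):
    """Weibull(shape=1, scale) draw, i.e. exponential with mean `scale`."""
    u = rng.random()
    return -scale * math.log1p(-u)


@njit(cache=True)
def _point_in_polygon(px, py, poly_x, poly_y):
    """Even-odd ray casting against a closed ring (first == last vertex)."""
    inside = False
    n = len(poly_x) - 1
    for i in range(n):
        x1, y1 = poly_x[i], poly_y[i]
        x2, y2 = poly_x[i + 1], poly_y[i + 1]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


@njit(cache=True)
def _home_range_kappa(dist, alpha):
    if dist <= 1.0:
        return 0.0
    return alpha * math.log(dist)


@njit(cache=True)
def _mate_search_weight(dist, delta, age_factor):
    """Relative attraction weight exp(−δ·d) · exp(−γ·a); 1/minK cancels
    in multinomial selection and is applied only for the bearing κ."""
    return math.exp(-delta * dist) * age_factor


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def draw_step_length(scale: float, rng: np.random.Generator, size=None):
    """Draw step length(s) in metres from Weibull(shape=1, scale).

    With shape 1 this is an exponential law whose mean equals ``scale``,
    the average distance moved in one 30-minute step.
    """
    if scale <= 0:
        raise ParameterError("Weibull scale must be positive")
    return rng.exponential(scale, size=size)


def home_range_kappa(dist, alpha: float):
    """Concentration of the pull towards the home-range centre.

    κ = α·ln(d), clamped at zero for d ≤ 1 m so that steps taken at the
    centre are unbiased.
    """
    d = np.asarray(dist, dtype=float)
    out = alpha * np.log(np.maximum(d, 1.0))
    return float(out) if out.ndim == 0 else out


def mate_search_kappa(dist, age_days, delta: float, gamma: float, min_k: float):
    """Concentration of attraction towards a mate-search COA.

    κ = (1/minK)·exp(−δ·d)·exp(−γ·a); strictly decreasing in both the
    distance d and the decoy age a (live animals have a = 0).
    """
    if min_k <= 0:
        raise ParameterError("minK must be positive")
    d = np.asarray(dist, dtype=float)
    a = np.asarray(age_days, dtype=float)
    out = np.exp(-delta * d) * np.exp(-gamma * a) / min_k
    return float(out) if out.ndim == 0 else out


def draw_bearing(mu: float, kappa: float, rng: np.random.Generator) -> float:
    """Draw a compass bearing in (−π, π] from von Mises(μ, κ).

    κ = 0 gives a uniformly random direction.
    """
    if kappa < 0:
        raise ParameterError("kappa must be non-negative")
    return _draw_vonmises(rng, float(mu), float(kappa))


def select_coa(kappas, rng: np.random.Generator):
    """Multinomial selection of one COA with probability κ_c / Σκ.

    ``kappas`` is a sequence of non-negative attraction weights (order
    defines the returned index).  Returns ``None`` for an empty candidate
    list; if all weights are zero the choice is uniform.
    """
    k = np.asarray(kappas, dtype=float)
    if k.size == 0:
        return None
    if np.any(k < 0) or not np.all(np.isfinite(k)):
        raise ParameterError("selection weights must be finite and non-negative")
    total = k.sum()
    if total == 0:
        return int(rng.integers(0, k.size))
    return int(rng.choice(k.size, p=k / total))


def effective_scale(dist_to_coa: float, base_scale: float) -> float:
    """Step-length scale while converging on a COA.

    When the COA is closer than the base scale (50 m), the scale shrinks to
    half the remaining distance so the walker settles onto the target.
    """
    if dist_to_coa < 0 or base_scale < 0:
        raise ParameterError("distances must be non-negative")
    return dist_to_coa / 2.0 if dist_to_coa < base_scale else base_scale


def bearing_to(from_xy, to_xy) -> float:
    """Compass bearing from one point to another (0 = north, east positive)."""
    dx = to_xy[0] - from_xy[0]
    dy = to_xy[1] - from_xy[1]
    return math.atan2(dx, dy)


def advance(loc, bearing: float, length: float):
    """Move from ``loc`` by ``length`` metres along a compass bearing."""
    x, y = loc
    return (x + length * math.sin(bearing), y + length * math.cos(bearing))


def constrained_step(
    loc,
    mu: float,
    kappa: float,
    scale: float,
    island,
    rng: np.random.Generator,
    max_tries: int = 20,
):
    """One step that must land inside the island.

    Redraws bearing and length until the landing point is inside (the
    population is closed: nobody swims off).  After ``max_tries`` failed
    draws the animal stays put.  Raises if the start point is already
    outside.
    """
    from .geometry import contains

    if not contains(island, loc):
        raise ValueError("constrained_step requires a start location inside the island")
    for _ in range(max_tries):
        b = draw_bearing(mu, kappa, rng)
        length = draw_step_length(scale, rng)
        candidate = advance(loc, b, length)
        if contains(island, candidate):
            return candidate
    return loc


# ---------------------------------------------------------------------------
# home-range trajectory utilities (calibration / diagnostics)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _simulate_home_range(rng, n_steps, alpha, scale):
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    x = 0.0
    y = 0.0
    for t in range(n_steps):
        d = math.hypot(x, y)
        kappa = _home_range_kappa(d, alpha)
        mu = math.atan2(-x, -y)  # bearing to the centre at the origin
        b = _draw_vonmises(rng, mu, kappa)
        ln = _draw_exponential(rng, scale)
        x += ln * math.sin(b)
        y += ln * math.cos(b)
        xs[t] = x
        ys[t] = y
    return xs, ys


def simulate_home_range_track(
    n_steps: int,
    alpha: float = 0.05,
    scale: float = 50.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a home-range walk on an unbounded plane from a centre at the
    origin; returns an (n_steps, 2) array of visited locations (metres)."""
    rng = np.random.default_rng(seed)
    xs, ys = _simulate_home_range(rng, int(n_steps), float(alpha), float(scale))
    return np.column_stack([xs, ys])


def mcp_area_km2(points: np.ndarray, fraction: float = 0.95) -> float:
    """Minimum-convex-polygon home-range estimate in km².

    Keeps the ``fraction`` of locations closest to the centroid (the
    standard 95% MCP convention) and returns the area of their convex hull.
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    d = np.hypot(*(pts - centroid).T)
    keep = pts[np.argsort(d)[: max(3, int(round(fraction * len(pts))))]]
    return ConvexHull(keep).volume / 1e6
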