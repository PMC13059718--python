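"""Two-variable feedback model of population growth, lipid ROS and ferroptosis.

The model couples the confluence fraction of a growing cell population,
``n``, to the average lipid ROS burden per live cell, ``r``:

.. math::

    \\frac{dn}{dt} &= \\alpha\\, n\\,(1 - n/K) - \\beta\\, n\\, \\sigma(r) \\\\
    \\frac{dr}{dt} &= a\\, \\alpha\\,(1 - n/K) - b\\, r + c\\, r

with the Hill death switch :math:`\\sigma(r) = r^h / (r_0^h + r^h)`.

Growth is logistic toward the carrying capacity ``K``.  ROS is produced in
proportion to the per-capita division rate (rapidly dividing sparse
populations generate the most), cleared at rate ``b`` per molecule by
scavenging systems (GPX4 and co.), and amplified autocatalytically at rate
``c`` by iron-catalysed Fenton chemistry.  Once ``r`` crosses the threshold
``r0``, lipid peroxidation outpaces repair and cells die by ferroptosis at a
per-capita rate approaching ``beta``.  The negative feedback (growth → ROS →
death → less growth) makes the long-term fate bistable: a confluent,
low-ROS, ferroptosis-resistant state coexists with a sparse, high-ROS,
ferroptosis-sensitive state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ModelParams",
    "ModelState",
    "Trajectory",
    "FixedPoint",
    "CANONICAL_PARAMS",
    "death_switch",
    "rhs",
    "simulate",
    "jacobian",
    "find_fixed_points",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a valid trajectory."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the growth / lipid-ROS / ferroptosis feedback model.

    Attributes
    ----------
    alpha : float
        Basal per-capita division rate (1/h).
    K : float
        Carrying capacity as a confluence fraction (dimensionless, > 0).
    beta : float
        Maximal per-capita ferroptotic death rate (1/h).
    a : float
        Lipid ROS generated per cell division (ROS units).
    b : float
        Lipid ROS clearance rate per molecule (1/h).
    c : float
        Fenton autocatalysis rate (1/h); must satisfy ``c < b`` so that
        net clearance keeps ROS bounded.
    r0 : float
        Lipid ROS death threshold (ROS units); sigma(r0) = 1/2.
    h : float
        Hill steepness of the death switch (dimensionless, >= 1).
    """

    alpha: float = 0.05
    K: float = 1.0
    beta: float = 0.04
    a: float = 4.0
    b: float = 0.10
    c: float = 0.02
    r0: float = 0.5
    h: float = 4.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K!r}")
        if self.b <= self.c:
            raise ValueError(
                f"require b > c for bounded ROS, got b={self.b!r}, c={self.c!r}"
            )
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h!r}")

    def with_(self, **overrides: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


#: Canonical default parameter set used throughout the test battery.
CANONICAL_PARAMS = ModelParams()


@dataclass(frozen=True)
class ModelState:
    """State of the model: confluence fraction ``n`` and per-cell lipid ROS ``r``."""

    n: float
    r: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and np.isfinite(self.r)):
            raise ValueError(f"state must be finite, got n={self.n!r}, r={self.r!r}")
        if self.n < 0 or self.r < 0:
            raise ValueError(f"state must be non-negative, got n={self.n!r}, r={self.r!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.n, self.r], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Time course of the model state.

    ``times`` are in hours and strictly increasing; ``n`` and ``r`` are the
    state arrays at those times; ``params`` records the parameters used.
    """

    times: np.ndarray
    n: np.ndarray
    r: np.ndarray
    params: ModelParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if not (len(self.times) == len(self.n) == len(self.r)):
            raise ValueError("times, n, r must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def state_at(self, i: int) -> ModelState:
        return ModelState(n=float(self.n[i]), r=float(self.r[i]))

    @property
    def final_state(self) -> ModelState:
        return self.state_at(-1)


Classification = Literal["stable", "saddle", "unstable", "unclassified"]


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the model with its linear stability classification."""

    state: ModelState
    eigenvalues: tuple[complex, complex]
    classification: Classification

    @property
    def is_stable(self) -> bool:
        return self.classification == "stable"


def death_switch(r, params: ModelParams, hard: bool = False):
    """Per-capita ferroptotic death multiplier sigma(r) in [0, 1].

    The default is a Hill function ``r^h / (r0^h + r^h)``: zero at r=0,
    one half exactly at the threshold r0, saturating at 1.  With
    ``hard=True`` the idealised step ``1[r > r0]`` is used instead.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("r must be finite and >= 0")
    if hard:
        out = (r > params.r0).astype(float)
    elif params.r0 == 0:
        # degenerate threshold: any positive ROS is lethal at full rate
        out = (r > 0).astype(float)
    else:
        x = r / params.r0
        xh = x**params.h
        out = xh / (1.0 + xh)
    return out if out.ndim else float(out)


def rhs(state: ModelState, params: ModelParams, hard_switch: bool = False) -> tuple[float, float]:
    """Time derivatives (dn/dt, dr/dt) of the feedback model."""
    dn, dr = _rhs_arrays(state.n, state.r, params, hard_switch)
    return float(dn), float(dr)


def _rhs_arrays(n, r, params: ModelParams, hard_switch: bool = False):
    """Vectorised right-hand side on raw arrays (no validation)."""
    p = params
    sigma = death_switch(np.maximum(r, 0.0), p, hard=hard_switch)
    growth_room = 1.0 - n / p.K
    dn = p.alpha * n * growth_room - p.beta * n * sigma
    dr = p.a * p.alpha * growth_room - p.b * r + p.c * r
    return dn, dr


def jacobian(state: ModelState, params: ModelParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the right-hand side at ``state``.

    Uses d(sigma)/dr = h * r^(h-1) * r0^h / (r0^h + r^h)^2 for the Hill
    switch; at r=0 with h>1 that derivative vanishes, and for h=1 it is
    1/r0.
    """
    p = params
    n, r = state.n, state.r
    sigma = death_switch(r, p)
    if p.r0 == 0:
        dsigma = 0.0
    elif r == 0:
        dsigma = 1.0 / p.r0 if p.h == 1 else 0.0
    else:
        rh = r**p.h
        r0h = p.r0**p.h
        dsigma = p.h * r ** (p.h - 1) * r0h / (r0h + rh) ** 2
    dfn_dn = p.alpha * (1.0 - 2.0 * n / p.K) - p.beta * sigma
    dfn_dr = -p.beta * n * dsigma
    dfr_dn = -p.a * p.alpha / p.K
    dfr_dr = -(p.b - p.c)
    return np.array([[dfn_dn, dfn_dr], [dfr_dn, dfr_dr]], dtype=float)


def simulate(
    params: ModelParams,
    init: ModelState,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    hard_switch: bool = False,
) -> Trajectory:
    """Integrate the model from ``init`` and return the state at ``times``.

    A stiff-capable adaptive integrator (LSODA) is used with tight default
    tolerances; the solution is deterministic for fixed inputs.  States are
    clipped at zero after integration; a clip beyond 1e-6 raises, since it
    would indicate an inaccurate solve rather than harmless round-off.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("times must be a 1-D array with at least one entry")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")

    if len(times) == 1 and times[0] == 0.0:
        return Trajectory(times=times, n=[init.n], r=[init.r], params=params)

    def f(t, y):
        dn, dr = _rhs_arrays(y[0], y[1], params, hard_switch)
        return (dn, dr)

    sol = solve_ivp(
        f,
        (float(times[0]), float(times[-1])) if len(times) > 1 else (0.0, float(times[0])),
        init.as_array(),
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    undershoot = -y.min(initial=0.0)
    if undershoot > 1e-6:
        raise IntegrationError(
            f"state went negative by {undershoot:.3g}; solver tolerance insufficient"
        )
    y = np.clip(y, 0.0, None)
    return Trajectory(times=times, n=y[0], r=y[1], params=params)


def _classify(eigenvalues: np.ndarray, zero_band: float = 1e-9) -> Classification:
    re = np.real(eigenvalues)
    if np.any(np.abs(re) <= zero_band):
        return "unclassified"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points(
    params: ModelParams,
    search_box: tuple[float, float] | None = None,
    grid_size: int = 20,
    tol: float = 1e-8,
    dedup_tol: float = 1e-5,
) -> list[FixedPoint]:
    """Locate and classify all steady states inside a search box.

    Multi-start Newton root finding is seeded from a ``grid_size`` x
    ``grid_size`` lattice over ``search_box = (r_max, n_max)`` plus the
    n=0 and r=0 axes (the extinction line carries the boundary steady
    state ``r* = a*alpha/(b-c)``).  Roots are deduplicated at
    ``dedup_tol`` and classified by the sign pattern of the Jacobian
    eigenvalue real parts.
    """
    if search_box is None:
        r_span = params.a * params.alpha / (params.b - params.c)
        search_box = (max(2.0 * r_span, 4.0 * params.r0, 1.0), 1.5 * params.K)
    r_max, n_max = search_box
    if r_max <= 0 or n_max <= 0:
        raise ValueError("search box extents must be positive")

    def f(y):
        return _rhs_arrays(y[0], y[1], params)

    starts: list[tuple[float, float]] = []
    r_grid = np.linspace(0.0, r_max, grid_size)
    n_grid = np.linspace(0.0, n_max, grid_size)
    for rr in r_grid:
        for nn in n_grid:
            starts.append((nn, rr))
    # axis starts help the boundary roots converge exactly onto the axes
    starts += [(0.0, rr) for rr in r_grid] + [(nn, 0.0) for nn in n_grid]

    found: list[np.ndarray] = []
    for y0 in starts:
        sol = root(f, np.asarray(y0, dtype=float), method="hybr", tol=1e-12)
        if not sol.success:
            continue
        y = sol.x
        # snap tiny negative round-off onto the axes, reject true negatives
        y = np.where(np.abs(y) < dedup_tol, 0.0, y)
        if y[0] < 0 or y[1] < 0:
            continue
        if y[0] > n_max * (1 + 1e-9) or y[1] > r_max * (1 + 1e-9):
            continue
        dn, dr = f(y)
        if math.hypot(dn, dr) >= tol:
            continue
        if any(np.linalg.norm(y - prev) <= dedup_tol for prev in found):
            continue
        found.append(y)

    out: list[FixedPoint] = []
    for y in found:
        st = ModelState(n=float(y[0]), r=float(y[1]))
        eig = np.linalg.eigvals(jacobian(st, params))
        out.append(
            FixedPoint(
                state=st,
                eigenvalues=(complex(eig[0]), complex(eig[1])),
                classification=_classify(eig),
            )
        )
    out.sort(key=lambda fp: (-fp.state.n, fp.state.r))
    return out
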