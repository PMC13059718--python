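"""Phase-plane analysis: nullclines, attractor assignment, basins of attraction.

The feedback model is bistable over a wide parameter range: a confluent,
ferroptosis-resistant steady state at (n=K, r=0) coexists with a sparse,
high-ROS, ferroptosis-sensitive one.  Which fate a culture reaches depends
only on its initial confluence and lipid ROS burden — the phase plane splits
into basins of attraction.  This module labels initial states by their
attractor via direct integration and quantifies how the basins shift when
treatments move parameters (GPX4 inhibition lowers the death threshold r0;
forcing OXPHOS with galactose raises the ROS yield per division a).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    FixedPoint,
    ModelParams,
    ModelState,
    IntegrationError,
    _rhs_arrays,
    death_switch,
    find_fixed_points,
)

__all__ = [
    "UNRESOLVED",
    "BasinGrid",
    "NullclineSet",
    "attractor_of",
    "compute_basins",
    "nullclines",
    "basin_area_fraction",
]

#: Label used for grid nodes that did not settle onto any attractor.
UNRESOLVED = -1


@dataclass(frozen=True)
class BasinGrid:
    """Attractor labels over a lattice of initial (r, n) states.

    ``labels[i, j]`` is the index into ``attractors`` of the stable fixed
    point reached from the initial state (n=n_axis[i], r=r_axis[j]), or
    ``UNRESOLVED``.
    """

    r_axis: np.ndarray
    n_axis: np.ndarray
    labels: np.ndarray
    attractors: list[FixedPoint]

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_axis", np.asarray(self.r_axis, dtype=float))
        object.__setattr__(self, "n_axis", np.asarray(self.n_axis, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if np.any(np.diff(self.r_axis) <= 0) or np.any(np.diff(self.n_axis) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if self.labels.shape != (len(self.n_axis), len(self.r_axis)):
            raise ValueError("labels shape must be (len(n_axis), len(r_axis))")
        bad = (self.labels != UNRESOLVED) & (
            (self.labels < 0) | (self.labels >= len(self.attractors))
        )
        if np.any(bad):
            raise ValueError("labels must index attractors or be UNRESOLVED")

    @property
    def unresolved_fraction(self) -> float:
        return float(np.mean(self.labels == UNRESOLVED))


@dataclass(frozen=True)
class NullclineSet:
    """Zero-growth curves of each variable as ordered (r, n) point lists."""

    n_nullclines: list[np.ndarray]  # each (m, 2) array of (r, n) with dn/dt = 0
    r_nullclines: list[np.ndarray]  # each (m, 2) array of (r, n) with dr/dt = 0


def _stable_attractors(params: ModelParams) -> list[FixedPoint]:
    return [fp for fp in find_fixed_points(params) if fp.is_stable]


def _scale(params: ModelParams, r_max: float | None) -> tuple[float, float]:
    if r_max is None:
        r_max = max(4.0 * params.r0, params.a * params.alpha / (params.b - params.c))
    return r_max, params.K


def _match(n: float, r: float, attractors: list[FixedPoint], tol: float, r_scale: float, n_scale: float) -> int:
    for i, fp in enumerate(attractors):
        d = np.hypot((r - fp.state.r) / r_scale, (n - fp.state.n) / n_scale)
        if d < tol:
            return i
    return UNRESOLVED


def attractor_of(
    init: ModelState,
    params: ModelParams,
    horizon: float = 2000.0,
    tol: float = 0.02,
    attractors: list[FixedPoint] | None = None,
    r_max: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> int:
    """Index of the stable fixed point a trajectory from ``init`` reaches.

    The state is integrated in stages up to ``horizon`` hours and matched
    against the stable attractors with tolerance ``tol`` in scaled
    coordinates (r / r_max, n / K); returns :data:`UNRESOLVED` if no
    attractor is reached within the horizon.
    """
    if attractors is None:
        attractors = _stable_attractors(params)
    if not attractors:
        raise ValueError("model has no stable attractor under these parameters")
    r_scale, n_scale = _scale(params, r_max)

    idx = _match(init.n, init.r, attractors, tol, r_scale, n_scale)
    if idx != UNRESOLVED:
        return idx

    def f(t, y):
        return _rhs_arrays(y[0], y[1], params)

    y = init.as_array()
    t = 0.0
    # geometric stages: most trajectories settle long before the horizon
    for t_next in np.asarray([0.1, 0.25, 0.5, 1.0]) * horizon:
        sol = solve_ivp(f, (t, t_next), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"basin integration failed: {sol.message}")
        y = sol.y[:, -1]
        t = t_next
        idx = _match(y[0], y[1], attractors, tol, r_scale, n_scale)
        if idx != UNRESOLVED:
            return idx
    return UNRESOLVED


def compute_basins(
    params: ModelParams,
    r_axis: np.ndarray | None = None,
    n_axis: np.ndarray | None = None,
    grid_size: int = 60,
    horizon: float = 2000.0,
    tol: float = 0.02,
    r_max: float | None = None,
) -> BasinGrid:
    """Label every node of an (r, n) lattice by the attractor it flows to.

    Defaults reproduce a basin map over r in [0, 4*r0] and n in
    [1e-3, 1.1*K].  Unresolved nodes keep the :data:`UNRESOLVED` label and
    are never silently assigned.
    """
    attractors = _stable_attractors(params)
    if not attractors:
        raise ValueError("model has no stable attractor under these parameters")
    r_span, _ = _scale(params, r_max)
    if r_axis is None:
        r_axis = np.linspace(0.0, 4.0 * params.r0, grid_size)
    if n_axis is None:
        n_axis = np.linspace(1e-3, 1.1 * params.K, grid_size)
    r_axis = np.asarray(r_axis, dtype=float)
    n_axis = np.asarray(n_axis, dtype=float)

    labels = np.full((len(n_axis), len(r_axis)), UNRESOLVED, dtype=int)
    for i, n0 in enumerate(n_axis):
        for j, r0_ in enumerate(r_axis):
            labels[i, j] = attractor_of(
                ModelState(n=float(n0), r=float(r0_)),
                params,
                horizon=horizon,
                tol=tol,
                attractors=attractors,
                r_max=r_span,
            )
    return BasinGrid(r_axis=r_axis, n_axis=n_axis, labels=labels, attractors=attractors)


def nullclines(
    params: ModelParams,
    r_axis: np.ndarray | None = None,
    n_points: int = 200,
    residual_tol: float = 1e-9,
) -> NullclineSet:
    """Nullcline curves of the model over an r range.

    The r-nullcline of the canonical form is the straight line
    ``n = K * (1 - (b - c) * r / (a * alpha))``; the n-nullcline is the
    union of the extinction axis n = 0 and the curve
    ``n = K * (1 - beta * sigma(r) / alpha)`` where that is non-negative.
    """
    p = params
    if r_axis is None:
        r_span, _ = _scale(p, None)
        r_axis = np.linspace(0.0, r_span, n_points)
    r_axis = np.asarray(r_axis, dtype=float)

    # dr/dt = 0  ->  linear in n
    n_on_r_null = p.K * (1.0 - (p.b - p.c) * r_axis / (p.a * p.alpha))
    keep = n_on_r_null >= 0
    r_null = np.column_stack([r_axis[keep], n_on_r_null[keep]])

    # dn/dt = 0  ->  n = 0 axis, plus the interior branch
    axis_branch = np.column_stack([r_axis, np.zeros_like(r_axis)])
    sigma = np.asarray(death_switch(r_axis, p))
    n_on_n_null = p.K * (1.0 - p.beta * sigma / p.alpha)
    keep = n_on_n_null >= 0
    branches = [axis_branch]
    if np.any(keep):
        branches.append(np.column_stack([r_axis[keep], n_on_n_null[keep]]))

    out = NullclineSet(n_nullclines=branches, r_nullclines=[r_null])
    for curves, comp in ((out.n_nullclines, 0), (out.r_nullclines, 1)):
        for curve in curves:
            dn, dr = _rhs_arrays(curve[:, 1], curve[:, 0], p)
            resid = np.abs(dn if comp == 0 else dr)
            if resid.max(initial=0.0) > residual_tol:
                raise AssertionError(
                    f"nullcline residual {resid.max():.3g} exceeds {residual_tol:.3g}"
                )
    return out


def basin_area_fraction(basins: BasinGrid, attractor_index: int) -> float:
    """Fraction of grid nodes labelled with ``attractor_index``.

    Fractions over all attractors plus the unresolved fraction partition
    the grid and sum to 1.
    """
    if attractor_index != UNRESOLVED and not (0 <= attractor_index < len(basins.attractors)):
        raise ValueError(f"attractor index {attractor_index} out of range")
    return float(np.mean(basins.labels == attractor_index))
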