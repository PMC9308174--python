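"""Finite-volume solver for the cell-density PDE on the 2-D reduced space.

The density u(t, theta) obeys

    du/dt = -div(V u) + R(theta, u) + nu * Laplace(u),

with zero Dirichlet boundary, V = v1 + v2 (+ any leukemic override), and the
logistic reaction against the landscape capacity.  The spatial scheme is a
conservative finite-volume update with either first-order upwind advection
plus centred diffusion, or (default) an exponential-fitting
Scharfetter-Gummel flux.  The exponential flux is positivity-preserving,
reduces to upwind at large cell Peclet number, and — because the v1 part of
the face velocity is taken from potential differences — makes the KDE
landscape an exact discrete stationary state of the drift-diffusion pair.
Time stepping is explicit Euler under a CFL guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SimulationResult
from .landscape import Landscape, signal


class SolverError(RuntimeError):
    pass


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (e^x - 1), the Scharfetter-Gummel weight."""
    x = np.clip(x, -500.0, 500.0)
    small = np.abs(x) < 1e-8
    denom = np.where(small, 1.0, np.expm1(x))
    return np.where(small, 1.0 - 0.5 * x, x / denom)


@dataclass
class ContinuumFields:
    """Everything the continuum stepper needs, frozen per scenario.

    ``v2x/v2y`` carry the s-independent part c * 2 (1 - a) r of the
    differentiation drift and are multiplied by s(t) each step;
    ``extra_vx/vy`` hold scenario overrides (e.g. c_aml * v_aml) that do
    not scale with s.  ``include_v1`` switches the attractor drift
    -nu * grad(U) on or off; it is discretized from face differences of U.
    """

    landscape: Landscape
    nu: float
    r_grid: np.ndarray | float = 0.0
    v2x: np.ndarray | float = 0.0
    v2y: np.ndarray | float = 0.0
    extra_vx: np.ndarray | float = 0.0
    extra_vy: np.ndarray | float = 0.0
    r_boost: np.ndarray | float = 0.0
    matured_w: np.ndarray | float = 0.0
    kappa: float = 0.0
    dbar: np.ndarray | float = 1.0   # scalar or per-grid-point death cap
    include_v1: bool = True
    scheme: str = "exponential"

    def __post_init__(self) -> None:
        if self.scheme not in ("exponential", "upwind"):
            raise SolverError(f"unknown scheme {self.scheme!r}")
        shape = self.landscape.shape
        for name in ("r_grid", "v2x", "v2y", "extra_vx", "extra_vy",
                     "r_boost", "matured_w"):
            val = getattr(self, name)
            if np.isscalar(val):
                setattr(self, name, np.full(shape, float(val)))
            elif np.shape(val) != shape:
                raise SolverError(f"{name} shape {np.shape(val)} != grid {shape}")

    # --- face velocities ------------------------------------------------
    def _face_velocities(self, s_value: float):
        ls = self.landscape
        m1, m2 = ls.shape
        # pad cell-centred velocity components with edge replication
        vx = s_value * self.v2x + self.extra_vx
        vy = s_value * self.v2y + self.extra_vy
        vxf = 0.5 * (np.vstack([vx[:1], vx]) + np.vstack([vx, vx[-1:]]))
        vyf = 0.5 * (np.hstack([vy[:, :1], vy]) + np.hstack([vy, vy[:, -1:]]))
        if self.include_v1:
            U = self.landscape.U
            Upx = np.vstack([U[:1], U, U[-1:]])       # (m1 + 2, m2)
            Upy = np.hstack([U[:, :1], U, U[:, -1:]])
            vxf = vxf - self.nu * (Upx[1:] - Upx[:-1]) / ls.dx
            vyf = vyf - self.nu * (Upy[:, 1:] - Upy[:, :-1]) / ls.dy
        return vxf, vyf  # shapes (m1 + 1, m2) and (m1, m2 + 1)

    def max_speed(self) -> tuple[float, float]:
        vxf, vyf = self._face_velocities(1.0)
        return float(np.abs(vxf).max()), float(np.abs(vyf).max())

    def cfl_dt(self, safety: float = 0.9) -> float:
        """Admissible explicit step: safety * min(dx^2/(4 nu), dx/max|V|)."""
        ls = self.landscape
        dmin = min(ls.dx, ls.dy)
        bound = np.inf
        if self.nu > 0:
            bound = dmin * dmin / (4.0 * self.nu)
        vx, vy = self.max_speed()
        if vx > 0:
            bound = min(bound, ls.dx / vx)
        if vy > 0:
            bound = min(bound, ls.dy / vy)
        # inf when velocity and diffusion both vanish: any dt is admissible
        return safety * bound

    def reaction(self, u: np.ndarray) -> np.ndarray:
        us = np.maximum(self.landscape.us, self.landscape.floor)
        d = np.minimum(u / us, self.dbar)
        return self.r_grid * (1.0 - d) * u + self.r_boost * u


@dataclass
class ContinuumState:
    """Density on the grid plus the running mass/signal traces."""

    u: np.ndarray
    t: float = 0.0
    s: float = 1.0
    mass_times: list[float] = field(default_factory=list)
    mass_trace: list[float] = field(default_factory=list)
    s_trace: list[float] = field(default_factory=list)
    undershoot_events: int = 0

    def copy(self) -> "ContinuumState":
        return ContinuumState(self.u.copy(), self.t, self.s,
                              list(self.mass_times), list(self.mass_trace),
                              list(self.s_trace), self.undershoot_events)


def cell_mass(u: np.ndarray, landscape: Landscape) -> float:
    """Finite-volume mass sum(u) * dx * dy (exactly what the fluxes conserve)."""
    return float(u.sum() * landscape.dx * landscape.dy)


def initial_condition(
    landscape: Landscape, fraction: float, stem_weights: np.ndarray
) -> ContinuumState:
    """u0 = fraction * u_s * w_stem: a stem-cell seed at a tenth of capacity."""
    if not 0.0 < fraction <= 1.0:
        raise SolverError("fraction must lie in (0, 1]")
    w = np.asarray(stem_weights, dtype=float)
    if w.shape != landscape.shape:
        raise SolverError("stem weight field shape mismatch")
    if not np.any(w > 0):
        raise SolverError("empty stem set: stem weights vanish everywhere")
    u0 = fraction * landscape.us * w
    u0[0, :] = u0[-1, :] = 0.0
    u0[:, 0] = u0[:, -1] = 0.0
    return ContinuumState(u0)


def _fluxes(u_pad, vf, nu, dx, scheme, axis):
    if axis == 0:
        u_l, u_r = u_pad[:-1, 1:-1], u_pad[1:, 1:-1]
    else:
        u_l, u_r = u_pad[1:-1, :-1], u_pad[1:-1, 1:]
    if scheme == "exponential" and nu > 0:
        pe = vf * dx / nu
        return (nu / dx) * (_bernoulli(-pe) * u_l - _bernoulli(pe) * u_r)
    adv = np.where(vf > 0, vf * u_l, vf * u_r)
    return adv - nu * (u_r - u_l) / dx


def step(
    state: ContinuumState,
    fields: ContinuumFields,
    dt: float,
    reflecting: bool = False,
) -> ContinuumState:
    """One explicit finite-volume step; mutates and returns ``state``.

    ``reflecting`` zeroes the boundary fluxes instead of imposing the zero
    Dirichlet ring (an internal testing mode in which mass is conserved
    exactly when R = 0).
    """
    ls = fields.landscape
    bound = fields.cfl_dt()
    if dt > bound * (1 + 1e-12):
        raise SolverError(
            f"dt = {dt} violates the CFL bound; use dt <= {bound:.3e}"
        )
    u = state.u
    area = ls.dx * ls.dy
    m = float((u * fields.matured_w).sum() * area)
    s = signal(m, fields.kappa) if fields.kappa > 0 else 1.0

    u_pad = np.pad(u, 1, mode="constant")  # zero Dirichlet ghosts
    vxf, vyf = fields._face_velocities(s)
    fx = _fluxes(u_pad, vxf, fields.nu, ls.dx, fields.scheme, axis=0)
    fy = _fluxes(u_pad, vyf, fields.nu, ls.dy, fields.scheme, axis=1)
    if reflecting:
        fx[0, :] = fx[-1, :] = 0.0
        fy[:, 0] = fy[:, -1] = 0.0

    div = (fx[1:] - fx[:-1]) / ls.dx + (fy[:, 1:] - fy[:, :-1]) / ls.dy
    u_new = u + dt * (-div + fields.reaction(u))
    if not reflecting:
        u_new[0, :] = u_new[-1, :] = 0.0
        u_new[:, 0] = u_new[:, -1] = 0.0
    neg = u_new < 0
    if np.any(neg):
        worst = float(u_new[neg].min())
        if worst < -1e-9 * max(1.0, float(u_new.max())):
            raise SolverError(f"negative density {worst:.3e}; reduce dt")
        state.undershoot_events += int(neg.sum())
        u_new[neg] = 0.0

    state.u = u_new
    state.t += dt
    state.s = s
    state.mass_times.append(state.t)
    state.mass_trace.append(cell_mass(u_new, ls))
    state.s_trace.append(s)
    return state


def simulate(
    state0: ContinuumState,
    fields: ContinuumFields,
    T: float,
    dt: float | None = None,
    snapshot_times: tuple[float, ...] = (),
    weights=None,
    reflecting: bool = False,
    stop_mass_ratio: float | None = None,
    equilibrium_tol: float | None = None,
) -> tuple[SimulationResult, ContinuumState]:
    """Advance the state to time ``state0.t + T`` recording snapshots.

    ``dt`` defaults to the CFL-safe step.  ``weights`` (a
    :class:`~statefate.quantify.TypeWeights`) adds per-type mass traces at
    snapshot times.  ``stop_mass_ratio`` ends the run early once total mass
    exceeds that multiple of the initial mass (a runaway-growth guard);
    ``equilibrium_tol`` ends it once |d rho / dt| / rho per unit time drops
    below the tolerance.
    """
    snapshot_times = tuple(sorted(snapshot_times))
    t0 = state0.t
    if snapshot_times and (snapshot_times[0] < t0 - 1e-9
                           or snapshot_times[-1] > t0 + T + 1e-9):
        raise SolverError("snapshot times must lie within [t0, t0 + T]")
    if dt is None:
        dt = fields.cfl_dt()
        if not np.isfinite(dt):
            raise SolverError("give dt explicitly when V = 0 and nu = 0")
    state = state0
    ls = fields.landscape
    m0 = cell_mass(state.u, ls)
    snaps, snap_times, type_rows = [], [], []
    pending = list(snapshot_times)

    def take_snapshot():
        snaps.append(state.u.copy())
        snap_times.append(state.t)
        if weights is not None:
            from .quantify import mass_by_type_grid
            masses = mass_by_type_grid(state.u, ls, weights)
            type_rows.append([masses[lab] for lab in weights.labels])

    while pending and pending[0] <= state.t + 1e-12:
        take_snapshot()
        pending.pop(0)

    n_steps = int(np.ceil(T / dt - 1e-12))
    check_every = max(1, int(round(1.0 / dt)))  # ~1 pseudotime unit
    last_mass, last_t = m0, state.t
    for k in range(n_steps):
        this_dt = min(dt, t0 + T - state.t)
        if this_dt <= 0:
            break
        step(state, fields, this_dt, reflecting=reflecting)
        while pending and pending[0] <= state.t + 1e-9:
            take_snapshot()
            pending.pop(0)
        if stop_mass_ratio is not None and m0 > 0 and \
                state.mass_trace[-1] >= stop_mass_ratio * m0:
            break
        if equilibrium_tol is not None and (k + 1) % check_every == 0:
            mass = state.mass_trace[-1]
            rate = abs(mass - last_mass) / max(mass, 1e-300) / (state.t - last_t)
            if rate < equilibrium_tol:
                break
            last_mass, last_t = mass, state.t

    result = SimulationResult(
        geometry="continuum",
        times=np.asarray(snap_times),
        mass_times=np.asarray(state.mass_times),
        mass=np.asarray(state.mass_trace),
        s_values=np.asarray(state.s_trace),
        snapshots=snaps,
        grid_x=ls.x,
        grid_y=ls.y,
        type_labels=list(weights.labels) if weights is not None else [],
        type_mass=np.asarray(type_rows) if type_rows else None,
    )
    return result, state
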