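"""Finite-volume discretization with Crank–Nicolson time stepping.

The five-field reaction–diffusion system is discretized on the cell-centered
raster of a :class:`~aedesgm.maps.GridMap`.  Diffusion (mobile phases F, M,
G only) uses the five-point flux stencil with arithmetic-mean face
coefficients and zero-flux (homogeneous Neumann) boundaries — the same
isolation assumption that underlies the single-cell ODE reduction, and the
choice that conserves mass exactly in the absence of reactions.  Reaction
terms are time-centered (averaged between the two time levels), so every
step solves a nonlinear system for the new fields, done here by a damped
Newton iteration on the full stacked state with an analytic sparse
Jacobian.

All fields are densities (mosquitoes/m²); domain totals are densities
summed times the cell area.  The invariant domain of the continuous model
(all fields non-negative, A ≤ k) is enforced after each step: tiny negative
round-off is clamped to zero, genuine violations raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .equilibrium import wild_equilibrium
from .maps import GridMap, HOUSE
from .parameters import ModelParameters

__all__ = [
    "SpatialState",
    "DiscretizationSpec",
    "SimulationResult",
    "alpha",
    "crank_nicolson_step",
    "simulate_pde",
    "wild_equilibrium_state",
    "CrankNicolsonSolver",
]

_FIELDS = ("E", "A", "F", "M", "G")
#: fields transported by diffusion, with their coefficient attribute
_DIFFUSIVE = {"F": "D_m", "M": "D_m", "G": "D_g"}

_NEG_CLAMP = 1e-9  # relative round-off tolerated below zero before clamping
_CAP_SLACK = 1e-9  # relative overshoot of A above k tolerated


def alpha(M: np.ndarray | float, G: np.ndarray | float) -> np.ndarray | float:
    """Wild-male mating share α = M/(M+G), with α = 1 when M = G = 0.

    Applied cell-wise; the M = G = 0 branch only matters at extinction,
    where the egg equation's F·M factor vanishes anyway.
    """
    M_arr = np.asarray(M, dtype=float)
    G_arr = np.asarray(G, dtype=float)
    if (M_arr < 0).any() or (G_arr < 0).any():
        raise ValueError("alpha requires non-negative male densities")
    tot = M_arr + G_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0.0, M_arr / np.where(tot > 0.0, tot, 1.0), 1.0)
    if np.isscalar(M) and np.isscalar(G):
        return float(out)
    return out


@dataclass(frozen=True)
class SpatialState:
    """Per-cell densities of the five phases at one instant."""

    E: np.ndarray
    A: np.ndarray
    F: np.ndarray
    M: np.ndarray
    G: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        shape = np.asarray(self.E).shape
        for name in _FIELDS:
            arr = np.ascontiguousarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError("all fields must share one (ny, nx) shape")
            if not np.isfinite(arr).all():
                raise ValueError(f"field {name} contains non-finite values")
            object.__setattr__(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.E.shape

    @classmethod
    def zeros(cls, grid: GridMap, t: float = 0.0) -> "SpatialState":
        z = np.zeros((grid.ny, grid.nx))
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(), t=t)

    def stack(self) -> np.ndarray:
        """Flatten to the solver ordering (E, A, F, M, G concatenated)."""
        return np.concatenate([getattr(self, f).ravel() for f in _FIELDS])

    @classmethod
    def from_stack(cls, u: np.ndarray, shape: tuple[int, int],
                   t: float) -> "SpatialState":
        n = shape[0] * shape[1]
        parts = [u[i * n:(i + 1) * n].reshape(shape) for i in range(5)]
        return cls(*parts, t=t)

    def totals(self, grid: GridMap) -> dict[str, float]:
        """Domain totals (individuals) of each phase."""
        a = grid.cell_area
        return {f"{name}_total": float(getattr(self, name).sum() * a)
                for name in _FIELDS}


@dataclass(frozen=True)
class DiscretizationSpec:
    """Numerical controls of the Crank–Nicolson step.

    ``dt`` defaults to one day.  The Newton iteration stops when the
    scaled residual max-norm falls below ``newton_tol``; it raises after
    ``max_newton_iter`` iterations.
    """

    dt: float = 1.0
    newton_tol: float = 1e-10
    max_newton_iter: int = 50
    boundary: str = "no-flux"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")
        if self.boundary != "no-flux":
            raise ValueError("only the no-flux boundary condition is supported")


def _neumann_laplacian(grid: GridMap) -> sp.csr_matrix:
    """Five-point Laplacian with zero-flux boundaries, unit diffusivity.

    Row i holds Σ_faces (U_nb − U_i)/h² over interior faces only; face
    diffusivities are arithmetic means, which for the piecewise-constant
    coefficients used here are constant anyway.
    """
    ny, nx = grid.ny, grid.nx
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    rows, cols, vals = [], [], []

    def add_faces(a: np.ndarray, b: np.ndarray, h2: float) -> None:
        for i, j in ((a, b), (b, a)):
            rows.append(i.ravel()); cols.append(j.ravel())
            vals.append(np.full(i.size, 1.0 / h2))
            rows.append(i.ravel()); cols.append(i.ravel())
            vals.append(np.full(i.size, -1.0 / h2))

    if nx > 1:
        add_faces(idx[:, :-1], idx[:, 1:], grid.dx**2)
    if ny > 1:
        add_faces(idx[:-1, :], idx[1:, :], grid.dy**2)
    if not rows:
        return sp.csr_matrix((n, n))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


class CrankNicolsonSolver:
    """Reusable stepper: caches the diffusion operator and index plumbing."""

    def __init__(self, params: ModelParameters, grid: GridMap,
                 spec: DiscretizationSpec | None = None):
        self.params = params
        self.grid = grid
        self.spec = spec or DiscretizationSpec()
        self.n = grid.n_cells
        lap = _neumann_laplacian(grid)
        blocks = []
        for name in _FIELDS:
            if name in _DIFFUSIVE:
                D = getattr(params, _DIFFUSIVE[name])
                blocks.append(D * lap)
            else:
                blocks.append(sp.csr_matrix((self.n, self.n)))
        self.L = sp.block_diag(blocks, format="csr")
        self.k = grid.k_field().ravel()
        self.identity = sp.identity(5 * self.n, format="csr")
        # solve small systems densely; the sparse factorization only pays
        # off once the grid is non-trivial
        self._dense = self.n <= 64
        self.last_newton_iters = 0

    # -- reaction terms -----------------------------------------------------
    def _reaction(self, u: np.ndarray) -> np.ndarray:
        p, n, k = self.params, self.n, self.k
        E, A, F, M, G = (u[i * n:(i + 1) * n] for i in range(5))
        tot = M + G
        al = np.where(tot > 0.0, M / np.where(tot > 0.0, tot, 1.0), 1.0)
        return np.concatenate([
            al * p.beta * F * M - p.e * E,
            p.e * E * (1.0 - A / k) - (p.eta_a + p.mu_a) * A,
            p.r * p.eta_a * A - p.mu_f * F,
            (1.0 - p.r) * p.eta_a * A - p.mu_m * M,
            -p.mu_g * G,
        ])

    def _reaction_jacobian(self, u: np.ndarray) -> sp.csr_matrix:
        """Analytic block-diagonal (per-cell 5×5) reaction Jacobian."""
        p, n, k = self.params, self.n, self.k
        E, A, F, M, G = (u[i * n:(i + 1) * n] for i in range(5))
        tot = M + G
        pos = tot > 0.0
        safe = np.where(pos, tot, 1.0)
        al = np.where(pos, M / safe, 1.0)
        dal_dM = np.where(pos, G / safe**2, 0.0)
        dal_dG = np.where(pos, -M / safe**2, 0.0)
        idx = np.arange(n)
        rows, cols, vals = [], [], []

        def put(fr: int, fc: int, d: np.ndarray) -> None:
            rows.append(fr * n + idx)
            cols.append(fc * n + idx)
            vals.append(d)

        ones = np.ones(n)
        put(0, 0, -p.e * ones)
        put(0, 2, al * p.beta * M)
        put(0, 3, p.beta * F * (al + M * dal_dM))
        put(0, 4, p.beta * F * M * dal_dG)
        put(1, 0, p.e * (1.0 - A / k))
        put(1, 1, -p.e * E / k - (p.eta_a + p.mu_a) * ones)
        put(2, 1, p.r * p.eta_a * ones)
        put(2, 2, -p.mu_f * ones)
        put(3, 1, (1.0 - p.r) * p.eta_a * ones)
        put(3, 3, -p.mu_m * ones)
        put(4, 4, -p.mu_g * ones)
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(5 * n, 5 * n),
        )

    # -- stepping -----------------------------------------------------------
    def step(self, state: SpatialState,
             release_field: np.ndarray | None = None,
             reaction: bool = True,
             smooth_start: bool = False) -> SpatialState:
        """Advance one step of length ``spec.dt``.

        The regular step is time-centered (Crank–Nicolson).  With
        ``smooth_start=True`` the step is taken as two backward-Euler
        half-steps instead (Rannacher startup): pulse releases make the GM
        field locally non-smooth, and the centered scheme is not
        positivity-preserving on such data at day-scale steps, while the
        L-stable half-steps damp the offending modes without degrading the
        global second-order accuracy.
        """
        spec = self.spec
        n = self.n
        u0 = state.stack()
        rel = np.zeros(5 * n)
        if release_field is not None:
            rf = np.asarray(release_field, dtype=float)
            if rf.shape != state.shape:
                raise ValueError("release_field shape mismatch")
            if (rf < 0).any():
                raise ValueError("release_field must be non-negative")
            rel[4 * n:] = rf.ravel()

        scale = max(1.0, float(np.abs(u0).max()))
        iters = 0
        if smooth_start:
            u1 = self._advance(u0, rel, 0.5 * spec.dt, 1.0, reaction, state.t)
            iters += self.last_newton_iters
            u1 = self._advance(u1, rel, 0.5 * spec.dt, 1.0, reaction,
                               state.t + 0.5 * spec.dt)
            iters += self.last_newton_iters
        else:
            u1 = self._advance(u0, rel, spec.dt, 0.5, reaction, state.t)
            iters = self.last_newton_iters
        self.last_newton_iters = iters
        return self._enforce_domain(u1, state.t + spec.dt, scale)

    def _advance(self, u0: np.ndarray, rel: np.ndarray, dt: float,
                 theta: float, reaction: bool, t: float,
                 depth: int = 0) -> np.ndarray:
        """One θ-scheme sub-step (θ=1/2 Crank–Nicolson, θ=1 backward Euler).

        If the damped Newton iteration fails to contract, or converges onto
        a root outside the invariant domain (the discrete system can have
        spurious far-away branches, reachable on the large state jumps of
        infrequent pulse releases), the sub-step is retried as two halves —
        for small enough steps Newton stays in the physical root's basin.
        Up to 6 refinement levels are attempted.
        """
        try:
            u1 = self._newton(u0, rel, dt, theta, reaction, t)
            self._check_domain(u1, max(1.0, float(np.abs(u0).max())), t + dt)
            return u1
        except RuntimeError:
            if depth >= 6:
                raise
        half = self._advance(u0, rel, dt / 2.0, theta, reaction, t, depth + 1)
        return self._advance(half, rel, dt / 2.0, theta, reaction,
                             t + dt / 2.0, depth + 1)

    def _check_domain(self, u1: np.ndarray, scale: float, t: float) -> None:
        neg = float(u1.min())
        if neg < -_NEG_CLAMP * scale:
            raise RuntimeError(
                f"invariant-domain violation at t={t}: field value {neg:.3e}"
            )
        n = self.n
        over = u1[n:2 * n] - self.k
        if (over > _CAP_SLACK * np.maximum(1.0, self.k) + 1e-12).any():
            raise RuntimeError(
                f"aquatic density exceeded carrying capacity at t={t}: "
                f"max overshoot {float(over.max()):.3e}"
            )

    def _newton(self, u0: np.ndarray, rel: np.ndarray, dt: float,
                theta: float, reaction: bool, t: float) -> np.ndarray:
        spec = self.spec
        explicit = self.L @ u0
        if reaction:
            explicit = explicit + self._reaction(u0)

        def residual(u1: np.ndarray) -> np.ndarray:
            r = u1 - u0 - dt * (theta * (self.L @ u1) +
                                (1.0 - theta) * explicit + rel)
            if reaction:
                r -= dt * theta * self._reaction(u1)
            return r

        # start Newton from the current state: the reaction terms are stiff
        # relative to a 1-day step, so an explicit predictor overshoots
        u1 = u0.copy()
        scale = max(1.0, float(np.abs(u0).max()), float(np.abs(rel).max()) * dt)
        res = residual(u1)
        norm = float(np.linalg.norm(res))
        iters = 0
        while float(np.abs(res).max()) > spec.newton_tol * scale:
            iters += 1
            if iters > spec.max_newton_iter:
                raise RuntimeError(
                    f"Newton did not converge in {spec.max_newton_iter} "
                    f"iterations at t={t} (dt={dt}): residual max "
                    f"{float(np.abs(res).max()):.3e}"
                )
            J = self.identity - dt * theta * self.L
            if reaction:
                J = J - dt * theta * self._reaction_jacobian(u1)
            if self._dense:
                delta = np.linalg.solve(J.toarray(), -res)
            else:
                delta = splu(J.tocsc()).solve(-res)
            # damped update: halve until the 2-norm decreases
            lam = 1.0
            for _ in range(12):
                trial = u1 + lam * delta
                tres = residual(trial)
                tnorm = float(np.linalg.norm(tres))
                if np.isfinite(tnorm) and tnorm < norm * (1.0 - 1e-4 * lam):
                    u1, res, norm = trial, tres, tnorm
                    break
                lam *= 0.5
            else:
                raise RuntimeError(
                    f"Newton line search stalled at t={t} (dt={dt}): "
                    f"residual 2-norm {norm:.3e}"
                )
        self.last_newton_iters = iters
        return u1

    def _enforce_domain(self, u1: np.ndarray, t: float,
                        scale: float) -> SpatialState:
        neg = float(u1.min())
        if neg < -_NEG_CLAMP * scale:
            raise RuntimeError(
                f"invariant-domain violation at t={t}: field value {neg:.3e}"
            )
        np.clip(u1, 0.0, None, out=u1)
        n = self.n
        A = u1[n:2 * n]
        over = A - self.k
        if (over > _CAP_SLACK * np.maximum(1.0, self.k) + 1e-12).any():
            raise RuntimeError(
                f"aquatic density exceeded carrying capacity at t={t}: "
                f"max overshoot {float(over.max()):.3e}"
            )
        np.minimum(A, self.k, out=A)
        return SpatialState.from_stack(u1, (self.grid.ny, self.grid.nx), t)


def crank_nicolson_step(
    params: ModelParameters,
    grid: GridMap,
    state: SpatialState,
    release_field: np.ndarray | None = None,
    spec: DiscretizationSpec | None = None,
    reaction: bool = True,
) -> SpatialState:
    """One Crank–Nicolson step (convenience wrapper building a solver).

    For long runs prefer :func:`simulate_pde`, which reuses the cached
    operator across steps.  ``reaction=False`` steps pure diffusion, which
    with no-flux boundaries conserves each field's total exactly.
    """
    return CrankNicolsonSolver(params, grid, spec).step(
        state, release_field, reaction=reaction)


@dataclass
class SimulationResult:
    """Per-day domain totals, optional snapshots and solver diagnostics."""

    totals: pd.DataFrame
    snapshots: dict[float, SpatialState] = field(default_factory=dict)
    newton_iterations: list[int] = field(default_factory=list)
    min_field_value: float = 0.0
    max_capacity_excess: float = -np.inf

    @property
    def final(self) -> pd.Series:
        return self.totals.iloc[-1]


def simulate_pde(
    params: ModelParameters,
    grid: GridMap,
    initial: SpatialState,
    schedule=None,
    horizon: float = 100.0,
    spec: DiscretizationSpec | None = None,
    snapshot_days: Sequence[float] = (),
    progress: Callable[[float, Mapping[str, float]], None] | None = None,
) -> SimulationResult:
    """Run the spatial model for ``horizon`` days.

    ``schedule`` may be None (no release), a constant per-cell density-rate
    array (mosquitoes/m²/day), or any object with a
    ``release_field(grid, t0, dt)`` method (see
    :class:`aedesgm.scenarios.ReleaseSchedule`), evaluated at the start of
    every step.  Returns per-day totals of all phases (individuals),
    snapshots at the requested days, and per-step Newton iteration counts.
    """
    spec = spec or DiscretizationSpec()
    if horizon < spec.dt:
        raise ValueError("horizon must be at least one time step")
    solver = CrankNicolsonSolver(params, grid, spec)
    state = replace(initial, t=0.0) if initial.t != 0.0 else initial

    want = sorted(float(d) for d in snapshot_days)
    snapshots: dict[float, SpatialState] = {}
    records = [{"day": 0.0, **state.totals(grid)}]
    iters: list[int] = []
    min_val = float(min(getattr(state, f).min() for f in _FIELDS))
    max_excess = float((state.A - grid.k_field()).max())
    if want and abs(want[0]) < 1e-12:
        snapshots[0.0] = state
        want.pop(0)

    n_steps = int(round(horizon / spec.dt))
    prev_rf: np.ndarray | None = None
    for step_no in range(n_steps):
        if schedule is None:
            rf = None
        elif hasattr(schedule, "release_field"):
            rf = schedule.release_field(grid, state.t, spec.dt)
        else:
            rf = np.asarray(schedule, dtype=float)
        # a release switching on or off makes the GM field non-smooth;
        # damp that step with the backward-Euler startup (see step())
        if rf is None and prev_rf is None:
            changed = False
        elif rf is None or prev_rf is None:
            changed = True
        else:
            changed = not np.array_equal(rf, prev_rf)
        state = solver.step(state, rf, smooth_start=changed)
        prev_rf = rf
        iters.append(solver.last_newton_iters)
        min_val = min(min_val, float(min(getattr(state, f).min() for f in _FIELDS)))
        max_excess = max(max_excess, float((state.A - grid.k_field()).max()))
        totals = state.totals(grid)
        records.append({"day": state.t, **totals})
        if progress is not None:
            progress(state.t, totals)
        while want and state.t >= want[0] - 1e-9:
            snapshots[want.pop(0)] = state
    df = pd.DataFrame.from_records(records)
    return SimulationResult(
        totals=df,
        snapshots=snapshots,
        newton_iterations=iters,
        min_field_value=min_val,
        max_capacity_excess=max_excess,
    )


def wild_equilibrium_state(params: ModelParameters, grid: GridMap) -> SpatialState:
    """Spatial state at the per-cell wild (no-release) equilibrium.

    Each cell is filled with its class's persistent equilibrium densities
    (per-cell totals divided by the cell area); cells whose class cannot
    sustain a population (Q0 < 1) start empty.
    """
    area = grid.cell_area
    fields = {name: np.zeros((grid.ny, grid.nx)) for name in _FIELDS}
    for cls, K in ((HOUSE, grid.K_house), (1 - HOUSE, grid.K_street)):
        mask = grid.cell_class == cls
        if not mask.any():
            continue
        top = wild_equilibrium(params, K, area).wild
        if top is None:
            continue
        st = top.state
        for name in _FIELDS:
            fields[name][mask] = getattr(st, name) / area
    return SpatialState(**fields, t=0.0)
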