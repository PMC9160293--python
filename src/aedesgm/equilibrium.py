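"""Single-cell ODE reduction, equilibria and critical GM release rates.

Integrating the reaction–diffusion system over one isolated grid cell
(no-flux faces) gives a five-dimensional ODE for the total populations
**E**, **A**, **F**, **M**, **G** in that cell:

    E' = α β/a · F M − e E
    A' = e E (1 − A/K) − (η_a + μ_a) A
    F' = r η_a A − μ_f F
    M' = (1 − r) η_a A − μ_m M
    G' = L − μ_g G

with α = M/(M+G) (α = 1 when M = G = 0), K the cell's total carrying
capacity and L the GM males released into the cell per day.  ``a`` is the
cell area in m²: β is a density-encounter coefficient (m²/day), so the
per-cell encounter term must carry 1/a.  With the default ``area=1`` the
formulas reduce to the classical unit-area form.

Stationary aquatic totals solve the cubic

    A³ − K A² + b K A + b c K = 0,
    b = (μ_a + η_a) μ_f μ_m a / ((1−r) r β η_a²),      c = μ_m L / ((1−r) η_a μ_g),

whose L = 0 limit factors into A · (A² − K A + b K): the wild equilibria
A* = K(1 ± sqrt(1 − 1/Q0))/2 with basic offspring number Q0 = K/(4b).
For L > 0 the roots come from Cardano's formula via the discriminant φ;
φ < 0 gives two admissible positive roots (the larger an attractor, the
smaller a saddle), φ > 0 none — the wild population collapses.  The
critical per-cell release rate L_c(K) solves φ = 0 in closed form, and the
domain-level critical rate applies L_c to the block-count-weighted mean
capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .maps import GridMap, map_composition
from .parameters import ModelParameters

__all__ = [
    "TotalPopulationState",
    "Equilibrium",
    "EquilibriumSet",
    "ode_rhs",
    "integrate_ode",
    "basic_offspring_number",
    "wild_equilibrium",
    "carrying_capacity_from_aquatic",
    "calibrate_carrying_capacities",
    "gm_cubic_roots",
    "classify_equilibria",
    "critical_release_rate",
    "domain_critical_release",
    "expected_equilibrium_curve",
]

ATTRACTOR = "attractor"
SADDLE = "saddle"
NON_ADMISSIBLE = "non-admissible"


@dataclass(frozen=True)
class TotalPopulationState:
    """Total individuals of each phase in one control cell."""

    E: float
    A: float
    F: float
    M: float
    G: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.A, self.F, self.M, self.G], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "TotalPopulationState":
        E, A, F, M, G = (float(v) for v in y)
        return cls(E, A, F, M, G)

    @classmethod
    def zero(cls) -> "TotalPopulationState":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Equilibrium:
    """One stationary point with admissibility and stability labels."""

    state: TotalPopulationState
    admissible: bool
    stability: str | None = None

    @property
    def aquatic(self) -> float:
        return self.state.A


@dataclass(frozen=True)
class EquilibriumSet:
    """All stationary points of the cell ODE for one (K, L) pair.

    ``equilibria`` holds the trivial point first, then the aquatic roots in
    increasing order.  ``phi`` is the Cardano discriminant (None on the
    pure wild branch where the quadratic is solved directly).
    """

    K: float
    L: float
    area: float
    Q0: float
    b: float
    c: float
    phi: float | None
    equilibria: tuple[Equilibrium, ...]

    @property
    def wild(self) -> Equilibrium | None:
        """The largest admissible non-trivial equilibrium (attractor branch)."""
        best = None
        for eq in self.equilibria:
            if eq.admissible and eq.aquatic > 0:
                if best is None or eq.aquatic > best.aquatic:
                    best = eq
        return best

    @property
    def admissible_aquatic(self) -> tuple[float, ...]:
        return tuple(eq.aquatic for eq in self.equilibria
                     if eq.admissible and eq.aquatic > 0)


# ---------------------------------------------------------------------------
# Reduced coefficients
# ---------------------------------------------------------------------------

def _beta_cell(p: ModelParameters, area: float) -> float:
    if area <= 0:
        raise ValueError(f"cell area must be positive, got {area}")
    return p.beta / area


def _b_coeff(p: ModelParameters, area: float) -> float:
    """Cubic coefficient b (units of population)."""
    return ((p.mu_a + p.eta_a) * p.mu_f * p.mu_m
            / ((1.0 - p.r) * p.r * _beta_cell(p, area) * p.eta_a**2))


def _c_coeff(p: ModelParameters, L: float) -> float:
    """Cubic coefficient c, proportional to the release rate L."""
    return p.mu_m * L / ((1.0 - p.r) * p.eta_a * p.mu_g)


def basic_offspring_number(p: ModelParameters, K: float, area: float = 1.0) -> float:
    """Basic offspring number Q0 = β r(1−r) η_a² K / (4 (η_a+μ_a) μ_f μ_m a).

    Q0 ≥ 1 is the persistence condition for the wild population; K enters
    linearly, so Q0 also reads K/(4b).
    """
    if K < 0:
        raise ValueError(f"carrying capacity K must be >= 0, got {K}")
    return K / (4.0 * _b_coeff(p, area))


# ---------------------------------------------------------------------------
# Right-hand side and integration
# ---------------------------------------------------------------------------

def _alpha_scalar(M: float, G: float) -> float:
    if M == 0.0 and G == 0.0:
        return 1.0
    return M / (M + G)


def ode_rhs(
    p: ModelParameters,
    state: TotalPopulationState | Sequence[float],
    K: float,
    L: float,
    area: float = 1.0,
) -> np.ndarray:
    """Per-day derivatives of the five total populations in one cell."""
    if isinstance(state, TotalPopulationState):
        E, A, F, M, G = state.as_array()
    else:
        E, A, F, M, G = (float(v) for v in state)
    assert K > 0 and L >= 0, "K must be positive and L non-negative"
    al = _alpha_scalar(M, G)
    beta = _beta_cell(p, area)
    return np.array([
        al * beta * F * M - p.e * E,
        p.e * E * (1.0 - A / K) - (p.eta_a + p.mu_a) * A,
        p.r * p.eta_a * A - p.mu_f * F,
        (1.0 - p.r) * p.eta_a * A - p.mu_m * M,
        L - p.mu_g * G,
    ])


def integrate_ode(
    p: ModelParameters,
    initial: TotalPopulationState | Sequence[float],
    K: float,
    L: float,
    horizon: float,
    dt: float = 1.0,
    area: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the cell ODE with a stiff-capable solver (LSODA).

    Returns ``(times, states)`` where ``times`` is the uniform grid
    ``0, dt, …, horizon`` and ``states`` has shape ``(len(times), 5)``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if horizon < dt:
        raise ValueError(f"horizon ({horizon}) must be >= dt ({dt})")
    y0 = (initial.as_array() if isinstance(initial, TotalPopulationState)
          else np.asarray(initial, dtype=float))
    n = int(round(horizon / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    sol = solve_ivp(
        lambda t, y: ode_rhs(p, y, K, L, area),
        (0.0, times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.isfinite(sol.y).all():
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return times, sol.y.T


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

def _companions(p: ModelParameters, A: float, K: float, L: float,
                area: float) -> TotalPopulationState:
    """Phase totals accompanying an aquatic root A (any sign)."""
    G = L / p.mu_g
    F = p.r * p.eta_a * A / p.mu_f
    M = (1.0 - p.r) * p.eta_a * A / p.mu_m
    denom = p.e * (1.0 - A / K)
    E = (p.mu_a + p.eta_a) * A / denom if denom != 0 else math.inf
    return TotalPopulationState(E, A, F, M, G)


def _trivial(p: ModelParameters, L: float) -> Equilibrium:
    state = TotalPopulationState(0.0, 0.0, 0.0, 0.0, L / p.mu_g)
    return Equilibrium(state=state, admissible=True)


def wild_equilibrium(p: ModelParameters, K: float, area: float = 1.0) -> EquilibriumSet:
    """Stationary points of the L = 0 (no GM release) cell ODE.

    For Q0 < 1 only the trivial extinction point exists inside the domain;
    for Q0 ≥ 1 the quadratic adds A* = K(1 + sqrt(1−1/Q0))/2 (the persistent
    wild population) and the smaller root K(1 − sqrt(1−1/Q0))/2 (a saddle
    separating the two attractors).
    """
    if K <= 0:
        raise ValueError(f"carrying capacity K must be positive, got {K}")
    b = _b_coeff(p, area)
    Q0 = K / (4.0 * b)
    eqs: list[Equilibrium] = [_trivial(p, 0.0)]
    if Q0 >= 1.0:
        s = math.sqrt(1.0 - 1.0 / Q0)
        for root in sorted((K * (1.0 - s) / 2.0, K * (1.0 + s) / 2.0)):
            if root > 0.0:
                eqs.append(Equilibrium(
                    state=_companions(p, root, K, 0.0, area),
                    admissible=0.0 <= root <= K,
                ))
    return EquilibriumSet(K=K, L=0.0, area=area, Q0=Q0, b=b, c=0.0,
                          phi=None, equilibria=tuple(eqs))


def carrying_capacity_from_aquatic(
    p: ModelParameters, A_star: float, area: float = 1.0
) -> float:
    """Invert the wild quadratic for K given an observed aquatic total.

    From A² − K A + b K = 0:  ``K = A² / (A − b)``.  This lets field
    estimates of the standing aquatic population (larval surveys) be turned
    into a cell carrying capacity.  Requires A_star > b; at A_star = b the
    denominator degenerates (that population is unattainable at any K).
    """
    if A_star <= 0:
        raise ValueError(f"A_star must be positive, got {A_star}")
    b = _b_coeff(p, area)
    denom = A_star - b
    if abs(denom) < 1e-300 or denom < 0:
        raise ValueError(
            f"degenerate inversion: A_star={A_star} must exceed b={b}"
        )
    return A_star**2 / denom


def _wild_female_total(p: ModelParameters, K: float, area: float) -> float:
    """Female total of the persistent wild equilibrium (0 when Q0 < 1)."""
    eqs = wild_equilibrium(p, K, area)
    top = eqs.wild
    return top.state.F if top is not None else 0.0


def calibrate_carrying_capacities(
    p: ModelParameters,
    grid: GridMap,
    F_target: float,
    street_weight: float = 1.0,
    capacity_ratio: float = 5.0,
) -> tuple[float, float]:
    """Fit per-cell capacities (K_house, K_street) to a female equilibrium.

    Solves ``n_h F*(K_h) + w n_s F*(K_s) = F_target`` under the breeding-site
    constraint ``K_h = ratio · K_s`` (80% of breeding places in houses →
    ratio 5) by bracketing in K_s.  ``street_weight`` (default 1, i.e. a
    plain block-count sum) exposes the alternative street-discounted
    aggregation convention.

    Returns the pair; the map is not modified (rebuild it with
    :func:`aedesgm.maps.with_capacities`).
    """
    if F_target <= 0:
        raise ValueError(f"F_target must be positive, got {F_target}")
    if grid.n_house < 1:
        raise ValueError("map must contain at least one house cell")
    area = grid.cell_area
    b = _b_coeff(p, area)
    n_h, n_s = grid.n_house, grid.n_street

    def total_female(K_s: float) -> float:
        return (n_h * _wild_female_total(p, capacity_ratio * K_s, area)
                + street_weight * n_s * _wild_female_total(p, K_s, area))

    # Street persistence (Q0 >= 1) requires K_s >= 4b; just above it the
    # total is already positive, so targets below that floor are infeasible.
    lo = 4.0 * b * (1.0 + 1e-12)
    floor = total_female(lo)
    if F_target <= floor:
        raise ValueError(
            f"F_target={F_target} is below the feasible range (> {floor:.6g}) "
            f"for a persistent street population (K_s > {4 * b:.6g})"
        )
    hi = lo * 2.0
    while total_female(hi) < F_target:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("calibration bracket expansion failed")
    K_s = brentq(lambda K: total_female(K) - F_target, lo, hi,
                 xtol=1e-14, rtol=8.9e-16)
    return capacity_ratio * K_s, K_s


def _cardano_roots(K: float, b: float, c: float) -> tuple[float, list[float]]:
    """Roots of A³ − K A² + b K A + b c K via Cardano; returns (phi, roots).

    The depressed cubic y³ + P y + Q (A = y + K/3) has
    P = bK − K²/3 and Q = −2K³/27 + bK²/3 + bcK; φ = (P/3)³ + (Q/2)².
    For φ > 0 there is one real root; for φ ≤ 0 three (trig form).
    """
    P = b * K - K**2 / 3.0
    Q = -2.0 * K**3 / 27.0 + b * K**2 / 3.0 + b * c * K
    phi = (P / 3.0) ** 3 + (Q / 2.0) ** 2
    shift = K / 3.0
    if phi > 0:
        sq = math.sqrt(phi)
        y = math.cbrt(-Q / 2.0 + sq) + math.cbrt(-Q / 2.0 - sq)
        roots = [y + shift]
    else:
        # three real roots: y_k = 2 sqrt(-P/3) cos((θ − 2πk)/3)
        m = math.sqrt(max(-P / 3.0, 0.0))
        if m == 0.0:
            roots = [shift] * 3
        else:
            cosarg = max(-1.0, min(1.0, 3.0 * Q / (2.0 * P * m)))
            theta = math.acos(cosarg)
            roots = sorted(2.0 * m * math.cos((theta - 2.0 * math.pi * k) / 3.0)
                           + shift for k in range(3))
    return phi, roots


def gm_cubic_roots(
    p: ModelParameters, K: float, L: float, area: float = 1.0
) -> EquilibriumSet:
    """Stationary aquatic totals under a constant daily GM release L.

    Solves the equilibrium cubic by Cardano's formula.  For 0 < L below the
    critical rate (φ < 0) there are two admissible positive roots — the
    larger one the suppressed-but-persistent population, the smaller a
    saddle — plus one negative, non-admissible root.  Beyond the critical
    rate (φ > 0) no admissible root remains and extinction is the only
    attractor.  At L = 0 the cubic factors through A = 0 into the wild
    quadratic.
    """
    if K <= 0:
        raise ValueError(f"carrying capacity K must be positive, got {K}")
    if L < 0:
        raise ValueError(f"release rate L must be >= 0, got {L}")
    b = _b_coeff(p, area)
    c = _c_coeff(p, L)
    if c == 0.0:
        # the cubic factors exactly through A = 0 into the wild quadratic
        phi = _cardano_roots(K, b, 0.0)[0]
        disc = K * K - 4.0 * b * K
        roots = ([] if disc < 0 else
                 sorted(((K - math.sqrt(disc)) / 2.0, (K + math.sqrt(disc)) / 2.0)))
    else:
        phi, roots = _cardano_roots(K, b, c)
    eqs: list[Equilibrium] = [_trivial(p, L)]
    for root in roots:
        if root == 0.0:  # duplicate of the trivial equilibrium
            continue
        eqs.append(Equilibrium(
            state=_companions(p, root, K, L, area),
            admissible=0.0 <= root <= K,
        ))
    return EquilibriumSet(K=K, L=L, area=area, Q0=K / (4.0 * b), b=b, c=c,
                          phi=phi, equilibria=tuple(eqs))


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

def _jacobian_fd(p: ModelParameters, y: np.ndarray, K: float, L: float,
                 area: float) -> np.ndarray:
    """Central-difference Jacobian of the cell ODE right-hand side."""
    n = 5
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (ode_rhs(p, yp, K, L, area) - ode_rhs(p, ym, K, L, area)) / (2 * h)
    if not np.isfinite(J).all():
        raise FloatingPointError("non-finite Jacobian at equilibrium")
    return J


def classify_equilibria(
    p: ModelParameters,
    K: float,
    L: float,
    equilibria: EquilibriumSet | Iterable[Equilibrium],
    area: float = 1.0,
) -> EquilibriumSet | tuple[Equilibrium, ...]:
    """Label each equilibrium attractor / saddle by numeric linearization.

    Evaluates the 5×5 Jacobian by central differences and inspects the
    eigenvalue real parts against a tolerance of 1e-9 × (largest rate).
    Non-admissible points keep the label "non-admissible".
    """
    rates = (p.beta, p.e, p.eta_a, p.mu_a, p.mu_f, p.mu_m, p.mu_g)
    tol = 1e-9 * max(rates)
    source = equilibria.equilibria if isinstance(equilibria, EquilibriumSet) else tuple(equilibria)
    labelled = []
    for eq in source:
        if not eq.admissible:
            labelled.append(Equilibrium(eq.state, eq.admissible, NON_ADMISSIBLE))
            continue
        J = _jacobian_fd(p, eq.state.as_array(), K, L, area)
        re = np.linalg.eigvals(J).real
        label = ATTRACTOR if (re < -tol).all() else SADDLE
        labelled.append(Equilibrium(eq.state, eq.admissible, label))
    if isinstance(equilibria, EquilibriumSet):
        return EquilibriumSet(
            K=equilibria.K, L=equilibria.L, area=equilibria.area,
            Q0=equilibria.Q0, b=equilibria.b, c=equilibria.c,
            phi=equilibria.phi, equilibria=tuple(labelled),
        )
    return tuple(labelled)


# ---------------------------------------------------------------------------
# Critical release rates
# ---------------------------------------------------------------------------

def critical_release_rate(p: ModelParameters, K: float, area: float = 1.0) -> float:
    """Closed-form critical daily GM release rate L_c for one cell.

    Solves φ(K, L) = 0 for L:

        L_c(K) = (1−r) η_a μ_g / (b K μ_m) ·
                 ( sqrt(−(4/27)(bK − K²/3)³) + 2K³/27 − bK²/3 )

    Requires K > 3b so the inner radicand is positive (equivalently
    Q0 > 3/4; below that the wild population cannot persist anyway).
    """
    if K <= 0:
        raise ValueError(f"carrying capacity K must be positive, got {K}")
    b = _b_coeff(p, area)
    inner = b * K - K**2 / 3.0
    if inner >= 0:
        raise ValueError(
            f"no critical rate: K={K} must exceed 3b={3 * b:.6g} "
            "for the radicand to be positive"
        )
    radic = -(4.0 / 27.0) * inner**3
    Lc = ((1.0 - p.r) * p.eta_a * p.mu_g / (b * K * p.mu_m)
          * (math.sqrt(radic) + 2.0 * K**3 / 27.0 - b * K**2 / 3.0))
    return Lc


def domain_critical_release(p: ModelParameters, grid: GridMap) -> float:
    """Critical homogeneous daily release per cell for a whole map.

    Applies L_c to the block-count-weighted mean capacity; multiply by the
    cell count for the domain-total daily release.
    """
    mean_K = map_composition(grid).mean_capacity
    return critical_release_rate(p, mean_K, grid.cell_area)


def expected_equilibrium_curve(
    p: ModelParameters,
    grid: GridMap,
    L_grid: Sequence[float],
) -> np.ndarray:
    """Expected domain aquatic equilibrium versus per-cell daily release.

    For each per-cell rate L, sums the attractor-branch aquatic root over
    all cells (0 where no admissible root survives).  Returns an array of
    shape ``(len(L_grid),)``; the curve is non-increasing and drops to zero
    once every cell class is beyond its critical rate.
    """
    area = grid.cell_area
    out = np.empty(len(L_grid))
    for i, L in enumerate(L_grid):
        total = 0.0
        for count, K in ((grid.n_house, grid.K_house),
                         (grid.n_street, grid.K_street)):
            if count == 0:
                continue
            eqs = gm_cubic_roots(p, K, float(L), area) if L > 0 else \
                wild_equilibrium(p, K, area)
            top = eqs.wild
            total += count * (top.aquatic if top is not None else 0.0)
        out[i] = total
    return out
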