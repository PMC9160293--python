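"""Release-strategy experiments: heterogeneity, localization, frequency.

The release strategies compared here keep the *total* number of released GM
males fixed and vary where and how often they are put out:

* **localized** — the whole amount lands on a small committed central
  footprint (38 cells, 950 m²), emulating the point-release practice of
  actual control programmes;
* **homogeneous** — the same amount is spread uniformly over the domain.

Amounts are expressed as a multiple of the domain female equilibrium
population (the conventional launch size is 11×), and a release *period*
of p days means one pulse of p days' worth every p days, so any 30-day
window always receives the same total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibrium import (
    expected_equilibrium_curve,
    wild_equilibrium,
)
from .fvm import (
    DiscretizationSpec,
    SimulationResult,
    simulate_pde,
    wild_equilibrium_state,
)
from .maps import GridMap, homogenize_map, reference_release_mask
from .parameters import ModelParameters

__all__ = [
    "ReleaseSchedule",
    "ScenarioResult",
    "make_release_schedule",
    "domain_female_equilibrium",
    "trajectory_metrics",
    "heterogeneity_comparison",
    "localization_comparison",
    "frequency_scan",
    "release_sweep",
]


@dataclass(frozen=True)
class ReleaseSchedule:
    """Pulsed GM-male releases on a cell set.

    ``cells`` is a boolean (ny, nx) mask, or None for the whole domain.
    ``amount_per_period`` GM males are released every ``period`` days
    starting on ``start_day``; each pulse is applied as a density rate over
    the time step containing the event, so the released total is exact
    regardless of dt.
    """

    cells: np.ndarray | None
    period: int = 1
    amount_per_period: float = 0.0
    start_day: float = 0.0

    def __post_init__(self) -> None:
        if self.period < 1 or int(self.period) != self.period:
            raise ValueError(f"period must be an integer >= 1, got {self.period}")
        if self.amount_per_period < 0:
            raise ValueError("amount_per_period must be >= 0")
        if self.cells is not None:
            mask = np.asarray(self.cells, dtype=bool)
            if not mask.any():
                raise ValueError("release cell set must not be empty")
            mask.setflags(write=False)
            object.__setattr__(self, "cells", mask)

    @property
    def daily_equivalent(self) -> float:
        """Released GM males per day averaged over the period."""
        return self.amount_per_period / self.period

    def release_field(self, grid: GridMap, t0: float, dt: float) -> np.ndarray | None:
        """Per-cell density rate (mosquitoes/m²/day) for the step [t0, t0+dt)."""
        if self.amount_per_period == 0.0:
            return None
        # pulses at start_day + m*period, m >= 0; each lands in exactly the
        # step whose interval [t0, t0+dt) contains it
        gap = (self.start_day - t0) % self.period  # time until next pulse
        event_time = t0 + gap
        if gap > dt - 1e-9 or event_time < self.start_day - 1e-9:
            return None
        if self.cells is None:
            area = grid.domain_area
            return np.full((grid.ny, grid.nx),
                           self.amount_per_period / (area * dt))
        if self.cells.shape != (grid.ny, grid.nx):
            raise ValueError("release mask shape does not match the map")
        area = float(self.cells.sum()) * grid.cell_area
        field = np.zeros((grid.ny, grid.nx))
        field[self.cells] = self.amount_per_period / (area * dt)
        return field


def domain_female_equilibrium(params: ModelParameters, grid: GridMap) -> float:
    """Total adult females at the per-cell wild equilibrium of a map."""
    total = 0.0
    for count, K in ((grid.n_house, grid.K_house),
                     (grid.n_street, grid.K_street)):
        if count == 0:
            continue
        top = wild_equilibrium(params, K, grid.cell_area).wild
        if top is not None:
            total += count * top.state.F
    return total


def make_release_schedule(
    kind: str,
    grid: GridMap,
    multiple_of_female_equilibrium: float,
    period: int = 1,
    params: ModelParameters | None = None,
    cells: np.ndarray | None = None,
    start_day: float = 0.0,
) -> ReleaseSchedule:
    """Build a schedule releasing a multiple of the female equilibrium.

    ``amount_per_period = multiple × F_eq × period``, so the daily
    equivalent is independent of the period.  ``kind`` is "localized"
    (committed central footprint unless ``cells`` is given) or
    "homogeneous" (spread over the whole map in proportion to area).
    """
    if multiple_of_female_equilibrium < 0:
        raise ValueError("the release multiple must be >= 0")
    if kind not in ("localized", "homogeneous"):
        raise ValueError(f"unknown release kind {kind!r}")
    params = params or ModelParameters()
    F_eq = domain_female_equilibrium(params, grid)
    amount = multiple_of_female_equilibrium * F_eq * period
    if kind == "homogeneous":
        mask = None
    else:
        mask = cells if cells is not None else reference_release_mask()
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (grid.ny, grid.nx):
            raise ValueError("release mask shape does not match the map")
    return ReleaseSchedule(cells=mask, period=period,
                           amount_per_period=amount, start_day=start_day)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """A run (or pair of runs) with its summary metrics.

    ``metrics`` holds percentages of the phase's initial total:
    ``max_decrease_pct`` (largest drop below the start), ``mean`` (window
    average of the total), and — when a reference run is attached —
    ``max_diff_pct``/``max_diff_day`` and ``end_diff_pct``.
    """

    run: SimulationResult
    reference: SimulationResult | None = None
    metrics: dict[str, float] | None = None


def trajectory_metrics(
    totals: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    phase: str = "A_total",
) -> dict[str, float]:
    """Summary metrics of one phase's domain-total trajectory.

    All percentages are relative to the phase's initial (day-0) total.
    With a reference trajectory (same time grid) the maximum absolute
    difference, its day, and the end-of-horizon difference are added.
    """
    series = totals[phase].to_numpy()
    initial = series[0]
    if initial <= 0:
        raise ValueError(f"initial {phase} must be positive for % metrics")
    out = {
        "initial": float(initial),
        "max_decrease_pct": float((1.0 - series.min() / initial) * 100.0),
        "mean": float(series.mean()),
        "final": float(series[-1]),
        "final_over_initial": float(series[-1] / initial),
    }
    if reference is not None:
        if len(reference) != len(totals) or not np.allclose(
            reference["day"], totals["day"]
        ):
            raise ValueError("runs must share one time grid")
        diff = np.abs(reference[phase].to_numpy() - series) / initial * 100.0
        i = int(diff.argmax())
        out["max_diff_pct"] = float(diff[i])
        out["max_diff_day"] = float(totals["day"].iloc[i])
        out["end_diff_pct"] = float(diff[-1])
    return out


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _run(params, grid, schedule, horizon, spec) -> SimulationResult:
    initial = wild_equilibrium_state(params, grid)
    return simulate_pde(params, grid, initial, schedule, horizon, spec)


def heterogeneity_comparison(
    params: ModelParameters,
    grid: GridMap,
    schedule_kind: str | None = "localized",
    multiple: float = 11.0,
    horizon: float = 100.0,
    spec: DiscretizationSpec | None = None,
    cells: np.ndarray | None = None,
) -> ScenarioResult:
    """Same scenario on the heterogeneous map vs its homogenized version.

    The homogenized arm puts every cell at the block-count-weighted mean
    capacity; each arm starts from its own wild equilibrium, isolating the
    effect of capacity heterogeneity on the dynamics.  ``schedule_kind``
    None runs the zero-release control.
    """
    homog = homogenize_map(grid)
    runs = []
    for g in (grid, homog):
        schedule = None if schedule_kind is None else make_release_schedule(
            schedule_kind, g, multiple, params=params, cells=cells)
        runs.append(_run(params, g, schedule, horizon, spec))
    metrics = trajectory_metrics(runs[0].totals, runs[1].totals)
    return ScenarioResult(run=runs[0], reference=runs[1], metrics=metrics)


def localization_comparison(
    params: ModelParameters,
    grid: GridMap,
    multiple: float = 11.0,
    horizon: float = 100.0,
    spec: DiscretizationSpec | None = None,
    cells: np.ndarray | None = None,
) -> ScenarioResult:
    """Localized vs homogeneous release of the same total daily amount."""
    loc = _run(params, grid,
               make_release_schedule("localized", grid, multiple,
                                     params=params, cells=cells),
               horizon, spec)
    hom = _run(params, grid,
               make_release_schedule("homogeneous", grid, multiple, params=params),
               horizon, spec)
    metrics = trajectory_metrics(loc.totals, hom.totals)
    return ScenarioResult(run=loc, reference=hom, metrics=metrics)


def frequency_scan(
    params: ModelParameters,
    grid: GridMap,
    multiple: float = 11.0,
    periods: Sequence[int] = tuple(range(1, 31)),
    horizon: float = 100.0,
    collapse_fraction: float = 0.5,
    spec: DiscretizationSpec | None = None,
    cells: np.ndarray | None = None,
) -> tuple[pd.DataFrame, int | None, dict[int, SimulationResult]]:
    """Scan release periods at a fixed 30-day total released amount.

    Each period p releases ``multiple × F_eq × p`` GM males every p days on
    the committed central footprint.  Returns a tidy frame (one row per
    period with the aquatic metrics), the critical period — the largest p
    whose aquatic total at the horizon has fallen below
    ``collapse_fraction`` of its initial value — and the raw runs.
    """
    rows = []
    runs: dict[int, SimulationResult] = {}
    for period in periods:
        schedule = make_release_schedule("localized", grid, multiple,
                                         period=int(period), params=params,
                                         cells=cells)
        res = _run(params, grid, schedule, horizon, spec)
        m = trajectory_metrics(res.totals)
        rows.append({"period": int(period), **m})
        runs[int(period)] = res
    df = pd.DataFrame(rows).set_index("period")
    collapsed = df.index[df["final_over_initial"] < collapse_fraction]
    threshold = int(collapsed.max()) if len(collapsed) else None
    return df, threshold, runs


def release_sweep(
    params: ModelParameters,
    grid: GridMap,
    L_grid: Sequence[float],
    horizon: float = 300.0,
    spec: DiscretizationSpec | None = None,
) -> pd.DataFrame:
    """Final aquatic totals of daily homogeneous releases vs the analytic curve.

    ``L_grid`` holds per-cell daily release rates.  For each L the domain
    is simulated for ``horizon`` days under a homogeneous daily release of
    ``L × n_cells`` and the final aquatic total is recorded next to the
    expected equilibrium (sum of the attractor-branch roots).
    """
    expected = expected_equilibrium_curve(params, grid, L_grid)
    rows = []
    for L, exp_A in zip(L_grid, expected):
        schedule = ReleaseSchedule(
            cells=None, period=1, amount_per_period=float(L) * grid.n_cells)
        res = _run(params, grid, schedule, horizon, spec)
        rows.append({
            "L_per_cell": float(L),
            "L_domain_total": float(L) * grid.n_cells,
            "final_aquatic": float(res.totals["A_total"].iloc[-1]),
            "expected_aquatic": float(exp_A),
        })
    return pd.DataFrame(rows)
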