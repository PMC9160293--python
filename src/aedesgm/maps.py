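"""Discretized heterogeneous city domain: house blocks versus streets.

The simulation domain is a rectangular raster of square-ish cells, each
labelled *house* (1) or *street* (0).  Heterogeneity enters the model only
through the aquatic carrying capacity: house blocks offer food and shelter
and carry a density ``k_house``, streets a smaller ``k_street``
(mosquitoes/m²).  Per-cell total capacities are always ``K = k · dx · dy``.

Coordinate convention: cell-centered grid, 0-based indices, ``cell_class``
is indexed ``[row, col]`` with row 0 at the top; cell (row j, col i) spans
``[i·dx, (i+1)·dx) × [j·dy, (j+1)·dy)``.

Because the real neighborhood raster the model was originally run on is not
distributed, :func:`reference_city_map` provides a committed synthetic
Manhattan-style stand-in with the documented composition: 40×40 cells of
5 m × 5 m, 1072 house cells (26800 m²) and 528 street cells (13200 m²).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "GridMap",
    "MapComposition",
    "map_from_matrix",
    "synthesize_city_map",
    "map_composition",
    "homogenize_map",
    "with_capacities",
    "reference_city_map",
    "reference_release_mask",
]

HOUSE = 1
STREET = 0


@dataclass(frozen=True)
class GridMap:
    """A labelled raster domain with per-class carrying capacities.

    Attributes
    ----------
    cell_class:
        ``(ny, nx)`` int array of {0 (street), 1 (house)} labels.
    dx, dy:
        Cell edge lengths in meters.
    k_house, k_street:
        Aquatic carrying-capacity densities (mosquitoes/m²) of the two
        cell classes, ``k_house >= k_street >= 0``.
    """

    cell_class: np.ndarray
    dx: float = 5.0
    dy: float = 5.0
    k_house: float = 0.1402
    k_street: float = 0.0280

    def __post_init__(self) -> None:
        arr = np.asarray(self.cell_class)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("cell_class must be a non-empty 2-D array")
        if not np.isin(arr, (STREET, HOUSE)).all():
            bad = arr[~np.isin(arr, (STREET, HOUSE))][0]
            raise ValueError(f"cell_class entries must be 0 or 1, found {bad!r}")
        arr = np.ascontiguousarray(arr, dtype=np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "cell_class", arr)
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("dx and dy must be strictly positive")
        if not 0 <= self.k_street <= self.k_house:
            raise ValueError(
                f"need k_house >= k_street >= 0, got {self.k_house}, {self.k_street}"
            )

    # -- geometry -----------------------------------------------------------
    @property
    def ny(self) -> int:
        return self.cell_class.shape[0]

    @property
    def nx(self) -> int:
        return self.cell_class.shape[1]

    @property
    def n_cells(self) -> int:
        return self.cell_class.size

    @property
    def cell_area(self) -> float:
        """Area of one cell, dx·dy (m²)."""
        return self.dx * self.dy

    @property
    def domain_area(self) -> float:
        return self.cell_area * self.n_cells

    # -- composition --------------------------------------------------------
    @property
    def n_house(self) -> int:
        return int(np.count_nonzero(self.cell_class == HOUSE))

    @property
    def n_street(self) -> int:
        return self.n_cells - self.n_house

    @property
    def area_house(self) -> float:
        return self.n_house * self.cell_area

    @property
    def area_street(self) -> float:
        return self.n_street * self.cell_area

    # -- capacities ---------------------------------------------------------
    @property
    def K_house(self) -> float:
        """Per-cell total capacity of a house cell (mosquitoes/cell)."""
        return self.k_house * self.cell_area

    @property
    def K_street(self) -> float:
        return self.k_street * self.cell_area

    def k_field(self) -> np.ndarray:
        """Per-cell capacity density field (ny, nx), mosquitoes/m²."""
        return np.where(self.cell_class == HOUSE, self.k_house, self.k_street)

    def K_field(self) -> np.ndarray:
        """Per-cell total capacity field (ny, nx), mosquitoes/cell."""
        return self.k_field() * self.cell_area


@dataclass(frozen=True)
class MapComposition:
    """Cell counts, areas and the block-count-weighted mean capacity."""

    n_house: int
    n_street: int
    area_house: float
    area_street: float
    K_house: float
    K_street: float
    mean_capacity: float


def map_from_matrix(
    matrix: Sequence[Sequence[int]] | np.ndarray,
    dx: float = 5.0,
    dy: float = 5.0,
    k_house: float = 0.1402,
    k_street: float = 0.0280,
) -> GridMap:
    """Build a :class:`GridMap` from a rectangular 0/1 label matrix.

    Row 0 of the matrix is the top row of the map.  Ragged rows and
    non-binary entries are rejected.
    """
    if not isinstance(matrix, np.ndarray):
        rows = [list(row) for row in matrix]
        if not rows:
            raise ValueError("matrix must have at least one row")
        widths = {len(row) for row in rows}
        if len(widths) != 1:
            raise ValueError(f"ragged matrix: row widths {sorted(widths)}")
        matrix = np.array(rows)
    return GridMap(
        cell_class=matrix, dx=dx, dy=dy, k_house=k_house, k_street=k_street
    )


def synthesize_city_map(
    nx: int = 40,
    ny: int = 40,
    street_period: int = 6,
    street_width: int = 1,
    seed: int = 0,
    dx: float = 5.0,
    dy: float = 5.0,
    k_house: float = 0.1402,
    k_street: float = 0.0280,
) -> GridMap:
    """Generate a Manhattan-style synthetic city map.

    Streets are periodic horizontal and vertical bands of ``street_width``
    cells every ``street_period`` cells; all other cells are house blocks.
    The seed only shifts the phase of the street grid, restricted to phases
    with the maximal street-band count, so the composition is a
    deterministic function of the geometry arguments alone.  With the
    defaults the house fraction is (33/40)² ≈ 0.68, close to the documented
    0.67 of the reference neighborhood.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if street_width < 1:
        raise ValueError("street_width must be >= 1 (use map_from_matrix for "
                         "street-less maps)")
    if street_period <= street_width:
        raise ValueError(
            f"street_period ({street_period}) must exceed street_width "
            f"({street_width})"
        )

    def _offsets(n: int) -> list[int]:
        counts = {off: int(((np.arange(n) + off) % street_period
                            < street_width).sum())
                  for off in range(street_period)}
        best = max(counts.values())
        return [off for off, c in counts.items() if c == best]

    rng = np.random.default_rng(seed)
    off_row = int(rng.choice(_offsets(ny)))
    off_col = int(rng.choice(_offsets(nx)))
    rows = (np.arange(ny) + off_row) % street_period < street_width
    cols = (np.arange(nx) + off_col) % street_period < street_width
    street = rows[:, None] | cols[None, :]
    matrix = np.where(street, STREET, HOUSE)
    return GridMap(cell_class=matrix, dx=dx, dy=dy, k_house=k_house, k_street=k_street)


def map_composition(grid: GridMap) -> MapComposition:
    """Summarize a map: counts, areas and the block-weighted mean capacity.

    The mean capacity ``(n_h K_h + n_s K_s) / (n_h + n_s)`` is the capacity
    a homogenized (single-class) map of the same domain would need to carry
    the same total; it feeds the domain-level critical release rate.
    """
    n_h, n_s = grid.n_house, grid.n_street
    mean_K = (n_h * grid.K_house + n_s * grid.K_street) / grid.n_cells
    return MapComposition(
        n_house=n_h,
        n_street=n_s,
        area_house=grid.area_house,
        area_street=grid.area_street,
        K_house=grid.K_house,
        K_street=grid.K_street,
        mean_capacity=mean_K,
    )


def homogenize_map(grid: GridMap) -> GridMap:
    """Replace every cell's capacity by the block-count-weighted mean.

    Geometry and labels become a single (house) class carrying the mean
    capacity density; used to isolate the effect of capacity heterogeneity.
    """
    mean_K = map_composition(grid).mean_capacity
    k_bar = mean_K / grid.cell_area
    return GridMap(
        cell_class=np.ones_like(grid.cell_class),
        dx=grid.dx,
        dy=grid.dy,
        k_house=k_bar,
        k_street=k_bar,
    )


def with_capacities(grid: GridMap, K_house: float, K_street: float) -> GridMap:
    """Return a copy of ``grid`` with per-cell total capacities replaced.

    Densities are derived as ``k = K / (dx·dy)`` — the single consistent
    convention used throughout the package.
    """
    return replace(
        grid,
        k_house=K_house / grid.cell_area,
        k_street=K_street / grid.cell_area,
    )


# ---------------------------------------------------------------------------
# Committed reference fixtures
# ---------------------------------------------------------------------------

_REFERENCE_HOUSE_CELLS = 1072
_TRIM_ROW_FLIPS = 17  # houses flipped to street to hit the documented count


def _build_reference_matrix() -> np.ndarray:
    """Construct the committed 40×40 reference matrix.

    Street bands every 6 cells (width 1, zero offset) give 1089 house
    cells; the leftmost 17 house cells of the bottom row are flipped to
    street so the composition matches the documented 1072 house / 528
    street cells exactly (26800 m² / 13200 m² at 5 m cells).
    """
    matrix = np.ones((40, 40), dtype=np.int8)
    matrix[::6, :] = STREET
    matrix[:, ::6] = STREET
    flipped = 0
    for i in range(matrix.shape[1]):
        if flipped == _TRIM_ROW_FLIPS:
            break
        if matrix[-1, i] == HOUSE:
            matrix[-1, i] = STREET
            flipped += 1
    assert int((matrix == HOUSE).sum()) == _REFERENCE_HOUSE_CELLS
    return matrix


def _build_reference_footprint() -> np.ndarray:
    """Construct the committed localized-release footprint mask.

    38 contiguous central cells (950 m² at 25 m²/cell), standing in for
    the ~944 m² central release rectangle of the original study area.
    """
    mask = np.zeros((40, 40), dtype=bool)
    mask[18:24, 19:25] = True  # 6×6 central block
    mask[21:23, 25] = True  # 2 extra cells -> 38 total
    assert int(mask.sum()) == 38
    return mask


def _load_matrix(name: str) -> np.ndarray:
    text = resources.files("aedesgm.data").joinpath(name).read_text(encoding="utf-8")
    rows = [
        [int(tok) for tok in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return np.array(rows)


def reference_city_map(k_house: float = 0.1402, k_street: float = 0.0280) -> GridMap:
    """The committed synthetic stand-in for the study neighborhood map.

    40×40 cells of 5 m × 5 m with 1072 house and 528 street cells.  The
    capacity densities default to nominal values; calibrated pipelines
    replace them via :func:`with_capacities`.
    """
    matrix = _load_matrix("reference_map.txt")
    return GridMap(cell_class=matrix, dx=5.0, dy=5.0,
                   k_house=k_house, k_street=k_street)


def reference_release_mask() -> np.ndarray:
    """Boolean (40, 40) mask of the committed localized-release footprint."""
    return _load_matrix("release_footprint.txt").astype(bool)
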