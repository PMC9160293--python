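"""Plain-text file formats: maps, schedules, parameter configs, time series.

Every format is line-oriented ASCII so runs are diffable and reproducible:

* **map files** — optional ``#`` header lines carrying ``key=value`` pairs
  (dx, dy, k_house, k_street), then one row of whitespace-separated 0/1
  tokens per grid row (row 0 = top);
* **schedule files** — flat ``key = value`` text (kind, period, multiple
  or amount, start_day, optional cells file);
* **parameter configs** — see :func:`aedesgm.parameters.read_parameter_file`;
* **time series** — CSV with columns day,E_total,A_total,F_total,M_total,
  G_total at fixed precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .maps import GridMap
from .parameters import ModelParameters
from .scenarios import ReleaseSchedule, make_release_schedule

__all__ = [
    "read_map_file",
    "write_map_file",
    "read_schedule_file",
    "write_timeseries",
    "read_timeseries",
]

_MAP_HEADER_KEYS = ("dx", "dy", "k_house", "k_street")
_TS_COLUMNS = ("day", "E_total", "A_total", "F_total", "M_total", "G_total")


def read_map_file(path, **overrides) -> GridMap:
    """Parse a map file; header values win over defaults, kwargs over both.

    Malformed tokens or ragged rows raise with the offending line number.
    Accepts LF and CRLF line endings.
    """
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    width: int | None = None
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("#").split():
                    if "=" not in token:
                        continue
                    key, _, value = token.partition("=")
                    if key in _MAP_HEADER_KEYS:
                        try:
                            header[key] = float(value)
                        except ValueError as exc:
                            raise ValueError(
                                f"{path}:{lineno}: bad header value {token!r}"
                            ) from exc
                continue
            try:
                row = [int(tok) for tok in line.split()]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer map token in {line!r}"
                ) from exc
            if any(v not in (0, 1) for v in row):
                raise ValueError(f"{path}:{lineno}: map tokens must be 0 or 1")
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row (got {len(row)} tokens, "
                    f"expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no map rows found")
    header.update(overrides)
    return GridMap(cell_class=np.array(rows), **header)


def write_map_file(grid: GridMap, path) -> None:
    """Write a map in the dialect :func:`read_map_file` parses."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# dx={grid.dx:.10g} dy={grid.dy:.10g} "
            f"k_house={grid.k_house:.10g} k_street={grid.k_street:.10g}\n"
        )
        for row in grid.cell_class:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_schedule_file(path, grid: GridMap,
                       params: ModelParameters | None = None) -> ReleaseSchedule:
    """Parse a release-schedule file into a :class:`ReleaseSchedule`.

    Keys: ``kind`` (localized | homogeneous), ``period`` (days, default 1),
    ``start_day`` (default 0), and exactly one of ``multiple`` (of the
    female equilibrium) or ``amount`` (GM males per release event);
    ``cells_file`` optionally points to a 0/1 mask in the map dialect for
    localized kinds.
    """
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            entries[key.strip()] = value.strip()
    kind = entries.pop("kind", "homogeneous")
    period = int(entries.pop("period", "1"))
    start_day = float(entries.pop("start_day", "0"))
    multiple = entries.pop("multiple", None)
    amount = entries.pop("amount", None)
    cells_file = entries.pop("cells_file", None)
    if entries:
        raise ValueError(f"{path}: unknown schedule keys {sorted(entries)}")
    if (multiple is None) == (amount is None):
        raise ValueError(f"{path}: give exactly one of 'multiple' or 'amount'")
    cells = None
    if cells_file is not None:
        mask_path = Path(path).parent / cells_file
        cells = np.array(read_map_file(mask_path).cell_class, dtype=bool)
    if multiple is not None:
        return make_release_schedule(
            kind, grid, float(multiple), period=period, params=params,
            cells=cells, start_day=start_day)
    if kind == "homogeneous":
        mask = None
    else:
        from .maps import reference_release_mask
        mask = cells if cells is not None else reference_release_mask()
    return ReleaseSchedule(cells=mask, period=period,
                           amount_per_period=float(amount),
                           start_day=start_day)


def write_timeseries(totals: pd.DataFrame, path) -> None:
    """Write per-day totals as CSV with deterministic fixed formatting."""
    missing = [c for c in _TS_COLUMNS if c not in totals.columns]
    if missing:
        raise ValueError(f"trajectory lacks columns {missing}")
    totals.loc[:, list(_TS_COLUMNS)].to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n")


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)
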