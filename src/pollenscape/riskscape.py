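"""Majority-rule riskscape grids.

Per-tree severities are aggregated onto a regular metric grid: each cell
takes the most frequent severity class among the trees it contains (ties
broken toward the more severe class and flagged), which turns overlapping
point symbols into a readable exposure map.  Grids are exported as ESRI
ASCII grid (plain-text raster with georeferencing header), GeoJSON cell
polygons, or a PNG rendered with the conventional color coding: high = red,
moderate = yellow, low = green, not reported = gray, empty = transparent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .allergenicity import Severity
from .inventory import Inventory
from .tabulation import SeverityAssignment

logger = logging.getLogger(__name__)

__all__ = ["RiskGrid", "rasterize_majority", "grid_from_points", "export_grid",
           "read_grid_asc"]

#: raster cell codes; empty cells use the ASCII-grid NODATA value
CELL_CODES = {
    Severity.HIGH: 3,
    Severity.MODERATE: 2,
    Severity.LOW: 1,
    Severity.NOT_REPORTED: 0,
}
NODATA = -9999

#: conventional color coding (RGBA)
COLORS = {
    Severity.HIGH: (0.84, 0.11, 0.13, 1.0),        # red
    Severity.MODERATE: (1.0, 0.85, 0.1, 1.0),      # yellow
    Severity.LOW: (0.2, 0.63, 0.17, 1.0),          # green
    Severity.NOT_REPORTED: (0.6, 0.6, 0.6, 1.0),   # gray
}

_SEVERITY_DESC = (Severity.HIGH, Severity.MODERATE, Severity.LOW,
                  Severity.NOT_REPORTED)


@dataclass
class RiskGrid:
    """A rasterized riskscape.

    ``counts`` has shape (n_rows, n_cols, 4) indexed by Severity value;
    ``modal`` holds Severity values with -1 for empty cells; row 0 is the
    southernmost row (y = origin_y .. origin_y + cell_size).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    counts: np.ndarray
    modal: np.ndarray
    tie: np.ndarray
    crs: str = "projected"
    city: str = ""
    dataset: str = ""

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    @property
    def total_trees(self) -> int:
        return int(self.counts.sum())

    def class_counts(self) -> dict:
        return {
            sev: int(self.counts[:, :, int(sev)].sum()) for sev in _SEVERITY_DESC
        }

    def cell(self, col: int, row: int) -> dict:
        return {
            "modal": (None if self.modal[row, col] < 0
                      else Severity(int(self.modal[row, col]))),
            "tie": bool(self.tie[row, col]),
            "counts": {
                sev: int(self.counts[row, col, int(sev)]) for sev in _SEVERITY_DESC
            },
        }


def _modal_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority class per cell, ties toward the more severe class.

    Scanning severities in descending order and taking the first maximum
    implements the conservative tie-break; the tie flag marks cells where
    two or more classes share the maximum count.
    """
    total = counts.sum(axis=2)
    best = counts.max(axis=2)
    modal = np.full(total.shape, -1, dtype=np.int8)
    for sev in reversed(_SEVERITY_DESC):  # ascending severity: later wins
        modal = np.where(
            (total > 0) & (counts[:, :, int(sev)] == best), int(sev), modal
        )
    n_at_max = (counts == best[:, :, None]).sum(axis=2)
    tie = (total > 0) & (n_at_max > 1) & (best > 0)
    return modal, tie


def grid_from_points(
    x, y, severities, cell_size: float,
    origin: Optional[tuple] = None, crs: str = "projected",
) -> RiskGrid:
    """Bin classed points into a majority grid.

    Cells are half-open intervals [origin + j·c, origin + (j+1)·c); points
    exactly on the upper boundary fall into a final padded cell, never
    dropped.
    """
    if cell_size <= 0:
        raise ValueError(f"cell size must be positive, got {cell_size}")
    if crs == "geographic":
        raise ValueError(
            "points are in geographic coordinates; reproject the inventory "
            "to a metric system before gridding"
        )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sev = np.asarray(severities, dtype=np.int64)
    if not (len(x) == len(y) == len(sev)):
        raise ValueError("x, y and severities disagree in length")
    if len(x) == 0:
        raise ValueError("no points to rasterize")
    if origin is None:
        origin = (float(x.min()), float(y.min()))
    ox, oy = float(origin[0]), float(origin[1])
    if np.any(x < ox) or np.any(y < oy):
        raise ValueError("points lie below the declared grid origin")

    col = np.floor((x - ox) / cell_size).astype(np.int64)
    row = np.floor((y - oy) / cell_size).astype(np.int64)
    n_cols = int(col.max()) + 1
    n_rows = int(row.max()) + 1

    counts = np.zeros((n_rows, n_cols, 4), dtype=np.int64)
    np.add.at(counts, (row, col, sev), 1)
    modal, tie = _modal_from_counts(counts)
    return RiskGrid(
        origin_x=ox, origin_y=oy, cell_size=float(cell_size),
        counts=counts, modal=modal, tie=tie, crs=crs,
    )


def rasterize_majority(
    assignment: SeverityAssignment,
    inv: Inventory,
    cell_size: float = 100.0,
    include_not_reported: bool = True,
    origin: Optional[tuple] = None,
) -> RiskGrid:
    """Rasterize one inventory's severity assignment.

    *Not reported* trees are rasterized as a gray class by default so the
    map shares the severity table's denominator; pass
    ``include_not_reported=False`` to map classified trees only.
    """
    if len(assignment) != len(inv):
        raise ValueError("assignment does not match inventory size")
    x = inv.frame["x"].to_numpy(dtype=float)
    y = inv.frame["y"].to_numpy(dtype=float)
    sev = assignment.classes.astype(np.int64)
    if not include_not_reported:
        keep = sev != int(Severity.NOT_REPORTED)
        x, y, sev = x[keep], y[keep], sev[keep]
        if len(x) == 0:
            raise ValueError("no classified trees to rasterize")
    grid = grid_from_points(x, y, sev, cell_size, origin=origin, crs=inv.crs)
    grid.city = inv.city
    grid.dataset = assignment.dataset
    return grid


# ---------------------------------------------------------------------------
# export

_SUPPORTED = ("asc", "geojson", "png")


def export_grid(grid: RiskGrid, path, fmt: Optional[str] = None) -> str:
    """Write a grid to disk; format inferred from the extension.

    Supported: ``asc`` (ESRI ASCII grid, integer class codes, NODATA for
    empty cells), ``geojson`` (one polygon feature per non-empty cell with
    class, counts and tie flag), ``png`` (color-coded image, transparent
    where empty).
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt not in _SUPPORTED:
        raise ValueError(
            f"unsupported grid format {fmt!r}; supported: {', '.join(_SUPPORTED)}"
        )
    if fmt == "asc":
        _write_asc(grid, path)
    elif fmt == "geojson":
        _write_geojson(grid, path)
    else:
        _write_png(grid, path)
    return path


def _class_codes(grid: RiskGrid) -> np.ndarray:
    codes = np.full((grid.n_rows, grid.n_cols), NODATA, dtype=np.int64)
    mask = grid.modal >= 0
    codes[mask] = grid.modal[mask]
    return codes


def _write_asc(grid: RiskGrid, path: str) -> None:
    codes = _class_codes(grid)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        # ASCII grids are written north-to-south
        for r in range(grid.n_rows - 1, -1, -1):
            fh.write(" ".join(str(v) for v in codes[r]) + "\n")


def read_grid_asc(path) -> tuple[np.ndarray, dict]:
    """Read back an ASCII grid: (modal class codes, header dict).

    Rows are returned south-to-north to match :class:`RiskGrid` layout.
    """
    header: dict = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(v) for v in parts])
    arr = np.array(rows[::-1], dtype=np.int64)
    return arr, header


def _write_geojson(grid: RiskGrid, path: str) -> None:
    from shapely.geometry import box, mapping

    c = grid.cell_size
    feats = []
    for r in range(grid.n_rows):
        for j in range(grid.n_cols):
            if grid.modal[r, j] < 0:
                continue
            cell = grid.cell(j, r)
            geom = box(
                grid.origin_x + j * c, grid.origin_y + r * c,
                grid.origin_x + (j + 1) * c, grid.origin_y + (r + 1) * c,
            )
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {
                        "severity": cell["modal"].label,
                        "tie": cell["tie"],
                        **{
                            f"n_{sev.label}": cell["counts"][sev]
                            for sev in _SEVERITY_DESC
                        },
                    },
                }
            )
    gj = {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {
            "city": grid.city, "dataset": grid.dataset,
            "cell_size": grid.cell_size, "crs": grid.crs,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(gj, fh)


def _write_png(grid: RiskGrid, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgba = np.zeros((grid.n_rows, grid.n_cols, 4), dtype=float)
    for sev, color in COLORS.items():
        mask = grid.modal == int(sev)
        rgba[mask] = color
    extent = (
        grid.origin_x, grid.origin_x + grid.n_cols * grid.cell_size,
        grid.origin_y, grid.origin_y + grid.n_rows * grid.cell_size,
    )
    fig, ax = plt.subplots(figsize=(6, 6 * grid.n_rows / max(grid.n_cols, 1)))
    ax.imshow(rgba, origin="lower", extent=extent, interpolation="nearest")
    title = " / ".join(p for p in (grid.city, grid.dataset) if p)
    if title:
        ax.set_title(title)
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
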