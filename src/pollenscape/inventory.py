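"""Reading, validating and summarizing municipal point-tree inventories.

An inventory is a city's census of public trees: one row per tree with a
botanical name and a coordinate pair.  Rows are cleaned (blank or
unparseable names, out-of-range coordinates, excluded status values are
dropped with per-reason counts), names are normalized through the taxonomy
module, and geographic coordinates are projected to the local UTM zone so
the riskscape grid can work in metres.

Internally an :class:`Inventory` is backed by a pandas DataFrame with one
row per tree and precomputed join keys; :class:`TreeRecord` objects are
materialized on demand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import _proj
from .taxonomy import SynonymTable, TaxonName, TaxonParseError, normalize_name

logger = logging.getLogger(__name__)

__all__ = ["TreeRecord", "LoadReport", "Inventory", "read_inventory", "summarize"]

#: DataFrame columns every Inventory frame carries
_COLUMNS = [
    "tree_id", "raw_name", "genus", "epithet", "hybrid", "cultivar",
    "rank", "species_key", "genus_key", "cultivar_key", "x", "y",
]


@dataclass(frozen=True)
class TreeRecord:
    """One tree: id, parsed taxon, position in the inventory's CRS."""

    tree_id: str
    taxon: TaxonName
    x: float
    y: float
    city: str


@dataclass
class LoadReport:
    """Per-reason accounting of rows read vs records kept."""

    rows_read: int = 0
    dropped_blank_name: int = 0
    dropped_unparseable: int = 0
    dropped_bad_coords: int = 0
    dropped_status: int = 0
    infraspecific_collapsed: int = 0
    duplicate_ids: int = 0

    @property
    def dropped_total(self) -> int:
        return (
            self.dropped_blank_name
            + self.dropped_unparseable
            + self.dropped_bad_coords
            + self.dropped_status
        )

    def as_dict(self) -> dict:
        return dict(vars(self), dropped_total=self.dropped_total)


class Inventory:
    """A city's point-tree census in one coordinate system.

    ``crs`` is ``"projected"`` (metres; ready for gridding, possibly after
    UTM projection at load) or ``"geographic"`` (degrees; the riskscape
    module will refuse it).
    """

    def __init__(
        self,
        city: str,
        frame: pd.DataFrame,
        crs: str = "projected",
        report: Optional[LoadReport] = None,
        region: Optional[str] = None,
    ):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"inventory frame missing columns {missing}")
        if crs not in ("projected", "geographic"):
            raise ValueError(f"unknown crs declaration {crs!r}")
        self.city = city
        self.frame = frame.reset_index(drop=True)
        self.crs = crs
        self.report = report or LoadReport(rows_read=len(frame))
        self.region = region

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[TreeRecord]:
        return iter(self.records())

    def records(self) -> list[TreeRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            taxon = TaxonName(
                raw=row.raw_name,
                genus=row.genus,
                epithet=row.epithet if isinstance(row.epithet, str) else None,
                hybrid=bool(row.hybrid),
                cultivar=row.cultivar if isinstance(row.cultivar, str) else None,
            )
            out.append(
                TreeRecord(str(row.tree_id), taxon, float(row.x), float(row.y), self.city)
            )
        return out

    @classmethod
    def from_taxa(
        cls,
        city: str,
        taxa: list[TaxonName],
        x,
        y,
        ids=None,
        crs: str = "projected",
        region: Optional[str] = None,
    ) -> "Inventory":
        """Build an inventory from parsed names and coordinate arrays."""
        n = len(taxa)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != n or len(y) != n:
            raise ValueError("taxa and coordinate arrays disagree in length")
        if ids is None:
            ids = [f"t{i:06d}" for i in range(n)]
        frame = pd.DataFrame(
            {
                "tree_id": [str(i) for i in ids],
                "raw_name": [t.raw for t in taxa],
                "genus": [t.genus for t in taxa],
                "epithet": [t.epithet for t in taxa],
                "hybrid": [t.hybrid for t in taxa],
                "cultivar": [t.cultivar for t in taxa],
                "rank": [t.rank for t in taxa],
                "species_key": [t.key("species") if t.epithet else None for t in taxa],
                "genus_key": [t.genus for t in taxa],
                "cultivar_key": [
                    t.key("cultivar") if t.cultivar else None for t in taxa
                ],
                "x": x,
                "y": y,
            }
        )
        return cls(city, frame, crs=crs, report=LoadReport(rows_read=n), region=region)


def _rows_from_geojson(path, column_map):
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    species_col = column_map["species"]
    id_col = column_map.get("id")
    rows = []
    for i, feat in enumerate(feats):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        if geom.get("type") != "Point":
            continue
        lon, lat = geom["coordinates"][:2]
        rows.append(
            {
                "tree_id": props.get(id_col, i) if id_col else i,
                "species": props.get(species_col),
                "x": lon,
                "y": lat,
                "status": props.get(column_map.get("status", ""), None),
            }
        )
    return pd.DataFrame(rows)


def read_inventory(
    path,
    column_map: dict,
    crs: str,
    city: str = "",
    sep: str = ",",
    synonyms: Optional[SynonymTable] = None,
    strict: bool = False,
    status_exclude: tuple = (),
    region: Optional[str] = None,
) -> Inventory:
    """Read a delimited-text or GeoJSON tree inventory.

    ``column_map`` names at least the ``species`` column and, for delimited
    files, the ``x``/``y`` coordinate columns (an ``id`` and ``status``
    column are optional).  ``crs`` declares the input coordinates:
    ``"projected"`` (metres) or ``"geographic"`` (lon/lat degrees, projected
    to the local UTM zone on load).  GeoJSON input is geographic by
    convention.

    Cleaning drops rows with blank or unparseable names, out-of-range or
    non-finite coordinates, and excluded status values; counts land in the
    load report.  In strict mode any dropped row aborts the load.  Zero
    surviving rows is always fatal.
    """
    path = str(path)
    if path.lower().endswith((".geojson", ".json")):
        raw = _rows_from_geojson(path, column_map)
        crs = "geographic"
        sp_col, x_col, y_col, status_col = "species", "x", "y", "status"
    else:
        raw = pd.read_csv(path, sep=sep, dtype=str)
        raw.columns = [c.strip() for c in raw.columns]
        sp_col = column_map["species"]
        x_col = column_map["x"]
        y_col = column_map["y"]
        status_col = column_map.get("status")
        for col in (sp_col, x_col, y_col):
            if col not in raw.columns:
                raise ValueError(f"inventory {path}: missing declared column {col!r}")
        id_col = column_map.get("id")
        raw = raw.rename(columns={sp_col: "species"})
        sp_col = "species"
        raw["tree_id"] = (
            raw[id_col].astype(str) if id_col and id_col in raw.columns
            else [str(i) for i in range(len(raw))]
        )

    report = LoadReport(rows_read=len(raw))

    def _bail(reason: str, detail: str):
        if strict:
            raise ValueError(f"inventory {path}: {reason}: {detail}")

    if status_col and status_col in raw.columns and status_exclude:
        excl = {str(s).casefold() for s in status_exclude}
        mask = raw[status_col].astype(str).str.casefold().isin(excl)
        report.dropped_status = int(mask.sum())
        if report.dropped_status:
            _bail("excluded status values present", f"{report.dropped_status} rows")
        raw = raw[~mask]

    # parse each distinct raw name once, then broadcast
    taxa_cache: dict[str, Optional[TaxonName]] = {}
    for s in raw[sp_col].astype("object").unique():
        text = "" if s is None or (isinstance(s, float) and np.isnan(s)) else str(s)
        if not text.strip():
            taxa_cache[str(s)] = None
            continue
        try:
            taxa_cache[str(s)] = normalize_name(text, synonyms)
        except TaxonParseError as err:
            logger.warning("dropping unparseable name %r (%s)", text, err)
            taxa_cache[str(s)] = None

    taxa, keep_idx = [], []
    xs = pd.to_numeric(raw[x_col] if x_col in raw.columns else raw["x"], errors="coerce")
    ys = pd.to_numeric(raw[y_col] if y_col in raw.columns else raw["y"], errors="coerce")
    for pos, (s, xv, yv) in enumerate(zip(raw[sp_col].astype("object"), xs, ys)):
        text = "" if s is None or (isinstance(s, float) and np.isnan(s)) else str(s)
        if not text.strip():
            report.dropped_blank_name += 1
            _bail("blank species name", f"row {pos}")
            continue
        taxon = taxa_cache.get(str(s))
        if taxon is None:
            report.dropped_unparseable += 1
            _bail("unparseable species name", repr(text))
            continue
        if not (np.isfinite(xv) and np.isfinite(yv)):
            report.dropped_bad_coords += 1
            _bail("non-finite coordinates", f"row {pos}")
            continue
        if crs == "geographic" and not (-180 <= xv <= 180 and -90 <= yv <= 90):
            report.dropped_bad_coords += 1
            _bail("geographic coordinates out of range", f"({xv}, {yv})")
            continue
        if taxon.infraspecific_collapsed:
            report.infraspecific_collapsed += 1
        taxa.append(taxon)
        keep_idx.append(pos)

    if not taxa:
        raise ValueError(f"inventory {path}: zero surviving rows after cleaning")

    kept = raw.iloc[keep_idx]
    ids = kept["tree_id"].tolist() if "tree_id" in kept.columns else None
    x_arr = xs.iloc[keep_idx].to_numpy(dtype=float)
    y_arr = ys.iloc[keep_idx].to_numpy(dtype=float)

    out_crs = crs
    if crs == "geographic":
        easting, northing, zone = _proj.utm_forward(y_arr, x_arr)
        logger.info("projected %s to UTM zone %d", city or path, zone)
        x_arr, y_arr = np.asarray(easting), np.asarray(northing)
        out_crs = "projected"

    inv = Inventory.from_taxa(
        city or path, taxa, x_arr, y_arr, ids=ids, crs=out_crs, region=region
    )
    if ids is not None:
        dup = len(ids) - len(set(ids))
        if dup:
            report.duplicate_ids = dup
            logger.warning("%s: %d duplicate tree ids (records kept)", city, dup)
    inv.report = report
    if report.infraspecific_collapsed:
        logger.info(
            "%s: %d infraspecific names collapsed to species rank",
            city, report.infraspecific_collapsed,
        )
    logger.info(
        "%s: read %d rows, kept %d (dropped %d)",
        city or path, report.rows_read, len(inv), report.dropped_total,
    )
    return inv


def summarize(inv: Inventory) -> dict:
    """Counts of trees, species and genera.

    Species are counted at species rank: a genus-only record ("Acer sp.")
    counts toward trees and genera but not species.
    """
    species = inv.frame["species_key"].dropna().nunique()
    genera = inv.frame["genus_key"].nunique()
    return {"trees": len(inv), "species": int(species), "genera": int(genera)}
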