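"""End-to-end run orchestration.

A single YAML config describes a run: the city inventories (path, column
map, CRS), the allergenicity datasets (entries file + scheme id or inline
scheme), grid settings, and the output directory.  ``run_full_analysis``
executes every stage — load, assign, tabulate, concordance, diversity,
riskscape grids — writes all outputs as delimited text / GeoJSON / ASCII
grids, and records a manifest (input checksums, config echo, seed, drop
counts) so a run is auditable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .allergenicity import (AllergenDataset, builtin_schemes, check_region,
                            load_dataset, scheme_from_config)
from .diversity import diversity_summary, summaries_frame
from .inventory import Inventory, read_inventory
from .riskscape import RiskGrid, export_grid, rasterize_majority
from .tabulation import (ConcordanceReport, SeverityTable, assign_severity,
                         high_range, severity_percentages, taxon_class_matrix)
from .taxonomy import SynonymTable, TaxonName

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "load_config", "run_full_analysis"]


@dataclass
class RunResult:
    """Everything one run produced, in memory."""

    severity_table: SeverityTable
    concordance: Optional[ConcordanceReport]
    diversity: list = field(default_factory=list)
    grids: dict = field(default_factory=dict)  # (city, dataset) -> RiskGrid
    high_ranges: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {err}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _load_inventories(cfg: dict, strict: bool,
                      synonyms: Optional[SynonymTable]) -> list[Inventory]:
    out = []
    for item in cfg.get("inventories", []):
        out.append(
            read_inventory(
                item["path"],
                column_map=item.get("columns", {"species": "species",
                                                "x": "x", "y": "y"}),
                crs=item.get("crs", "projected"),
                city=item.get("city", Path(item["path"]).stem),
                sep=item.get("sep", ","),
                synonyms=synonyms,
                strict=strict,
                status_exclude=tuple(item.get("status_exclude", ())),
                region=item.get("region"),
            )
        )
    if not out:
        raise ValueError("config lists no inventories")
    return out


def _load_datasets(cfg: dict,
                   synonyms: Optional[SynonymTable]) -> list[AllergenDataset]:
    out = []
    for item in cfg.get("datasets", []):
        scheme = item.get("scheme")
        if isinstance(scheme, dict):
            scheme = scheme_from_config(scheme)
        elif isinstance(scheme, str):
            scheme = builtin_schemes()[scheme]
        else:
            raise ValueError(
                f"dataset {item.get('name')!r}: scheme must be a builtin id "
                "or an inline mapping"
            )
        out.append(
            load_dataset(
                item["entries"],
                scheme=scheme,
                name=item.get("name"),
                synonyms=synonyms,
                sep=item.get("sep", ","),
                region=item.get("region"),
            )
        )
    if not out:
        raise ValueError("config lists no datasets")
    return out


def run_full_analysis(
    config: dict | str | Path,
    out_dir: Optional[str | Path] = None,
    seed: int = 0,
    strict: bool = False,
    write: bool = True,
) -> RunResult:
    """Run every pipeline stage from a config mapping or YAML path.

    Outputs (when ``write``): severity_table.csv, high_ranges.csv,
    concordance_matrix.csv + concordance_agreement.csv, diversity.csv,
    per-(city, dataset) riskscape grids (.asc + .geojson), and
    manifest.json.  Any stage failure aborts with the stage name.
    """
    config_path = None
    if not isinstance(config, dict):
        config_path = str(config)
        config = load_config(config)
    out_dir = Path(out_dir or config.get("output", "pollenscape_out"))

    input_files = [config_path] if config_path else []

    try:
        synonyms = None
        if config.get("synonyms"):
            synonyms = SynonymTable.from_file(config["synonyms"])
            input_files.append(config["synonyms"])
        inventories = _load_inventories(config, strict, synonyms)
        input_files += [i["path"] for i in config["inventories"]]
    except Exception as err:
        raise PipelineError("load-inventories", err) from err

    try:
        datasets = _load_datasets(config, synonyms)
        input_files += [d["entries"] for d in config["datasets"]]
    except Exception as err:
        raise PipelineError("load-datasets", err) from err

    grid_cfg = config.get("grid", {})
    cell_size = float(grid_cfg.get("cell_size", 100.0))
    include_nr = bool(grid_cfg.get("include_not_reported", True))
    grid_formats = tuple(grid_cfg.get("formats", ("asc", "geojson")))

    table = SeverityTable()
    grids: dict = {}
    try:
        for inv in inventories:
            for ds in datasets:
                check_region(ds, inv.region)
                assignment = assign_severity(inv, ds)
                table.append(severity_percentages(assignment))
                grids[(inv.city, ds.name)] = rasterize_majority(
                    assignment, inv, cell_size=cell_size,
                    include_not_reported=include_nr,
                )
    except Exception as err:
        raise PipelineError("tabulate", err) from err

    try:
        ranges = [high_range(table, inv.city) for inv in inventories]
    except Exception as err:
        raise PipelineError("high-range", err) from err

    concordance = None
    try:
        if len(datasets) >= 2:
            taxa: dict[str, TaxonName] = {}
            for inv in inventories:
                for row in inv.frame[
                    ["genus", "epithet", "hybrid", "cultivar"]
                ].drop_duplicates().itertuples(index=False):
                    t = TaxonName(
                        raw="", genus=row.genus,
                        epithet=row.epithet if isinstance(row.epithet, str) else None,
                        hybrid=bool(row.hybrid),
                        cultivar=row.cultivar if isinstance(row.cultivar, str) else None,
                    )
                    taxa[t.key(t.rank)] = t
            concordance = taxon_class_matrix(
                datasets, [taxa[k] for k in sorted(taxa)]
            )
    except Exception as err:
        raise PipelineError("concordance", err) from err

    try:
        div = []
        for inv in inventories:
            for level in ("species", "genus"):
                div.append(diversity_summary(inv, level))
    except Exception as err:
        raise PipelineError("diversity", err) from err

    manifest = {
        "package": "pollenscape",
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "inputs": {
            str(p): _sha256(p) for p in input_files if p and Path(p).exists()
        },
        "load_reports": {inv.city: inv.report.as_dict() for inv in inventories},
        "diversity_note": (
            "species-level profiles exclude genus-only records; genus-level "
            "profiles count every record"
        ),
        "rounding": "display percents rounded half-away-from-zero to integers",
    }

    result = RunResult(
        severity_table=table, concordance=concordance, diversity=div,
        grids=grids, high_ranges=ranges, manifest=manifest,
    )
    if write:
        _write_outputs(result, out_dir, grid_formats)
    return result


def _write_outputs(result: RunResult, out_dir: Path, grid_formats) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.severity_table.to_frame().to_csv(
        out_dir / "severity_table.csv", index=False
    )
    pd.DataFrame(result.high_ranges).to_csv(
        out_dir / "high_ranges.csv", index=False
    )
    if result.concordance is not None:
        result.concordance.to_frame().to_csv(
            out_dir / "concordance_matrix.csv", index=False
        )
        result.concordance.agreement_frame().to_csv(
            out_dir / "concordance_agreement.csv", index=False
        )
    summaries_frame(result.diversity).to_csv(
        out_dir / "diversity.csv", index=False
    )
    for (city, ds_name), grid in sorted(result.grids.items()):
        stem = f"riskscape_{_slug(city)}_{_slug(ds_name)}"
        for fmt in grid_formats:
            export_grid(grid, out_dir / f"{stem}.{fmt}")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("run outputs written to %s", out_dir)


def _slug(s: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in s.strip().lower())
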