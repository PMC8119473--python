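"""Allergenicity data sources and harmonization to a common severity scale.

Published tree-pollen allergenicity resources (AAAAI, AIA, ARL, Citree, EAN,
INSPQ, OPALS, Pollen.com, RNSA) disagree in vocabulary (verbal classes, star
ratings, a 1-10 numeric scale) and in taxonomic granularity (genus-level,
species-level, or mixed with cultivars).  Here every source is modelled as an
:class:`AllergenDataset` — taxon entries plus a :class:`ClassScheme` that
maps its native labels onto the common four-valued severity scale — and a
taxon's severity is resolved with rank fallback: cultivar entry, then
species, then genus; no entry at any rank means *not reported*.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd
import yaml

from .taxonomy import SynonymTable, TaxonName, normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "Severity",
    "ClassScheme",
    "AllergenDataset",
    "harmonize_label",
    "lookup_severity",
    "load_dataset",
    "builtin_schemes",
]


class Severity(enum.IntEnum):
    """Common severity scale; integer order is the severity order.

    ``high > moderate > low > not_reported`` — the order used for
    conservative tie-breaking in tabulation and rasterization.
    """

    NOT_REPORTED = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return _SEVERITY_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        try:
            return _SEVERITY_FROM_LABEL[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown severity label {label!r}") from None


_SEVERITY_LABELS = {
    Severity.HIGH: "high",
    Severity.MODERATE: "moderate",
    Severity.LOW: "low",
    Severity.NOT_REPORTED: "not_reported",
}
_SEVERITY_FROM_LABEL = {v: k for k, v in _SEVERITY_LABELS.items()}

#: severities a scheme may map onto (never not_reported)
CLASSIFIED = (Severity.HIGH, Severity.MODERATE, Severity.LOW)


def _norm_label(label) -> str:
    return " ".join(str(label).split()).casefold()


@dataclass(frozen=True)
class ClassScheme:
    """How one data source's native labels map to the common scale.

    ``kind`` is "categorical" (verbal classes, star ratings) or "numeric"
    (an ordered score with breakpoints, e.g. OPALS 1-10 with 1-3 low,
    4-6 moderate, 7-10 high).
    """

    scheme_id: str
    kind: str
    #: categorical: normalized label -> Severity
    labels: dict = field(default_factory=dict)
    #: numeric: severity -> (lo, hi) inclusive integer breakpoints
    breakpoints: dict = field(default_factory=dict)
    region: Optional[str] = None
    description: str = ""

    def __post_init__(self):
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "numeric" and not self.breakpoints:
            raise ValueError(f"numeric scheme {self.scheme_id} needs breakpoints")
        if self.kind == "categorical" and not self.labels:
            raise ValueError(f"categorical scheme {self.scheme_id} needs labels")

    @property
    def numeric_range(self) -> tuple[int, int]:
        los = [lo for lo, _ in self.breakpoints.values()]
        his = [hi for _, hi in self.breakpoints.values()]
        return min(los), max(his)


def harmonize_label(label, scheme: ClassScheme) -> Severity:
    """Map one original label to the common severity scale.

    Always returns one of high/moderate/low; an undeclared or out-of-range
    label raises ``ValueError``.
    """
    if scheme.kind == "numeric":
        try:
            score = int(str(label).strip())
        except ValueError:
            raise ValueError(
                f"scheme {scheme.scheme_id}: label {label!r} is not an integer score"
            ) from None
        lo, hi = scheme.numeric_range
        if not lo <= score <= hi:
            raise ValueError(
                f"scheme {scheme.scheme_id}: score {score} outside {lo}-{hi}"
            )
        for sev, (blo, bhi) in scheme.breakpoints.items():
            if blo <= score <= bhi:
                return sev
        raise ValueError(
            f"scheme {scheme.scheme_id}: score {score} not covered by breakpoints"
        )
    key = _norm_label(label)
    try:
        return scheme.labels[key]
    except KeyError:
        raise ValueError(
            f"scheme {scheme.scheme_id}: label {label!r} not declared"
        ) from None


@dataclass
class AllergenDataset:
    """One allergenicity source: harmonized entries keyed by taxon.

    Entries are keyed at cultivar, species or genus level; keys are stored
    hybrid-marker-free, so *Platanus ×acerifolia* and *Platanus acerifolia*
    resolve identically.  ``granularity`` is inferred from entry ranks:
    "genus-level", "species-level" or "mixed".
    """

    name: str
    scheme: ClassScheme
    entries: dict = field(default_factory=dict)  # key -> Severity
    original_labels: dict = field(default_factory=dict)  # key -> raw label
    entry_levels: dict = field(default_factory=dict)  # key -> genus|species|cultivar
    region: Optional[str] = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def granularity(self) -> str:
        levels = set(self.entry_levels.values())
        if levels <= {"genus"}:
            return "genus-level"
        if levels <= {"species"}:
            return "species-level"
        return "mixed"

    def add_entry(self, taxon: TaxonName, label) -> None:
        sev = harmonize_label(label, self.scheme)
        level = taxon.rank
        key = taxon.key(level)
        if key in self.entries and self.entries[key] != sev:
            raise ValueError(
                f"dataset {self.name}: conflicting entries for {key!r}: "
                f"{self.original_labels[key]!r} vs {label!r}"
            )
        self.entries[key] = sev
        self.original_labels[key] = str(label)
        self.entry_levels[key] = level

    def lookup(self, taxon: TaxonName) -> tuple[Severity, str]:
        return lookup_severity(self, taxon)


def lookup_severity(
    dataset: AllergenDataset, taxon: TaxonName
) -> tuple[Severity, str]:
    """Resolve a taxon's severity with rank fallback.

    Precedence: cultivar key, then species key, then genus key; the first
    hit wins.  Total: with no hit at any level the result is
    ``(NOT_REPORTED, "none")``.  The second element records the matched
    level for provenance/audit.
    """
    if taxon.cultivar is not None:
        hit = dataset.entries.get(taxon.key("cultivar"))
        if hit is not None:
            return hit, "cultivar"
    if taxon.epithet:
        hit = dataset.entries.get(taxon.key("species"))
        if hit is not None:
            return hit, "species"
    hit = dataset.entries.get(taxon.key("genus"))
    if hit is not None:
        return hit, "genus"
    return Severity.NOT_REPORTED, "none"


def load_dataset(
    entries_file,
    scheme: ClassScheme | str,
    name: Optional[str] = None,
    synonyms: Optional[SynonymTable] = None,
    sep: str = ",",
    region: Optional[str] = None,
) -> AllergenDataset:
    """Load an allergenicity dataset from a delimited entries file.

    The file needs columns ``taxon`` and ``label`` (extra columns such as
    ``notes`` are ignored).  ``scheme`` may be a :class:`ClassScheme` or the
    id of a built-in one.  Duplicate rows with conflicting labels are an
    error; an empty file yields a valid dataset where every lookup is
    *not reported*.
    """
    if isinstance(scheme, str):
        scheme = builtin_schemes()[scheme]
    ds = AllergenDataset(
        name=name or scheme.scheme_id,
        scheme=scheme,
        region=region if region is not None else scheme.region,
    )
    frame = pd.read_csv(entries_file, sep=sep, dtype=str, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("taxon", "label"):
        if col not in frame.columns:
            raise ValueError(f"entries file {entries_file}: missing column {col!r}")
    for _, row in frame.iterrows():
        taxon = normalize_name(row["taxon"], synonyms)
        ds.add_entry(taxon, row["label"])
    logger.info(
        "loaded dataset %s: %d entries, granularity %s",
        ds.name, len(ds), ds.granularity,
    )
    return ds


def check_region(dataset: AllergenDataset, city_region: Optional[str]) -> bool:
    """Warn when a dataset is applied outside its declared region.

    Returns True when the combination is unflagged (either side undeclared
    or regions match case-insensitively).
    """
    if not dataset.region or not city_region:
        return True
    if dataset.region.strip().casefold() == city_region.strip().casefold():
        return True
    logger.warning(
        "dataset %s declared for region %r applied to city in region %r; "
        "allergenicity assessments may not transfer across regions",
        dataset.name, dataset.region, city_region,
    )
    return False


_SCHEME_CACHE: Optional[dict] = None


def _parse_scheme(sid: str, cfg: dict) -> ClassScheme:
    kind = cfg.get("kind", "categorical")
    labels: dict = {}
    breakpoints: dict = {}
    if kind == "numeric":
        for sev_label, pair in cfg["breakpoints"].items():
            breakpoints[Severity.from_label(sev_label)] = (int(pair[0]), int(pair[1]))
    else:
        for sev_label, lab_list in cfg["labels"].items():
            sev = Severity.from_label(sev_label)
            if isinstance(lab_list, str):
                lab_list = [lab_list]
            for lab in lab_list:
                key = _norm_label(lab)
                if key in labels and labels[key] != sev:
                    raise ValueError(
                        f"scheme {sid}: label {lab!r} mapped to two severities"
                    )
                labels[key] = sev
    return ClassScheme(
        scheme_id=sid,
        kind=kind,
        labels=labels,
        breakpoints=breakpoints,
        region=cfg.get("region"),
        description=cfg.get("description", ""),
    )


def scheme_from_config(cfg: dict) -> ClassScheme:
    """Build a scheme from a config mapping (as in the pipeline YAML)."""
    sid = cfg.get("id") or cfg.get("scheme_id")
    if not sid:
        raise ValueError("scheme config needs an 'id'")
    return _parse_scheme(sid, cfg)


def builtin_schemes() -> dict[str, ClassScheme]:
    """The nine published classification schemes, by id.

    AAAAI, AIA, ARL, Citree, EAN, INSPQ, OPALS, Pollen.com and RNSA, each
    with its native labels and their mapping onto high/moderate/low.
    """
    global _SCHEME_CACHE
    if _SCHEME_CACHE is None:
        text = (
            resources.files("pollenscape.data").joinpath("schemes.yaml").read_text(
                encoding="utf-8"
            )
        )
        raw = yaml.safe_load(text)
        _SCHEME_CACHE = {sid: _parse_scheme(sid, cfg) for sid, cfg in raw.items()}
    return dict(_SCHEME_CACHE)
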