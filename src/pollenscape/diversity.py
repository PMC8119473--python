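"""Taxonomic diversity of an urban canopy.

Relative abundances at genus or species level, the Shannon index
H = −Σ p_i ln p_i (natural log), the effective number of species e^H (the
Hill number of order 1 — the richness of an equally-abundant community with
the same H, a "true diversity" directly comparable across cities), and the
cumulative-coverage count (how many top-ranked taxa account for a given
share of all trees — the dominance statistic behind "14 genera cover 90%
of the canopy").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inventory import Inventory

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceProfile",
    "DiversitySummary",
    "relative_abundance",
    "shannon_index",
    "effective_species",
    "cumulative_coverage_count",
    "diversity_summary",
]


@dataclass
class AbundanceProfile:
    """Taxon counts and proportions at one taxonomic level."""

    level: str  # "genus" | "species"
    counts: dict  # taxon key -> int count
    excluded_records: int = 0  # genus-only records left out of a species profile

    def __post_init__(self):
        if not self.counts:
            raise ValueError("empty abundance profile")
        bad = {t: c for t, c in self.counts.items() if c <= 0 or int(c) != c}
        if bad:
            raise ValueError(f"non-positive or non-integer counts: {bad}")
        self.counts = {t: int(c) for t, c in self.counts.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict:
        n = self.total
        return {t: c / n for t, c in self.counts.items()}

    @property
    def richness(self) -> int:
        return len(self.counts)

    def p(self) -> np.ndarray:
        n = self.total
        return np.array(list(self.counts.values()), dtype=float) / n


@dataclass
class DiversitySummary:
    """H, e^H, richness and coverage counts for one inventory × level."""

    city: str
    level: str
    trees: int
    richness: int
    shannon: float
    effective_species: float
    coverage: dict = field(default_factory=dict)  # theta -> count
    excluded_records: int = 0

    def as_dict(self) -> dict:
        d = {
            "city": self.city,
            "level": self.level,
            "trees": self.trees,
            "richness": self.richness,
            "shannon": self.shannon,
            "effective_species": self.effective_species,
            "excluded_records": self.excluded_records,
        }
        for theta, k in sorted(self.coverage.items()):
            d[f"coverage_{int(round(theta * 100))}"] = k
        return d


def relative_abundance(inv: Inventory, level: str) -> AbundanceProfile:
    """Taxon abundance profile of an inventory at genus or species level.

    At species level, genus-only records (e.g. "Acer sp.") carry no species
    identity and are excluded (and counted); at genus level every record
    counts.
    """
    if len(inv) == 0:
        raise ValueError("empty inventory")
    if level == "genus":
        counts = inv.frame["genus_key"].value_counts()
        excluded = 0
    elif level == "species":
        keys = inv.frame["species_key"]
        excluded = int(keys.isna().sum())
        counts = keys.dropna().value_counts()
        if excluded:
            logger.info(
                "%s: %d genus-only records excluded from the species profile",
                inv.city, excluded,
            )
        if counts.empty:
            raise ValueError("no species-rank records in inventory")
    else:
        raise ValueError(f"unknown level {level!r}")
    return AbundanceProfile(
        level=level, counts=counts.to_dict(), excluded_records=excluded
    )


def shannon_index(profile: AbundanceProfile) -> float:
    """Shannon diversity H = −Σ p_i ln p_i in nats; 0 for a single taxon."""
    p = profile.p()
    return float(-np.sum(p * np.log(p)))


def effective_species(h: float) -> float:
    """Effective number of species e^H (Hill number of order 1)."""
    if h < 0:
        raise ValueError(f"Shannon index must be non-negative, got {h}")
    return math.exp(h)


def cumulative_coverage_count(profile: AbundanceProfile, theta: float) -> int:
    """Minimal number of top-abundance taxa whose cumulative share ≥ theta.

    Taxa are ranked by descending abundance; ties broken lexicographically
    by taxon key for determinism.
    """
    if not 0 < theta <= 1:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    items = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = profile.total
    acc = 0
    for k, (_, c) in enumerate(items, start=1):
        acc += c
        # compare in integer arithmetic: acc/total >= theta
        if acc >= theta * total:
            return k
    return len(items)


def diversity_summary(
    inv: Inventory, level: str, thetas: tuple = (0.9,)
) -> DiversitySummary:
    """One-stop diversity summary for an inventory at one level."""
    profile = relative_abundance(inv, level)
    h = shannon_index(profile)
    return DiversitySummary(
        city=inv.city,
        level=level,
        trees=len(inv),
        richness=profile.richness,
        shannon=h,
        effective_species=effective_species(h),
        coverage={t: cumulative_coverage_count(profile, t) for t in thetas},
        excluded_records=profile.excluded_records,
    )


def summaries_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
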