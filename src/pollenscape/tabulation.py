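"""Per-tree severity assignment, city × dataset severity tables, and
cross-dataset concordance.

This is the heart of the riskscape comparison: every tree in a city's
inventory is assigned a severity under each allergenicity dataset (rank
fallback, *not reported* when absent), the per-city percentages are
tabulated with the *not reported* trees kept in the denominator, and the
spread of the "percent highly allergenic" figure across datasets — the
high-severity range — quantifies how much the choice of dataset alone
changes the apparent risk.

Exact percentages are kept as :class:`fractions.Fraction` so that row sums
and between-dataset differences are exact; display percentages are rounded
half-away-from-zero to integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .allergenicity import AllergenDataset, Severity, lookup_severity
from .inventory import Inventory
from .taxonomy import TaxonName

logger = logging.getLogger(__name__)

__all__ = [
    "SeverityAssignment",
    "SeverityRow",
    "SeverityTable",
    "ConcordanceReport",
    "assign_severity",
    "severity_percentages",
    "flag_row",
    "high_range",
    "taxon_class_matrix",
]

_SEV_ORDER = (Severity.HIGH, Severity.MODERATE, Severity.LOW, Severity.NOT_REPORTED)


def _round_half_away(frac: Fraction) -> int:
    """Round a non-negative exact percentage half-away-from-zero."""
    return int((frac * 100 * 2 + 1) // 2)


@dataclass
class SeverityAssignment:
    """Per-tree severities of one inventory under one dataset."""

    city: str
    dataset: str
    classes: np.ndarray  # int8 array of Severity values, one per tree
    provenance: np.ndarray  # matched level per tree: cultivar|species|genus|none

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.int8)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if len(self.classes) != len(self.provenance):
            raise ValueError("classes/provenance length mismatch")

    def __len__(self) -> int:
        return len(self.classes)

    def counts(self) -> dict:
        vals, cnts = np.unique(self.classes, return_counts=True)
        out = {sev: 0 for sev in _SEV_ORDER}
        for v, c in zip(vals, cnts):
            out[Severity(int(v))] = int(c)
        return out


def assign_severity(inv: Inventory, ds: AllergenDataset) -> SeverityAssignment:
    """Assign each tree its severity under one dataset.

    Lookup is total (rank fallback, else *not reported*), so every tree gets
    exactly one class; resolution is done once per distinct taxon and
    broadcast over the inventory.
    """
    frame = inv.frame
    # distinct taxa by their most specific key triple
    key_cols = frame[["cultivar_key", "species_key", "genus_key", "hybrid"]]
    uniq = key_cols.drop_duplicates()
    sev_map: dict[tuple, tuple[int, str]] = {}
    for row in uniq.itertuples(index=False):
        genus, _, epithet = (
            (row.species_key.partition(" ")) if isinstance(row.species_key, str)
            else (row.genus_key, "", None)
        )
        cultivar = None
        if isinstance(row.cultivar_key, str):
            cultivar = row.cultivar_key.rpartition("|")[2]
        taxon = TaxonName(
            raw="", genus=genus, epithet=epithet or None,
            hybrid=bool(row.hybrid), cultivar=cultivar,
        )
        sev, level = lookup_severity(ds, taxon)
        sev_map[
            (row.cultivar_key, row.species_key, row.genus_key, row.hybrid)
        ] = (int(sev), level)

    keys = list(
        zip(frame["cultivar_key"], frame["species_key"], frame["genus_key"],
            frame["hybrid"])
    )
    classes = np.fromiter((sev_map[k][0] for k in keys), dtype=np.int8, count=len(keys))
    prov = np.array([sev_map[k][1] for k in keys], dtype=object)
    return SeverityAssignment(inv.city, ds.name, classes, prov)


@dataclass
class SeverityRow:
    """One (city, dataset) row: exact fractions, rounded percents, flags."""

    city: str
    dataset: str
    n_trees: int
    fractions: dict  # Severity -> Fraction, sums to 1 exactly
    modal: Severity = Severity.NOT_REPORTED
    modal_tie: bool = False
    over_50: tuple = ()

    def __post_init__(self):
        if sum(self.fractions.values()) != 1:
            raise ValueError("exact severity fractions must sum to 1")
        self.modal, self.modal_tie, self.over_50 = flag_row(self.fractions)

    @property
    def percents(self) -> dict:
        """Nearest-integer display percentages (half-away-from-zero)."""
        return {sev: _round_half_away(f) for sev, f in self.fractions.items()}

    def as_dict(self) -> dict:
        d = {"city": self.city, "dataset": self.dataset, "n_trees": self.n_trees}
        for sev in _SEV_ORDER:
            d[f"frac_{sev.label}"] = float(self.fractions[sev])
        for sev in _SEV_ORDER:
            d[f"pct_{sev.label}"] = self.percents[sev]
        d["modal"] = self.modal.label
        d["modal_tie"] = self.modal_tie
        d["over_50"] = ";".join(s.label for s in self.over_50)
        return d


def severity_percentages(assignment: SeverityAssignment) -> SeverityRow:
    """Tabulate one assignment into a severity-table row.

    The denominator is ALL trees, *not reported* included — a tree whose
    taxon no dataset describes still stands in the city.
    """
    n = len(assignment)
    if n == 0:
        raise ValueError("empty severity assignment")
    counts = assignment.counts()
    fractions = {sev: Fraction(counts[sev], n) for sev in _SEV_ORDER}
    return SeverityRow(
        city=assignment.city,
        dataset=assignment.dataset,
        n_trees=n,
        fractions=fractions,
    )


def flag_row(fractions: dict) -> tuple[Severity, bool, tuple]:
    """Modal class and >50% flags, computed on exact fractions.

    Ties on the modal share are broken toward the more severe class
    (conservative risk communication) and flagged.  The >50% flag uses
    strict inequality.
    """
    best = max(fractions.values())
    tied = [sev for sev in _SEV_ORDER if fractions[sev] == best]
    modal = max(tied)  # Severity order: high > moderate > low > not_reported
    over = tuple(
        sev for sev in _SEV_ORDER if fractions[sev] > Fraction(1, 2)
    )
    return modal, len(tied) > 1, over


class SeverityTable:
    """Rows keyed (city, dataset); the city × dataset severity tabulation."""

    def __init__(self, rows: Sequence[SeverityRow] = ()):
        self.rows: list[SeverityRow] = list(rows)
        seen = set()
        for r in self.rows:
            key = (r.city, r.dataset)
            if key in seen:
                raise ValueError(f"duplicate severity-table row {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def append(self, row: SeverityRow) -> None:
        if any(r.city == row.city and r.dataset == row.dataset for r in self.rows):
            raise ValueError(f"duplicate severity-table row {(row.city, row.dataset)}")
        self.rows.append(row)

    def city_rows(self, city: str) -> list[SeverityRow]:
        return [r for r in self.rows if r.city == city]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.rows])

    @classmethod
    def from_percent_rows(cls, frame: pd.DataFrame) -> "SeverityTable":
        """Build a table from published rounded percentages.

        ``frame`` is long-format with columns city, severity, and one column
        per dataset holding integer percents (the shape such tables are
        printed in).  Rounded values may not sum to exactly 100, so exact
        fractions are reconstructed as percent/total for flag purposes.
        """
        datasets = [c for c in frame.columns if c not in ("city", "severity")]
        rows = []
        for city, sub in frame.groupby("city", sort=False):
            sub = sub.set_index("severity")
            for ds in datasets:
                pcts = {
                    sev: int(sub.loc[sev.label, ds]) for sev in _SEV_ORDER
                }
                total = sum(pcts.values())
                fractions = {
                    sev: Fraction(pcts[sev], total) for sev in _SEV_ORDER
                }
                rows.append(
                    SeverityRow(
                        city=city, dataset=ds, n_trees=0, fractions=fractions
                    )
                )
        return cls(rows)

    def high_range(self, city: str):
        return high_range(self, city)


def high_range(table: SeverityTable, city: str) -> dict:
    """Min/max percent-high across datasets for one city.

    Extrema are taken over the rounded display percents — the scale such
    figures are reported on.  Returns min, max, and the datasets attaining
    them (first occurrence on ties).
    """
    rows = table.city_rows(city)
    if not rows:
        raise ValueError(f"no severity-table rows for city {city!r}")
    pcts = [(r.percents[Severity.HIGH], r.dataset) for r in rows]
    lo = min(pcts, key=lambda t: t[0])
    hi = max(pcts, key=lambda t: t[0])
    return {
        "city": city,
        "min": lo[0],
        "max": hi[0],
        "argmin": lo[1],
        "argmax": hi[1],
        "width": hi[0] - lo[0],
    }


@dataclass
class ConcordanceReport:
    """Taxon × dataset severity matrix and pairwise agreement.

    Agreement between two datasets is the fraction of taxa, among those both
    classify as something other than *not reported*, on which they assign
    the same severity; pairs with no overlap are reported as such.
    """

    matrix: pd.DataFrame  # index: taxon key; columns: dataset names; values: labels
    agreement: dict  # (dsA, dsB) -> float in [0,1] or None (no overlap)
    discordant: list  # taxon keys with >1 distinct classified severity

    def to_frame(self) -> pd.DataFrame:
        return self.matrix.reset_index(names="taxon")

    def agreement_frame(self) -> pd.DataFrame:
        rows = [
            {"dataset_a": a, "dataset_b": b,
             "agreement": (np.nan if v is None else v)}
            for (a, b), v in sorted(self.agreement.items())
        ]
        return pd.DataFrame(rows)


def taxon_class_matrix(
    datasets: Sequence[AllergenDataset], taxa: Sequence[TaxonName]
) -> ConcordanceReport:
    """Resolve each taxon under each dataset and measure pairwise agreement."""
    if len(datasets) < 2:
        raise ValueError("concordance needs at least 2 datasets")
    keys = []
    cells: dict[str, list] = {ds.name: [] for ds in datasets}
    for taxon in taxa:
        keys.append(taxon.key(taxon.rank))
        for ds in datasets:
            sev, _ = lookup_severity(ds, taxon)
            cells[ds.name].append(sev)
    matrix = pd.DataFrame(cells, index=pd.Index(keys, name="taxon"))

    agreement: dict = {}
    for a, b in combinations([ds.name for ds in datasets], 2):
        both = matrix[
            (matrix[a] != Severity.NOT_REPORTED)
            & (matrix[b] != Severity.NOT_REPORTED)
        ]
        agreement[(a, b)] = (
            None if both.empty else float((both[a] == both[b]).mean())
        )

    classified = matrix.apply(
        lambda row: {s for s in row if s != Severity.NOT_REPORTED}, axis=1
    )
    discordant = [k for k, s in classified.items() if len(s) > 1]

    labelled = matrix.apply(lambda col: col.map(lambda s: Severity(s).label))
    return ConcordanceReport(
        matrix=labelled, agreement=agreement, discordant=discordant
    )
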