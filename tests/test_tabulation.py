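from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenscape import (Severity, SeverityTable, assign_severity, flag_row,
                         high_range, normalize_name, severity_percentages,
                         taxon_class_matrix)
from pollenscape.simulate import SYNTHETIC_SCHEME
from pollenscape.tabulation import SeverityAssignment, SeverityRow
from pollenscape.allergenicity import AllergenDataset
from conftest import make_dataset, make_inventory


def assignment_from_labels(labels, city="c", dataset="d"):
    classes = np.array([int(Severity.from_label(l)) for l in labels],
                       dtype=np.int8)
    prov = np.array(["species"] * len(labels), dtype=object)
    return SeverityAssignment(city, dataset, classes, prov)


def fractions_from_percents(h, m, l, nr):
    total = h + m + l + nr
    return {Severity.HIGH: Fraction(h, total),
            Severity.MODERATE: Fraction(m, total),
            Severity.LOW: Fraction(l, total),
            Severity.NOT_REPORTED: Fraction(nr, total)}


# --- assign_severity --------------------------------------------------------

def test_assignment_composition_of_lookup():
    inv = make_inventory(["Betula pendula", "Betula pendula", "Tilia cordata",
                          "Ginkgo biloba"])
    ds = make_dataset("d", {"Betula": "high", "Tilia": "low"})
    a = assign_severity(inv, ds)
    assert [Severity(int(c)).label for c in a.classes] == [
        "high", "high", "low", "not_reported"]
    assert list(a.provenance) == ["genus", "genus", "genus", "none"]


def test_empty_dataset_assigns_all_not_reported():
    inv = make_inventory(["Betula pendula", "Tilia cordata"])
    ds = AllergenDataset(name="empty", scheme=SYNTHETIC_SCHEME)
    a = assign_severity(inv, ds)
    assert set(a.classes.tolist()) == {int(Severity.NOT_REPORTED)}


def test_genus_only_record_with_species_only_dataset():
    inv = make_inventory(["Acer sp."])
    ds = make_dataset("d", {"Acer platanoides": "moderate"})
    a = assign_severity(inv, ds)
    assert a.classes[0] == int(Severity.NOT_REPORTED)


# --- severity_percentages ---------------------------------------------------

def test_percentages_arithmetic():
    row = severity_percentages(
        assignment_from_labels(["high", "high", "low", "not_reported"]))
    assert row.percents == {Severity.HIGH: 50, Severity.MODERATE: 0,
                            Severity.LOW: 25, Severity.NOT_REPORTED: 25}
    assert sum(row.fractions.values()) == 1


def test_rounded_thirds_sum_to_99():
    row = severity_percentages(
        assignment_from_labels(["high", "moderate", "low"]))
    assert row.percents[Severity.HIGH] == 33
    assert sum(row.percents.values()) == 99
    assert sum(row.fractions.values()) == 1


def test_all_not_reported_row():
    row = severity_percentages(
        assignment_from_labels(["not_reported"] * 5))
    assert row.percents[Severity.NOT_REPORTED] == 100
    assert row.modal == Severity.NOT_REPORTED


def test_empty_assignment_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        severity_percentages(assignment_from_labels([]))


def test_rounding_half_away_from_zero():
    # 1 of 200 trees = 0.5% -> rounds to 1, not 0
    row = severity_percentages(
        assignment_from_labels(["high"] + ["low"] * 199))
    assert row.percents[Severity.HIGH] == 1


# --- flag_row ----------------------------------------------------------------

def test_flags_modal_without_underline():
    modal, tie, over = flag_row(fractions_from_percents(50, 0, 25, 25))
    assert modal == Severity.HIGH and not tie and over == ()


def test_flags_published_extreme_row():
    # 74/17/9/0: modal high, high underlined (>50%)
    modal, tie, over = flag_row(fractions_from_percents(74, 17, 9, 0))
    assert modal == Severity.HIGH and not tie
    assert over == (Severity.HIGH,)


def test_tie_broken_toward_more_severe_and_flagged():
    modal, tie, over = flag_row(fractions_from_percents(40, 40, 20, 0))
    assert modal == Severity.HIGH and tie


def test_exactly_50_percent_is_not_underlined():
    modal, _, over = flag_row(fractions_from_percents(50, 30, 20, 0))
    assert over == ()


# --- high_range --------------------------------------------------------------

def make_table(city, highs):
    rows = []
    for name, h in highs.items():
        rows.append(SeverityRow(
            city=city, dataset=name, n_trees=100,
            fractions=fractions_from_percents(h, 0, 0, 100 - h)))
    return SeverityTable(rows)


def test_high_range_published_montreal_row():
    highs = {"AAAAI": 50, "AIA": 1, "ARL": 4, "Citree": 3, "EAN": 14,
             "INSPQ": 26, "OPALS": 74, "Pollen.com": 18, "RNSA": 14}
    rng = high_range(make_table("Montreal", highs), "Montreal")
    assert (rng["min"], rng["max"]) == (1, 74)
    assert rng["argmin"] == "AIA" and rng["argmax"] == "OPALS"


def test_high_range_single_and_pair():
    rng = high_range(make_table("c", {"only": 12}), "c")
    assert (rng["min"], rng["max"]) == (12, 12)
    rng = high_range(make_table("c", {"a": 10, "b": 30}), "c")
    assert (rng["min"], rng["max"]) == (10, 30)


@settings(max_examples=100, derandomize=True)
@given(st.dictionaries(st.from_regex(r"ds[a-z]{1,5}", fullmatch=True),
                       st.integers(0, 100), min_size=1, max_size=8),
       st.integers(0, 100))
def test_adding_a_dataset_only_widens_the_range(highs, extra):
    before = high_range(make_table("c", highs), "c")
    highs2 = dict(highs)
    highs2["zz-extra"] = extra
    after = high_range(make_table("c", highs2), "c")
    assert after["min"] <= before["min"] <= before["max"] <= after["max"]


# --- conservation properties -------------------------------------------------

@settings(max_examples=300, derandomize=True)
@given(st.lists(st.sampled_from(["high", "moderate", "low", "not_reported"]),
                min_size=1, max_size=400))
def test_row_conservation_properties(labels):
    row = severity_percentages(assignment_from_labels(labels))
    assert sum(row.fractions.values()) == 1  # exact
    assert 98 <= sum(row.percents.values()) <= 102
    unmatched = labels.count("not_reported")
    assert row.fractions[Severity.NOT_REPORTED] == Fraction(unmatched,
                                                            len(labels))


def test_dominant_entry_flip_changes_percent_high_by_its_abundance():
    """Flipping one taxon's class high -> low moves percent-high by exactly
    that taxon's relative abundance (the dominance-amplification mechanism)."""
    names = ["Acer platanoides"] * 37 + ["Betula pendula"] * 12 + \
            ["Tilia cordata"] * 5
    inv = make_inventory(names)
    base = {"Betula pendula": "high", "Tilia cordata": "moderate"}
    ds_high = make_dataset("hi", dict(base, **{"Acer platanoides": "high"}))
    ds_low = make_dataset("lo", dict(base, **{"Acer platanoides": "low"}))
    row_high = severity_percentages(assign_severity(inv, ds_high))
    row_low = severity_percentages(assign_severity(inv, ds_low))
    diff = row_high.fractions[Severity.HIGH] - row_low.fractions[Severity.HIGH]
    assert diff == Fraction(37, 54)  # exact equality of exact fractions


# --- concordance -------------------------------------------------------------

def test_identical_datasets_agree_perfectly():
    entries = {"Betula pendula": "high", "Tilia cordata": "low"}
    report = taxon_class_matrix(
        [make_dataset("a", entries), make_dataset("b", entries)],
        [normalize_name(t) for t in entries],
    )
    assert report.agreement[("a", "b")] == 1.0
    assert report.discordant == []


def test_disjoint_coverage_reports_no_overlap():
    report = taxon_class_matrix(
        [make_dataset("a", {"Betula pendula": "high"}),
         make_dataset("b", {"Tilia cordata": "low"})],
        [normalize_name("Betula pendula"), normalize_name("Tilia cordata")],
    )
    assert report.agreement[("a", "b")] is None


def test_partial_agreement_and_discordant_listing():
    taxa = [normalize_name(t) for t in
            ("Betula pendula", "Quercus rubra", "Ginkgo biloba")]
    a = make_dataset("a", {"Betula pendula": "high", "Quercus rubra": "high"})
    b = make_dataset("b", {"Betula pendula": "high", "Quercus rubra": "low",
                           "Ginkgo biloba": "moderate"})
    report = taxon_class_matrix([a, b], taxa)
    assert report.agreement[("a", "b")] == 0.5
    assert report.discordant == ["Quercus rubra"]


def test_concordance_needs_two_datasets():
    with pytest.raises(ValueError):
        taxon_class_matrix([make_dataset("a", {"Tilia": "low"})], [])
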