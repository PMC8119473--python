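import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenscape import (Severity, builtin_schemes, harmonize_label,
                         load_dataset, lookup_severity, normalize_name)
from conftest import make_dataset

SCHEMES = builtin_schemes()

# every published source's original labels and their common-scale class
CATEGORICAL_MAPPINGS = {
    "AAAAI": {
        "Highly allergenic plants": Severity.HIGH,
        "Allergenic plants": Severity.MODERATE,
        "Low-allergenic plants": Severity.LOW,
    },
    "AIA": {
        "Species whose planting should be avoided": Severity.HIGH,
        "Species whose planting should be limited and/or avoided in certain locations":
            Severity.MODERATE,
        "Species whose planting has no restrictions": Severity.LOW,
    },
    "ARL": {
        "Highly allergenic": Severity.HIGH,
        "Moderately allergenic": Severity.MODERATE,
        "In high enough numbers may cause allergic reactions": Severity.LOW,
    },
    "Citree": {
        "High allergy potential": Severity.HIGH,
        "Medium allergy potential": Severity.MODERATE,
        "Low allergy potential": Severity.LOW,
    },
    "EAN": {
        "High allergenicity": Severity.HIGH,
        "Moderate allergenicity": Severity.MODERATE,
        "Low allergenicity": Severity.LOW,
    },
    "INSPQ": {
        "***": Severity.HIGH,
        "**": Severity.MODERATE,
        "*": Severity.LOW,
    },
    "Pollen.com": {
        "Severe allergenicity": Severity.HIGH,
        "Moderate allergenicity": Severity.MODERATE,
        "Mild allergenicity": Severity.LOW,
    },
    "RNSA": {
        "Strong allergy potential": Severity.HIGH,
        "Medium allergy potential": Severity.MODERATE,
        "Moderate allergy potential": Severity.MODERATE,
        "Low allergy potential": Severity.LOW,
        "Non-allergenic species": Severity.LOW,
    },
}

OPALS_BREAKPOINTS = {1: Severity.LOW, 2: Severity.LOW, 3: Severity.LOW,
                     4: Severity.MODERATE, 5: Severity.MODERATE,
                     6: Severity.MODERATE, 7: Severity.HIGH, 8: Severity.HIGH,
                     9: Severity.HIGH, 10: Severity.HIGH}


def test_all_nine_schemes_shipped():
    assert sorted(SCHEMES) == sorted(
        ["AAAAI", "AIA", "ARL", "Citree", "EAN", "INSPQ", "OPALS",
         "Pollen.com", "RNSA"]
    )


@pytest.mark.parametrize(
    "scheme_id,label,expected",
    [
        (sid, label, sev)
        for sid, mapping in CATEGORICAL_MAPPINGS.items()
        for label, sev in mapping.items()
    ],
)
def test_categorical_harmonization_exhaustive(scheme_id, label, expected):
    assert harmonize_label(label, SCHEMES[scheme_id]) == expected


@pytest.mark.parametrize("score,expected", sorted(OPALS_BREAKPOINTS.items()))
def test_opals_breakpoints_exhaustive(score, expected):
    assert harmonize_label(score, SCHEMES["OPALS"]) == expected


@pytest.mark.parametrize("score", [0, 11, -1])
def test_opals_out_of_range_rejected(score):
    with pytest.raises(ValueError):
        harmonize_label(score, SCHEMES["OPALS"])


def test_harmonize_is_case_and_space_insensitive():
    assert harmonize_label("  highly  allergenic PLANTS ",
                           SCHEMES["AAAAI"]) == Severity.HIGH


def test_undeclared_label_names_the_label():
    with pytest.raises(ValueError, match="nonsense"):
        harmonize_label("nonsense", SCHEMES["EAN"])


def test_harmonize_never_yields_not_reported():
    for scheme in SCHEMES.values():
        if scheme.kind == "numeric":
            lo, hi = scheme.numeric_range
            results = {harmonize_label(s, scheme) for s in range(lo, hi + 1)}
        else:
            results = {harmonize_label(lab, scheme) for lab in scheme.labels}
        assert Severity.NOT_REPORTED not in results
        assert results <= {Severity.HIGH, Severity.MODERATE, Severity.LOW}


# --- dataset loading --------------------------------------------------------

def test_load_dataset_mixed_granularity(tmp_path, three_class_scheme):
    path = tmp_path / "ds.csv"
    path.write_text(
        "taxon,label\nBetula pendula,high\nAlnus,high\nTilia,low\n"
    )
    ds = load_dataset(path, three_class_scheme)
    assert len(ds) == 3
    assert ds.granularity == "mixed"


def test_load_dataset_conflicting_duplicate(tmp_path, three_class_scheme):
    path = tmp_path / "ds.csv"
    path.write_text("taxon,label\nBetula pendula,high\nBetula pendula,low\n")
    with pytest.raises(ValueError, match="Betula pendula"):
        load_dataset(path, three_class_scheme)


def test_load_dataset_consistent_duplicate_ok(tmp_path, three_class_scheme):
    path = tmp_path / "ds.csv"
    path.write_text("taxon,label\nBetula pendula,high\nBetula pendula,high\n")
    assert len(load_dataset(path, three_class_scheme)) == 1


def test_load_empty_dataset_everything_not_reported(tmp_path,
                                                    three_class_scheme):
    path = tmp_path / "ds.csv"
    path.write_text("taxon,label\n")
    ds = load_dataset(path, three_class_scheme)
    assert len(ds) == 0
    sev, level = lookup_severity(ds, normalize_name("Ginkgo biloba"))
    assert sev == Severity.NOT_REPORTED and level == "none"


# --- lookup precedence ------------------------------------------------------

def test_species_entry_overrides_genus(toy_dataset):
    sev, level = lookup_severity(toy_dataset,
                                 normalize_name("Acer platanoides"))
    assert sev == Severity.MODERATE and level == "species"


def test_genus_fallback(toy_dataset):
    sev, level = lookup_severity(toy_dataset, normalize_name("Acer rubrum"))
    assert sev == Severity.HIGH and level == "genus"


def test_no_entry_at_any_level_is_not_reported(toy_dataset):
    sev, level = lookup_severity(toy_dataset, normalize_name("Ginkgo biloba"))
    assert sev == Severity.NOT_REPORTED and level == "none"


def test_hybrid_resolves_to_marker_free_species_entry(toy_dataset):
    sev, level = lookup_severity(toy_dataset,
                                 normalize_name("Platanus x acerifolia"))
    assert sev == Severity.MODERATE and level == "species"


def test_cultivar_entry_takes_precedence():
    ds = make_dataset("c", {
        "Acer platanoides 'Crimson King'": "low",
        "Acer platanoides": "moderate",
        "Acer": "high",
    })
    sev, level = lookup_severity(
        ds, normalize_name("Acer platanoides 'Crimson King'"))
    assert sev == Severity.LOW and level == "cultivar"
    # a sibling cultivar without its own entry falls back to the species
    sev, level = lookup_severity(
        ds, normalize_name("Acer platanoides 'Emerald Queen'"))
    assert sev == Severity.MODERATE and level == "species"


def test_genus_only_record_ignores_species_entries():
    ds = make_dataset("s", {"Acer platanoides": "moderate"})
    sev, level = lookup_severity(ds, normalize_name("Acer sp."))
    assert sev == Severity.NOT_REPORTED and level == "none"


# --- fallback contract property suite ---------------------------------------

_genus = st.from_regex(r"[A-Z][a-z]{2,6}", fullmatch=True)
_epithet = st.from_regex(r"[a-z]{2,8}", fullmatch=True)
_label = st.sampled_from(["high", "moderate", "low"])


@st.composite
def dataset_and_taxon(draw):
    entries = {}
    for _ in range(draw(st.integers(0, 6))):
        g = draw(_genus)
        key = g if draw(st.booleans()) else f"{g} {draw(_epithet)}"
        entries[key] = draw(_label)
    taxon_text = draw(_genus)
    if draw(st.booleans()):
        taxon_text += f" {draw(_epithet)}"
    return entries, taxon_text


@settings(max_examples=300, derandomize=True)
@given(dataset_and_taxon())
def test_lookup_total_and_deterministic(data):
    entries, taxon_text = data
    ds = make_dataset("p", entries)
    taxon = normalize_name(taxon_text)
    first = lookup_severity(ds, taxon)
    assert first == lookup_severity(ds, taxon)
    assert first[0] in set(Severity)
    assert first[1] in ("cultivar", "species", "genus", "none")


@settings(max_examples=300, derandomize=True)
@given(dataset_and_taxon(), _genus, _epithet, _label)
def test_unrelated_insertion_never_changes_result(data, other_genus,
                                                  other_epithet, other_label):
    """Adding an entry for a different genus never changes a taxon's class."""
    entries, taxon_text = data
    taxon = normalize_name(taxon_text)
    if other_genus == taxon.genus:
        other_genus += "x"
    before = lookup_severity(make_dataset("a", entries), taxon)
    augmented = dict(entries)
    augmented[f"{other_genus} {other_epithet}"] = other_label
    augmented.setdefault(other_genus, other_label)
    after = lookup_severity(make_dataset("b", augmented), taxon)
    assert before == after


@settings(max_examples=300, derandomize=True)
@given(dataset_and_taxon(), _epithet, _label)
def test_species_insertion_only_affects_that_species(data, new_epithet,
                                                     new_label):
    """Precedence monotonicity: a new species entry changes results only for
    that species; other members of the genus keep their class."""
    entries, taxon_text = data
    taxon = normalize_name(taxon_text)
    new_key = f"{taxon.genus} {new_epithet}"
    before = lookup_severity(make_dataset("a", entries), taxon)
    augmented = dict(entries)
    if new_key in augmented:
        augmented.pop(new_key)
    augmented[new_key] = new_label
    after = lookup_severity(make_dataset("b", augmented), taxon)
    if taxon.key(taxon.rank) == new_key:
        assert after[0] == Severity.from_label(new_label)
    else:
        assert before == after
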