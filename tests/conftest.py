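import numpy as np
import pytest

from pollenscape import (AllergenDataset, ClassScheme, Inventory, Severity,
                         normalize_name)
from pollenscape.simulate import SYNTHETIC_SCHEME


@pytest.fixture
def three_class_scheme():
    return ClassScheme(
        scheme_id="toy",
        kind="categorical",
        labels={
            "high": Severity.HIGH,
            "moderate": Severity.MODERATE,
            "low": Severity.LOW,
        },
    )


def make_dataset(name, entries, scheme=None):
    """Dataset from {name string: severity label} pairs."""
    ds = AllergenDataset(name=name, scheme=scheme or SYNTHETIC_SCHEME)
    for taxon_text, label in entries.items():
        ds.add_entry(normalize_name(taxon_text), label)
    return ds


@pytest.fixture
def toy_dataset(three_class_scheme):
    return make_dataset(
        "toy",
        {
            "Betula pendula": "high",
            "Alnus": "high",
            "Acer": "high",
            "Acer platanoides": "moderate",
            "Tilia": "low",
            "Platanus acerifolia": "moderate",
        },
        scheme=three_class_scheme,
    )


def make_inventory(names, city="Toyville", x=None, y=None, crs="projected"):
    taxa = [normalize_name(n) for n in names]
    n = len(taxa)
    rng = np.random.default_rng(7)
    if x is None:
        x = rng.uniform(0, 1000, n)
    if y is None:
        y = rng.uniform(0, 1000, n)
    return Inventory.from_taxa(city, taxa, x, y, crs=crs)


@pytest.fixture
def toy_inventory():
    return make_inventory(
        [
            "Betula pendula",
            "Betula pendula",
            "Tilia cordata",
            "Ginkgo biloba",
            "Acer platanoides",
            "Acer sp.",
            "Platanus x acerifolia",
            "Quercus rubra",
        ]
    )


@pytest.fixture
def inventory_csv(tmp_path):
    path = tmp_path / "trees.csv"
    path.write_text(
        "id,species,easting,northing\n"
        "1,Acer platanoides,100,200\n"
        "2,Acer platanoides,110,210\n"
        "3,Betula pendula,500,600\n"
        "4,,400,100\n"
        "5,Tilia cordata,300,300\n"
    )
    return path
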