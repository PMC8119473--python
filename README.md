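# pollenscape

Urban trees are a major source of allergenic pollen, but the reference
resources that rate a taxon's pollen allergenicity (AAAAI, AIA, ARL, Citree,
EAN, INSPQ, OPALS, Pollen.com, RNSA) disagree — in vocabulary, in taxonomic
granularity, and often in the rating itself. Because a city's public canopy
is usually dominated by a handful of species, swapping one allergenicity
source for another can flip the apparent exposure risk of whole
neighbourhoods. `pollenscape` is a pipeline for quantifying and mapping that
effect over municipal tree inventories. It is aimed at urban-forestry and
environmental-health analysts who have a point inventory (one row per public
tree with a botanical name and coordinates) and one or more allergenicity
lookup tables.

## What it computes

* **Harmonization** — each source's native labels (verbal classes, star
  ratings, the OPALS 1–10 score) are mapped onto a common severity scale
  {high, moderate, low, not_reported}; e.g. OPALS 7–10 → high, 4–6 →
  moderate, 1–3 → low.
* **Severity assignment with rank fallback** — every tree resolves through
  cultivar → species → genus precedence; a taxon no source describes is
  *not reported* and stays in the denominator.
* **Severity tables** — per (city, dataset): exact fractions (kept as
  rationals, so rows sum to 1 exactly) and rounded display percents, with
  the modal class and any class above 50% flagged. The **high-severity
  range** — min/max percent-high across datasets for one city — is the
  headline disagreement statistic.
* **Concordance** — a taxon × dataset severity matrix with pairwise
  agreement fractions over the taxa both sources classify.
* **True diversity** — Shannon index H = −Σ pᵢ ln pᵢ and the effective
  number of species e^H (Hill number of order 1), plus the minimal number of
  top taxa covering a given share of all trees.
* **Riskscapes** — per-tree severities rasterized onto a metric grid by the
  majority rule (each cell takes the most frequent class among its trees,
  ties broken toward the more severe class and flagged), exported as ESRI
  ASCII grid, GeoJSON cell polygons, or PNG (high = red, moderate = yellow,
  low = green, not reported = gray).
* **Synthetic cities** — a generator with geometric-series species
  abundances (one dominance parameter k), uniform or clustered positions,
  and allergenicity datasets with controlled coverage, granularity and
  disagreement rate against a known ground truth, so the whole pipeline is
  testable without downloading any municipal data.

## Worked example

The repository ships a fictional 15-tree city and two fictional
allergenicity sources (an OPALS-style numeric one and an EAN-style
categorical one) under `examples/`:

```
pollenscape run -c examples/config.yaml --out smallville_out
```

prints

```
      city dataset  n_trees  frac_high  frac_moderate  frac_low  frac_not_reported  pct_high  pct_moderate  pct_low  pct_not_reported modal  modal_tie over_50
Smallville   alpha       15   0.800000            0.0  0.133333           0.066667        80             0       13                 7  high      False    high
Smallville    beta       15   0.133333            0.0  0.733333           0.133333        13             0       73                13   low      False     low
Smallville: percent-high ranges 13-80 (min beta, max alpha)
```

Under source *alpha* 80% of Smallville's trees are highly allergenic; under
*beta* it is 13% — the same trees, different reference data. The output
directory also contains the concordance matrix, the diversity summary
(8 species, H = 1.946, e^H = 7.0 effective species; 7 species cover 90% of
the trees) and one riskscape grid per (city, dataset) in `.asc` and
`.geojson` form. Re-running with the same config and seed reproduces every
file byte for byte (a `manifest.json` records input checksums and the
configuration).

The same machinery is available as a library:

```python
from pollenscape import published_severity_table, high_range

table = published_severity_table()   # bundled published city × dataset percents
print(high_range(table, "Montreal"))
# {'city': 'Montreal', 'min': 1, 'max': 74, 'argmin': 'AIA', 'argmax': 'OPALS', 'width': 73}
```

Across nine published sources the share of Montreal's public trees rated
highly allergenic ranges from 1% to 74% — the uncertainty a map user
inherits from the choice of reference data alone.

Other subcommands: `pollenscape table`, `concord`, `map`, and
`pollenscape simulate -c sim.yaml --seed N --out dir`, which writes a
synthetic inventory, dataset entry files, a scheme config and the ground
truth in exactly the formats the real pipeline consumes.

Real municipal inventories (e.g. the open-data censuses of Barcelona,
Montreal, New York City, Paris, Vancouver) are supported through the same
config: declare the species/coordinate columns and the CRS (geographic
inputs are projected to the local UTM zone on load), and supply per-source
entry files — several of the published sources are proprietary or
web-resident, so the package ships their classification *schemes* (see
`src/pollenscape/data/schemes.yaml`) but not their per-taxon entries.

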