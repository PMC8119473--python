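# Methods

## Problem and model

A city's allergenic-pollen riskscape is estimated from two inputs: a public
tree inventory (points with botanical names) and an allergenicity reference
that rates each taxon's pollen. The pipeline treats the reference as the
uncertain quantity: it harmonizes several references onto one ordinal
severity scale, computes the exposure summary under each, and reports the
spread. No aerobiology is modelled — a tree contributes its severity class
at its location, nothing about emission, phenology or dispersion. The unit
of analysis is the tree; all percentages are shares of the total public tree
count.

### Severity scale and harmonization

The common scale is {high, moderate, low, not_reported} with the total order
high > moderate > low > not_reported used wherever a tie must break. Each
source is described by a `ClassScheme`: either categorical (a finite label
set, each label mapped to exactly one of high/moderate/low) or numeric (an
integer score with inclusive breakpoints, e.g. the OPALS 1–10 scale with
1–3 → low, 4–6 → moderate, 7–10 → high). Harmonization is total over a
scheme's declared labels and never yields *not_reported* — absence of an
entry, not a label, encodes ignorance. Label matching is case- and
whitespace-insensitive. The nine published schemes ship in
`data/schemes.yaml`; per-taxon entry files are user-supplied because several
sources are proprietary or web-resident.

### Name normalization and rank fallback

Botanical names are parsed to (genus, epithet, hybrid flag, quoted cultivar)
with diacritics stripped and hybrid markers ("x", "×" between genus and
epithet or glued to the epithet) removed from join keys — a hybrid and its
marker-free spelling are one taxon for lookup. Only single-quoted cultivars
are recognized; unquoted trailing capitalized tokens are treated as
authority strings, since heuristics for unquoted trade names misfire too
often. "sp./spp./species" force genus rank; infraspecific ranks (var.,
subsp., f.) are collapsed to species rank and counted in the load report.
Synonymy is a user-supplied two-column file applied once after lexical
normalization; the table must already be a fixed point (no accepted name is
itself a key), which makes application idempotent by construction.

Severity resolution uses cultivar → species → genus precedence, first hit
wins; no hit at any rank is *not_reported*. The matched rank is kept as
provenance on every tree. Within-dataset species/genus contradictions are
legal (they are different keys); contradictory duplicates of the *same* key
are a load error.

### Tabulation

Per (city, dataset) the severity shares are kept as exact rationals
(`fractions.Fraction`), so rows sum to 1 identically and differences between
datasets are exact — this is what makes the dominance-amplification law
(below) testable as an equality rather than a tolerance. Display percents
are integers rounded half-away-from-zero; rounded rows may sum to 100 ± 2.
The *not_reported* trees always stay in the denominator (an optional
classified-only denominator exists but is off by default). The modal class
and any class strictly above 50% are flagged; modal ties break toward the
more severe class and carry a tie flag — a conservative choice for risk
communication. The high-severity range of a city is the min/max of the
rounded percent-high across datasets, reported with the datasets attaining
them.

Cross-dataset concordance is the taxon × dataset matrix of resolved
severities; pairwise agreement is the fraction of identically-classified
taxa among those both datasets classify (≠ not_reported), with no-overlap
pairs reported as such rather than as 0.

### Diversity

Relative abundances are computed at genus and species level; at species
level, genus-only records are excluded (and counted) rather than spread
pro-rata — exclusion is auditable, imputation is not. Shannon diversity
H = −Σ pᵢ ln pᵢ uses natural log only; the effective number of species is
e^H. The coverage count (minimal number of top taxa whose cumulative share
reaches θ) sorts by descending abundance with lexicographic tie-break for
determinism. No other Hill orders, rarefaction or beta diversity are
provided.

### Riskscape grids

Points must be in a projected metric system; geographic inventories are
projected to the local UTM zone (inferred from the mean longitude) at load,
using an in-package WGS84 transverse-Mercator forward transform (standard
series expansion, sub-millimetre accuracy within a zone — negligible against
any sensible cell size). Cells are half-open intervals [origin + j·c,
origin + (j+1)·c); points exactly on the upper extent land in a final padded
cell, never dropped. Each occupied cell takes the most frequent severity
among its trees (majority rule), severe-side tie-break with a tie flag;
per-class counts are conserved exactly. *Not reported* trees are rasterized
as a gray class by default so the map and the table share one denominator.
The default cell size is 100 m — a city-block scale that keeps single street
trees visible without reducing the map to per-point noise; it is
configurable, and exports go to ESRI ASCII grid (text raster with
georeferencing header and integer class codes), GeoJSON cell polygons
carrying counts and tie flags, and PNG with the conventional
red/yellow/green/gray coding.

## Synthetic data: what it emulates, what it does not

The generator reproduces the mechanism of interest — independent references
that disagree on few taxa, amplified by canopy dominance — not any real
city. Species abundances follow a geometric series pᵢ ∝ k(1−k)^(i−1): a
single parameter spans even canopies (k → 0) to strongly dominated ones; the
defaults (50 species in 20 genera, 100,000 trees, k = 0.3, i.e. the top
species near 30% of the canopy, uniform positions in a 5 km box) describe a
mid-sized, strongly dominated public inventory of the kind that motivates
the analysis. Tree counts are multinomial in the generating proportions, so
the analytic Shannon index H* and e^{H*} of the generating distribution are
known and the pipeline's estimates can be checked for convergence
(relative error < 1% at n = 2×10⁵). Ground-truth severities are drawn
uniformly from {high, moderate, low} per species. Synthetic datasets cover a
random fraction of taxa at species or genus granularity (a genus's true
class is that of its most abundant member species) and perturb each covered
taxon's class with probability δ by one severity step, direction random,
clamped — one-step perturbation mimics the high↔moderate↔low adjacency of
real dataset conflicts. The clustered spatial model (uniform parents,
isotropic Gaussian offspring, 25 parents, σ = 150 m) exists for structured
map tests; uniform is the default.

What passing tests on synthetic data do *not* show: real inventories carry
misspellings, coordinate errors, dead/stump records and private-tree gaps;
real references disagree non-randomly (systematically by genus and region);
real abundance curves are not exactly geometric. The cleaning, fallback and
tabulation logic is exercised by construction, but quantitative results on
real cities depend on data quality the generator does not emulate.

### The dominance-amplification law

If two datasets differ only in one taxon's class (high vs low), the
percent-high gap between them equals that taxon's relative abundance at the
matched rank — exactly, by construction of the tabulation. The simulation
experiment (`mechanism_experiment`) runs a battery of independently
perturbed datasets (δ = 0.3, five datasets) over cities at k = 0.05 vs
k = 0.6 (20 replicates, n = 10⁵, 50 species) and records the mean width of
the high-severity range: stronger dominance (lower e^H) yields a strictly
wider range. These problem sizes keep the full suite and the acceptance
script fast while leaving the multinomial noise far below the effects being
measured.

## Numerical and design choices

* Exact fractions via `fractions.Fraction` in tabulation; floats only at
  the export boundary.
* Rounding half-away-from-zero for display percents (rounding convention of
  the bundled published table is unknown; the two conventions differ by at
  most one point and the choice is recorded in the run manifest).
* High-range extrema over *rounded* percents, matching how such figures are
  printed and quoted.
* All severity tie-breaks (modal class, raster majority) go toward the more
  severe class and are flagged.
* All randomness flows from one seeded `numpy` generator; re-running any
  command with the same config and seed reproduces tabular outputs byte for
  byte. Run manifests record input checksums, config, seed and drop counts.
* Unparseable or blank names drop with counts by default; `--strict` aborts
  instead. Duplicate tree ids warn but keep records — records, not ids, are
  the unit.
* Empty synonym table, empty dataset (all lookups not_reported) and
  single-taxon inventories are all valid inputs with defined results.

## Known limitations

* No pollen emission, phenology, dispersion or cross-reactivity modelling;
  the riskscape is a standing-stock map, not an aerobiological forecast.
* Genus fallback assumes within-genus homogeneity wherever a source reports
  only the genus — exactly the assumption the concordance analysis is meant
  to expose, so results should be read jointly with the provenance columns.
* Applying a reference outside its region of origin is flagged with a
  warning (when regions are declared), not prevented.
* The bundled published percentages are rounded integers; reconstructed
  fractions inherit that rounding.
* GeoTIFF is not among the raster export formats; the ASCII grid plus
  GeoJSON outputs import cleanly into desktop GIS tools.
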