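# Minimal pipeline config: one fictional city, two allergenicity sources
# (an OPALS-style numeric one and an EAN-style categorical one).
synonyms: examples/synonyms.csv
inventories:
  - city: Smallville
    path: examples/trees_smallville.csv
    crs: projected          # coordinates already in metres
    columns: {species: species, x: x, y: y, id: id}
datasets:
  - name: alpha
    entries: examples/dataset_alpha.csv
    scheme: OPALS           # built-in scheme id
  - name: beta
    entries: examples/dataset_beta.csv
    scheme: EAN
grid:
  cell_size: 100
  formats: [asc, geojson]
output: smallville_out
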