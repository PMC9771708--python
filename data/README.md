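# External data directory

Place the curated Northwest Pacific occurrence matrix here to enable the
published-data checks in `tests/test_acceptance.py`:

- `vent_site_by_species.csv` — 36 vent sites x 117 species, first column the
  site id (matching the ids in the bundled metadata table, e.g. `NKIR`,
  `SmsC`), header row the species names, cells 0/1.

The table is distributed as an Excel spreadsheet in the journal supplement of
the source article and is not bundled with this repository.  Convert the
sheet to CSV (one helper: open in any spreadsheet tool or use
`python -c "import pandas as pd; pd.read_excel('TableS1.xlsx', index_col=0).to_csv('data/vent_site_by_species.csv')"`,
adjusting sheet name/range as needed).

The per-site metadata (coordinates, depth, tectonic setting) is already
bundled inside the package (`ventnet.load_vent_site_table()`) and requires no
download.
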