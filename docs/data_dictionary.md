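# Data dictionary

Dialects of every file `paleodairy` reads or writes.

## Inputs

### PSM table (`psms.csv`)
CSV, UTF-8, '.' decimal separator; one row per peptide spectral match.

| column | type | meaning |
|---|---|---|
| `sample_id` | text | individual/sample identifier |
| `peptide` | text | uppercase 20-letter amino-acid sequence |
| `protein_accession` | text | accession of the matched protein; `DECOY_` prefix implies a decoy |
| `protein_family` | text | milk family (`BLG`, `BLG-I`, `BLG-II`, `alpha-S1-casein`, `alpha-S2-casein`, `alpha-lactalbumin`, `other-milk`) or `other` |
| `e_value` | real > 0 | search-engine expectation value |
| `is_decoy` | 0/1 | decoy flag |
| `n_deamidation_mods` | int ≥ 0 | observed N/Q→D/E modifications (≤ N+Q residues in the peptide) |

### Oral-signature table (`ossd.csv`)
`match_key,category`; categories: `oral_bacteria`, `human_immune_oral`,
`handling_contaminant`, `lab_contaminant`. `match_key` unique.

### Milk reference (`milk_reference.fasta`)
FASTA with header dialect `>accession|family=BLG|taxon=Bos`.

### Exclusion list (`exclusion_list.txt`)
One accession per line; `#` comments and blank lines ignored.

### Taxonomy (`taxonomy.tsv`)
`child<TAB>parent<TAB>rank`, one edge per line; single implicit root.

### Consumers (`consumers.csv`)
`individual_id,delta15N,measurement_sd` (‰).

### Dates (`dates.csv`)
`lab_code,c14_age,sd` (14C years BP); an optional `individual_id` column
links dates to individuals.

### Calibration curve (`*.14c`)
Comma-separated `cal BP, 14C age BP, error`; `#`-prefixed headers
skipped; extra columns ignored; cal BP strictly monotone.

### Manifest (`manifest.csv`, file-based runs)
`individual_id,site,period`; periods: `eneolithic`, `early_bronze`,
`middle_late_bronze`.

## Outputs (`run-all`)

### `individuals.csv`
One row per individual, always including excluded individuals.

| column | meaning |
|---|---|
| `individual_id`, `site`, `period` | identity |
| `excluded` | 0/1 |
| `exclusion_reason` | `validation_failed:*` or `preservation_failed:*`, empty if included |
| `authenticity_percent` | oral-signature authenticity (empty if not screened) |
| `dairy_call` | `positive` / `equivocal` / `negative` (empty if excluded) |
| `dairy_families` | `+`-joined milk families present |
| `f_freshwater_mean`, `f_freshwater_sd` | diet-mixing posterior (dated Eneolithic individuals) |
| `date_lo95_calBP`, `date_hi95_calBP` | mixed-curve 95% interval, older bound first |

### `summary.json`
`per_period` and `overall` tallies (`n_extracted`, `n_preserved`,
`n_dairy_positive`, `n_equivocal`, `n_negative`, plus formatted
`preservation` and `dairy_positive` strings) and `warnings`.

### `specificity_histogram.csv`
`taxon_node,n_psms`: milk PSM counts per assigned LCA node.

### `oxcal_model.txt`
OxCal Plot block (Curve/Delta_R/Mix_Curves/R_Date) for the dated
individuals, ASCII quotes.

### `run.log`
Timestamp-free log of thresholds applied and per-individual exclusions
(kept deterministic so reruns are byte-identical).

## Synthetic-cohort extras

`truth.csv` (`truth_preserved`, `truth_authenticity_target`,
`truth_dairy_call`, `truth_taxa` per individual) and
`isotope_truth.csv` (`truth_f_freshwater`, `truth_cal_bp`,
`truth_delta_r`, plus the simulated `delta15N` and `c14_age`).

## Stage outputs (CLI subcommands)

`preservation.csv` (per-sample category counts, authenticity, threshold,
pass flag), `diet_posteriors.csv`
(`individual_id,f_mean,f_sd,lo95,hi95,percent_mean,percent_sd`),
`calibration.csv`
(`lab_code,mode_calBP,lo95_calBP,hi95_calBP,lo95_calendar,hi95_calendar`).
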