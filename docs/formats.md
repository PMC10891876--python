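# File format reference

All artefacts are plain text.

## MGF (spectra, seed spectra)

Standard `BEGIN IONS` / `END IONS` blocks. Required: `PEPMASS`; `CHARGE`
defaults to 1+ with a logged note when absent; retention time from
`RTINSECONDS` (divided by 60) or `RTINMINUTES` — minutes are the unit
everywhere inside the package. Peaks are written as `m/z intensity` with
4 and 1 decimals respectively.

The `TITLE` line carries identity and provenance:

    TITLE=<spectrum id>|seed=<0|1>|sample=<sample id>

so the seed flag and sample association survive round trips.

## Feature matrix CSV + sample metadata CSV

Matrix: one row per feature.

| column | meaning |
| --- | --- |
| `feature_id` | unique feature identifier |
| `mz` | feature m/z (Th) |
| `rt` | retention time (min) |
| *sample ids...* | peak area per sample (empty cells read as 0, logged) |

Metadata sidecar: one row per sample.

| column | meaning |
| --- | --- |
| `sample_id` | matches a matrix column |
| `strain_label` | culture strain (or a blank label) |
| `replicate_index` | 1..4 |
| `is_blank` | boolean; exactly one blank per experiment by default |
| `dry_biomass_mg` | dry biomass, mg; empty for blanks |

Every matrix sample column must appear in the metadata (error otherwise).

## Ground-truth CSV (synthetic fixtures)

`feature_id, group, subclass, chlorinated, strains, role` where `strains`
is `;`-joined and `role` is one of `monoisotopic | adduct | isotopologue
| decoy | blank`.

## Diagnostic-ion registry CSV

`group, subclass, mz, label, role[, note]` with `role` in
`required | required_intense | subclass | chlorine_evidence`. The
companion immonium table is `residue, mz`. Both ship inside the package
(`cyanopept/data/`) and can be replaced via
`DiagnosticRuleRegistry.from_csv`.

## GraphML (molecular network)

Node attributes: `precursor_mz`, `rt`, `provenance`
(`extract|seed|shared`), `strains` (comma-joined), `cluster` (component
id), `group` (majority annotation). Edge attributes: `cosine`,
`matched_ions`.

## Pipeline outputs

`run_pipeline` writes into its output directory: the raw fixture
(`features_raw.csv`, `samples.csv`, `spectra.mgf`, `ground_truth.csv`),
`classifications.tsv`, the deconvoluted statistics table
(`features_stats.csv` + `samples_stats.csv`, `scaled_matrix.csv`),
`deconvolution_audit.tsv` (feature, rule, detail), PCA tables
(`pca_scores.csv`, `pca_loadings.csv`), `significance.tsv`,
`volcano.tsv`, `loading_labels.txt`, `relative_abundance.tsv`,
`network.graphml`, `distribution_table.tsv`, SVG plots under `plots/`,
and a JSON-lines run log (`run_log.jsonl`) echoing every threshold and
parameter per stage.
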