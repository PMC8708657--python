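# barcodekit

A toolkit for comparative evaluation of DNA barcode reference libraries.
It bundles the two families of species-identification methodology that are
usually run in separate tools:

- **Unsupervised / distance-based** — pairwise genetic distances (simple p,
  JC69, K80 with pairwise deletion), the Best Match / Best Close Match /
  All Species Barcodes identification criteria with sequence- and
  species-level rollups, and automatic barcode-gap partitioning (prior
  divergence scan, gap detection with relative width X, recursive
  single-linkage splitting, TRUE/AMBIGUOUS/INCORRECT/SINGLETON group tags).
- **Supervised / learning-based** — per-column encoding of alignments and
  alignment-free k-mer features (exact spectrum, gappy with bounded span,
  mismatch with Hamming balls), stratified k-fold cross-validation of
  nearest-neighbour / random-forest / multinomial-logistic / margin
  classifiers with accuracy, probability RMSE, per-class TPR/FPR and
  species rollups, and corrected resampled paired t-tests for ranking
  classifiers.

A seeded synthetic generator produces barcode sets with controlled
intra/interspecific divergence, singleton species, indels and missing data,
and serves as the test bed for everything else.

## CLI

Every step is a subcommand of `barcodekit` (see `barcodekit --help`):

```sh
# make a toy dataset: 20 species x 4 members, planted barcode gap
barcodekit simulate --species 20 --members 4 --length 600 \
    --intra 0.005 --inter 0.08 --seed 1 --out demo

# curation filters (length is "more than", counted over non-gap bases)
barcodekit curate demo.fasta --min-length 400 --min-conspecifics 3

# distance-based identification and gap partitioning
barcodekit distances demo.fasta --model jc69 --out dm.tsv
barcodekit identify demo.fasta --criterion bcm --threshold 0.03
barcodekit identify demo.fasta --criterion asb --threshold percentile:95
barcodekit abgd demo.fasta --pmin 0.001 --pmax 0.1 --gap-width 1.5

# featurization and cross-validated classification
barcodekit featurize demo.fasta --scheme gappy --k 5 --g 1 --out features.tsv
barcodekit evaluate demo.fasta --classifier knn --scheme spectrum --k 4 \
    --folds 10 --repeats 10 --seed 1
barcodekit compare scores.tsv --baseline knn

# the full pipeline from a TOML config
barcodekit run --config run.toml
barcodekit selftest
```

FASTA headers carry the species label and accession; the default dialect is
`Species_name|accession` and is configurable via `--label-spec` (e.g.
`--label-spec accession|species`).

`barcodekit run` writes `report.json`, `tables/*.tsv` and `run.log` under
the configured output directory; identical configs and seeds produce
byte-identical reports. A minimal config:

```toml
[dataset]
source = "synthetic"          # or "fasta" with [dataset.fasta] path = "..."
[dataset.synthetic]
n_species = 20
members_per_species = 4
seq_length = 600
intra_divergence = 0.005
inter_divergence = 0.08
seed = 1

[unsupervised]
model = "simple"
threshold = 0.03              # or "percentile:95"

[supervised]
schemes = ["spectrum", "gappy"]
k_values = [2, 3]
nn_values = [1, 3]
classifiers = ["knn", "rf"]
baseline = "knn"
folds = 10
repeats = 2
seed = 1

[output]
dir = "out"
```

## Package layout

| module | contents |
| --- | --- |
| `barcodekit.io` | FASTA read/write, label specs, curation filters, summaries |
| `barcodekit.distances` | site bookkeeping, p/JC69/K80, distance matrices |
| `barcodekit.identify` | BM/BCM/ASB criteria, percentile thresholds, rollups |
| `barcodekit.abgd` | gap detection, single-linkage partitioning, prior scan |
| `barcodekit.features` | aligned encoding, spectrum/gappy/mismatch k-mers |
| `barcodekit.classify` | stratified CV, native k-NN, delegated estimators, metrics |
| `barcodekit.compare` | corrected resampled paired t-test, classifier ranking |
| `barcodekit.synth` | seeded synthetic barcode generator |
| `barcodekit.workflow` | end-to-end pipeline behind `barcodekit run` |
| `barcodekit.fixtures` | hand-verified toy datasets behind `barcodekit selftest` |
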