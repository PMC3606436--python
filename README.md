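# mirlassonet

Lasso regression over biological networks for inferring **functional
disease–miRNA associations**.

MicroRNAs (miRNAs) repress hundreds of genes each, and their dysregulation is
implicated in many diseases, but experimentally validated disease–miRNA links
are sparse. `mirlassonet` infers such links *functionally*: if the genes that
make up a disease's signature are well explained by the target profiles of a
few miRNAs, those miRNAs are candidate drivers of the disease. The package is
aimed at computational biologists who have (or can export) disease expression
data, text-mining gene–disease tables, sequence-based miRNA target
predictions and a protein–protein interaction (PPI) network.

## The model

For each disease *i*, the signature vector over a common gene universe is
regressed on the influence profiles of all miRNAs:

```
DiseaseSig(i) = Σ_j NetmiR_j · β_j + λ P(β),     P(β) = Σ_j ½ |β_j|
```

* **DiseaseSig(i)** — the disease's gene signature: the union of (a) the top
  *k* up- and down-regulated genes by a SAM-style moderated *d*-statistic,
  `d = (mean_case − mean_control) / (s + s₀)`, and (b) text-mined genes with
  relevance score > 0 and more than ten citations. Encoded as binary
  membership over the universe by default.
* **NetmiR_j** — the binary influence profile of miRNA *j*: its directly
  predicted targets **plus** *indirect* targets, i.e. genes that are not
  targeted themselves but have at least five PPI neighbors among *j*'s
  targets (one propagation step through the protein context).
* **β_j** — how strongly miRNA *j* explains the disease signature. The L1
  penalty zeroes most coefficients; λ is chosen by 10-fold cross-validation
  (minimum mean held-out squared error). Positive coefficients become scored
  disease–miRNA edges; negative ones carry no biological interpretation here
  and are dropped by default.

The solver is cyclic coordinate descent with soft-threshold updates,
warm-started along a decreasing log-spaced λ path. Predicted networks are
validated against a gold-standard edge set by per-disease and pooled ROC/AUC,
with Fisher-exact and hypergeometric enrichment as classical baselines.

## Worked example

Everything runs end to end on coupled synthetic data with planted
disease→miRNA ground truth:

```sh
mirlassonet run-all --simulate --seed 17 --outdir demo/
```

prints

```
predicted 62 associations; mean per-disease AUC = 1.000 (pooled 0.999)
```

i.e. on the default benchmark (600 genes, 50 miRNAs, 8 diseases with 3
planted causal miRNAs each) the fitted models recover 62 positive-coefficient
disease–miRNA edges whose ranking separates the 24 planted gold-standard
pairs from the 376 non-planted pairs essentially perfectly. `demo/` contains
every intermediate artifact (`signatures.gmt`, `netmir.tsv`,
`associations.tsv`, `roc_report.tsv`, a provenance `manifest.json`), each of
which can also be produced stage by stage with the `simulate`, `signatures`,
`netmir`, `fit`, `enrich` and `validate` subcommands on your own files.

The same workflow from Python:

```python
from mirlassonet import SynthConfig, generate_all, run_pipeline

data = generate_all(SynthConfig(seed=17))
result = run_pipeline(data.expression, data.text, data.direct_targets,
                      data.ppi, data.gold)
print(result.mean_disease_auc)          # 1.0
print(result.fits[0].summary())         # per-disease coefficient table
```

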