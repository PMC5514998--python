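# turnoverscan

Phylogenetic comparative analysis of gene expression against cellular
turnover across human cell types and tissues.

Different cell types in one body live for very different times — from
~2 days for circulating monocytes to ~32,850 days (a lifetime) for
neocortical neurons. Treating per-tissue turnover (in days) as a
quantitative "cellular lifespan" trait, this package asks which genes'
expression tracks that trait across 21 somatic cell types and tissues,
while accounting for the fact that related tissues share expression by
descent: tissue mean profiles are not independent observations.

It is aimed at computational biologists analyzing a gene x sample
expression matrix (RNA-seq counts or pre-normalized values) together
with a per-tissue trait table.

## The model

For gene *g* with per-tissue mean log2 expression **y** and trait
**x** = log10(turnover days), the package fits the PGLS regression

```
y = b0 + b1 x + eps,    eps ~ N(0, sigma^2 V)
```

where **V** is an evolutionary covariance on the tissue tree — Brownian
motion (shared root-to-MRCA path lengths **C**), Pagel's lambda
(off-diagonals of **C** scaled by lambda in [0, 1]), or stationary
Ornstein-Uhlenbeck (exp(−alpha d) on patristic distances **d**). The
covariance family is chosen per gene by AIC from the gene's marginal
distribution, the slope is tested by GLS under the selected covariance,
and the genome-wide scan is FDR-controlled with Storey q-values
(default q ≤ 0.05). The tissue tree itself is built by neighbor joining
on 1 − Pearson expression distances with gene-resampling bootstrap
supports. A simulation-based phylogenetic ANOVA tests group-specific
expression (e.g. a muscle or neuron group against all other tissues),
and a leave-tissues-out re-scan probes robustness of the significant
set. See `docs/methods.md` for the full model description.

A synthetic-data generator produces tissue trees, turnover traits and
expression matrices (with replicates) under exactly these model
assumptions, with a planted, truth-tracked fraction of
turnover-correlated genes — so every stage of the pipeline is
verifiable end to end without any external data.

## Worked example

Simulate a 21-tissue, 1,000-gene dataset with 5% of genes linearly
dependent on log-turnover (|slope| uniform in [0.5, 1.0]), run the QC
and the scan, and score the result against the planted truth:

```python
import turnoverscan as ts

cfg = ts.SimulationConfig(n_tissues=21, n_genes=1000, frac_signal=0.05,
                          slope_range=(0.5, 1.0), sigma2=0.25, seed=7)
tree, trait, profiles, matrix, truth = ts.simulate_dataset(cfg)

qc = ts.qc_replicate_correlation(matrix)
print("min replicate r:", round(qc.min_pairwise_pearson.min(), 3))

table = ts.TurnoverTable.from_trait(trait)
results = ts.scan_genes(profiles, table, tree)
genes, n_neg, n_pos = ts.significant_set(results, 0.05)
print("significant:", len(genes), "negative:", n_neg, "positive:", n_pos)
print(ts.evaluate_against_truth(results, truth, 0.05))
```

prints

```
min replicate r: 0.957
significant: 51 negative: 27 positive: 24
{'n_genes': 1000, 'n_planted': 50, 'n_discoveries': 51,
 'n_false_discoveries': 3, 'fdp': 0.0588, 'power': 0.96,
 'slope_bias': 0.0131, 'model_recovery': 0.825}
```

Reading: simulated biological replicates correlate at ≥ 0.957 within
tissues (passing the 0.90 reproducibility bar used for real
replicates); the scan calls 51 genes at q ≤ 0.05, recovering 48 of the
50 planted genes (power 0.96) with 3 false discoveries (realized FDP
0.059, matching the nominal 0.05 rate in expectation) and essentially
unbiased slope estimates. The top hits' slopes (e.g. −0.97 for
`G00925`) estimate the change in log2 expression per decade of
turnover.

The same pipeline runs on real data by replacing the simulate step with
file inputs — a tab-separated expression matrix, a sample→tissue
metadata table, and a turnover table; the 21-tissue human turnover
table (monocytes 2 d … neurons 32,850 d) ships with the package at
`turnoverscan.turnover_fixture_path()`.

Command-line interface (mirrors the library):

```
turnoverscan simulate --n-tissues 21 --n-genes 1000 --frac-signal 0.05 \
    --seed 7 --out-dir ds/
turnoverscan scan --expression ds/expression.tsv --metadata ds/metadata.tsv \
    --turnover ds/turnover.tsv --tree ds/tree.nwk --out results.tsv
turnoverscan run --config config.yaml     # full pipeline + manifest
```

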