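# mrcae — multi-run concrete autoencoder feature selection

`mrcae` selects a **stable subset of actual features** (genes, lncRNAs, …)
from a high-dimensional expression matrix, entirely unsupervised, and then
asks two downstream questions about the selection: *can these features
identify the sample classes?* (stratified k-fold linear-SVM evaluation) and
*are they prognostic?* (median-split Kaplan–Meier / log-rank screening).

It is aimed at transcriptomics analyses — bulk or single-cell — where latent
embeddings (PCA, autoencoders) are unsatisfying because the downstream
biology needs *named* features, and where a single stochastic selection run
is unsatisfying because it is not reproducible.

## The method

A **concrete autoencoder (CAE)** replaces the encoder of an ordinary
autoencoder with a *concrete selection layer* of `k` nodes. Node `j` holds
logits `α_j ∈ R^n` over the `n` input features and, during training, draws a
relaxed one-hot weight vector from the concrete (Gumbel-softmax)
distribution

```
w_j = softmax((α_j + g) / T),   g ~ Gumbel(0,1) i.i.d.
```

encoding a sample `x` as `z_j = w_j · x`. A small MLP decoder (300-300,
leaky ReLU 0.1, 10% dropout) reconstructs all `n` features from the `k`
selections, trained by Adam (lr 0.002, 300 epochs) on mean squared error
with the temperature annealed exponentially `10 → 0.1`. As `T → 0` each node
commits to a single *actual* input feature.

Because the selection is stochastic, different runs pick different,
comparably informative subsets. The **multi-run system (mrCAE)** trains `R`
independent CAEs, counts for every feature the number of runs selecting it,
and ranks features by that frequency: the Top-N prefix is the *stable set*.
A feature's cross-run frequency is a direct stability score, in the spirit
of bootstrap support values.

For prognosis, each candidate feature's cohort is split at its median
expression (group A ≤ median, group B above), compared with the two-group
log-rank test, and assigned the hazard ratio `HR = (O_A/E_A)/(O_B/E_B)` from
the log-rank internals; a feature is flagged prognostic when `p ≤ 0.05` and
`HR ≠ 1`.

The concrete selection layer, its training loop and the survival statistics
are implemented in NumPy (with a few numba kernels on the hot paths);
scikit-learn provides splitting and the SVM; a synthetic-cohort module with
*planted* driver features and survival effects makes the whole pipeline
testable end-to-end with no data download.

## Worked example

```python
from mrcae import (SyntheticSpec, generate_expression, CAEConfig,
                   run_mrcae, build_frequency_table, top_n,
                   score_feature_set)

# a cohort of 500 samples x 200 features with 10 planted drivers
m, labels, drivers = generate_expression(SyntheticSpec(seed=11))

# 10 independent CAE runs, k = 10 features each
runs = run_mrcae(m, CAEConfig(k=10), n_runs=10, base_seed=100, labels=labels)
print("run 0 selected:", sorted(runs[0].selected_unique))

table = build_frequency_table(runs)
stable = top_n(table, 10)
print("stable Top-10:", stable.ranked)
print("drivers recovered:", len(stable.as_set() & set(drivers)), "/ 10")

metrics = score_feature_set(m, labels, stable.as_set(), n_folds=5, seed=0)
print(f"5-fold linear-SVM accuracy: {metrics.accuracy:.3f}")
```

Output:

```
run 0 selected: ['DEP0000', 'DRIVER001', 'DRIVER002', 'DRIVER003', 'DRIVER005',
 'DRIVER006', 'DRIVER007', 'DRIVER008', 'DRIVER009']
stable Top-10: [('DRIVER005', 10), ('DRIVER006', 10), ('DRIVER007', 10),
 ('DRIVER008', 9), ('DRIVER003', 8), ('DRIVER004', 8), ('DRIVER001', 5),
 ('DRIVER002', 5), ('DRIVER009', 5), ('DRIVER000', 4)]
drivers recovered: 10 / 10
5-fold linear-SVM accuracy: 1.000
```

A single run recovers most of the planted drivers (here 8 of 10, two
selector nodes having collapsed onto already-selected features and one pick
landing on a dependent proxy); the frequency-ranked Top-10 of the ten-run
system recovers all ten — the stability aggregation is exactly what repairs
single-run stochasticity.

The same flow is available from the shell:

```bash
mrcae simulate --seed 11 --out-prefix sim/
mrcae mrcae-run --in sim/expression.tsv --labels sim/labels.tsv \
      --k 10 --n-runs 10 --base-seed 100 --out-dir runs/
mrcae aggregate runs/run_*.json --top 10 --out stable.tsv
mrcae evaluate --in sim/expression.tsv --labels sim/labels.tsv \
      --features stable.tsv --folds 5 --seed 0 --out metrics.tsv
mrcae survival --in sim/expression.tsv --clinical sim/clinical.tsv \
      --features stable.tsv --out prognostic.tsv
```

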