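# assayscope

Bioactivity databases mix measurements from wildly different biological
assays — radioligand displacement on membranes, cAMP accumulation in cells,
kinase activity in biochemical preparations — and models trained on the
pooled data inherit that unexplained heterogeneity. The only assay-level
record that is almost always present is a short free-text description.
`assayscope` makes that text usable: it builds machine-readable descriptors
from assay descriptions and metadata, clusters similar assays into
interpretable topics, measures how much between-assay variance those
clusters explain, and trains proteochemometric (PCM) regression models that
consume compound, protein, and assay context jointly.

It is aimed at computational chemists and cheminformaticians who curate
ChEMBL/Papyrus-style exports and build bioactivity models on them.

## What it computes

* **Descriptors** (`assayscope.descriptors`) — metadata one-hot
  fingerprints (properties that are 100% defined with ≤ 40 categories),
  1024-bit binary bag-of-words over stemmed, stop-word-filtered
  descriptions, and dense embeddings behind a pluggable embedder contract
  (a deterministic hash-projection embedder ships with the package).
* **Topic clustering** (`assayscope.topics`) — unique descriptions are
  reduced to 5 dimensions with UMAP, density-clustered with HDBSCAN, and
  summarized with class-based TF-IDF
  `W(t,c) = tf(t,c) · ln(1 + A/f(t))`; density outliers are optionally
  reassigned to the most cosine-similar cluster. `AssayTopicModel.fit()`
  returns a results object with labels, topic words, and `summary()`.
* **Cluster evaluation** (`assayscope.evaluation`) — purity, normalized
  purity `(purity − p_modal)/(1 − p_modal)`, homogeneity / completeness /
  V-measure, adjusted mutual information, Fowlkes–Mallows.
* **Replicate variance** (`assayscope.variance`) — group-size-weighted mean
  absolute deviation of repeated (target, compound) measurements, overall
  and within assay clusters.
* **PCM models** (`assayscope.pcm`) — median-aggregated pChEMBL targets;
  ECFP6 molecule block, Hellberg z-scale protein block from a FASTA
  alignment, optional assay block; train-only variance/correlation feature
  filters; random and Bemis–Murcko scaffold splits; gradient-boosted trees
  with a masked multitask squared loss (`PCMModel.fit()` →
  `PCMResults` with metrics, importances, `summary()`).
* **Synthetic data** (`assayscope.synthetic`) — archetype-structured assay
  corpora and additive-effect bioactivity tables with full ground truth,
  so every stage is testable without downloads.

## Worked example

```python
import assayscope as ax

# 1000 synthetic assay descriptions from 5 archetypes, with ground truth
sim = ax.generate_assay_corpus(n_per_archetype=200, seed=7)
emb = ax.embed_descriptions(sim.corpus, ax.hash_projection_embedder(64, 0))
cfg = ax.ClusteringConfig(min_cluster_size=16, outlier_reduction=True, seed=0)
res = ax.AssayTopicModel(sim.corpus, emb, cfg).fit()
print(res.summary().to_string(index=False))

h, c, v = ax.homogeneity_completeness_v(res.record_labels, sim.true_archetype)
print(f"homogeneity={h:.3f} completeness={c:.3f}")
```

prints

```
 cluster  n_records  n_unique_descriptions                                      topic_words
       0        202                    202                gs, htrf, adenylyl, epac, accumul
       1        201                    201       flipr, transient, ionomycin, flux, calcium
       2        200                    200 phosphoryl, km, peptid, luminesc, autophosphoryl
       3        199                    199         growth, xtt, cytotox, cultur, antiprolif
       4        198                    198           125i, nonspecif, displac, 3h, competit
homogeneity=0.988 completeness=0.988
```

The five recovered topics correspond one-to-one to the five planted assay
archetypes (cAMP accumulation, calcium flux, enzyme inhibition, cell
proliferation, radioligand displacement — readable off the stemmed topic
words), and 98.8% label agreement says almost every description landed in
the right cluster.

Those clusters explain measurement variance:

```python
bio = ax.generate_bioactivity(n_targets=10, n_compounds_per_target=50, seed=7)
models = ax.fit_topic_model(bio.assays.corpus,
    ax.embed_descriptions(bio.assays.corpus, ax.hash_projection_embedder(64, 0)),
    ax.ClusteringConfig(min_cluster_size=16, seed=0), n_repeats=3)
rep = ax.deviation_report(bio.table, models=models)
print(f"overall MAD = {rep.overall_weighted_mad:.3f}")
print(f"within-cluster MAD = {rep.within_cluster_weighted_mad:.3f} ± {rep.within_cluster_sd:.3f}")
```

prints

```
overall MAD = 0.261
within-cluster MAD = 0.189 ± 0.017
```

i.e. repeated measurements of the same protein–compound pair deviate by
0.26 log units on average, and grouping measurements by fitted assay
cluster removes a substantial part of that deviation — the archetype
offsets the generator planted.

There is also a CLI over the same stages
(`assayscope simulate | filter | descriptors | cluster | evaluate |
variance | dataset | train`); every run writes a manifest with its
parameters, seeds and input hashes.

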