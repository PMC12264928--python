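# Methods

`assayscope` turns the free-text descriptions and categorical metadata of
biological assays into machine-usable context, and feeds that context into
bioactivity regression. This note records the models and procedures
implemented, the parameters that matter, what the synthetic data does and
does not emulate, and the numerical and design choices made where the
design was open.

## Data model and curation filters

An *assay record* is a free-text description plus categorical metadata
(assay type, BAO format, standard type, taxon, confidence score, source,
curation level, relationship type, preferred target name). A *bioactivity
point* is one (compound, target, assay) measurement expressed as a pChEMBL
value, i.e. −log10 of a molar activity/affinity, which puts IC50/EC50/Ki/KD
readouts on one log scale.

Curation follows the standard recipe for ChEMBL/Papyrus-style exports:

* keep binding (B) and functional (F) assays only;
* drop descriptions longer than 500 Unicode characters (counted after
  stripping surrounding whitespace; the boundary value 500 is retained —
  the rule is a strict "more than");
* drop censored values, low-quality flags, and compounds above 1000 Da;
* keep only targets with **more than** 100 unique compounds, applied *after*
  all row-level filters (the only order-sensitive step);
* an optional user-supplied exclusion list of assay/document identifiers
  covers removals that cannot be derived from the table itself (e.g.
  publications describing allosteric modulators).

Every filter appends its parameters and removal counts to the container's
provenance, so a processed table carries its own history.

## Assay descriptors

Three descriptor families, all row-aligned with the corpus:

* **Metadata fingerprint** — one-hot blocks over every metadata property
  that is 100% defined and has ≤ 40 categories. Each property block sums to
  exactly 1 per record; categories unseen when applying a trained
  fingerprint to new records produce an all-zero block plus a warning.
* **Bag-of-words fingerprint** — descriptions are lowercased, tokenized
  into alphanumeric runs of length ≥ 2 (digits kept, so tokens like `3h`
  and `cgs21680` survive), stop-word-filtered (scikit-learn's English list
  plus a configurable assay-specific list), and Porter-stemmed. Stop words
  are matched on surface forms *before* stemming, because stop lists are
  unstemmed words. The vocabulary is the top 1024 tokens by document
  frequency, ties broken lexicographically; bits are binary presence, not
  counts.
* **Embeddings** — any embedder satisfying a small contract (name, fixed
  dimension, 500-character input cap, determinism flag) plugs in;
  pretrained language models are adapters outside the test path. Each
  *unique* description is embedded once and broadcast to all records
  sharing it. The shipped `hash_projection_embedder` maps the 4096-bucket
  hashed token counts of a description through a seeded Gaussian matrix and
  L2-normalizes; by the Johnson–Lindenstrauss argument it approximately
  preserves token-count cosines (verified by Monte-Carlo at dimension 1024,
  where the deviation stays well under 0.15), which is the property the
  downstream clustering actually needs.

## Topic clustering

Unique descriptions (exact string equality after trimming) are clustered:

1. reduce embeddings to 5 dimensions with UMAP (15 neighbors, minimum
   distance 0.1, seeded and hence deterministic); a semisupervised mode
   passes categorical metadata labels as UMAP targets, with missing labels
   treated as unlabeled. A PCA reducer is available behind the same
   contract for fast tests — the contract, not the implementation, is
   normative;
2. density-cluster with HDBSCAN (scikit-learn implementation) at a minimum
   cluster size from {16, 32, 64, 128}; low-density points get label −1;
   non-outlier labels are relabeled 0..K−1 by descending cluster size;
3. weight tokens per cluster with class-based TF-IDF:
   `W(t, c) = tf(t, c) · ln(1 + A / f(t))`, where `tf(t, c)` counts token
   `t` in the concatenation of cluster `c`'s documents, `f(t)` is the
   token's total count, and `A` is the mean token count per cluster.
   Outlier documents are excluded from fitting;
4. topic words are the top-k tokens per cluster by weight (lexicographic
   tie-break; absent tokens never appear);
5. optional outlier reduction assigns each outlier document to the cluster
   whose c-TF-IDF row is most cosine-similar to the document's token-count
   vector (ties to the lower cluster id; zero-overlap documents go to the
   largest cluster, logged).

Because the reduction is stochastic across seeds, fits are repeated (3
repeats with distinct seeds by default) and downstream metrics are reported
as mean ± sd over repeats. Outlier reassignment operates at the level of
unique descriptions, and every record inherits the label of its unique
description.

## Cluster evaluation

Agreement between a clustering and categorical labels is scored with
purity, normalized purity, homogeneity/completeness/V-measure, adjusted
mutual information (arithmetic-mean normalization, permutation-model
expectation), and Fowlkes–Mallows. Normalized purity is

    (purity − p_modal) / (1 − p_modal)

with `p_modal` the prevalence of the most frequent label: 1 for label-pure
clusterings, 0 when clustering is no better than always predicting the
modal label, negative when worse. It is computed over records (weighting by
data volume), not over unique descriptions. Records with a missing label
are excluded per metric call, not corpus-wide. Entropies use natural logs;
the metrics are base-invariant because only entropy ratios enter (asserted
in the tests). Degenerate conventions: homogeneity is 1 when the category
entropy is 0, completeness is 1 when the cluster entropy is 0, and an AMI
with a zero denominator (both labelings trivial) is defined as 0 with a
warning.

## Replicate-variance decomposition

A replicate group is the set of pChEMBL values sharing (target, compound) —
optionally further keyed by assay cluster. The group statistic is the mean
absolute deviation (MAD) **about the group mean**; groups of size 1 carry no
deviation information and are excluded from both numerator and weights. The
corpus statistic is the group-size-weighted mean of per-group MADs.
Comparing the overall statistic with the within-cluster statistic (mean ±
sd over clustering repeats) quantifies how much between-assay variance the
clustering explains. The overall statistic pools all protein families; a
per-family breakdown is also reported when family labels are supplied.

## PCM modeling

Feature rows concatenate three blocks with recorded boundaries:

* **molecule** — 2048-bit ECFP6 (Morgan radius 3) on standardized
  structures (largest fragment kept, charges neutralized; RDKit);
* **protein** — Hellberg z-scales (z1 hydrophilicity, z2 size/bulk, z3
  polarity) per aligned position of a multiple sequence alignment read from
  FASTA; gaps and unknown residue codes encode as (0, 0, 0);
* **assay** (optional) — any descriptor family keyed by the row's context.

Measurements aggregate to the median pChEMBL (even counts: midpoint of the
two central values) per (compound, target) for the context-free control,
additionally per assay cluster for multitask models, or per unique
description for assay-descriptor models. At inference the caller supplies a
description (or its descriptor) alongside compound and protein.

Low-variance (< 0.05) columns are dropped first, then for every remaining
pair with |Pearson r| > 0.8 the later column is dropped; the mask is
computed on training rows only and applied to both splits. Splits are
90/10, either uniform random or by Bemis–Murcko scaffold: whole scaffold
groups are assigned to the test side — smallest groups first, in seeded
order among equal sizes, until the target fraction is reached — so no
scaffold ever appears on both sides and the realized fraction lands close
to the target whenever scaffolds are plentiful.

The regressor is a gradient-boosted tree ensemble (scikit-learn decision
trees as base learners) with a masked multitask squared loss: each round
fits one depth-8 tree per task on that task's observed residuals only, so
masked entries contribute nothing to the fit. Defaults: at most 1000 trees,
learning rate 0.1, minimum 50 points per leaf, 80% row subsampling per
tree, early stopping on masked R² over a seeded 10% holdout of the training
rows with a patience of 20 rounds (the realized tree count is the best
iteration). Single-task fitting is the one-column full-mask case of the
same code path, which is why a multitask model with one fully observed task
reproduces the single-task predictions bit for bit at a fixed seed.

Validation reports R², RMSE and Kendall's tau-b (tie-corrected) on the test
set, as mean ± sd over three repeats with different split seeds; multitask
metrics are computed per task on its observed entries and combined as the
task-size-weighted average, excluding tasks with fewer than 2 test points.
Feature importance is the cumulative squared-error reduction (tree impurity
decrease, which is additive) attributed to each feature over the used
trees, reported with descriptor-block attribution over the top 30 features.

## Synthetic data

The generator emulates the structure — not the content — of curated
ChEMBL/Papyrus exports:

* five assay archetypes (radioligand displacement, cAMP accumulation,
  calcium flux, enzyme inhibition, cell proliferation) with disjoint
  keyword pools and a shared filler vocabulary; descriptions are 8–20
  tokens, ~60% archetype keywords and ~40% filler; metadata is sampled from
  archetype-conditional distributions;
* bioactivity follows `pchembl = mu_t + beta_c + delta_archetype + eps`
  with `mu_t ~ N(6.5, 0.5²)` per target, `beta_c ~ N(0, 1)` per compound,
  `delta ~ N(0, offset_sd²)` drawn once per archetype, and Gaussian noise;
  each pair is measured in `Poisson(replicate_rate) + 1` assays with
  uniformly sampled archetypes;
* SMILES come from a packaged combinatorial drug-like library (1296
  RDKit-valid synthetic structures, 53 Bemis–Murcko scaffolds); protein
  sequences are equal-length mutants of a random consensus, hence
  pre-aligned.

Default study conditions used by the test suite and the acceptance script:
archetype recovery on 5 × 200 descriptions with 64-dimensional
hash-projection embeddings; variance decomposition on 10 targets × 50
compounds (replicate rate 2, offset sd 0.5, noise sd 0.3); PCM comparison
on 10 targets × 100 compounds (offset sd 0.7, noise sd 0.3) with three
split seeds. These sizes keep a full run on one CPU in minutes while
leaving every effect detectable.

What passing tests on this generator show: the pipeline recovers planted
archetype structure from token-level signal, the variance decomposition
recovers a known additive offset structure, and an assay-context block
carries predictive signal a context-free model cannot express. What they do
**not** show: performance on real free-text descriptions (paraphrase,
misspellings, protocol boilerplate, correlated vocabulary between
categories), real chemistry (activity cliffs, scaffold–activity coupling),
censored values, or non-additive assay effects — none of which the
generator simulates.

## Numerical choices

* MAD of a constant group returns exactly 0 (short-circuited before the
  floating-point mean).
* c-TF-IDF uses natural logarithm via `log1p`.
* Cluster relabeling and topic-word ordering break ties deterministically
  (cluster size then original id; weight then token).
* Correlation filter: NaN correlations (possible under constant slices)
  count as 0, i.e. never trigger a drop.
* The early-stopping monitor is skipped (all trees kept up to the maximum)
  when the holdout has fewer than 2 observed entries or zero target
  variance.
* All randomness flows through `numpy.random.default_rng` seeded per stage;
  per-tree seeds are drawn from the stage generator in a fixed order, which
  makes every fit bit-reproducible.

## Known limitations

* The hash-projection embedder captures token overlap only; it cannot
  resolve synonymy or word order, so it is a geometry stand-in for language
  models, not a replacement.
* The masked boosting ensemble fits one tree per task per round; with very
  many sparse tasks this is slower and less regularized than shared-tree
  multitask schemes.
* Scaffold splits treat acyclic molecules as one shared (empty) scaffold
  group, following the Bemis–Murcko convention.
* The curation step trusts the input table's quality flags; no SMILES
  validity checking happens at read time (standardization failures surface
  at featurization, as row-level errors).
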