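"""Neural-topic-style clustering of assay descriptions.

Pipeline (per fit): deduplicate descriptions, reduce their embeddings to a
low-dimensional manifold (UMAP by default, optionally supervised by
categorical labels), density-cluster with HDBSCAN, weight tokens per cluster
with class-based TF-IDF, extract topic words, and optionally reassign
density outliers to their most similar cluster by c-TF-IDF cosine.

The class-based TF-IDF weight of token ``t`` in cluster ``c`` is

    W(t, c) = tf(t, c) * ln(1 + A / f(t))

where ``tf(t, c)`` counts ``t`` in the concatenation of the cluster's
documents, ``f(t)`` is the total count of ``t`` over all clusters, and ``A``
is the mean token count per cluster.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import AssayCorpus
from .descriptors import DescriptorMatrix, preprocess_description
from .errors import ParameterError


@dataclass
class ClusteringConfig:
    """Knobs of the description-clustering pipeline."""

    n_components: int = 5
    n_neighbors: int = 15
    min_dist: float = 0.1
    min_cluster_size: int = 16
    supervision_labels: Sequence | None = None  # per unique description
    outlier_reduction: bool = True
    seed: int = 0
    reducer: str = "umap"  # "umap" or "pca" (fast surrogate honoring the contract)

    def __post_init__(self):
        if self.min_cluster_size < 2:
            raise ParameterError("min_cluster_size must be >= 2")
        if self.n_components < 2:
            raise ParameterError("n_components must be >= 2")


@dataclass
class ClusterAssignment:
    """Cluster label per unique description; -1 marks density outliers."""

    labels: np.ndarray
    description_index: dict[int, list[int]] | None = None  # unique idx -> record idxs

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == -1))


@dataclass
class CTFIDFModel:
    """Per-cluster token weights (clusters x vocabulary)."""

    vocabulary: list[str]
    weights: np.ndarray  # shape (n_clusters, n_vocab)
    cluster_ids: list[int]
    cluster_token_totals: np.ndarray = field(default=None)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)


def reduce_embeddings(embeddings: np.ndarray, config: ClusteringConfig) -> np.ndarray:
    """Reduce unique-description embeddings to ``config.n_components`` dims.

    UMAP (seeded, hence deterministic) by default; when
    ``config.supervision_labels`` is given the reduction is semisupervised
    with categorical targets (missing labels encoded as unlabeled).  The
    ``"pca"`` reducer is a fast linear surrogate honoring the same contract.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if config.reducer == "pca":
        from sklearn.decomposition import PCA
        k = min(config.n_components, n, embeddings.shape[1])
        reduced = PCA(n_components=k, random_state=config.seed).fit_transform(embeddings)
        if k < config.n_components:
            reduced = np.pad(reduced, ((0, 0), (0, config.n_components - k)))
        return reduced
    if n < config.n_neighbors + 1:
        raise ParameterError(
            f"{n} unique descriptions but n_neighbors={config.n_neighbors}; "
            "use a smaller n_neighbors")
    import umap  # deferred: numba compilation is slow at import

    y = None
    if config.supervision_labels is not None:
        series = pd.Series(list(config.supervision_labels))
        codes = pd.Categorical(series).codes.astype(int)  # -1 = missing/unlabeled
        y = codes
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        reducer = umap.UMAP(
            n_components=config.n_components, n_neighbors=config.n_neighbors,
            min_dist=config.min_dist, random_state=config.seed,
            target_metric="categorical",
        )
        reduced = reducer.fit_transform(embeddings, y=y)
    return np.asarray(reduced, dtype=float)


def cluster_reduced(reduced: np.ndarray, min_cluster_size: int) -> ClusterAssignment:
    """Density-cluster the reduced space with HDBSCAN.

    Non-outlier labels are relabeled 0..K-1 by descending cluster size;
    outliers keep label -1.
    """
    from sklearn.cluster import HDBSCAN

    reduced = np.asarray(reduced, dtype=float)
    if reduced.shape[0] < min_cluster_size:
        raise ParameterError("fewer points than min_cluster_size")
    raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit(reduced).labels_
    labels = np.full(raw.shape, -1, dtype=int)
    uniq, counts = np.unique(raw[raw >= 0], return_counts=True)
    order = sorted(zip(uniq, counts), key=lambda uc: (-uc[1], uc[0]))
    for new, (old, _) in enumerate(order):
        labels[raw == old] = new
    if not len(uniq):
        warnings.warn("HDBSCAN labeled every point an outlier")
    return ClusterAssignment(labels=labels)


def fit_ctfidf(documents: Sequence[Sequence[str]], labels: Sequence[int]) -> CTFIDFModel:
    """Fit class-based TF-IDF on tokenized documents with cluster labels.

    Documents labeled -1 (outliers) are excluded from fitting.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(documents):
        raise ParameterError("labels must cover documents")
    cluster_ids = sorted(set(labels[labels >= 0]))
    if not cluster_ids:
        raise ParameterError("need at least one non-outlier cluster")

    tf: dict[int, dict[str, int]] = {c: {} for c in cluster_ids}
    for doc, lab in zip(documents, labels):
        if lab < 0:
            continue
        counts = tf[lab]
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    empty = [c for c in cluster_ids if not tf[c]]
    if empty:
        warnings.warn(f"clusters {empty} have no tokens and were dropped from c-TF-IDF")
        cluster_ids = [c for c in cluster_ids if tf[c]]
        if not cluster_ids:
            raise ParameterError("no cluster has any tokens")

    vocabulary = sorted({tok for c in cluster_ids for tok in tf[c]})
    index = {t: j for j, t in enumerate(vocabulary)}
    tf_matrix = np.zeros((len(cluster_ids), len(vocabulary)))
    for i, c in enumerate(cluster_ids):
        for tok, cnt in tf[c].items():
            tf_matrix[i, index[tok]] = cnt

    f = tf_matrix.sum(axis=0)                  # total count of each token
    a = tf_matrix.sum() / len(cluster_ids)     # mean token count per cluster
    weights = tf_matrix * np.log1p(a / f)
    totals = tf_matrix.sum(axis=1)
    return CTFIDFModel(vocabulary=vocabulary, weights=weights,
                       cluster_ids=list(cluster_ids), cluster_token_totals=totals)


def topic_words(model: CTFIDFModel, k: int = 10) -> dict[int, list[str]]:
    """Top-k tokens per cluster by descending c-TF-IDF weight
    (lexicographic tie-break); tokens absent from a cluster never appear."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    out: dict[int, list[str]] = {}
    for i, c in enumerate(model.cluster_ids):
        row = model.weights[i]
        present = [(model.vocabulary[j], row[j]) for j in np.nonzero(row > 0)[0]]
        present.sort(key=lambda tw: (-tw[1], tw[0]))
        out[c] = [t for t, _ in present[:k]]
    return out


def reassign_outliers(
    model: CTFIDFModel,
    documents: Sequence[Sequence[str]],
    labels: Sequence[int],
) -> np.ndarray:
    """Assign each outlier document to the cluster whose c-TF-IDF row is most
    cosine-similar to the document's token-count vector.

    Non-outlier labels are untouched; ties go to the lower cluster id; a
    document with no vocabulary overlap goes to the largest cluster.
    """
    labels = np.asarray(labels, dtype=int).copy()
    out_idx = np.nonzero(labels == -1)[0]
    if len(out_idx) == 0:
        return labels
    index = {t: j for j, t in enumerate(model.vocabulary)}
    norms = np.linalg.norm(model.weights, axis=1)
    sizes = np.bincount(labels[labels >= 0], minlength=max(model.cluster_ids) + 1)
    largest = int(np.argmax(sizes))
    n_unmatched = 0
    for i in out_idx:
        vec = np.zeros(len(model.vocabulary))
        for tok in documents[i]:
            j = index.get(tok)
            if j is not None:
                vec[j] += 1
        vnorm = np.linalg.norm(vec)
        if vnorm == 0:
            labels[i] = largest
            n_unmatched += 1
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            cosines = (model.weights @ vec) / (norms * vnorm)
        cosines = np.nan_to_num(cosines, nan=-np.inf)
        best = int(np.argmax(cosines))  # argmax takes the first (lowest id) on ties
        labels[i] = model.cluster_ids[best]
    if n_unmatched:
        warnings.warn(f"{n_unmatched} outlier documents had no vocabulary overlap; "
                      "assigned to the largest cluster")
    return labels


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class TopicModelResults:
    """One fitted clustering of unique assay descriptions."""

    assignment: ClusterAssignment
    ctfidf: CTFIDFModel
    topic_words: dict[int, list[str]]
    config: ClusteringConfig
    seed: int
    unique_descriptions: list[str]
    record_labels: np.ndarray          # per corpus record
    assay_ids: list[str]
    pre_reduction_labels: np.ndarray   # unique-description labels before outlier reassignment

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.assignment.labels[self.assignment.labels >= 0])))

    def labels_by_assay(self) -> dict[str, int]:
        return dict(zip(self.assay_ids, (int(v) for v in self.record_labels)))

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.record_labels).value_counts().sort_index()

    def summary(self, top_k: int = 5) -> pd.DataFrame:
        """Per-cluster table: record count, unique descriptions, top words."""
        rows = []
        rec = pd.Series(self.record_labels).value_counts()
        uniq = pd.Series(self.assignment.labels).value_counts()
        for c in sorted(self.topic_words):
            rows.append({
                "cluster": c,
                "n_records": int(rec.get(c, 0)),
                "n_unique_descriptions": int(uniq.get(c, 0)),
                "topic_words": ", ".join(self.topic_words[c][:top_k]),
            })
        return pd.DataFrame(rows)

    def write_assignment(self, path: str | Path) -> None:
        desc_to_uid = {d: i for i, d in enumerate(self.unique_descriptions)}
        pre = self.pre_reduction_labels
        rows = []
        for assay_id, label, desc in zip(self.assay_ids, self.record_labels,
                                         self._record_descriptions):
            uid = desc_to_uid[desc]
            rows.append({"assay_id": assay_id, "unique_description_id": uid,
                         "cluster": int(label),
                         "is_reassigned_outlier": bool(pre[uid] == -1)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_topic_words(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {str(c): words for c, words in self.topic_words.items()}, indent=2))


class AssayTopicModel:
    """Topic model over an assay corpus and an embedding descriptor matrix.

    Parameters
    ----------
    corpus : AssayCorpus
        Records whose (deduplicated) descriptions are clustered.
    embeddings : DescriptorMatrix or ndarray
        Row-aligned dense embeddings of the descriptions.
    config : ClusteringConfig
    """

    def __init__(self, corpus: AssayCorpus, embeddings, config: ClusteringConfig | None = None):
        self.corpus = corpus
        values = embeddings.values if isinstance(embeddings, DescriptorMatrix) else np.asarray(embeddings)
        if values.shape[0] != len(corpus):
            raise ParameterError("embeddings are not row-aligned with the corpus")
        self.embeddings = np.asarray(values, dtype=float)
        self.config = config or ClusteringConfig()

        # deduplicate on whitespace-trimmed description
        keys = [r.description.strip() for r in corpus.records]
        self._record_keys = keys
        seen: dict[str, int] = {}
        first_rows = []
        for i, key in enumerate(keys):
            if key not in seen:
                seen[key] = len(first_rows)
                first_rows.append(i)
        self.unique_descriptions = [keys[i] for i in first_rows]
        self._unique_rows = np.asarray(first_rows)
        self._record_to_unique = np.asarray([seen[k] for k in keys])
        if len(self.unique_descriptions) < 2:
            raise ParameterError("corpus has fewer than 2 unique descriptions; nothing to cluster")

    def fit(self, seed: int | None = None) -> TopicModelResults:
        """Run reduce -> cluster -> c-TF-IDF -> topic words (-> outlier
        reassignment) once and return the fitted results."""
        config = replace(self.config, seed=self.config.seed if seed is None else seed)
        unique_embeddings = self.embeddings[self._unique_rows]
        reduced = reduce_embeddings(unique_embeddings, config)
        assignment = cluster_reduced(reduced, config.min_cluster_size)
        pre_labels = assignment.labels.copy()

        documents = [preprocess_description(d) for d in self.unique_descriptions]
        if np.all(assignment.labels == -1):
            raise ParameterError("every description is a density outlier; no clusters to model")
        ctfidf = fit_ctfidf(documents, assignment.labels)
        labels = assignment.labels
        if config.outlier_reduction:
            labels = reassign_outliers(ctfidf, documents, labels)
        final = ClusterAssignment(
            labels=labels,
            description_index={int(u): list(np.nonzero(self._record_to_unique == u)[0])
                               for u in range(len(self.unique_descriptions))})
        record_labels = labels[self._record_to_unique]
        result = TopicModelResults(
            assignment=final, ctfidf=ctfidf, topic_words=topic_words(ctfidf),
            config=config, seed=config.seed,
            unique_descriptions=list(self.unique_descriptions),
            record_labels=record_labels, assay_ids=list(self.corpus.assay_ids),
            pre_reduction_labels=pre_labels)
        result._record_descriptions = self._record_keys
        return result

    def fit_repeats(self, n_repeats: int = 3, base_seed: int | None = None) -> list[TopicModelResults]:
        """Fit ``n_repeats`` times with distinct seeds (stochastic pipeline;
        downstream metrics are reported as mean +/- sd over these repeats)."""
        base = self.config.seed if base_seed is None else base_seed
        return [self.fit(seed=base + i) for i in range(n_repeats)]


def fit_topic_model(
    corpus: AssayCorpus,
    embeddings,
    config: ClusteringConfig | None = None,
    n_repeats: int = 3,
) -> list[TopicModelResults]:
    """Functional wrapper: fit ``n_repeats`` topic models with distinct seeds."""
    return AssayTopicModel(corpus, embeddings, config).fit_repeats(n_repeats=n_repeats)
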