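"""Description clustering: c-TF-IDF, topic words, outlier reassignment,
reduction/clustering contracts and pipeline determinism."""

import math

import numpy as np
import pytest

from assayscope.corpus import AssayCorpus, AssayRecord
from assayscope.descriptors import embed_descriptions, hash_projection_embedder
from assayscope.errors import ParameterError
from assayscope.synthetic import generate_assay_corpus
from assayscope.topics import (
    AssayTopicModel, ClusteringConfig, cluster_reduced, fit_ctfidf,
    fit_topic_model, reassign_outliers, reduce_embeddings, topic_words)


def brute_force_ctfidf(documents, labels):
    """Independent c-TF-IDF: W(t,c) = tf(t,c) * ln(1 + A/f(t)) computed with
    plain dict arithmetic."""
    clusters = sorted({l for l in labels if l >= 0})
    tf = {c: {} for c in clusters}
    for doc, lab in zip(documents, labels):
        if lab < 0:
            continue
        for tok in doc:
            tf[lab][tok] = tf[lab].get(tok, 0) + 1
    vocab = sorted({t for c in clusters for t in tf[c]})
    f = {t: sum(tf[c].get(t, 0) for c in clusters) for t in vocab}
    a = sum(f.values()) / len(clusters)
    return {(c, t): tf[c].get(t, 0) * math.log(1 + a / f[t])
            for c in clusters for t in vocab}, vocab, clusters


def random_corpus(rng, n_docs, n_clusters):
    words = [f"w{i}" for i in range(12)]
    docs = [[words[rng.integers(len(words))] for _ in range(rng.integers(1, 8))]
            for _ in range(n_docs)]
    labels = rng.integers(0, n_clusters, size=n_docs)
    labels[0] = 0  # ensure at least one non-outlier cluster
    return docs, labels


class TestCTFIDF:
    def test_hand_example(self):
        # clusters: c0 = "a a b", c1 = "b c"; A = 2.5 tokens per cluster
        model = fit_ctfidf([["a", "a", "b"], ["b", "c"]], [0, 1])
        w = {(c, t): model.weights[i, j]
             for i, c in enumerate(model.cluster_ids)
             for j, t in enumerate(model.vocabulary)}
        assert w[(0, "a")] == pytest.approx(2 * math.log(1 + 2.5 / 2), abs=1e-10)
        assert w[(1, "c")] == pytest.approx(1 * math.log(1 + 2.5 / 1), abs=1e-10)
        assert w[(1, "a")] == 0.0  # token absent from cluster

    def test_single_cluster_monotone_in_tf(self):
        model = fit_ctfidf([["x", "x", "x", "y"]], [0])
        w = dict(zip(model.vocabulary, model.weights[0]))
        assert w["x"] > w["y"]

    def test_matches_brute_force_on_random_corpora(self, rng):
        for _ in range(30):
            docs, labels = random_corpus(rng, int(rng.integers(2, 11)),
                                         int(rng.integers(2, 5)))
            model = fit_ctfidf(docs, labels)
            expected, vocab, clusters = brute_force_ctfidf(docs, labels)
            assert model.vocabulary == vocab
            assert model.cluster_ids == clusters
            for i, c in enumerate(clusters):
                for j, t in enumerate(vocab):
                    assert model.weights[i, j] == pytest.approx(
                        expected[(c, t)], abs=1e-12)

    def test_outliers_excluded_from_fit(self):
        with_outlier = fit_ctfidf([["a"], ["b"], ["z", "z"]], [0, 1, -1])
        without = fit_ctfidf([["a"], ["b"]], [0, 1])
        assert with_outlier.vocabulary == without.vocabulary
        assert np.allclose(with_outlier.weights, without.weights)

    def test_no_cluster_is_error(self):
        with pytest.raises(ParameterError):
            fit_ctfidf([["a"]], [-1])


class TestTopicWords:
    def test_hand_example_top1(self):
        model = fit_ctfidf([["a", "a", "b"], ["b", "c"]], [0, 1])
        words = topic_words(model, k=1)
        assert words[0] == ["a"] and words[1] == ["c"]

    def test_k_larger_than_vocabulary(self):
        model = fit_ctfidf([["a", "b"]], [0])
        assert len(topic_words(model, k=99)[0]) == 2

    def test_equal_weights_break_lexicographically(self):
        model = fit_ctfidf([["b", "a"], ["c"]], [0, 1])
        assert topic_words(model, k=2)[0] == ["a", "b"]

    def test_absent_tokens_never_listed(self):
        model = fit_ctfidf([["a"], ["b"]], [0, 1])
        assert "b" not in topic_words(model, k=10)[0]


class TestReassignOutliers:
    def test_no_outliers_identity(self):
        model = fit_ctfidf([["a"], ["b"]], [0, 1])
        labels = reassign_outliers(model, [["a"], ["b"]], [0, 1])
        assert labels.tolist() == [0, 1]

    def test_outlier_equal_to_cluster_doc(self):
        docs = [["a", "a"], ["b", "b"], ["b", "b"]]
        model = fit_ctfidf(docs, [0, 1, -1])
        labels = reassign_outliers(model, docs, [0, 1, -1])
        assert labels.tolist() == [0, 1, 1]

    def test_hand_cosine_argmax(self):
        docs = [["a", "a", "b"], ["b", "c"], ["a", "b"]]
        model = fit_ctfidf(docs, [0, 1, -1])
        labels = reassign_outliers(model, docs, [0, 1, -1])
        # brute-force cosine of count vector (a:1, b:1) against both rows
        vec = np.array([1.0, 1.0, 0.0])  # vocabulary = [a, b, c]
        cosines = [model.weights[i] @ vec
                   / (np.linalg.norm(model.weights[i]) * np.linalg.norm(vec))
                   for i in range(2)]
        assert labels[2] == int(np.argmax(cosines))

    def test_zero_overlap_goes_to_largest_cluster(self):
        docs = [["a"], ["a"], ["b"], ["zzz"]]
        model = fit_ctfidf(docs, [0, 0, 1, -1])
        with pytest.warns(UserWarning, match="no vocabulary overlap"):
            labels = reassign_outliers(model, docs, [0, 0, 1, -1])
        assert labels[3] == 0

    def test_never_touches_non_outliers_and_removes_all_minus_one(self, rng):
        docs, labels = random_corpus(rng, 20, 3)
        labels = labels.copy()
        labels[5:9] = -1
        model = fit_ctfidf(docs, labels)
        out = reassign_outliers(model, docs, labels)
        assert np.all(out[labels >= 0] == labels[labels >= 0])
        assert np.all(out >= 0)


def blob_embeddings(rng, n_per_blob=200, n_blobs=2, dim=8, sep=30.0):
    centers = rng.normal(0, 1, size=(n_blobs, dim)) * sep
    points = np.vstack([centers[i] + rng.normal(0, 1, size=(n_per_blob, dim))
                        for i in range(n_blobs)])
    truth = np.repeat(np.arange(n_blobs), n_per_blob)
    return points, truth


class TestClusterReduced:
    def test_two_blobs_two_clusters(self, rng):
        points, truth = blob_embeddings(rng)
        assignment = cluster_reduced(points, min_cluster_size=16)
        assert assignment.n_clusters == 2
        assert (assignment.labels >= 0).mean() >= 0.95

    def test_min_cluster_size_contract(self, rng):
        points, _ = blob_embeddings(rng, n_per_blob=100)
        assignment = cluster_reduced(points, min_cluster_size=16)
        sizes = np.bincount(assignment.labels[assignment.labels >= 0])
        assert sizes.min() >= 16

    def test_uniform_noise_mostly_outliers(self, rng):
        points = rng.uniform(0, 1, size=(200, 5))
        with pytest.warns(UserWarning, match="outlier"):
            assignment = cluster_reduced(points, min_cluster_size=128)
        assert assignment.n_outliers >= 190

    def test_labels_ranked_by_size(self, rng):
        points = np.vstack([blob_embeddings(rng, n_per_blob=n)[0][:n]
                            for n in (150, 60)])
        points = np.vstack([rng.normal(0, 1, (150, 8)),
                            rng.normal(50, 1, (60, 8))])
        assignment = cluster_reduced(points, min_cluster_size=16)
        sizes = np.bincount(assignment.labels[assignment.labels >= 0])
        assert np.all(np.diff(sizes) <= 0)


class TestReduceEmbeddings:
    def test_output_shape_umap(self, rng):
        points = rng.normal(size=(120, 32))
        reduced = reduce_embeddings(points, ClusteringConfig(seed=0))
        assert reduced.shape == (120, 5)

    def test_umap_seeded_determinism(self, rng):
        points = rng.normal(size=(120, 16))
        config = ClusteringConfig(seed=3)
        assert np.array_equal(reduce_embeddings(points, config),
                              reduce_embeddings(points, config))

    def test_too_few_rows_parameter_error(self, rng):
        with pytest.raises(ParameterError, match="n_neighbors"):
            reduce_embeddings(rng.normal(size=(10, 4)), ClusteringConfig())

    def test_blob_separation_preserved(self, rng):
        points, truth = blob_embeddings(rng, n_per_blob=100, dim=16)
        reduced = reduce_embeddings(points, ClusteringConfig(seed=0, reducer="pca"))
        d_intra = np.linalg.norm(
            reduced[truth == 0] - reduced[truth == 0].mean(axis=0), axis=1).mean()
        d_inter = np.linalg.norm(reduced[truth == 0].mean(axis=0)
                                 - reduced[truth == 1].mean(axis=0))
        assert d_inter > d_intra

    def test_semisupervised_labels_accepted(self, rng):
        points, truth = blob_embeddings(rng, n_per_blob=60, dim=8)
        labels = [str(t) if i % 3 else None for i, t in enumerate(truth)]  # partial labels
        config = ClusteringConfig(seed=0, supervision_labels=labels)
        reduced = reduce_embeddings(points, config)
        assert reduced.shape == (120, 5)


@pytest.fixture(scope="module")
def sim():
    return generate_assay_corpus(n_per_archetype=60, seed=11)


@pytest.fixture(scope="module")
def embeddings(sim):
    return embed_descriptions(sim.corpus, hash_projection_embedder(32, 0))


class TestTopicModelPipeline:
    def test_pipeline_deterministic(self, sim, embeddings):
        config = ClusteringConfig(min_cluster_size=10, reducer="pca", seed=4)
        a = AssayTopicModel(sim.corpus, embeddings, config).fit()
        b = AssayTopicModel(sim.corpus, embeddings, config).fit()
        assert np.array_equal(a.record_labels, b.record_labels)
        assert a.topic_words == b.topic_words
        assert np.allclose(a.ctfidf.weights, b.ctfidf.weights)

    def test_repeats_have_distinct_seeds(self, sim, embeddings):
        config = ClusteringConfig(min_cluster_size=10, reducer="pca", seed=0)
        models = fit_topic_model(sim.corpus, embeddings, config, n_repeats=3)
        assert len({m.seed for m in models}) == 3

    def test_every_record_inherits_unique_description_label(self, sim, embeddings):
        config = ClusteringConfig(min_cluster_size=10, reducer="pca", seed=0)
        result = AssayTopicModel(sim.corpus, embeddings, config).fit()
        by_desc = {}
        for rec, lab in zip(sim.corpus.records, result.record_labels):
            key = rec.description.strip()
            assert by_desc.setdefault(key, lab) == lab

    def test_outlier_reduction_removes_all_outlier_labels(self, sim, embeddings):
        config = ClusteringConfig(min_cluster_size=10, reducer="pca", seed=0,
                                  outlier_reduction=True)
        result = AssayTopicModel(sim.corpus, embeddings, config).fit()
        assert np.all(result.record_labels >= 0)

    def test_all_identical_descriptions_rejected(self):
        records = [AssayRecord(f"A{i}", "same text", "B", "Ki", "BAO_1")
                   for i in range(20)]
        corpus = AssayCorpus(records)
        with pytest.raises(ParameterError, match="unique"):
            AssayTopicModel(corpus, np.zeros((20, 4)))

    def test_misaligned_embeddings_rejected(self, sim):
        with pytest.raises(ParameterError, match="aligned"):
            AssayTopicModel(sim.corpus, np.zeros((3, 4)))

    def test_assignment_tsv_roundtrip(self, sim, embeddings, tmp_path):
        import pandas as pd

        config = ClusteringConfig(min_cluster_size=10, reducer="pca", seed=0)
        result = AssayTopicModel(sim.corpus, embeddings, config).fit()
        result.write_assignment(tmp_path / "assign.tsv")
        frame = pd.read_csv(tmp_path / "assign.tsv", sep="\t")
        assert len(frame) == len(sim.corpus)
        assert (frame["cluster"].to_numpy() == result.record_labels).all()
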