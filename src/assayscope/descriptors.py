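"""Assay descriptors: metadata fingerprints, bag-of-words, text embeddings.

Three descriptor families turn assay records into numeric rows aligned with
the corpus:

* ``metadata_fp`` — one-hot blocks over fully defined categorical metadata
  properties with at most 40 categories;
* ``bow_fp`` — binary presence bits over a stemmed, stop-word-filtered
  vocabulary capped at 1024 terms;
* ``embedding`` — dense vectors produced by any embedder satisfying the
  :class:`EmbedderSpec` contract (pretrained language models plug in here;
  the shipped :func:`hash_projection_embedder` is a deterministic,
  dependency-free embedder whose geometry follows token-count cosines).
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._porter import porter_stem
from .corpus import ASSAY_METADATA_FIELDS, AssayCorpus
from .errors import DomainError, ParameterError

#: default assay-specific stop words; configurable, not ground truth
DEFAULT_ASSAY_STOPWORDS = frozenset({
    "assay", "human", "activity", "compound", "inhibition", "effect",
    "cells", "evaluated", "against",
})

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass
class DescriptorMatrix:
    """Dense descriptor matrix with rows aligned to corpus order."""

    values: np.ndarray
    kind: str  # one of {"metadata_fp", "bow_fp", "embedding"}
    feature_names: list[str] | None = None
    embedder_name: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.kind in ("metadata_fp", "bow_fp"):
            if self.feature_names is None or len(self.feature_names) != self.values.shape[1]:
                raise ParameterError("fingerprint matrices need feature_names matching columns")
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ParameterError(f"{self.kind} matrices must be binary")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save(self, path: str | Path) -> None:
        """Write values as whitespace-delimited text with a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.values, fmt="%.8g")
        sidecar = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "embedder_name": self.embedder_name,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorMatrix":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = np.atleast_2d(np.loadtxt(path))
        return cls(values=values, kind=sidecar["kind"],
                   feature_names=sidecar["feature_names"],
                   embedder_name=sidecar["embedder_name"], meta=sidecar.get("meta", {}))


@dataclass
class VocabularySpec:
    """Frozen bag-of-words vocabulary plus its preprocessing record."""

    terms: list[str]
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ParameterError("vocabulary terms must be unique")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"terms": self.terms, "preprocessing": self.preprocessing}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VocabularySpec":
        d = json.loads(Path(path).read_text())
        return cls(terms=d["terms"], preprocessing=d.get("preprocessing", {}))


@dataclass
class EmbedderSpec:
    """Contract an embedding backend must satisfy."""

    name: str
    dimension: int
    max_input_chars: int = 500
    deterministic: bool = True


# ---------------------------------------------------------------------------
# metadata fingerprints
# ---------------------------------------------------------------------------

def select_metadata_properties(
    corpus: AssayCorpus,
    required_coverage: float = 1.0,
    max_categories: int = 40,
) -> list[str]:
    """Metadata properties usable as one-hot blocks.

    A property qualifies when its non-missing coverage is at least
    ``required_coverage`` and it has at most ``max_categories`` unique
    categories; returned in the canonical field order.
    """
    if len(corpus) == 0:
        raise ParameterError("cannot select properties on an empty corpus")
    n = len(corpus)
    selected = []
    for prop in ASSAY_METADATA_FIELDS:
        values = [getattr(r, prop) for r in corpus.records]
        defined = [v for v in values if v is not None]
        coverage = len(defined) / n
        if coverage < required_coverage:
            continue
        if len(set(defined)) > max_categories or not defined:
            continue
        selected.append(prop)
    return selected


def build_metadata_fingerprint(corpus: AssayCorpus, properties: Sequence[str]) -> DescriptorMatrix:
    """One-hot encode the given metadata properties (one block per property).

    Every property must be fully defined on the corpus; within each record
    each property block sums to exactly 1.
    """
    n = len(corpus)
    categories: dict[str, list[str]] = {}
    for prop in properties:
        values = [getattr(r, prop) for r in corpus.records]
        if any(v is None for v in values):
            raise ParameterError(f"property {prop!r} is not fully defined on the corpus")
        categories[prop] = sorted(set(values))

    names = [f"{prop}={cat}" for prop in properties for cat in categories[prop]]
    matrix = np.zeros((n, len(names)), dtype=np.uint8)
    col = 0
    for prop in properties:
        index = {cat: col + j for j, cat in enumerate(categories[prop])}
        for i, rec in enumerate(corpus.records):
            matrix[i, index[getattr(rec, prop)]] = 1
        col += len(categories[prop])
    return DescriptorMatrix(values=matrix, kind="metadata_fp", feature_names=names,
                            meta={"properties": list(properties), "categories": categories})


def apply_metadata_fingerprint(corpus: AssayCorpus, reference: DescriptorMatrix) -> DescriptorMatrix:
    """Encode new records against a previously built fingerprint.

    Categories unseen at build time yield an all-zero block for that
    property, with a warning.
    """
    properties = reference.meta["properties"]
    categories = reference.meta["categories"]
    names = list(reference.feature_names)
    matrix = np.zeros((len(corpus), len(names)), dtype=np.uint8)
    col = 0
    unseen = 0
    for prop in properties:
        index = {cat: col + j for j, cat in enumerate(categories[prop])}
        for i, rec in enumerate(corpus.records):
            value = getattr(rec, prop)
            if value in index:
                matrix[i, index[value]] = 1
            else:
                unseen += 1
        col += len(categories[prop])
    if unseen:
        warnings.warn(f"{unseen} record/property values had categories unseen at build "
                      "time; encoded as all-zero blocks")
    return DescriptorMatrix(values=matrix, kind="metadata_fp", feature_names=names,
                            meta=dict(reference.meta))


# ---------------------------------------------------------------------------
# bag-of-words
# ---------------------------------------------------------------------------

def preprocess_description(
    text: str,
    language_stopwords: Iterable[str] | None = None,
    assay_stopwords: Iterable[str] | None = None,
) -> list[str]:
    """Tokenize a description: lowercase, alphanumeric runs of length >= 2,
    stop-word removal (surface forms, before stemming), Porter stemming.
    Order and duplicates are preserved."""
    lang = frozenset(language_stopwords) if language_stopwords is not None else ENGLISH_STOP_WORDS
    extra = frozenset(assay_stopwords) if assay_stopwords is not None else DEFAULT_ASSAY_STOPWORDS
    tokens = [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= 2]
    return [porter_stem(t) for t in tokens if t not in lang and t not in extra]


def build_bow_fingerprint(
    corpus: AssayCorpus,
    max_bits: int = 1024,
    language_stopwords: Iterable[str] | None = None,
    assay_stopwords: Iterable[str] | None = None,
) -> tuple[DescriptorMatrix, VocabularySpec]:
    """Binary bag-of-words fingerprint over preprocessed descriptions.

    The vocabulary is the ``max_bits`` tokens with highest document
    frequency (ties broken lexicographically); bits are presence, not
    counts.
    """
    if len(corpus) == 0:
        raise ParameterError("cannot build a bag of words on an empty corpus")
    docs = [preprocess_description(r.description, language_stopwords, assay_stopwords)
            for r in corpus.records]
    df_counts: dict[str, int] = {}
    for doc in docs:
        for tok in set(doc):
            df_counts[tok] = df_counts.get(tok, 0) + 1
    ranked = sorted(df_counts, key=lambda t: (-df_counts[t], t))
    terms = ranked[:max_bits]
    vocab = VocabularySpec(terms=terms, preprocessing={
        "stemmer": "porter",
        "token_rule": "lowercase alphanumeric runs, length >= 2",
        "language_stopwords": "sklearn-english" if language_stopwords is None else "custom",
        "assay_stopwords": sorted(assay_stopwords if assay_stopwords is not None
                                  else DEFAULT_ASSAY_STOPWORDS),
        "selection": f"top {max_bits} by document frequency, lexicographic ties",
    })
    matrix = bow_from_vocabulary(corpus, vocab, language_stopwords, assay_stopwords)
    matrix.meta["mean_bits_per_record"] = float(matrix.values.sum(axis=1).mean())
    return matrix, vocab


def bow_from_vocabulary(
    corpus: AssayCorpus,
    vocab: VocabularySpec,
    language_stopwords: Iterable[str] | None = None,
    assay_stopwords: Iterable[str] | None = None,
) -> DescriptorMatrix:
    """Reconstruct the binary matrix for a corpus from a frozen vocabulary."""
    index = {t: j for j, t in enumerate(vocab.terms)}
    matrix = np.zeros((len(corpus), len(vocab.terms)), dtype=np.uint8)
    for i, rec in enumerate(corpus.records):
        for tok in preprocess_description(rec.description, language_stopwords, assay_stopwords):
            j = index.get(tok)
            if j is not None:
                matrix[i, j] = 1
    return DescriptorMatrix(values=matrix, kind="bow_fp", feature_names=list(vocab.terms))


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

class HashProjectionEmbedder:
    """Deterministic text embedder: hashed token counts through a seeded
    Gaussian projection, L2-normalized.

    Approximately preserves cosine similarity of the underlying 4096-bucket
    hashed token-count vectors (Johnson–Lindenstrauss), which suffices to
    separate keyword-distinct assay archetypes.
    """

    n_buckets = 4096

    def __init__(self, dimension: int, seed: int, name: str | None = None):
        if dimension < 2:
            raise ParameterError("embedding dimension must be >= 2")
        self.spec = EmbedderSpec(name=name or f"hash-projection-{dimension}-s{seed}",
                                 dimension=dimension, deterministic=True)
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((self.n_buckets, dimension)) / np.sqrt(dimension)

    @staticmethod
    def _bucket(token: str) -> int:
        digest = hashlib.md5(token.encode("utf-8")).digest()
        return int.from_bytes(digest[:4], "little") % HashProjectionEmbedder.n_buckets

    def hashed_counts(self, text: str) -> np.ndarray:
        counts = np.zeros(self.n_buckets)
        for tok in preprocess_description(text):
            counts[self._bucket(tok)] += 1
        return counts

    def __call__(self, text: str) -> np.ndarray:
        vec = self.hashed_counts(text) @ self._projection
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def hash_projection_embedder(dimension: int, seed: int) -> HashProjectionEmbedder:
    """Factory for the deterministic hash-projection embedder."""
    return HashProjectionEmbedder(dimension=dimension, seed=seed)


def embed_descriptions(corpus: AssayCorpus, embedder) -> DescriptorMatrix:
    """Embed every unique description once and broadcast to all records
    sharing it.  ``embedder`` must expose ``.spec`` (:class:`EmbedderSpec`)
    and be callable on a string."""
    spec: EmbedderSpec = embedder.spec
    too_long = [r.assay_id for r in corpus.records
                if len(r.description) > spec.max_input_chars]
    if too_long:
        raise ParameterError(
            f"descriptions longer than {spec.max_input_chars} chars for records "
            f"{too_long[:5]}; filter the corpus first")
    cache: dict[str, np.ndarray] = {}
    rows = np.empty((len(corpus), spec.dimension))
    for i, rec in enumerate(corpus.records):
        key = rec.description.strip()
        if key not in cache:
            try:
                vec = np.asarray(embedder(rec.description), dtype=float)
            except Exception as exc:  # noqa: BLE001 - contract: name the record
                raise DomainError(f"embedder {spec.name!r} failed on record "
                                  f"{rec.assay_id!r}: {exc}") from exc
            if vec.shape != (spec.dimension,):
                raise DomainError(f"embedder {spec.name!r} returned shape {vec.shape}, "
                                  f"expected ({spec.dimension},)")
            cache[key] = vec
        rows[i] = cache[key]
    return DescriptorMatrix(values=rows, kind="embedding", embedder_name=spec.name,
                            meta={"n_unique_descriptions": len(cache)})
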