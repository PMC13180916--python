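"""Semantic features: age-of-acquisition norms, corpus-trained static
word embeddings, pairwise embedding-distance statistics, vocabulary
spectral clustering, and per-subject cluster-trajectory features.

Embeddings are trained on the cohort's own transcripts with function
words excluded. The estimator is a positive-PMI co-occurrence matrix
factorized by truncated SVD — a deterministic count-based member of the
word2vec family (it factorizes the same shifted-PMI objective skip-gram
approximates). Clustering is spectral on a cosine-affinity
nearest-neighbor graph, stratified by task.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._types import MISSING, AnnotatedTranscript, Task, Token

__all__ = [
    "EmbeddingModel",
    "ClusterModel",
    "aoa_stats",
    "train_embeddings",
    "embedding_distance_stats",
    "cluster_vocabulary",
    "cluster_trajectory_features",
]


def aoa_stats(tokens: Sequence[Token], aoa: dict[str, float]) -> dict[str, float]:
    """Mean/SD (sample) of word age of acquisition over in-lexicon
    tokens, plus the matched-token coverage fraction."""
    normalized = [t.normalized for t in tokens if t.is_word]
    ages = [aoa[w] for w in normalized if w in aoa]
    if not normalized or not ages:
        return {"aoa_mean": MISSING, "aoa_sd": MISSING, "aoa_coverage": 0.0}
    arr = np.asarray(ages)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {
        "aoa_mean": float(arr.mean()),
        "aoa_sd": sd,
        "aoa_coverage": len(ages) / len(normalized),
    }


@dataclass
class EmbeddingModel:
    vocabulary: list[str]
    vectors: np.ndarray  # (V, d), row i is vocabulary[i]
    manifest: dict

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("vocabulary/vector row mismatch")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def save(self, path: str | Path) -> None:
        """Plain-text word-vector format: word + d floats per line."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            for w, v in zip(self.vocabulary, self.vectors):
                fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with open(path) as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        vecs = np.asarray(rows, dtype=np.float64)
        if vecs.shape != (n, d):
            raise ValueError("word-vector file does not match its header")
        return cls(vocab, vecs, {"source": str(path)})


def _content_sentences(corpus: Iterable[AnnotatedTranscript]) -> list[list[str]]:
    sents = []
    for tr in corpus:
        for sent in tr.sentences:
            row = [t.normalized for t in sent if t.is_content]
            if row:
                sents.append(row)
    return sents


def train_embeddings(
    corpus: Iterable[AnnotatedTranscript],
    d: int = 100,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    min_vocab: int = 50,
    min_count: int = 1,
) -> EmbeddingModel:
    """Train static word embeddings on the transcripts' content words.

    Counts symmetric-window co-occurrences, forms the positive PMI
    matrix and takes a rank-``d`` truncated SVD; rows are scaled by the
    square root of the singular values. Fully deterministic (dense SVD
    with fixed component signs); ``seed`` is recorded in the manifest.
    ``epochs`` is recorded in the manifest for interface parity with
    iterative trainers; the count-based estimator needs a single pass.
    """
    sentences = _content_sentences(corpus)
    counts: dict[str, int] = {}
    for s in sentences:
        for w in s:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if len(vocab) < min_vocab:
        raise ValueError(
            f"corpus has {len(vocab)} content types < min_vocab={min_vocab}; "
            "import pretrained vectors instead"
        )
    index = {w: i for i, w in enumerate(vocab)}
    v = len(vocab)
    cooc = np.zeros((v, v), dtype=np.float64)
    for s in sentences:
        ids = [index[w] for w in s if w in index]
        for i, a in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    cooc[a, ids[j]] += 1.0
    total = cooc.sum()
    if total == 0:
        raise ValueError("no co-occurrences in corpus")
    row = cooc.sum(axis=1, keepdims=True)
    col = cooc.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(cooc * total / (row @ col))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    k = min(d, v - 1)
    # dense LAPACK SVD: bit-reproducible, unlike iterative solvers whose
    # restarts draw from process-global state on degenerate spectra
    u_full, s_full, _vt = np.linalg.svd(ppmi, full_matrices=False)
    u, s = u_full[:, :k], s_full[:k]
    # fix sign: largest-magnitude entry of each component positive
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    vectors = u * np.sqrt(s)
    if k < d:
        vectors = np.hstack([vectors, np.zeros((v, d - k))])
    corpus_hash = hashlib.sha256(
        "\n".join(" ".join(s) for s in sentences).encode()
    ).hexdigest()[:16]
    manifest = {
        "corpus_hash": corpus_hash, "d": d, "window": window,
        "epochs": epochs, "seed": seed, "estimator": "ppmi_svd",
    }
    return EmbeddingModel(vocab, vectors, manifest)


def _pair_stats(vectors: list[np.ndarray], pairs: list[tuple[int, int]]):
    eu, cos = [], []
    for i, j in pairs:
        a, b = vectors[i], vectors[j]
        eu.append(float(np.linalg.norm(a - b)))
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        cos.append(float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0)
    def _ms(x):
        arr = np.asarray(x)
        return float(arr.mean()), (float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
    return _ms(eu), _ms(cos)


def embedding_distance_stats(
    transcript: AnnotatedTranscript, model: EmbeddingModel
) -> dict[str, float]:
    """Embedding-distance statistics for the IMG and SVF tasks.

    Over consecutive in-vocabulary content-token pairs: mean/SD Euclidean
    distance and cosine similarity; over all unordered pairs of tokens:
    mean/SD Euclidean distance (plus cosine for symmetry).
    """
    if transcript.task == Task.PPE:
        raise ValueError("embedding distances are computed for IMG and SVF only")
    words = [t.normalized for t in transcript.tokens() if t.is_content]
    vecs = [model.vector(w) for w in words if w in model]
    keys = (
        "emb_consec_eucl_mean", "emb_consec_eucl_sd",
        "emb_consec_cos_mean", "emb_consec_cos_sd",
        "emb_pair_eucl_mean", "emb_pair_eucl_sd",
        "emb_pair_cos_mean", "emb_pair_cos_sd",
    )
    if len(vecs) < 2:
        return {k: MISSING for k in keys}
    consec = [(i, i + 1) for i in range(len(vecs) - 1)]
    allpairs = [(i, j) for i in range(len(vecs)) for j in range(i + 1, len(vecs))]
    (ce_m, ce_s), (cc_m, cc_s) = _pair_stats(vecs, consec)
    (pe_m, pe_s), (pc_m, pc_s) = _pair_stats(vecs, allpairs)
    return dict(zip(keys, (ce_m, ce_s, cc_m, cc_s, pe_m, pe_s, pc_m, pc_s)))


@dataclass
class ClusterModel:
    assignment: dict[str, int]  # word -> cluster id in 0..k-1
    centroids: np.ndarray  # (k, d)
    task: Task
    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if set(self.assignment.values()) - set(range(self.k)):
            raise ValueError("cluster ids must lie in 0..k-1")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "task": self.task.value, "k": self.k,
            "assignment": self.assignment,
            "centroids": [list(map(float, c)) for c in self.centroids],
        }, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(d["assignment"], np.asarray(d["centroids"]),
                   Task(d["task"]), d["k"])


def cluster_vocabulary(
    model: EmbeddingModel,
    k: int = 10,
    seed: int = 0,
    task: Task | str = Task.IMG,
    n_neighbors: int = 10,
) -> ClusterModel:
    """Spectral clustering of the embedding vocabulary.

    Affinity = (1 + cosine)/2 sparsified to the symmetrized
    ``n_neighbors``-nearest-neighbor graph; assignments are seeded.
    Centroids are mean embedding vectors per cluster.
    """
    v = len(model.vocabulary)
    if k > v:
        raise ValueError(f"k={k} exceeds vocabulary size {v}")
    if k == v:
        assignment = {w: i for i, w in enumerate(model.vocabulary)}
        return ClusterModel(assignment, model.vectors.copy(), Task(task), k)
    x = model.vectors
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    xn = x / norms
    aff = (1.0 + xn @ xn.T) / 2.0
    nb = min(n_neighbors, v - 1)
    # keep each row's nb strongest off-diagonal links, then symmetrize
    mask = np.zeros_like(aff, dtype=bool)
    a = aff.copy()
    np.fill_diagonal(a, -np.inf)
    idx = np.argpartition(-a, nb - 1, axis=1)[:, :nb]
    rows = np.repeat(np.arange(v), nb)
    mask[rows, idx.ravel()] = True
    mask |= mask.T
    sparse_aff = np.where(mask, aff, 0.0)
    np.fill_diagonal(sparse_aff, 1.0)

    from sklearn.cluster import SpectralClustering

    sc = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed,
        assign_labels="kmeans", n_init=10,
    )
    labels = sc.fit_predict(sparse_aff)
    # relabel clusters deterministically by first vocabulary occurrence
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    labels = np.array([remap[lab] for lab in labels])
    assignment = {w: int(lab) for w, lab in zip(model.vocabulary, labels)}
    centroids = np.vstack([
        x[labels == c].mean(axis=0) if np.any(labels == c) else np.zeros(x.shape[1])
        for c in range(k)
    ])
    return ClusterModel(assignment, centroids, Task(task), k)


def cluster_trajectory_features(
    tokens: Sequence[Token] | Sequence[str],
    cluster_model: ClusterModel,
) -> dict[str, float]:
    """Cluster-visit trajectory of a subject's in-vocabulary tokens.

    Emits: distinct clusters visited; transitions (consecutive pairs in
    different clusters); mean/SD words per visited cluster; revisits
    (transitions into an already-visited cluster); mean/SD Euclidean
    distance and cosine similarity over unordered pairs of distinct
    visited-cluster centroids. Out-of-vocabulary tokens are dropped.
    """
    words = [
        (t.normalized if isinstance(t, Token) else str(t)) for t in tokens
    ]
    seq = [cluster_model.assignment[w] for w in words
           if w in cluster_model.assignment]
    keys = (
        "clu_visited", "clu_transitions", "clu_words_per_cluster_mean",
        "clu_words_per_cluster_sd", "clu_revisits",
        "clu_centroid_eucl_mean", "clu_centroid_eucl_sd",
        "clu_centroid_cos_mean", "clu_centroid_cos_sd",
    )
    if not seq:
        return {k: MISSING for k in keys}
    visited: set[int] = {seq[0]}
    transitions = 0
    revisits = 0
    for prev, cur in zip(seq, seq[1:]):
        if cur != prev:
            transitions += 1
            if cur in visited:
                revisits += 1
            visited.add(cur)
    counts = {c: seq.count(c) for c in visited}
    cvals = np.asarray(list(counts.values()), dtype=float)
    out = {
        "clu_visited": float(len(visited)),
        "clu_transitions": float(transitions),
        "clu_words_per_cluster_mean": float(cvals.mean()),
        "clu_words_per_cluster_sd": float(cvals.std(ddof=1)) if cvals.size > 1 else 0.0,
        "clu_revisits": float(revisits),
    }
    vis = sorted(visited)
    if len(vis) < 2:
        out.update({k: MISSING for k in keys[5:]})
        return out
    cents = [cluster_model.centroids[c] for c in vis]
    pairs = [(i, j) for i in range(len(vis)) for j in range(i + 1, len(vis))]
    (e_m, e_s), (c_m, c_s) = _pair_stats(cents, pairs)
    out.update({
        "clu_centroid_eucl_mean": e_m, "clu_centroid_eucl_sd": e_s,
        "clu_centroid_cos_mean": c_m, "clu_centroid_cos_sd": c_s,
    })
    return out
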