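import math

import numpy as np
import pytest

from cogspeech._types import AnnotatedTranscript, Task, Token
from cogspeech.semantic import (
    ClusterModel,
    EmbeddingModel,
    aoa_stats,
    cluster_trajectory_features,
    cluster_vocabulary,
    embedding_distance_stats,
    train_embeddings,
)


def corpus_transcript(sentences, task=Task.IMG, upos="NOUN"):
    idx, sents = 0, []
    for s in sentences:
        sents.append([Token(w, w, upos, idx + k) for k, w in enumerate(s)])
        idx += len(s)
    return AnnotatedTranscript(task=task, sentences=sents, subject_id="c")


def shared_context_corpus():
    sents = []
    for i in range(150):
        sents.append([["gato", "perro"][i % 2], "come", "pienso", "casa"])
        sents.append(["mesa", "madera", "silla", "cocina"])
    sents += [[f"filler{i}", f"cosa{i % 7}", "objeto"] for i in range(60)]
    return corpus_transcript(sents)


class TestAoa:
    def test_hand_arithmetic(self):
        toks = [Token("perro", "perro", "NOUN", 0), Token("casa", "casa", "NOUN", 1)]
        s = aoa_stats(toks, {"perro": 3.0, "casa": 4.0})
        assert s["aoa_mean"] == pytest.approx(3.5)
        assert s["aoa_sd"] == pytest.approx(math.sqrt(0.5), abs=1e-9)
        assert s["aoa_coverage"] == 1.0

    def test_single_match_sd_zero(self):
        toks = [Token("perro", "perro", "NOUN", 0), Token("xq", "xq", "NOUN", 1)]
        s = aoa_stats(toks, {"perro": 3.0})
        assert s["aoa_sd"] == 0.0 and s["aoa_coverage"] == 0.5

    def test_no_match_flagged(self):
        toks = [Token("xq", "xq", "NOUN", 0)]
        s = aoa_stats(toks, {"perro": 3.0})
        assert math.isnan(s["aoa_mean"]) and s["aoa_coverage"] == 0.0


class TestEmbeddings:
    def test_shared_contexts_raise_cosine(self):
        m = train_embeddings([shared_context_corpus()], d=30, seed=1)

        def cos(a, b):
            va, vb = m.vector(a), m.vector(b)
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        assert cos("gato", "perro") > cos("gato", "mesa")

    def test_bit_reproducible(self):
        tr = shared_context_corpus()
        m1 = train_embeddings([tr], d=25, seed=3)
        m2 = train_embeddings([tr], d=25, seed=3)
        assert np.array_equal(m1.vectors, m2.vectors)

    def test_function_words_excluded(self):
        sents = [["gato", "el", "perro", "de", "casa"]] * 60
        idx, built = 0, []
        for s in sents:
            toks = []
            for k, w in enumerate(s):
                upos = "DET" if w == "el" else "ADP" if w == "de" else "NOUN"
                toks.append(Token(w, w, upos, idx + k))
            idx += len(s)
            built.append(toks)
        tr = AnnotatedTranscript(task=Task.IMG, sentences=built, subject_id="c")
        m = train_embeddings([tr], d=5, seed=0, min_vocab=3)
        assert "el" not in m.vocabulary and "de" not in m.vocabulary

    def test_small_corpus_rejected(self):
        tr = corpus_transcript([["a", "b", "c"]])
        with pytest.raises(ValueError, match="min_vocab"):
            train_embeddings([tr], min_vocab=50)

    def test_text_roundtrip(self, tmp_path):
        m = train_embeddings([shared_context_corpus()], d=10, seed=0)
        m.save(tmp_path / "vec.txt")
        back = EmbeddingModel.load(tmp_path / "vec.txt")
        assert back.vocabulary == m.vocabulary
        assert np.array_equal(back.vectors, m.vectors)


def toy_model(vectors):
    vocab = sorted(vectors)
    return EmbeddingModel(vocab, np.array([vectors[w] for w in vocab], float), {})


class TestDistanceStats:
    def test_identical_vectors(self):
        m = toy_model({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        tr = corpus_transcript([["a", "b"]])
        s = embedding_distance_stats(tr, m)
        assert s["emb_consec_cos_mean"] == pytest.approx(1.0)
        assert s["emb_consec_eucl_mean"] == pytest.approx(0.0)

    def test_all_pairs_match_enumeration(self):
        vecs = {"a": [0.0, 0.0], "b": [3.0, 0.0], "c": [0.0, 4.0]}
        m = toy_model(vecs)
        tr = corpus_transcript([["a", "b", "c"]])
        s = embedding_distance_stats(tr, m)
        dists = [3.0, 4.0, 5.0]  # brute-force pair loop over (a,b),(a,c),(b,c)
        assert s["emb_pair_eucl_mean"] == pytest.approx(np.mean(dists))
        assert s["emb_pair_eucl_sd"] == pytest.approx(np.std(dists, ddof=1))

    def test_ppe_refused(self):
        m = toy_model({"a": [1.0, 0.0]})
        tr = corpus_transcript([["a", "a"]], task=Task.PPE)
        with pytest.raises(ValueError, match="IMG and SVF"):
            embedding_distance_stats(tr, m)


class TestClustering:
    def test_blob_recovery(self, rng):
        c1, c2 = np.array([4, 0, 0, 0, 0.0]), np.array([0, 4, 0, 0, 0.0])
        vecs = np.vstack([c1 + rng.normal(0, 0.3, (30, 5)),
                          c2 + rng.normal(0, 0.3, (30, 5))])
        m = EmbeddingModel([f"w{i}" for i in range(60)], vecs, {})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cluster_vocabulary(m, k=2, seed=0)
        lab = np.array([cm.assignment[w] for w in m.vocabulary])
        agree = max(np.mean(lab[:30] == 0) + np.mean(lab[30:] == 1),
                    np.mean(lab[:30] == 1) + np.mean(lab[30:] == 0)) / 2
        assert agree >= 0.95

    def test_k_equals_vocab_gives_singletons(self):
        m = toy_model({f"w{i}": [float(i), 1.0] for i in range(6)})
        cm = cluster_vocabulary(m, k=6, seed=0)
        assert sorted(cm.assignment.values()) == list(range(6))

    def test_seeded_determinism(self, rng):
        vecs = rng.normal(size=(40, 6))
        m = EmbeddingModel([f"w{i}" for i in range(40)], vecs, {})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cluster_vocabulary(m, k=4, seed=9).assignment
            b = cluster_vocabulary(m, k=4, seed=9).assignment
        assert a == b

    def test_k_above_vocab_rejected(self):
        m = toy_model({"a": [1.0, 0], "b": [0, 1.0]})
        with pytest.raises(ValueError):
            cluster_vocabulary(m, k=3)

    def test_json_roundtrip(self, tmp_path, rng):
        m = toy_model({f"w{i}": rng.normal(size=3).tolist() for i in range(8)})
        cm = cluster_vocabulary(m, k=8, seed=0)
        cm.save(tmp_path / "c.json")
        back = ClusterModel.load(tmp_path / "c.json")
        assert back.assignment == cm.assignment and back.k == cm.k


def make_cluster_model(assignment, k, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    cents = rng.normal(size=(k, dim))
    return ClusterModel(assignment, cents, Task.SVF, k)


def ref_trajectory(seq):
    """Independent linear recount of the trajectory statistics."""
    visited, transitions, revisits = {seq[0]}, 0, 0
    for prev, cur in zip(seq, seq[1:]):
        if cur != prev:
            transitions += 1
            if cur in visited:
                revisits += 1
            visited.add(cur)
    return len(visited), transitions, revisits


class TestTrajectories:
    @pytest.mark.parametrize("seq,expect", [
        ([1, 1, 2, 1, 3], (3, 3, 1)),
        ([1, 2, 1, 2], (2, 3, 2)),
        ([0, 0, 0], (1, 0, 0)),
    ])
    def test_linear_scan_examples(self, seq, expect):
        k = max(seq) + 2
        words = [f"w{i}" for i in range(len(seq))]
        cm = make_cluster_model(dict(zip(words, seq)), k)
        f = cluster_trajectory_features(words, cm)
        assert (f["clu_visited"], f["clu_transitions"], f["clu_revisits"]) == \
            tuple(map(float, expect))

    def test_single_cluster_pairwise_missing(self):
        cm = make_cluster_model({"a": 0, "b": 0}, 2)
        f = cluster_trajectory_features(["a", "b", "a"], cm)
        assert f["clu_visited"] == 1.0 and f["clu_transitions"] == 0.0
        assert math.isnan(f["clu_centroid_eucl_mean"])

    def test_matches_bruteforce_on_random_sequences(self, rng):
        k = 6
        words = [f"w{i}" for i in range(50)]
        for _ in range(1000):
            assign = {w: int(rng.integers(k)) for w in words}
            cm = make_cluster_model(assign, k)
            n = int(rng.integers(1, 30))
            toks = [words[int(rng.integers(50))] for _ in range(n)]
            f = cluster_trajectory_features(toks, cm)
            seq = [assign[w] for w in toks]
            v, t, r = ref_trajectory(seq)
            assert (f["clu_visited"], f["clu_transitions"], f["clu_revisits"]) \
                == (float(v), float(t), float(r))
            # invariants
            assert t <= len(seq) - 1 and r <= t and v <= min(cm.k, len(seq))

    def test_oov_tokens_dropped(self):
        cm = make_cluster_model({"a": 0, "b": 1}, 2)
        f_with = cluster_trajectory_features(["a", "zzz", "b"], cm)
        f_without = cluster_trajectory_features(["a", "b"], cm)
        assert f_with == f_without
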