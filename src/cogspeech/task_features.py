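"""Task-specific features.

IMG: spatial semantic-graph features over content information units
(CIUs) of the described picture — each CIU has normalized image
coordinates (origin top-left, [0,1]x[0,1]) and a quadrant.
SVF: animal-list statistics (repetitions, intrusions, repetition gaps).
PPE: sentiment/emotion scores through a pluggable backend; the shipped
default is a deterministic keyword-counting backend for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from ._types import MISSING, Token

__all__ = [
    "CIUMention",
    "SentimentScores",
    "default_ciu_lexicon",
    "detect_ciu_mentions",
    "ciu_graph_features",
    "svf_features",
    "sentiment_features",
    "KeywordSentimentBackend",
    "register_sentiment_backend",
    "get_sentiment_backend",
]


@dataclass(frozen=True)
class CIUMention:
    ciu_id: str
    start: int  # token span [start, end) over the token list scanned
    end: int
    x: float
    y: float
    quadrant: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CIU mention span must be non-empty")


def default_ciu_lexicon() -> dict[str, dict]:
    """Editable picture-scene CIU inventory shipped with the package.

    This is a synthetic stand-in layout (plausible keywords and
    coordinates for a kitchen-scene description), not measured from any
    published picture; replace it with a study-specific inventory via
    ``io.load_lexicon(path, "ciu")`` for real analyses. Tests rely on
    the scene generator instead, so this resource is not load-bearing.
    """
    import importlib.resources
    import json

    from ._types import normalize_token

    text = (importlib.resources.files("cogspeech") / "resources"
            / "ciu_scene_synthetic.json").read_text()
    out = {}
    for e in json.loads(text):
        key = " ".join(normalize_token(w) for w in str(e["keyword"]).split())
        out[key] = {"ciu_id": e["ciu_id"], "x": float(e["x"]),
                    "y": float(e["y"]), "quadrant": e["quadrant"]}
    return out


def _normalized_words(tokens: Sequence[Token] | Sequence[str]) -> list[str]:
    out = []
    for t in tokens:
        if isinstance(t, Token):
            out.append(t.normalized if t.is_word else "")
        else:
            out.append(str(t).lower())
    return out


def detect_ciu_mentions(
    tokens: Sequence[Token] | Sequence[str],
    ciu_lexicon: dict[str, dict],
) -> list[CIUMention]:
    """Leftmost-longest keyword scan over normalized tokens.

    Multiword keys (space-separated in the lexicon) are matched as
    contiguous token runs; overlaps resolve to the leftmost, then
    longest, match.
    """
    words = _normalized_words(tokens)
    keys = {tuple(k.split()): v for k, v in ciu_lexicon.items()}
    max_len = max((len(k) for k in keys), default=1)
    mentions: list[CIUMention] = []
    i = 0
    n = len(words)
    while i < n:
        matched = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = tuple(words[i:i + length])
            if cand in keys:
                matched = (length, keys[cand])
                break
        if matched is None:
            i += 1
            continue
        length, entry = matched
        mentions.append(CIUMention(
            ciu_id=str(entry["ciu_id"]), start=i, end=i + length,
            x=float(entry["x"]), y=float(entry["y"]),
            quadrant=str(entry["quadrant"]),
        ))
        i += length
    return mentions


_QUADRANTS = ("UL", "UR", "LL", "LR")


def ciu_graph_features(
    mentions: Sequence[CIUMention],
    ciu_lexicon: dict[str, dict],
    total_words: int,
) -> dict[str, float]:
    """Spatial trajectory features over the ordered CIU mentions.

    Distances are Euclidean in normalized image coordinates; the
    "distance between different CIUs" averages over consecutive pairs of
    *distinct* mentions (self-transitions travel 0 and are excluded from
    that mean). Words-per-CIU attributes the tokens between consecutive
    mention onsets to the earlier CIU (tail tokens to the last).
    """
    quadrant_inventory = {q: 0 for q in _QUADRANTS}
    seen_ids: dict[str, str] = {}
    for entry in ciu_lexicon.values():
        cid = str(entry["ciu_id"])
        if cid not in seen_ids:
            seen_ids[cid] = entry["quadrant"]
            quadrant_inventory[entry["quadrant"]] += 1

    out: dict[str, float] = {}
    ids = [m.ciu_id for m in mentions]
    distinct = list(dict.fromkeys(ids))
    out["ciu_count"] = float(len(distinct))
    out["ciu_mentions"] = float(len(ids))
    mention_tokens = sum(m.end - m.start for m in mentions)
    out["ciu_concreteness"] = (
        mention_tokens / total_words if total_words > 0 else MISSING
    )

    # repetitions
    consecutive_rep = sum(1 for a, b in zip(ids, ids[1:]) if a == b)
    rep_total = len(ids) - len(distinct)
    out["ciu_rep_consecutive"] = float(consecutive_rep)
    out["ciu_rep_nonconsecutive"] = float(rep_total - consecutive_rep)

    # per-quadrant coverage: distinct CIUs mentioned / CIUs in quadrant
    mentioned_by_quadrant = {q: set() for q in _QUADRANTS}
    for m in mentions:
        mentioned_by_quadrant[m.quadrant].add(m.ciu_id)
    for q in _QUADRANTS:
        inv = quadrant_inventory[q]
        out[f"ciu_coverage_{q.lower()}"] = (
            len(mentioned_by_quadrant[q]) / inv if inv > 0 else MISSING
        )

    if len(mentions) < 2:
        for k in ("ciu_dist_mean", "ciu_dx_mean", "ciu_dx_sd", "ciu_dy_mean",
                  "ciu_dy_sd", "ciu_same_quadrant_transitions",
                  "ciu_cross_to_same_quadrant_ratio"):
            out[k] = MISSING
        out["ciu_words_per_ciu_mean"] = (
            float(total_words) if len(mentions) == 1 else MISSING
        )
        return out

    dists, dxs, dys = [], [], []
    same_q = 0
    cross_q = 0
    for a, b in zip(mentions, mentions[1:]):
        dx, dy = abs(b.x - a.x), abs(b.y - a.y)
        dxs.append(dx)
        dys.append(dy)
        if a.ciu_id != b.ciu_id:
            dists.append(math.hypot(b.x - a.x, b.y - a.y))
            if a.quadrant == b.quadrant:
                same_q += 1
            else:
                cross_q += 1
    out["ciu_dist_mean"] = float(np.mean(dists)) if dists else MISSING
    out["ciu_dx_mean"] = float(np.mean(dxs))
    out["ciu_dx_sd"] = float(np.std(dxs, ddof=1)) if len(dxs) > 1 else 0.0
    out["ciu_dy_mean"] = float(np.mean(dys))
    out["ciu_dy_sd"] = float(np.std(dys, ddof=1)) if len(dys) > 1 else 0.0
    out["ciu_same_quadrant_transitions"] = float(same_q)
    out["ciu_cross_to_same_quadrant_ratio"] = (
        cross_q / same_q if same_q > 0 else MISSING
    )

    # words per CIU: onset-to-onset windows, tail to the last mention
    onsets = [m.start for m in mentions]
    spans = [b - a for a, b in zip(onsets, onsets[1:])]
    spans.append(max(total_words - onsets[-1], mentions[-1].end - mentions[-1].start))
    out["ciu_words_per_ciu_mean"] = float(np.mean(spans))
    return out


def svf_features(
    tokens: Sequence[Token] | Sequence[str],
    animal_lexicon: dict[str, str],
) -> dict[str, float]:
    """Animal-naming statistics for the one-minute fluency task.

    The animal sequence is the ordered list of lexicon matches with
    variants canonicalized. Repetition gaps count the animal mentions
    strictly between a repeat and its most recent prior occurrence
    (intrusions excluded from the gap count).
    """
    words = _normalized_words(tokens)
    if isinstance(tokens[0] if tokens else "", Token):
        content = [t for t in tokens if isinstance(t, Token) and t.is_content]
        content_words = [t.normalized for t in content]
    else:
        content_words = [w for w in words if w]
    animals = [animal_lexicon[w] for w in words if w in animal_lexicon]
    total = len(animals)
    unique = len(set(animals))
    out: dict[str, float] = {
        "svf_total_animals": float(total),
        "svf_unique_animals": float(unique),
        "svf_repeated_animals": float(total - unique),
    }
    if total == 0:
        out["svf_unique_proportion"] = MISSING
        out["svf_nonanimal_proportion"] = MISSING
        out["svf_repetition_gap_sum"] = 0.0
        out["svf_repetition_gap_mean"] = MISSING
        return out
    out["svf_unique_proportion"] = unique / total
    n_content = len(content_words)
    n_animal_content = sum(1 for w in content_words if w in animal_lexicon)
    out["svf_nonanimal_proportion"] = (
        (n_content - n_animal_content) / n_content if n_content > 0 else MISSING
    )
    gaps: list[int] = []
    last_pos: dict[str, int] = {}
    for pos, a in enumerate(animals):
        if a in last_pos:
            gaps.append(pos - last_pos[a] - 1)
        last_pos[a] = pos
    out["svf_repetition_gap_sum"] = float(sum(gaps))
    out["svf_repetition_gap_mean"] = float(np.mean(gaps)) if gaps else MISSING
    return out


# ---------------------------------------------------------------------------
# Sentiment backends


@dataclass(frozen=True)
class SentimentScores:
    positive: float
    negative: float
    neutral: float
    sadness: float = 0.0
    happiness: float = 0.0
    anger: float = 0.0
    disgust: float = 0.0
    fear: float = 0.0
    surprise: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0, 1]")
        if abs(self.positive + self.negative + self.neutral - 1.0) > 1e-6:
            raise ValueError("sentiment triple must sum to 1")

    def as_features(self) -> dict[str, float]:
        return {f"ts_sentiment_{k}_ppe": getattr(self, k)
                for k in self.__dataclass_fields__}


class SentimentBackend(Protocol):
    def __call__(self, text: str) -> SentimentScores: ...


_DEFAULT_POSITIVE = ("feliz", "alegre", "bonito", "bien", "genial", "amor",
                     "happy", "great", "good", "wonderful", "love", "joy")
_DEFAULT_NEGATIVE = ("triste", "mal", "horrible", "miedo", "enfado", "asco",
                     "sad", "bad", "awful", "fear", "angry", "disgust")
_DEFAULT_EMOTIONS = {
    "sadness": ("triste", "llorar", "sad", "cry"),
    "happiness": ("feliz", "alegre", "happy", "joy"),
    "anger": ("enfado", "rabia", "angry", "rage"),
    "disgust": ("asco", "disgust", "gross"),
    "fear": ("miedo", "fear", "scared"),
    "surprise": ("sorpresa", "surprise", "surprised"),
}


class KeywordSentimentBackend:
    """Deterministic keyword-counting sentiment scorer.

    Counts valence and emotion keywords over lowercased tokens and
    normalizes; empty or keyword-free text scores neutral = 1. Serves as
    the shipped test backend; transformer backends can be registered
    under the same contract.
    """

    def __init__(self, positive=_DEFAULT_POSITIVE, negative=_DEFAULT_NEGATIVE,
                 emotions=None):
        self.positive = frozenset(positive)
        self.negative = frozenset(negative)
        self.emotions = {k: frozenset(v)
                         for k, v in (emotions or _DEFAULT_EMOTIONS).items()}

    def __call__(self, text: str) -> SentimentScores:
        words = [w.strip(".,;:!?¡¿\"'").lower() for w in text.split()]
        pos = sum(1 for w in words if w in self.positive)
        neg = sum(1 for w in words if w in self.negative)
        total = pos + neg
        if total == 0:
            triple = (0.0, 0.0, 1.0)
        else:
            triple = (pos / total, neg / total, 0.0)
        emo_counts = {k: sum(1 for w in words if w in v)
                      for k, v in self.emotions.items()}
        emo_total = sum(emo_counts.values())
        emo = {k: (c / emo_total if emo_total else 0.0)
               for k, c in emo_counts.items()}
        return SentimentScores(positive=triple[0], negative=triple[1],
                               neutral=triple[2], **emo)


_BACKENDS: dict[str, Callable[[], SentimentBackend]] = {
    "keyword": KeywordSentimentBackend,
}


def register_sentiment_backend(name: str,
                               factory: Callable[[], SentimentBackend]) -> None:
    _BACKENDS[name] = factory


def get_sentiment_backend(name: str = "keyword") -> SentimentBackend:
    if name not in _BACKENDS:
        raise KeyError(f"unknown sentiment backend {name!r}; "
                       f"registered: {sorted(_BACKENDS)}")
    return _BACKENDS[name]()


def sentiment_features(text: str,
                       backend: SentimentBackend | str = "keyword"
                       ) -> SentimentScores:
    """Score a PPE narrative with the configured sentiment backend."""
    if isinstance(backend, str):
        backend = get_sentiment_backend(backend)
    return backend(text)
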