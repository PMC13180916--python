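"""Lexical features: POS-category ratios, lexical-diversity indices
(MTLD, MATTR, Guiraud/Herdan/Maas/Uber) and word-frequency statistics.

POS-based features apply only to the picture-description (IMG) and
personal-experience (PPE) tasks; frequency-based features apply to all
three tasks. Diversity metrics operate on normalized surface forms
(no lemmatization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._types import MISSING, AnnotatedTranscript, Task, Token

__all__ = [
    "DiversityConfig",
    "pos_category_ratios",
    "mtld",
    "mattr",
    "richness_indices",
    "log_frequency_stats",
    "lexical_feature_vector",
]


@dataclass(frozen=True)
class DiversityConfig:
    """Defaults follow the study protocol: MTLD at thresholds 0.65/0.70/0.75,
    MATTR with a 10-token window and 5-token stride, and content-only
    recomputation restricted to nouns, verbs, adjectives and adverbs."""

    mtld_thresholds: tuple[float, ...] = (0.65, 0.70, 0.75)
    mattr_window: int = 10
    mattr_stride: int = 5
    content_upos: frozenset[str] = frozenset({"NOUN", "VERB", "ADJ", "ADV"})

    def __post_init__(self) -> None:
        if any(not (0.0 < t < 1.0) for t in self.mtld_thresholds):
            raise ValueError("MTLD thresholds must lie in (0, 1)")
        if self.mattr_window < 2:
            raise ValueError("MATTR window must be >= 2")
        if self.mattr_stride < 1:
            raise ValueError("MATTR stride must be >= 1")


_RATIO_CATEGORIES = {
    "noun": ("NOUN",),
    "verb": ("VERB",),
    "adj": ("ADJ",),
    "adv": ("ADV",),
    "aux": ("AUX",),
    "adp": ("ADP",),
}


def pos_category_ratios(transcript: AnnotatedTranscript) -> dict[str, float]:
    """Proportions of six POS categories over non-punctuation tokens,
    plus the adjective:noun, adjective:verb and noun:verb cross-ratios.

    Restricted to IMG and PPE; a zero-denominator cross-ratio is flagged
    missing (NaN).
    """
    if transcript.task == Task.SVF:
        raise ValueError("POS ratios are computed only for IMG and PPE tasks")
    words = transcript.words()
    if not words:
        raise ValueError("transcript has no non-punctuation tokens")
    n = len(words)
    counts = {name: sum(1 for t in words if t.upos in tags)
              for name, tags in _RATIO_CATEGORIES.items()}
    out = {f"{name}_ratio": c / n for name, c in counts.items()}
    for num, den in (("adj", "noun"), ("adj", "verb"), ("noun", "verb")):
        out[f"{num}_to_{den}"] = (
            counts[num] / counts[den] if counts[den] > 0 else MISSING
        )
    return out


def _mtld_one_direction(types_seq: list[str], threshold: float) -> float:
    factors = 0.0
    seen: set[str] = set()
    n_window = 0
    ttr = 1.0
    for tok in types_seq:
        seen.add(tok)
        n_window += 1
        ttr = len(seen) / n_window
        if ttr < threshold:
            factors += 1.0
            seen.clear()
            n_window = 0
            ttr = 1.0
    if n_window > 0 and ttr < 1.0:
        factors += (1.0 - ttr) / (1.0 - threshold)
    if factors == 0.0:
        # text never dipped below threshold: define the score as its length
        return float(len(types_seq))
    return len(types_seq) / factors


def mtld(tokens: list[str], threshold: float = 0.72) -> float:
    """Bidirectional measure of textual lexical diversity.

    A factor completes whenever the running type-token ratio drops
    strictly below ``threshold``; the trailing partial factor counts as
    ``(1 - TTR_end) / (1 - threshold)``. The score is the mean of the
    forward and reverse passes of ``N / factors``.
    """
    if not tokens:
        raise ValueError("MTLD needs at least one token")
    fwd = _mtld_one_direction(list(tokens), threshold)
    rev = _mtld_one_direction(list(tokens)[::-1], threshold)
    return 0.5 * (fwd + rev)


def mattr(tokens: list[str], window: int = 10, stride: int = 5) -> float:
    """Moving-average type-token ratio over strided full windows.

    Windows start at 0, stride, 2*stride, ... while a full window fits;
    a sequence shorter than the window falls back to the whole-sequence
    type-token ratio.
    """
    if not tokens:
        raise ValueError("MATTR needs at least one token")
    n = len(tokens)
    if n < window:
        return len(set(tokens)) / n
    ttrs = [
        len(set(tokens[s:s + window])) / window
        for s in range(0, n - window + 1, stride)
    ]
    return float(np.mean(ttrs))


def richness_indices(tokens: list[str]) -> dict[str, float]:
    """Type-token richness: Guiraud V/sqrt(N), Herdan lnV/lnN,
    Maas (lnN-lnV)/(lnN)^2 and Uber (lnN)^2/(lnN-lnV) (natural logs).

    All-distinct texts (V = N) have Maas 0 and an undefined Uber index.
    """
    n = len(tokens)
    if n < 2:
        return {k: MISSING for k in ("guiraud", "herdan", "maas", "uber")}
    v = len(set(tokens))
    ln_n, ln_v = math.log(n), math.log(v)
    out = {
        "guiraud": v / math.sqrt(n),
        "herdan": ln_v / ln_n,
        "maas": (ln_n - ln_v) / ln_n**2,
        "uber": ln_n**2 / (ln_n - ln_v) if v < n else MISSING,
    }
    return out


def log_frequency_stats(tokens: list[Token],
                        wordfreq: dict[str, float]) -> dict[str, float]:
    """Mean/SD of log10 word frequency over content (non-functional)
    tokens found in the lexicon; out-of-vocabulary tokens are skipped
    and counted."""
    content = [t.normalized for t in tokens if t.is_content]
    logs = [math.log10(wordfreq[w]) for w in content if w in wordfreq]
    oov = len(content) - len(logs)
    if not logs:
        return {"logfreq_mean": MISSING, "logfreq_sd": MISSING,
                "logfreq_oov_count": float(oov)}
    arr = np.asarray(logs)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"logfreq_mean": float(arr.mean()), "logfreq_sd": sd,
            "logfreq_oov_count": float(oov)}


def _fmt_threshold(t: float) -> str:
    return f"{t:.2f}".replace(".", "")


def lexical_feature_vector(
    transcript: AnnotatedTranscript,
    config: DiversityConfig | None = None,
    wordfreq: dict[str, float] | None = None,
) -> dict[str, float]:
    """Assemble the lexical feature map for one transcript with task
    gating: POS-based metrics only for IMG/PPE, frequency statistics for
    every task. Names follow ``lx_<metric>[_content][_t<threshold>]_<task>``.
    """
    config = config or DiversityConfig()
    task = transcript.task.value.lower()
    out: dict[str, float] = {}

    if wordfreq is not None:
        for k, v in log_frequency_stats(transcript.tokens(), wordfreq).items():
            out[f"lx_{k}_{task}"] = v

    if transcript.task == Task.SVF:
        return out

    for k, v in pos_category_ratios(transcript).items():
        out[f"lx_{k}_{task}"] = v

    words = [t.normalized for t in transcript.words()]
    content = [t.normalized for t in transcript.tokens()
               if t.upos in config.content_upos]
    for thr in config.mtld_thresholds:
        suffix = _fmt_threshold(thr)
        out[f"lx_mtld_t{suffix}_{task}"] = mtld(words, thr) if words else MISSING
        out[f"lx_mtld_content_t{suffix}_{task}"] = (
            mtld(content, thr) if content else MISSING
        )
    out[f"lx_mattr_content_{task}"] = (
        mattr(content, config.mattr_window, config.mattr_stride)
        if content else MISSING
    )
    out[f"lx_mattr_{task}"] = (
        mattr(words, config.mattr_window, config.mattr_stride) if words else MISSING
    )
    for k, v in richness_indices(words).items():
        out[f"lx_{k}_{task}"] = v
    return out
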