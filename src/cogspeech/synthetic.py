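"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: Zipfian token
streams with parse annotations, animal-fluency sequences with planted
repetition structure, harmonic audio with known F0 and voicing
intervals, picture-description scenes with known CIU trajectories, and
cohort tables with planted group effects, demographics and CSF analyte
mixtures around the ATN thresholds. Truth records carry the values the
corresponding feature modules are expected to recover. All randomness
flows from explicit seeds via named substreams so any stage can be
re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from ._types import (
    ROOT,
    AnnotatedTranscript,
    AudioClip,
    CohortTable,
    ConstituencyNode,
    CSFPanel,
    DepArc,
    SubjectRecord,
    Task,
    Token,
    DOMAINS,
    COMPOSITE_DOMAINS,
)
from .modeling import ATN_ABETA_RATIO, ATN_PTAU181, ATN_TTAU

__all__ = [
    "CohortSpec",
    "gen_transcript",
    "gen_svf_sequence",
    "gen_audio_clip",
    "gen_ciu_scene",
    "gen_cohort_table",
    "ANIMALS",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    import hashlib

    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, tag % (2**31)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Transcripts

_DEFAULT_POS_PROFILE = {
    "NOUN": 0.28, "VERB": 0.20, "ADJ": 0.10, "ADV": 0.08, "DET": 0.12,
    "ADP": 0.10, "PRON": 0.06, "AUX": 0.04, "CCONJ": 0.02,
}


def _random_tree(words: list[str], rng: np.random.Generator,
                 root: bool = True) -> ConstituencyNode:
    label = "S" if root else str(rng.choice(["NP", "VP", "PP", "X"]))
    if len(words) == 1:
        return ConstituencyNode("T" if not root else "S",
                                children=[ConstituencyNode("T", token=words[0])]
                                if root else None,
                                token=None if root else words[0])
    split = int(rng.integers(1, len(words)))
    left = _random_tree(words[:split], rng, root=False)
    right = _random_tree(words[split:], rng, root=False)
    return ConstituencyNode(label, children=[left, right])


def gen_transcript(
    vocab_size: int = 50,
    length: int = 80,
    zipf_s: float = 1.1,
    pos_profile: Optional[dict[str, float]] = None,
    seed: int = 0,
    task: Task | str = Task.IMG,
    subject_id: str = "synthetic",
) -> tuple[AnnotatedTranscript, dict]:
    """Zipfian token stream with POS tags, parse trees and dependencies.

    ``zipf_s = 0`` draws uniformly; larger exponents concentrate mass on
    few types. Each vocabulary word has a fixed POS drawn from
    ``pos_profile``. Returns (transcript, truth) where truth records the
    realized type and token counts.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    profile = dict(pos_profile or _DEFAULT_POS_PROFILE)
    total = sum(profile.values())
    if total <= 0 or any(v < 0 for v in profile.values()):
        raise ValueError("inconsistent POS profile")
    tags = sorted(profile)
    probs = np.array([profile[t] for t in tags]) / total
    rng = _substream(seed, "transcript")
    vocab = [f"w{i:04d}" for i in range(vocab_size)]
    vocab_pos = {w: tags[int(rng.choice(len(tags), p=probs))] for w in vocab}
    weights = 1.0 / np.arange(1, vocab_size + 1) ** zipf_s
    weights /= weights.sum()
    draw = rng.choice(vocab_size, size=length, p=weights)
    surfaces = [vocab[i] for i in draw]

    sentences: list[list[Token]] = []
    trees: list[ConstituencyNode] = []
    arcs: list[list[DepArc]] = []
    idx = 0
    pos_cursor = 0
    while pos_cursor < length:
        n = int(np.clip(rng.normal(9, 2), 3, 14))
        chunk = surfaces[pos_cursor:pos_cursor + n]
        pos_cursor += n
        toks = [Token(w, w, vocab_pos[w], idx + k) for k, w in enumerate(chunk)]
        idx += len(toks)
        sentences.append(toks)
        trees.append(_random_tree(chunk, rng))
        root_local = 0
        sent_arcs = [DepArc(ROOT, root_local, "root")]
        for k in range(1, len(toks)):
            head = root_local if rng.random() < 0.5 else k - 1
            sent_arcs.append(DepArc(head, k, "dep"))
        arcs.append(sent_arcs)

    transcript = AnnotatedTranscript(
        task=Task(task), sentences=sentences, constituency=trees,
        dependency=arcs, subject_id=subject_id,
    )
    truth = {"tokens": length, "types": len(set(surfaces)),
             "vocab_pos": vocab_pos}
    return transcript, truth


# ---------------------------------------------------------------------------
# SVF sequences

ANIMALS = (
    "perro", "gato", "caballo", "vaca", "oveja", "cerdo", "conejo", "raton",
    "leon", "tigre", "elefante", "jirafa", "mono", "oso", "lobo", "zorro",
    "aguila", "paloma", "gallina", "pato", "pez", "tiburon", "ballena",
    "delfin", "serpiente", "lagarto", "rana", "tortuga", "abeja", "hormiga",
)
_INTRUSIONS = ("mesa", "silla", "coche", "casa", "arbol", "libro")


def gen_svf_sequence(
    n_unique: int = 8,
    n_repeats: int = 2,
    n_intrusions: int = 1,
    gap_pattern: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> tuple[list[str], dict]:
    """Animal-naming sequence with an exact planted repetition structure.

    ``gap_pattern[i]`` is the number of animal mentions strictly between
    repeat *i* and the most recent prior occurrence of the same animal.
    Raises on infeasible patterns. Truth carries the expected
    fluency-feature values.
    """
    rng = _substream(seed, "svf")
    if n_unique < 1 or n_unique > len(ANIMALS):
        raise ValueError(f"n_unique must be in 1..{len(ANIMALS)}")
    order = list(rng.permutation(len(ANIMALS))[:n_unique])
    seq = [ANIMALS[i] for i in order]
    gaps: list[int] = []
    remaining = list(gap_pattern) if gap_pattern is not None else None
    if remaining is not None and len(remaining) != n_repeats:
        raise ValueError("gap_pattern length must equal n_repeats")
    for _rep in range(n_repeats):
        # a position is a valid repeat target iff its animal does not
        # recur later (so it is that animal's most recent occurrence)
        feasible = {len(seq) - 1 - p for p in range(len(seq))
                    if seq[p] not in seq[p + 1:]}
        if remaining is not None:
            # requested gaps form a multiset; realize any feasible one
            g = next((g for g in sorted(remaining, reverse=True)
                      if g in feasible), None)
            if g is None:
                raise ValueError(
                    f"gap pattern {gap_pattern} infeasible: none of "
                    f"{sorted(remaining)} realizable at this step"
                )
            remaining.remove(g)
        else:
            choices = sorted(feasible)
            g = int(choices[rng.integers(len(choices))])
        gaps.append(g)
        seq.append(seq[len(seq) - 1 - g])
    tokens = list(seq)
    for _ in range(n_intrusions):
        w = str(rng.choice(_INTRUSIONS))
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens.insert(pos, w)
    total = n_unique + n_repeats
    truth = {
        "svf_total_animals": float(total),
        "svf_unique_animals": float(n_unique),
        "svf_repeated_animals": float(n_repeats),
        "svf_unique_proportion": n_unique / total,
        "svf_nonanimal_proportion": n_intrusions / (total + n_intrusions),
        "svf_repetition_gap_sum": float(sum(gaps)),
        "svf_repetition_gap_mean": (sum(gaps) / len(gaps)) if gaps else None,
        "gaps": gaps,
    }
    return tokens, truth


def animal_lexicon() -> dict[str, str]:
    """Identity lexicon over the built-in animal inventory."""
    return {a: a for a in ANIMALS}


# ---------------------------------------------------------------------------
# Audio


def gen_audio_clip(
    f0: float = 220.0,
    voiced_pattern: Sequence[bool] = (True, False, True),
    snr_db: Optional[float] = None,
    duration: float = 1.5,
    seed: int = 0,
    rate: int = 16000,
    n_harmonics: int = 5,
) -> tuple[AudioClip, dict]:
    """Harmonic tone segments interleaved with silence (or noise).

    Each entry of ``voiced_pattern`` occupies duration/len(pattern)
    seconds; voiced segments carry a harmonic complex at ``f0`` with
    1/h harmonic rolloff. ``snr_db`` adds white noise across the whole
    clip at the stated SNR relative to the tone power (None = clean).
    Truth holds the voiced intervals and the F0.
    """
    rng = _substream(seed, "audio")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    seg = duration / len(voiced_pattern)
    intervals = []
    for i, on in enumerate(voiced_pattern):
        if not on:
            continue
        a, b = i * seg, (i + 1) * seg
        sel = (t >= a) & (t < b)
        tone = sum((1.0 / h) * np.sin(2 * np.pi * h * f0 * t[sel] + h)
                   for h in range(1, n_harmonics + 1))
        x[sel] = tone
        intervals.append((a, min(b, duration)))
    peak = np.abs(x).max()
    if peak > 0:
        x *= 0.6 / peak
    if snr_db is not None and intervals:
        sig_power = np.mean(x[x != 0] ** 2)
        noise_sd = np.sqrt(sig_power / 10 ** (snr_db / 10))
        x = x + rng.normal(0, noise_sd, size=n)
        np.clip(x, -1, 1, out=x)
    truth = {
        "f0": f0,
        "f0_semitone": 12 * np.log2(f0 / 27.5),
        "voiced_intervals": intervals,
    }
    return AudioClip(samples=x, rate=rate), truth


# ---------------------------------------------------------------------------
# CIU scenes

_QUAD_BOX = {"UL": (0.0, 0.5, 0.0, 0.5), "UR": (0.5, 1.0, 0.0, 0.5),
             "LL": (0.0, 0.5, 0.5, 1.0), "LR": (0.5, 1.0, 0.5, 1.0)}


def gen_ciu_scene(
    n_cius: int = 6,
    quadrant_layout: Optional[Sequence[str]] = None,
    trajectory: Optional[Sequence[int]] = None,
    seed: int = 0,
    max_fillers: int = 3,
) -> tuple[dict, list[str], dict]:
    """Synthetic picture scene: a CIU lexicon with coordinates, a token
    stream realizing the requested mention trajectory (filler tokens
    interleaved), and the independently recounted truth features."""
    rng = _substream(seed, "scene")
    if quadrant_layout is None:
        quadrant_layout = [str(q) for q in
                           rng.choice(list(_QUAD_BOX), size=n_cius)]
    if len(quadrant_layout) != n_cius:
        raise ValueError("quadrant_layout length must equal n_cius")
    lexicon: dict[str, dict] = {}
    info = []
    for i, q in enumerate(quadrant_layout):
        x0, x1, y0, y1 = _QUAD_BOX[q]
        x = float(rng.uniform(x0 + 0.02, x1 - 0.02))
        y = float(rng.uniform(y0 + 0.02, y1 - 0.02))
        key = f"ciu{i:02d}"
        lexicon[key] = {"ciu_id": f"C{i:02d}", "x": x, "y": y, "quadrant": q}
        info.append((key, f"C{i:02d}", x, y, q))
    if trajectory is None:
        trajectory = [int(v) for v in
                      rng.integers(0, n_cius, size=max(3, n_cius))]
    if any(not (0 <= ix < n_cius) for ix in trajectory):
        raise ValueError("trajectory index out of range")
    tokens: list[str] = []
    onsets = []
    for ix in trajectory:
        for _ in range(int(rng.integers(0, max_fillers + 1))):
            tokens.append("eh")
        onsets.append(len(tokens))
        tokens.append(info[ix][0])
    for _ in range(int(rng.integers(0, max_fillers + 1))):
        tokens.append("eh")

    truth = _recount_ciu_truth(trajectory, info, onsets, len(tokens))
    return lexicon, tokens, truth


def _recount_ciu_truth(trajectory, info, onsets, total_words) -> dict:
    # independent straightforward recount of the scene trajectory
    ids = [info[ix][1] for ix in trajectory]
    xs = [info[ix][2] for ix in trajectory]
    ys = [info[ix][3] for ix in trajectory]
    qs = [info[ix][4] for ix in trajectory]
    truth: dict[str, float] = {}
    truth["ciu_mentions"] = float(len(ids))
    truth["ciu_count"] = float(len(set(ids)))
    truth["ciu_concreteness"] = len(ids) / total_words if total_words else None
    consec = sum(1 for a, b in zip(ids, ids[1:]) if a == b)
    truth["ciu_rep_consecutive"] = float(consec)
    truth["ciu_rep_nonconsecutive"] = float(
        len(ids) - len(set(ids)) - consec
    )
    quota = {}
    for _key, cid, _x, _y, q in info:
        quota.setdefault(q, set()).add(cid)
    seen_q: dict[str, set] = {}
    for cid, q in zip(ids, qs):
        seen_q.setdefault(q, set()).add(cid)
    for q in ("UL", "UR", "LL", "LR"):
        if q in quota:
            truth[f"ciu_coverage_{q.lower()}"] = (
                len(seen_q.get(q, set())) / len(quota[q])
            )
    if len(ids) >= 2:
        dists = [np.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])
                 for i in range(len(ids) - 1) if ids[i + 1] != ids[i]]
        truth["ciu_dist_mean"] = float(np.mean(dists)) if dists else None
        dxs = [abs(xs[i + 1] - xs[i]) for i in range(len(ids) - 1)]
        dys = [abs(ys[i + 1] - ys[i]) for i in range(len(ids) - 1)]
        truth["ciu_dx_mean"] = float(np.mean(dxs))
        truth["ciu_dy_mean"] = float(np.mean(dys))
        same = sum(1 for i in range(len(ids) - 1)
                   if ids[i + 1] != ids[i] and qs[i + 1] == qs[i])
        cross = sum(1 for i in range(len(ids) - 1)
                    if ids[i + 1] != ids[i] and qs[i + 1] != qs[i])
        truth["ciu_same_quadrant_transitions"] = float(same)
        truth["ciu_cross_to_same_quadrant_ratio"] = (
            cross / same if same > 0 else None
        )
        spans = [onsets[i + 1] - onsets[i] for i in range(len(onsets) - 1)]
        spans.append(max(total_words - onsets[-1], 1))
        truth["ciu_words_per_ciu_mean"] = float(np.mean(spans))
    return truth


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass
class CohortSpec:
    """Statistical recipe for a synthetic cohort table.

    Informative features are Gaussian with a planted between-group shift
    of ``effect_size`` standard deviations (per unit of the group's
    effect level); noise features are standard normal everywhere.
    Composites are a seeded linear combination of the informative
    features plus Gaussian noise scaled to a target R². CSF analytes are
    per-group lognormal mixtures placed strictly on the intended side of
    the ATN thresholds.
    """

    n: int = 200
    groups: tuple[tuple[str, float], ...] = (("SCD", 0.5), ("aMCI", 0.5))
    effect_levels: dict[str, float] = field(default_factory=dict)
    n_informative: int = 5
    n_noise: int = 45
    effect_size: float = 1.2
    age_means: dict[str, float] = field(default_factory=dict)
    education_means: dict[str, float] = field(default_factory=dict)
    age_sd: float = 7.0
    education_sd: float = 3.5
    sex_p_female: float = 0.55
    confound_demographics: bool = False
    atn_positive_p: dict[str, float] = field(default_factory=dict)
    composite_r2: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(p for _g, p in self.groups) - 1.0) > 1e-9:
            raise ValueError("group prevalences must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        labels = [g for g, _p in self.groups]
        if not self.effect_levels:
            self.effect_levels = {g: float(i) for i, g in enumerate(labels)}
        if not self.age_means:
            base = {"SCD": 68.0, "naMCI": 71.0, "aMCI": 72.0, "ADD": 76.0,
                    "nonADD": 75.0}
            self.age_means = {
                g: (base.get(g, 70.0) if self.confound_demographics else 70.0)
                for g in labels
            }
        if not self.education_means:
            base = {"SCD": 12.0, "naMCI": 10.0, "aMCI": 10.0, "ADD": 9.0,
                    "nonADD": 9.0}
            self.education_means = {
                g: (base.get(g, 11.0) if self.confound_demographics else 11.0)
                for g in labels
            }
        if not self.atn_positive_p:
            base = {"SCD": 0.25, "naMCI": 0.45, "aMCI": 0.60, "ADD": 0.90,
                    "nonADD": 0.40}
            self.atn_positive_p = {g: base.get(g, 0.5) for g in labels}


_MMSE_MEANS = {"SCD": 28.5, "naMCI": 26.5, "aMCI": 26.0, "ADD": 20.0,
               "nonADD": 21.0}


def gen_cohort_table(spec: CohortSpec) -> tuple[CohortTable, dict]:
    """Generate a cohort table plus its truth record.

    Truth: informative feature names, the closed-form Bayes AUC of the
    two extreme effect levels (Φ(‖δ‖/√2) with δ the planted mean shift),
    the intended ATN flags per subject and the composite loadings.
    """
    rng = _substream(spec.seed, "cohort")
    labels = [g for g, _p in spec.groups]
    prevalence = np.array([p for _g, p in spec.groups])
    assignment = rng.choice(len(labels), size=spec.n, p=prevalence)
    m, k = spec.n_informative, spec.n_noise
    inf_names = [f"ft_inf_{i:02d}" for i in range(m)]
    noise_names = [f"ft_noise_{i:02d}" for i in range(k)]
    loadings = rng.normal(0, 1, size=m) if m else np.zeros(0)

    records: list[SubjectRecord] = []
    feat_rows: list[dict[str, float]] = []
    atn_truth: dict[str, tuple] = {}
    signals = np.zeros(spec.n)
    X_inf = np.zeros((spec.n, m))
    for i in range(spec.n):
        g = labels[assignment[i]]
        level = spec.effect_levels[g]
        x_inf = rng.normal(spec.effect_size * level, 1.0, size=m)
        X_inf[i] = x_inf
        x_noise = rng.normal(0.0, 1.0, size=k)
        signals[i] = float(x_inf @ loadings) if m else 0.0
        feat_rows.append({**dict(zip(inf_names, x_inf)),
                          **dict(zip(noise_names, x_noise))})

        a_pos = rng.random() < spec.atn_positive_p[g]
        t_pos = rng.random() < spec.atn_positive_p[g]
        n_pos = rng.random() < spec.atn_positive_p[g]
        margin = lambda: float(np.abs(rng.normal(0.35, 0.12)) + 0.05)  # noqa: E731
        abeta = ATN_ABETA_RATIO * np.exp(-margin() if a_pos else margin())
        ptau = ATN_PTAU181 * np.exp(margin() if t_pos else -margin())
        ttau = ATN_TTAU * np.exp(margin() if n_pos else -margin())
        sid = f"S{i:04d}"
        atn_truth[sid] = (a_pos, t_pos, n_pos)
        records.append(SubjectRecord(
            subject_id=sid,
            diagnosis=g,
            age=float(rng.normal(spec.age_means[g], spec.age_sd)),
            sex="F" if rng.random() < spec.sex_p_female else "M",
            education=float(max(0.0, rng.normal(spec.education_means[g],
                                                spec.education_sd))),
            mmse=float(np.clip(rng.normal(_MMSE_MEANS.get(g, 26.0), 1.8), 0, 30)),
            composites={},
            csf=CSFPanel(abeta_ratio=float(abeta), ptau181=float(ptau),
                         ttau=float(ttau)),
        ))

    # composites: shared linear signal + noise scaled to the target R^2
    sig_sd = float(signals.std()) if m else 0.0
    r2 = spec.composite_r2
    noise_sd = (sig_sd * np.sqrt((1 - r2) / r2)) if (sig_sd > 0 and r2 > 0) else 1.0
    for i, rec in enumerate(records):
        for dom in COMPOSITE_DOMAINS:
            rec.composites[dom] = float(
                signals[i] + rng.normal(0, noise_sd)
            )

    feature_meta = {}
    for j, name in enumerate(inf_names + noise_names):
        feature_meta[name] = (DOMAINS[j % len(DOMAINS)], "img")
    table = CohortTable(records, feat_rows, feature_meta)

    lo = min(spec.effect_levels[g] for g in labels)
    hi = max(spec.effect_levels[g] for g in labels)
    delta = spec.effect_size * (hi - lo) * np.ones(m)
    bayes_auc = float(norm.cdf(np.linalg.norm(delta) / np.sqrt(2))) if m else 0.5
    truth = {
        "informative": inf_names,
        "bayes_auc": bayes_auc,
        "atn": atn_truth,
        "loadings": loadings.tolist(),
        "composite_r2": r2,
        "groups": labels,
    }
    return table, truth
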