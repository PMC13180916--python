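"""End-to-end orchestration: per-subject feature assembly across tasks
and domains, cohort simulation, training and explanation.

The per-subject feature namespace is prefix-tagged by domain
(``ac_``/``lx_``/``sy_`` acoustic, lexical, syntactic; ``aoa_``,
``emb_``, ``clu_`` semantic; ``ciu_``, ``svf_``, ``ts_`` task-specific)
and suffix-tagged by source task, so the cohort table can be scoped to
single tasks or the combined set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._types import (
    AnnotatedTranscript,
    AudioClip,
    CohortTable,
    SubjectRecord,
    Task,
)
from . import acoustic as ac
from . import lexical as lx
from . import semantic as se
from . import syntactic as sy
from . import task_features as tf
from .io import write_feature_table

__all__ = [
    "domain_of_feature",
    "extract_subject_features",
    "assemble_cohort_table",
    "simulate_speech_cohort",
    "run_pipeline",
]

_PREFIX_DOMAIN = (
    ("ac_", "acoustic"),
    ("lx_", "lexical"),
    ("sy_", "syntactic"),
    ("se_", "semantic"),
    ("ts_", "task_specific"),
)


def domain_of_feature(name: str) -> str:
    for prefix, domain in _PREFIX_DOMAIN:
        if name.startswith(prefix):
            return domain
    raise ValueError(f"feature {name!r} has no recognized domain prefix")


def _task_suffix(name: str) -> str:
    for t in ("img", "svf", "ppe"):
        if name.endswith(f"_{t}") or f"_{t}_" in name:
            return t
    return "img"


def extract_subject_features(
    transcripts: dict[Task, AnnotatedTranscript],
    clips: Optional[dict[Task, AudioClip]] = None,
    wordfreq: Optional[dict[str, float]] = None,
    aoa: Optional[dict[str, float]] = None,
    animal_lex: Optional[dict[str, str]] = None,
    ciu_lex: Optional[dict[str, dict]] = None,
    embedding_models: Optional[dict[Task, se.EmbeddingModel]] = None,
    cluster_models: Optional[dict[Task, se.ClusterModel]] = None,
    sentiment_backend: str = "keyword",
) -> dict[str, float]:
    """Assemble the full multidomain feature map for one subject."""
    out: dict[str, float] = {}
    for task, tr in transcripts.items():
        tag = task.value.lower()
        out.update(lx.lexical_feature_vector(tr, wordfreq=wordfreq))
        if task in (Task.IMG, Task.PPE):
            out.update(sy.syntactic_feature_vector(tr))
        if aoa is not None:
            for k, v in se.aoa_stats(tr.tokens(), aoa).items():
                out[f"se_{k}_{tag}"] = v
        if task in (Task.IMG, Task.SVF) and embedding_models and task in embedding_models:
            model = embedding_models[task]
            for k, v in se.embedding_distance_stats(tr, model).items():
                out[f"se_{k}_{tag}"] = v
            if cluster_models and task in cluster_models:
                feats = se.cluster_trajectory_features(
                    tr.content_tokens(), cluster_models[task]
                )
                for k, v in feats.items():
                    out[f"se_{k}_{tag}"] = v
        if task == Task.SVF and animal_lex is not None:
            for k, v in tf.svf_features(tr.tokens(), animal_lex).items():
                out[f"ts_{k}_svf"] = v
        if task == Task.IMG and ciu_lex is not None:
            words = tr.words()
            mentions = tf.detect_ciu_mentions(words, ciu_lex)
            feats = tf.ciu_graph_features(mentions, ciu_lex, len(words))
            for k, v in feats.items():
                out[f"ts_{k}_img"] = v
        if task == Task.PPE:
            text = " ".join(t.surface for t in tr.words())
            out.update(tf.sentiment_features(text, sentiment_backend).as_features())
    if clips:
        for task, clip in clips.items():
            out.update(ac.acoustic_feature_vector(clip, task=task.value.lower()))
    return out


def assemble_cohort_table(
    records: list[SubjectRecord],
    feature_rows: list[dict[str, float]],
) -> CohortTable:
    names = sorted({n for row in feature_rows for n in row})
    meta = {n: (domain_of_feature(n), _task_suffix(n)) for n in names}
    return CohortTable(records, feature_rows, meta)


# ---------------------------------------------------------------------------
# Cohort simulation through the real extraction path


def simulate_speech_cohort(
    n_subjects: int = 30,
    seed: int = 0,
    with_audio: bool = False,
    groups: tuple[tuple[str, float], ...] = (("SCD", 0.5), ("aMCI", 0.5)),
) -> tuple[CohortTable, dict]:
    """Simulate a cohort of subjects with per-task transcripts (and
    optionally audio), then run the actual extraction pipeline.

    Impaired groups draw from a smaller vocabulary with a steeper Zipf
    exponent (lower lexical diversity) and produce more fluency
    repetitions, so downstream group contrasts carry real signal via
    the extraction path.
    """
    from .synthetic import (
        CohortSpec,
        animal_lexicon,
        gen_audio_clip,
        gen_cohort_table,
        gen_svf_sequence,
        gen_transcript,
        _substream,
    )
    from ._types import Token

    spec = CohortSpec(n=n_subjects, groups=groups, n_informative=0, n_noise=1,
                      seed=seed)
    base_table, truth = gen_cohort_table(spec)
    rng = _substream(seed, "speech")
    animal_lex = animal_lexicon()
    rows = []
    for rec in base_table.records:
        impaired = rec.diagnosis.value != "SCD"
        vocab = 40 if impaired else 110
        zipf = 1.3 if impaired else 0.9
        sub_seed = int(rng.integers(2**31))
        transcripts = {}
        for task in (Task.IMG, Task.PPE):
            tr, _ = gen_transcript(vocab_size=vocab, length=90, zipf_s=zipf,
                                   seed=sub_seed + (task == Task.PPE),
                                   task=task, subject_id=rec.subject_id)
            transcripts[task] = tr
        n_unique = int(np.clip(rng.normal(8 if impaired else 14, 2), 3, 22))
        n_rep = int(rng.integers(2, 5)) if impaired else int(rng.integers(0, 2))
        try:
            svf_tokens, _ = gen_svf_sequence(n_unique=n_unique, n_repeats=n_rep,
                                             n_intrusions=1, seed=sub_seed)
        except ValueError:
            svf_tokens, _ = gen_svf_sequence(n_unique=n_unique, n_repeats=0,
                                             n_intrusions=1, seed=sub_seed)
        toks = [Token(w, w, "NOUN", i) for i, w in enumerate(svf_tokens)]
        transcripts[Task.SVF] = AnnotatedTranscript(
            task=Task.SVF, sentences=[toks], subject_id=rec.subject_id
        )
        clips = None
        if with_audio:
            f0 = float(rng.uniform(110, 240))
            clip, _ = gen_audio_clip(f0=f0, voiced_pattern=(True, False, True),
                                     snr_db=25.0, duration=1.2, seed=sub_seed)
            clips = {Task.IMG: clip}
        rows.append(extract_subject_features(
            transcripts, clips=clips, animal_lex=animal_lex,
        ))
    table = assemble_cohort_table(base_table.records, rows)
    return table, truth


# ---------------------------------------------------------------------------
# Full deterministic run


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_subjects: int = 40,
    with_audio: bool = False,
    model_family: str = "rf",
    selection_budget: tuple[int, int] = (20, 8),
    tpe_budget: tuple[int, int] = (20, 10),
) -> dict:
    """simulate → extract → train → explain, writing deterministic
    artifacts (feature table, metric summary, attribution and bias
    reports) under ``outdir``."""
    from .explain import bias_audit, domain_importance, shapley_attributions
    from .modeling import (
        NSGA2FeatureSelector,
        fit_and_evaluate,
        stratified_matched_split,
        tpe_hyperparameter_search,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_speech_cohort(n_subjects=n_subjects, seed=seed,
                                          with_audio=with_audio)
    write_feature_table(table, outdir / "features.csv")

    subj = table.subject_frame()
    ids = list(subj.index)
    split = stratified_matched_split(table, seed=seed)
    y = (subj["diagnosis"] != "SCD").astype(int).to_numpy()
    X = np.nan_to_num(table.features.to_numpy(float))
    tr = [ids.index(i) for i in split.train_ids]
    te = [ids.index(i) for i in split.test_ids]

    selector = NSGA2FeatureSelector(pop_size=selection_budget[0],
                                    n_gen=selection_budget[1],
                                    random_state=seed, cv=3)
    selector.fit(X[tr], y[tr])
    mask = selector.support_
    params, cv_score = tpe_hyperparameter_search(
        model_family, X[tr], y[tr], mask, n_iter=tpe_budget[0],
        n_random=tpe_budget[1], cv=3, seed=seed,
    )
    report = fit_and_evaluate(
        X[tr], y[tr], X[te], y[te], model_family=model_family, mask=mask,
        params=params, seed=seed, train_ids=split.train_ids,
        test_ids=split.test_ids, task_name="SCD_vs_CI",
    )
    sel_names = [n for n, m in zip(table.feature_names, mask) if m]
    from .modeling import make_model

    model = make_model(model_family, "classification", params, seed)
    model.fit(X[tr][:, mask], y[tr])
    attributions = shapley_attributions(
        model, X[te][:, mask], feature_names=sel_names, seed=seed,
        background=X[tr][:, mask], sample_ids=split.test_ids,
    )
    groups = {n: table.domain_of(n) for n in sel_names}
    dom_imp = domain_importance(attributions, groups)
    audit = bias_audit(report.predictions, table.records, attributions, groups)

    summary = pd.DataFrame([{"task": "SCD_vs_CI", "model": model_family,
                             "n_features": int(mask.sum()),
                             "cv_score": cv_score, **report.metrics}])
    summary.to_csv(outdir / "summary.csv", index=False)
    pd.DataFrame(attributions.values, index=attributions.sample_ids,
                 columns=attributions.feature_names).to_csv(
        outdir / "attributions.csv")
    (outdir / "domain_importance.json").write_text(
        json.dumps({k: round(v, 12) for k, v in sorted(dom_imp.items())},
                   sort_keys=True, indent=2))
    (outdir / "bias_audit.json").write_text(json.dumps({
        "sex_p": None if np.isnan(audit.sex_p) else round(audit.sex_p, 12),
        "age_p": None if np.isnan(audit.age_p) else round(audit.age_p, 12),
        "education_p": None if np.isnan(audit.education_p)
        else round(audit.education_p, 12),
        "flags": audit.flags, "skipped": audit.skipped,
    }, sort_keys=True, indent=2))
    return {
        "table": table, "truth": truth, "split": split, "report": report,
        "selection": selector.selection_result_, "attributions": attributions,
        "domain_importance": dom_imp, "bias_audit": audit,
    }
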