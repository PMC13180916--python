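"""Readers and writers for the pipeline's external formats.

Formats handled: CoNLL-U transcripts (UPOS + dependency columns),
Penn-style bracketed constituency trees (one per sentence, aligned to the
CoNLL-U file by sentence index), PCM WAV audio, resource lexicons
(CSV/JSON) and the assembled cohort feature table (CSV plus a JSON
metadata sidecar carrying domain and task tags).
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._types import (
    ROOT,
    AnnotatedTranscript,
    AudioClip,
    CohortTable,
    ConstituencyNode,
    CSFPanel,
    DepArc,
    Diagnosis,
    SubjectRecord,
    Task,
    Token,
    normalize_token,
    COMPOSITE_DOMAINS,
)

__all__ = [
    "parse_conllu_document",
    "transcript_to_conllu",
    "parse_bracketed_tree",
    "parse_bracketed_forest",
    "load_audio",
    "save_audio",
    "load_lexicon",
    "write_feature_table",
    "read_feature_table",
]


class ParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CoNLL-U


def parse_conllu_document(
    text: str,
    task: Union[Task, str],
    subject_id: str = "",
    trees: Optional[list[Optional[ConstituencyNode]]] = None,
) -> AnnotatedTranscript:
    """Parse a CoNLL-U document into an annotated transcript.

    Multiword-token range lines (ID like ``1-2``) are skipped and their
    component tokens kept; empty nodes (ID like ``1.1``) are skipped.
    Dependency arcs are built from the HEAD/DEPREL columns, with HEAD=0
    mapping to the synthetic ROOT.
    """
    sentences: list[list[Token]] = []
    arcs: list[list[DepArc]] = []
    cur_tokens: list[tuple[int, Token]] = []
    cur_heads: list[tuple[int, int, str]] = []
    global_index = 0
    any_dep = False

    def flush():
        nonlocal cur_tokens, cur_heads
        if not cur_tokens:
            return
        local_of = {cid: i for i, (cid, _t) in enumerate(cur_tokens)}
        sentences.append([t for _cid, t in cur_tokens])
        sent_arcs = []
        for cid, head, rel in cur_heads:
            if head == 0:
                sent_arcs.append(DepArc(ROOT, local_of[cid], rel))
            else:
                if head not in local_of:
                    raise ParseError(f"HEAD {head} refers to a missing token id")
                sent_arcs.append(DepArc(local_of[head], local_of[cid], rel))
        arcs.append(sent_arcs)
        cur_tokens, cur_heads = [], []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(f"line {lineno}: expected >=4 tab-separated columns")
        tid = cols[0]
        if "-" in tid or "." in tid:
            continue  # multiword range / empty node: components carry the data
        try:
            cid = int(tid)
        except ValueError as e:
            raise ParseError(f"line {lineno}: bad token id {tid!r}") from e
        surface, upos = cols[1], cols[3]
        if upos == "_" or not upos:
            raise ParseError(f"line {lineno}: missing UPOS tag")
        try:
            tok = Token(surface, normalize_token(surface), upos, global_index)
        except ValueError as e:
            raise ParseError(f"line {lineno}: {e}") from e
        global_index += 1
        cur_tokens.append((cid, tok))
        if len(cols) >= 8 and cols[6] not in ("_", ""):
            try:
                head = int(cols[6])
            except ValueError as e:
                raise ParseError(f"line {lineno}: bad HEAD {cols[6]!r}") from e
            cur_heads.append((cid, head, cols[7] if cols[7] != "_" else "dep"))
            any_dep = True
    flush()

    return AnnotatedTranscript(
        task=Task(task),
        sentences=sentences,
        constituency=trees,
        dependency=arcs if any_dep else None,
        subject_id=subject_id,
    )


def transcript_to_conllu(transcript: AnnotatedTranscript) -> str:
    """Serialize a transcript back to CoNLL-U (round-trip companion)."""
    lines: list[str] = []
    dep = transcript.dependency
    for si, sent in enumerate(transcript.sentences):
        head_of: dict[int, tuple[int, str]] = {}
        if dep is not None:
            for a in dep[si]:
                head_of[a.dependent] = (0 if a.head == ROOT else a.head + 1, a.relation)
        for li, tok in enumerate(sent):
            h, rel = head_of.get(li, ("_", "_"))
            lines.append(
                "\t".join(
                    [str(li + 1), tok.surface, "_", tok.upos, "_", "_", str(h), rel,
                     "_", "_"]
                )
            )
        lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bracketed constituency trees


def _tokenize_brackets(text: str) -> list[str]:
    return text.replace("(", " ( ").replace(")", " ) ").split()


def parse_bracketed_tree(text: str) -> ConstituencyNode:
    """Parse one Penn-style bracketed tree, e.g. ``(S (NP (D the)))``."""
    toks = _tokenize_brackets(text)
    if not toks:
        raise ParseError("empty tree string")
    pos = 0

    def parse_node() -> ConstituencyNode:
        nonlocal pos
        if toks[pos] != "(":
            raise ParseError(f"expected '(' at token {pos}")
        pos += 1
        if pos >= len(toks) or toks[pos] in "()":
            raise ParseError("missing node label")
        label = toks[pos]
        pos += 1
        children: list[ConstituencyNode] = []
        leaf: Optional[str] = None
        while pos < len(toks) and toks[pos] != ")":
            if toks[pos] == "(":
                children.append(parse_node())
            else:
                leaf = toks[pos]
                pos += 1
        if pos >= len(toks):
            raise ParseError("unbalanced brackets: missing ')'")
        pos += 1  # consume ')'
        if children and leaf is not None:
            raise ParseError(f"node {label} mixes children and a leaf")
        if leaf is not None:
            return ConstituencyNode(label, token=leaf)
        if not children:
            raise ParseError(f"node {label} is empty")
        return ConstituencyNode(label, children=children)

    node = parse_node()
    if pos != len(toks):
        raise ParseError("unbalanced brackets: trailing input")
    return node


def parse_bracketed_forest(text: str) -> list[ConstituencyNode]:
    """Parse one tree per non-empty line."""
    return [parse_bracketed_tree(ln) for ln in text.splitlines() if ln.strip()]


# ---------------------------------------------------------------------------
# Audio


def load_audio(path: Union[str, Path], target_rate: int = 16000) -> AudioClip:
    """Load a PCM WAV file as a mono clip resampled to ``target_rate``.

    Multi-channel input is averaged across channels; integer PCM is
    scaled to [-1, 1]. Resampling is polyphase (scipy ``resample_poly``).
    """
    from scipy.io import wavfile

    try:
        rate, data = wavfile.read(str(path))
    except Exception as e:  # noqa: BLE001 - surface as I/O error
        raise IOError(f"cannot read WAV file {path}: {e}") from e
    if data.size == 0:
        raise IOError(f"empty WAV file: {path}")
    x = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        x = x / float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        frac = Fraction(target_rate, rate)
        from scipy.signal import resample_poly

        x = resample_poly(x, frac.numerator, frac.denominator)
    np.clip(x, -1.0, 1.0, out=x)
    return AudioClip(samples=x, rate=target_rate)


def save_audio(clip: AudioClip, path: Union[str, Path]) -> None:
    """Write a clip as 16-bit PCM WAV."""
    from scipy.io import wavfile

    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.rate, (x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# Lexicons

_QUADRANTS = ("UL", "UR", "LL", "LR")


def load_lexicon(path: Union[str, Path], kind: str,
                 fold_accents: bool = False) -> dict:
    """Load a resource lexicon.

    kinds:
      - ``ciu``: JSON list of {keyword(s), ciu_id, x, y, quadrant}
      - ``animals``: CSV with ``name`` (canonical) and optional pipe-separated
        ``variants``; returns variant/canonical → canonical
      - ``aoa``: CSV with ``word`` and ``age`` columns → word → age (years)
      - ``wordfreq``: CSV with ``word`` and ``frequency`` columns
    Keys are normalized (lowercase, punctuation-stripped; accent folding per
    config). Duplicate keys are rejected.
    """
    path = Path(path)
    norm = lambda s: normalize_token(str(s), fold_accents)  # noqa: E731

    def _insert(out: dict, key: str, value, offenders: list):
        if key in out:
            offenders.append(key)
        out[key] = value

    offenders: list[str] = []
    if kind == "ciu":
        entries = json.loads(path.read_text())
        out: dict[str, dict] = {}
        for e in entries:
            kw = e.get("keyword") or e.get("keywords")
            if kw is None or "ciu_id" not in e:
                raise SchemaError("CIU entry needs keyword(s) and ciu_id")
            for col in ("x", "y", "quadrant"):
                if col not in e:
                    raise SchemaError(f"CIU entry missing column {col!r}")
            if e["quadrant"] not in _QUADRANTS:
                raise SchemaError(
                    f"CIU quadrant {e['quadrant']!r} not in {_QUADRANTS}"
                )
            if not (0.0 <= e["x"] <= 1.0 and 0.0 <= e["y"] <= 1.0):
                raise SchemaError("CIU coordinates must lie in [0,1]x[0,1]")
            kws = kw if isinstance(kw, list) else [kw]
            for k in kws:
                key = " ".join(norm(w) for w in str(k).split())
                _insert(out, key, {
                    "ciu_id": e["ciu_id"], "x": float(e["x"]), "y": float(e["y"]),
                    "quadrant": e["quadrant"],
                }, offenders)
    elif kind == "animals":
        df = pd.read_csv(path)
        if "name" not in df.columns:
            raise SchemaError("animal lexicon needs a 'name' column")
        out = {}
        for _, row in df.iterrows():
            canonical = norm(row["name"])
            _insert(out, canonical, canonical, offenders)
            variants = row.get("variants")
            if isinstance(variants, str) and variants.strip():
                for v in variants.split("|"):
                    _insert(out, norm(v), canonical, offenders)
    elif kind in ("aoa", "wordfreq"):
        value_col = "age" if kind == "aoa" else "frequency"
        df = pd.read_csv(path)
        for col in ("word", value_col):
            if col not in df.columns:
                raise SchemaError(f"{kind} lexicon needs a {col!r} column")
        out = {}
        for _, row in df.iterrows():
            _insert(out, norm(row["word"]), float(row[value_col]), offenders)
    else:
        raise ValueError(f"unknown lexicon kind {kind!r}")
    if offenders:
        raise SchemaError(f"duplicate lexicon keys: {sorted(set(offenders))}")
    return out


# ---------------------------------------------------------------------------
# Cohort feature table <-> CSV + JSON sidecar

_SUBJECT_COLS = [
    "diagnosis", "age", "sex", "education", "mmse",
    *(f"composite_{k}" for k in COMPOSITE_DOMAINS),
    "csf_abeta_ratio", "csf_ptau181", "csf_ttau",
]


def write_feature_table(table: CohortTable, csv_path: Union[str, Path]) -> Path:
    """Write the cohort table as CSV plus a ``<name>.meta.json`` sidecar.

    Floats are serialized with repr precision so write→read round-trips
    are lossless to <=1e-12 relative.
    """
    csv_path = Path(csv_path)
    subj = table.subject_frame()
    df = pd.concat([subj.drop(columns=["subject_id"]), table.features], axis=1)
    df.index.name = "subject_id"
    df.to_csv(csv_path, float_format=None)
    sidecar = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(
        {
            "feature_meta": {
                n: {"domain": d, "task": t} for n, (d, t) in sorted(table.feature_meta.items())
            },
            "subject_columns": _SUBJECT_COLS,
        },
        indent=2, sort_keys=True,
    ))
    return sidecar


def read_feature_table(csv_path: Union[str, Path]) -> CohortTable:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    if not sidecar.exists():
        raise SchemaError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    feature_meta = {
        n: (m["domain"], m["task"]) for n, m in meta["feature_meta"].items()
    }
    df = pd.read_csv(csv_path, index_col="subject_id")
    missing = set(feature_meta) - set(df.columns)
    if missing:
        raise SchemaError(f"CSV lacks features declared in sidecar: {sorted(missing)}")
    records, feat_rows = [], []
    for sid, row in df.iterrows():
        csf_vals = {
            k: (None if pd.isna(row[f"csf_{k}"]) else float(row[f"csf_{k}"]))
            for k in ("abeta_ratio", "ptau181", "ttau")
        }
        csf = CSFPanel(**csf_vals) if any(v is not None for v in csf_vals.values()) else None
        records.append(SubjectRecord(
            subject_id=str(sid),
            diagnosis=Diagnosis(row["diagnosis"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            education=float(row["education"]),
            mmse=float(row["mmse"]),
            composites={
                k: float(row[f"composite_{k}"]) for k in COMPOSITE_DOMAINS
                if f"composite_{k}" in row and not pd.isna(row[f"composite_{k}"])
            },
            csf=csf,
        ))
        feat_rows.append({n: float(row[n]) for n in feature_meta})
    return CohortTable(records, feat_rows, feature_meta)
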