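"""Core domain objects shared by every pipeline stage.

The pipeline consumes three spoken tasks per subject — picture description
(IMG), one-minute semantic verbal fluency (SVF), and a positive personal
experience narrative (PPE) — each as a 16 kHz mono recording plus an
annotated transcript (universal POS tags, optional constituency and
dependency structures).  Subjects additionally carry demographics, MMSE,
cognitive composite scores and optional CSF biomarkers.
"""

from __future__ import annotations

import enum
import math
import unicodedata
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Task",
    "Diagnosis",
    "Token",
    "DepArc",
    "ROOT",
    "AnnotatedTranscript",
    "ConstituencyNode",
    "AudioClip",
    "CSFPanel",
    "SubjectRecord",
    "CohortTable",
    "UPOS_TAGS",
    "CONTENT_UPOS",
    "FUNCTION_UPOS",
    "DOMAINS",
    "normalize_token",
    "MISSING",
]

#: Sentinel for a feature that could not be computed (propagates through
#: pandas as NaN and is flagged in the metadata sidecar).
MISSING = float("nan")

UPOS_TAGS = frozenset(
    {
        "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
        "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
    }
)

#: Content words carry lexical meaning; everything else is treated as
#: functional for lexicon matching, embeddings and frequency statistics.
CONTENT_UPOS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})
FUNCTION_UPOS = frozenset(
    {"DET", "PRON", "ADP", "AUX", "CCONJ", "SCONJ", "PART", "PUNCT", "SYM",
     "INTJ", "NUM", "X"}
)

DOMAINS = ("acoustic", "lexical", "syntactic", "semantic", "task_specific")

_PUNCT_CHARS = "".join(
    chr(c) for c in range(0x2100) if unicodedata.category(chr(c)).startswith("P")
)


class Task(str, enum.Enum):
    IMG = "IMG"
    SVF = "SVF"
    PPE = "PPE"


class Diagnosis(str, enum.Enum):
    SCD = "SCD"
    naMCI = "naMCI"
    aMCI = "aMCI"
    ADD = "ADD"
    nonADD = "nonADD"


def normalize_token(surface: str, fold_accents: bool = False) -> str:
    """Lowercase and strip leading/trailing punctuation.

    Accent folding is off by default because the Spanish norm lexicons
    (age of acquisition, word frequency) carry accented entries.
    """
    s = surface.lower().strip().strip(_PUNCT_CHARS)
    if fold_accents:
        s = "".join(
            c for c in unicodedata.normalize("NFD", s)
            if unicodedata.category(c) != "Mn"
        )
    return s


@dataclass(frozen=True)
class Token:
    surface: str
    normalized: str
    upos: str
    index: int

    def __post_init__(self) -> None:
        if self.upos not in UPOS_TAGS:
            raise ValueError(f"unknown UPOS tag {self.upos!r}")
        if self.upos != "PUNCT" and not self.normalized:
            raise ValueError(
                f"token {self.surface!r} normalizes to empty but is not PUNCT"
            )

    @property
    def is_content(self) -> bool:
        return self.upos in CONTENT_UPOS

    @property
    def is_word(self) -> bool:
        return self.upos != "PUNCT"


#: Synthetic root index used as the head of each sentence's root arc.
ROOT = -1


@dataclass(frozen=True)
class DepArc:
    """Dependency arc with sentence-local 0-based token indices."""

    head: int  # ROOT (-1) for the sentence root
    dependent: int
    relation: str = "dep"


class ConstituencyNode:
    """Node of a Penn-style constituency tree.

    Preterminals carry exactly one leaf token (a string); internal nodes
    carry ordered child nodes.
    """

    __slots__ = ("label", "children", "token")

    def __init__(self, label: str, children: Optional[list] = None,
                 token: Optional[str] = None):
        if (children is None or not children) and token is None:
            raise ValueError("node needs children or a leaf token")
        if children and token is not None:
            raise ValueError("node cannot be both internal and preterminal")
        self.label = label
        self.children: list[ConstituencyNode] = list(children or [])
        self.token = token

    @property
    def is_preterminal(self) -> bool:
        return self.token is not None

    def leaves(self) -> list[str]:
        if self.is_preterminal:
            return [self.token]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def preterminals(self) -> Iterator["ConstituencyNode"]:
        if self.is_preterminal:
            yield self
        else:
            for c in self.children:
                yield from c.preterminals()

    def to_bracketed(self) -> str:
        if self.is_preterminal:
            return f"({self.label} {self.token})"
        inner = " ".join(c.to_bracketed() for c in self.children)
        return f"({self.label} {inner})"

    def __repr__(self) -> str:  # pragma: no cover
        return f"ConstituencyNode({self.to_bracketed()!r})"


@dataclass
class AnnotatedTranscript:
    task: Task
    sentences: list[list[Token]]
    constituency: Optional[list[Optional[ConstituencyNode]]] = None
    dependency: Optional[list[list[DepArc]]] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        idx = [t.index for s in self.sentences for t in s]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("token indices must be strictly increasing")
        if self.dependency is not None:
            for sent, arcs in zip(self.sentences, self.dependency):
                n = len(sent)
                for a in arcs:
                    if not (0 <= a.dependent < n) or not (a.head == ROOT or 0 <= a.head < n):
                        raise ValueError("dependency arc index out of range")
        if self.constituency is not None:
            for sent, tree in zip(self.sentences, self.constituency):
                if tree is None:
                    continue
                words = [t.surface for t in sent if t.is_word]
                if tree.leaves() != words and tree.leaves() != [t.surface for t in sent]:
                    raise ValueError("constituency leaf order must match tokens")

    def tokens(self) -> list[Token]:
        return [t for s in self.sentences for t in s]

    def words(self) -> list[Token]:
        return [t for t in self.tokens() if t.is_word]

    def content_tokens(self) -> list[Token]:
        return [t for t in self.tokens() if t.is_content]

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


@dataclass
class AudioClip:
    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip is mono: samples must be 1-D")
        if self.samples.size == 0:
            raise ValueError("empty audio clip")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class CSFPanel:
    """CSF analytes used for ATN dichotomization (pg/mL except the ratio)."""

    abeta_ratio: Optional[float] = None  # Aβ1-42/Aβ1-40
    ptau181: Optional[float] = None
    ttau: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("abeta_ratio", "ptau181", "ttau"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"CSF {name} must be strictly positive, got {v}")


COMPOSITE_DOMAINS = (
    "memory", "attention", "visuospatial", "executive", "language",
    "orientation", "praxis",
)


@dataclass
class SubjectRecord:
    subject_id: str
    diagnosis: Diagnosis
    age: float
    sex: str  # "F" | "M"
    education: float
    mmse: float
    composites: dict[str, float] = field(default_factory=dict)
    csf: Optional[CSFPanel] = None

    def __post_init__(self) -> None:
        self.diagnosis = Diagnosis(self.diagnosis)
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not (0 <= self.mmse <= 30) and not math.isnan(self.mmse):
            raise ValueError(f"MMSE must lie in [0, 30], got {self.mmse}")


class CohortTable:
    """One row per subject: demographics/clinical columns plus a
    domain-tagged feature vector sharing one namespace across rows."""

    def __init__(self, records: list[SubjectRecord],
                 features: "list[dict[str, float]]",
                 feature_meta: dict[str, tuple[str, str]]):
        if len(records) != len(features):
            raise ValueError("records and feature rows differ in length")
        names = set(feature_meta)
        for row in features:
            if set(row) - names:
                raise ValueError("feature row outside the declared namespace")
        for name, (domain, _task) in feature_meta.items():
            if domain not in DOMAINS:
                raise ValueError(f"unknown feature domain {domain!r} for {name}")
        self.records = list(records)
        self.feature_meta = dict(feature_meta)
        self.feature_names = sorted(feature_meta)
        import pandas as pd

        self.features = pd.DataFrame(
            [{n: row.get(n, MISSING) for n in self.feature_names} for row in features],
            index=[r.subject_id for r in records],
            columns=self.feature_names,
            dtype=float,
        )

    def __len__(self) -> int:
        return len(self.records)

    def subject_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "diagnosis": r.diagnosis.value,
                "age": r.age,
                "sex": r.sex,
                "education": r.education,
                "mmse": r.mmse,
            }
            for k in COMPOSITE_DOMAINS:
                row[f"composite_{k}"] = r.composites.get(k, MISSING)
            row["csf_abeta_ratio"] = (
                r.csf.abeta_ratio if r.csf and r.csf.abeta_ratio is not None else MISSING
            )
            row["csf_ptau181"] = (
                r.csf.ptau181 if r.csf and r.csf.ptau181 is not None else MISSING
            )
            row["csf_ttau"] = r.csf.ttau if r.csf and r.csf.ttau is not None else MISSING
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id", drop=False)

    def domain_of(self, feature: str) -> str:
        return self.feature_meta[feature][0]
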