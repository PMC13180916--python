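"""Syntactic complexity scores from constituency and dependency trees.

The Yngve score measures left-branching memory load (children numbered
right-to-left, word score = sum along the root-to-leaf path); the
Frazier score counts the chain of nodes a word opens (ascending while
the current node is the leftmost child, sentence nodes weighted 1.5).
Tree depth and root-dependency out-degree complete the set. All scores
are averaged per sentence, then across sentences; they apply only to
the IMG and PPE tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._types import MISSING, ROOT, AnnotatedTranscript, ConstituencyNode, Task

__all__ = [
    "SyntacticConfig",
    "yngve_mean",
    "frazier_mean",
    "depth_stats",
    "root_dependency_stats",
    "syntactic_feature_vector",
]


@dataclass(frozen=True)
class SyntacticConfig:
    #: node labels scored 1.5 on the Frazier chain (sentence-type nodes)
    s_labels: frozenset[str] = frozenset({"S", "ROOT", "SBAR", "sentence"})
    #: drop punctuation preterminals before scoring
    exclude_punct_leaves: bool = False


def _yngve_scores(node: ConstituencyNode, depth_sum: float,
                  out: list[float]) -> None:
    if node.is_preterminal:
        out.append(depth_sum)
        return
    n = len(node.children)
    for i, child in enumerate(node.children):
        # children numbered right-to-left starting at 0
        _yngve_scores(child, depth_sum + (n - 1 - i), out)


def yngve_mean(tree: ConstituencyNode) -> float:
    """Mean Yngve score over the words of one tree."""
    scores: list[float] = []
    _yngve_scores(tree, 0.0, scores)
    if not scores:
        raise ValueError("tree has no leaves")
    return float(np.mean(scores))


def frazier_mean(tree: ConstituencyNode,
                 config: SyntacticConfig = SyntacticConfig()) -> float:
    """Mean Frazier score over the words of one tree.

    For each word, ascend from its preterminal while the current node is
    the leftmost child of its parent; each parent so reached scores 1
    (1.5 when its label is a sentence node). A parentless preterminal
    (single-word tree) scores itself once.
    """
    parent: dict[int, ConstituencyNode] = {}

    def walk(node: ConstituencyNode) -> None:
        for c in node.children:
            parent[id(c)] = node
            walk(c)

    walk(tree)
    scores: list[float] = []
    for pre in tree.preterminals():
        if id(pre) not in parent:  # degenerate single-preterminal tree
            scores.append(1.5 if pre.label in config.s_labels else 1.0)
            continue
        score, node = 0.0, pre
        while id(node) in parent:
            par = parent[id(node)]
            if par.children[0] is not node:
                break
            score += 1.5 if par.label in config.s_labels else 1.0
            node = par
        scores.append(score)
    if not scores:
        raise ValueError("tree has no leaves")
    return float(np.mean(scores))


def depth_stats(tree: ConstituencyNode) -> dict[str, float]:
    """Maximum and mean leaf depth (edges from the root to each leaf)."""
    depths: list[int] = []

    def walk(node: ConstituencyNode, d: int) -> None:
        if node.is_preterminal:
            depths.append(d + 1)  # preterminal -> leaf edge
            return
        for c in node.children:
            walk(c, d + 1)

    walk(tree, 0)
    return {"max_depth": float(max(depths)), "mean_depth": float(np.mean(depths))}


def root_dependency_stats(transcript: AnnotatedTranscript) -> dict[str, float]:
    """Max and mean out-degree of each sentence's root token (arcs whose
    head is the token governed by the synthetic ROOT)."""
    if transcript.dependency is None:
        return {"rootdep_max": MISSING, "rootdep_mean": MISSING}
    degrees: list[int] = []
    for arcs in transcript.dependency:
        roots = [a.dependent for a in arcs if a.head == ROOT]
        if not roots:
            continue
        root = roots[0]
        degrees.append(sum(1 for a in arcs if a.head == root))
    if not degrees:
        return {"rootdep_max": MISSING, "rootdep_mean": MISSING}
    return {"rootdep_max": float(max(degrees)),
            "rootdep_mean": float(np.mean(degrees))}


def syntactic_feature_vector(
    transcript: AnnotatedTranscript,
    config: SyntacticConfig = SyntacticConfig(),
) -> dict[str, float]:
    """Per-task syntactic feature map; sentence scores are averaged with
    equal weight, sentences without parses skipped. SVF is refused."""
    if transcript.task == Task.SVF:
        raise ValueError("syntactic features are computed only for IMG and PPE")
    task = transcript.task.value.lower()
    yngve, frazier, dmax, dmean = [], [], [], []
    trees = transcript.constituency or []
    for tree in trees:
        if tree is None:
            continue
        yngve.append(yngve_mean(tree))
        frazier.append(frazier_mean(tree, config))
        d = depth_stats(tree)
        dmax.append(d["max_depth"])
        dmean.append(d["mean_depth"])
    out = {
        f"sy_yngve_mean_{task}": float(np.mean(yngve)) if yngve else MISSING,
        f"sy_frazier_mean_{task}": float(np.mean(frazier)) if frazier else MISSING,
        f"sy_depth_max_{task}": float(np.mean(dmax)) if dmax else MISSING,
        f"sy_depth_mean_{task}": float(np.mean(dmean)) if dmean else MISSING,
    }
    rd = root_dependency_stats(transcript)
    out[f"sy_rootdep_max_{task}"] = rd["rootdep_max"]
    out[f"sy_rootdep_mean_{task}"] = rd["rootdep_mean"]
    return out
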