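import numpy as np
import pytest

from cogspeech._types import AnnotatedTranscript, Task, Token


def make_transcript(upos_seq, task=Task.IMG, words=None, subject_id="t"):
    """Single-sentence transcript from a UPOS sequence (surface wN or given)."""
    words = words or [f"w{i}" for i in range(len(upos_seq))]
    toks = [Token(w, w.lower(), u, i) for i, (w, u) in enumerate(zip(words, upos_seq))]
    return AnnotatedTranscript(task=task, sentences=[toks], subject_id=subject_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_tree_text():
    return "(S (NP (D the) (N dog)) (VP (V barks)))"


@pytest.fixture
def conllu_two_sentences():
    # 2 sentences, 7 token lines, with dependency columns
    return (
        "# sent_id = 1\n"
        "1\tEl\t_\tDET\t_\t_\t2\tdet\t_\t_\n"
        "2\tperro\t_\tNOUN\t_\t_\t3\tnsubj\t_\t_\n"
        "3\tladra\t_\tVERB\t_\t_\t0\troot\t_\t_\n"
        "\n"
        "1\tYo\t_\tPRON\t_\t_\t2\tnsubj\t_\t_\n"
        "2\tcomo\t_\tVERB\t_\t_\t0\troot\t_\t_\n"
        "3\tpan\t_\tNOUN\t_\t_\t2\tobj\t_\t_\n"
        "4\t.\t_\tPUNCT\t_\t_\t2\tpunct\t_\t_\n"
    )
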