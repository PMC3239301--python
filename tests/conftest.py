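"""Shared fixtures and corpus-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from silverner import (
    AnnotatedCorpus,
    Annotation,
    AnnotatorProfile,
    Document,
    Sentence,
    TruthSpec,
    generate_truth,
    sentence_key,
    simulate_annotator,
)


def build_corpus(source, sentences, annotations):
    """Hand-build a corpus.

    *sentences*: list of ``(doc_id, sent_id, text)``;
    *annotations*: list of ``(key, char_start, char_end, group)`` or
    ``(key, cs, ce, group, concept_ids)``.
    """
    docs: dict[str, list[Sentence]] = {}
    index: dict[str, Sentence] = {}
    for doc_id, sent_id, text in sentences:
        sent = Sentence.from_text(sent_id, text)
        docs.setdefault(doc_id, []).append(sent)
        index[sentence_key(doc_id, sent_id)] = sent
    anns = []
    for item in annotations:
        key, cs, ce, group, *rest = item
        cids = rest[0] if rest else ()
        anns.append(Annotation.make(key, index[key], cs, ce, group, cids, source))
    corpus = AnnotatedCorpus(
        source=source,
        documents=tuple(Document(d, tuple(s)) for d, s in docs.items()),
        annotations=tuple(anns),
    )
    return corpus.canonicalised()


@pytest.fixture(scope="session")
def truth_corpus():
    """A 50-document synthetic ground-truth corpus (pinned seed)."""
    return generate_truth(TruthSpec(n_documents=50, seed=7))


@pytest.fixture(scope="session")
def noisy_annotators(truth_corpus):
    """Five mildly noisy simulated annotators over the shared truth text."""
    profiles = [
        AnnotatorProfile(
            source=f"a{i}", miss_rate=0.1, spurious_rate=0.2,
            boundary_jitter=0.1, inflection_rate=0.2, tag_confusion_rate=0.1,
            seed=700 + i,
        )
        for i in range(5)
    ]
    return [simulate_annotator(truth_corpus, p) for p in profiles]


def random_harmonisation_instance(rng: np.random.Generator):
    """A small random multi-source instance for oracle cross-checks.

    Three one-sentence documents over a tiny vocabulary with both frequent
    and rare words, 2-5 sources, and at most 6 annotations per sentence
    pooled over all sources.
    """
    vocab = ["alpha", "beta", "gamma", "delta", "the", "of", "kinase", "tumour"]
    sentences = []
    for d in range(3):
        words = [vocab[i] for i in rng.integers(0, len(vocab), size=rng.integers(6, 11))]
        sentences.append((f"d{d}", "s0", " ".join(words)))
    k = int(rng.integers(2, 6))
    sources = [f"p{i}" for i in range(k)]
    groups = ["CHED", "PRGE"]

    per_source: dict[str, list] = {s: [] for s in sources}
    base = build_corpus("shared", sentences, [])
    index = base.sentence_index()
    for doc_id, sent_id, _ in sentences:
        key = sentence_key(doc_id, sent_id)
        tokens = index[key].tokens
        n_anns = int(rng.integers(0, 7))
        windows = []
        for _ in range(n_anns):
            if windows and rng.random() < 0.5:
                ts, te = windows[int(rng.integers(len(windows)))]
                # sometimes nudge a boundary by one token
                if rng.random() < 0.4 and te - ts >= 2:
                    ts += 1
                elif rng.random() < 0.4 and te < len(tokens):
                    te += 1
            else:
                ts = int(rng.integers(0, len(tokens)))
                te = min(len(tokens), ts + 1 + int(rng.integers(0, 3)))
            windows.append((ts, te))
            src = sources[int(rng.integers(k))]
            group = groups[int(rng.integers(len(groups)))]
            cs, ce = tokens[ts][1], tokens[te - 1][2]
            per_source[src].append((key, cs, ce, group, (f"id{ts}-{te}",)))
    corpora = [build_corpus(s, sentences, per_source[s]) for s in sources]
    return corpora
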