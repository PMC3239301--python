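"""Domain types: annotations, sentences, documents, annotated corpora.

One :class:`AnnotatedCorpus` holds the output of exactly one annotation
source (one "contribution") over a shared sentence-segmented text.  Character
offsets are 0-based half-open Unicode code-point offsets *within the
sentence*; token extents are derived as the minimal token window covering the
character extent.  Sentence segmentation always comes from the input — this
toolkit never re-segments text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from .weighting import tokenize

__all__ = [
    "DEFAULT_GROUPS",
    "Annotation",
    "Sentence",
    "Document",
    "AnnotatedCorpus",
    "Violation",
    "validate",
    "sentence_key",
    "annotation_sort_key",
]

#: The four semantic groups: chemicals/drugs, genes/proteins,
#: diseases/disorders, species.  Extensions must be registered explicitly
#: (``extra_groups=`` on readers and validators).
DEFAULT_GROUPS: tuple[str, ...] = ("CHED", "PRGE", "DISO", "SPE")


def sentence_key(doc_id: str, sent_id: str) -> str:
    """The global sentence identifier ``docid.sentid``."""
    return f"{doc_id}.{sent_id}"


@dataclass(frozen=True)
class Sentence:
    """One sentence: id, raw text, and its token layer.

    ``tokens`` is an ordered tuple of ``(lowercased token, char_start,
    char_end)`` with non-overlapping extents inside ``text``.
    """

    id: str
    text: str
    tokens: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_text(cls, id: str, text: str) -> "Sentence":
        return cls(id=id, text=text, tokens=tuple(tokenize(text)))

    def token_window(self, char_start: int, char_end: int) -> tuple[int, int]:
        """Minimal half-open token window covering [char_start, char_end).

        A token is covered if its extent overlaps the character range.  May
        be empty (start == end) when the range falls entirely between tokens.
        """
        start = end = 0
        found_first = False
        for i, (_, ts, te) in enumerate(self.tokens):
            if te > char_start and ts < char_end:
                if not found_first:
                    start = i
                    found_first = True
                end = i + 1
        if not found_first:
            # empty window positioned at the first token to the right
            for i, (_, ts, _) in enumerate(self.tokens):
                if ts >= char_end:
                    return (i, i)
            n = len(self.tokens)
            return (n, n)
        return (start, end)


@dataclass(frozen=True)
class Annotation:
    """One typed entity mention: a character span in one sentence.

    ``concept_ids`` are opaque identifier strings (e.g. UMLS or UniProtKb
    accessions); they are carried through harmonisation but never resolved.
    """

    sentence_id: str
    char_start: int
    char_end: int
    surface: str
    group: str
    concept_ids: tuple[str, ...] = ()
    source: str = ""
    token_start: int = 0
    token_end: int = 0

    @classmethod
    def make(
        cls,
        key: str,
        sentence: Sentence,
        char_start: int,
        char_end: int,
        group: str,
        concept_ids: Iterable[str] = (),
        source: str = "",
    ) -> "Annotation":
        """Construct an annotation, deriving surface and token extent."""
        if not 0 <= char_start < char_end <= len(sentence.text):
            raise ValueError(
                f"character extent [{char_start}, {char_end}) invalid for "
                f"sentence {key!r} of length {len(sentence.text)}"
            )
        ts, te = sentence.token_window(char_start, char_end)
        return cls(
            sentence_id=key,
            char_start=char_start,
            char_end=char_end,
            surface=sentence.text[char_start:char_end],
            group=group,
            concept_ids=tuple(concept_ids),
            source=source,
            token_start=ts,
            token_end=te,
        )

    @property
    def length(self) -> int:
        return self.char_end - self.char_start

    def with_source(self, source: str) -> "Annotation":
        return replace(self, source=source)


@dataclass(frozen=True)
class Document:
    id: str
    sentences: tuple[Sentence, ...]


def annotation_sort_key(ann: Annotation) -> tuple:
    """Canonical within-sentence ordering: left-to-right, longer-first on
    ties, then group / source / concept ids for full determinism."""
    return (ann.char_start, -ann.char_end, ann.group, ann.source, ann.concept_ids)


@dataclass
class AnnotatedCorpus:
    """The annotations of one source over a sentence-segmented document set."""

    source: str
    documents: tuple[Document, ...]
    annotations: tuple[Annotation, ...]
    _index: dict[str, Sentence] | None = field(
        default=None, repr=False, compare=False
    )

    def sentence_index(self) -> dict[str, Sentence]:
        """Map ``docid.sentid`` -> :class:`Sentence` (cached)."""
        if self._index is None:
            index: dict[str, Sentence] = {}
            for doc in self.documents:
                for sent in doc.sentences:
                    index[sentence_key(doc.id, sent.id)] = sent
            self._index = index
        return self._index

    def annotations_by_sentence(self) -> dict[str, list[Annotation]]:
        grouped: dict[str, list[Annotation]] = {}
        for ann in self.annotations:
            grouped.setdefault(ann.sentence_id, []).append(ann)
        return grouped

    def sentence_keys(self) -> Iterator[str]:
        for doc in self.documents:
            for sent in doc.sentences:
                yield sentence_key(doc.id, sent.id)

    def with_source(self, source: str) -> "AnnotatedCorpus":
        """Relabel the corpus (and every annotation) with a new source id."""
        return AnnotatedCorpus(
            source=source,
            documents=self.documents,
            annotations=tuple(a.with_source(source) for a in self.annotations),
        )

    def canonicalised(self) -> "AnnotatedCorpus":
        """Return a copy with annotations in canonical corpus order:
        document order, sentence order, then :func:`annotation_sort_key`."""
        order = {key: i for i, key in enumerate(self.sentence_keys())}
        anns = sorted(
            self.annotations,
            key=lambda a: (order.get(a.sentence_id, len(order)), annotation_sort_key(a)),
        )
        return AnnotatedCorpus(
            source=self.source, documents=self.documents, annotations=tuple(anns)
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate` (data, not an
    exception)."""

    document_id: str
    sentence_id: str
    rule: str
    message: str
    annotation: Annotation | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.sentence_id}: {self.message}"


def validate(
    corpus: AnnotatedCorpus, extra_groups: Iterable[str] = ()
) -> list[Violation]:
    """Check every type invariant; return a list of violations (empty iff ok).

    Rules checked: unique sentence ids per document, resolvable sentence
    references, in-range character extents, surface == text slice, minimal
    token window, registered semantic group, annotation source == corpus
    source.
    """
    groups = set(DEFAULT_GROUPS) | set(extra_groups)
    violations: list[Violation] = []
    index: dict[str, tuple[str, Sentence]] = {}
    for doc in corpus.documents:
        seen: set[str] = set()
        for sent in doc.sentences:
            if sent.id in seen:
                violations.append(
                    Violation(doc.id, sentence_key(doc.id, sent.id),
                              "sentence-id-unique",
                              f"duplicate sentence id {sent.id!r} in document {doc.id!r}")
                )
            seen.add(sent.id)
            index[sentence_key(doc.id, sent.id)] = (doc.id, sent)
    for ann in corpus.annotations:
        entry = index.get(ann.sentence_id)
        if entry is None:
            violations.append(
                Violation("?", ann.sentence_id, "sentence-resolves",
                          f"annotation references unknown sentence {ann.sentence_id!r}",
                          ann)
            )
            continue
        doc_id, sent = entry
        if not (0 <= ann.char_start < ann.char_end <= len(sent.text)):
            violations.append(
                Violation(doc_id, ann.sentence_id, "extent-in-range",
                          f"extent [{ann.char_start}, {ann.char_end}) outside "
                          f"sentence of length {len(sent.text)}", ann)
            )
            continue
        if sent.text[ann.char_start:ann.char_end] != ann.surface:
            violations.append(
                Violation(doc_id, ann.sentence_id, "surface-matches-slice",
                          f"surface {ann.surface!r} != slice "
                          f"{sent.text[ann.char_start:ann.char_end]!r}", ann)
            )
        if (ann.token_start, ann.token_end) != sent.token_window(
            ann.char_start, ann.char_end
        ):
            violations.append(
                Violation(doc_id, ann.sentence_id, "token-window-minimal",
                          f"token extent [{ann.token_start}, {ann.token_end}) is "
                          "not the minimal window covering the character extent",
                          ann)
            )
        if ann.group not in groups:
            violations.append(
                Violation(doc_id, ann.sentence_id, "group-registered",
                          f"unknown semantic group {ann.group!r}", ann)
            )
        if ann.source != corpus.source:
            violations.append(
                Violation(doc_id, ann.sentence_id, "source-consistent",
                          f"annotation source {ann.source!r} != corpus source "
                          f"{corpus.source!r}", ann)
            )
    return violations
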