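"""Reading and writing annotated corpora: inline XML and standoff TSV.

Two interchange representations are supported, both lossless for the corpora
they can express:

* **Inline XML** — a minimal dialect in the spirit of the IeXML exchange
  format: ``<corpus source="...">`` containing ``<doc id="...">`` containing
  one ``<s id="...">`` per sentence, with entity mentions marked inline as
  ``<e grp="PRGE" ids="id1|id2" src="P01">...</e>``.  Elements may nest
  (a mention inside a longer mention) but same-sentence partial overlap is
  not expressible — use standoff for that.
* **Standoff** — ``corpus.txt`` with one ``docid.sentid<TAB>text`` line per
  sentence plus ``corpus.ann``, a TSV of
  ``sentence_key, char_start, char_end, surface, group, concept_ids, source``
  (concept ids pipe-separated, ``-`` when absent).  Standoff can carry any
  corpus, including overlapping annotations.

Writers are canonical: fixed attribute order, UTF-8, one sentence per line,
sorted annotations — two writes of equal corpora are byte-identical, and
``read(write(c)) == c`` field for field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

from .model import (
    AnnotatedCorpus,
    Annotation,
    DEFAULT_GROUPS,
    Document,
    Sentence,
    annotation_sort_key,
    sentence_key,
)

__all__ = [
    "CorpusFormatError",
    "read_inline_xml",
    "write_inline_xml",
    "read_standoff",
    "write_standoff",
]


class CorpusFormatError(ValueError):
    """Malformed or inexpressible corpus data in an interchange file."""


def _check_group(group: str, groups: set[str], where: str) -> None:
    if group not in groups:
        raise CorpusFormatError(f"{where}: unknown semantic group {group!r}")


def _parse_ids(raw: str | None) -> tuple[str, ...]:
    if raw is None or raw in ("", "-"):
        return ()
    return tuple(raw.split("|"))


# ---------------------------------------------------------------------------
# inline XML
# ---------------------------------------------------------------------------

def read_inline_xml(
    path: str | Path, extra_groups: Iterable[str] = ()
) -> AnnotatedCorpus:
    """Parse an inline-XML corpus file.

    Every ``<e>`` element becomes one :class:`Annotation`, with character
    offsets recomputed from its position in the sentence text (the sentence
    text is the file's text content with tags stripped).  Raises
    :class:`CorpusFormatError` on malformed XML (with the parser's line
    number) or dialect violations.
    """
    path = Path(path)
    groups = set(DEFAULT_GROUPS) | set(extra_groups)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "corpus":
        raise CorpusFormatError(f"{path}: root element must be <corpus>, got <{root.tag}>")
    source = root.get("source")
    if source is None:
        raise CorpusFormatError(f"{path}: <corpus> missing source attribute")

    documents: list[Document] = []
    annotations: list[Annotation] = []
    for doc_el in root:
        if doc_el.tag is etree.Comment:
            continue
        if doc_el.tag != "doc":
            raise CorpusFormatError(f"{path}: unexpected element <{doc_el.tag}> under <corpus>")
        doc_id = doc_el.get("id")
        if doc_id is None or "." in doc_id:
            raise CorpusFormatError(
                f"{path}: <doc> needs an id attribute without '.' (got {doc_id!r})"
            )
        sentences: list[Sentence] = []
        for s_el in doc_el:
            if s_el.tag != "s":
                raise CorpusFormatError(
                    f"{path}: unexpected element <{s_el.tag}> under <doc id={doc_id!r}>"
                )
            s_id = s_el.get("id")
            if s_id is None:
                raise CorpusFormatError(f"{path}: <s> in doc {doc_id!r} missing id")
            key = sentence_key(doc_id, s_id)
            parts: list[str] = []
            spans: list[tuple[int, int, str, tuple[str, ...], str]] = []

            def walk(el, pos: int) -> int:
                if el.text:
                    parts.append(el.text)
                    pos += len(el.text)
                for child in el:
                    if child.tag != "e":
                        raise CorpusFormatError(
                            f"{path}: sentence {key}: unexpected element <{child.tag}>"
                        )
                    grp = child.get("grp")
                    if grp is None:
                        raise CorpusFormatError(
                            f"{path}: sentence {key}: <e> missing grp attribute"
                        )
                    _check_group(grp, groups, f"{path}: sentence {key}")
                    start = pos
                    pos = walk(child, pos)
                    if pos == start:
                        raise CorpusFormatError(
                            f"{path}: sentence {key}: empty <e grp={grp!r}> element"
                        )
                    spans.append(
                        (start, pos, grp, _parse_ids(child.get("ids")),
                         child.get("src") or source)
                    )
                    if child.tail:
                        parts.append(child.tail)
                        pos += len(child.tail)
                return pos

            walk(s_el, 0)
            sentence = Sentence.from_text(s_id, "".join(parts))
            sentences.append(sentence)
            for cs, ce, grp, ids, src in spans:
                annotations.append(
                    Annotation.make(key, sentence, cs, ce, grp, ids, src)
                )
        documents.append(Document(id=doc_id, sentences=tuple(sentences)))

    corpus = AnnotatedCorpus(
        source=source, documents=tuple(documents), annotations=tuple(annotations)
    )
    return corpus.canonicalised()


def _render_sentence(sent: Sentence, anns: list[Annotation], key: str) -> str:
    """Serialise one sentence with inline entity elements.

    Annotations must be nested or disjoint; same-sentence partial overlap
    raises :class:`CorpusFormatError` directing the caller to standoff.
    """
    ordered = sorted(anns, key=annotation_sort_key)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if b.char_start >= a.char_end:
                continue
            # b starts inside a: require containment
            if b.char_end > a.char_end:
                raise CorpusFormatError(
                    f"sentence {key}: annotations [{a.char_start},{a.char_end}) and "
                    f"[{b.char_start},{b.char_end}) overlap without nesting; "
                    "use the standoff format for this corpus"
                )

    def attrs(a: Annotation) -> str:
        out = [f"grp={quoteattr(a.group)}"]
        if a.concept_ids:
            out.append(f"ids={quoteattr('|'.join(a.concept_ids))}")
        out.append(f"src={quoteattr(a.source)}")
        return " ".join(out)

    def render(span_start: int, span_end: int, items: list[Annotation]) -> str:
        # items: annotations fully inside [span_start, span_end), canonical order
        out: list[str] = []
        pos = span_start
        i = 0
        while i < len(items):
            a = items[i]
            inner = [b for b in items[i + 1:] if b.char_start >= a.char_start
                     and b.char_end <= a.char_end]
            out.append(escape(sent.text[pos:a.char_start]))
            out.append(f"<e {attrs(a)}>")
            out.append(render(a.char_start, a.char_end, inner))
            out.append("</e>")
            pos = a.char_end
            i += 1 + len(inner)
        out.append(escape(sent.text[pos:span_end]))
        return "".join(out)

    body = render(0, len(sent.text), ordered)
    return f"<s id={quoteattr(sent.id)}>{body}</s>"


def write_inline_xml(corpus: AnnotatedCorpus, path: str | Path) -> None:
    """Write the canonical inline-XML serialisation of *corpus*.

    Deterministic (fixed attribute order, sorted annotations, newline per
    sentence); :func:`read_inline_xml` inverts it exactly.  Refuses corpora
    with same-sentence partial overlaps.
    """
    by_sentence = corpus.annotations_by_sentence()
    lines = [f"<corpus source={quoteattr(corpus.source)}>"]
    for doc in corpus.documents:
        lines.append(f"<doc id={quoteattr(doc.id)}>")
        for sent in doc.sentences:
            key = sentence_key(doc.id, sent.id)
            lines.append(_render_sentence(sent, by_sentence.get(key, []), key))
        lines.append("</doc>")
    lines.append("</corpus>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# standoff
# ---------------------------------------------------------------------------

def read_standoff(
    text_path: str | Path,
    ann_path: str | Path,
    extra_groups: Iterable[str] = (),
) -> AnnotatedCorpus:
    """Read a standoff corpus: sentence-per-line text plus annotation TSV.

    Offsets are resolved (and the surface column checked) against the text
    file; errors name the offending row.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    groups = set(DEFAULT_GROUPS) | set(extra_groups)

    documents: list[Document] = []
    current_doc: str | None = None
    current_sents: list[Sentence] = []
    index: dict[str, Sentence] = {}
    for lineno, line in enumerate(
        text_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line:
            continue
        try:
            key, text = line.split("\t", 1)
            doc_id, s_id = key.split(".", 1)
        except ValueError:
            raise CorpusFormatError(
                f"{text_path}:{lineno}: expected 'docid.sentid<TAB>text'"
            ) from None
        if doc_id != current_doc:
            if current_doc is not None:
                documents.append(Document(current_doc, tuple(current_sents)))
            current_doc, current_sents = doc_id, []
        sent = Sentence.from_text(s_id, text)
        current_sents.append(sent)
        index[key] = sent
    if current_doc is not None:
        documents.append(Document(current_doc, tuple(current_sents)))

    source: str | None = None
    annotations: list[Annotation] = []
    for lineno, line in enumerate(
        ann_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#source="):
                source = line[len("#source="):]
            continue
        cols = line.split("\t")
        if len(cols) != 7:
            raise CorpusFormatError(
                f"{ann_path}:{lineno}: expected 7 TSV columns, got {len(cols)}"
            )
        key, cs_s, ce_s, surface, group, ids_raw, src = cols
        sent = index.get(key)
        if sent is None:
            raise CorpusFormatError(
                f"{ann_path}:{lineno}: unknown sentence key {key!r}"
            )
        try:
            cs, ce = int(cs_s), int(ce_s)
        except ValueError:
            raise CorpusFormatError(
                f"{ann_path}:{lineno}: non-integer offsets {cs_s!r}/{ce_s!r}"
            ) from None
        if not (0 <= cs < ce <= len(sent.text)):
            raise CorpusFormatError(
                f"{ann_path}:{lineno}: offsets [{cs}, {ce}) out of range for "
                f"sentence {key!r} of length {len(sent.text)}"
            )
        if sent.text[cs:ce] != surface:
            raise CorpusFormatError(
                f"{ann_path}:{lineno}: surface {surface!r} does not match text "
                f"slice {sent.text[cs:ce]!r}"
            )
        _check_group(group, groups, f"{ann_path}:{lineno}")
        if source is None:
            source = src
        elif src != source:
            raise CorpusFormatError(
                f"{ann_path}:{lineno}: mixed sources {src!r} vs {source!r}; a "
                "standoff corpus holds exactly one source"
            )
        annotations.append(
            Annotation.make(key, sent, cs, ce, group, _parse_ids(ids_raw), src)
        )

    corpus = AnnotatedCorpus(
        source=source or "",
        documents=tuple(documents),
        annotations=tuple(annotations),
    )
    return corpus.canonicalised()


def write_standoff(corpus: AnnotatedCorpus, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``corpus.txt`` and ``corpus.ann`` into *out_dir* (created if
    needed); returns the two paths.  Canonical and lossless for any corpus,
    including overlapping annotations the inline dialect rejects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    text_path = out_dir / "corpus.txt"
    ann_path = out_dir / "corpus.ann"

    text_lines = []
    for doc in corpus.documents:
        if "." in doc.id:
            raise CorpusFormatError(f"document id {doc.id!r} may not contain '.'")
        for sent in doc.sentences:
            text_lines.append(f"{sentence_key(doc.id, sent.id)}\t{sent.text}")
    text_path.write_text("\n".join(text_lines) + "\n", encoding="utf-8")

    ann_lines = [f"#source={corpus.source}"]
    for ann in corpus.canonicalised().annotations:
        ids = "|".join(ann.concept_ids) if ann.concept_ids else "-"
        ann_lines.append(
            "\t".join(
                (ann.sentence_id, str(ann.char_start), str(ann.char_end),
                 ann.surface, ann.group, ids, ann.source)
            )
        )
    ann_path.write_text("\n".join(ann_lines) + "\n", encoding="utf-8")
    return text_path, ann_path
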