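"""Tokenisation, corpus-wide IDF weights, and IDF-weighted cosine similarity.

The similarity primitive used throughout harmonisation and evaluation is the
cosine between sparse token vectors built from an annotation's token extent,
where each token is weighted by tf x idf.  Tokens occurring in every document
carry weight 0 and therefore never influence a score: a boundary disagreement
that only adds or removes such a token (a determiner, say) is invisible to the
cosine, which is what makes a high acceptance threshold like 0.98 workable for
near-identical entity spans.

Tokenisation is deliberately minimal: lowercase, split on any maximal run of
non-alphanumeric characters, no stemming.  Inflectional variants such as
"tumour" / "tumours" remain distinct tokens — that kind of disagreement is a
genuine annotation phenomenon and must not be normalised away here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .model import Annotation, Document, Sentence

__all__ = [
    "tokenize",
    "IdfTable",
    "TokenVector",
    "compute_idf",
    "annotation_vector",
    "cosine",
    "ZeroNormError",
]

# Maximal runs of alphanumeric characters; underscore counts as a separator.
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class ZeroNormError(ValueError):
    """Raised when a cosine is requested for a vector of norm zero."""


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split *text* into lowercased tokens with character extents.

    Returns a list of ``(token, char_start, char_end)`` triples with 0-based,
    half-open extents into the original string.  Deterministic; "" -> [].

    >>> [t for t, _, _ in tokenize("IL-2R binds")]
    ['il', '2r', 'binds']
    """
    return [(m.group().lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass
class IdfTable:
    """Inverse-document-frequency weights over a shared corpus.

    ``weight(t) = ln(N / df(t))`` with document frequencies counted at the
    document level (a token occurring five times in one document has df 1).
    Tokens never seen during computation get the smoothed weight
    ``ln(N) + 1`` — finite and strictly larger than any observed token's.
    """

    n_documents: int
    df: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("IdfTable requires at least one document")
        for token, count in self.df.items():
            if not 1 <= count <= self.n_documents:
                raise ValueError(
                    f"df[{token!r}]={count} outside [1, {self.n_documents}]"
                )

    def weight(self, token: str) -> float:
        count = self.df.get(token)
        if count is None:
            return math.log(self.n_documents) + 1.0
        return math.log(self.n_documents / count)

    # -- persistence ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write ``token \\t df`` rows under a ``#n_documents=N`` header."""
        lines = [f"#n_documents={self.n_documents}"]
        lines.extend(f"{t}\t{c}" for t, c in sorted(self.df.items()))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdfTable":
        text = Path(path).read_text(encoding="utf-8")
        lines = [ln for ln in text.splitlines() if ln]
        if not lines or not lines[0].startswith("#n_documents="):
            raise ValueError(f"{path}: missing #n_documents header")
        n = int(lines[0].split("=", 1)[1])
        df: dict[str, int] = {}
        for ln in lines[1:]:
            token, count = ln.split("\t")
            df[token] = int(count)
        return cls(n_documents=n, df=df)


def compute_idf(documents: "Iterable[Document]") -> IdfTable:
    """Compute document-level IDF weights over the shared corpus text.

    *documents* is any iterable of :class:`~silverner.model.Document`; pass
    ``corpus.documents`` for a single annotated corpus (all contributions
    share the text, so any one of them defines the table).
    """
    n = 0
    df: dict[str, int] = {}
    for doc in documents:
        n += 1
        seen: set[str] = set()
        for sent in doc.sentences:
            for token, _, _ in sent.tokens:
                seen.add(token)
        for token in seen:
            df[token] = df.get(token, 0) + 1
    if n == 0:
        raise ValueError("cannot compute IDF over an empty corpus")
    return IdfTable(n_documents=n, df=df)


@dataclass
class TokenVector:
    """Sparse tf x idf vector over the tokens of one annotation extent."""

    weights: dict[str, float]
    origin: "Annotation | None" = None
    _norm: float | None = field(default=None, repr=False, compare=False)

    @property
    def norm(self) -> float:
        if self._norm is None:
            self._norm = math.sqrt(sum(w * w for w in self.weights.values()))
        return self._norm


def annotation_vector(
    annotation: "Annotation", sentence: "Sentence", idf: IdfTable
) -> TokenVector:
    """Build the tf x idf vector over the annotation's token extent.

    Repeated tokens accumulate term frequency multiplicatively.  Raises
    ``ValueError`` if the extent covers no token.
    """
    tokens = sentence.tokens[annotation.token_start : annotation.token_end]
    if not tokens:
        raise ValueError(
            f"annotation {annotation.surface!r} in sentence "
            f"{annotation.sentence_id!r} covers no token"
        )
    tf: dict[str, int] = {}
    for token, _, _ in tokens:
        tf[token] = tf.get(token, 0) + 1
    weights = {t: n * idf.weight(t) for t, n in tf.items()}
    return TokenVector(weights=weights, origin=annotation)


def cosine(a: TokenVector | Mapping[str, float], b: TokenVector | Mapping[str, float]) -> float:
    """Cosine similarity of two sparse non-negative vectors, in [0, 1].

    Symmetric; 1.0 iff the vectors are proportional.  Raises
    :class:`ZeroNormError` if either norm is zero — the caller decides the
    policy (harmonisation treats such pairs as non-alignable).
    """
    wa = a.weights if isinstance(a, TokenVector) else a
    wb = b.weights if isinstance(b, TokenVector) else b
    na = math.sqrt(sum(w * w for w in wa.values()))
    nb = math.sqrt(sum(w * w for w in wb.values()))
    if na == 0.0 or nb == 0.0:
        raise ZeroNormError("cosine undefined for a zero-norm vector")
    if len(wb) < len(wa):
        wa, wb = wb, wa
    dot = sum(w * wb[t] for t, w in wa.items() if t in wb)
    return min(1.0, dot / (na * nb))
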