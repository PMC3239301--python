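"""Scoring a predicted corpus against a reference: P / R / F per group.

Three span-matching predicates are supported, from strictest to most
lenient:

* **exact** — identical character extents;
* **nested** — one extent contains the other (either direction; equality
  counts);
* **cosine** — token extents overlap and the IDF-weighted cosine of the two
  token vectors is strictly above a threshold tau (presets 0.98 and 0.9).

True positives are counted by a maximum-cardinality one-to-one matching
between predictions and references within each sentence and group, so one
prediction can never claim several references.  Precision, recall and the
F-measure (harmonic mean) follow, with the usual zero conventions so that
degenerate submissions score rather than crash.  The report carries a
macro-averaged row over groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import AnnotatedCorpus, Annotation, Sentence, annotation_sort_key
from .weighting import IdfTable, ZeroNormError, annotation_vector, compute_idf, cosine

__all__ = [
    "MatchMode",
    "EXACT",
    "NESTED",
    "COS98",
    "COS90",
    "DEFAULT_MODES",
    "EvalCell",
    "EvalReport",
    "span_match",
    "match_annotations",
    "evaluate_corpus",
]

AVERAGE_GROUP = "avg"


@dataclass(frozen=True)
class MatchMode:
    """One span-matching scheme: ``exact``, ``nested`` or ``cosine`` (with
    threshold)."""

    kind: str
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "nested", "cosine"):
            raise ValueError(f"unknown match kind {self.kind!r}")
        if (self.tau is not None) != (self.kind == "cosine"):
            raise ValueError("tau must be given iff kind == 'cosine'")

    @property
    def label(self) -> str:
        if self.kind == "cosine":
            return f"cos{self.tau:g}"
        return self.kind

    @classmethod
    def parse(cls, text: str) -> "MatchMode":
        """Parse a mode label such as ``exact``, ``nested`` or ``cos0.98``."""
        text = text.strip()
        if text in ("exact", "nested"):
            return cls(text)
        m = re.fullmatch(r"cos(0?\.\d+|1(\.0*)?)", text)
        if m:
            return cls("cosine", float(m.group(1)))
        raise ValueError(f"cannot parse match mode {text!r}")


EXACT = MatchMode("exact")
NESTED = MatchMode("nested")
COS98 = MatchMode("cosine", 0.98)
COS90 = MatchMode("cosine", 0.9)
DEFAULT_MODES: tuple[MatchMode, ...] = (EXACT, NESTED, COS98, COS90)


def span_match(
    pred: Annotation,
    ref: Annotation,
    mode: MatchMode,
    sentence: Sentence | None = None,
    idf: IdfTable | None = None,
) -> bool:
    """Does *pred* match *ref* under *mode*?  Both must belong to the same
    sentence and semantic group.  Cosine mode needs *sentence* and *idf*;
    a zero-norm vector never matches."""
    if pred.sentence_id != ref.sentence_id or pred.group != ref.group:
        raise ValueError("span_match requires same sentence and group")
    if mode.kind == "exact":
        return (pred.char_start, pred.char_end) == (ref.char_start, ref.char_end)
    if mode.kind == "nested":
        return (
            (pred.char_start <= ref.char_start and ref.char_end <= pred.char_end)
            or (ref.char_start <= pred.char_start and pred.char_end <= ref.char_end)
        )
    if sentence is None or idf is None:
        raise ValueError("cosine matching requires the sentence and an IdfTable")
    if not (pred.token_start < ref.token_end and ref.token_start < pred.token_end):
        return False
    try:
        score = cosine(
            annotation_vector(pred, sentence, idf),
            annotation_vector(ref, sentence, idf),
        )
    except (ZeroNormError, ValueError):
        return False
    return score > mode.tau


def _pair_score(
    pred: Annotation,
    ref: Annotation,
    mode: MatchMode,
    sentence: Sentence | None,
    idf: IdfTable | None,
) -> float | None:
    """Matching score for a pair, or None when the pair does not match."""
    if not span_match(pred, ref, mode, sentence, idf):
        return None
    if mode.kind != "cosine":
        return 1.0
    return cosine(
        annotation_vector(pred, sentence, idf),
        annotation_vector(ref, sentence, idf),
    )


def match_annotations(
    preds: Sequence[Annotation],
    refs: Sequence[Annotation],
    mode: MatchMode,
    sentence: Sentence | None = None,
    idf: IdfTable | None = None,
) -> list[tuple[int, int]]:
    """Maximum-cardinality one-to-one matching between *preds* and *refs*.

    Among maximum matchings, total cosine score is maximised (assignment
    problem); the result is deterministic.  Returns index pairs into the
    canonically sorted inputs as given.
    """
    if not preds or not refs:
        return []
    weight = np.zeros((len(preds), len(refs)))
    for i, p in enumerate(preds):
        for j, r in enumerate(refs):
            s = _pair_score(p, r, mode, sentence, idf)
            if s is not None:
                # cardinality strictly dominates the score tie-break
                weight[i, j] = 1000.0 + s
    rows, cols = linear_sum_assignment(weight, maximize=True)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if weight[i, j] > 0.0]


@dataclass
class EvalCell:
    group: str
    mode: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    empty_reference: bool = False


@dataclass
class EvalReport:
    """Per-(group, mode) counts and scores, plus a macro-average row."""

    cells: list[EvalCell] = field(default_factory=list)

    def get(self, group: str, mode: str | MatchMode) -> EvalCell:
        label = mode.label if isinstance(mode, MatchMode) else mode
        for cell in self.cells:
            if cell.group == group and cell.mode == label:
                return cell
        raise KeyError((group, label))

    def f(self, group: str, mode: str | MatchMode) -> float:
        return self.get(group, mode).f_measure

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": c.group,
                    "mode": c.mode,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f": c.f_measure,
                    "empty_reference": c.empty_reference,
                }
                for c in self.cells
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def _sample_documents(
    corpus: AnnotatedCorpus, n_documents: int, seed: int
) -> set[str]:
    ids = [d.id for d in corpus.documents]
    if n_documents >= len(ids):
        return set(ids)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_documents, replace=False)
    return {ids[i] for i in chosen}


def evaluate_corpus(
    pred: AnnotatedCorpus,
    ref: AnnotatedCorpus,
    modes: Iterable[MatchMode] = DEFAULT_MODES,
    groups: Iterable[str] | None = None,
    sample: tuple[int, int] | None = None,
    idf: IdfTable | None = None,
) -> EvalReport:
    """Evaluate *pred* against *ref* under every mode, per semantic group.

    The corpora must share sentence text.  ``sample=(n_documents, seed)``
    restricts the evaluation to a seed-deterministic random document subset
    (the full corpus when n exceeds the document count).  When *groups* is
    None, every group present in either corpus is scored.  The IDF table for
    cosine modes defaults to one computed over the shared text.  A group
    absent from the reference is scored with the zero conventions and
    flagged ``empty_reference``.
    """
    modes = tuple(modes)
    ref_index = ref.sentence_index()
    pred_index = pred.sentence_index()
    keys = list(ref.sentence_keys())
    if list(pred.sentence_keys()) != keys:
        raise ValueError("prediction and reference do not share the same sentences")
    for key in keys:
        if pred_index[key].text != ref_index[key].text:
            raise ValueError(f"sentence {key} text differs between pred and ref")

    doc_subset: set[str] | None = None
    if sample is not None:
        n_documents, seed = sample
        doc_subset = _sample_documents(ref, n_documents, seed)

    def in_sample(key: str) -> bool:
        return doc_subset is None or key.split(".", 1)[0] in doc_subset

    if any(m.kind == "cosine" for m in modes) and idf is None:
        idf = compute_idf(ref.documents)

    if groups is None:
        group_list = sorted(
            {a.group for a in ref.annotations} | {a.group for a in pred.annotations}
        )
    else:
        group_list = list(groups)

    pred_by_sent = pred.annotations_by_sentence()
    ref_by_sent = ref.annotations_by_sentence()

    report = EvalReport()
    per_mode_cells: dict[str, list[EvalCell]] = {m.label: [] for m in modes}
    for group in group_list:
        ref_empty = True
        counts = {m.label: [0, 0, 0] for m in modes}  # tp, fp, fn
        for key in keys:
            if not in_sample(key):
                continue
            preds = sorted(
                (a for a in pred_by_sent.get(key, ()) if a.group == group),
                key=annotation_sort_key,
            )
            refs = sorted(
                (a for a in ref_by_sent.get(key, ()) if a.group == group),
                key=annotation_sort_key,
            )
            if refs:
                ref_empty = False
            if not preds and not refs:
                continue
            sentence = ref_index[key]
            for m in modes:
                matched = match_annotations(preds, refs, m, sentence, idf)
                tp = len(matched)
                counts[m.label][0] += tp
                counts[m.label][1] += len(preds) - tp
                counts[m.label][2] += len(refs) - tp
        for m in modes:
            tp, fp, fn = counts[m.label]
            precision, recall, f = _prf(tp, fp, fn)
            cell = EvalCell(
                group=group, mode=m.label, tp=tp, fp=fp, fn=fn,
                precision=precision, recall=recall, f_measure=f,
                empty_reference=ref_empty,
            )
            report.cells.append(cell)
            per_mode_cells[m.label].append(cell)

    # macro average over groups, per mode
    for m in modes:
        cells = per_mode_cells[m.label]
        if not cells:
            continue
        report.cells.append(
            EvalCell(
                group=AVERAGE_GROUP,
                mode=m.label,
                tp=sum(c.tp for c in cells),
                fp=sum(c.fp for c in cells),
                fn=sum(c.fn for c in cells),
                precision=float(np.mean([c.precision for c in cells])),
                recall=float(np.mean([c.recall for c in cells])),
                f_measure=float(np.mean([c.f_measure for c in cells])),
            )
        )
    return report
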