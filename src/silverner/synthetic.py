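"""Synthetic ground-truth corpora and simulated imperfect annotators.

Real silver-standard construction starts from a large shared text corpus and
K independent NER systems.  Neither is needed to exercise the harmonisation
mathematics: the alignment sees only tokens, document frequencies and span
extents.  This module therefore generates sentences as synthetic token
sequences — a Zipf-weighted common vocabulary with planted entity mentions
from per-group lexicons — and simulates annotators whose errors reproduce
the disagreement phenomena observed between real annotation systems:

* **missed entities** (false negatives) — an annotator simply fails to mark
  a true mention;
* **spurious entities** (false positives) — a non-entity token window is
  marked, plausibly, since filler text contains occasional entity-lexicon
  words;
* **boundary jitter** — a mention is extended or truncated by one token,
  e.g. absorbing a neighbouring low-content word;
* **tag confusion** — an ambiguous mention (the "insulin" case) is emitted
  with the alternate semantic group, e.g. PRGE instead of CHED;
* **inflectional boundaries** — when the text prints an inflected surface
  ("tumours"), an annotator may mark only the stem ("tumour"): a sub-token
  character-boundary disagreement that span alignment can resolve.

Generation metadata needed by the simulator (the alternate group of an
ambiguous mention; the printed inflectional suffix) rides along in the truth
annotations' opaque concept ids, prefixed ``alt:`` and ``infl:``, so a truth
corpus is self-describing even after a file round-trip.  Simulated
annotators carry only the primary concept id.

Everything is deterministic under the spec / profile seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .evaluate import DEFAULT_MODES, EvalReport, MatchMode, evaluate_corpus
from .harmonise import (
    HarmonisationConfig,
    HarmonisationStats,
    SweepEntry,
    harmonise_corpus,
    vote_sweep,
)
from .model import (
    AnnotatedCorpus,
    Annotation,
    DEFAULT_GROUPS,
    Document,
    Sentence,
    sentence_key,
)
from .weighting import IdfTable, compute_idf

__all__ = [
    "TruthSpec",
    "AnnotatorProfile",
    "LexiconEntry",
    "RecoveryReport",
    "generate_truth",
    "simulate_annotator",
    "recovery_experiment",
]

_ALT_PREFIX = "alt:"
_INFL_PREFIX = "infl:"


@dataclass(frozen=True)
class LexiconEntry:
    """One entity name: 1–4 tokens, optionally tag-ambiguous and/or carrying
    an inflectional variant suffix on its last token."""

    entity_id: str
    group: str
    tokens: tuple[str, ...]
    alt_group: str | None = None
    variant_suffix: str | None = None


@dataclass(frozen=True)
class TruthSpec:
    """Parameters of the synthetic ground-truth corpus.

    Defaults describe a desk-scale stand-in for an abstract collection:
    100 documents of 4–7 sentences, a 2000-word common vocabulary sampled
    with Zipf-like weights (so the most frequent words approach IDF 0, the
    way determiners and prepositions do), 40 entity names per semantic
    group, and on average 2 entity mentions per sentence (Poisson).
    """

    n_documents: int = 100
    sentences_per_document: tuple[int, int] = (4, 7)
    n_common_words: int = 2000
    lexicon_size: int = 40
    entities_per_sentence: float = 2.0
    variant_fraction: float = 0.3
    ambiguous_fraction: float = 0.2
    distractor_rate: float = 0.05
    filler_run: tuple[int, int] = (2, 5)
    groups: tuple[str, ...] = DEFAULT_GROUPS
    ambiguity_pairs: tuple[tuple[str, str], ...] = (("CHED", "PRGE"),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_documents < 1 or self.lexicon_size < 1 or self.n_common_words < 1:
            raise ValueError("all corpus size parameters must be positive")
        if self.entities_per_sentence < 0:
            raise ValueError("entities_per_sentence must be >= 0")
        if self.filler_run[0] < 2:
            raise ValueError("filler runs must be >= 2 tokens (entity separation)")
        if not self.groups:
            raise ValueError("at least one semantic group is required")


@dataclass(frozen=True)
class AnnotatorProfile:
    """Error rates of one simulated annotation system."""

    source: str
    miss_rate: float = 0.1
    spurious_rate: float = 0.2
    boundary_jitter: float = 0.1
    tag_confusion_rate: float = 0.0
    inflection_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "boundary_jitter", "tag_confusion_rate",
                     "inflection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")


def build_lexicons(spec: TruthSpec, rng: np.random.Generator) -> dict[str, list[LexiconEntry]]:
    """Deterministically draw per-group entity lexicons from group-specific
    word pools."""
    alt_of: dict[str, str] = {}
    for a, b in spec.ambiguity_pairs:
        alt_of[a] = b
        alt_of[b] = a
    n_ambiguous = int(round(spec.ambiguous_fraction * spec.lexicon_size))
    length_probs = np.array([0.45, 0.30, 0.15, 0.10])
    lexicons: dict[str, list[LexiconEntry]] = {}
    for group in spec.groups:
        pool = [f"{group.lower()}{i:03d}" for i in range(2 * spec.lexicon_size)]
        entries: list[LexiconEntry] = []
        seen: set[tuple[str, ...]] = set()
        while len(entries) < spec.lexicon_size:
            n_tokens = int(rng.choice(4, p=length_probs)) + 1
            tokens = tuple(pool[i] for i in rng.choice(len(pool), size=n_tokens))
            if tokens in seen:
                continue
            seen.add(tokens)
            i = len(entries)
            entries.append(
                LexiconEntry(
                    entity_id=f"{group}-{i:03d}",
                    group=group,
                    tokens=tokens,
                    alt_group=alt_of.get(group) if i < n_ambiguous else None,
                    variant_suffix="s" if rng.random() < spec.variant_fraction else None,
                )
            )
        lexicons[group] = entries
    return lexicons


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / (np.arange(n) + 2.0)
    return w / w.sum()


def generate_truth(spec: TruthSpec) -> AnnotatedCorpus:
    """Generate the ground-truth corpus (source ``"truth"``).

    Sentences mix Zipf-weighted common words (with occasional entity-word
    distractors) and planted entity mentions separated by at least two
    filler tokens; every planted mention is recorded as a truth annotation.
    """
    rng = np.random.default_rng(spec.seed)
    lexicons = build_lexicons(spec, rng)
    for group in spec.groups:
        if not lexicons[group]:
            raise ValueError(f"empty entity lexicon for group {group!r}")
    common = [f"cw{i:04d}" for i in range(spec.n_common_words)]
    probs = _zipf_probs(spec.n_common_words)
    all_entity_words = [w for g in spec.groups for e in lexicons[g] for w in e.tokens]

    documents: list[Document] = []
    annotations: list[Annotation] = []
    lo, hi = spec.sentences_per_document
    flo, fhi = spec.filler_run
    for di in range(spec.n_documents):
        doc_id = f"d{di:04d}"
        n_sent = int(rng.integers(lo, hi + 1))
        sentences: list[Sentence] = []
        for si in range(n_sent):
            s_id = f"s{si}"
            key = sentence_key(doc_id, s_id)
            k = int(rng.poisson(spec.entities_per_sentence))
            run_lengths = rng.integers(flo, fhi + 1, size=k + 1)
            n_filler = int(run_lengths.sum())
            filler_words = [
                common[i] for i in rng.choice(spec.n_common_words, size=n_filler, p=probs)
            ]
            distract = rng.random(n_filler) < spec.distractor_rate
            for fi in np.flatnonzero(distract):
                filler_words[fi] = all_entity_words[
                    int(rng.integers(len(all_entity_words)))
                ]

            words: list[str] = []
            # planned entities: (first_word_idx, n_words, entry, suffix_printed)
            plan: list[tuple[int, int, LexiconEntry, bool]] = []
            f_cursor = 0
            for ei in range(k):
                take = int(run_lengths[ei])
                words.extend(filler_words[f_cursor : f_cursor + take])
                f_cursor += take
                group = spec.groups[int(rng.integers(len(spec.groups)))]
                entry = lexicons[group][int(rng.integers(spec.lexicon_size))]
                printed = list(entry.tokens)
                suffix_printed = False
                if entry.variant_suffix and rng.random() < 0.5:
                    printed[-1] = printed[-1] + entry.variant_suffix
                    suffix_printed = True
                plan.append((len(words), len(printed), entry, suffix_printed))
                words.extend(printed)
            words.extend(filler_words[f_cursor:])

            starts: list[int] = []
            pos = 0
            for w in words:
                starts.append(pos)
                pos += len(w) + 1
            text = " ".join(words)
            sentence = Sentence.from_text(s_id, text)
            sentences.append(sentence)
            for first, n_words, entry, suffix_printed in plan:
                cs = starts[first]
                last = first + n_words - 1
                ce = starts[last] + len(words[last])
                cids = [entry.entity_id]
                if entry.alt_group:
                    cids.append(_ALT_PREFIX + entry.alt_group)
                if suffix_printed:
                    cids.append(_INFL_PREFIX + entry.variant_suffix)
                annotations.append(
                    Annotation.make(key, sentence, cs, ce, entry.group, cids, "truth")
                )
        documents.append(Document(id=doc_id, sentences=tuple(sentences)))
    return AnnotatedCorpus(
        source="truth", documents=tuple(documents), annotations=tuple(annotations)
    ).canonicalised()


def _primary_ids(ann: Annotation) -> tuple[str, ...]:
    return tuple(
        c for c in ann.concept_ids
        if not c.startswith((_ALT_PREFIX, _INFL_PREFIX))
    )


def _marker(ann: Annotation, prefix: str) -> str | None:
    for c in ann.concept_ids:
        if c.startswith(prefix):
            return c[len(prefix):]
    return None


def simulate_annotator(
    truth: AnnotatedCorpus,
    profile: AnnotatorProfile,
    groups: Sequence[str] | None = None,
) -> AnnotatedCorpus:
    """Derive one imperfect annotator's corpus from the truth.

    Per truth annotation: drop with ``miss_rate``; swap to the alternate
    group with ``tag_confusion_rate`` (ambiguous mentions only); perturb the
    extent by one token with ``boundary_jitter``; otherwise, for mentions
    printed with an inflectional suffix, mark only the stem with
    ``inflection_rate``.  Spurious mentions (Poisson ``spurious_rate`` per
    sentence) are placed on token windows clear of any true mention.
    Deterministic under ``profile.seed``; the random stream consumes one
    draw per decision point regardless of the rates, so changing one rate
    never perturbs the other channels.
    """
    rng = np.random.default_rng(profile.seed)
    if groups is None:
        groups = sorted({a.group for a in truth.annotations}) or list(DEFAULT_GROUPS)
    index = truth.sentence_index()
    by_sent = truth.annotations_by_sentence()
    out: list[Annotation] = []
    for key in truth.sentence_keys():
        sentence = index[key]
        anns = by_sent.get(key, [])
        for ann in anns:
            if rng.random() < profile.miss_rate:
                continue
            group = ann.group
            alt = _marker(ann, _ALT_PREFIX)
            if alt is not None and rng.random() < profile.tag_confusion_rate:
                group = alt
            cids = _primary_ids(ann)
            jittered = False
            if rng.random() < profile.boundary_jitter:
                ts, te = ann.token_start, ann.token_end
                ops = []
                if ts > 0:
                    ops.append("extend_left")
                if te < len(sentence.tokens):
                    ops.append("extend_right")
                if te - ts >= 2:
                    ops.extend(("trunc_first", "trunc_last"))
                if ops:
                    op = ops[int(rng.integers(len(ops)))]
                    if op == "extend_left":
                        ts -= 1
                    elif op == "extend_right":
                        te += 1
                    elif op == "trunc_first":
                        ts += 1
                    else:
                        te -= 1
                    cs = sentence.tokens[ts][1]
                    ce = sentence.tokens[te - 1][2]
                    out.append(
                        Annotation.make(key, sentence, cs, ce, group, cids,
                                        profile.source)
                    )
                    jittered = True
            if jittered:
                continue
            cs, ce = ann.char_start, ann.char_end
            suffix = _marker(ann, _INFL_PREFIX)
            if suffix is not None and rng.random() < profile.inflection_rate:
                ce -= len(suffix)
            out.append(
                Annotation.make(key, sentence, cs, ce, group, cids, profile.source)
            )
        # spurious mentions over token windows clear of true mentions
        n_spurious = int(rng.poisson(profile.spurious_rate))
        if n_spurious:
            blocked: set[int] = set()
            for ann in anns:
                blocked.update(range(ann.token_start - 1, ann.token_end + 1))
            free = [
                i for i in range(len(sentence.tokens)) if i not in blocked
            ]
            free_set = set(free)
            for _ in range(n_spurious):
                length = 2 if rng.random() < 0.3 else 1
                while length >= 1:
                    cands = [
                        i for i in free
                        if all(i + d in free_set for d in range(length))
                    ]
                    if cands:
                        break
                    length -= 1
                if length < 1:
                    continue
                start = cands[int(rng.integers(len(cands)))]
                for d in range(length):
                    free_set.discard(start + d)
                free = [i for i in free if i not in range(start, start + length)]
                cs = sentence.tokens[start][1]
                ce = sentence.tokens[start + length - 1][2]
                group = groups[int(rng.integers(len(groups)))]
                out.append(
                    Annotation.make(key, sentence, cs, ce, group, (), profile.source)
                )
    return AnnotatedCorpus(
        source=profile.source, documents=truth.documents, annotations=tuple(out)
    ).canonicalised()


@dataclass
class RecoveryReport:
    """End-to-end record of one truth -> K annotators -> silver experiment."""

    truth: AnnotatedCorpus
    annotators: dict[str, AnnotatedCorpus]
    idf: IdfTable
    silver: AnnotatedCorpus
    stats: HarmonisationStats
    silver_vs_truth: EvalReport
    annotator_vs_truth: dict[str, EvalReport]
    annotator_vs_silver: dict[str, EvalReport]
    sweep: list[SweepEntry] = field(default_factory=list)
    sweep_vs_truth: list[tuple[int, EvalReport]] = field(default_factory=list)

    def mean_annotator_f(self, mode: str | MatchMode, group: str = "avg") -> float:
        values = [r.f(group, mode) for r in self.annotator_vs_truth.values()]
        return float(np.mean(values))

    def consensus_gain(self, mode: str | MatchMode, group: str = "avg") -> float:
        """Silver-vs-truth F minus the mean annotator-vs-truth F."""
        return self.silver_vs_truth.f(group, mode) - self.mean_annotator_f(mode, group)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.silver_vs_truth.cells:
            rows.append({"corpus": "silver_vs_truth", "group": cell.group,
                         "mode": cell.mode, "precision": cell.precision,
                         "recall": cell.recall, "f": cell.f_measure})
        for src, report in self.annotator_vs_truth.items():
            for cell in report.cells:
                rows.append({"corpus": f"{src}_vs_truth", "group": cell.group,
                             "mode": cell.mode, "precision": cell.precision,
                             "recall": cell.recall, "f": cell.f_measure})
        return pd.DataFrame(rows)


def recovery_experiment(
    spec: TruthSpec,
    profiles: Sequence[AnnotatorProfile],
    config: HarmonisationConfig | None = None,
    modes: Iterable[MatchMode] = DEFAULT_MODES,
    sweep_votes: Iterable[int] | None = None,
) -> RecoveryReport:
    """Generate truth, simulate K annotators, harmonise, and evaluate.

    Evaluates silver vs truth and every annotator vs truth and vs silver in
    all *modes*, and runs the vote sweep (default 2..K) with a silver-vs-
    truth evaluation per vote threshold.
    """
    config = config or HarmonisationConfig()
    if len(profiles) < config.votes:
        raise ValueError(
            f"need at least votes={config.votes} annotator profiles, "
            f"got {len(profiles)}"
        )
    if len({p.source for p in profiles}) != len(profiles):
        raise ValueError("annotator profiles must carry distinct source ids")
    modes = tuple(modes)
    truth = generate_truth(spec)
    corpora = [simulate_annotator(truth, p, groups=spec.groups) for p in profiles]
    idf = compute_idf(truth.documents)
    silver, stats = harmonise_corpus(corpora, config, idf=idf)
    silver_vs_truth = evaluate_corpus(silver, truth, modes, idf=idf)
    annotator_vs_truth = {
        c.source: evaluate_corpus(c, truth, modes, idf=idf) for c in corpora
    }
    annotator_vs_silver = {
        c.source: evaluate_corpus(c, silver, modes, idf=idf) for c in corpora
    }
    votes = list(sweep_votes) if sweep_votes is not None else list(
        range(2, len(profiles) + 1)
    )
    sweep = vote_sweep(corpora, config, votes, idf=idf)
    sweep_vs_truth = [
        (entry.votes, evaluate_corpus(entry.silver, truth, modes, idf=idf))
        for entry in sweep
    ]
    return RecoveryReport(
        truth=truth,
        annotators={c.source: c for c in corpora},
        idf=idf,
        silver=silver,
        stats=stats,
        silver_vs_truth=silver_vs_truth,
        annotator_vs_truth=annotator_vs_truth,
        annotator_vs_silver=annotator_vs_silver,
        sweep=sweep,
        sweep_vs_truth=sweep_vs_truth,
    )
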