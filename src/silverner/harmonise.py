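"""Consensus ("silver standard") construction from K independent annotators.

Per sentence and semantic group, annotations from all contributing sources
are pairwise aligned: a pair aligns when the token extents overlap and the
IDF-weighted cosine of their token vectors exceeds the acceptance threshold
tau (default 0.98, strict inequality).  Clusters are the connected components
of the resulting alignment graph.  A cluster yields a consensus annotation
when at least ``votes`` *distinct* sources contributed to it (n-vote
agreement, default 2); the consensus takes the boundaries of the shortest
member (character extent), so boundary disagreements resolve toward the
tighter span.  Ties and output order are fully deterministic, so silver
output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AnnotatedCorpus,
    Annotation,
    Sentence,
    annotation_sort_key,
)
from .weighting import IdfTable, ZeroNormError, annotation_vector, compute_idf, cosine

__all__ = [
    "HarmonisationConfig",
    "AlignmentResult",
    "Cluster",
    "HarmonisationStats",
    "SweepEntry",
    "align_pair",
    "cluster_sentence",
    "select_consensus",
    "harmonise_corpus",
    "vote_sweep",
]

CONSENSUS_SOURCE = "consensus"


@dataclass(frozen=True)
class HarmonisationConfig:
    """Tunable knobs of the harmonisation step.

    tau
        Cosine acceptance threshold in (0, 1]; a pair aligns only when its
        score is strictly above tau.  0.98 is the standard setting.
    votes
        Minimum number of distinct agreeing sources for acceptance (>= 1).
    boundary_policy
        ``"shortest"`` (default) or ``"longest"`` member extent wins.
    groups
        Semantic groups to harmonise; ``None`` means every group present.
    """

    tau: float = 0.98
    votes: int = 2
    boundary_policy: str = "shortest"
    groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.votes < 1:
            raise ValueError(f"votes must be >= 1, got {self.votes}")
        if self.boundary_policy not in ("shortest", "longest"):
            raise ValueError(f"unknown boundary policy {self.boundary_policy!r}")


@dataclass(frozen=True)
class AlignmentResult:
    annotation_a: Annotation
    annotation_b: Annotation
    score: float
    aligned: bool


@dataclass
class Cluster:
    """A connected component of the per-sentence alignment graph."""

    members: tuple[Annotation, ...]
    sources: frozenset[str]
    consensus: Annotation | None = None


def align_pair(
    a: Annotation,
    b: Annotation,
    sentence: Sentence,
    idf: IdfTable,
    tau: float = 0.98,
) -> AlignmentResult:
    """Score one annotation pair; aligned iff token extents overlap and
    cosine > tau.  A zero-norm vector (all tokens weightless) makes the pair
    non-alignable with reported score 0."""
    if a.sentence_id != b.sentence_id:
        raise ValueError("align_pair requires annotations in the same sentence")
    if a.group != b.group:
        raise ValueError("align_pair requires annotations of the same group")
    overlap = a.token_start < b.token_end and b.token_start < a.token_end
    if not overlap:
        return AlignmentResult(a, b, 0.0, False)
    try:
        score = cosine(
            annotation_vector(a, sentence, idf),
            annotation_vector(b, sentence, idf),
        )
    except (ZeroNormError, ValueError):
        return AlignmentResult(a, b, 0.0, False)
    return AlignmentResult(a, b, score, score > tau)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_sentence(
    annotations: Sequence[Annotation],
    sentence: Sentence,
    idf: IdfTable,
    config: HarmonisationConfig,
) -> list[Cluster]:
    """Cluster same-sentence, same-group annotations from any number of
    sources into the connected components of the pairwise alignment graph.

    Output order is deterministic: clusters by leftmost character start
    (then canonical member order); members in canonical order.
    """
    anns = sorted(annotations, key=annotation_sort_key)
    n = len(anns)
    uf = _UnionFind(n)
    # vectors once per annotation; zero-norm/no-token extents stay singleton
    vectors = []
    for a in anns:
        try:
            vectors.append(annotation_vector(a, sentence, idf))
        except ValueError:
            vectors.append(None)
    for i in range(n):
        if vectors[i] is None or vectors[i].norm == 0.0:
            continue
        for j in range(i + 1, n):
            if vectors[j] is None or vectors[j].norm == 0.0:
                continue
            a, b = anns[i], anns[j]
            if not (a.token_start < b.token_end and b.token_start < a.token_end):
                continue
            if cosine(vectors[i], vectors[j]) > config.tau:
                uf.union(i, j)
    components: dict[int, list[Annotation]] = {}
    for i, a in enumerate(anns):
        components.setdefault(uf.find(i), []).append(a)
    clusters = [
        Cluster(members=tuple(members), sources=frozenset(m.source for m in members))
        for _, members in sorted(components.items())
    ]
    clusters.sort(key=lambda c: annotation_sort_key(c.members[0]))
    return clusters


def select_consensus(
    cluster: Cluster, config: HarmonisationConfig
) -> Annotation | None:
    """Apply the vote filter and boundary policy to one cluster.

    Returns ``None`` when fewer than ``config.votes`` distinct sources
    contributed.  Otherwise the member with the shortest (or longest)
    character extent wins; ties break by smallest char_start, then
    lexicographically smallest source id.  The consensus carries the union
    of the members' concept ids and source ``"consensus"``.
    """
    if not cluster.members:
        raise ValueError("select_consensus requires a non-empty cluster")
    if len(cluster.sources) < config.votes:
        return None
    sign = 1 if config.boundary_policy == "shortest" else -1
    winner = min(
        cluster.members,
        key=lambda m: (sign * m.length, m.char_start, m.source),
    )
    merged_ids: list[str] = []
    for m in sorted(cluster.members, key=lambda m: (m.source, annotation_sort_key(m))):
        for cid in m.concept_ids:
            if cid not in merged_ids:
                merged_ids.append(cid)
    return Annotation(
        sentence_id=winner.sentence_id,
        char_start=winner.char_start,
        char_end=winner.char_end,
        surface=winner.surface,
        group=winner.group,
        concept_ids=tuple(merged_ids),
        source=CONSENSUS_SOURCE,
        token_start=winner.token_start,
        token_end=winner.token_end,
    )


@dataclass
class HarmonisationStats:
    """Per-group bookkeeping of one harmonisation run."""

    input_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    cluster_counts: dict[str, int] = field(default_factory=dict)
    accepted_counts: dict[str, int] = field(default_factory=dict)
    vote_histogram: dict[str, dict[int, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self.cluster_counts):
            row = {
                "group": group,
                "clusters": self.cluster_counts[group],
                "accepted": self.accepted_counts.get(group, 0),
            }
            for src, n in sorted(self.input_counts.get(group, {}).items()):
                row[f"in_{src}"] = n
            for v, n in sorted(self.vote_histogram.get(group, {}).items()):
                row[f"votes_{v}"] = n
            rows.append(row)
        return pd.DataFrame(rows).fillna(0)


def _check_shared_text(corpora: Sequence[AnnotatedCorpus]) -> None:
    ref = corpora[0]
    ref_keys = list(ref.sentence_keys())
    ref_index = ref.sentence_index()
    for other in corpora[1:]:
        other_index = other.sentence_index()
        keys = list(other.sentence_keys())
        if keys != ref_keys:
            extra = next((k for k in keys if k not in ref_index), None)
            missing = next((k for k in ref_keys if k not in other_index), None)
            raise ValueError(
                f"corpora {ref.source!r} and {other.source!r} do not share the "
                f"same sentences (first divergence: "
                f"{extra or missing or 'ordering'})"
            )
        for key in ref_keys:
            if ref_index[key].text != other_index[key].text:
                raise ValueError(
                    f"sentence {key} differs between sources {ref.source!r} "
                    f"and {other.source!r}"
                )


def _iter_sentence_clusters(
    corpora: Sequence[AnnotatedCorpus],
    idf: IdfTable,
    config: HarmonisationConfig,
):
    """Yield ``(key, sentence, group, clusters)`` in canonical corpus order."""
    shared = corpora[0]
    index = shared.sentence_index()
    per_corpus = [c.annotations_by_sentence() for c in corpora]
    groups = config.groups
    for key in shared.sentence_keys():
        sentence = index[key]
        pooled: dict[str, list[Annotation]] = {}
        for grouped in per_corpus:
            for ann in grouped.get(key, ()):
                pooled.setdefault(ann.group, []).append(ann)
        for group in sorted(pooled):
            if groups is not None and group not in groups:
                continue
            clusters = cluster_sentence(pooled[group], sentence, idf, config)
            yield key, sentence, group, clusters


def harmonise_corpus(
    corpora: Sequence[AnnotatedCorpus],
    config: HarmonisationConfig | None = None,
    idf: IdfTable | None = None,
) -> tuple[AnnotatedCorpus, HarmonisationStats]:
    """Harmonise K annotated corpora over identical text into a silver corpus.

    All corpora must share the same documents, sentence ids and sentence
    text, and carry distinct source ids; ``K >= config.votes`` is required.
    When *idf* is not supplied it is computed over the shared corpus text.
    Returns the consensus corpus (source ``"consensus"``) and per-group
    statistics.
    """
    config = config or HarmonisationConfig()
    if not corpora:
        raise ValueError("harmonise_corpus requires at least one corpus")
    sources = [c.source for c in corpora]
    if len(set(sources)) != len(sources):
        raise ValueError(f"duplicate source ids among inputs: {sources}")
    if len(corpora) < config.votes:
        raise ValueError(
            f"vote threshold {config.votes} exceeds the number of "
            f"contributing sources ({len(corpora)})"
        )
    _check_shared_text(corpora)
    if idf is None:
        idf = compute_idf(corpora[0].documents)

    stats = HarmonisationStats()
    consensus_anns: list[Annotation] = []
    for key, _sentence, group, clusters in _iter_sentence_clusters(
        corpora, idf, config
    ):
        g_inputs = stats.input_counts.setdefault(group, {})
        g_hist = stats.vote_histogram.setdefault(group, {})
        stats.cluster_counts[group] = stats.cluster_counts.get(group, 0) + len(clusters)
        for cluster in clusters:
            for m in cluster.members:
                g_inputs[m.source] = g_inputs.get(m.source, 0) + 1
            nv = len(cluster.sources)
            g_hist[nv] = g_hist.get(nv, 0) + 1
            consensus = select_consensus(cluster, config)
            if consensus is not None:
                cluster.consensus = consensus
                consensus_anns.append(consensus)
                stats.accepted_counts[group] = (
                    stats.accepted_counts.get(group, 0) + 1
                )
    silver = AnnotatedCorpus(
        source=CONSENSUS_SOURCE,
        documents=corpora[0].documents,
        annotations=tuple(consensus_anns),
    ).canonicalised()
    return silver, stats


@dataclass
class SweepEntry:
    votes: int
    silver: AnnotatedCorpus
    stats: HarmonisationStats


def vote_sweep(
    corpora: Sequence[AnnotatedCorpus],
    config: HarmonisationConfig | None = None,
    votes_range: Iterable[int] = range(2, 7),
    idf: IdfTable | None = None,
) -> list[SweepEntry]:
    """Harmonise once per vote threshold in *votes_range*.

    Clustering depends only on tau, so accepted annotation sets are nested
    across increasing v and counts are non-increasing.
    """
    config = config or HarmonisationConfig()
    if idf is None and corpora:
        idf = compute_idf(corpora[0].documents)
    entries = []
    for v in votes_range:
        cfg = HarmonisationConfig(
            tau=config.tau,
            votes=v,
            boundary_policy=config.boundary_policy,
            groups=config.groups,
        )
        silver, stats = harmonise_corpus(corpora, cfg, idf=idf)
        entries.append(SweepEntry(votes=v, silver=silver, stats=stats))
    return entries
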