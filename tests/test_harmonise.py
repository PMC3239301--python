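"""Alignment, clustering, vote filtering and consensus selection."""

import numpy as np
import pytest

from silverner import (
    Cluster,
    HarmonisationConfig,
    IdfTable,
    align_pair,
    cluster_sentence,
    compute_idf,
    harmonise_corpus,
    select_consensus,
    vote_sweep,
)
from silverner.model import Annotation, Sentence
from tests.conftest import build_corpus, random_harmonisation_instance
from tests.oracles import oracle_harmonise, silver_tuples


def _ann(sent, cs, ce, group="PRGE", source="p1", cids=()):
    return Annotation.make("d1.s1", sent, cs, ce, group, cids, source)


@pytest.fixture
def sentence():
    return Sentence.from_text("s1", "the insulin receptor binds insulin")


@pytest.fixture
def idf():
    # "the" everywhere (weight 0); content words rare
    return IdfTable(n_documents=100, df={"the": 100, "insulin": 5,
                                         "receptor": 3, "binds": 10})


def test_align_identical_and_disjoint_spans(sentence, idf):
    a = _ann(sentence, 4, 20, source="p1")   # "insulin receptor"
    b = _ann(sentence, 4, 20, source="p2")
    result = align_pair(a, b, sentence, idf)
    assert result.aligned and result.score == pytest.approx(1.0)
    # same term, different occurrence: token-disjoint, never aligned
    c = _ann(sentence, 27, 34, source="p2")  # second "insulin"
    assert not align_pair(a, c, sentence, idf).aligned


def test_zero_weight_boundary_token_alignment(sentence, idf):
    a = _ann(sentence, 0, 20, source="p1")   # "the insulin receptor"
    b = _ann(sentence, 4, 20, source="p2")   # "insulin receptor"
    result = align_pair(a, b, sentence, idf, tau=0.98)
    assert result.score == pytest.approx(1.0)
    assert result.aligned


def test_align_zero_norm_vector_is_non_alignable(idf):
    sent = Sentence.from_text("s1", "the the insulin")
    a = _ann(sent, 0, 3, source="p1")   # "the" — idf 0, zero norm
    b = _ann(sent, 0, 7, source="p2")
    result = align_pair(a, b, sent, idf)
    assert not result.aligned and result.score == 0.0


def test_align_requires_same_sentence_and_group(sentence, idf):
    a = _ann(sentence, 4, 11, group="PRGE")
    b = _ann(sentence, 4, 11, group="CHED")
    with pytest.raises(ValueError):
        align_pair(a, b, sentence, idf)


def test_chain_clustering_connected_components():
    # a=[x], b=[x y], c=[y]: a~b and b~c align at tau=0.5 but a,c are
    # token-disjoint -> one component of three under transitivity
    sent = Sentence.from_text("s1", "xxx yyy")
    idf = IdfTable(n_documents=10, df={"xxx": 2, "yyy": 2})
    a = _ann(sent, 0, 3, source="p1")
    b = _ann(sent, 0, 7, source="p2")
    c = _ann(sent, 4, 7, source="p3")
    config = HarmonisationConfig(tau=0.5, votes=2)
    assert align_pair(a, b, sent, idf, 0.5).aligned
    assert align_pair(b, c, sent, idf, 0.5).aligned
    assert not align_pair(a, c, sent, idf, 0.5).aligned
    clusters = cluster_sentence([a, b, c], sent, idf, config)
    assert len(clusters) == 1 and set(clusters[0].sources) == {"p1", "p2", "p3"}
    # at tau=0.98 the chain breaks apart: cosine(a,b) = 1/sqrt(2)
    high = cluster_sentence([a, b, c], sent, idf, HarmonisationConfig(tau=0.98))
    assert len(high) == 3


def test_cluster_counts_and_disjoint_annotation(sentence, idf):
    config = HarmonisationConfig()
    a = _ann(sentence, 4, 20, source="p1")
    b = _ann(sentence, 4, 20, source="p2")
    c = _ann(sentence, 27, 34, source="p3")
    clusters = cluster_sentence([a, b, c], sentence, idf, config)
    assert [len(cl.members) for cl in clusters] == [2, 1]
    identical = cluster_sentence(
        [_ann(sentence, 4, 20, source=f"p{i}") for i in range(3)],
        sentence, idf, config,
    )
    assert len(identical) == 1 and len(identical[0].sources) == 3


def test_consensus_shortest_boundary_and_vote_counting(sentence, idf):
    long = _ann(sentence, 0, 20, source="p1", cids=("c1",))
    short = _ann(sentence, 4, 20, source="p2", cids=("c2",))
    mid = _ann(sentence, 4, 20, source="p3", cids=("c1", "c3"))
    cluster = Cluster(members=(long, short, mid),
                      sources=frozenset({"p1", "p2", "p3"}))
    consensus = select_consensus(cluster, HarmonisationConfig(votes=3))
    assert (consensus.char_start, consensus.char_end) == (4, 20)
    assert consensus.surface == "insulin receptor"
    assert consensus.source == "consensus"
    assert consensus.concept_ids == ("c1", "c2", "c3")  # union, order-stable
    # shortest tie -> smaller char_start, then smaller source id
    tie = Cluster(members=(short, mid), sources=frozenset({"p2", "p3"}))
    assert select_consensus(tie, HarmonisationConfig(votes=2)).concept_ids[0] == "c2"
    # votes count distinct sources, not annotations
    dup = Cluster(members=(long, short, short.with_source("p1")),
                  sources=frozenset({"p1", "p2"}))
    assert select_consensus(dup, HarmonisationConfig(votes=3)) is None
    assert select_consensus(cluster, HarmonisationConfig(votes=4)) is None


def test_longest_boundary_policy(sentence, idf):
    members = (_ann(sentence, 0, 20, source="p1"), _ann(sentence, 4, 20, source="p2"))
    cluster = Cluster(members=members, sources=frozenset({"p1", "p2"}))
    cfg = HarmonisationConfig(votes=2, boundary_policy="longest")
    assert select_consensus(cluster, cfg).char_start == 0


def test_harmonise_idempotence_and_source_checks(truth_corpus):
    copies = [truth_corpus.with_source(f"c{i}") for i in range(3)]
    for votes in (1, 2, 3):
        silver, _ = harmonise_corpus(copies, HarmonisationConfig(votes=votes))
        assert silver_tuples(silver) == silver_tuples(truth_corpus)
    with pytest.raises(ValueError, match="vote threshold"):
        harmonise_corpus(copies, HarmonisationConfig(votes=4))
    with pytest.raises(ValueError, match="duplicate source"):
        harmonise_corpus([truth_corpus, truth_corpus])


def test_harmonise_rejects_divergent_text(truth_corpus):
    other = build_corpus("b", [("d0000", "s0", "totally different text")], [])
    with pytest.raises(ValueError, match="not share|differs"):
        harmonise_corpus([truth_corpus.with_source("a"), other],
                         HarmonisationConfig(votes=1))


def test_harmonise_permutation_invariance(noisy_annotators):
    config = HarmonisationConfig(votes=2)
    forward, _ = harmonise_corpus(noisy_annotators, config)
    backward, _ = harmonise_corpus(list(reversed(noisy_annotators)), config)
    assert forward == backward


def test_consensus_never_invents_spans(noisy_annotators):
    silver, _ = harmonise_corpus(noisy_annotators, HarmonisationConfig(votes=2))
    member_spans = {
        (a.sentence_id, a.char_start, a.char_end, a.group)
        for c in noisy_annotators for a in c.annotations
    }
    for ann in silver.annotations:
        assert (ann.sentence_id, ann.char_start, ann.char_end, ann.group) in member_spans
        assert ann.surface in {
            a.surface for c in noisy_annotators for a in c.annotations
        }


def test_tau_monotonicity_cluster_counts(noisy_annotators):
    idf = compute_idf(noisy_annotators[0].documents)
    counts = []
    for tau in (0.5, 0.9, 0.98):
        _, stats = harmonise_corpus(
            noisy_annotators, HarmonisationConfig(tau=tau, votes=2), idf=idf
        )
        counts.append(sum(stats.cluster_counts.values()))
    assert counts == sorted(counts)  # raising tau never merges clusters


def test_vote_sweep_monotone_and_v1_accepts_every_cluster(noisy_annotators):
    entries = vote_sweep(noisy_annotators, votes_range=range(1, 6))
    sizes = [len(e.silver.annotations) for e in entries]
    assert sizes == sorted(sizes, reverse=True)
    total_clusters = sum(entries[0].stats.cluster_counts.values())
    assert sizes[0] == total_clusters  # v=1: every cluster yields a consensus


def test_harmonise_matches_bruteforce_on_small_instances():
    rng = np.random.default_rng(42)
    for _ in range(30):
        corpora = random_harmonisation_instance(rng)
        tau = float(rng.choice([0.5, 0.9, 0.98]))
        votes = int(rng.integers(1, len(corpora) + 1))
        silver, _ = harmonise_corpus(
            corpora, HarmonisationConfig(tau=tau, votes=votes)
        )
        assert silver_tuples(silver) == oracle_harmonise(corpora, tau, votes)


def test_stats_bookkeeping(noisy_annotators):
    silver, stats = harmonise_corpus(noisy_annotators, HarmonisationConfig(votes=2))
    for group, hist in stats.vote_histogram.items():
        accepted = sum(n for v, n in hist.items() if v >= 2)
        assert accepted == stats.accepted_counts.get(group, 0)
        assert sum(hist.values()) == stats.cluster_counts[group]
    assert len(silver.annotations) == sum(stats.accepted_counts.values())
    frame = stats.to_frame()
    assert set(frame["group"]) == set(stats.cluster_counts)
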