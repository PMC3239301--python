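"""Span matching, one-to-one TP counting, and P/R/F reports."""

import numpy as np
import pytest

from silverner import (
    COS90,
    COS98,
    DEFAULT_MODES,
    EXACT,
    NESTED,
    HarmonisationConfig,
    IdfTable,
    MatchMode,
    compute_idf,
    evaluate_corpus,
    harmonise_corpus,
    match_annotations,
    span_match,
)
from silverner.model import Annotation, Sentence
from tests.conftest import build_corpus
from tests.oracles import oracle_max_matching_size


@pytest.fixture
def sentence():
    return Sentence.from_text("s1", "the human insulin receptor binds")


@pytest.fixture
def idf():
    return IdfTable(n_documents=100, df={"the": 100, "human": 30,
                                         "insulin": 5, "receptor": 3, "binds": 10})


def _ann(sent, cs, ce, group="PRGE", source="x"):
    return Annotation.make("d1.s1", sent, cs, ce, group, (), source)


def test_match_mode_parsing():
    assert MatchMode.parse("exact") == EXACT
    assert MatchMode.parse("cos0.98") == COS98
    assert MatchMode.parse("cos0.9").tau == 0.9
    with pytest.raises(ValueError):
        MatchMode.parse("fuzzy")
    with pytest.raises(ValueError):
        MatchMode("exact", tau=0.5)


def test_span_match_modes(sentence, idf):
    whole = _ann(sentence, 10, 26)       # "insulin receptor"
    inner = _ann(sentence, 10, 26)
    nested = _ann(sentence, 4, 26)       # "human insulin receptor"
    crossing = _ann(sentence, 4, 17)     # "human insulin"
    right = _ann(sentence, 10, 32)       # "insulin receptor binds"
    # identical spans satisfy every mode
    for mode in DEFAULT_MODES:
        assert span_match(whole, inner, mode, sentence, idf)
    # containment either direction, no containment for crossing overlap
    assert span_match(whole, nested, NESTED)
    assert span_match(nested, whole, NESTED)
    assert not span_match(crossing, right, NESTED)
    assert not span_match(whole, nested, EXACT)
    # cosine: "human insulin receptor" vs "insulin receptor" share the heavy
    # tokens but "human" (df 40) carries real weight -> below 0.98
    assert not span_match(nested, whole, COS98, sentence, idf)
    assert span_match(nested, whole, MatchMode("cosine", 0.9), sentence, idf)


def test_one_to_one_matching_prevents_double_credit(sentence, idf):
    ref = [_ann(sentence, 10, 26)]
    preds = [_ann(sentence, 10, 26), _ann(sentence, 10, 26)]
    pairs = match_annotations(preds, ref, EXACT, sentence, idf)
    assert len(pairs) == 1  # one TP; the duplicate prediction is an FP


def test_matching_cardinality_equals_bruteforce(sentence, idf):
    rng = np.random.default_rng(3)
    tokens = sentence.tokens
    for _ in range(100):
        def rand_anns(n, source):
            out = []
            for _ in range(n):
                ts = int(rng.integers(0, len(tokens)))
                te = min(len(tokens), ts + 1 + int(rng.integers(0, 3)))
                out.append(_ann(sentence, tokens[ts][1], tokens[te - 1][2],
                                source=source))
            return out

        preds = rand_anns(int(rng.integers(0, 6)), "p")
        refs = rand_anns(int(rng.integers(0, 6)), "r")
        mode = (EXACT, NESTED, COS98, COS90)[int(rng.integers(4))]
        got = len(match_annotations(preds, refs, mode, sentence, idf))
        adj = np.array(
            [[span_match(p, r, mode, sentence, idf) for r in refs] for p in preds]
        ).reshape(len(preds), len(refs))
        assert got == oracle_max_matching_size(adj)


def test_evaluate_formulas_and_conventions():
    sentences = [("d1", "s1", "aa bb cc dd ee ff")]
    ref = build_corpus("ref", sentences, [
        ("d1.s1", 0, 2, "CHED"), ("d1.s1", 3, 5, "CHED"), ("d1.s1", 6, 8, "CHED"),
    ])
    pred = build_corpus("pred", sentences, [
        ("d1.s1", 0, 2, "CHED"), ("d1.s1", 3, 5, "CHED"), ("d1.s1", 9, 11, "CHED"),
    ])
    report = evaluate_corpus(pred, ref, modes=(EXACT,))
    cell = report.get("CHED", "exact")
    assert (cell.tp, cell.fp, cell.fn) == (2, 1, 1)
    assert cell.precision == pytest.approx(2 / 3, abs=1e-4)
    assert cell.recall == pytest.approx(2 / 3, abs=1e-4)
    assert cell.f_measure == pytest.approx(2 / 3, abs=1e-4)
    # empty prediction: zero conventions, no crash
    empty = build_corpus("pred", sentences, [])
    zero = evaluate_corpus(empty, ref, modes=(EXACT,)).get("CHED", "exact")
    assert (zero.precision, zero.recall, zero.f_measure) == (0.0, 0.0, 0.0)
    # empty reference group is flagged
    flipped = evaluate_corpus(ref, empty, modes=(EXACT,)).get("CHED", "exact")
    assert flipped.empty_reference and flipped.f_measure == 0.0


def test_self_evaluation_is_perfect(truth_corpus):
    report = evaluate_corpus(truth_corpus, truth_corpus)
    for cell in report.cells:
        assert cell.f_measure == pytest.approx(1.0)
        assert cell.fp == 0 and cell.fn == 0


def test_swapping_pred_and_ref_swaps_precision_and_recall(
    truth_corpus, noisy_annotators
):
    pred = noisy_annotators[0]
    fwd = evaluate_corpus(pred, truth_corpus)
    rev = evaluate_corpus(truth_corpus, pred)
    for cell in fwd.cells:
        mirror = rev.get(cell.group, cell.mode)
        assert cell.precision == pytest.approx(mirror.recall, abs=1e-12)
        assert cell.recall == pytest.approx(mirror.precision, abs=1e-12)
        assert cell.f_measure == pytest.approx(mirror.f_measure, abs=1e-12)


def test_macro_average_row(truth_corpus, noisy_annotators):
    report = evaluate_corpus(noisy_annotators[0], truth_corpus, modes=(EXACT,))
    groups = [c for c in report.cells if c.group != "avg"]
    avg = report.get("avg", "exact")
    assert avg.f_measure == pytest.approx(
        np.mean([c.f_measure for c in groups]), abs=1e-12
    )


def test_sampled_evaluation_is_seed_deterministic(truth_corpus, noisy_annotators):
    pred = noisy_annotators[1]
    r1 = evaluate_corpus(pred, truth_corpus, modes=(EXACT,), sample=(10, 5))
    r2 = evaluate_corpus(pred, truth_corpus, modes=(EXACT,), sample=(10, 5))
    assert r1.to_frame().equals(r2.to_frame())
    full = evaluate_corpus(pred, truth_corpus, modes=(EXACT,), sample=(10**6, 0))
    # a 10-document sample sees strictly fewer reference annotations
    sampled_refs = sum(c.tp + c.fn for c in r1.cells if c.group != "avg")
    full_refs = sum(c.tp + c.fn for c in full.cells if c.group != "avg")
    assert 0 < sampled_refs < full_refs
    assert full.to_frame().equals(
        evaluate_corpus(pred, truth_corpus, modes=(EXACT,)).to_frame()
    )


def test_text_mismatch_rejected(truth_corpus):
    other = build_corpus("x", [("d0000", "s0", "different")], [])
    with pytest.raises(ValueError):
        evaluate_corpus(other, truth_corpus)


def test_silver_recall_side_consistency(truth_corpus, noisy_annotators):
    """Evaluating one input source against the silver corpus at the
    harmonisation tau: every silver annotation whose cluster contained that
    source must be matched, i.e. recall equals that coverage fraction."""
    config = HarmonisationConfig(tau=0.98, votes=2)
    idf = compute_idf(truth_corpus.documents)
    silver, _ = harmonise_corpus(noisy_annotators, config, idf=idf)
    src = noisy_annotators[0]
    report = evaluate_corpus(src, silver, modes=(COS98,), idf=idf)
    # the annotator can only miss silver annotations it never contributed to,
    # so recall vs silver must be at least the overall vote density implies;
    # concretely every exact-span contribution is recovered:
    exact = evaluate_corpus(src, silver, modes=(EXACT,), idf=idf)
    assert report.get("avg", "cos0.98").recall >= exact.get("avg", "exact").recall
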