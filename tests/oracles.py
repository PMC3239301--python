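"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's sparse-vector, union-find and
assignment machinery: dense numpy vectors over an explicit vocabulary,
networkx connected components, and exhaustive backtracking for maximum
matchings.  They share only the public data model (annotations carry their
token extents as data).
"""

from __future__ import annotations

import math
import re
from collections import Counter

import networkx as nx
import numpy as np

_WORD = re.compile(r"[^\W_]+", re.UNICODE)


def oracle_tokens(text):
    return [m.group().lower() for m in _WORD.finditer(text)]


def oracle_idf(documents):
    """Document-level df counting, reimplemented from the definition."""
    n = 0
    df = Counter()
    for doc in documents:
        n += 1
        seen = set()
        for sent in doc.sentences:
            seen.update(oracle_tokens(sent.text))
        for t in seen:
            df[t] += 1
    return n, df


def _weight(token, n, df):
    if token in df:
        return math.log(n / df[token])
    return math.log(n) + 1.0


def oracle_dense_cosine(ann_a, ann_b, sentence, n, df):
    """Dense dot-product cosine over the union vocabulary; None if either
    vector has zero norm."""
    toks_a = [t for t, _, _ in sentence.tokens[ann_a.token_start:ann_a.token_end]]
    toks_b = [t for t, _, _ in sentence.tokens[ann_b.token_start:ann_b.token_end]]
    vocab = sorted(set(toks_a) | set(toks_b))
    va = np.array([toks_a.count(t) * _weight(t, n, df) for t in vocab])
    vb = np.array([toks_b.count(t) * _weight(t, n, df) for t in vocab])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return None
    return min(1.0, float(va @ vb) / (na * nb))


def _canonical_key(ann):
    return (ann.char_start, -ann.char_end, ann.group, ann.source, ann.concept_ids)


def oracle_harmonise(corpora, tau, votes, boundary_policy="shortest"):
    """Exhaustive harmonisation: all pairwise alignments, explicit graph
    components, distinct-source vote filter, boundary rule with documented
    tie-breaks.  Returns a sorted list of consensus annotation tuples."""
    n, df = oracle_idf(corpora[0].documents)
    index = {}
    for doc in corpora[0].documents:
        for sent in doc.sentences:
            index[f"{doc.id}.{sent.id}"] = sent
    pooled = {}
    for corpus in corpora:
        for ann in corpus.annotations:
            pooled.setdefault((ann.sentence_id, ann.group), []).append(ann)

    out = []
    for (key, group), anns in pooled.items():
        sentence = index[key]
        g = nx.Graph()
        g.add_nodes_from(range(len(anns)))
        for i in range(len(anns)):
            for j in range(i + 1, len(anns)):
                a, b = anns[i], anns[j]
                if not (a.token_start < b.token_end and b.token_start < a.token_end):
                    continue
                score = oracle_dense_cosine(a, b, sentence, n, df)
                if score is not None and score > tau:
                    g.add_edge(i, j)
        for component in nx.connected_components(g):
            members = [anns[i] for i in component]
            if len({m.source for m in members}) < votes:
                continue
            sign = 1 if boundary_policy == "shortest" else -1
            winner = min(
                members,
                key=lambda m: (sign * (m.char_end - m.char_start),
                               m.char_start, m.source),
            )
            merged = []
            for m in sorted(members, key=lambda m: (m.source, _canonical_key(m))):
                for cid in m.concept_ids:
                    if cid not in merged:
                        merged.append(cid)
            out.append(
                (key, winner.char_start, winner.char_end, group,
                 winner.surface, tuple(merged))
            )
    return sorted(out)


def silver_tuples(corpus):
    """Project a silver corpus onto the oracle's comparison tuples."""
    return sorted(
        (a.sentence_id, a.char_start, a.char_end, a.group, a.surface, a.concept_ids)
        for a in corpus.annotations
    )


def oracle_max_matching_size(match):
    """Maximum bipartite matching cardinality by exhaustive backtracking.

    *match* is a 2D boolean array (preds x refs); feasible up to ~6x6.
    """
    match = np.asarray(match, dtype=bool)
    n_pred, n_ref = match.shape

    def rec(i, used):
        if i == n_pred:
            return 0
        best = rec(i + 1, used)  # leave pred i unmatched
        for j in range(n_ref):
            if match[i, j] and j not in used:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())
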