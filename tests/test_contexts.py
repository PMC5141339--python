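"""Context construction and KL-divergence verb ranking."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from narraframe.contexts import (
    Context,
    ContextError,
    VerbCounts,
    build_contexts,
    corpus_verb_distribution,
    extract_context,
    kl_score,
    rank_context_verbs,
)
from narraframe.corpus import Corpus

from conftest import make_post, make_sentence, random_toy_corpus


def brute_force_rank(corpus, lex, a, b, top_k=None, min_count=1):
    """Independent oracle: exhaustive sentence scan + naive sort.

    Counts verbs by scanning raw sentence tokens for the two actants'
    terms, computes probabilities as exact fractions, and sorts with the
    documented tie rules.
    """
    terms = {name: {t[0] for t in lex.terms[name]} for name in lex.names}
    ctx_counts, all_counts = {}, {}
    for s in corpus.sentences:
        tokens = [t.lower() for t, _ in s.tokens]
        for _, stem in s.verbs_stemmed:
            all_counts[stem] = all_counts.get(stem, 0) + 1
        has_a = any(t in terms[a] for t in tokens)
        has_b = any(t in terms[b] for t in tokens)
        if has_a and has_b:
            for _, stem in s.verbs_stemmed:
                ctx_counts[stem] = ctx_counts.get(stem, 0) + 1
    n_ctx = sum(ctx_counts.values())
    n_all = sum(all_counts.values())
    rows = []
    for verb, c in ctx_counts.items():
        if c < min_count:
            continue
        p_pair = Fraction(c, n_ctx)
        p_corpus = Fraction(all_counts[verb], n_all)
        kl = float(p_pair) * math.log2(float(p_pair) / float(p_corpus))
        rows.append((verb, c, kl))
    rows.sort(key=lambda r: (-r[2], -r[1], r[0]))
    if top_k is not None:
        rows = rows[:top_k]
    return [(v, c) for v, c, _ in rows]


def test_corpus_verb_distribution_hand_count():
    sentences = [
        make_sentence("p1", 0, [("x", "NOUN")], [(0, "us"), (0, "us")]),
        make_sentence("p2", 0, [("x", "NOUN")],
                      [(0, "have")] * 5 + [(0, "sign")] * 3),
    ]
    corpus = Corpus(posts=[make_post(post_id="p1"), make_post(post_id="p2")],
                    sentences=sentences)
    counts = corpus_verb_distribution(corpus)
    assert counts.N == 10
    assert counts.probability("us") == pytest.approx(0.2)


def test_single_verb_corpus_probability_one():
    corpus = Corpus(posts=[make_post(post_id="p1")], sentences=[
        make_sentence("p1", 0, [("run", "VERB")], [(0, "run")]),
    ])
    assert corpus_verb_distribution(corpus).probability("run") == 1.0


def test_verbless_corpus_is_fatal():
    corpus = Corpus(posts=[make_post(post_id="p1")], sentences=[
        make_sentence("p1", 0, [("x", "NOUN")], []),
    ])
    with pytest.raises(ContextError):
        corpus_verb_distribution(corpus)


def test_extract_context_filters_to_cooccurring_sentences():
    corpus, lex = random_toy_corpus(seed=42)
    ctx = extract_context(corpus, "Alpha", "Beta", lex)
    terms = {"Alpha": "cat", "Beta": "dog"}
    expected_ids = [
        s.sent_id for s in corpus.sentences
        if {"cat", "dog"} <= {t.lower() for t, _ in s.tokens}
    ]
    assert ctx.sentence_ids == expected_ids
    # verbwise dominance: context counts never exceed corpus counts
    corpus_counts = corpus_verb_distribution(corpus)
    for verb, c in ctx.verb_counts.counts.items():
        assert c <= corpus_counts[verb]


def test_extract_context_errors_and_empty():
    corpus, lex = random_toy_corpus(seed=1)
    with pytest.raises(ContextError):
        extract_context(corpus, "Alpha", "Alpha", lex)
    with pytest.raises(ContextError):
        extract_context(corpus, "Alpha", "Nobody", lex)


@pytest.mark.parametrize("p_pair,p_corpus,expected", [
    (2 / 3, 0.2, (2 / 3) * math.log2((2 / 3) / 0.2)),  # ~1.158
    (0.3, 0.3, 0.0),
    (1 / 3, 0.5, (1 / 3) * math.log2((1 / 3) / 0.5)),  # ~ -0.195
    (0.0, 0.4, 0.0),
])
def test_kl_score_values(p_pair, p_corpus, expected):
    assert kl_score(p_pair, p_corpus) == pytest.approx(expected, abs=1e-12)


def test_kl_score_containment_violation_fatal():
    with pytest.raises(ContextError):
        kl_score(0.5, 0.0)


@settings(max_examples=50, deadline=None)
@given(st.floats(0.01, 0.5), st.floats(0.0, 0.49))
def test_kl_monotone_in_p_pair_above_marginal(p_corpus, bump):
    """Holding the marginal fixed, the score increases with p_pair once
    p_pair >= p_corpus."""
    lo = kl_score(p_corpus, p_corpus)
    hi = kl_score(min(1.0, p_corpus + bump + 1e-6), p_corpus)
    assert hi >= lo


def test_rank_context_verbs_toy_example():
    ctx = Context(actant_pair=("A", "B"), sentence_ids=["s1"],
                  verb_counts=VerbCounts({"us": 2, "have": 1}))
    corpus_counts = VerbCounts({"us": 2, "have": 5, "sign": 3})
    scores = rank_context_verbs(ctx, corpus_counts, min_count=1)
    assert [s.verb for s in scores] == ["us", "have"]
    assert scores[0].kl_score == pytest.approx((2 / 3) * math.log2((2 / 3) / 0.2))
    assert scores[1].kl_score < 0
    assert [s.rank for s in scores] == [1, 2]


def test_rank_ties_fall_back_to_frequency_then_lexicographic():
    # context distribution equal to the corpus distribution: all scores 0
    ctx = Context(actant_pair=("A", "B"), sentence_ids=["s1"],
                  verb_counts=VerbCounts({"walk": 2, "run": 2, "jump": 4}))
    corpus_counts = VerbCounts({"walk": 2, "run": 2, "jump": 4})
    scores = rank_context_verbs(ctx, corpus_counts, min_count=1)
    assert all(s.kl_score == pytest.approx(0.0) for s in scores)
    assert [s.verb for s in scores] == ["jump", "run", "walk"]


def test_min_count_floor_excludes_rare_verbs():
    ctx = Context(actant_pair=("A", "B"), sentence_ids=["s1"],
                  verb_counts=VerbCounts({"us": 7, "rare": 2}))
    corpus_counts = VerbCounts({"us": 10, "rare": 2})
    scores = rank_context_verbs(ctx, corpus_counts, min_count=5)
    assert [s.verb for s in scores] == ["us"]


def test_empty_context_ranks_to_empty_list():
    ctx = Context(actant_pair=("A", "B"), sentence_ids=[],
                  verb_counts=VerbCounts())
    assert rank_context_verbs(ctx, VerbCounts({"us": 1}), min_count=1) == []


def test_probabilities_normalise():
    corpus, lex = random_toy_corpus(seed=9)
    counts = corpus_verb_distribution(corpus)
    assert sum(counts.distribution().values()) == pytest.approx(1.0, abs=1e-9)
    contexts = build_contexts(corpus, lex)
    for ctx in contexts.values():
        if ctx.verb_counts.N:
            assert sum(ctx.verb_counts.distribution().values()) == pytest.approx(
                1.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_ranking_matches_brute_force_oracle(seed):
    """Exact agreement with the exhaustive-scan + naive-sort oracle."""
    corpus, lex = random_toy_corpus(seed=seed)
    counts = corpus_verb_distribution(corpus) if any(
        s.verbs_stemmed for s in corpus.sentences) else None
    if counts is None:
        return
    ctx = extract_context(corpus, "Alpha", "Beta", lex)
    got = [(s.verb, s.count_in_context)
           for s in rank_context_verbs(ctx, counts, top_k=None, min_count=1)]
    assert got == brute_force_rank(corpus, lex, "Alpha", "Beta")
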