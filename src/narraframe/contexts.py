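"""Actant-pair contexts and KL-divergence verb significance ranking.

The statistical core of the pipeline.  A *context* for an unordered actant
pair (A, B) is the set of all sentences in which the two actants co-occur.
A verb v is *contextually significant* when its conditional probability in
the context, P_pair(v) = N_v(C)/N(C), greatly exceeds its corpus-wide
marginal, P_corpus(v) = N_v/N (counts over verb occurrences, not
sentences).  Verbs are ranked by the pointwise Kullback-Leibler divergence
contribution

    kl(v) = P_pair(v) * log2(P_pair(v) / P_corpus(v)),

which vanishes when P_pair = P_corpus — attenuating commonplace auxiliary
verbs — and is negative for verbs rarer in the context than in the corpus.
Probabilities are raw relative frequencies; no smoothing or priors.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .corpus import Corpus, Sentence
from .lexicons import ActantLexicon, ActantMention, index_mentions

logger = logging.getLogger(__name__)


class ContextError(ValueError):
    pass


@dataclass
class VerbCounts:
    """Stemmed-verb occurrence counts and their total N."""

    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    def probability(self, verb: str) -> float:
        n = self.N
        return self.counts.get(verb, 0) / n if n else 0.0

    def distribution(self) -> Dict[str, float]:
        n = self.N
        return {v: c / n for v, c in self.counts.items()} if n else {}

    def __getitem__(self, verb: str) -> int:
        return self.counts.get(verb, 0)


@dataclass
class Context:
    """All sentences where two actants co-occur, with their verb counts."""

    actant_pair: Tuple[str, str]  # sorted, unordered semantics
    sentence_ids: List[str]
    verb_counts: VerbCounts

    @property
    def label(self) -> str:
        return f"{self.actant_pair[0]}<->{self.actant_pair[1]}"

    @property
    def n_sentences(self) -> int:
        return len(self.sentence_ids)


@dataclass(frozen=True)
class VerbScore:
    """One verb's probabilities and KL significance within a context."""

    verb: str
    count_in_context: int
    p_pair: float
    p_corpus: float
    kl_score: float
    rank: int


def corpus_verb_distribution(corpus: Corpus) -> VerbCounts:
    """Marginal verb-occurrence counts over every sentence in the corpus."""
    if corpus.posts and not corpus.sentences:
        raise ContextError("corpus must be segmented and tagged first")
    counts: Counter = Counter()
    for sentence in corpus.sentences:
        for _, stem in sentence.verbs_stemmed:
            counts[stem] += 1
    if not counts:
        raise ContextError("corpus contains no verbs; probabilities undefined")
    return VerbCounts(counts=dict(counts))


def extract_context(
    corpus: Corpus,
    a: str,
    b: str,
    lex: ActantLexicon,
    mentions: Optional[Mapping[str, Sequence[ActantMention]]] = None,
) -> Context:
    """Build the context for actants ``a`` and ``b``.

    ``mentions`` may carry a precomputed :func:`~narraframe.lexicons.index_mentions`
    result to avoid rescanning the corpus for every pair.
    """
    if a == b:
        raise ContextError("a context requires two distinct actants")
    for name in (a, b):
        if name not in lex:
            raise ContextError(f"unknown actant {name!r}")
    if mentions is None:
        mentions = index_mentions(corpus, lex)
    pair = tuple(sorted((a, b)))
    sentence_ids: List[str] = []
    counts: Counter = Counter()
    for sentence in corpus.sentences:
        present = {m.actant for m in mentions.get(sentence.sent_id, ())}
        if a in present and b in present:
            sentence_ids.append(sentence.sent_id)
            for _, stem in sentence.verbs_stemmed:
                counts[stem] += 1
    if not sentence_ids:
        logger.warning("context %s<->%s is empty", a, b)
    return Context(actant_pair=pair, sentence_ids=sentence_ids,
                   verb_counts=VerbCounts(counts=dict(counts)))


def build_contexts(
    corpus: Corpus,
    lex: ActantLexicon,
    pairs: Optional[Iterable[Tuple[str, str]]] = None,
) -> Dict[Tuple[str, str], Context]:
    """Contexts for the given pairs (default: all pairs with co-occurrences).

    One pass over the corpus; returns a dict keyed by sorted actant pair.
    """
    mentions = index_mentions(corpus, lex)
    wanted = None
    if pairs is not None:
        wanted = {tuple(sorted(p)) for p in pairs}
        for p in wanted:
            if p[0] == p[1]:
                raise ContextError("a context requires two distinct actants")
    out: Dict[Tuple[str, str], Dict] = {}
    for sentence in corpus.sentences:
        present = sorted({m.actant for m in mentions.get(sentence.sent_id, ())})
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                pair = (present[i], present[j])
                if wanted is not None and pair not in wanted:
                    continue
                slot = out.setdefault(pair, {"ids": [], "counts": Counter()})
                slot["ids"].append(sentence.sent_id)
                for _, stem in sentence.verbs_stemmed:
                    slot["counts"][stem] += 1
    contexts = {
        pair: Context(actant_pair=pair, sentence_ids=slot["ids"],
                      verb_counts=VerbCounts(counts=dict(slot["counts"])))
        for pair, slot in out.items()
    }
    if wanted is not None:
        for pair in wanted:
            contexts.setdefault(
                pair, Context(actant_pair=pair, sentence_ids=[],
                              verb_counts=VerbCounts()))
    return contexts


def kl_score(p_pair: float, p_corpus: float) -> float:
    """Pointwise KL contribution ``p_pair * log2(p_pair / p_corpus)``.

    Returns 0 when ``p_pair`` is 0.  ``p_corpus`` must be positive whenever
    ``p_pair`` is (guaranteed when the context is a subset of the corpus).
    """
    if p_pair == 0.0:
        return 0.0
    if p_corpus <= 0.0:
        raise ContextError(
            "p_pair > 0 with p_corpus = 0 violates context containment"
        )
    return p_pair * math.log2(p_pair / p_corpus)


def rank_context_verbs(
    ctx: Context,
    corpus_counts: VerbCounts,
    top_k: Optional[int] = 10,
    min_count: int = 5,
) -> List[VerbScore]:
    """Score and rank every verb occurring in a context.

    Sorted by descending KL score; ties broken by descending context count,
    then lexicographically.  Verbs with fewer than ``min_count`` context
    occurrences are excluded (a floor against singleton artifacts); the
    list is truncated to ``top_k`` (``None`` keeps all).
    """
    n_ctx = ctx.verb_counts.N
    if n_ctx == 0:
        logger.warning("ranking requested for empty context %s", ctx.label)
        return []
    n_corpus = corpus_counts.N
    scored = []
    for verb in sorted(ctx.verb_counts.counts):
        c = ctx.verb_counts.counts[verb]
        if c < min_count:
            continue
        p_pair = c / n_ctx
        p_corpus = corpus_counts[verb] / n_corpus
        scored.append((verb, c, p_pair, p_corpus, kl_score(p_pair, p_corpus)))
    scored.sort(key=lambda t: (-t[4], -t[1], t[0]))
    if top_k is not None:
        scored = scored[:top_k]
    return [
        VerbScore(verb=v, count_in_context=c, p_pair=pp, p_corpus=pc,
                  kl_score=kl, rank=i + 1)
        for i, (v, c, pp, pc, kl) in enumerate(scored)
    ]


def write_rankings_csv(
    rankings: Mapping[Tuple[str, str], Sequence[VerbScore]],
    path: str | Path,
) -> Path:
    """Write per-context verb rankings as CSV (the machine-readable analog
    of a top-verbs-per-context table)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["context", "verb", "count_in_context",
                         "p_pair", "p_corpus", "kl_score", "rank"])
        for pair in sorted(rankings):
            for s in rankings[pair]:
                writer.writerow([
                    f"{pair[0]}<->{pair[1]}", s.verb, s.count_in_context,
                    f"{s.p_pair:.10g}", f"{s.p_corpus:.10g}",
                    f"{s.kl_score:.10g}", s.rank,
                ])
    return path
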