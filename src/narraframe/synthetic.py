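"""Synthetic forum-corpus generator with known ground truth.

Runs the pipeline's generative story model forwards: a user picks a pair
of actants and draws a verb from the distribution of relationships among
them — a background verb distribution optionally mixed, for *planted*
pairs, with a uniform draw over one relationship category's verbs at
mixing weight epsilon.  Sentences instantiate simple
``SOURCE verb TARGET`` templates tuned so the POS backend tags the verb
slot as a verb (validated at generation time); posts are attributed to
users who arrive over calendar months and stay active for an
exponentially distributed tenure; a keyword is injected into posts at a
configurable rate.  Every statistical property downstream stages estimate
is therefore available in closed form from :func:`ground_truth`.

A user's tenure is modelled directly as the span between their first and
last post, both of which are emitted, so the observed activity duration
coincides with the configured exponential tenure.  No natural-language
realism and no topical drift are attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._text import VERB_TAGS, RuleTagger, porter_stem, tokenize
from .corpus import Corpus, Post
from .lexicons import (
    ActantLexicon,
    RelationshipLexicon,
    applicability_of,
    load_actant_lexicon,
    load_relationship_lexicon,
)


class GeneratorError(ValueError):
    pass


#: background verb usage (surface base forms -> relative weight); a Zipf-like
#: mix of auxiliaries and common forum verbs, normalised at config build.
DEFAULT_BACKGROUND = {
    "have": 16, "is": 10, "do": 6, "get": 5, "think": 5, "know": 5,
    "want": 4, "say": 4, "go": 4, "make": 3, "see": 3, "take": 3,
    "tell": 3, "need": 3, "come": 2, "find": 2, "give": 2, "use": 2,
    "ask": 2, "feel": 2, "try": 2, "like": 2, "help": 1.5, "talk": 1.5,
    "read": 1.5, "learn": 1.5, "start": 1, "believe": 1, "live": 1,
    "play": 1, "write": 1, "hear": 1, "keep": 1, "let": 1, "show": 1,
    "send": 1, "follow": 1, "attend": 0.5, "require": 0.5, "sign": 0.5,
    "claim": 0.5, "protect": 0.5, "cause": 0.5, "allow": 0.5,
}

# determiners before the actant slots pin noun/verb homograph terms
# ("exempt", "vaccinate") to their noun reading, so the sentence's only verb
# is the verb slot and the realized verb distribution equals the configured one
_TEMPLATES = (
    "the {src} {verb} the {tgt} .",
    "the {src} really {verb} the {tgt} .",
    "the {src} {verb} the {tgt} again .",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``planted`` maps an *ordered* actant pair (source, target) to a
    relationship-category name and a mixing weight epsilon in [0, 1];
    ``pair_weights`` are sampling weights over ``pairs`` (normalised).
    """

    actant_lexicon: ActantLexicon
    relationship_lexicon: RelationshipLexicon
    background_verbs: Dict[str, float]
    pairs: List[Tuple[str, str]]
    pair_weights: List[float]
    planted: Dict[Tuple[str, str], Tuple[str, float]] = field(default_factory=dict)
    months: int = 12
    start: str = "2008-01"
    posts_per_month: int = 200
    sentences_per_post: Tuple[int, int] = (1, 3)
    user_arrival_per_month: float = 20.0
    arrival_months: Optional[int] = None
    n_users_month0: Optional[int] = None
    activity_mean_days: float = 300.0
    clip_to_range: bool = True
    keyword: str = "exemption"
    keyword_rate: float = 0.05
    site_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        total = float(sum(self.background_verbs.values()))
        if not self.background_verbs or total <= 0:
            raise GeneratorError("background verb distribution is unnormalizable")
        self.background_verbs = {
            k: v / total for k, v in self.background_verbs.items()
        }
        if len(self.pairs) != len(self.pair_weights):
            raise GeneratorError("pairs and pair_weights must align")
        wtotal = float(sum(self.pair_weights))
        if wtotal <= 0:
            raise GeneratorError("pair weights are unnormalizable")
        self.pair_weights = [w / wtotal for w in self.pair_weights]
        for pair, (category, eps) in self.planted.items():
            if not 0.0 <= eps <= 1.0:
                raise GeneratorError("epsilon must lie in [0, 1]")
            if tuple(sorted(pair)) not in {tuple(sorted(p)) for p in self.pairs}:
                raise GeneratorError(f"planted pair {pair} not in sampled pairs")
            block = applicability_of(
                self.actant_lexicon.category_of(pair[0]),
                self.actant_lexicon.category_of(pair[1]),
            )
            try:
                self.relationship_lexicon.stems(category, block)
            except KeyError:
                raise GeneratorError(
                    f"category {category!r} not applicable to pair {pair}"
                )


def _all_pairs(lex: ActantLexicon) -> List[Tuple[str, str]]:
    names = list(lex.names)
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """All 55 default actant pairs, uniform weights, no planted signal."""
    alex = load_actant_lexicon()
    rlex = load_relationship_lexicon()
    pairs = _all_pairs(alex)
    cfg = dict(
        actant_lexicon=alex, relationship_lexicon=rlex,
        background_verbs=dict(DEFAULT_BACKGROUND),
        pairs=pairs, pair_weights=[1.0] * len(pairs), seed=seed,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def planted_config(
    seed: int = 0,
    source: str = "Parents",
    target: str = "Exemptions",
    category: str = "Seek or aver",
    epsilon: float = 0.3,
    n_pair_sentences: int = 2000,
    **overrides,
) -> GeneratorConfig:
    """One planted directed relationship at mixing weight epsilon.

    The planted pair carries a third of the sentence mass, so the expected
    number of pair sentences is ``n_pair_sentences`` when the total
    sentence budget is three times that.
    """
    alex = load_actant_lexicon()
    rlex = load_relationship_lexicon()
    pairs = _all_pairs(alex)
    key = tuple(sorted((source, target)))
    weights = []
    others = len(pairs) - 1
    for p in pairs:
        weights.append(1.0 / 3.0 if tuple(sorted(p)) == key else (2.0 / 3.0) / others)
    total_posts = 3 * n_pair_sentences
    months = 12
    cfg = dict(
        actant_lexicon=alex, relationship_lexicon=rlex,
        background_verbs=dict(DEFAULT_BACKGROUND),
        pairs=pairs, pair_weights=weights,
        planted={(source, target): (category, epsilon)},
        months=months, posts_per_month=total_posts // months,
        sentences_per_post=(1, 1),
        user_arrival_per_month=10.0, keyword_rate=0.0, seed=seed,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def trend_config(
    seed: int = 0, keyword_rate: float = 0.05, months: int = 36,
    posts_per_month: int = 1000, **overrides,
) -> GeneratorConfig:
    """Keyword-injection study conditions.

    Actant pairs exclude the keyword's own actant (Exemptions) and the
    background excludes its verbs, so the keyword appears only through
    injection at the configured rate.
    """
    alex = load_actant_lexicon()
    rlex = load_relationship_lexicon()
    pairs = [p for p in _all_pairs(alex) if "Exemptions" not in p]
    cfg = dict(
        actant_lexicon=alex, relationship_lexicon=rlex,
        background_verbs=dict(DEFAULT_BACKGROUND),
        pairs=pairs, pair_weights=[1.0] * len(pairs),
        months=months, posts_per_month=posts_per_month,
        sentences_per_post=(1, 2), user_arrival_per_month=8.0,
        keyword="exemption", keyword_rate=keyword_rate, seed=seed,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def duration_config(
    seed: int = 0, n_users: int = 5000, activity_mean_days: float = 300.0,
    **overrides,
) -> GeneratorConfig:
    """Tenure-distribution study conditions: a single arrival cohort whose
    first/last posts delimit an exponential activity span."""
    alex = load_actant_lexicon()
    rlex = load_relationship_lexicon()
    pairs = _all_pairs(alex)
    cfg = dict(
        actant_lexicon=alex, relationship_lexicon=rlex,
        background_verbs=dict(DEFAULT_BACKGROUND),
        pairs=pairs, pair_weights=[1.0] * len(pairs),
        months=1, posts_per_month=0,
        n_users_month0=n_users, user_arrival_per_month=0.0,
        arrival_months=1, activity_mean_days=activity_mean_days,
        clip_to_range=False, keyword_rate=0.0, seed=seed,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def validate_templates(cfg: GeneratorConfig, min_rate: float = 0.99) -> float:
    """Check that the tagger sees the template verb slot as a verb.

    Instantiates every template with a deterministic sample of actant
    terms and all candidate verbs; returns the verb-tagging rate and
    raises if it falls below ``min_rate``.
    """
    tagger = RuleTagger()
    verbs = sorted(cfg.background_verbs)
    for entry in cfg.relationship_lexicon.entries:
        verbs.extend(entry.surfaces)
    verbs = sorted(set(verbs))
    term_samples = []
    for name in cfg.actant_lexicon.names:
        for phrase in cfg.actant_lexicon.terms[name][:2]:
            term_samples.append(" ".join(phrase))
    ok = total = 0
    for template in _TEMPLATES:
        for vi, verb in enumerate(verbs):
            src = term_samples[vi % len(term_samples)]
            tgt = term_samples[(vi + 7) % len(term_samples)]
            text = template.format(src=src, verb=verb, tgt=tgt)
            tokens = tokenize(text)
            tags = tagger.tag(tokens)
            vpos = len(tokenize(template.split("{verb}")[0].format(src=src)))
            total += 1
            if tags[vpos] in VERB_TAGS:
                ok += 1
    rate = ok / total
    if rate < min_rate:
        raise GeneratorError(
            f"template verb slot tagged as verb in only {rate:.1%} of samples"
        )
    return rate


@dataclass
class _User:
    user_id: str
    first_day: pd.Timestamp
    last_day: pd.Timestamp


def _month_bounds(period: pd.Period) -> Tuple[pd.Timestamp, pd.Timestamp]:
    return period.start_time.normalize(), period.end_time.normalize()


def generate_corpus(cfg: GeneratorConfig) -> Corpus:
    """Generate a corpus under the configured study conditions.

    Deterministic under a fixed seed (byte-identical JSONL output).
    """
    validate_templates(cfg)
    rng = np.random.default_rng(cfg.seed)
    months = pd.period_range(cfg.start, periods=cfg.months, freq="M")
    corpus_start = months[0].start_time.normalize()
    corpus_end = months[-1].end_time.normalize()

    # --- users -----------------------------------------------------------
    users: List[_User] = []
    arrival_months = cfg.arrival_months if cfg.arrival_months is not None else cfg.months
    for mi in range(arrival_months):
        m_start, m_end = _month_bounds(months[mi])
        days_in_month = (m_end - m_start).days + 1
        if mi == 0 and cfg.n_users_month0 is not None:
            n_arrivals = cfg.n_users_month0
        else:
            n_arrivals = int(rng.poisson(cfg.user_arrival_per_month))
        for _ in range(n_arrivals):
            offset = int(rng.integers(0, days_in_month))
            first = m_start + pd.Timedelta(days=offset)
            duration = float(rng.exponential(cfg.activity_mean_days))
            last = first + pd.Timedelta(days=int(duration))
            if cfg.clip_to_range:
                last = min(last, corpus_end)
            users.append(_User(
                user_id=f"u{len(users) + 1:05d}", first_day=first, last_day=last,
            ))
    if not users:
        raise GeneratorError("no users generated; check arrival configuration")

    # --- verb samplers ---------------------------------------------------
    bg_surfaces = sorted(cfg.background_verbs)
    bg_probs = np.array([cfg.background_verbs[v] for v in bg_surfaces])
    planted_by_sorted = {
        tuple(sorted(k)): (k, v) for k, v in cfg.planted.items()
    }
    category_surfaces: Dict[Tuple[str, str], Sequence[str]] = {}
    for pair, ((src, tgt), (category, eps)) in (
        (p, (k, v)) for p, (k, v) in planted_by_sorted.items()
    ):
        block = applicability_of(
            cfg.actant_lexicon.category_of(src),
            cfg.actant_lexicon.category_of(tgt),
        )
        category_surfaces[pair] = cfg.relationship_lexicon.surfaces(category, block)

    def draw_sentence(pair: Tuple[str, str]) -> str:
        skey = tuple(sorted(pair))
        planted = planted_by_sorted.get(skey)
        if planted is not None:
            (src_a, tgt_a), (category, eps) = planted
            if rng.random() < eps:
                surfaces = category_surfaces[skey]
                verb = surfaces[int(rng.integers(0, len(surfaces)))]
            else:
                verb = bg_surfaces[int(rng.choice(len(bg_surfaces), p=bg_probs))]
        else:
            if rng.random() < 0.5:
                src_a, tgt_a = pair
            else:
                tgt_a, src_a = pair
            verb = bg_surfaces[int(rng.choice(len(bg_surfaces), p=bg_probs))]
        src_terms = cfg.actant_lexicon.terms[src_a]
        tgt_terms = cfg.actant_lexicon.terms[tgt_a]
        src = " ".join(src_terms[int(rng.integers(0, len(src_terms)))])
        tgt = " ".join(tgt_terms[int(rng.integers(0, len(tgt_terms)))])
        template = _TEMPLATES[int(rng.integers(0, len(_TEMPLATES)))]
        return template.format(src=src, verb=verb, tgt=tgt)

    pair_probs = np.array(cfg.pair_weights)

    def draw_post_text() -> str:
        lo, hi = cfg.sentences_per_post
        n_sent = int(rng.integers(lo, hi + 1))
        sentences = []
        for _ in range(n_sent):
            pair = cfg.pairs[int(rng.choice(len(cfg.pairs), p=pair_probs))]
            sentences.append(draw_sentence(pair))
        if cfg.keyword_rate > 0 and rng.random() < cfg.keyword_rate:
            sentences.append(f"what about {cfg.keyword} ?")
        return " ".join(sentences)

    # --- posts -----------------------------------------------------------
    events: List[Tuple[pd.Timestamp, str, str, str]] = []  # date, user, thread, text

    def thread_for(date: pd.Timestamp) -> str:
        mi = (date.year - corpus_start.year) * 12 + date.month - corpus_start.month
        return f"t{mi:03d}-{int(rng.integers(0, 40)):02d}"

    endpoint_counts: Dict[int, int] = {}
    for user in users:
        for day in ([user.first_day] if user.last_day == user.first_day
                    else [user.first_day, user.last_day]):
            events.append((day, user.user_id, thread_for(day), draw_post_text()))
            if corpus_start <= day <= corpus_end:
                mi = (day.year - corpus_start.year) * 12 + day.month - corpus_start.month
                endpoint_counts[mi] = endpoint_counts.get(mi, 0) + 1

    for mi, month in enumerate(months):
        m_start, m_end = _month_bounds(month)
        n_stream = max(0, cfg.posts_per_month - endpoint_counts.get(mi, 0))
        if n_stream == 0:
            continue
        active = [
            u for u in users
            if u.first_day <= m_end and u.last_day >= m_start
        ]
        for _ in range(n_stream):
            if active:
                user = active[int(rng.integers(0, len(active)))]
                lo = max(user.first_day, m_start)
                hi = min(user.last_day, m_end)
            else:  # degenerate month with no active users: one-day visitor
                user = _User(
                    user_id=f"u{len(users) + 1:05d}",
                    first_day=m_start, last_day=m_start,
                )
                users.append(user)
                lo = hi = m_start
            span = (hi - lo).days
            date = lo + pd.Timedelta(days=int(rng.integers(0, span + 1)))
            events.append((date, user.user_id, thread_for(date), draw_post_text()))

    events.sort(key=lambda e: (e[0], e[1]))
    posts = [
        Post(post_id=f"p{i + 1:07d}", thread_id=thread, user_id=user_id,
             timestamp=date, text=text, site_id=cfg.site_id)
        for i, (date, user_id, thread, text) in enumerate(events)
    ]
    return Corpus(posts=posts)


def ground_truth(cfg: GeneratorConfig) -> dict:
    """Closed-form expectations implied by a generator configuration.

    Returns stem-level verb distributions (background, per planted pair,
    and corpus marginal), the expected top KL verb per planted pair, the
    expected monthly keyword proportion, and the tenure mean.
    """
    bg_stems: Dict[str, float] = {}
    for surface, p in cfg.background_verbs.items():
        stem = porter_stem(surface)
        bg_stems[stem] = bg_stems.get(stem, 0.0) + p

    pair_dists: Dict[Tuple[str, str], Dict[str, float]] = {}
    for pair in cfg.pairs:
        skey = tuple(sorted(pair))
        dist = dict(bg_stems)
        for (src, tgt), (category, eps) in cfg.planted.items():
            if tuple(sorted((src, tgt))) != skey:
                continue
            block = applicability_of(
                cfg.actant_lexicon.category_of(src),
                cfg.actant_lexicon.category_of(tgt),
            )
            stems = cfg.relationship_lexicon.stems(category, block)
            dist = {v: (1.0 - eps) * p for v, p in dist.items()}
            for stem in stems:
                dist[stem] = dist.get(stem, 0.0) + eps / len(stems)
        pair_dists[skey] = dist

    corpus_dist: Dict[str, float] = {}
    for pair, weight in zip(cfg.pairs, cfg.pair_weights):
        for stem, p in pair_dists[tuple(sorted(pair))].items():
            corpus_dist[stem] = corpus_dist.get(stem, 0.0) + weight * p

    expected_top1: Dict[Tuple[str, str], str] = {}
    for (src, tgt), (category, eps) in cfg.planted.items():
        skey = tuple(sorted((src, tgt)))
        dist = pair_dists[skey]
        scores = {
            v: p * math.log2(p / corpus_dist[v])
            for v, p in dist.items() if p > 0
        }
        expected_top1[(src, tgt)] = max(scores, key=lambda v: (scores[v], v))

    return {
        "background_stem_distribution": bg_stems,
        "pair_stem_distributions": pair_dists,
        "corpus_stem_distribution": corpus_dist,
        "expected_top1_stem": expected_top1,
        "expected_monthly_keyword_proportion": cfg.keyword_rate,
        "activity_mean_days": cfg.activity_mean_days,
    }
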