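"""Actant and relationship lexicons, and actant-mention matching.

The actant lexicon names the narrative agents and objects (individual,
institutional, object categories) with their associated word sets; the
relationship lexicon groups verbs into binary-opposition categories that
become directed edge labels.  Packaged defaults cover the vaccination-
exemption domain; custom lexicons load from YAML/JSON.

Matching is asymmetric on purpose: actant terms are matched on raw
(lowercased) tokens, never stems, while relationship verbs are stored and
queried as Porter stems.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from ._text import NOUN_TAGS, porter_stem
from .corpus import Corpus, Sentence

logger = logging.getLogger(__name__)

ACTANT_CATEGORIES = ("individual", "institutional", "object")
APPLICABILITIES = ("individual_institutional", "object")


class LexiconError(ValueError):
    """Fatal lexicon configuration problem."""


@dataclass(frozen=True)
class ActantMention:
    """An actant term matched in a sentence; span is 0-based half-open."""

    sent_id: str
    actant: str
    start: int
    end: int


@dataclass
class ActantLexicon:
    """Actant name -> category + term set; declaration order is significant."""

    names: List[str]
    categories: Dict[str, str]
    terms: Dict[str, Tuple[Tuple[str, ...], ...]]  # tokenized phrases
    #: validation report: (term, first actant, shadowed actant)
    duplicates: List[Tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        # first-declared actant wins a contested term
        self._term_map: Dict[Tuple[str, ...], str] = {}
        self._max_len = 1
        for name in self.names:
            for phrase in self.terms[name]:
                if phrase in self._term_map:
                    owner = self._term_map[phrase]
                    if owner != name:
                        self.duplicates.append((" ".join(phrase), owner, name))
                        logger.warning(
                            "term %r claimed by %r and %r; %r wins",
                            " ".join(phrase), owner, name, owner,
                        )
                    continue
                self._term_map[phrase] = name
                self._max_len = max(self._max_len, len(phrase))

    def category_of(self, actant: str) -> str:
        return self.categories[actant]

    def __contains__(self, actant: str) -> bool:
        return actant in self.categories

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class RelationshipEntry:
    name: str
    applicability: str
    stems: Tuple[str, ...]
    surfaces: Tuple[str, ...]


@dataclass
class RelationshipLexicon:
    """Binary-opposition verb categories, keyed by (stem, applicability)."""

    entries: List[RelationshipEntry]
    #: validation report: (stem, applicability, first category, shadowed)
    duplicates: List[Tuple[str, str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        self._by_block: Dict[str, Dict[str, str]] = {a: {} for a in APPLICABILITIES}
        for entry in self.entries:
            block = self._by_block[entry.applicability]
            for stem in entry.stems:
                if stem in block:
                    if block[stem] != entry.name:
                        self.duplicates.append(
                            (stem, entry.applicability, block[stem], entry.name)
                        )
                    continue
                block[stem] = entry.name

    def category_names(self) -> List[str]:
        seen = []
        for e in self.entries:
            if e.name not in seen:
                seen.append(e.name)
        return seen

    def lookup(self, stem: str, applicability: str) -> Optional[str]:
        """Category containing the stem in the given applicability block."""
        if applicability not in self._by_block:
            raise LexiconError(f"unknown applicability {applicability!r}")
        return self._by_block[applicability].get(stem)

    def stems(self, name: str, applicability: str) -> Tuple[str, ...]:
        for e in self.entries:
            if e.name == name and e.applicability == applicability:
                return e.stems
        raise KeyError((name, applicability))

    def surfaces(self, name: str, applicability: str) -> Tuple[str, ...]:
        for e in self.entries:
            if e.name == name and e.applicability == applicability:
                return e.surfaces
        raise KeyError((name, applicability))


def _load_config(path_or_data) -> dict:
    if isinstance(path_or_data, dict):
        return path_or_data
    path = Path(path_or_data)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_actant_lexicon(source=None) -> ActantLexicon:
    """Load an actant lexicon from YAML/JSON (``None`` -> packaged default).

    Every actant needs at least one term and a known category; a term
    claimed by two actants goes to the first-declared one with a warning
    recorded in ``lexicon.duplicates``.
    """
    if source is None:
        with resources.files("narraframe.data").joinpath("actants.yaml").open(
            "r", encoding="utf-8"
        ) as fh:
            data = yaml.safe_load(fh)
    else:
        data = _load_config(source)
    if "actants" not in data:
        raise LexiconError("actant lexicon must have an 'actants' list")
    names, categories, terms = [], {}, {}
    for entry in data["actants"]:
        name = entry.get("name")
        cat = entry.get("category")
        raw_terms = entry.get("terms")
        if not name:
            raise LexiconError("actant entry without a name")
        if cat not in ACTANT_CATEGORIES:
            raise LexiconError(f"actant {name!r}: unknown category {cat!r}")
        if not raw_terms:
            raise LexiconError(f"actant {name!r} has an empty term set")
        names.append(name)
        categories[name] = cat
        phrases = []
        for term in raw_terms:
            phrase = tuple(str(term).lower().split())
            if phrase and phrase not in phrases:
                phrases.append(phrase)
        terms[name] = tuple(phrases)
    return ActantLexicon(names=names, categories=categories, terms=terms)


def load_relationship_lexicon(source=None, strict: bool = False) -> RelationshipLexicon:
    """Load a relationship lexicon (``None`` -> packaged default).

    Verbs are stemmed at load.  A stem appearing in two categories of the
    same applicability block is recorded in ``lexicon.duplicates`` (the
    first-declared category wins at query time); with ``strict=True`` it is
    a fatal configuration error instead.
    """
    if source is None:
        with resources.files("narraframe.data").joinpath(
            "relationships.yaml"
        ).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = _load_config(source)
    if "relationships" not in data:
        raise LexiconError("relationship lexicon must have a 'relationships' list")
    entries = []
    for entry in data["relationships"]:
        name = entry.get("name")
        applicability = entry.get("applicability")
        verbs = entry.get("verbs")
        if not name:
            raise LexiconError("relationship entry without a name")
        if applicability not in APPLICABILITIES:
            raise LexiconError(
                f"relationship {name!r}: unknown applicability {applicability!r}"
            )
        if not verbs:
            raise LexiconError(f"relationship {name!r} has an empty verb set")
        surfaces, stems = [], []
        for verb in verbs:
            surface = str(verb).lower()
            stem = porter_stem(surface)
            if stem not in stems:
                surfaces.append(surface)
                stems.append(stem)
        entries.append(RelationshipEntry(
            name=name, applicability=applicability,
            stems=tuple(stems), surfaces=tuple(surfaces),
        ))
    lexicon = RelationshipLexicon(entries=entries)
    if lexicon.duplicates:
        msg = "; ".join(
            f"stem {s!r} in both {a!r} and {b!r} ({block} block)"
            for s, block, a, b in lexicon.duplicates
        )
        if strict:
            raise LexiconError(f"duplicate verb stems within a block: {msg}")
        logger.warning("relationship lexicon validation: %s", msg)
    return lexicon


def applicability_of(cat_a: str, cat_b: str) -> str:
    """Applicability block for a pair of actant categories."""
    for cat in (cat_a, cat_b):
        if cat not in ACTANT_CATEGORIES:
            raise LexiconError(f"unknown actant category {cat!r}")
    if "object" in (cat_a, cat_b):
        return "object"
    return "individual_institutional"


def match_actants(sentence: Sentence, lex: ActantLexicon) -> List[ActantMention]:
    """Find actant mentions in a sentence, longest match first.

    Matching is case-insensitive on raw tokens; a token consumed by a
    phrase match ("center for disease control") is unavailable to shorter
    matches; mentions are returned in token order.
    """
    lowered = [tok.lower() for tok, _ in sentence.tokens]
    mentions: List[ActantMention] = []
    i = 0
    n = len(lowered)
    while i < n:
        matched = False
        for span in range(min(lex._max_len, n - i), 0, -1):
            phrase = tuple(lowered[i:i + span])
            actant = lex._term_map.get(phrase)
            if actant is not None:
                mentions.append(ActantMention(
                    sent_id=sentence.sent_id, actant=actant,
                    start=i, end=i + span,
                ))
                i += span
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def index_mentions(
    corpus: Corpus, lex: ActantLexicon
) -> Dict[str, List[ActantMention]]:
    """Match actants in every sentence; keyed by sentence id."""
    if not corpus.is_annotated():
        raise LexiconError("corpus must be segmented and tagged first")
    return {s.sent_id: match_actants(s, lex) for s in corpus.sentences}


def ranked_noun_list(corpus: Corpus, top_k: Optional[int] = None) -> List[Tuple[str, int]]:
    """High-frequency nouns, an aid for building new actant lexicons.

    Noun-tagged tokens are counted case-insensitively and sorted by
    descending frequency, ties broken lexicographically.
    """
    if corpus.posts and not corpus.sentences:
        raise LexiconError("corpus must be segmented and tagged first")
    counts: Counter = Counter()
    for sentence in corpus.sentences:
        for tok, tag in sentence.tokens:
            if tag in NOUN_TAGS:
                counts[tok.lower()] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k] if top_k is not None else ranked
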