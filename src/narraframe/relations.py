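"""Directed actant-actant relationship extraction.

Once a context's significant verbs are known, each occurrence of such a
verb in a context sentence is turned into at most one directed
:class:`RelationInstance`: the verb's relationship category becomes the
edge label, and the edge direction follows token order between two actant
mentions in the sentence.

Direction rule (shallow by design — no dependency parsing): a verb token
is only considered when at least one actant mention lies on each side of
it.  Among all ordered pairs of mentions of distinct actants (source
before target in token order) whose actant-category combination gives the
verb a relationship category, the pair closest to the verb is chosen.  On
simple subject-verb-object sentences this reduces to the nearest
preceding / nearest following mentions; when the surface object is not a
category-compatible actant (e.g. a verb taking the central object as its
grammatical object while relating two actants mentioned earlier), the
nearest compatible pair still yields the intended edge.  Negation and
modality are not modelled.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .corpus import Sentence
from .lexicons import (
    ActantLexicon,
    ActantMention,
    RelationshipLexicon,
    applicability_of,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelationInstance:
    """One directed, categorised relationship occurrence in a sentence."""

    sent_id: str
    verb: str  # stem
    category: str
    source: str  # actant name
    target: str
    source_span: Tuple[int, int]
    verb_position: int
    target_span: Tuple[int, int]


def map_verb_to_category(
    verb: str, rlex: RelationshipLexicon, applicability: str
) -> Optional[str]:
    """Relationship category of a stemmed verb in an applicability block,
    or ``None`` when the verb belongs to no category there."""
    return rlex.lookup(verb, applicability)


def extract_relations(
    sentence: Sentence,
    mentions: Sequence[ActantMention],
    significant_verbs: Set[str],
    rlex: RelationshipLexicon,
    alex: ActantLexicon,
) -> List[RelationInstance]:
    """Relation instances for one sentence of a context.

    ``significant_verbs`` is the stem set from the context's verb ranking.
    Each significant-verb token yields at most one instance (see the
    module docstring for the direction rule); the result is independent of
    the order in which mentions were discovered.
    """
    ordered = sorted(mentions, key=lambda m: (m.start, m.end, m.actant))
    instances: List[RelationInstance] = []
    for vpos, stem in sentence.verbs_stemmed:
        if stem not in significant_verbs:
            continue
        before = [m for m in ordered if m.end <= vpos]
        after = [m for m in ordered if m.start > vpos]
        if not before or not after:
            continue
        best = None
        for i, src in enumerate(ordered):
            for tgt in ordered[i + 1:]:
                if src.actant == tgt.actant:
                    continue
                block = applicability_of(
                    alex.category_of(src.actant), alex.category_of(tgt.actant)
                )
                category = rlex.lookup(stem, block)
                if category is None:
                    continue
                distance = min(abs(vpos - src.start), abs(vpos - (src.end - 1))) + \
                    min(abs(vpos - tgt.start), abs(vpos - (tgt.end - 1)))
                key = (distance, src.start, tgt.start)
                if best is None or key < best[0]:
                    best = (key, src, tgt, category)
        if best is None:
            continue
        _, src, tgt, category = best
        instances.append(RelationInstance(
            sent_id=sentence.sent_id, verb=stem, category=category,
            source=src.actant, target=tgt.actant,
            source_span=(src.start, src.end), verb_position=vpos,
            target_span=(tgt.start, tgt.end),
        ))
    return instances


def extract_context_relations(
    corpus_sentences: Iterable[Sentence],
    mentions_by_sentence,
    context_sentence_ids: Set[str],
    significant_verbs: Set[str],
    rlex: RelationshipLexicon,
    alex: ActantLexicon,
) -> List[RelationInstance]:
    """Relations over all sentences of one context."""
    instances: List[RelationInstance] = []
    for sentence in corpus_sentences:
        if sentence.sent_id not in context_sentence_ids:
            continue
        instances.extend(extract_relations(
            sentence, mentions_by_sentence.get(sentence.sent_id, ()),
            significant_verbs, rlex, alex,
        ))
    return instances


def write_relations_csv(
    instances: Sequence[RelationInstance], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sentence_id", "verb", "category", "source", "target"])
        for inst in instances:
            writer.writerow([inst.sent_id, inst.verb, inst.category,
                             inst.source, inst.target])
    return path
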