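"""Deterministic text primitives: tokenizer, sentence splitter, Porter stemmer,
and a rule-based part-of-speech tagger.

The pipeline deliberately relies on shallow, reproducible annotation — nouns
and verbs are the only categories downstream stages consume, and determinism
matters more than linguistic perfection on noisy forum text.  The tagger is a
pluggable backend: any object with a ``tag(tokens) -> tags`` method over a
tagset that distinguishes nouns and verbs can replace :class:`RuleTagger`.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Sequence

# ---------------------------------------------------------------------------
# Tokenisation and sentence segmentation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z]+)?|[^\sA-Za-z0-9]")

#: words that commonly precede a period without ending a sentence
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "st", "vs", "etc", "eg", "ie", "e.g", "i.e",
    "jr", "sr", "prof", "dept", "approx", "inc",
}

_SENT_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+|$)")


def tokenize(text: str) -> List[str]:
    """Split text into word and punctuation tokens.

    Alphanumeric runs (with an optional internal apostrophe) are words;
    every other non-space character is its own token, so hyphenated forms
    like ``tax-exempt`` yield ``["tax", "-", "exempt"]``.
    """
    return _TOKEN_RE.findall(text)


def split_sentences(text: str) -> List[str]:
    """Rule-based sentence segmentation on terminal punctuation.

    Splits on ``.``, ``!`` and ``?`` followed by whitespace, with an
    abbreviation guard; text without terminal punctuation is one sentence.
    """
    sentences: List[str] = []
    start = 0
    for match in _SENT_BOUNDARY_RE.finditer(text):
        candidate = text[start:match.end(1)]
        # guard: "Dr." / "etc." do not end a sentence
        preceding = candidate[:match.start(1) - start]
        last_word = preceding.rstrip().rsplit(None, 1)
        if last_word and last_word[-1].lower().strip("().,;:") in _ABBREVIATIONS:
            continue
        if candidate.strip():
            sentences.append(candidate.strip())
        start = match.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------


class PorterStemmer:
    """The Porter (1980) suffix-stripping algorithm.

    Two departures, both taken from Porter's own later revisions of the
    algorithm, are applied:

    * step 1c turns a final ``y`` into ``i`` only when the ``y`` is preceded
      by a consonant and the stem is longer than a single consonant
      (``pray`` stays ``pray``; ``deny`` becomes ``deni``);
    * tokens of length <= 2 are returned unchanged (``is``, ``go``, ``us``).

    Under these rules inflections collapse as the pipeline requires:
    ``funded``/``funds`` -> ``fund``, ``use``/``used``/``using`` -> ``us``,
    ``requires`` -> ``requir``.
    """

    _VOWELS = frozenset("aeiou")

    def _is_consonant(self, word: str, i: int) -> bool:
        ch = word[i]
        if ch in self._VOWELS:
            return False
        if ch == "y":
            return i == 0 or not self._is_consonant(word, i - 1)
        return True

    def _measure(self, stem: str) -> int:
        """Number of vowel->consonant transitions (the *m* of the algorithm)."""
        m = 0
        prev_vowel = False
        for i in range(len(stem)):
            cons = self._is_consonant(stem, i)
            if cons and prev_vowel:
                m += 1
            prev_vowel = not cons
        return m

    def _has_vowel(self, stem: str) -> bool:
        return any(not self._is_consonant(stem, i) for i in range(len(stem)))

    def _ends_double_consonant(self, word: str) -> bool:
        return (
            len(word) >= 2
            and word[-1] == word[-2]
            and self._is_consonant(word, len(word) - 1)
        )

    def _ends_cvc(self, word: str) -> bool:
        return (
            len(word) >= 3
            and self._is_consonant(word, len(word) - 3)
            and not self._is_consonant(word, len(word) - 2)
            and self._is_consonant(word, len(word) - 1)
            and word[-1] not in "wxy"
        )

    def _replace(self, word: str, suffix: str, repl: str) -> str:
        return word[: len(word) - len(suffix)] + repl

    def _step1a(self, word: str) -> str:
        if word.endswith("sses"):
            return word[:-2]
        if word.endswith("ies"):
            return word[:-2]
        if word.endswith("ss"):
            return word
        if word.endswith("s"):
            return word[:-1]
        return word

    def _step1b(self, word: str) -> str:
        if word.endswith("eed"):
            if self._measure(word[:-3]) > 0:
                return word[:-1]
            return word
        stripped = None
        if word.endswith("ed") and self._has_vowel(word[:-2]):
            stripped = word[:-2]
        elif word.endswith("ing") and self._has_vowel(word[:-3]):
            stripped = word[:-3]
        if stripped is None:
            return word
        if stripped.endswith(("at", "bl", "iz")):
            return stripped + "e"
        if self._ends_double_consonant(stripped) and stripped[-1] not in "lsz":
            return stripped[:-1]
        if self._measure(stripped) == 1 and self._ends_cvc(stripped):
            return stripped + "e"
        return stripped

    def _step1c(self, word: str) -> str:
        # departure: y -> i only after a consonant, never on e.g. "by"/"say"
        if (
            word.endswith("y")
            and len(word) > 2
            and self._is_consonant(word, len(word) - 2)
        ):
            return word[:-1] + "i"
        return word

    _STEP2 = [
        ("ational", "ate"), ("ization", "ize"), ("iveness", "ive"),
        ("fulness", "ful"), ("ousness", "ous"), ("tional", "tion"),
        ("biliti", "ble"), ("entli", "ent"), ("ousli", "ous"),
        ("ation", "ate"), ("alism", "al"), ("aliti", "al"),
        ("iviti", "ive"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"),
        ("ator", "ate"), ("eli", "e"),
    ]

    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"),
        ("iciti", "ic"), ("ical", "ic"), ("ness", ""), ("ful", ""),
    ]

    _STEP4 = [
        "ement", "ance", "ence", "able", "ible", "ment",
        "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize",
        "ion", "al", "er", "ic", "ou",
    ]

    def _step2(self, word: str) -> str:
        for suffix, repl in self._STEP2:
            if word.endswith(suffix):
                stem = word[: -len(suffix)]
                if self._measure(stem) > 0:
                    return stem + repl
                return word
        return word

    def _step3(self, word: str) -> str:
        for suffix, repl in self._STEP3:
            if word.endswith(suffix):
                stem = word[: -len(suffix)]
                if self._measure(stem) > 0:
                    return stem + repl
                return word
        return word

    def _step4(self, word: str) -> str:
        for suffix in self._STEP4:
            if word.endswith(suffix):
                stem = word[: -len(suffix)]
                if self._measure(stem) > 1:
                    if suffix == "ion" and not stem.endswith(("s", "t")):
                        return word
                    return stem
                return word
        return word

    def _step5a(self, word: str) -> str:
        if word.endswith("e"):
            stem = word[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._ends_cvc(stem)):
                return stem
        return word

    def _step5b(self, word: str) -> str:
        if (
            self._measure(word) > 1
            and self._ends_double_consonant(word)
            and word.endswith("l")
        ):
            return word[:-1]
        return word

    def stem(self, word: str) -> str:
        word = word.lower()
        if len(word) <= 2:
            return word
        word = self._step1a(word)
        word = self._step1b(word)
        word = self._step1c(word)
        word = self._step2(word)
        word = self._step3(word)
        word = self._step4(word)
        word = self._step5a(word)
        word = self._step5b(word)
        return word


_STEMMER = PorterStemmer()


def porter_stem(word: str) -> str:
    """Stem a single word with the module-level :class:`PorterStemmer`."""
    return _STEMMER.stem(word)


# ---------------------------------------------------------------------------
# Rule-based POS tagger
# ---------------------------------------------------------------------------

#: simplified tagset
NOUN, VERB, ADJ, ADV = "NOUN", "VERB", "ADJ", "ADV"
PRON, DET, ADP, CONJ = "PRON", "DET", "ADP", "CONJ"
PRT, NUM, PUNCT, X = "PRT", "NUM", "PUNCT", "X"

VERB_TAGS = frozenset({VERB})
NOUN_TAGS = frozenset({NOUN})

_DETS = frozenset(
    "a an the this that these those my your his her its our their some any "
    "no each every another such both all".split()
)
_PRONOUNS = frozenset(
    "i we us you he she it they them me him who whom someone anyone everyone "
    "something anything nothing everybody nobody myself yourself themselves "
    "itself".split()
)
_ADPS = frozenset(
    "in on at of for with by from about into over under after before between "
    "through during against within without across among around upon toward "
    "towards per via".split()
)
_CONJS = frozenset(
    "and or but nor because although while if when than whether since unless "
    "so yet".split()
)
_PRTS = frozenset(["to", "not", "n't"])
_ADVS = frozenset(
    "very really often never always also just still too then there here now "
    "maybe perhaps usually sometimes already even only quite rather soon "
    "again away back today yesterday tomorrow".split()
)
_ADJS = frozenset(
    "religious medical new old good bad big little small many few much more "
    "most other same own free sure several important public private local "
    "national early late young high low long short sick healthy safe legal "
    "dear first last next able likely whole".split()
)

#: auxiliary and modal verb forms — tagged VERB so commonplace verbs enter the
#: background distribution, where the KL weighting is meant to attenuate them
_AUX_FORMS = frozenset(
    "am is are was were be been being do does did done doing have has had "
    "having will would can could shall should may might must".split()
)

_VERB_BASES = [
    # relationship-model verbs
    "force", "require", "need", "follow", "mandate",
    "recommend", "tell", "say", "object", "ask", "learn", "teach",
    "protect", "injure", "damage",
    "use", "submit", "ignore",
    "vaccinate", "unvaccinate", "vax", "unvax", "receive", "get", "inject",
    "exclude", "allow", "exempt", "believe", "request", "deny", "accept",
    "enter", "enroll", "attend", "go", "send", "homeschool",
    "seek", "file", "sign", "claim", "exercise", "lie",
    "approve", "abuse", "grant", "oppose",
    "expose", "contract", "cause", "develop", "suffer", "die", "vomit",
    "diagnose",
    # common verbs seen in forum prose
    "want", "think", "know", "give", "take", "make", "see", "come", "find",
    "feel", "leave", "put", "mean", "keep", "let", "begin", "help", "talk",
    "turn", "start", "show", "hear", "play", "run", "move", "like", "live",
    "write", "prove", "read", "sit", "stand", "lose", "pay", "meet", "include",
    "set", "decide", "obtain", "furnish", "bind", "determine", "rule",
    "offer", "choose", "increase", "qualify", "belong", "concern", "refuse",
    "document", "link", "raise", "report", "work", "pray", "wonder", "worry",
    "discuss", "post", "share", "join", "visit", "call", "try", "avoid",
    "question", "resist", "buy", "bring", "happen", "stay", "wait", "agree",
    "explain", "plan", "hope", "love", "hate", "remember", "forget", "trust",
    "fund",
]

_IRREGULAR_FORMS = {
    "say": ["says", "said", "saying"],
    "go": ["goes", "went", "gone", "going"],
    "get": ["gets", "got", "gotten", "getting"],
    "take": ["takes", "took", "taken", "taking"],
    "tell": ["tells", "told", "telling"],
    "think": ["thinks", "thought", "thinking"],
    "know": ["knows", "knew", "known", "knowing"],
    "give": ["gives", "gave", "given", "giving"],
    "write": ["writes", "wrote", "written", "writing"],
    "seek": ["seeks", "sought", "seeking"],
    "teach": ["teaches", "taught", "teaching"],
    "send": ["sends", "sent", "sending"],
    "lie": ["lies", "lay", "lain", "lied", "lying"],
    "choose": ["chooses", "chose", "chosen", "choosing"],
    "find": ["finds", "found", "finding"],
    "bind": ["binds", "bound", "binding"],
    "make": ["makes", "made", "making"],
    "see": ["sees", "saw", "seen", "seeing"],
    "come": ["comes", "came", "coming"],
    "feel": ["feels", "felt", "feeling"],
    "leave": ["leaves", "left", "leaving"],
    "meet": ["meets", "met", "meeting"],
    "pay": ["pays", "paid", "paying"],
    "hear": ["hears", "heard", "hearing"],
    "buy": ["buys", "bought", "buying"],
    "bring": ["brings", "brought", "bringing"],
    "stand": ["stands", "stood", "standing"],
    "begin": ["begins", "began", "begun", "beginning"],
    "keep": ["keeps", "kept", "keeping"],
    "run": ["runs", "ran", "running"],
    "sit": ["sits", "sat", "sitting"],
    "lose": ["loses", "lost", "losing"],
    "mean": ["means", "meant", "meaning"],
    "put": ["puts", "putting"],
    "let": ["lets", "letting"],
    "set": ["sets", "setting"],
    "read": ["reads", "reading"],
    "try": ["tries", "tried", "trying"],
    "qualify": ["qualifies", "qualified", "qualifying"],
    "deny": ["denies", "denied", "denying"],
    "worry": ["worries", "worried", "worrying"],
}


def _inflect(base: str) -> Iterable[str]:
    """Regular inflections of a verb base (3sg, past, gerund)."""
    yield base
    if base.endswith(("s", "x", "z", "ch", "sh", "o")):
        yield base + "es"
    elif base.endswith("y") and len(base) > 2 and base[-2] not in "aeiou":
        yield base[:-1] + "ies"
    else:
        yield base + "s"
    if base.endswith("e"):
        yield base + "d"
        yield base[:-1] + "ing"
    else:
        yield base + "ed"
        yield base + "ing"
        # consonant doubling (submit -> submitted)
        if (
            len(base) >= 3
            and base[-1] not in "aeiouwxy"
            and base[-2] in "aeiou"
            and base[-3] not in "aeiou"
        ):
            yield base + base[-1] + "ed"
            yield base + base[-1] + "ing"


def _build_verb_forms() -> frozenset:
    forms = set()
    for base in _VERB_BASES:
        forms.update(_inflect(base))
        for irr in _IRREGULAR_FORMS.get(base, ()):
            forms.add(irr)
    return frozenset(forms)


_VERB_FORMS = _build_verb_forms()

_NUM_RE = re.compile(r"^\d+([.,]\d+)*$")


class RuleTagger:
    """Deterministic lexicon-and-suffix POS tagger.

    Closed-class words are tagged from fixed lists; known verb forms are
    tagged ``VERB`` unless the preceding token is a determiner, adjective,
    adposition or numeral (in which position English noun/verb homographs
    such as "use", "file" or "order" are nouns); unknown words default to
    ``NOUN``.  Same tokens always give the same tags.
    """

    def tag(self, tokens: Sequence[str]) -> List[str]:
        tags: List[str] = []
        for tok in tokens:
            low = tok.lower()
            if not any(c.isalnum() for c in tok):
                tags.append(PUNCT)
            elif _NUM_RE.match(low):
                tags.append(NUM)
            elif low in _DETS:
                tags.append(DET)
            elif low in _PRONOUNS:
                tags.append(PRON)
            elif low in _ADPS:
                tags.append(ADP)
            elif low in _CONJS:
                tags.append(CONJ)
            elif low in _PRTS:
                tags.append(PRT)
            elif low in _ADVS:
                tags.append(ADV)
            elif low in _AUX_FORMS:
                tags.append(VERB)
            elif low in _VERB_FORMS:
                prev = self._prev_content_tag(tags)
                if prev in (DET, ADJ, ADP, NUM):
                    tags.append(NOUN)
                else:
                    tags.append(VERB)
            elif low in _ADJS:
                tags.append(ADJ)
            elif low.endswith("ly") and len(low) > 4:
                tags.append(ADV)
            elif low.endswith(("ed", "ing")) and len(low) > 5:
                prev = self._prev_content_tag(tags)
                tags.append(NOUN if prev in (DET, ADJ, ADP, NUM) else VERB)
            else:
                tags.append(NOUN)
        return tags

    @staticmethod
    def _prev_content_tag(tags: List[str]) -> str | None:
        """Most recent tag, looking through adverbs and particles ("not")."""
        for t in reversed(tags):
            if t not in (ADV, PRT):
                return t
        return None
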