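"""Shared fixtures: lexicons, handcrafted corpora, and toy-corpus builders."""

from __future__ import annotations

import random

import pandas as pd
import pytest

from narraframe.corpus import Corpus, Post, Sentence, segment_and_tag
from narraframe.lexicons import load_actant_lexicon, load_relationship_lexicon

#: the contextual sentence whose single relation instance anchors the
#: relation-extraction direction rule (Parents -> Religious institutions)
WORKED_EXAMPLE = (
    "Here is some New York info: (sample exemption letters here) Here is "
    "info about how you do not have to prove membership in a church in "
    "order to use a religious exemption"
)


@pytest.fixture(scope="session")
def alex():
    return load_actant_lexicon()


@pytest.fixture(scope="session")
def rlex():
    return load_relationship_lexicon()


def make_post(post_id="p1", thread="t1", user="u1", ts="2008-05-01", text="",
              site=""):
    return Post(post_id=post_id, thread_id=thread, user_id=user,
                timestamp=pd.Timestamp(ts), text=text, site_id=site)


def make_sentence(post_ref: str, index: int, words, verbs):
    """Build an annotated sentence directly: ``words`` are (token, tag)
    pairs, ``verbs`` are (position, stem) pairs."""
    return Sentence(post_ref=post_ref, index=index,
                    tokens=tuple(words), verbs_stemmed=tuple(verbs))


@pytest.fixture
def worked_example_corpus():
    corpus = Corpus(posts=[make_post(text=WORKED_EXAMPLE)])
    return segment_and_tag(corpus)


def random_toy_corpus(seed: int, max_sentences: int = 50):
    """A random toy corpus of annotated sentences over a miniature world.

    Three single-token actant terms (cat/dog/bird) and five verbs; tags and
    stems are assigned directly so the toy world is independent of the
    tagger.  Returns (corpus, mini actant lexicon).
    """
    from narraframe.lexicons import ActantLexicon

    rng = random.Random(seed)
    actant_terms = {"Alpha": "cat", "Beta": "dog", "Gamma": "bird"}
    verbs = ["run", "jump", "walk", "look", "hide"]
    n = rng.randint(3, max_sentences)
    posts, sentences = [], []
    for i in range(n):
        post_id = f"p{i}"
        posts.append(make_post(post_id=post_id, ts="2008-01-02"))
        words, vlist = [], []
        for j in range(rng.randint(1, 6)):
            if rng.random() < 0.5:
                term = rng.choice(list(actant_terms.values()))
                words.append((term, "NOUN"))
            else:
                verb = rng.choice(verbs)
                vlist.append((len(words), verb))
                words.append((verb, "VERB"))
        sentences.append(make_sentence(post_id, 0, words, vlist))
    corpus = Corpus(posts=posts, sentences=sentences)
    lex = ActantLexicon(
        names=list(actant_terms),
        categories={"Alpha": "individual", "Beta": "institutional",
                    "Gamma": "object"},
        terms={name: ((term,),) for name, term in actant_terms.items()},
    )
    return corpus, lex
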