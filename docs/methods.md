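# Methods

This note documents the models, the defaults, and the design choices made
where the design was genuinely open; it states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Story model

Posts are modelled as partial activations of a hidden narrative
framework: a user picks a pair of actants and draws from the distribution
of relationships between them. Estimation inverts this model with
deliberately shallow linguistic machinery — nouns and verbs only, no
dependency parsing, no coreference, no negation or modality handling —
on the premise that with large corpora and persistent story signals,
minimal NLP information suffices and determinism is worth more than
per-sentence accuracy.

### Linguistic annotation

- **Sentence segmentation** is rule based: terminal punctuation with an
  abbreviation guard; text without terminal punctuation is one sentence.
- **POS tagging** is a pluggable backend contract (`tag(tokens) -> tags`
  over a tagset distinguishing nouns and verbs). The default backend is a
  deterministic lexicon-and-suffix tagger: closed-class word lists,
  a verb-form lexicon expanded from ~170 base verbs with regular and
  irregular inflections, a noun/verb homograph rule (a known verb form
  after a determiner/adjective/adposition reads as a noun), `-ly`/`-ed`/
  `-ing` suffix heuristics, and a noun default. Auxiliaries and modals
  are tagged as verbs on purpose: they populate the background
  distribution that the KL weighting is designed to attenuate.
- **Stemming** is the Porter (1980) algorithm with two departures taken
  from its author's later revisions: final `y -> i` only after a
  consonant, and tokens of length ≤ 2 returned unchanged. Only verbs are
  stemmed; actant terms are matched on raw lowercased tokens. This
  asymmetry is intentional — actant word sets are curated surface forms
  (including plural forms where wanted, e.g. the "exemptions" entry added
  to the Exemptions actant), while verb inflections must collapse
  ("funded"/"funds" → "fund", "use"/"used"/"using" → "us").

### Contexts and verb significance

For a pair (A, B), the context is the set of sentences mentioning both.
With N_v(C)/N(C) the in-context verb counts and N_v/N the corpus counts
(occurrence counts, not per-sentence indicators), a verb is ranked by the
pointwise KL contribution `p_pair · log2(p_pair / p_corpus)`. Properties
that matter: it is zero at p_pair = p_corpus, increasing in p_pair above
the marginal, and negative below it, so commonplace verbs are attenuated
and verbs rarer in the corpus but concentrated in the context rise. The
log base only rescales scores and cannot change a ranking.

Estimates are raw relative frequencies — no smoothing or priors. The
marginal is computed over the loaded corpus (the choice of reference
corpus is exposed by simply loading a different one). Defaults:
`top_k = 10` ranked verbs per context, `min_count = 5` in-context
occurrences (a floor against singleton artifacts; set `min_count = 1`
on toy corpora). Ties break by descending context count, then
lexicographically, making rankings total and reproducible.

### Relationship extraction and direction

Relationship categories are binary oppositions over stemmed verb sets in
two applicability blocks: individual/institutional pairs, and pairs
involving an object. The packaged default keeps the source table
verbatim, including its spelling "Grant or withold" and the stem "get"
appearing in two object-block categories; the loader reports such
duplicates and resolves them to the first-declared category (a strict
mode turns them into fatal configuration errors for custom lexicons).

The direction rule is surface word order, isolated in one operation so
alternates can be swapped in: a significant-verb token is considered only
when at least one actant mention lies on each side of it; among all
ordered mention pairs of distinct actants whose category combination
gives the verb a relationship category, the pair closest to the verb is
chosen, with source = earlier mention. On simple subject–verb–object
sentences this is exactly the nearest-preceding/nearest-following rule;
when the grammatical object is not a category-compatible actant (the
canonical religious-exemption sentence, where the verb takes the central
object as its object while relating two actants mentioned earlier), the
nearest compatible pair still yields the intended directed edge. Each
verb token emits at most one instance, avoiding quadratic spurious edges.
Negation is not modelled; a "do not have to …" sentence contributes the
same edge as its affirmative — a documented limitation of the shallow
approach.

### Story graphs and aggregation

Edges are (source, target, category) with weight = number of supporting
relation instances; KL scores remain available upstream as metadata.
Counts were chosen over scores because they are interpretable and
conserve exactly under aggregation, which makes the merge order-invariant
and associative (verified by property tests). Narrative-role annotation
(orientation / threat / strategy / resolution) is configuration-driven,
never inferred: aligning edges with the four-part personal-experience-
narrative scheme is an interpretive step.

## Topic traps (CRWT-style)

The co-occurrence network takes threads as documents (sentence-level
granularity is available), nouns after stopword removal as nodes, and
co-document counts as edge weights. Trap detection is recursive Louvain
modularity partition on the weighted graph — modularity is precisely the
excess probability that a stationary random walk stays within parts —
with per-trap word weights given by PageRank on the trap's induced
subgraph (damping 0.85, tolerance 1e-10, max 1000 iterations; weights
sum to 1 within every trap). Recursion stops at `max_depth` (default 3),
below a 4-node size floor, or when no split improves modularity;
disconnected components are processed independently under a synthetic
root. The original trap-detection objective lives in prior work; this
implementation reproduces the documented behaviour and is named
"CRWT-style" accordingly, with no claim of equivalence to the reference
implementation. LDA is deliberately not implemented.

## Trends

All trend series are per UTC calendar month. A post "contains" the
keyword when it appears as a standalone case-insensitive token;
`token+plural` mode also folds the bare plural. Both modes are
first-class because the underlying notion of "the word X" is
tokenization-dependent. A user is *new* in the month of their first post
and counts toward the keyword numerator only for keyword posts within
that joining month (counting any later keyword post is the documented
alternative). Months with zero posts are emitted with missing — not
zero — proportions. The duration histogram uses half-open 90-day bins
(3 months); day-resolution timestamps are expected, and month-resolution
corpora would quantize durations to ~30-day multiples.

## Synthetic generator

The generator runs the story model forwards and is the oracle for every
downstream stage. What it emulates:

- sentence templates `the SOURCE verb the TARGET .` (with light
  variation), with actant terms drawn uniformly from the lexicon and the
  verb drawn from `(1−ε)·background + ε·uniform(planted category)` for
  planted pairs, background otherwise. The determiners before the actant
  slots pin noun/verb homograph terms ("exempt", "vaccinate") to their
  noun reading, so the realized verb distribution equals the configured
  one; a validation step asserts at generation time that the tagger sees
  the verb slot as a verb in ≥ 99% of template instantiations;
- a background verb distribution (Zipf-like over ~45 auxiliaries and
  common forum verbs) standing in for conversational filler;
- user arrival by monthly Poisson cohorts and an exponential activity
  tenure (default mean 300 days) realized directly as the span between a
  user's first and last post, both emitted — so the observed duration
  estimand coincides with the configured tenure distribution;
- keyword injection as an extra verb-free sentence per post with
  probability q.

Preset study conditions: `planted_config` (one planted directed pair
carrying one third of the sentence mass, so ~2000 pair sentences in a
6000-sentence corpus at the default size, ε = 0.3), `trend_config`
(36 months × 1000 posts, q = 0.05, with pairs excluding the Exemptions
actant so the keyword occurs only by injection), `duration_config`
(a single 5000-user cohort, no monthly stream). What the generator does
**not** emulate: natural-language variation, topical drift, negation,
multi-actant sentences beyond the template pair, or bursty exogenous
events. Tests passing on synthetic corpora therefore certify the
estimation machinery under the model's own assumptions, not robustness
to real forum language; on real corpora the shallow tagger and the
word-order direction rule are the components most likely to degrade.

`ground_truth` returns the implied stem-level distributions (background,
per planted pair, corpus mixture), the closed-form top-KL stem per
planted pair, the expected monthly keyword proportion, and the tenure
mean.

## Numerical choices and degenerate inputs

- `kl_score(0, ·) = 0`; `p_pair > 0` with `p_corpus = 0` is a fatal
  containment violation (impossible when the context is built from the
  same corpus as the marginal).
- A corpus with zero verbs is fatal for probability estimation; an empty
  context is valid and ranks to an empty list with a warning.
- Probability normalisation is exact up to 1e-9 (asserted in tests);
  aggregation conservation is exact integer equality.
- Duration-slope fitting uses unweighted least squares on log counts
  over bins with ≥ 5 users, trading tail noise against bias.
- Determinism throughout: fixed seeds give byte-identical generated
  corpora and pipeline outputs; community detection and PageRank are
  seeded/tolerance-pinned.

## Problem sizes

Default test and acceptance runs use corpora of a few thousand posts
(planted recovery: 100 replicates × 6000 sentences; trends: 36 months ×
1000 posts; duration: 5000 users; trap recovery: 50 networks of 40
nodes), sizes at which the closed-form expectations are separated from
sampling noise by comfortable margins.
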