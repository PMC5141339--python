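"""End-to-end pipeline orchestration.

Runs tag -> contexts -> verb ranking -> relation extraction -> story
graphs -> narrative framework -> trends (-> topic traps), writing every
intermediate as a documented file and a manifest that records the
configuration hash, seed and package versions, so a run is reproducible
byte for byte under a fixed seed and fixed backend versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .contexts import (
    build_contexts,
    corpus_verb_distribution,
    rank_context_verbs,
    write_rankings_csv,
)
from .corpus import Corpus, read_corpus, segment_and_tag, write_annotated
from .graphs import aggregate, build_story_graph, export_graph
from .lexicons import (
    ActantLexicon,
    RelationshipLexicon,
    index_mentions,
    load_actant_lexicon,
    load_relationship_lexicon,
)
from .relations import extract_relations, write_relations_csv
from .topics import build_cooccurrence_network, detect_traps, export_traps_json
from .trends import (
    activity_duration_histogram,
    monthly_signal,
    write_histogram_csv,
    write_signal_csv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    corpus_path: str
    output_dir: str
    actant_lexicon_path: Optional[str] = None  # None -> packaged default
    relationship_lexicon_path: Optional[str] = None
    pairs: str = "all"  # "all", "A:B,C:D", or "Exemptions:*"
    top_k: int = 10
    min_count: int = 5
    keyword: str = "exemption"
    keyword_mode: str = "token"
    topics: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.top_k < 1:
            raise PipelineError("top_k must be >= 1")
        if not Path(self.corpus_path).exists():
            raise PipelineError(f"corpus file {self.corpus_path} does not exist")
        for p in (self.actant_lexicon_path, self.relationship_lexicon_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"lexicon file {p} does not exist")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _resolve_pairs(spec: str, lex: ActantLexicon) -> Optional[List[Tuple[str, str]]]:
    if spec == "all":
        return None
    pairs: List[Tuple[str, str]] = []
    for chunk in spec.split(","):
        a, _, b = chunk.strip().partition(":")
        if b == "*":
            for other in lex.names:
                if other != a:
                    pairs.append(tuple(sorted((a, other))))
        else:
            pairs.append(tuple(sorted((a, b))))
    for pair in pairs:
        for name in pair:
            if name not in lex:
                raise PipelineError(f"unknown actant {name!r} in pair spec")
    return pairs


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run artifact directory.

    Any stage failure leaves partial outputs in place and a manifest whose
    ``failed_stage`` marks where the run stopped.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: str(v) for k, v in cfg.__dict__.items()},
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "versions": {"narraframe": __version__},
        "stages": {},
        "failed_stage": None,
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["failed_stage"] = name
                manifest["stages"][name] = {"error": str(exc)}
                _write_manifest(out, manifest)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3)
            }
            return result
        return wrap

    alex = load_actant_lexicon(cfg.actant_lexicon_path)
    rlex = load_relationship_lexicon(cfg.relationship_lexicon_path)

    corpus = stage("read")(lambda: read_corpus(cfg.corpus_path))
    stage("tag")(lambda: segment_and_tag(corpus))
    stage("cache_annotated")(lambda: write_annotated(corpus, out / "annotated.jsonl"))

    mentions = stage("match")(lambda: index_mentions(corpus, alex))
    wanted = _resolve_pairs(cfg.pairs, alex)
    contexts = stage("contexts")(
        lambda: build_contexts(corpus, alex, pairs=wanted)
    )
    with (out / "contexts.csv").open("w", encoding="utf-8") as fh:
        fh.write("context,n_sentences,n_verbs\n")
        for pair in sorted(contexts):
            ctx = contexts[pair]
            fh.write(f"{ctx.label},{ctx.n_sentences},{ctx.verb_counts.N}\n")

    marginal = stage("marginal")(lambda: corpus_verb_distribution(corpus))
    rankings = stage("rank")(lambda: {
        pair: rank_context_verbs(ctx, marginal, top_k=cfg.top_k,
                                 min_count=cfg.min_count)
        for pair, ctx in sorted(contexts.items())
        if ctx.verb_counts.N > 0
    })
    write_rankings_csv(rankings, out / "verb_ranks.csv")

    def _relations():
        sentences_by_id = {s.sent_id: s for s in corpus.sentences}
        per_context = {}
        all_instances = []
        for pair, scores in sorted(rankings.items()):
            significant = {s.verb for s in scores}
            instances = []
            for sid in contexts[pair].sentence_ids:
                instances.extend(extract_relations(
                    sentences_by_id[sid], mentions.get(sid, ()),
                    significant, rlex, alex,
                ))
            per_context[pair] = instances
            all_instances.extend(instances)
        write_relations_csv(all_instances, out / "relations.csv")
        return per_context

    per_context_relations = stage("relations")(_relations)

    def _graphs():
        graphs = []
        for pair, instances in sorted(per_context_relations.items()):
            graph = build_story_graph(
                contexts[pair].label, pair, instances, alex
            )
            graphs.append(graph)
            safe = contexts[pair].label.replace(" ", "_").replace("<->", "--")
            export_graph(graph, out / f"story_{safe}.json", "json")
        framework = aggregate(graphs)
        export_graph(framework, out / "framework.graphml", "graphml")
        export_graph(framework, out / "framework.json", "json")
        export_graph(framework, out / "framework.dot", "dot")
        return framework

    stage("graphs")(_graphs)

    def _trends():
        for site in corpus.sites or [""]:
            site_posts = [p for p in corpus.posts if p.site_id == site]
            sub = Corpus(posts=site_posts)
            signal = monthly_signal(sub, cfg.keyword, cfg.keyword_mode)
            suffix = f"_{site}" if site and len(corpus.sites) > 1 else ""
            write_signal_csv(signal, out / f"trends{suffix}.csv", site_id=site)
            hist = activity_duration_histogram(sub)
            write_histogram_csv(hist, out / f"duration_histogram{suffix}.csv")

    stage("trends")(_trends)

    if cfg.topics:
        def _topics():
            net = build_cooccurrence_network(corpus)
            traps = detect_traps(net, seed=cfg.seed)
            export_traps_json(traps, out / "topics.json")
        stage("topics")(_topics)

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
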