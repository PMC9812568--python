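"""Synthetic knowledge graphs and labeled corpora with KG-informative ambiguity.

The generator emulates, at desk scale, the situation that motivates
knowledge-enhanced NER: some surface forms are *ambiguous* - they occur both
as genuine entity mentions and as plain words - and the only in-sentence
signal that resolves them is the co-occurrence of a KG-neighbor entity (a
"cue", e.g. an alias linked by a "same as" edge). By construction:

* an ambiguous mention is labeled as an entity iff a cue mention (a KG
  neighbor of its node) occurs in the same sentence;
* a dictionary (gazetteer) tagger is perfect when ``p_amb = 0`` and provably
  imperfect when ``p_amb > 0``, while a gazetteer augmented with the KG cue
  check recovers perfect F1 - the dependency signal is *sufficient*.

Entity surfaces are pronounceable pseudo-words, disjoint from the distractor
vocabulary, so nothing is memorizable from real-world lexical knowledge.
Generation is a pure function of (config, seed). A fraction of multi-word
surfaces deliberately share their first word with a surface of a different
category, so concept-level knowledge (which surface a token belongs to) has
measurable value even without edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import Corpus, Sentence, Span, bio_from_spans
from .kg import KnowledgeGraph, match_entities, normalize_surface

__all__ = [
    "ConfigMismatchError",
    "SynthBundle",
    "SynthConfig",
    "corpus_stats",
    "cue_rule_predict",
    "gazetteer_predict",
    "generate_bundle",
    "generate_corpus",
    "generate_kg",
]

CATEGORIES = ("Disease", "Drug", "Target")
_SAME = "same_as"
_CROSS = {("Disease", "Drug"): "treated_by", ("Disease", "Target"): "caused_by",
          ("Drug", "Target"): "acts_on"}


class ConfigMismatchError(ValueError):
    """The supplied KG was not produced by :func:`generate_kg` with this config."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    ``p_amb`` is the fraction of base entity surface forms that also occur
    as plain (O-labeled) words; ``alias_rate`` the probability an entity
    gets a "same as" alias; ``cross_edge_rate`` the probability of an edge
    to an entity of another category; ``shared_word_rate`` the probability a
    multi-word surface reuses a word from another category's surface.
    """

    n_entities: int = 30
    categories: tuple[str, ...] = CATEGORIES
    alias_rate: float = 0.5
    cross_edge_rate: float = 0.3
    p_amb: float = 0.4
    shared_word_rate: float = 0.25
    n_train: int = 600
    n_dev: int = 100
    n_test: int = 200
    sentence_length: tuple[int, int] = (8, 20)
    vocab_size: int = 500
    mention_count_probs: tuple[float, ...] = (0.15, 0.40, 0.30, 0.15)
    seed: int = 17

    def __post_init__(self):
        for p in (self.alias_rate, self.cross_edge_rate, self.p_amb, self.shared_word_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_entities, self.n_train, self.n_dev, self.n_test, self.vocab_size) < 1:
            raise ValueError("counts must be >= 1")
        if self.sentence_length[0] < 8 or self.sentence_length[1] < self.sentence_length[0]:
            raise ValueError("sentence_length must be (lo, hi) with 8 <= lo <= hi")


@dataclass
class SynthBundle:
    """A generated KG plus train/dev/test corpora and the ambiguity oracle.

    ``oracle`` records every ambiguous decision: sentence id, token span,
    surface form, whether the occurrence was positive (entity) and which cue
    licensed it. Splits are disjoint at the sentence (token-sequence) level.
    """

    kg: KnowledgeGraph
    corpora: dict[str, Corpus]
    oracle: list[dict]
    config: SynthConfig

    @property
    def ambiguous_forms(self) -> set[str]:
        return {
            normalize_surface(s)
            for s, m in zip(self.kg.surface_forms, self.kg.node_meta)
            if m.get("ambiguous")
        }


# ---------------------------------------------------------------------------
# pseudo-word lexicon

_CONS = "bdfglmnprstvz"
_VOW = "aeiou"


def _word_stream(rng: np.random.Generator, taken: set[str]):
    """Endless unique pronounceable pseudo-words (2-3 CV syllables)."""
    while True:
        n_syll = int(rng.integers(2, 4))
        w = "".join(
            _CONS[rng.integers(len(_CONS))] + _VOW[rng.integers(len(_VOW))]
            for _ in range(n_syll)
        )
        if w not in taken:
            taken.add(w)
            yield w


def _distractor_vocab(cfg: SynthConfig) -> tuple[list[str], set[str]]:
    rng = np.random.default_rng([cfg.seed, 0])
    taken: set[str] = set()
    stream = _word_stream(rng, taken)
    vocab = list(itertools.islice(stream, cfg.vocab_size))
    return vocab, taken


# ---------------------------------------------------------------------------
# knowledge graph

def generate_kg(cfg: SynthConfig) -> KnowledgeGraph:
    """Generate the entity inventory and dependency edges.

    Base entities get 1-3-word surfaces; aliases (``alias_rate``) join their
    entity by a "same as" edge; cross-category edges appear at
    ``cross_edge_rate``. A ``p_amb`` fraction of base entities is flagged
    ambiguous; every ambiguous entity is guaranteed at least one unambiguous
    KG neighbor (an alias is added if needed) so a cue always exists.
    """
    _, taken = _distractor_vocab(cfg)  # reserve distractor words
    rng = np.random.default_rng([cfg.seed, 1])
    stream = _word_stream(rng, taken)

    surfaces: list[str] = []
    categories: list[str] = []
    meta: list[dict] = []
    used_surfaces: set[str] = set()

    def new_surface(category: str, alias: bool) -> int:
        n_words = int(rng.integers(1, 4))
        words: list[str]
        if (
            n_words >= 2
            and surfaces
            and rng.random() < cfg.shared_word_rate
        ):
            donors = [i for i, c in enumerate(categories) if c != category]
            if donors:
                donor = surfaces[int(rng.choice(donors))].split()
                words = [donor[0]] + [next(stream) for _ in range(n_words - 1)]
            else:
                words = [next(stream) for _ in range(n_words)]
        else:
            words = [next(stream) for _ in range(n_words)]
        surface = " ".join(words)
        while surface in used_surfaces:  # extremely unlikely; regenerate
            words = [next(stream) for _ in range(n_words)]
            surface = " ".join(words)
        used_surfaces.add(surface)
        surfaces.append(surface)
        categories.append(category)
        meta.append({"ambiguous": False, "alias": alias, "synthetic": True})
        return len(surfaces) - 1

    import networkx as nx

    g = nx.Graph()
    base_by_cat: dict[str, list[int]] = {c: [] for c in cfg.categories}
    for cat in cfg.categories:
        for _ in range(cfg.n_entities):
            i = new_surface(cat, alias=False)
            g.add_node(i)
            base_by_cat[cat].append(i)
            if rng.random() < cfg.alias_rate:
                j = new_surface(cat, alias=True)
                g.add_edge(i, j, relations={_SAME})

    all_base = [i for ids in base_by_cat.values() for i in ids]
    for i in all_base:
        if rng.random() < cfg.cross_edge_rate:
            cat = categories[i]
            others = [j for j in all_base if categories[j] != cat and j != i]
            j = int(rng.choice(others))
            key = tuple(sorted((categories[i], categories[j])))
            rel = _CROSS.get(key, "related_to")
            if not g.has_edge(i, j):
                g.add_edge(i, j, relations={rel})

    for i in all_base:
        if rng.random() < cfg.p_amb:
            meta[i]["ambiguous"] = True

    # guarantee every ambiguous entity an unambiguous neighbor (the cue)
    for i in list(all_base):
        if meta[i]["ambiguous"]:
            nbrs = list(g.neighbors(i)) if i in g else []
            if not any(not meta[j]["ambiguous"] for j in nbrs):
                j = new_surface(categories[i], alias=True)
                g.add_edge(i, j, relations={_SAME})

    g.add_nodes_from(range(len(surfaces)))
    return KnowledgeGraph(
        surface_forms=surfaces, categories=list(categories), graph=g, node_meta=meta
    )


# ---------------------------------------------------------------------------
# corpora

def _unambiguous_neighbors(kg: KnowledgeGraph, node: int) -> list[int]:
    return [j for j in kg.neighbors(node) if not kg.node_meta[j].get("ambiguous")]


def _compose_sentence(
    rng: np.random.Generator,
    kg: KnowledgeGraph,
    cfg: SynthConfig,
    vocab: list[str],
    sent_id: str,
) -> tuple[Sentence, list[dict]]:
    # mentions are drawn from base entities so the operative ambiguity level
    # equals p_amb; aliases enter sentences as cues
    base = [i for i in range(kg.n_nodes) if not kg.node_meta[i].get("alias")]
    k = int(rng.choice(len(cfg.mention_count_probs), p=cfg.mention_count_probs))

    chosen: list[int] = []
    plan: list[dict] = []
    for _ in range(k):
        for _attempt in range(30):
            node = int(base[rng.integers(len(base))])
            if node in chosen:
                continue
            if kg.node_meta[node].get("ambiguous"):
                positive = bool(rng.random() < 0.5)
                if positive:
                    negatives = [m["node"] for m in plan if not m["labeled"]]
                    if any(kg.graph.has_edge(node, b) for b in negatives):
                        continue
                    cues = [
                        c
                        for c in _unambiguous_neighbors(kg, node)
                        if c not in chosen
                        and not any(kg.graph.has_edge(c, b) for b in negatives)
                    ]
                    if not cues:
                        continue
                    cue = int(rng.choice(cues))
                    chosen += [node, cue]
                    plan.append({"node": node, "labeled": True, "ambiguous": True, "cue": cue})
                    plan.append({"node": cue, "labeled": True, "ambiguous": False, "cue": None})
                else:
                    # a negative must have no KG neighbor among the other mentions
                    if any(kg.graph.has_edge(node, m["node"]) for m in plan):
                        continue
                    chosen.append(node)
                    plan.append({"node": node, "labeled": False, "ambiguous": True, "cue": None})
            else:
                # an unambiguous mention must not accidentally cue a negative
                if any(
                    not m["labeled"] and kg.graph.has_edge(node, m["node"]) for m in plan
                ):
                    continue
                chosen.append(node)
                plan.append({"node": node, "labeled": True, "ambiguous": False, "cue": None})
            break

    rng.shuffle(plan)
    lo, hi = cfg.sentence_length
    n_base = int(rng.integers(lo, hi + 1))
    base = [vocab[int(rng.integers(len(vocab)))] for _ in range(n_base)]
    slots = sorted(rng.choice(np.arange(1, n_base), size=len(plan), replace=False).tolist())

    tokens: list[str] = []
    spans: list[Span] = []
    oracle: list[dict] = []
    prev = 0
    for slot, m in zip(slots, plan):
        tokens.extend(base[prev:slot])
        words = kg.surface_forms[m["node"]].split()
        start = len(tokens)
        tokens.extend(words)
        end = len(tokens)
        if m["labeled"]:
            spans.append(Span(start, end, kg.categories[m["node"]]))
        if m["ambiguous"]:
            oracle.append(
                {
                    "sentence_id": sent_id,
                    "start": start,
                    "end": end,
                    "surface": kg.surface_forms[m["node"]],
                    "positive": m["labeled"],
                    "cue_surface": kg.surface_forms[m["cue"]] if m["cue"] is not None else None,
                }
            )
        prev = slot
    tokens.extend(base[prev:])
    labels = bio_from_spans(spans, len(tokens))
    return Sentence(tokens=tokens, labels=labels, id=sent_id), oracle


def generate_corpus(kg: KnowledgeGraph, cfg: SynthConfig) -> SynthBundle:
    """Generate train/dev/test corpora over a KG from :func:`generate_kg`.

    Sentences are streams of distractor words with entity mentions spliced
    in (always separated by at least one distractor, so greedy matching
    recovers the inserted spans exactly). Splits share no token sequence.
    """
    if not kg.node_meta or "ambiguous" not in kg.node_meta[0]:
        raise ConfigMismatchError("kg lacks generator metadata; use generate_kg")
    vocab, vocab_set = _distractor_vocab(cfg)
    for s in kg.surface_forms:
        if any(w in vocab_set for w in s.split()):
            raise ConfigMismatchError("kg lexicon overlaps the distractor vocabulary")

    rng = np.random.default_rng([cfg.seed, 2])
    seen: set[tuple[str, ...]] = set()
    corpora: dict[str, Corpus] = {}
    oracle: list[dict] = []
    for split, count in (("train", cfg.n_train), ("dev", cfg.n_dev), ("test", cfg.n_test)):
        sentences: list[Sentence] = []
        while len(sentences) < count:
            sid = f"{split}-{len(sentences):05d}"
            sent, entries = _compose_sentence(rng, kg, cfg, vocab, sid)
            key = tuple(sent.tokens)
            if key in seen:
                continue
            seen.add(key)
            sentences.append(sent)
            for e in entries:
                e["split"] = split
            oracle.extend(entries)
        corpora[split] = Corpus.from_sentences(sentences, split=split)
    return SynthBundle(kg=kg, corpora=corpora, oracle=oracle, config=cfg)


def generate_bundle(cfg: SynthConfig | None = None, **overrides) -> SynthBundle:
    """Convenience: KG + corpora in one call."""
    cfg = replace(cfg or SynthConfig(), **overrides) if overrides else (cfg or SynthConfig())
    return generate_corpus(generate_kg(cfg), cfg)


# ---------------------------------------------------------------------------
# stats and reference decision rules

def corpus_stats(bundle: SynthBundle) -> pd.DataFrame:
    """Per-category mention counts per split, KG node counts, and overlap.

    "common" counts distinct mention surface forms that also appear in the
    KG lexicon (by construction all mentions come from the KG, so this
    equals the number of distinct forms actually used).
    """
    cats = list(bundle.config.categories)
    rows = {}
    mention_forms: dict[str, set[str]] = {c: set() for c in cats}
    counts = {(c, s): 0 for c in cats for s in bundle.corpora}
    for split, corpus in bundle.corpora.items():
        for sent in corpus:
            from .corpus import spans_from_bio, validate_bio

            for sp in spans_from_bio(validate_bio(sent.labels)):
                counts[(sp.category, split)] += 1
                form = normalize_surface(" ".join(sent.tokens[sp.start : sp.end]))
                mention_forms[sp.category].add(form)
    kg_forms = {c: set() for c in cats}
    for s, c in zip(bundle.kg.surface_forms, bundle.kg.categories):
        if c in kg_forms:
            kg_forms[c].add(normalize_surface(s))
    for c in cats:
        rows[c] = {
            **{f"mentions_{s}": counts[(c, s)] for s in bundle.corpora},
            "kg_nodes": len(kg_forms[c]),
            "common": len(mention_forms[c] & kg_forms[c]),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "category"
    return df


def gazetteer_predict(corpus: Corpus, kg: KnowledgeGraph, max_ngram: int = 6) -> list[list[str]]:
    """Label every dictionary-matched n-gram as an entity of its KG category."""
    out = []
    for sent in corpus:
        matches = match_entities(sent, kg, max_ngram=max_ngram)
        spans = [m.span for m in matches]
        out.append(bio_from_spans(spans, len(sent)))
    return out


def cue_rule_predict(
    corpus: Corpus,
    kg: KnowledgeGraph,
    ambiguous_forms: set[str],
    max_ngram: int = 6,
) -> list[list[str]]:
    """Gazetteer plus KG cue check: the oracle decision rule.

    Unambiguous matches are kept; an ambiguous match is kept iff some other
    match in the sentence is a first-order KG neighbor of its node.
    """
    out = []
    for sent in corpus:
        matches = match_entities(sent, kg, max_ngram=max_ngram)
        kept = []
        for m in matches:
            form = normalize_surface(kg.surface_forms[m.node_id])
            if form not in ambiguous_forms:
                kept.append(m.span)
            elif any(
                o is not m and kg.graph.has_edge(m.node_id, o.node_id) for o in matches
            ):
                kept.append(m.span)
        out.append(bio_from_spans(kept, len(sent)))
    return out
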