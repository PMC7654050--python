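"""Synthetic corpora, dictionaries, parses and embeddings.

The generator emulates the statistical structure the triage pipeline
assumes: positive abstracts contain (with configurable probability) a
sentence holding two protein mentions, an interaction word and a
mutation token — the planted PPIAM pattern — while negative abstracts
contain such a sentence only at a background rate. Both classes share
neutral decoy sentences (single proteins, protein + interaction without
mutation) so the label signal is carried by the co-occurrence pattern,
not by vocabulary alone. Labels can be flipped at a noise rate; the
pre-noise label is kept in the annotations.

Everything is deterministic per seed, byte for byte, and is emitted in
exactly the formats the pipeline reads (JSONL corpus, one-term-per-line
dictionaries, CoNLL-U parses, word2vec-text embeddings).

No attempt is made at realistic sentence grammar; the planted sentence
follows one fixed template so that the documented dependency-path
example (interior tokens [<iw>, PROT2, fails], relations
[nsubj, nmod, conj, nsubj]) is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus import Corpus, Document, write_corpus
from .depgraph import DependencyGraph, PseudoParser, mask_proteins, write_conllu
from .embeddings import EmbeddingTable
from .lexicon import AMINO_ACIDS, TermDictionary, find_mentions, MatcherIndex
from .preprocess import split_sentences, train_sentence_model

INTERACTION_WORDS = ("binds", "interacts", "phosphorylates", "activates",
                     "inhibits", "associates")
MUTATION_WORDS = ("variant", "mutant", "mutation", "substitution")

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``prevalence`` is applied as an exact quota (``round(n_docs *
    prevalence)`` positive labels before noise). ``pattern_rate`` is the
    probability that a positive document contains a planted PPIAM
    sentence; ``background_rate`` the probability that a negative one
    does. ``noise_rate`` flips each final label independently.
    """

    n_docs: int = 200
    prevalence: float = 0.42
    pattern_rate: float = 1.0
    background_rate: float = 0.05
    noise_rate: float = 0.0
    n_proteins: int = 30
    n_background_words: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "pattern_rate", "background_rate",
                     "noise_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")


@dataclass
class DocAnnotation:
    true_label: int      # pre-noise label (determined by the planted signal)
    label: int           # observed (possibly flipped) label
    planted: list[dict]  # one entry per planted PPIAM sentence
    mentions: list[tuple[str, str]]  # gold (kind, surface) pairs


@dataclass
class GeneratedCorpus:
    corpus: Corpus
    annotations: dict[str, DocAnnotation]
    protein_terms: list[str]
    interaction_terms: list[str]
    mutation_terms: list[str]
    config: GeneratorConfig

    @property
    def vocabulary(self) -> list[str]:
        """All word tokens the generator can emit (for embedding tables)."""
        words = set(self.protein_terms) | set(self.interaction_terms) \
            | set(self.mutation_terms)
        for ann in self.annotations.values():
            for _, surface in ann.mentions:
                words.add(surface)
        for doc in self.corpus:
            words.update(t for t in doc.text.split() if t.isalnum())
        return sorted(words)


def _nonsense_word(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
                   for _ in range(n_syllables))


def _mutation_code(rng: np.random.Generator) -> str:
    aas = list(AMINO_ACIDS)
    return (rng.choice(aas) + str(rng.integers(10, 999)) + rng.choice(aas))


def generate_corpus(config: GeneratorConfig) -> GeneratedCorpus:
    """Corpus plus gold annotations and the three term dictionaries."""
    rng = np.random.default_rng(config.seed)
    proteins = [f"Gene{i}p" for i in range(1, config.n_proteins + 1)]
    background = sorted({_nonsense_word(rng) for _ in
                         range(config.n_background_words * 2)})[:config.n_background_words]
    if not background:
        background = ["filler"]

    n_pos = round(config.n_docs * config.prevalence)
    labels = np.array([1] * n_pos + [0] * (config.n_docs - n_pos))
    rng.shuffle(labels)

    def bg_word() -> str:
        return background[rng.integers(0, len(background))]

    def protein() -> str:
        return proteins[rng.integers(0, len(proteins))]

    def planted_sentence() -> tuple[str, dict]:
        p1 = protein()
        p2 = protein()
        while p2 == p1:
            p2 = protein()
        iw = INTERACTION_WORDS[rng.integers(0, len(INTERACTION_WORDS))]
        code = _mutation_code(rng)
        text = f"{p1} {iw} {p2} , but the {code} variant fails ."
        return text, {"p1": p1, "p2": p2, "iw": iw, "code": code}

    def decoy_sentence() -> tuple[str, list[tuple[str, str]]]:
        kind = rng.integers(0, 3)
        if kind == 0:  # plain background
            return (f"the {bg_word()} of {bg_word()} was {bg_word()} "
                    f"in {bg_word()} ."), []
        if kind == 1:  # single protein, no relation
            p = protein()
            return (f"{p} was {bg_word()} in the {bg_word()} assay ."), \
                [("protein", p)]
        p1, p2 = protein(), protein()  # interaction without any mutation word
        iw = INTERACTION_WORDS[rng.integers(0, len(INTERACTION_WORDS))]
        return (f"{p1} {iw} {p2} in {bg_word()} cells ."), \
            [("protein", p1), ("protein", p2), ("interaction", iw)]

    docs: list[Document] = []
    annotations: dict[str, DocAnnotation] = {}
    for i, true_label in enumerate(labels):
        doc_id = f"SYN{i + 1:05d}"
        has_pattern = bool(
            rng.random() < (config.pattern_rate if true_label == 1
                            else config.background_rate))
        sentences: list[str] = []
        planted_meta: list[dict] = []
        gold: list[tuple[str, str]] = []
        n_decoys = int(rng.integers(2, 5))
        for _ in range(n_decoys):
            s, ms = decoy_sentence()
            sentences.append(s)
            gold.extend(ms)
        if has_pattern:
            s, meta = planted_sentence()
            pos = int(rng.integers(0, len(sentences) + 1))
            sentences.insert(pos, s)
            planted_meta.append(meta)
            gold.extend([("protein", meta["p1"]), ("protein", meta["p2"]),
                         ("interaction", meta["iw"]),
                         ("mutation", meta["code"]), ("mutation", "variant")])
        title = f"{bg_word()} {bg_word()} study of {bg_word()}"
        observed = int(true_label)
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            observed = 1 - observed
        docs.append(Document(doc_id=doc_id, title=title,
                             body=" ".join(sentences), label=observed))
        annotations[doc_id] = DocAnnotation(
            true_label=int(true_label), label=observed,
            planted=planted_meta, mentions=gold)

    return GeneratedCorpus(
        corpus=Corpus(docs, provenance=f"synthetic seed={config.seed}"),
        annotations=annotations,
        protein_terms=proteins,
        interaction_terms=list(INTERACTION_WORDS),
        mutation_terms=list(MUTATION_WORDS),
        config=config,
    )


def generate_parses(gen: GeneratedCorpus) -> list[DependencyGraph]:
    """Deterministic pseudo-parses of every masked sentence.

    Runs the same preprocessing the pipeline runs (sentence model
    trained on the corpus, dictionary tagging, protein masking) and
    parses each sentence with the pseudo-parser, so planted sentences
    receive the fixed documented subgraph.
    """
    model = train_sentence_model(gen.corpus)
    matchers = {}
    for kind, terms in (("protein", gen.protein_terms),
                        ("interaction", gen.interaction_terms),
                        ("mutation", gen.mutation_terms)):
        if terms:
            matchers[kind] = MatcherIndex(
                TermDictionary(kind=kind, terms=frozenset(terms)))
    parser = PseudoParser()
    graphs: list[DependencyGraph] = []
    for doc in gen.corpus:
        tokdoc = split_sentences(doc, model)
        mentions = find_mentions(tokdoc, matchers)
        for sent in tokdoc.sentences:
            masked = mask_proteins(sent, mentions)
            graphs.append(parser.parse(masked.tokens,
                                       sentence_ref=(doc.doc_id, sent.index)))
    return graphs


def generate_embeddings(vocabulary: list[str], d: int, seed: int,
                        ) -> EmbeddingTable:
    """Unit-norm random vectors for every vocabulary word."""
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    rng = np.random.default_rng(seed)
    vectors = {}
    for w in vocabulary:
        v = rng.standard_normal(d)
        vectors[w] = v / np.linalg.norm(v)
    return EmbeddingTable(vectors)


def make_fixtures(out_dir: str | Path, config: Optional[GeneratorConfig] = None,
                  embedding_dim: int = 16) -> dict[str, Path]:
    """Write a complete fixture set into ``out_dir``.

    Emits corpus.jsonl, proteins.txt / interactions.txt / mutations.txt,
    parses.conllu and embeddings.txt; returns the path of each artifact.
    """
    config = config or GeneratorConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = generate_corpus(config)
    paths = {"corpus": write_corpus(gen.corpus, out / "corpus.jsonl")}
    for kind, terms in (("proteins", gen.protein_terms),
                        ("interactions", gen.interaction_terms),
                        ("mutations", gen.mutation_terms)):
        p = out / f"{kind}.txt"
        p.write_text("\n".join(terms) + "\n", encoding="utf-8")
        paths[kind] = p
    paths["parses"] = write_conllu(generate_parses(gen), out / "parses.conllu")
    table = generate_embeddings(gen.vocabulary, embedding_dim, config.seed)
    paths["embeddings"] = table.to_word2vec_text(out / "embeddings.txt")
    return paths
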