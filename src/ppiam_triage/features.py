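"""Abstract-level feature assembly.

Every abstract becomes one fixed-width sparse vector built from named
blocks:

- TF-IDF of the top-k stemmed, stopword-filtered unigrams and bigrams,
  with the unsmoothed formula TF-IDF(t,d,D) = TF(t,d) * ln(N / df(t));
- frequencies of the three key-term kinds per token;
- counts of triplet shortest-path lengths over bins 1..10 and 11+ for
  the three typed paths (33 features) and the protein-mutation paths
  (11 features);
- counts of triplet probabilities over four fixed bins;
- TF-IDF of token unigrams/bigrams along protein->mutation shortest
  paths (stopwords retained) and plain counts of dependency-relation
  unigrams/bigrams along those paths;
- key-term frequencies over shortest-path interior tokens;
- the same path n-grams over polarity-augmented tokens (suffixed
  ``_PPIPOS`` / ``_PPINEG`` by pair polarity) plus 22 counts of
  positive/negative pairs over the length bins;
- optionally, a TF-IDF-weighted average word embedding of the abstract
  and a plain average embedding of path interior tokens.

The whole pipeline is exposed as :class:`TriageFeaturizer`, a
scikit-learn transformer (``fit`` on a training corpus fixes all
vocabularies; ``transform`` maps documents to the fixed feature space).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .candidates import DEFAULT_CANDIDATE_CAP, extract_candidates
from .corpus import Corpus, Document
from .depgraph import (DependencyGraph, MaskedSentence, PairPath, PseudoParser,
                       TypedPaths, mask_proteins, paths_for_candidates)
from .embeddings import EmbeddingTable
from .lexicon import (Mention, MatcherIndex, TermDictionary, find_mentions,
                      match_mutation_nomenclature, simplify_appositives)
from .ppi import (LogisticPathScorer, PairPolarity, TripletScore,
                  bin_probabilities, label_pairs, score_triplets)
from .preprocess import (SentenceBoundaryModel, TokenizedDocument,
                         split_sentences, train_sentence_model)
from .stem import stem_token
from .stopwords import STOPWORDS

#: path-length bins 1, 2, ..., 10, 11+
N_LENGTH_BINS = 11
PATH_BIN_LABELS = [str(i) for i in range(1, 11)] + ["11+"]

#: suffixes distinguishing terms on positive / negative pair paths
POSITIVE_SUFFIX = "_PPIPOS"
NEGATIVE_SUFFIX = "_PPINEG"

_PLACEHOLDER_RE = re.compile(r"^PROT[0-9]+$")


def length_bin(length: Optional[int]) -> int:
    """Bin index for a path length; None (unreachable) maps to 11+."""
    if length is None or length >= N_LENGTH_BINS:
        return N_LENGTH_BINS - 1
    if length < 1:
        raise ValueError(f"path length must be >= 1, got {length}")
    return length - 1


# ---------------------------------------------------------------------------
# printed-formula TF-IDF and count vectorizers


class PrintedTfidf:
    """TF-IDF with the unsmoothed formula TF(t,d) * ln(N / df(t)).

    TF is the raw in-document count; df the number of training
    documents containing the term; N the training corpus size. When
    ``max_terms`` is given, only the terms with highest document
    frequency are retained (ties broken lexicographically). Terms with
    df == N are retained but carry zero weight by the formula.
    """

    def __init__(self, max_terms: Optional[int] = None):
        self.max_terms = max_terms
        self.vocabulary_: dict[str, int] = {}
        self.idf_: dict[str, float] = {}
        self.n_docs_ = 0

    def fit(self, docs_terms: Sequence[Sequence[str]]) -> "PrintedTfidf":
        df: dict[str, int] = {}
        for terms in docs_terms:
            for t in set(terms):
                df[t] = df.get(t, 0) + 1
        ranked = sorted(df, key=lambda t: (-df[t], t))
        if self.max_terms is not None:
            ranked = ranked[: self.max_terms]
        kept = sorted(ranked)
        self.vocabulary_ = {t: i for i, t in enumerate(kept)}
        self.n_docs_ = len(docs_terms)
        self.idf_ = {t: math.log(self.n_docs_ / df[t]) for t in kept}
        return self

    @property
    def feature_names_(self) -> list[str]:
        return sorted(self.vocabulary_, key=self.vocabulary_.get)

    def transform_one(self, terms: Sequence[str]) -> dict[int, float]:
        tf: dict[str, int] = {}
        for t in terms:
            if t in self.vocabulary_:
                tf[t] = tf.get(t, 0) + 1
        return {self.vocabulary_[t]: c * self.idf_[t] for t, c in tf.items()}

    def __len__(self) -> int:
        return len(self.vocabulary_)


class CountVocab:
    """Plain count vectorizer over a vocabulary fixed at fit time."""

    def __init__(self) -> None:
        self.vocabulary_: dict[str, int] = {}

    def fit(self, docs_terms: Sequence[Sequence[str]]) -> "CountVocab":
        vocab = sorted({t for terms in docs_terms for t in terms})
        self.vocabulary_ = {t: i for i, t in enumerate(vocab)}
        return self

    @property
    def feature_names_(self) -> list[str]:
        return sorted(self.vocabulary_, key=self.vocabulary_.get)

    def transform_one(self, terms: Sequence[str]) -> dict[int, float]:
        out: dict[int, float] = {}
        for t in terms:
            i = self.vocabulary_.get(t)
            if i is not None:
                out[i] = out.get(i, 0.0) + 1.0
        return out

    def __len__(self) -> int:
        return len(self.vocabulary_)


# ---------------------------------------------------------------------------
# block-level operations


def keyterm_frequencies(mentions: Sequence[Mention], n_tokens: int,
                        ) -> tuple[float, float, float]:
    """(protein, interaction, mutation) mention counts per token."""
    if n_tokens <= 0:
        raise ValueError("token count must be positive")
    counts = {"protein": 0, "interaction": 0, "mutation": 0}
    for m in mentions:
        counts[m.kind] += 1
    return (counts["protein"] / n_tokens, counts["interaction"] / n_tokens,
            counts["mutation"] / n_tokens)


def triplet_path_length_bins(typed_paths: Sequence[TypedPaths]) -> list[int]:
    """33 counts: 3 typed paths x 11 length bins."""
    bins = [0] * (3 * N_LENGTH_BINS)
    for tp in typed_paths:
        for type_idx, path in enumerate(tp.as_tuple()):
            L = path.length if path is not None else None
            bins[type_idx * N_LENGTH_BINS + length_bin(L)] += 1
    return bins


def pair_path_length_bins(pair_paths: Sequence[PairPath]) -> list[int]:
    """11 counts of protein-mutation path lengths."""
    bins = [0] * N_LENGTH_BINS
    for pp in pair_paths:
        L = pp.path.length if pp.path is not None else None
        bins[length_bin(L)] += 1
    return bins


def path_token_ngrams(pair_paths: Sequence[PairPath],
                      suffix_by_pair: Optional[Sequence[str]] = None,
                      ) -> tuple[list[str], list[str]]:
    """Interior-token unigrams and bigrams over all pair paths, in the
    protein -> mutation direction; optional per-pair suffix augmentation."""
    unis: list[str] = []
    bis: list[str] = []
    for k, pp in enumerate(pair_paths):
        if pp.path is None:
            continue
        toks = pp.path.interior_tokens
        if suffix_by_pair is not None:
            toks = [t + suffix_by_pair[k] for t in toks]
        unis.extend(toks)
        bis.extend(f"{a}/{b}" for a, b in zip(toks, toks[1:]))
    return unis, bis


def path_relation_ngrams(pair_paths: Sequence[PairPath],
                         suffix_by_pair: Optional[Sequence[str]] = None,
                         ) -> tuple[list[str], list[str]]:
    """Dependency-relation unigrams and bigrams along pair paths."""
    unis: list[str] = []
    bis: list[str] = []
    for k, pp in enumerate(pair_paths):
        if pp.path is None:
            continue
        rels = list(pp.path.relation_sequence)
        if suffix_by_pair is not None:
            rels = [r + suffix_by_pair[k] for r in rels]
        unis.extend(rels)
        bis.extend(f"{a}/{b}" for a, b in zip(rels, rels[1:]))
    return unis, bis


def path_keyterm_frequencies(pair_paths: Sequence[PairPath],
                             interaction_terms: Iterable[str] = (),
                             mutation_terms: Iterable[str] = (),
                             ) -> tuple[float, float, float]:
    """Key-term fractions over all pair-path interior tokens.

    Endpoints (the protein mention and the mutation word) are never
    counted. Interior protein mentions are the masked placeholders.
    Returns (0, 0, 0) when there are no interior tokens.
    """
    iw = {t.lower() for t in interaction_terms}
    mu = {t.lower() for t in mutation_terms}
    total = 0
    counts = [0, 0, 0]
    for pp in pair_paths:
        if pp.path is None:
            continue
        for tok in pp.path.interior_tokens:
            total += 1
            if _PLACEHOLDER_RE.match(tok):
                counts[0] += 1
            if tok.lower() in iw:
                counts[1] += 1
            if tok.lower() in mu or match_mutation_nomenclature(tok):
                counts[2] += 1
    if total == 0:
        return (0.0, 0.0, 0.0)
    return (counts[0] / total, counts[1] / total, counts[2] / total)


def pair_polarity_bins(pair_paths: Sequence[PairPath],
                       polarities: Sequence[PairPolarity]) -> list[int]:
    """22 counts: positive pairs then negative pairs over length bins."""
    if len(pair_paths) != len(polarities):
        raise ValueError("one polarity per pair path is required")
    bins = [0] * (2 * N_LENGTH_BINS)
    for pp, pol in zip(pair_paths, polarities):
        L = pp.path.length if pp.path is not None else None
        offset = 0 if pol.polarity == "positive" else N_LENGTH_BINS
        bins[offset + length_bin(L)] += 1
    return bins


# ---------------------------------------------------------------------------
# per-document analysis


@dataclass
class DocAnalysis:
    """Everything the feature blocks need from one document."""

    doc_id: str
    n_tokens: int
    raw_tokens: list[str]
    mentions: list[Mention]
    uni_terms: list[str]
    bi_terms: list[str]
    typed_paths: list[TypedPaths]
    pair_paths: list[PairPath]
    scores: list[TripletScore]
    polarities: list[PairPolarity]


def ngram_terms(tokdoc: TokenizedDocument) -> tuple[list[str], list[str]]:
    """Stemmed, stopword-filtered unigrams and within-sentence bigrams."""
    unis: list[str] = []
    bis: list[str] = []
    for sent in tokdoc.sentences:
        kept = [stem_token(t) for t in sent.tokens
                if any(c.isalnum() for c in t) and t.lower() not in STOPWORDS]
        unis.extend(kept)
        bis.extend(f"{a}/{b}" for a, b in zip(kept, kept[1:]))
    return unis, bis


# ---------------------------------------------------------------------------
# the transformer


class TriageFeaturizer(BaseEstimator, TransformerMixin):
    """Corpus -> sparse feature matrix, scikit-learn style.

    Parameters
    ----------
    protein_terms, interaction_terms, mutation_terms
        The three key-term dictionaries (iterables of terms).
    scorer
        Triplet-probability scorer; defaults to the packaged logistic
        path-length scorer.
    parser
        Fallback dependency parser for masked sentences without a
        supplied parse; defaults to the deterministic pseudo-parser.
    parses
        Optional mapping ``(doc_id, sentence_index) -> DependencyGraph``
        of externally produced parses (e.g. read from CoNLL-U).
    k_uni, k_bi
        Retained unigram / bigram vocabulary sizes (clamped to the
        available vocabulary).
    embeddings
        Optional :class:`EmbeddingTable` or path to a word2vec text
        file; adds the two embedding-average blocks.
    sentence_model
        Optional pre-trained sentence boundary model; trained on the
        fit corpus when omitted.
    candidate_cap
        Per-sentence cap on enumerated triplets and pairs.
    ci_min_len
        Protein terms at least this long match case-insensitively.
    """

    def __init__(self, protein_terms: Iterable[str] = (),
                 interaction_terms: Iterable[str] = (),
                 mutation_terms: Iterable[str] = (),
                 scorer=None, parser=None, parses=None,
                 k_uni: int = 5000, k_bi: int = 5000,
                 embeddings=None, sentence_model=None,
                 candidate_cap: int = DEFAULT_CANDIDATE_CAP,
                 ci_min_len: int = 4):
        self.protein_terms = protein_terms
        self.interaction_terms = interaction_terms
        self.mutation_terms = mutation_terms
        self.scorer = scorer
        self.parser = parser
        self.parses = parses
        self.k_uni = k_uni
        self.k_bi = k_bi
        self.embeddings = embeddings
        self.sentence_model = sentence_model
        self.candidate_cap = candidate_cap
        self.ci_min_len = ci_min_len

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None) -> "TriageFeaturizer":
        docs = self._as_documents(X)
        if not docs:
            raise ValueError("cannot fit on an empty corpus")
        self._prepare(docs)
        analyses = [self._analyze(d) for d in docs]
        self._fit_vocabularies(docs, analyses)
        return self

    def fit_transform(self, X, y=None):
        docs = self._as_documents(X)
        if not docs:
            raise ValueError("cannot fit on an empty corpus")
        self._prepare(docs)
        analyses = [self._analyze(d) for d in docs]
        self._fit_vocabularies(docs, analyses)
        return self._matrix(analyses)

    def transform(self, X):
        if not hasattr(self, "uni_vec_"):
            raise ValueError("TriageFeaturizer is not fitted")
        docs = self._as_documents(X)
        return self._matrix([self._analyze(d) for d in docs])

    # -- internals --------------------------------------------------------

    @staticmethod
    def _as_documents(X) -> list[Document]:
        if isinstance(X, Corpus):
            return list(X)
        docs = list(X)
        for d in docs:
            if not isinstance(d, Document):
                raise TypeError(f"expected Document instances, got {type(d)!r}")
        return docs

    def _prepare(self, docs: list[Document]) -> None:
        if self.sentence_model is not None:
            self.sentence_model_ = self.sentence_model
        else:
            self.sentence_model_ = train_sentence_model(Corpus(docs))
        self.matchers_ = {}
        for kind, terms in (("protein", self.protein_terms),
                            ("interaction", self.interaction_terms),
                            ("mutation", self.mutation_terms)):
            terms = frozenset(terms)
            if terms:
                self.matchers_[kind] = MatcherIndex(
                    TermDictionary(kind=kind, terms=terms),
                    ci_min_len=self.ci_min_len)
        self.scorer_ = self.scorer or LogisticPathScorer()
        self.parser_ = self.parser or PseudoParser()
        if isinstance(self.embeddings, (str,)) or hasattr(self.embeddings, "__fspath__"):
            self.embeddings_ = EmbeddingTable.from_word2vec_text(self.embeddings)
        else:
            self.embeddings_ = self.embeddings  # EmbeddingTable or None

    def _analyze(self, doc: Document) -> DocAnalysis:
        tokdoc = split_sentences(doc, self.sentence_model_)
        mentions = find_mentions(tokdoc, self.matchers_)
        tokdoc, mentions = simplify_appositives(tokdoc, mentions)
        triplets, pairs = extract_candidates(tokdoc, mentions,
                                             cap=self.candidate_cap)
        sent_by_index = {s.index: s for s in tokdoc.sentences}
        typed_paths: list[TypedPaths] = []
        pair_paths: list[PairPath] = []
        indices = sorted({t.sentence_index for t in triplets}
                         | {p.sentence_index for p in pairs})
        parses = self.parses or {}
        for idx in indices:
            sent = sent_by_index[idx]
            masked = mask_proteins(sent, mentions)
            graph = parses.get((doc.doc_id, idx))
            if graph is None:
                graph = self.parser_.parse(masked.tokens,
                                           sentence_ref=(doc.doc_id, idx))
            t_here = [t for t in triplets if t.sentence_index == idx]
            p_here = [p for p in pairs if p.sentence_index == idx]
            tp, pp = paths_for_candidates(graph, masked, t_here, p_here)
            typed_paths.extend(tp)
            pair_paths.extend(pp)
        scores = score_triplets(typed_paths, self.scorer_)
        polarities = label_pairs([pp.pair for pp in pair_paths], scores)
        raw_tokens = [t for s in tokdoc.sentences for t in s.tokens]
        unis, bis = ngram_terms(tokdoc)
        return DocAnalysis(doc_id=doc.doc_id, n_tokens=len(raw_tokens),
                           raw_tokens=raw_tokens, mentions=mentions,
                           uni_terms=unis, bi_terms=bis,
                           typed_paths=typed_paths, pair_paths=pair_paths,
                           scores=scores, polarities=polarities)

    def _fit_vocabularies(self, docs: list[Document],
                          analyses: list[DocAnalysis]) -> None:
        self.n_docs_ = len(docs)
        self.uni_vec_ = PrintedTfidf(max_terms=self.k_uni).fit(
            [a.uni_terms for a in analyses])
        self.bi_vec_ = PrintedTfidf(max_terms=self.k_bi).fit(
            [a.bi_terms for a in analyses])

        path_unis, path_bis, rel_unis, rel_bis = [], [], [], []
        aug_unis, aug_bis, aug_rel_unis, aug_rel_bis = [], [], [], []
        for a in analyses:
            u, b = path_token_ngrams(a.pair_paths)
            path_unis.append(u)
            path_bis.append(b)
            ru, rb = path_relation_ngrams(a.pair_paths)
            rel_unis.append(ru)
            rel_bis.append(rb)
            suffixes = self._suffixes(a)
            au, ab = path_token_ngrams(a.pair_paths, suffixes)
            aug_unis.append(au)
            aug_bis.append(ab)
            aru, arb = path_relation_ngrams(a.pair_paths, suffixes)
            aug_rel_unis.append(aru)
            aug_rel_bis.append(arb)
        self.path_uni_vec_ = PrintedTfidf().fit(path_unis)
        self.path_bi_vec_ = PrintedTfidf().fit(path_bis)
        self.rel_uni_vec_ = CountVocab().fit(rel_unis)
        self.rel_bi_vec_ = CountVocab().fit(rel_bis)
        self.aug_uni_vec_ = PrintedTfidf().fit(aug_unis)
        self.aug_bi_vec_ = PrintedTfidf().fit(aug_bis)
        self.aug_rel_uni_vec_ = CountVocab().fit(aug_rel_unis)
        self.aug_rel_bi_vec_ = CountVocab().fit(aug_rel_bis)

        # document frequencies for embedding weights (raw lowercase tokens)
        emb_df: dict[str, int] = {}
        for a in analyses:
            for t in {t.lower() for t in a.raw_tokens if t.lower() not in STOPWORDS}:
                emb_df[t] = emb_df.get(t, 0) + 1
        self.emb_df_ = emb_df

        # single-token key-term sets for path key-term frequencies
        self.iw_tokens_ = {t.lower() for t in self.interaction_terms}
        self.mu_tokens_ = {t.lower() for t in self.mutation_terms}

        self._build_layout()

    def _suffixes(self, a: DocAnalysis) -> list[str]:
        return [POSITIVE_SUFFIX if p.polarity == "positive" else NEGATIVE_SUFFIX
                for p in a.polarities]

    def _build_layout(self) -> None:
        names: list[str] = []
        slices: dict[str, tuple[int, int]] = {}

        def block(name: str, labels: list[str]) -> None:
            start = len(names)
            names.extend(f"{name}:{lab}" for lab in labels)
            slices[name] = (start, len(names))

        block("tfidf_uni", self.uni_vec_.feature_names_)
        block("tfidf_bi", self.bi_vec_.feature_names_)
        block("keyterm_freqs", ["protein", "interaction", "mutation"])
        block("triplet_path_bins",
              [f"type{t}:{lab}" for t in (1, 2, 3) for lab in PATH_BIN_LABELS])
        block("protmut_path_bins", PATH_BIN_LABELS)
        block("triplet_prob_bins",
              ["[0,0.3)", "[0.3,0.5)", "[0.5,0.7)", "[0.7,1.0]"])
        block("path_uni", self.path_uni_vec_.feature_names_)
        block("path_bi", self.path_bi_vec_.feature_names_)
        block("deprel_uni", self.rel_uni_vec_.feature_names_)
        block("deprel_bi", self.rel_bi_vec_.feature_names_)
        block("path_keyterm_freqs", ["protein", "interaction", "mutation"])
        block("aug_path_uni", self.aug_uni_vec_.feature_names_)
        block("aug_path_bi", self.aug_bi_vec_.feature_names_)
        block("aug_deprel_uni", self.aug_rel_uni_vec_.feature_names_)
        block("aug_deprel_bi", self.aug_rel_bi_vec_.feature_names_)
        block("pair_polarity_bins",
              [f"pos:{lab}" for lab in PATH_BIN_LABELS]
              + [f"neg:{lab}" for lab in PATH_BIN_LABELS])
        if self.embeddings_ is not None:
            d = self.embeddings_.dim
            block("emb_doc", [str(i) for i in range(d)])
            block("emb_path", [str(i) for i in range(d)])
        self.feature_names_ = names
        self.block_slices_ = slices
        self.n_features_ = len(names)

    # -- transform --------------------------------------------------------

    def _row(self, a: DocAnalysis) -> dict[int, float]:
        row: dict[int, float] = {}
        sl = self.block_slices_

        def put(name: str, values: dict[int, float] | Sequence[float]) -> None:
            start = sl[name][0]
            if isinstance(values, dict):
                for i, v in values.items():
                    if v:
                        row[start + i] = v
            else:
                for i, v in enumerate(values):
                    if v:
                        row[start + i] = float(v)

        put("tfidf_uni", self.uni_vec_.transform_one(a.uni_terms))
        put("tfidf_bi", self.bi_vec_.transform_one(a.bi_terms))
        if a.n_tokens > 0:
            put("keyterm_freqs", keyterm_frequencies(a.mentions, a.n_tokens))
        put("triplet_path_bins", triplet_path_length_bins(a.typed_paths))
        put("protmut_path_bins", pair_path_length_bins(a.pair_paths))
        put("triplet_prob_bins", bin_probabilities(a.scores))
        u, b = path_token_ngrams(a.pair_paths)
        put("path_uni", self.path_uni_vec_.transform_one(u))
        put("path_bi", self.path_bi_vec_.transform_one(b))
        ru, rb = path_relation_ngrams(a.pair_paths)
        put("deprel_uni", self.rel_uni_vec_.transform_one(ru))
        put("deprel_bi", self.rel_bi_vec_.transform_one(rb))
        put("path_keyterm_freqs",
            path_keyterm_frequencies(a.pair_paths, self.iw_tokens_,
                                     self.mu_tokens_))
        suffixes = self._suffixes(a)
        au, ab = path_token_ngrams(a.pair_paths, suffixes)
        put("aug_path_uni", self.aug_uni_vec_.transform_one(au))
        put("aug_path_bi", self.aug_bi_vec_.transform_one(ab))
        aru, arb = path_relation_ngrams(a.pair_paths, suffixes)
        put("aug_deprel_uni", self.aug_rel_uni_vec_.transform_one(aru))
        put("aug_deprel_bi", self.aug_rel_bi_vec_.transform_one(arb))
        put("pair_polarity_bins", pair_polarity_bins(a.pair_paths, a.polarities))
        if self.embeddings_ is not None:
            put("emb_doc", self._emb_doc(a))
            put("emb_path", self._emb_path(a))
        for i, v in row.items():
            if not np.isfinite(v):
                raise ValueError(
                    f"non-finite feature value in {self._block_of(i)!r} "
                    f"for document {a.doc_id!r}")
        return row

    def _block_of(self, col: int) -> str:
        for name, (start, stop) in self.block_slices_.items():
            if start <= col < stop:
                return name
        return "?"

    def _emb_doc(self, a: DocAnalysis) -> np.ndarray:
        table = self.embeddings_
        acc = np.zeros(table.dim)
        wsum = 0.0
        tf: dict[str, int] = {}
        for t in a.raw_tokens:
            low = t.lower()
            if low not in STOPWORDS:
                tf[low] = tf.get(low, 0) + 1
        for low, count in tf.items():
            vec = table.get(low)
            if vec is None:
                continue
            idf = math.log(self.n_docs_ / max(self.emb_df_.get(low, 1), 1))
            w = count * idf
            if w <= 0:
                continue
            acc += w * vec
            wsum += w
        return acc / wsum if wsum > 0 else acc

    def _emb_path(self, a: DocAnalysis) -> np.ndarray:
        table = self.embeddings_
        acc = np.zeros(table.dim)
        n = 0
        for pp in a.pair_paths:
            if pp.path is None:
                continue
            for tok in pp.path.interior_tokens:
                vec = table.get(tok)
                if vec is not None:
                    acc += vec
                    n += 1
        return acc / n if n else acc

    def _matrix(self, analyses: list[DocAnalysis]) -> sp.csr_matrix:
        indptr = [0]
        indices: list[int] = []
        data: list[float] = []
        for a in analyses:
            row = self._row(a)
            for i in sorted(row):
                indices.append(i)
                data.append(row[i])
            indptr.append(len(indices))
        return sp.csr_matrix((data, indices, indptr),
                             shape=(len(analyses), self.n_features_))
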