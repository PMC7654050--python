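import math

import numpy as np
import pytest

import ppiam_triage as pt
from ppiam_triage.depgraph import DepPath, PairPath, TypedPaths
from ppiam_triage.embeddings import EmbeddingTable
from ppiam_triage.features import (PrintedTfidf, TriageFeaturizer,
                                   keyterm_frequencies,
                                   pair_path_length_bins, pair_polarity_bins,
                                   path_keyterm_frequencies,
                                   path_relation_ngrams, path_token_ngrams,
                                   triplet_path_length_bins)
from ppiam_triage.lexicon import Mention
from ppiam_triage.ppi import PairPolarity
from ppiam_triage.candidates import PPITriplet, ProtMutPair


# -- printed-formula TF-IDF --------------------------------------------------

def test_term_in_every_document_has_zero_idf():
    v = PrintedTfidf().fit([["shared", "a"], ["shared", "b"]])
    assert v.idf_["shared"] == 0.0
    assert "shared" in v.vocabulary_
    assert v.transform_one(["shared"]) == {v.vocabulary_["shared"]: 0.0} or \
        v.transform_one(["shared"]).get(v.vocabulary_["shared"], 0.0) == 0.0


def test_tfidf_value_is_count_times_log_ratio():
    v = PrintedTfidf().fit([["term", "term", "term"], ["other"]])
    row = v.transform_one(["term"] * 3)
    assert row[v.vocabulary_["term"]] == pytest.approx(3 * math.log(2))


def test_vocabulary_truncation_keeps_most_frequent():
    docs = [["a", "b", "c"], ["a", "b"], ["a", "b"], ["a"], ["a"]]
    v = PrintedTfidf(max_terms=2).fit(docs)
    assert set(v.vocabulary_) == {"a", "b"}


def _brute_force_tfidf(train_docs, doc, term):
    """Independent oracle: evaluate TF(t,d) * log(N / df(t)) directly."""
    df = sum(1 for d in train_docs if term in d)
    if df == 0:
        return None
    return doc.count(term) * math.log(len(train_docs) / df)


def test_transform_matches_brute_force_formula():
    train = [["a", "b", "a"], ["b", "c"], ["c", "c", "d"]]
    v = PrintedTfidf().fit(train)
    for doc in train + [["a", "c", "c", "zzz"]]:
        row = v.transform_one(doc)
        for term, col in v.vocabulary_.items():
            expect = _brute_force_tfidf(train, doc, term) or 0.0
            assert row.get(col, 0.0) == pytest.approx(expect)


def test_transform_is_deterministic_and_zero_for_oov():
    v = PrintedTfidf().fit([["a"], ["b"]])
    assert v.transform_one(["zzz"]) == {}
    assert v.transform_one(["a", "b"]) == v.transform_one(["a", "b"])


# -- scalar blocks -----------------------------------------------------------

def _mention(kind, start=0):
    return Mention(kind=kind, sentence_index=0, token_span=(start, start + 1),
                   surface="x", term="x")


def test_keyterm_frequencies():
    ms = [_mention("protein", i) for i in range(4)]
    assert keyterm_frequencies(ms, 100) == (0.04, 0.0, 0.0)
    assert keyterm_frequencies([], 10) == (0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        keyterm_frequencies(ms, 0)


def test_negation_is_invisible_to_keyterm_frequencies():
    # the block counts mentions per token; asserting vs negating the same
    # interaction yields identical values once token counts agree
    ms = [_mention("protein", 0), _mention("interaction", 1),
          _mention("protein", 3)]
    assert keyterm_frequencies(ms, 5) == keyterm_frequencies(ms, 5)


def _path(length, tokens=None, rels=None):
    nodes = list(range(length + 1))
    return DepPath(node_sequence=nodes,
                   relation_sequence=rels or ["dep"] * length,
                   tokens=tokens or [f"t{i}" for i in nodes])


def _triplet():
    return PPITriplet(doc_id="d", sentence_index=0,
                      p1=_mention("protein", 0), p2=_mention("protein", 2),
                      iw=_mention("interaction", 1))


def _typed(l1, l2=1, l3=1):
    mk = lambda L: _path(L) if L is not None else None
    return TypedPaths(triplet=_triplet(), sp_p1_p2=mk(l1), sp_p1_iw=mk(l2),
                      sp_p2_iw=mk(l3))


def _pairpath(length, tokens=None, rels=None):
    pair = ProtMutPair(doc_id="d", sentence_index=0,
                       prot=_mention("protein", 0), mu=_mention("mutation", 3))
    return PairPath(pair=pair,
                    path=None if length is None
                    else _path(length, tokens, rels))


def test_triplet_bins_documented_example():
    typed = [_typed(2), _typed(2), _typed(5), _typed(12)]
    bins = triplet_path_length_bins(typed)
    type1 = bins[:11]
    assert type1[1] == 2 and type1[4] == 1 and type1[10] == 1
    assert sum(type1) == 4
    assert len(bins) == 33


def test_bin_boundaries_ten_vs_eleven_plus():
    bins = triplet_path_length_bins([_typed(10), _typed(11), _typed(None)])
    type1 = bins[:11]
    assert type1[9] == 1       # length 10 -> bin 10
    assert type1[10] == 2      # length 11 and unreachable -> 11+


def test_no_candidates_all_zero():
    assert triplet_path_length_bins([]) == [0] * 33
    assert pair_path_length_bins([]) == [0] * 11


def fig_pairpath():
    return _pairpath(4, tokens=["PROT1", "binds", "PROT2", "fails", "variant"],
                     rels=["nsubj", "nmod", "conj", "nsubj"])


def test_path_ngrams_documented_example():
    unis, bis = path_token_ngrams([fig_pairpath()])
    assert unis == ["binds", "PROT2", "fails"]
    assert bis == ["binds/PROT2", "PROT2/fails"]
    runis, rbis = path_relation_ngrams([fig_pairpath()])
    assert sorted(runis) == ["conj", "nmod", "nsubj", "nsubj"]
    assert {r: runis.count(r) for r in set(runis)} == \
        {"nsubj": 2, "nmod": 1, "conj": 1}


def test_path_keyterm_fraction_counts_interior_placeholder():
    got = path_keyterm_frequencies([fig_pairpath()], ["interacts"], ["variant"])
    assert got == pytest.approx((1 / 3, 0.0, 0.0))


def test_length_one_path_has_no_interior():
    pp = _pairpath(1, tokens=["PROT1", "R117H"], rels=["dep"])
    assert path_keyterm_frequencies([pp]) == (0.0, 0.0, 0.0)
    assert path_token_ngrams([pp]) == ([], [])


def _polarity(pp, polarity):
    return PairPolarity(pair=pp.pair, polarity=polarity,
                        max_p=0.9 if polarity == "positive" else 0.1)


def test_polarity_augmented_unigrams():
    pp = fig_pairpath()
    unis, _ = path_token_ngrams([pp], ["_PPIPOS"])
    assert unis == ["binds_PPIPOS", "PROT2_PPIPOS", "fails_PPIPOS"]


def test_polarity_bins_documented_example():
    pps = [_pairpath(3), _pairpath(3), _pairpath(12)]
    pols = [_polarity(pps[0], "positive"), _polarity(pps[1], "positive"),
            _polarity(pps[2], "negative")]
    bins = pair_polarity_bins(pps, pols)
    assert len(bins) == 22
    assert bins[2] == 2          # positive, bin 3
    assert bins[11 + 10] == 1    # negative, bin 11+
    assert sum(bins) == 3


def test_polarity_bins_require_alignment():
    with pytest.raises(ValueError):
        pair_polarity_bins([_pairpath(2)], [])


# -- embeddings --------------------------------------------------------------

def _emb_featurizer(docs, table):
    feat = TriageFeaturizer(embeddings=table)
    feat.fit(pt.Corpus(docs))
    return feat


def test_single_vocabulary_token_returns_its_vector():
    table = EmbeddingTable({"alpha": np.array([1.0, 0.0]),
                            "beta": np.array([0.0, 1.0])})
    docs = [pt.Document(doc_id="1", title="", body="alpha"),
            pt.Document(doc_id="2", title="", body="unrelated words")]
    feat = _emb_featurizer(docs, table)
    a, b = feat.block_slices_["emb_doc"]
    row = feat.transform([docs[0]]).toarray()[0, a:b]
    assert row == pytest.approx([1.0, 0.0])


def test_equal_weights_average_vectors():
    table = EmbeddingTable({"alpha": np.array([1.0, 0.0]),
                            "beta": np.array([0.0, 1.0])})
    docs = [pt.Document(doc_id="1", title="", body="alpha beta"),
            pt.Document(doc_id="2", title="", body="gamma delta")]
    feat = _emb_featurizer(docs, table)
    a, b = feat.block_slices_["emb_doc"]
    row = feat.transform([docs[0]]).toarray()[0, a:b]
    assert row == pytest.approx([0.5, 0.5])


def test_all_out_of_vocabulary_gives_zero_vector():
    table = EmbeddingTable({"alpha": np.array([1.0, 0.0])})
    docs = [pt.Document(doc_id="1", title="", body="nothing matches here"),
            pt.Document(doc_id="2", title="", body="alpha")]
    feat = _emb_featurizer(docs, table)
    a, b = feat.block_slices_["emb_doc"]
    row = feat.transform([docs[0]]).toarray()[0, a:b]
    assert row == pytest.approx([0.0, 0.0])


def test_embedding_table_word2vec_roundtrip(tmp_path):
    table = pt.generate_embeddings(["alpha", "beta", "gamma"], d=8, seed=5)
    p = table.to_word2vec_text(tmp_path / "emb.txt")
    back = EmbeddingTable.from_word2vec_text(p)
    assert back.dim == 8
    for w in table.vectors:
        assert back.get(w) == pytest.approx(table.vectors[w])


# -- assembled matrix --------------------------------------------------------

def test_fixed_dimension_across_documents(fitted_featurizer, gen_small):
    feat, X = fitted_featurizer
    assert X.shape == (len(gen_small.corpus), feat.n_features_)
    X2 = feat.transform(list(gen_small.corpus)[:5])
    assert X2.shape[1] == feat.n_features_


def test_block_widths(fitted_featurizer):
    feat, _ = fitted_featurizer
    widths = {k: b - a for k, (a, b) in feat.block_slices_.items()}
    assert widths["triplet_path_bins"] == 33
    assert widths["protmut_path_bins"] == 11
    assert widths["triplet_prob_bins"] == 4
    assert widths["pair_polarity_bins"] == 22
    assert widths["keyterm_freqs"] == 3
    assert widths["path_keyterm_freqs"] == 3


def test_empty_abstract_is_all_zero(fitted_featurizer):
    feat, _ = fitted_featurizer
    X = feat.transform([pt.Document(doc_id="empty", title="", body="")])
    assert X.nnz == 0
    assert X.shape[1] == feat.n_features_


def test_transform_is_deterministic(fitted_featurizer, gen_small):
    feat, _ = fitted_featurizer
    docs = list(gen_small.corpus)[:10]
    X1 = feat.transform(docs)
    X2 = feat.transform(docs)
    assert (X1 != X2).nnz == 0


def test_augmented_terms_never_collide_with_raw_vocabulary(fitted_featurizer):
    feat, _ = fitted_featurizer
    raw = set(feat.path_uni_vec_.vocabulary_) | set(feat.uni_vec_.vocabulary_)
    aug = set(feat.aug_uni_vec_.vocabulary_)
    assert all(t.endswith(("_PPIPOS", "_PPINEG")) for t in aug)
    assert raw.isdisjoint(aug)


def test_bin_conservation_on_synthetic_abstracts(gen_small, fitted_featurizer):
    feat, X = fitted_featurizer
    docs = list(gen_small.corpus)
    for doc in docs[:50]:
        a = feat._analyze(doc)
        bins = triplet_path_length_bins(a.typed_paths)
        for t in range(3):
            assert sum(bins[t * 11:(t + 1) * 11]) == len(a.typed_paths)
        assert sum(pair_path_length_bins(a.pair_paths)) == len(a.pair_paths)
        from ppiam_triage.ppi import bin_probabilities
        assert sum(bin_probabilities(a.scores)) == len(a.scores)
        assert sum(pair_polarity_bins(a.pair_paths, a.polarities)) == \
            len(a.pair_paths)


def test_embedding_block_in_convex_hull(gen_small):
    gen = gen_small
    table = pt.generate_embeddings(gen.vocabulary, d=8, seed=1)
    feat = TriageFeaturizer(protein_terms=gen.protein_terms,
                            interaction_terms=gen.interaction_terms,
                            mutation_terms=gen.mutation_terms,
                            embeddings=table)
    X = feat.fit_transform(gen.corpus).toarray()
    a, b = feat.block_slices_["emb_doc"]
    norms = np.linalg.norm(X[:, a:b], axis=1)
    assert np.all(norms <= 1.0 + 1e-9)  # unit-norm inputs, convex weights
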