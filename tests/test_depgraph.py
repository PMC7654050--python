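import numpy as np
import pytest

import ppiam_triage as pt
from ppiam_triage.depgraph import (DependencyGraph, PseudoParser,
                                   mask_proteins, paths_for_candidates,
                                   read_conllu, shortest_path, write_conllu)
from ppiam_triage.lexicon import Mention
from ppiam_triage.preprocess import Sentence

# The documented example sentence, masked: the protein -> mutation path
# PROT1 -> variant must have interior [binds, PROT2, fails] and relations
# [nsubj, nmod, conj, nsubj].
FIG_TOKENS = ["PROT1", "binds", "PROT2", ",", "but", "the", "R117H",
              "variant", "fails", "."]
FIG_EDGES = [(1, 0, "nsubj"), (-1, 1, "root"), (1, 2, "nmod"),
             (2, 3, "punct"), (3, 4, "cc"), (4, 5, "det"), (5, 6, "dep"),
             (8, 7, "nsubj"), (2, 8, "conj"), (8, 9, "punct")]


def fig_graph():
    return DependencyGraph(tokens=list(FIG_TOKENS), edges=list(FIG_EDGES),
                           sentence_ref=("fig", 0))


# -- masking -----------------------------------------------------------------

def _sentence(tokens):
    return Sentence(index=0, tokens=list(tokens), char_span=(0, 1))


def _prot(span, term=None, surface=None):
    surface = surface or " ".join(f"t{i}" for i in range(*span))
    return Mention(kind="protein", sentence_index=0, token_span=span,
                   surface=surface, term=term or surface)


def test_multiword_mention_collapses_to_one_placeholder():
    s = _sentence(["Tubulin", "folding", "cofactor", "A", "binds", "actin"])
    ms = [_prot((0, 4), term="Tubulin folding cofactor A"),
          _prot((5, 6), term="actin")]
    masked = mask_proteins(s, ms)
    assert masked.tokens == ["PROT1", "binds", "PROT2"]
    assert masked.mask_map["PROT1"].term == "Tubulin folding cofactor A"


def test_no_protein_mentions_identity():
    s = _sentence(["nothing", "here"])
    masked = mask_proteins(s, [])
    assert masked.tokens == ["nothing", "here"]
    assert masked.mask_map == {}


def test_repeated_term_shares_placeholder():
    s = _sentence(["GeneAp", "binds", "GeneAp"])
    ms = [_prot((0, 1), term="GeneAp"), _prot((2, 3), term="GeneAp")]
    masked = mask_proteins(s, ms)
    assert masked.tokens == ["PROT1", "binds", "PROT1"]


def test_overlapping_mentions_rejected():
    s = _sentence(["a", "b", "c"])
    ms = [_prot((0, 2)), _prot((1, 3))]
    with pytest.raises(ValueError):
        mask_proteins(s, ms)


# -- CoNLL-U -----------------------------------------------------------------

def _conllu_row(i, form, head, rel):
    return "\t".join([str(i), form, "_", "_", "_", "_", str(head), rel,
                      "_", "_"])


def test_read_conllu_structure(tmp_path):
    p = tmp_path / "x.conllu"
    p.write_text("# sent_id = doc1:0\n"
                 + _conllu_row(1, "It", 2, "nsubj") + "\n"
                 + _conllu_row(2, "binds", 0, "root") + "\n"
                 + _conllu_row(3, "X", 2, "obj") + "\n"
                 + _conllu_row(4, ".", 2, "punct") + "\n\n")
    graphs = read_conllu(p)
    assert len(graphs) == 1
    g = graphs[0]
    assert len(g.tokens) == 4
    assert sum(1 for h, _, _ in g.edges if h >= 0) == 3
    assert g.sentence_ref == ("doc1", 0)


def test_read_conllu_empty_file(tmp_path):
    p = tmp_path / "empty.conllu"
    p.write_text("")
    assert read_conllu(p) == []


def test_read_conllu_malformed_names_sentence(tmp_path):
    p = tmp_path / "bad.conllu"
    p.write_text(_conllu_row(1, "ok", 0, "root") + "\n\nonly three cols\n")
    with pytest.raises(ValueError, match="sentence 2"):
        read_conllu(p)


def test_conllu_roundtrip(tmp_path):
    p = write_conllu([fig_graph()], tmp_path / "fig.conllu")
    back = read_conllu(p)[0]
    assert back.tokens == FIG_TOKENS
    assert sorted(back.edges) == sorted(FIG_EDGES)
    assert back.sentence_ref == ("fig", 0)


def test_fig_fixture_contains_documented_edges():
    g = fig_graph()
    undirected = {(min(h, d), max(h, d), rel) for h, d, rel in g.edges if h >= 0}
    # binds-PROT1 nsubj, binds-PROT2 nmod, PROT2-fails conj, fails-variant nsubj
    assert (0, 1, "nsubj") in undirected
    assert (1, 2, "nmod") in undirected
    assert (2, 8, "conj") in undirected
    assert (7, 8, "nsubj") in undirected


# -- shortest paths ----------------------------------------------------------

def test_fig_path_interior_and_length():
    path = shortest_path(fig_graph(), 0, 7)  # PROT1 -> variant
    assert path.length == 4
    assert path.interior_tokens == ["binds", "PROT2", "fails"]
    assert path.relation_sequence == ["nsubj", "nmod", "conj", "nsubj"]


def test_adjacent_nodes_length_one():
    path = shortest_path(fig_graph(), 0, 1)
    assert path.length == 1
    assert path.interior_tokens == []


def test_invalid_ordinals_rejected():
    g = fig_graph()
    with pytest.raises(ValueError):
        shortest_path(g, 0, 99)
    with pytest.raises(ValueError):
        shortest_path(g, 3, 3)


def test_disconnected_returns_none():
    g = DependencyGraph(tokens=["a", "b", "c"], edges=[(0, 1, "dep")])
    assert shortest_path(g, 0, 2) is None


def _enumerate_simple_paths(adj, source, target):
    """Independent oracle: exhaustive DFS over all simple paths."""
    best = None
    stack = [(source, [source])]
    while stack:
        node, path = stack.pop()
        if node == target:
            if best is None or len(path) - 1 < best:
                best = len(path) - 1
            continue
        for nbr in adj[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr]))
    return best


def _random_graph(rng, n):
    edges = []
    deps = set()
    for _ in range(rng.integers(0, 2 * n)):
        h, d = int(rng.integers(0, n)), int(rng.integers(0, n))
        if h != d and d not in deps:
            deps.add(d)
            edges.append((h, d, "dep"))
    return DependencyGraph(tokens=[f"t{i}" for i in range(n)], edges=edges)


def test_shortest_path_matches_exhaustive_enumeration():
    rng = np.random.default_rng(20240915)
    for _ in range(250):
        n = int(rng.integers(2, 11))
        g = _random_graph(rng, n)
        adj = {i: sorted(v for v, _ in nbrs)
               for i, nbrs in g.adjacency().items()}
        a, b = rng.choice(n, size=2, replace=False)
        got = shortest_path(g, int(a), int(b))
        expect = _enumerate_simple_paths(adj, int(a), int(b))
        assert (got.length if got else None) == expect
        # symmetry of the undirected path length
        rev = shortest_path(g, int(b), int(a))
        assert (rev.length if rev else None) == expect
        if got is not None:
            assert len(got.relation_sequence) == len(got.node_sequence) - 1


# -- typed candidate paths ---------------------------------------------------

def _fig_candidates():
    p1 = Mention(kind="protein", sentence_index=0, token_span=(0, 1),
                 surface="GeneAp", term="GeneAp")
    p2 = Mention(kind="protein", sentence_index=0, token_span=(2, 3),
                 surface="GeneBp", term="GeneBp")
    iw = Mention(kind="interaction", sentence_index=0, token_span=(1, 2),
                 surface="binds", term="binds")
    mu = Mention(kind="mutation", sentence_index=0, token_span=(7, 8),
                 surface="variant", term="variant")
    triplet = pt.PPITriplet(doc_id="fig", sentence_index=0, p1=p1, p2=p2, iw=iw)
    pair = pt.ProtMutPair(doc_id="fig", sentence_index=0, prot=p1, mu=mu)
    sent = _sentence(["GeneAp", "binds", "GeneBp", ",", "but", "the",
                      "R117H", "variant", "fails", "."])
    masked = mask_proteins(sent, [p1, p2])
    return masked, [triplet], [pair]


def test_each_triplet_yields_three_typed_paths():
    masked, triplets, pairs = _fig_candidates()
    tp, pp = paths_for_candidates(fig_graph(), masked, triplets, pairs)
    assert len(tp) == 1
    assert all(p is not None for p in tp[0].as_tuple())
    assert [p.length for p in tp[0].as_tuple()] == [2, 1, 1]


def test_pair_path_relation_sequence_matches_documented_example():
    masked, triplets, pairs = _fig_candidates()
    _, pp = paths_for_candidates(fig_graph(), masked, triplets, pairs)
    assert pp[0].path.relation_sequence == ["nsubj", "nmod", "conj", "nsubj"]


def test_disconnected_pair_recorded_with_sentinel():
    masked, triplets, pairs = _fig_candidates()
    g = DependencyGraph(tokens=list(FIG_TOKENS),
                        edges=[(1, 0, "nsubj")])  # variant unreachable
    _, pp = paths_for_candidates(g, masked, [], pairs)
    assert len(pp) == 1
    assert pp[0].path is None


def test_token_count_mismatch_skips_with_warning():
    masked, triplets, pairs = _fig_candidates()
    g = DependencyGraph(tokens=["only", "two"], edges=[(0, 1, "dep")])
    with pytest.warns(UserWarning):
        tp, pp = paths_for_candidates(g, masked, triplets, pairs)
    assert tp == [] and pp == []


def test_shortest_path_lengths_match_networkx():
    """Cross-check the BFS against an independent graph library."""
    import networkx as nx
    rng = np.random.default_rng(55)
    for _ in range(60):
        n = int(rng.integers(2, 11))
        g = _random_graph(rng, n)
        G = nx.Graph()
        G.add_nodes_from(range(n))
        G.add_edges_from((h, d) for h, d, _ in g.edges)
        a, b = rng.choice(n, size=2, replace=False)
        got = shortest_path(g, int(a), int(b))
        try:
            expect = nx.shortest_path_length(G, int(a), int(b))
        except nx.NetworkXNoPath:
            expect = None
        assert (got.length if got else None) == expect


# -- pseudo-parser -----------------------------------------------------------

def test_pseudo_parser_reproduces_documented_subgraph():
    g = PseudoParser().parse(FIG_TOKENS)
    path = shortest_path(g, 0, 7)
    assert path.interior_tokens == ["binds", "PROT2", "fails"]
    assert path.relation_sequence == ["nsubj", "nmod", "conj", "nsubj"]


def test_pseudo_parser_single_token_sentence():
    g = PseudoParser().parse(["Hello"])
    assert len(g.tokens) == 1
    assert all(h < 0 for h, _, _ in g.edges)
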