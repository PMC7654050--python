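"""Dependency graphs, protein masking, and shortest paths.

Parses are consumed, not produced: any parser that emits CoNLL-U can
feed the pipeline. Protein mentions are collapsed to placeholder tokens
PROT1, PROT2, ... before parsing (multi-word names confuse parsers and
the placeholder is what path features should see). Shortest paths are
computed over the undirected view of the dependency graph with a
deterministic tie-break: breadth-first search visiting neighbors in
ascending token ordinal, first path found wins.

A deterministic pseudo-parser (right-branching chain with heuristic
labels, plus a fixed subgraph for the planted pattern sentences emitted
by the synthetic generator) ships for tests and fixtures.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .candidates import PPITriplet, ProtMutPair
from .lexicon import Mention
from .preprocess import Sentence

#: path length recorded for unreachable endpoint pairs (maps to the 11+ bin)
UNREACHABLE = None


@dataclass
class DependencyGraph:
    """Labeled dependency graph of one sentence.

    ``edges`` are (head, dependent, relation) with 0-based token
    ordinals; a head of -1 marks attachment to the virtual root, which
    is excluded from path search.
    """

    tokens: list[str]
    edges: list[tuple[int, int, str]]
    sentence_ref: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        heads_seen: set[int] = set()
        for h, d, rel in self.edges:
            if not (-1 <= h < n) or not (0 <= d < n):
                raise ValueError(f"edge ({h},{d},{rel}) out of range for {n} tokens")
            if not rel:
                raise ValueError("relation labels must be non-empty")
            if d in heads_seen:
                raise ValueError(f"token {d} has more than one head")
            heads_seen.add(d)
        self._adj: Optional[dict[int, list[tuple[int, str]]]] = None

    def adjacency(self) -> dict[int, list[tuple[int, str]]]:
        """Undirected adjacency, neighbors sorted by ascending ordinal.
        Root attachments are excluded."""
        if self._adj is None:
            adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(len(self.tokens))}
            for h, d, rel in self.edges:
                if h < 0:
                    continue
                adj[h].append((d, rel))
                adj[d].append((h, rel))
            for nbrs in adj.values():
                nbrs.sort(key=lambda x: x[0])
            self._adj = adj
        return self._adj


@dataclass
class DepPath:
    """A shortest path in a dependency graph, endpoints included."""

    node_sequence: list[int]
    relation_sequence: list[str]
    tokens: list[str]

    def __post_init__(self) -> None:
        if len(self.relation_sequence) != len(self.node_sequence) - 1:
            raise ValueError("relation count must be node count - 1")
        if len(self.tokens) != len(self.node_sequence):
            raise ValueError("token count must equal node count")

    @property
    def length(self) -> int:
        return len(self.node_sequence) - 1

    @property
    def interior_tokens(self) -> list[str]:
        return self.tokens[1:-1]


def shortest_path(graph: DependencyGraph, source: int, target: int,
                  ) -> Optional[DepPath]:
    """Undirected minimum-edge path from ``source`` to ``target``.

    Ties are broken deterministically by BFS with neighbors visited in
    ascending ordinal. Returns None when the endpoints are disconnected.
    """
    n = len(graph.tokens)
    for x in (source, target):
        if not (0 <= x < n):
            raise ValueError(f"ordinal {x} out of range for {n} tokens")
    if source == target:
        raise ValueError("source and target must differ")
    adj = graph.adjacency()
    parent: dict[int, tuple[int, str]] = {}
    seen = {source}
    queue: deque[int] = deque([source])
    while queue:
        u = queue.popleft()
        if u == target:
            break
        for v, rel in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = (u, rel)
                queue.append(v)
    if target not in seen:
        return None
    nodes = [target]
    rels: list[str] = []
    while nodes[-1] != source:
        u, rel = parent[nodes[-1]]
        rels.append(rel)
        nodes.append(u)
    nodes.reverse()
    rels.reverse()
    return DepPath(node_sequence=nodes, relation_sequence=rels,
                   tokens=[graph.tokens[i] for i in nodes])


# ---------------------------------------------------------------------------
# protein masking


@dataclass
class MaskedSentence:
    """Sentence with protein mentions collapsed to PROT1, PROT2, ...

    ``mask_map`` maps placeholder -> representative mention; repeated
    occurrences of the same dictionary term share one placeholder.
    ``index_map`` maps original token ordinal -> masked ordinal.
    """

    tokens: list[str]
    mask_map: dict[str, Mention]
    index_map: dict[int, int]
    placeholder_positions: dict[tuple[int, int], int]  # original span -> masked ordinal


def mask_proteins(sentence: Sentence, mentions: Sequence[Mention]) -> MaskedSentence:
    prots = sorted((m for m in mentions
                    if m.kind == "protein" and m.sentence_index == sentence.index),
                   key=lambda m: m.token_span)
    for a, b in zip(prots, prots[1:]):
        if b.start < a.end:
            raise ValueError("overlapping protein mentions cannot be masked")
    term_to_placeholder: dict[str, str] = {}
    mask_map: dict[str, Mention] = {}
    masked: list[str] = []
    index_map: dict[int, int] = {}
    placeholder_positions: dict[tuple[int, int], int] = {}
    spans = {m.token_span: m for m in prots}
    i = 0
    n = len(sentence.tokens)
    starts = {m.start: m for m in prots}
    while i < n:
        m = starts.get(i)
        if m is not None:
            key = m.term.lower()
            if key not in term_to_placeholder:
                ph = f"PROT{len(term_to_placeholder) + 1}"
                term_to_placeholder[key] = ph
                mask_map[ph] = m
            ph = term_to_placeholder[key]
            pos = len(masked)
            masked.append(ph)
            placeholder_positions[m.token_span] = pos
            for k in range(m.start, m.end):
                index_map[k] = pos
            i = m.end
        else:
            index_map[i] = len(masked)
            masked.append(sentence.tokens[i])
            i += 1
    return MaskedSentence(tokens=masked, mask_map=mask_map,
                          index_map=index_map,
                          placeholder_positions=placeholder_positions)


# ---------------------------------------------------------------------------
# CoNLL-U

def read_conllu(path: str | Path) -> list[DependencyGraph]:
    """Read dependency graphs from a CoNLL-U file.

    One graph per sentence block. ``# sent_id = <doc_id>:<index>``
    comments populate ``sentence_ref``. Multiword-token ranges and empty
    nodes are skipped; HEAD 0 becomes a virtual-root attachment.
    """
    graphs: list[DependencyGraph] = []
    tokens: list[str] = []
    rows: list[tuple[int, int, str]] = []
    sent_ref: tuple[str, int] = ("", 0)
    ordinal = 0

    def flush() -> None:
        nonlocal tokens, rows, sent_ref, ordinal
        if tokens:
            ordinal += 1
            try:
                graphs.append(DependencyGraph(tokens=tokens, edges=rows,
                                              sentence_ref=sent_ref))
            except ValueError as e:
                raise ValueError(f"sentence {ordinal}: {e}") from e
        tokens, rows, sent_ref = [], [], ("", 0)

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    if key.strip() == "sent_id":
                        ref = value.strip()
                        doc_id, _, idx = ref.rpartition(":")
                        try:
                            sent_ref = (doc_id, int(idx))
                        except ValueError:
                            sent_ref = (ref, 0)
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ValueError(
                    f"{path}:{lineno} (sentence {ordinal + 1}): expected 10 "
                    f"tab-separated columns, got {len(cols)}")
            tok_id, form, _lemma, _upos, _xpos, _feats, head, deprel = cols[:8]
            if "-" in tok_id or "." in tok_id:
                continue
            try:
                tid = int(tok_id)
                h = int(head)
            except ValueError as e:
                raise ValueError(
                    f"{path}:{lineno} (sentence {ordinal + 1}): bad ID/HEAD") from e
            if tid != len(tokens) + 1:
                raise ValueError(
                    f"{path}:{lineno} (sentence {ordinal + 1}): non-sequential token id")
            tokens.append(form)
            rows.append((h - 1, tid - 1, deprel))
    flush()
    return graphs


def write_conllu(graphs: Iterable[DependencyGraph], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for g in graphs:
            doc_id, idx = g.sentence_ref
            if doc_id:
                fh.write(f"# sent_id = {doc_id}:{idx}\n")
            head_of = {d: (h, rel) for h, d, rel in g.edges}
            for i, tok in enumerate(g.tokens):
                h, rel = head_of.get(i, (-1, "root"))
                fh.write("\t".join([str(i + 1), tok, "_", "_", "_", "_",
                                    str(h + 1), rel, "_", "_"]) + "\n")
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# typed candidate paths


@dataclass
class TypedPaths:
    """The three typed shortest paths of one triplet: sp(p1,p2),
    sp(p1,iw), sp(p2,iw). A None entry means the endpoints were
    disconnected in the parse."""

    triplet: PPITriplet
    sp_p1_p2: Optional[DepPath]
    sp_p1_iw: Optional[DepPath]
    sp_p2_iw: Optional[DepPath]

    def as_tuple(self) -> tuple[Optional[DepPath], ...]:
        return (self.sp_p1_p2, self.sp_p1_iw, self.sp_p2_iw)


@dataclass
class PairPath:
    """The protein -> mutation shortest path of one pair."""

    pair: ProtMutPair
    path: Optional[DepPath]


def _endpoint(masked: MaskedSentence, mention: Mention) -> Optional[int]:
    if mention.kind == "protein":
        return masked.placeholder_positions.get(mention.token_span)
    return masked.index_map.get(mention.start)


def paths_for_candidates(graph: DependencyGraph, masked: MaskedSentence,
                         triplets: Sequence[PPITriplet],
                         pairs: Sequence[ProtMutPair],
                         ) -> tuple[list[TypedPaths], list[PairPath]]:
    """Typed paths for every candidate of one (masked, parsed) sentence.

    Candidates whose endpoints cannot be located in the graph (token
    mismatch between the masked sentence and the parse) are skipped with
    a warning. Endpoints that coincide after masking (e.g. a pair whose
    mutation token sits inside the protein mention) are skipped too.
    """
    if len(graph.tokens) != len(masked.tokens):
        warnings.warn(
            f"parse for {graph.sentence_ref} has {len(graph.tokens)} tokens "
            f"but masked sentence has {len(masked.tokens)}; candidates skipped")
        return [], []
    t_out: list[TypedPaths] = []
    for t in triplets:
        e1, e2, ei = (_endpoint(masked, t.p1), _endpoint(masked, t.p2),
                      _endpoint(masked, t.iw))
        if e1 is None or e2 is None or ei is None:
            warnings.warn(f"triplet endpoint missing in graph {graph.sentence_ref}")
            continue
        def sp(a: int, b: int) -> Optional[DepPath]:
            if a == b:
                return None
            return shortest_path(graph, a, b)
        t_out.append(TypedPaths(triplet=t, sp_p1_p2=sp(e1, e2),
                                sp_p1_iw=sp(e1, ei), sp_p2_iw=sp(e2, ei)))
    p_out: list[PairPath] = []
    for p in pairs:
        ep, em = _endpoint(masked, p.prot), _endpoint(masked, p.mu)
        if ep is None or em is None:
            warnings.warn(f"pair endpoint missing in graph {graph.sentence_ref}")
            continue
        path = shortest_path(graph, ep, em) if ep != em else None
        p_out.append(PairPath(pair=p, path=path))
    return t_out, p_out


# ---------------------------------------------------------------------------
# deterministic pseudo-parser

_DET = {"the", "a", "an", "this", "that", "these", "those"}
_ADP = {"of", "in", "with", "by", "for", "to", "on", "at", "from"}
_CC = {"and", "or", "but", "nor"}


class PseudoParser:
    """Deterministic stand-in parser for tests and synthetic fixtures.

    Ordinary sentences become a right-branching chain (token i attaches
    to token i-1) with heuristic relation labels. Sentences matching the
    planted pattern of the synthetic generator — ``PROT1 <iw> PROT2 ...
    <mut> variant fails ...`` — receive a fixed subgraph so that the
    protein-to-mutation shortest path has interior tokens
    [<iw>, PROT2, fails] with relations [nsubj, nmod, conj, nsubj].
    """

    def parse(self, tokens: Sequence[str], sentence_ref: tuple[str, int] = ("", 0),
              ) -> DependencyGraph:
        tokens = list(tokens)
        heads, rels = self._chain(tokens)
        planted = self._planted_indices(tokens)
        if planted is not None:
            i1, iw, i2, ifails, ivar = planted
            heads[i1], rels[i1] = iw, "nsubj"
            heads[iw], rels[iw] = -1, "root"
            heads[i2], rels[i2] = iw, "nmod"
            heads[ifails], rels[ifails] = i2, "conj"
            heads[ivar], rels[ivar] = ifails, "nsubj"
        edges = [(h, d, rel) for d, (h, rel) in enumerate(zip(heads, rels))]
        return DependencyGraph(tokens=tokens, edges=edges, sentence_ref=sentence_ref)

    @staticmethod
    def _planted_indices(tokens: Sequence[str]) -> Optional[tuple[int, int, int, int, int]]:
        try:
            i1 = list(tokens).index("PROT1")
        except ValueError:
            return None
        if (i1 + 2 < len(tokens) and tokens[i1 + 2] == "PROT2"
                and "variant" in tokens and "fails" in tokens):
            ivar = list(tokens).index("variant")
            ifails = list(tokens).index("fails")
            if ifails > i1 + 2 and ivar < ifails:
                return i1, i1 + 1, i1 + 2, ifails, ivar
        return None

    @staticmethod
    def _chain(tokens: Sequence[str]) -> tuple[list[int], list[str]]:
        heads = [i - 1 for i in range(len(tokens))]
        rels = []
        for i, tok in enumerate(tokens):
            low = tok.lower()
            if i == 0:
                rels.append("root")
            elif not any(c.isalnum() for c in tok):
                rels.append("punct")
            elif low in _DET:
                rels.append("det")
            elif low in _ADP:
                rels.append("case")
            elif low in _CC:
                rels.append("cc")
            else:
                rels.append("dep")
        return heads, rels
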