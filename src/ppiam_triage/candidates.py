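"""Important-sentence selection and candidate enumeration.

A sentence is important when it can host a candidate relation: at least
two protein mentions plus an interaction word (a PPI triplet
``(p1, p2, iw)``), or at least one protein mention plus a
mutation-related word (a protein-mutation pair ``(Prot, mu)``). All
within-sentence combinations are enumerated, capped per sentence to
guard against pathological mention counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable

from .lexicon import Mention
from .preprocess import TokenizedDocument

#: per-sentence cap on enumerated triplets and pairs (reading order)
DEFAULT_CANDIDATE_CAP = 50


@dataclass(frozen=True)
class PPITriplet:
    """Two protein mentions and an interaction word in one sentence;
    ``p1`` is the earlier-starting protein mention."""

    doc_id: str
    sentence_index: int
    p1: Mention
    p2: Mention
    iw: Mention

    def __post_init__(self) -> None:
        if not (self.p1.sentence_index == self.p2.sentence_index
                == self.iw.sentence_index == self.sentence_index):
            raise ValueError("triplet mentions must share one sentence")
        if self.p1.token_span >= self.p2.token_span:
            raise ValueError("p1 must start before p2")


@dataclass(frozen=True)
class ProtMutPair:
    doc_id: str
    sentence_index: int
    prot: Mention
    mu: Mention

    def __post_init__(self) -> None:
        if self.prot.sentence_index != self.mu.sentence_index:
            raise ValueError("pair mentions must share one sentence")


def _by_sentence(mentions: Iterable[Mention], kind: str, index: int) -> list[Mention]:
    return sorted((m for m in mentions
                   if m.kind == kind and m.sentence_index == index),
                  key=lambda m: m.token_span)


def select_important_sentences(tokdoc: TokenizedDocument,
                               mentions: list[Mention]) -> set[int]:
    """Indices of sentences that can host a triplet or a pair."""
    selected: set[int] = set()
    for sent in tokdoc.sentences:
        n_prot = sum(1 for m in mentions
                     if m.kind == "protein" and m.sentence_index == sent.index)
        n_iw = sum(1 for m in mentions
                   if m.kind == "interaction" and m.sentence_index == sent.index)
        n_mu = sum(1 for m in mentions
                   if m.kind == "mutation" and m.sentence_index == sent.index)
        if (n_prot >= 2 and n_iw >= 1) or (n_prot >= 1 and n_mu >= 1):
            selected.add(sent.index)
    return selected


def enumerate_triplets(doc_id: str, sentence_index: int,
                       mentions: list[Mention],
                       cap: int = DEFAULT_CANDIDATE_CAP) -> list[PPITriplet]:
    """All protein-mention pairs x interaction words in one sentence."""
    prots = _by_sentence(mentions, "protein", sentence_index)
    iws = _by_sentence(mentions, "interaction", sentence_index)
    out: list[PPITriplet] = []
    for (p1, p2), iw in product(combinations(prots, 2), iws):
        if len(out) >= cap:
            break
        out.append(PPITriplet(doc_id=doc_id, sentence_index=sentence_index,
                              p1=p1, p2=p2, iw=iw))
    return out


def enumerate_pairs(doc_id: str, sentence_index: int,
                    mentions: list[Mention],
                    cap: int = DEFAULT_CANDIDATE_CAP) -> list[ProtMutPair]:
    """Cartesian product of protein x mutation mentions in one sentence."""
    prots = _by_sentence(mentions, "protein", sentence_index)
    mus = _by_sentence(mentions, "mutation", sentence_index)
    out: list[ProtMutPair] = []
    for prot, mu in product(prots, mus):
        if len(out) >= cap:
            break
        out.append(ProtMutPair(doc_id=doc_id, sentence_index=sentence_index,
                               prot=prot, mu=mu))
    return out


def extract_candidates(tokdoc: TokenizedDocument, mentions: list[Mention],
                       cap: int = DEFAULT_CANDIDATE_CAP,
                       ) -> tuple[list[PPITriplet], list[ProtMutPair]]:
    """Triplets and pairs from every important sentence of a document."""
    triplets: list[PPITriplet] = []
    pairs: list[ProtMutPair] = []
    for idx in sorted(select_important_sentences(tokdoc, mentions)):
        triplets.extend(enumerate_triplets(tokdoc.doc_id, idx, mentions, cap))
        pairs.extend(enumerate_pairs(tokdoc.doc_id, idx, mentions, cap))
    return triplets, pairs
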