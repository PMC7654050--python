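"""Key-term dictionaries and mention tagging.

Three term classes drive the pipeline: protein names, interaction words
("binds", "interacts with", ...) and mutation-related words ("variant",
"mutant", ...). Dictionary matching is leftmost-longest over token
sequences (a token-level trie scan); mutation mentions additionally come
from a regular expression for standard substitution nomenclature
(``R117H``) and HGVS-like ``c.`` / ``p.`` prefixes.

Appositive duplicate mentions — a parenthesized protein acronym directly
after the spelled-out name, "Tubulin folding cofactor A (TFCA), which
captures ..." — are deleted together with their parentheses before
candidate extraction.

The mutation dictionary itself is built from a labeled corpus by ranking
candidate terms on the class document-frequency differential
``|f+(t) - f-(t)|``; an accept list stands in for manual review.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus import Corpus
from .preprocess import Sentence, TokenizedDocument, tokenize_words
from .stem import stem_token

KINDS = ("protein", "interaction", "mutation")

#: 20 standard amino-acid one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: substitution nomenclature, e.g. R117H
SUBSTITUTION_RE = re.compile(rf"^[{AMINO_ACIDS}][0-9]+[{AMINO_ACIDS}]$")
#: HGVS-like coding / protein prefixes, e.g. c.76A>T, p.R117H
HGVS_PREFIX_RE = re.compile(r"^[cp]\.[A-Za-z0-9>*+_-]+$")

#: regex-tagged mentions carry this in place of a dictionary term
NOMENCLATURE_TAG = "<nomenclature>"


def match_mutation_nomenclature(token: str,
                                patterns: Optional[Sequence[re.Pattern]] = None) -> bool:
    """True iff ``token`` is a mutation code under the configured patterns."""
    pats = patterns if patterns is not None else (SUBSTITUTION_RE, HGVS_PREFIX_RE)
    return any(p.match(token) for p in pats)


@dataclass(frozen=True)
class TermDictionary:
    kind: str
    terms: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        object.__setattr__(self, "terms", frozenset(self.terms))
        for t in self.terms:
            if not t or t != t.strip():
                raise ValueError(f"term {t!r} is empty or has surrounding whitespace")

    @classmethod
    def from_file(cls, kind: str, path: str | Path) -> "TermDictionary":
        """One term per line, UTF-8; blank lines and ``#`` comments skipped."""
        terms = set()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                terms.add(line)
        return cls(kind=kind, terms=frozenset(terms), source=str(path))

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text("\n".join(sorted(self.terms)) + "\n", encoding="utf-8")
        return path


@dataclass(frozen=True)
class Mention:
    """A typed span located in one tokenized sentence. ``token_span`` is
    0-based half-open over the sentence's tokens."""

    kind: str
    sentence_index: int
    token_span: tuple[int, int]
    surface: str
    term: str

    @property
    def start(self) -> int:
        return self.token_span[0]

    @property
    def end(self) -> int:
        return self.token_span[1]


class MatcherIndex:
    """Leftmost-longest dictionary matcher over token sequences.

    Case policy (applied to protein dictionaries): terms of at least
    ``ci_min_len`` characters match case-insensitively, shorter terms
    (gene-symbol-like) match case-sensitively. Other kinds match
    case-insensitively throughout.
    """

    def __init__(self, dictionary: TermDictionary, ci_min_len: int = 4):
        if not dictionary.terms:
            raise ValueError("cannot build a matcher from an empty dictionary")
        self.kind = dictionary.kind
        self.ci_min_len = ci_min_len
        # token-tuple trie keyed by lowercased tokens; terminals carry the
        # original term tokens and whether case-insensitive matching applies
        self._trie: dict = {}
        self.max_len = 1
        for term in dictionary.terms:
            toks = tokenize_words(term)
            if not toks:
                continue
            self.max_len = max(self.max_len, len(toks))
            ci = (self.kind != "protein") or (len(term) >= ci_min_len)
            node = self._trie
            for t in toks:
                node = node.setdefault(t.lower(), {})
            node.setdefault(None, []).append((tuple(toks), ci))

    def scan(self, tokens: Sequence[str], sentence_index: int = 0) -> list[Mention]:
        """Non-overlapping leftmost-longest mentions in a token sequence."""
        mentions: list[Mention] = []
        i = 0
        n = len(tokens)
        while i < n:
            best_end = None
            best_term = None
            node = self._trie
            j = i
            while j < n:
                child = node.get(tokens[j].lower())
                if child is None:
                    break
                node = child
                j += 1
                for term_toks, ci in node.get(None, ()):
                    if ci or tuple(tokens[i:j]) == term_toks:
                        best_end, best_term = j, " ".join(term_toks)
            if best_end is not None:
                mentions.append(Mention(
                    kind=self.kind, sentence_index=sentence_index,
                    token_span=(i, best_end),
                    surface=" ".join(tokens[i:best_end]), term=best_term))
                i = best_end
            else:
                i += 1
        return mentions


def build_trie(dictionary: TermDictionary, ci_min_len: int = 4) -> MatcherIndex:
    return MatcherIndex(dictionary, ci_min_len=ci_min_len)


def find_mentions(tokdoc: TokenizedDocument,
                  matchers: dict[str, MatcherIndex],
                  mutation_patterns: Optional[Sequence[re.Pattern]] = None,
                  ) -> list[Mention]:
    """All mentions of all kinds, per sentence, in reading order.

    Mutation mentions combine dictionary hits with nomenclature-regex
    hits; regex hits overlapping a dictionary mention are dropped.
    """
    mentions: list[Mention] = []
    for sent in tokdoc.sentences:
        for kind in KINDS:
            matcher = matchers.get(kind)
            found = matcher.scan(sent.tokens, sent.index) if matcher else []
            if kind == "mutation":
                covered = {k for m in found for k in range(m.start, m.end)}
                for t_idx, tok in enumerate(sent.tokens):
                    if t_idx not in covered and match_mutation_nomenclature(
                            tok, mutation_patterns):
                        found.append(Mention(
                            kind="mutation", sentence_index=sent.index,
                            token_span=(t_idx, t_idx + 1), surface=tok,
                            term=NOMENCLATURE_TAG))
                found.sort(key=lambda m: m.token_span)
            mentions.extend(found)
    mentions.sort(key=lambda m: (m.sentence_index, m.token_span, m.kind))
    return mentions


def simplify_appositives(tokdoc: TokenizedDocument, mentions: list[Mention],
                         ) -> tuple[TokenizedDocument, list[Mention]]:
    """Delete parenthesized duplicate protein mentions, to a fixed point.

    A protein mention wrapped in parentheses whose opening parenthesis
    immediately follows another protein mention is removed together with
    its parentheses; all downstream token spans are re-indexed.
    """
    changed = True
    while changed:
        changed = False
        for sent in tokdoc.sentences:
            sent_mentions = [m for m in mentions if m.sentence_index == sent.index]
            prots = sorted((m for m in sent_mentions if m.kind == "protein"),
                           key=lambda m: m.token_span)
            target = None
            for k in range(1, len(prots)):
                prev, cur = prots[k - 1], prots[k]
                if (cur.start == prev.end + 1
                        and prev.end < len(sent.tokens)
                        and sent.tokens[prev.end] == "("
                        and cur.end < len(sent.tokens)
                        and sent.tokens[cur.end] == ")"):
                    target = cur
                    break
            if target is None:
                continue
            lo, hi = target.start - 1, target.end + 1  # include parentheses
            width = hi - lo
            sent.tokens[lo:hi] = []
            new_mentions: list[Mention] = []
            for m in mentions:
                if m.sentence_index != sent.index:
                    new_mentions.append(m)
                    continue
                if m == target:
                    continue
                a, b = m.token_span
                if a >= hi:
                    a, b = a - width, b - width
                elif b > lo:
                    if m.kind == target.kind and (a, b) == target.token_span:
                        continue
                    if a >= lo:  # inside the removed region
                        continue
                new_mentions.append(replace(m, token_span=(a, b)))
            mentions = new_mentions
            changed = True
            break
    return tokdoc, mentions


@dataclass
class MutationLexiconReport:
    """Candidate mutation terms ranked by the class-frequency differential."""

    ranked_terms: list[tuple[str, float, float, float]]  # (t, f+, f-, |f+ - f-|)
    accepted: list[str]

    def to_tsv(self, path: str | Path) -> Path:
        import pandas as pd
        accepted = set(self.accepted)
        df = pd.DataFrame(self.ranked_terms,
                          columns=["term", "f_pos", "f_neg", "diff"])
        df["accepted"] = df["term"].isin(accepted)
        path = Path(path)
        df.to_csv(path, sep="\t", index=False)
        return path


def build_mutation_lexicon(train_corpus: Corpus,
                           accept_list: Iterable[str],
                           min_df: int = 5) -> MutationLexiconReport:
    """Rank stemmed unigram candidates by ``|f+(t) - f-(t)|``.

    f+(t) and f-(t) are document frequencies: the fraction of positive
    (resp. negative) abstracts containing the term. Candidates are all
    stemmed unigrams with corpus document frequency >= ``min_df``.
    """
    unlabeled = [d.doc_id for d in train_corpus if d.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled documents: {unlabeled}")
    doc_terms: list[tuple[int, set[str]]] = []
    for doc in train_corpus:
        terms = {stem_token(t) for t in tokenize_words(doc.text)}
        doc_terms.append((doc.label, terms))
    df_all: dict[str, int] = {}
    for _, terms in doc_terms:
        for t in terms:
            df_all[t] = df_all.get(t, 0) + 1
    candidates = sorted(t for t, c in df_all.items() if c >= min_df)
    n_pos = sum(1 for lab, _ in doc_terms if lab == 1)
    n_neg = len(doc_terms) - n_pos
    rows = []
    for t in candidates:
        fp = sum(1 for lab, terms in doc_terms if lab == 1 and t in terms)
        fn = sum(1 for lab, terms in doc_terms if lab == 0 and t in terms)
        f_pos = fp / n_pos if n_pos else 0.0
        f_neg = fn / n_neg if n_neg else 0.0
        rows.append((t, f_pos, f_neg, abs(f_pos - f_neg)))
    rows.sort(key=lambda r: (-r[3], r[0]))
    accept = set(accept_list)
    accepted = [t for (t, *_rest) in rows if t in accept]
    return MutationLexiconReport(ranked_terms=rows, accepted=accepted)


def restrict_to_fold(dictionary: TermDictionary, fold_corpus: Corpus,
                     ci_min_len: int = 4) -> TermDictionary:
    """Subset of terms that actually occur in the fold's documents.

    Used so that a dictionary built on the full training data leaks no
    held-out-only terms into fold predictions.
    """
    if not dictionary.terms:
        return dictionary
    matcher = MatcherIndex(dictionary, ci_min_len=ci_min_len)
    present: set[str] = set()
    for doc in fold_corpus:
        toks = tokenize_words(doc.text)
        for m in matcher.scan(toks):
            present.add(m.term)
        if len(present) == len(dictionary.terms):
            break
    kept = {t for t in dictionary.terms if " ".join(tokenize_words(t)) in present}
    return TermDictionary(kind=dictionary.kind, terms=frozenset(kept),
                          source=dictionary.source + " [fold-restricted]")
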