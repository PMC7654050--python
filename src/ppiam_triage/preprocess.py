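"""Sentence and word tokenization.

Biomedical abstracts are dense in abbreviations ("Fig.", "et al.", "E.",
"i.e.") that defeat off-the-shelf sentence splitters, so the sentence
boundary model here is trained on the corpus itself: a Punkt-style
frequency heuristic collects period-terminated token types that almost
always carry their period and treats them as abbreviations which never
end a sentence.

Word tokenization is rule based: split on whitespace, detach leading and
trailing punctuation as single-character tokens, and keep internal
hyphens, digits and periods so that identifiers and mutation codes
(``R117H``, ``p.R117H``, ``IL-2``) survive as single tokens.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .corpus import Corpus, Document

_TERMINALS = ".!?"
# Characters detached from the edges of whitespace-separated chunks.
_EDGE_PUNCT = ".,;:!?()[]{}\"'`%" + "“”‘’"


def tokenize_words(sentence_text: str) -> list[str]:
    """Tokenize one sentence into word and punctuation tokens."""
    tokens: list[str] = []
    for chunk in sentence_text.split():
        head: list[str] = []
        tail: list[str] = []
        while chunk and chunk[0] in _EDGE_PUNCT:
            head.append(chunk[0])
            chunk = chunk[1:]
        while chunk and chunk[-1] in _EDGE_PUNCT:
            tail.append(chunk[-1])
            chunk = chunk[:-1]
        tokens.extend(head)
        if chunk:
            tokens.append(chunk)
        tokens.extend(reversed(tail))
    return tokens


@dataclass
class Sentence:
    """One sentence of a document: ordinal, tokens, and character span
    (0-based, half-open) into the document text."""

    index: int
    tokens: list[str]
    char_span: tuple[int, int]

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass
class TokenizedDocument:
    doc_id: str
    sentences: list[Sentence]
    text: str = ""


class SentenceBoundaryModel:
    """Abbreviation-aware sentence splitter.

    A period-terminated token type is learned as an abbreviation when its
    with-period form accounts for more than ``threshold`` of the type's
    occurrences and the with-period form occurs at least ``min_count``
    times in the training corpus. Learned abbreviations (and a small seed
    set of common scientific ones) suppress sentence boundaries.
    """

    #: always-on abbreviations; the trained set extends this
    SEED_ABBREVIATIONS = frozenset({"e.g.", "i.e.", "et al.", "al.", "vs.", "cf."})

    def __init__(self, abbreviations: Optional[set[str]] = None,
                 threshold: float = 0.8, min_count: int = 3):
        self.abbreviations: set[str] = set(abbreviations or ())
        self.threshold = threshold
        self.min_count = min_count

    # -- training ---------------------------------------------------------

    @classmethod
    def train(cls, corpus: Corpus, threshold: float = 0.8,
              min_count: int = 3) -> "SentenceBoundaryModel":
        if len(corpus) == 0:
            raise ValueError("cannot train a sentence model on an empty corpus")
        other_punct = "".join(c for c in _EDGE_PUNCT if c != ".")
        with_period: dict[str, int] = {}   # occurrences carrying the period
        mid_sentence: dict[str, int] = {}  # of those, followed by a lowercase/digit word
        total: dict[str, int] = {}         # occurrences of the type with or without period
        for doc in corpus:
            chunks = doc.text.split()
            for i, chunk in enumerate(chunks):
                stripped = chunk.strip(other_punct)
                if stripped.endswith("."):
                    t = stripped.rstrip(".").lower()
                    if not t or not any(ch.isalpha() for ch in t):
                        continue
                    with_period[t] = with_period.get(t, 0) + 1
                    total[t] = total.get(t, 0) + 1
                    nxt = chunks[i + 1].lstrip(other_punct) if i + 1 < len(chunks) else ""
                    if nxt and (nxt[0].islower() or nxt[0].isdigit()):
                        mid_sentence[t] = mid_sentence.get(t, 0) + 1
                else:
                    t = stripped.lower()
                    if t:
                        total[t] = total.get(t, 0) + 1
        abbrevs = {
            t + "." for t, wp in with_period.items()
            if wp >= min_count
            and wp / total[t] > threshold
            and mid_sentence.get(t, 0) >= 1
        }
        return cls(abbreviations=abbrevs, threshold=threshold, min_count=min_count)

    def is_abbreviation(self, word_with_period: str) -> bool:
        w = word_with_period.lower()
        return w in self.abbreviations or w in self.SEED_ABBREVIATIONS

    # -- splitting --------------------------------------------------------

    def split(self, text: str) -> list[tuple[int, int]]:
        """Character spans of sentences (0-based, half-open, whitespace
        trimmed). A run of terminal punctuation followed by whitespace or
        end-of-text ends a sentence unless the word carrying a ``.`` is a
        learned abbreviation."""
        spans: list[tuple[int, int]] = []
        start = 0
        i = 0
        n = len(text)
        while i < n:
            ch = text[i]
            if ch in _TERMINALS:
                j = i
                while j + 1 < n and text[j + 1] in _TERMINALS + ")]\"'":
                    j += 1
                at_break = (j + 1 >= n) or text[j + 1].isspace()
                if at_break and not self._suppressed(text, i):
                    spans.append((start, j + 1))
                    i = j + 1
                    while i < n and text[i].isspace():
                        i += 1
                    start = i
                    continue
                i = j + 1
                continue
            i += 1
        if start < n and text[start:].strip():
            spans.append((start, n))
        # trim whitespace inside spans
        trimmed = []
        for a, b in spans:
            while a < b and text[a].isspace():
                a += 1
            while b > a and text[b - 1].isspace():
                b -= 1
            if a < b:
                trimmed.append((a, b))
        return trimmed

    def _suppressed(self, text: str, dot_index: int) -> bool:
        if text[dot_index] != ".":
            return False
        # word carrying this period
        a = dot_index
        while a > 0 and not text[a - 1].isspace():
            a -= 1
        word = text[a:dot_index + 1]
        core = word.lstrip("".join(c for c in _EDGE_PUNCT if c != "."))
        if self.is_abbreviation(core):
            return True
        # two-word abbreviations such as "et al."
        if a > 0:
            b = a - 1
            while b > 0 and text[b - 1].isspace():
                b -= 1
            c = b
            while c > 0 and not text[c - 1].isspace():
                c -= 1
            if self.is_abbreviation(text[c:b] + " " + core):
                return True
        return False

    # -- persistence ------------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"abbreviations": sorted(self.abbreviations),
                   "threshold": self.threshold, "min_count": self.min_count}
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SentenceBoundaryModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(abbreviations=set(payload["abbreviations"]),
                   threshold=payload["threshold"], min_count=payload["min_count"])

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, SentenceBoundaryModel)
                and self.abbreviations == other.abbreviations
                and self.threshold == other.threshold
                and self.min_count == other.min_count)


def train_sentence_model(corpus: Corpus, threshold: float = 0.8,
                         min_count: int = 3) -> SentenceBoundaryModel:
    return SentenceBoundaryModel.train(corpus, threshold=threshold,
                                       min_count=min_count)


def split_sentences(doc: Document, model: SentenceBoundaryModel) -> TokenizedDocument:
    """Split a document into tokenized sentences with character spans."""
    text = doc.text
    sentences = []
    for idx, (a, b) in enumerate(model.split(text)):
        toks = tokenize_words(text[a:b])
        if toks:
            sentences.append(Sentence(index=idx, tokens=toks, char_span=(a, b)))
    # re-number in case empty spans were dropped
    for i, s in enumerate(sentences):
        s.index = i
    return TokenizedDocument(doc_id=doc.doc_id, sentences=sentences, text=text)
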