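"""Corpus containers and I/O.

A corpus is an ordered collection of abstracts (title + body) with an
optional binary relevance label: 1 if the abstract mentions at least one
protein-protein interaction affected by a mutation (PPIAM), 0 otherwise.

Two on-disk dialects are supported: JSONL (canonical, read/write, keys
``id``/``title``/``body``/``label``/``split``) and a PubTator-like
title/abstract text dialect (``PMID|t|...`` / ``PMID|a|...``, read-only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence


@dataclass(frozen=True)
class Document:
    """One abstract: the unit of triage.

    ``label`` is 1 for relevant (contains a PPIAM), 0 for not relevant,
    None when unlabeled (prediction-time corpora).
    """

    doc_id: str
    title: str
    body: str
    label: Optional[int] = None
    split_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")
        if self.title is None or self.body is None:
            raise ValueError("title and body may be empty but not absent")

    @property
    def text(self) -> str:
        """Title and body joined by a single space (the text used downstream)."""
        if not self.title:
            return self.body
        if not self.body:
            return self.title
        return self.title + " " + self.body


class Corpus:
    """Ordered, id-unique collection of :class:`Document`."""

    def __init__(self, documents: Sequence[Document], provenance: str = ""):
        seen: set[str] = set()
        for d in documents:
            if d.doc_id in seen:
                raise ValueError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)
        self.documents: list[Document] = list(documents)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Corpus) and self.documents == other.documents

    def label_counts(self) -> dict[int, int]:
        """Counts of labeled documents by label; unlabeled ones are skipped."""
        counts: dict[int, int] = {}
        for d in self.documents:
            if d.label is not None:
                counts[d.label] = counts.get(d.label, 0) + 1
        return counts

    def subset(self, doc_ids: Sequence[str]) -> "Corpus":
        wanted = set(doc_ids)
        return Corpus([d for d in self.documents if d.doc_id in wanted],
                      provenance=self.provenance)


@dataclass(frozen=True)
class CorpusStats:
    size: int
    positives: int
    negatives: int
    prevalence: float


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Summary counts of a fully labeled corpus.

    Raises if any document is unlabeled (prediction corpora cannot be
    summarised by class).
    """
    unlabeled = [d.doc_id for d in corpus if d.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled documents: {unlabeled}")
    pos = sum(1 for d in corpus if d.label == 1)
    neg = len(corpus) - pos
    prevalence = pos / len(corpus) if len(corpus) else float("nan")
    return CorpusStats(size=len(corpus), positives=pos, negatives=neg,
                       prevalence=prevalence)


def read_corpus(path: str | Path, dialect: str = "jsonl") -> Corpus:
    """Read a corpus file in the ``jsonl`` or ``pubtator`` dialect."""
    path = Path(path)
    if dialect == "jsonl":
        return _read_jsonl(path)
    if dialect == "pubtator":
        return _read_pubtator(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_jsonl(path: Path) -> Corpus:
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}:{lineno}: malformed JSON record: {e}") from e
            if not isinstance(rec, dict) or "id" not in rec:
                raise ValueError(f"{path}:{lineno}: record must be an object with an 'id' key")
            label = rec.get("label")
            if label is not None:
                label = int(label)
            docs.append(Document(
                doc_id=str(rec["id"]),
                title=rec.get("title", ""),
                body=rec.get("body", ""),
                label=label,
                split_tag=rec.get("split"),
            ))
    return Corpus(docs, provenance=str(path))


def _read_pubtator(path: Path) -> Corpus:
    # PMID|t|title and PMID|a|abstract lines; annotation lines (tab-separated)
    # and blank separators are skipped. Labels are not carried by this dialect.
    titles: dict[str, str] = {}
    bodies: dict[str, str] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or "\t" in line:
                continue
            parts = line.split("|", 2)
            if len(parts) != 3 or parts[1] not in ("t", "a"):
                raise ValueError(f"{path}:{lineno}: malformed PubTator line")
            pmid, kind, text = parts
            if pmid not in titles and pmid not in bodies:
                order.append(pmid)
            if kind == "t":
                titles[pmid] = text
            else:
                bodies[pmid] = text
    docs = [Document(doc_id=pmid, title=titles.get(pmid, ""),
                     body=bodies.get(pmid, "")) for pmid in order]
    return Corpus(docs, provenance=str(path))


def write_corpus(corpus: Corpus, path: str | Path, dialect: str = "jsonl") -> Path:
    """Write a corpus as JSONL; returns the path written.

    ``read_corpus(write_corpus(c))`` reproduces ``c`` field for field, and
    repeated writes of the same corpus are byte-identical.
    """
    if dialect != "jsonl":
        raise ValueError(f"write supports only the jsonl dialect, got {dialect!r}")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus:
            rec: dict = {"id": d.doc_id, "title": d.title, "body": d.body}
            if d.label is not None:
                rec["label"] = d.label
            if d.split_tag is not None:
                rec["split"] = d.split_tag
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    return path
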