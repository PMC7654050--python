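"""Word-embedding tables in word2vec text format.

The format is one header line ``<vocab_size> <dim>`` followed by one
line per word: the word and its vector components, space separated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np


class EmbeddingTable:
    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table is empty")
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dim = next(iter(vectors.values())).shape[0]

    def __contains__(self, word: str) -> bool:
        return word in self.vectors or word.lower() in self.vectors

    def get(self, word: str) -> Optional[np.ndarray]:
        v = self.vectors.get(word)
        if v is None:
            v = self.vectors.get(word.lower())
        return v

    def __len__(self) -> int:
        return len(self.vectors)

    @classmethod
    def from_word2vec_text(cls, path: str | Path) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec text header")
            n_words, dim = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < dim + 1:
                    raise ValueError(f"{path}: row for {parts[0]!r} has wrong arity")
                vectors[parts[0]] = np.array(parts[1:dim + 1], dtype=float)
        if len(vectors) != n_words:
            raise ValueError(f"{path}: header promises {n_words} words, "
                             f"found {len(vectors)}")
        return cls(vectors)

    def to_word2vec_text(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for w in self.vectors:
                comps = " ".join(repr(float(x)) for x in self.vectors[w])
                fh.write(f"{w} {comps}\n")
        return path
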