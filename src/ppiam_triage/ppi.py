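"""Triplet-probability scoring, probability binning, pair polarity.

The probability that a PPI triplet describes a true interaction comes
from a pluggable scorer. The packaged reference scorer is a logistic
function of the three typed shortest-path lengths — terms close to each
other in the parse are more likely to be in a real relation — and is a
deterministic stand-in for any external relation-extraction model a
user may plug in (the plug-in contract is a callable
``scorer(triplet, typed_paths, graph) -> probability``).

Per-abstract features downstream use four probability bins
[0, 0.3), [0.3, 0.5), [0.5, 0.7), [0.7, 1.0], and each protein-mutation
pair is labeled positive when the best triplet probability for its
protein in the abstract exceeds 0.5 (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

from .candidates import PPITriplet, ProtMutPair
from .depgraph import DepPath, DependencyGraph, TypedPaths

PROBABILITY_BIN_EDGES = (0.0, 0.3, 0.5, 0.7, 1.0)

#: path length substituted for disconnected endpoints when scoring
SENTINEL_PATH_LENGTH = 15

#: strict threshold separating positive from negative pairs
PAIR_POLARITY_THRESHOLD = 0.5


class TripletScorer(Protocol):
    def __call__(self, triplet: PPITriplet, paths: TypedPaths,
                 graph: Optional[DependencyGraph]) -> float: ...


class LogisticPathScorer:
    """Reference scorer: sigmoid(intercept + slope * (L1 + L2 + L3)).

    Defaults (intercept 2.0, slope -0.5, sentinel length 15) score
    tightly-connected triplets above 0.5 and unparseable ones near 0.
    """

    def __init__(self, intercept: float = 2.0, slope: float = -0.5,
                 sentinel: int = SENTINEL_PATH_LENGTH):
        self.intercept = intercept
        self.slope = slope
        self.sentinel = sentinel

    def _length(self, path: Optional[DepPath]) -> int:
        return path.length if path is not None else self.sentinel

    def __call__(self, triplet: PPITriplet, paths: TypedPaths,
                 graph: Optional[DependencyGraph] = None) -> float:
        z = self.intercept + self.slope * sum(self._length(p) for p in paths.as_tuple())
        return 1.0 / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class TripletScore:
    triplet: PPITriplet
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")


@dataclass(frozen=True)
class PairPolarity:
    pair: ProtMutPair
    polarity: str  # "positive" | "negative"
    max_p: float


def score_triplets(typed_paths: Sequence[TypedPaths],
                   scorer: Optional[TripletScorer] = None,
                   graph: Optional[DependencyGraph] = None,
                   ) -> list[TripletScore]:
    """One probability per triplet; scorer outputs outside [0,1] raise."""
    scorer = scorer or LogisticPathScorer()
    out = []
    for tp in typed_paths:
        p = float(scorer(tp.triplet, tp, graph))
        out.append(TripletScore(triplet=tp.triplet, probability=p))
    return out


def bin_probabilities(scores: Sequence[TripletScore | float]) -> list[int]:
    """Counts over [0,0.3), [0.3,0.5), [0.5,0.7), [0.7,1.0]."""
    counts = [0, 0, 0, 0]
    for s in scores:
        p = s.probability if isinstance(s, TripletScore) else float(s)
        if p < PROBABILITY_BIN_EDGES[1]:
            counts[0] += 1
        elif p < PROBABILITY_BIN_EDGES[2]:
            counts[1] += 1
        elif p < PROBABILITY_BIN_EDGES[3]:
            counts[2] += 1
        else:
            counts[3] += 1
    return counts


def label_pairs(pairs: Sequence[ProtMutPair],
                scores: Sequence[TripletScore]) -> list[PairPolarity]:
    """Polarity of each pair from the abstract's triplet probabilities.

    For pair (Prot, mu): max_p is the highest probability over all
    triplets in the same abstract whose p1 or p2 is the same dictionary
    term as Prot; positive iff max_p > 0.5 (strict). A protein occurring
    in no triplet gets max_p = 0 (negative).
    """
    best: dict[str, float] = {}
    for s in scores:
        for prot in (s.triplet.p1, s.triplet.p2):
            key = prot.term.lower()
            best[key] = max(best.get(key, 0.0), s.probability)
    out = []
    for pair in pairs:
        max_p = best.get(pair.prot.term.lower(), 0.0)
        polarity = "positive" if max_p > PAIR_POLARITY_THRESHOLD else "negative"
        out.append(PairPolarity(pair=pair, polarity=polarity, max_p=max_p))
    return out
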