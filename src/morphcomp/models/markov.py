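"""Bigram Markov models and the morpheme unigram baseline.

Both are trained by token-weighted maximum likelihood with Lidstone
smoothing: every training sequence contributes its counts multiplied by
the source word's token frequency.  Sequence probabilities are products
of transition probabilities over adjacent units, delimited by begin and
end sentinels, so word length is properly accounted for.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from ..trees import UNK
from .smoothing import SmoothingConfig, lidstone_log_prob

__all__ = ["BOS", "EOS", "BigramModel", "UnigramModel", "train_bigram", "train_unigram"]

BOS = "<s>"
EOS = "</s>"

WeightedSeq = Tuple[Sequence[str], float]


def _check_training(sequences: List[WeightedSeq]) -> None:
    if not sequences:
        raise ValueError("empty training set")
    for seq, w in sequences:
        if not seq:
            raise ValueError("empty training sequence")
        if w < 0:
            raise ValueError("negative sequence weight")


@dataclass
class BigramModel:
    """First-order Markov model over characters, syllables or morphemes.

    The smoothing vocabulary is the observed unit types plus the end
    sentinel plus the unknown type; successor distributions for every
    context therefore sum to one.
    """

    unit_kind: str
    vocab: Tuple[str, ...]  # observed unit types, sorted
    counts: Dict[str, Dict[str, float]]
    config: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self) -> None:
        self._types = set(self.vocab)
        self._totals = {c: sum(d.values()) for c, d in self.counts.items()}
        # |V| = unit types + EOS (+ UNK)
        self.vocab_size = len(self.vocab) + 1 + (1 if self.config.include_unknown else 0)

    def _map(self, unit: str) -> str:
        if unit in self._types or unit in (BOS, EOS):
            return unit
        return UNK

    def successors(self) -> List[str]:
        out = list(self.vocab) + [EOS]
        if self.config.include_unknown:
            out.append(UNK)
        return out

    def log_transition(self, context: str, unit: str) -> float:
        context = self._map(context)
        unit = self._map(unit)
        c = self.counts.get(context, {}).get(unit, 0.0)
        total = self._totals.get(context, 0.0)
        return lidstone_log_prob(c, total, self.config.alpha, self.vocab_size)

    def logprob(self, sequence: Sequence[str]) -> float:
        """Natural-log probability of a unit sequence, including the
        transitions from BOS and into EOS."""
        if not sequence:
            raise ValueError("cannot score an empty sequence")
        units = [BOS, *sequence, EOS]
        return sum(
            self.log_transition(a, b) for a, b in zip(units, units[1:])
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "type": "bigram",
            "unit_kind": self.unit_kind,
            "vocab": list(self.vocab),
            "counts": {c: dict(d) for c, d in self.counts.items()},
            "alpha": self.config.alpha,
            "include_unknown": self.config.include_unknown,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BigramModel":
        return cls(
            unit_kind=d["unit_kind"],
            vocab=tuple(d["vocab"]),
            counts={c: dict(v) for c, v in d["counts"].items()},
            config=SmoothingConfig(d["alpha"], d["include_unknown"]),
        )


def train_bigram(
    sequences: Iterable[WeightedSeq],
    config: SmoothingConfig = SmoothingConfig(),
    unit_kind: str = "character",
) -> BigramModel:
    """Token-weighted MLE bigram training.

    Each sequence contributes ``weight`` to every adjacent-pair count,
    including BOS -> first unit and last unit -> EOS.
    """
    sequences = list(sequences)
    _check_training(sequences)
    counts: Dict[str, Dict[str, float]] = defaultdict(lambda: defaultdict(float))
    types: set = set()
    for seq, w in sequences:
        types.update(seq)
        units = [BOS, *seq, EOS]
        for a, b in zip(units, units[1:]):
            counts[a][b] += w
    return BigramModel(
        unit_kind=unit_kind,
        vocab=tuple(sorted(types)),
        counts={c: dict(d) for c, d in counts.items()},
        config=config,
    )


@dataclass
class UnigramModel:
    """Token-weighted morpheme unigram: p(sequence) = prod p(m).

    No positional sentinels — this is the morpheme-frequency reference
    distribution used in the SLOR denominator, not a sequence model.
    """

    counts: Dict[str, float]
    config: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self) -> None:
        self.total = sum(self.counts.values())
        self.vocab_size = len(self.counts) + (1 if self.config.include_unknown else 0)

    def log_prob(self, unit: str) -> float:
        c = self.counts.get(unit, 0.0)
        return lidstone_log_prob(c, self.total, self.config.alpha, self.vocab_size)

    def logprob(self, sequence: Sequence[str]) -> float:
        if not sequence:
            raise ValueError("cannot score an empty sequence")
        return sum(self.log_prob(u) for u in sequence)

    def to_dict(self) -> dict:
        return {
            "type": "unigram",
            "counts": dict(self.counts),
            "alpha": self.config.alpha,
            "include_unknown": self.config.include_unknown,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnigramModel":
        return cls(dict(d["counts"]), SmoothingConfig(d["alpha"], d["include_unknown"]))


def train_unigram(
    sequences: Iterable[WeightedSeq],
    config: SmoothingConfig = SmoothingConfig(),
) -> UnigramModel:
    sequences = list(sequences)
    _check_training(sequences)
    counts: Dict[str, float] = defaultdict(float)
    for seq, w in sequences:
        for u in seq:
            counts[u] += w
    return UnigramModel(dict(counts), config)
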