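"""Hidden Markov model over category-tagged morpheme strings.

Supervised training on tagged sequences (the flattened view of the
derivation trees): weighted counts of tag transitions, including the
begin/end sentinels, and of per-tag morpheme emissions, each Lidstone-
smoothed over its own vocabulary (tags + EOS for transitions, morpheme
types + unknown for emissions).  Scoring marginalizes over all tag
paths with the forward algorithm in log space.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from scipy.special import logsumexp

from ..trees import UNK
from .markov import BOS, EOS
from .smoothing import SmoothingConfig, lidstone_log_prob

__all__ = ["HMMModel", "train_hmm"]

TaggedSeq = Sequence[Tuple[str, str]]  # (morpheme, tag)


@dataclass
class HMMModel:
    tags: Tuple[str, ...]
    trans_counts: Dict[str, Dict[str, float]]  # context tag (or BOS) -> next tag / EOS
    emis_counts: Dict[str, Dict[str, float]]  # tag -> morpheme
    config: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self) -> None:
        self._trans_totals = {c: sum(d.values()) for c, d in self.trans_counts.items()}
        self._emis_totals = {t: sum(d.values()) for t, d in self.emis_counts.items()}
        self._morphemes = set()
        for d in self.emis_counts.values():
            self._morphemes.update(d)
        self.n_trans_vocab = len(self.tags) + 1  # tags + EOS
        self.n_emis_vocab = len(self._morphemes) + (
            1 if self.config.include_unknown else 0
        )

    def log_transition(self, context: str, tag: str) -> float:
        c = self.trans_counts.get(context, {}).get(tag, 0.0)
        total = self._trans_totals.get(context, 0.0)
        return lidstone_log_prob(c, total, self.config.alpha, self.n_trans_vocab)

    def log_emission(self, tag: str, morpheme: str) -> float:
        if morpheme not in self._morphemes:
            morpheme = UNK
        c = self.emis_counts.get(tag, {}).get(morpheme, 0.0)
        total = self._emis_totals.get(tag, 0.0)
        return lidstone_log_prob(c, total, self.config.alpha, self.n_emis_vocab)

    def logprob(self, morphemes: Sequence[str]) -> float:
        """Forward algorithm: log sum over all tag paths of the product
        of transition and emission probabilities."""
        if not morphemes:
            raise ValueError("cannot score an empty sequence")
        tags = self.tags
        alpha = [
            self.log_transition(BOS, t) + self.log_emission(t, morphemes[0])
            for t in tags
        ]
        for m in morphemes[1:]:
            alpha = [
                logsumexp(
                    [a + self.log_transition(s, t) for a, s in zip(alpha, tags)]
                )
                + self.log_emission(t, m)
                for t in tags
            ]
        final = [a + self.log_transition(t, EOS) for a, t in zip(alpha, tags)]
        return float(logsumexp(final))

    def to_dict(self) -> dict:
        return {
            "type": "hmm",
            "tags": list(self.tags),
            "trans_counts": {c: dict(d) for c, d in self.trans_counts.items()},
            "emis_counts": {c: dict(d) for c, d in self.emis_counts.items()},
            "alpha": self.config.alpha,
            "include_unknown": self.config.include_unknown,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        return cls(
            tags=tuple(d["tags"]),
            trans_counts={c: dict(v) for c, v in d["trans_counts"].items()},
            emis_counts={c: dict(v) for c, v in d["emis_counts"].items()},
            config=SmoothingConfig(d["alpha"], d["include_unknown"]),
        )


def train_hmm(
    tagged_sequences: Iterable[Tuple[TaggedSeq, float]],
    config: SmoothingConfig = SmoothingConfig(),
) -> HMMModel:
    tagged_sequences = list(tagged_sequences)
    if not tagged_sequences:
        raise ValueError("empty training set")
    trans: Dict[str, Dict[str, float]] = defaultdict(lambda: defaultdict(float))
    emis: Dict[str, Dict[str, float]] = defaultdict(lambda: defaultdict(float))
    tags: set = set()
    for seq, w in tagged_sequences:
        if not seq:
            raise ValueError("empty training sequence")
        if w < 0:
            raise ValueError("negative sequence weight")
        chain = [BOS] + [t for _, t in seq] + [EOS]
        for a, b in zip(chain, chain[1:]):
            trans[a][b] += w
        for m, t in seq:
            emis[t][m] += w
            tags.add(t)
    return HMMModel(
        tags=tuple(sorted(tags)),
        trans_counts={c: dict(d) for c, d in trans.items()},
        emis_counts={c: dict(d) for c, d in emis.items()},
        config=config,
    )
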