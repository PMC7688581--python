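"""Probabilistic context-free grammar over morphological derivations.

Rules come in four head-lexicalized shapes (see
:func:`morphcomp.trees.extract_rules`): suffixation ``X -> Y s``,
prefixation ``X -> p Y``, zero conversion ``X -> Y`` and root insertion
``X -> m``.  Training is token-weighted relative-frequency estimation of
``P(rhs | lhs)`` with Lidstone smoothing per left-hand side over its
observed right-hand sides plus one unseen-root event per category, so
novel roots receive unknown-root mass while unattested affix
combinations simply fail to parse (a structural zero, reported as
``-inf``).  Scoring sums over all parses — the inside algorithm over
morpheme spans, with unary chains resolved exactly by a geometric-series
(matrix-inverse) closure — under a smoothed start-category distribution
estimated from the training trees' root labels.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ..trees import AFF, NT, ROOT, UNK, MorphTree, Rule, extract_rules
from .smoothing import SmoothingConfig, lidstone_log_prob

__all__ = ["PCFGModel", "train_pcfg", "rule_to_str", "rule_from_str"]

RHS = Tuple[Tuple[str, str], ...]
UNK_RHS: RHS = ((ROOT, UNK),)


def rule_to_str(lhs: str, rhs: RHS) -> str:
    return lhs + " -> " + " ".join(f"{kind}:{sym}" for kind, sym in rhs)


def rule_from_str(s: str) -> Rule:
    lhs, right = s.split(" -> ")
    rhs = tuple(tuple(item.split(":", 1)) for item in right.split(" "))
    return lhs, rhs  # type: ignore[return-value]


@dataclass
class PCFGModel:
    rule_counts: Dict[str, Dict[RHS, float]]
    start_counts: Dict[str, float]
    config: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self) -> None:
        self._totals = {l: sum(d.values()) for l, d in self.rule_counts.items()}
        cats = set(self.rule_counts) | set(self.start_counts)
        for d in self.rule_counts.values():
            for rhs in d:
                for kind, sym in rhs:
                    if kind == NT:
                        cats.add(sym)
        self.categories: Tuple[str, ...] = tuple(sorted(cats))
        self._start_total = sum(self.start_counts.values())
        # per-category known roots, for unknown-root fallback
        self._roots: Dict[str, set] = {c: set() for c in self.categories}
        for lhs, d in self.rule_counts.items():
            for rhs in d:
                if len(rhs) == 1 and rhs[0][0] == ROOT:
                    self._roots[lhs].add(rhs[0][1])

    # -- probabilities ------------------------------------------------------

    def _vocab_size(self, lhs: str) -> int:
        n_observed = len(self.rule_counts.get(lhs, {}))
        extra = 1 if self.config.include_unknown else 0  # the unseen-root event
        return n_observed + extra

    def log_rule_prob(self, lhs: str, rhs: RHS) -> float:
        """Smoothed log P(rhs | lhs); ``rhs`` may be the unknown-root event."""
        observed = self.rule_counts.get(lhs, {})
        if rhs not in observed and rhs != UNK_RHS:
            return float("-inf")
        if rhs == UNK_RHS and not self.config.include_unknown and rhs not in observed:
            return float("-inf")
        c = observed.get(rhs, 0.0)
        return lidstone_log_prob(
            c, self._totals.get(lhs, 0.0), self.config.alpha, self._vocab_size(lhs)
        )

    def rule_prob(self, lhs: str, rhs: RHS, smoothed: bool = True) -> float:
        """P(rhs | lhs); with ``smoothed=False`` the raw token-weighted
        relative frequency (the recovery target for a known grammar)."""
        if not smoothed:
            total = self._totals.get(lhs, 0.0)
            if total == 0:
                return 0.0
            return self.rule_counts.get(lhs, {}).get(rhs, 0.0) / total
        lp = self.log_rule_prob(lhs, rhs)
        return math.exp(lp) if np.isfinite(lp) else 0.0

    def log_start_prob(self, cat: str) -> float:
        if cat not in self.categories:
            return float("-inf")
        c = self.start_counts.get(cat, 0.0)
        return lidstone_log_prob(
            c, self._start_total, self.config.alpha, len(self.categories)
        )

    # -- inside algorithm ---------------------------------------------------

    def _terminal_probs(self, morpheme: str) -> Dict[str, float]:
        """P(cat expands to this morpheme as a root), with unknown-root
        fallback for categories that never emitted it."""
        out = {}
        for cat in self.categories:
            rhs = ((ROOT, morpheme),)
            lp = (
                self.log_rule_prob(cat, rhs)
                if morpheme in self._roots[cat]
                else self.log_rule_prob(cat, UNK_RHS)
            )
            if np.isfinite(lp):
                out[cat] = math.exp(lp)
        return out

    def _unary_closure(self, base: Dict[str, float]) -> Dict[str, float]:
        """Exact sum over unary chains: solve (I - U) x = b where
        U[x, y] = P(X -> Y | X)."""
        cats = self.categories
        idx = {c: i for i, c in enumerate(cats)}
        U = np.zeros((len(cats), len(cats)))
        any_unary = False
        for lhs, d in self.rule_counts.items():
            for rhs in d:
                if len(rhs) == 1 and rhs[0][0] == NT:
                    p = self.rule_prob(lhs, rhs)
                    if p > 0:
                        U[idx[lhs], idx[rhs[0][1]]] = p
                        any_unary = True
        if not any_unary:
            return base
        b = np.zeros(len(cats))
        for c, v in base.items():
            b[idx[c]] = v
        x = np.linalg.solve(np.eye(len(cats)) - U, b)
        return {c: float(v) for c, v in zip(cats, x) if v > 0}

    def inside(self, morphemes: Sequence[str]) -> Dict[str, float]:
        """Inside probabilities over the whole span, per category."""
        n = len(morphemes)
        if n == 0:
            raise ValueError("cannot parse an empty sequence")
        chart: Dict[Tuple[int, int], Dict[str, float]] = {}
        for i in range(n):
            chart[(i, i + 1)] = self._unary_closure(self._terminal_probs(morphemes[i]))
        for span in range(2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span
                cell: Dict[str, float] = defaultdict(float)
                for lhs, d in self.rule_counts.items():
                    for rhs in d:
                        if len(rhs) != 2:
                            continue
                        if rhs[1][0] == AFF:  # X -> Y s ; suffix is the last morpheme
                            if morphemes[j - 1] == rhs[1][1]:
                                sub = chart[(i, j - 1)].get(rhs[0][1], 0.0)
                                if sub > 0:
                                    cell[lhs] += self.rule_prob(lhs, rhs) * sub
                        elif rhs[0][0] == AFF:  # X -> p Y ; prefix is the first morpheme
                            if morphemes[i] == rhs[0][1]:
                                sub = chart[(i + 1, j)].get(rhs[1][1], 0.0)
                                if sub > 0:
                                    cell[lhs] += self.rule_prob(lhs, rhs) * sub
                chart[(i, j)] = self._unary_closure(dict(cell))
        return chart[(0, n)]

    def logprob(self, morphemes: Sequence[str]) -> float:
        """Natural log of the sum over all parses (any start category,
        weighted by the start distribution); ``-inf`` when the affix
        skeleton licenses no parse at all."""
        inside = self.inside(morphemes)
        total = 0.0
        for cat, v in inside.items():
            lp = self.log_start_prob(cat)
            if np.isfinite(lp):
                total += math.exp(lp) * v
        return math.log(total) if total > 0 else float("-inf")

    def parseable(self, morphemes: Sequence[str]) -> bool:
        return bool(self.inside(morphemes))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "type": "pcfg",
            "rules": {
                rule_to_str(l, rhs): c
                for l, d in self.rule_counts.items()
                for rhs, c in d.items()
            },
            "start_counts": dict(self.start_counts),
            "alpha": self.config.alpha,
            "include_unknown": self.config.include_unknown,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCFGModel":
        rule_counts: Dict[str, Dict[RHS, float]] = defaultdict(dict)
        for s, c in d["rules"].items():
            lhs, rhs = rule_from_str(s)
            rule_counts[lhs][rhs] = c
        return cls(
            rule_counts=dict(rule_counts),
            start_counts=dict(d["start_counts"]),
            config=SmoothingConfig(d["alpha"], d["include_unknown"]),
        )


def train_pcfg(
    trees: Iterable[Tuple[MorphTree, float]],
    config: SmoothingConfig = SmoothingConfig(),
) -> PCFGModel:
    """Token-weighted relative-frequency PCFG estimation from trees."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty training set")
    rule_counts: Dict[str, Dict[RHS, float]] = defaultdict(lambda: defaultdict(float))
    start_counts: Dict[str, float] = defaultdict(float)
    for tree, w in trees:
        if w < 0:
            raise ValueError("negative tree weight")
        start_counts[tree.label] += w
        for lhs, rhs in extract_rules(tree):
            rule_counts[lhs][rhs] += w
    return PCFGModel(
        rule_counts={l: dict(d) for l, d in rule_counts.items()},
        start_counts=dict(start_counts),
        config=config,
    )
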