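"""Independent brute-force oracles used by the tests.

These deliberately avoid the dynamic-programming code paths they check:
the HMM oracle enumerates every tag path, the PCFG oracle enumerates
every derivation tree and multiplies its rule probabilities.
"""

import itertools
import math

import numpy as np

from morphcomp.models import BOS, EOS, SmoothingConfig, train_hmm, train_pcfg
from morphcomp.trees import AFF, NT, ROOT, UNK, MorphTree


def hmm_brute_force(model, morphemes):
    """Sum over all tag paths of transition x emission products."""
    total = 0.0
    for tags in itertools.product(model.tags, repeat=len(morphemes)):
        lp = model.log_transition(BOS, tags[0])
        for a, b in zip(tags, tags[1:]):
            lp += model.log_transition(a, b)
        for t, m in zip(tags, morphemes):
            lp += model.log_emission(t, m)
        lp += model.log_transition(tags[-1], EOS)
        total += math.exp(lp)
    return math.log(total) if total > 0 else float("-inf")


def _enum_derivations(model, seq, cat, i, j):
    """All derivation probabilities of seq[i:j] rooted in ``cat``.

    Assumes the grammar has no unary rules (the random grammars used
    with this oracle are built that way)."""
    out = []
    if j - i == 1:
        m = seq[i]
        rhs = ((ROOT, m),)
        if m in model._roots.get(cat, ()):  # noqa: SLF001 - test oracle
            lp = model.log_rule_prob(cat, rhs)
        else:
            lp = model.log_rule_prob(cat, ((ROOT, UNK),))
        if np.isfinite(lp):
            out.append(math.exp(lp))
    if j - i >= 2:
        for rhs in model.rule_counts.get(cat, {}):
            if len(rhs) != 2:
                continue
            p_rule = model.rule_prob(cat, rhs)
            if rhs[1][0] == AFF and seq[j - 1] == rhs[1][1]:
                for p_sub in _enum_derivations(model, seq, rhs[0][1], i, j - 1):
                    out.append(p_rule * p_sub)
            elif rhs[0][0] == AFF and seq[i] == rhs[0][1]:
                for p_sub in _enum_derivations(model, seq, rhs[1][1], i + 1, j):
                    out.append(p_rule * p_sub)
    return out


def pcfg_brute_force(model, morphemes):
    """Sum over all derivation trees, any start category."""
    total = 0.0
    for cat in model.categories:
        lp_start = model.log_start_prob(cat)
        if not np.isfinite(lp_start):
            continue
        for p in _enum_derivations(model, morphemes, cat, 0, len(morphemes)):
            total += math.exp(lp_start) * p
    return math.log(total) if total > 0 else float("-inf")


def random_hmm(rng, n_tags=None, alpha=0.1):
    """A small HMM trained on a random weighted tagged corpus."""
    tags = ["X", "Y", "Z"][: n_tags or rng.integers(1, 4)]
    morphs = ["a", "b", "c"]
    corpus = []
    for _ in range(rng.integers(2, 6)):
        length = rng.integers(1, 4)
        seq = [
            (morphs[rng.integers(len(morphs))], tags[rng.integers(len(tags))])
            for _ in range(length)
        ]
        corpus.append((seq, float(rng.integers(1, 5))))
    return train_hmm(corpus, SmoothingConfig(alpha))


def random_tree(rng, cats, affixes, roots, depth):
    cat = cats[rng.integers(len(cats))]
    if depth <= 1 or rng.random() < 0.4:
        return MorphTree(cat, (roots[rng.integers(len(roots))],))
    sub = random_tree(rng, cats, affixes, roots, depth - 1)
    affix = affixes[rng.integers(len(affixes))]
    if rng.random() < 0.5:
        return MorphTree(cat, (sub, affix))
    return MorphTree(cat, (affix, sub))


def random_pcfg(rng, n_cats=None, alpha=0.1):
    """A small PCFG (no unary rules) trained on random weighted trees."""
    cats = ["X", "Y", "Z"][: n_cats or rng.integers(1, 4)]
    affixes = ["p", "q"]
    roots = ["a", "b"]
    corpus = [
        (random_tree(rng, cats, affixes, roots, depth=3), float(rng.integers(1, 5)))
        for _ in range(rng.integers(2, 7))
    ]
    return train_pcfg(corpus, SmoothingConfig(alpha))
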