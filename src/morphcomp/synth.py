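"""Synthetic ground-truth data generators.

Two generators make the whole pipeline testable without licensed
lexical resources or crowdsourced ratings:

* :func:`sample_lexicon` draws a derivational lexicon from a known
  :class:`GroundTruthGrammar` — a small PCFG over morphological
  categories whose affix rules mirror the ten linear (suffix-suffix)
  and eight nested (prefix-suffix) derivational structures the stimulus
  builder targets — and assigns Zipf-profiled token frequencies.
* :func:`simulate_judgments` draws 1–7 Likert ratings from a latent
  linear model with by-subject, by-word and by-order (presentation
  position) random intercepts, discretized by fixed cut-points — the
  same generative structure the evaluation stage assumes when it fits
  crossed random-intercept models to real ratings.

All sampling is driven by explicit seeds; there is no global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lexicon import EXCLUSION_FLAGS, LexicalEntry, Lexicon
from .trees import AFF, NT, ROOT, MorphTree, Rule, tree_to_struclab

__all__ = [
    "GroundTruthGrammar",
    "default_grammar",
    "sample_lexicon",
    "sample_lexicon_tokens",
    "JudgmentSimConfig",
    "simulate_participants",
    "simulate_judgments",
]


class GrammarError(ValueError):
    pass


@dataclass(frozen=True)
class GroundTruthGrammar:
    """A known generating grammar for synthetic lexicons.

    ``expansions`` maps each category to ``(rhs, probability)`` pairs in
    the rule notation of :mod:`morphcomp.trees`: suffixation
    ``((NT, Y), (AFF, s))``, prefixation ``((AFF, p), (NT, Y))``, zero
    conversion ``((NT, Y),)`` and root insertion ``((ROOT, m),)``.
    Probabilities conditioned on each category sum to one, so the
    grammar doubles as the recovery target for PCFG training.
    """

    categories: Tuple[str, ...]
    expansions: Mapping[str, Tuple[Tuple[Tuple[Tuple[str, str], ...], float], ...]]
    start_probs: Mapping[str, float]
    zipf_exponent: float = 1.0

    def __post_init__(self) -> None:
        for cat, exps in self.expansions.items():
            total = sum(p for _, p in exps)
            if abs(total - 1.0) > 1e-9:
                raise GrammarError(f"expansion probabilities for {cat} sum to {total}")
            for rhs, p in exps:
                if not (0.0 < p <= 1.0):
                    raise GrammarError(f"probability {p} for {cat} -> {rhs} out of (0,1]")
        if abs(sum(self.start_probs.values()) - 1.0) > 1e-9:
            raise GrammarError("start probabilities must sum to 1")

    def rule_probability(self, lhs: str, rhs: Tuple[Tuple[str, str], ...]) -> float:
        for r, p in self.expansions[lhs]:
            if r == rhs:
                return p
        return 0.0

    def rules(self) -> List[Tuple[Rule, float]]:
        out = []
        for cat, exps in self.expansions.items():
            for rhs, p in exps:
                out.append(((cat, rhs), p))
        return out

    def sample_tree(self, rng: np.random.Generator, max_depth: int) -> MorphTree:
        """Sample one derivation; ``max_depth`` bounds the node depth
        (1 = a bare root), forcing root insertion at the bound."""
        cat = self._choice(rng, list(self.start_probs), list(self.start_probs.values()))
        return self._expand(rng, cat, max_depth)

    def _expand(self, rng: np.random.Generator, cat: str, depth: int) -> MorphTree:
        exps = self.expansions[cat]
        if depth <= 1:
            exps = tuple((rhs, p) for rhs, p in exps if rhs[0][0] == ROOT)
            if not exps:
                raise GrammarError(f"category {cat} has no root expansions at depth bound")
            total = sum(p for _, p in exps)
            exps = tuple((rhs, p / total) for rhs, p in exps)
        rhs = self._choice(rng, [r for r, _ in exps], [p for _, p in exps])
        if rhs[0][0] == ROOT:
            return MorphTree(cat, (rhs[0][1],))
        if len(rhs) == 1:  # unary / zero conversion
            return MorphTree(cat, (self._expand(rng, rhs[0][1], depth - 1),))
        if rhs[1][0] == AFF:  # suffixation
            sub = self._expand(rng, rhs[0][1], depth - 1)
            return MorphTree(cat, (sub, rhs[1][1]))
        sub = self._expand(rng, rhs[1][1], depth - 1)  # prefixation
        return MorphTree(cat, (rhs[0][1], sub))

    @staticmethod
    def _choice(rng, items, probs):
        idx = rng.choice(len(items), p=np.asarray(probs) / np.sum(probs))
        return items[idx]


# ---------------------------------------------------------------------------
# Default grammar
# ---------------------------------------------------------------------------

# Derivational rule skeleton: ten suffix-suffix (linear) and eight
# prefix-suffix (nested) trimorphemic structures, decomposed into their
# component binary rules.  Outer suffixes: al, ity, ship, er, ize, ally,
# ly, ness, ist, ism; outer prefixes: pre, sub, super, inter, over, non,
# de, un.
_SUFFIX_RULES = [
    ("A", "N", "al"),
    ("N", "A", "ity"),
    ("N", "N", "ship"),
    ("N", "V", "er"),
    ("V", "A", "ize"),
    ("B", "A", "ally"),
    ("B", "A", "ly"),
    ("N", "A", "ness"),
    ("N", "N", "ist"),
    ("N", "A", "ism"),
    # inner-only rules completing the structures
    ("N", "V", "ion"),
    ("A", "V", "able"),
    ("N", "V", "or"),
    ("A", "N", "ic"),
    ("A", "N", "y"),
    ("A", "N", "ous"),
]
_PREFIX_RULES = [
    ("N", "pre", "N"),
    ("A", "sub", "A"),
    ("A", "super", "A"),
    ("A", "inter", "A"),
    ("A", "over", "A"),
    ("N", "non", "N"),
    ("V", "de", "V"),
    ("A", "un", "A"),
]
_UNARY_RULES = [("N", "V"), ("V", "N")]

_ONSETS = (
    "b d f g k l m n p r s t v z w h "
    "bl br cl cr dr fl fr gl gr pl pr sc sk sl sm sn sp st sw tr"
).split()
_VOWELS = "a e i o u".split()
_CODAS = "b d g k l m n p r s t ck nd nt st mp".split()


def _make_roots(n: int, offset: int = 0) -> List[str]:
    """Deterministic inventory of pronounceable CVC root strings."""
    combos = itertools.product(_ONSETS, _VOWELS, _CODAS)
    pool = ["".join(c) for c in combos]
    return pool[offset : offset + n]


def default_grammar(
    n_roots_per_cat: int = 600,
    root_mass: float = 0.50,
    suffix_mass: float = 0.35,
    prefix_mass: float = 0.12,
    unary_mass: float = 0.03,
    zipf_exponent: float = 1.0,
) -> GroundTruthGrammar:
    """The stock generating grammar used by tests and demos.

    Each of N, V, A gets a disjoint root inventory with a shallow
    power-law profile; B is affix-derived only (no adverbial roots).
    Within each category the structural mass is split evenly across
    that category's suffix, prefix and unary rules.
    """
    cats = ("N", "V", "A", "B")
    roots = {
        "N": _make_roots(n_roots_per_cat, 0),
        "V": _make_roots(n_roots_per_cat, n_roots_per_cat),
        "A": _make_roots(n_roots_per_cat, 2 * n_roots_per_cat),
        "B": [],
    }
    expansions: Dict[str, list] = {c: [] for c in cats}
    for cat in cats:
        suff = [(l, y, s) for (l, y, s) in _SUFFIX_RULES if l == cat]
        pref = [(l, p, y) for (l, p, y) in _PREFIX_RULES if l == cat]
        una = [(l, y) for (l, y) in _UNARY_RULES if l == cat]
        r_mass, s_mass, p_mass, u_mass = root_mass, suffix_mass, prefix_mass, unary_mass
        if not roots[cat]:
            # redistribute the root mass to structural rules
            scale = 1.0 / (s_mass + p_mass + u_mass)
            r_mass, s_mass, p_mass, u_mass = 0.0, s_mass * scale, p_mass * scale, u_mass * scale
        if roots[cat]:
            weights = np.array([1.0 / (i + 5.0) for i in range(len(roots[cat]))])
            weights = weights / weights.sum() * r_mass
            for m, w in zip(roots[cat], weights):
                expansions[cat].append((((ROOT, m),), float(w)))
        for rules, mass, make in (
            (suff, s_mass, lambda l, y, s: ((NT, y), (AFF, s))),
            (pref, p_mass, lambda l, p, y: ((AFF, p), (NT, y))),
            (una, u_mass, lambda l, y: ((NT, y),)),
        ):
            if rules:
                for r in rules:
                    expansions[cat].append((make(*r), mass / len(rules)))
        total = sum(p for _, p in expansions[cat])
        expansions[cat] = [(rhs, p / total) for rhs, p in expansions[cat]]
    start = {"N": 0.35, "V": 0.25, "A": 0.3, "B": 0.1}
    return GroundTruthGrammar(
        categories=cats,
        expansions={c: tuple(v) for c, v in expansions.items()},
        start_probs=start,
        zipf_exponent=zipf_exponent,
    )


# ---------------------------------------------------------------------------
# Lexicon sampling
# ---------------------------------------------------------------------------


def _entry_from_tree(tree: MorphTree, freq: int, flags: frozenset) -> LexicalEntry:
    leaves = tree.leaves()
    if len(leaves) == 1:
        status = "M" if tree.is_root_node else "Z"
    else:
        status = "C"
    return LexicalEntry(
        surface="".join(leaves),
        token_freq=freq,
        status=status,
        struclab=tree_to_struclab(tree),
        tree=tree,
        flags=flags,
    )


def sample_lexicon(
    grammar: GroundTruthGrammar,
    n_types: int,
    max_depth: int = 3,
    seed: int = 0,
    f_max: int = 1_000_000,
    flag_rate: float = 0.3,
    max_attempts_per_type: int = 500,
) -> Lexicon:
    """Sample ``n_types`` distinct word types from the grammar.

    Types are collected from an i.i.d. stream of derivations, so
    first-appearance order tracks generating probability; the type at
    collection rank *r* receives token frequency
    ``round(f_max * r**(-zipf_exponent))``.  A fraction ``flag_rate`` of
    entries is randomly marked with an exclusion flag (stem allomorphy /
    orthographic substitution / semantic opacity stand-ins), emulating
    the annotation-based filtering the stimulus builder performs.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    rng = np.random.default_rng(seed)
    seen: Dict[str, MorphTree] = {}
    order: List[str] = []
    attempts = 0
    budget = max_attempts_per_type * n_types
    while len(seen) < n_types:
        if attempts >= budget:
            raise RuntimeError(
                f"grammar produced only {len(seen)}/{n_types} distinct types "
                f"within {budget} attempts"
            )
        attempts += 1
        try:
            tree = grammar.sample_tree(rng, max_depth)
        except GrammarError:
            # depth bound hit a category with no root expansions; the
            # attempt budget still guards against impossible grammars
            continue
        surface = "".join(tree.leaves())
        if surface not in seen:
            seen[surface] = tree
            order.append(surface)
    flag_pool = sorted(EXCLUSION_FLAGS)
    lex = Lexicon()
    for rank, surface in enumerate(order, start=1):
        freq = int(round(f_max * rank ** (-grammar.zipf_exponent)))
        flags = frozenset()
        if flag_rate > 0 and rng.random() < flag_rate:
            flags = frozenset({flag_pool[rng.integers(len(flag_pool))]})
        lex.add(_entry_from_tree(seen[surface], freq, flags))
    return lex


def sample_lexicon_tokens(
    grammar: GroundTruthGrammar,
    n_tokens: int,
    max_depth: int = 8,
    seed: int = 0,
    flag_rate: float = 0.0,
) -> Lexicon:
    """Sample a token stream and return types with their empirical counts.

    Unlike :func:`sample_lexicon`, token frequencies here are multinomial
    counts under the grammar itself, so token-weighted rule frequencies
    estimated from the result converge to the generating probabilities —
    the parameter-recovery regime.  A generous ``max_depth`` keeps the
    truncation bias negligible.
    """
    rng = np.random.default_rng(seed)
    counts: Dict[str, int] = {}
    trees: Dict[str, MorphTree] = {}
    for _ in range(n_tokens):
        tree = grammar.sample_tree(rng, max_depth)
        surface = "".join(tree.leaves())
        counts[surface] = counts.get(surface, 0) + 1
        if surface not in trees:
            trees[surface] = tree
    flag_pool = sorted(EXCLUSION_FLAGS)
    lex = Lexicon()
    for surface in sorted(counts, key=lambda s: (-counts[s], s)):
        flags = frozenset()
        if flag_rate > 0 and rng.random() < flag_rate:
            flags = frozenset({flag_pool[rng.integers(len(flag_pool))]})
        lex.add(_entry_from_tree(trees[surface], counts[surface], flags))
    return lex


# ---------------------------------------------------------------------------
# Judgment simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JudgmentSimConfig:
    """Configuration of the latent-variable Likert simulator.

    The latent response for participant *p* rating word *w* at position
    *o* is ``intercept + beta * score(w) + u_p + u_w + u_o + e`` with
    independent mean-zero normal intercepts and residual; the rating is
    the 1–7 bin of the latent value under ``cutpoints``.  With
    ``standardize_scores`` the word scores are z-scored first, so
    ``beta`` is in residual-SD-per-score-SD units across score scales.
    """

    n_participants: int = 180
    n_lists: int = 6
    beta: float = 0.5
    intercept: float = 0.0
    sd_subject: float = 0.3
    sd_word: float = 0.2
    sd_order: float = 0.1
    sd_resid: float = 1.0
    cutpoints: Tuple[float, ...] = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)
    n_incomplete: int = 0
    standardize_scores: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_subject", "sd_word", "sd_order", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        cp = self.cutpoints
        if len(cp) != 6 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be 6 strictly increasing values")


def simulate_participants(
    n: int = 180,
    n_non_native: int = 5,
    n_foreign_born: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Participant metadata with planted exclusion triggers.

    ``n_non_native`` participants report a non-English native language
    and a further ``n_foreign_born`` report a non-USA birthplace; the
    remainder are native USA-born English speakers.
    """
    if n_non_native + n_foreign_born > n:
        raise ValueError("more flagged participants than participants")
    rng = np.random.default_rng(seed)
    ids = [f"p{i:03d}" for i in range(1, n + 1)]
    flagged = rng.choice(n, size=n_non_native + n_foreign_born, replace=False)
    native = ["English"] * n
    birth = ["USA"] * n
    for k, idx in enumerate(flagged):
        if k < n_non_native:
            native[idx] = "Spanish"
        else:
            birth[idx] = "Canada"
    return pd.DataFrame(
        {"participant": ids, "native_language": native, "birthplace": birth}
    )


def _default_design(words: Sequence[str], n_lists: int) -> pd.DataFrame:
    if len(words) % n_lists:
        raise ValueError("word count must be divisible by n_lists")
    per = len(words) // n_lists
    rows = []
    for k in range(n_lists):
        chunk = list(words[k * per : (k + 1) * per])
        for pos, w in enumerate(chunk, start=1):
            rows.append((k + 1, pos, w))
        for pos, w in enumerate(reversed(chunk), start=1):
            rows.append((n_lists + k + 1, pos, w))
    return pd.DataFrame(rows, columns=["list", "position", "word"])


def simulate_judgments(
    words: Sequence[str],
    scores: Mapping[str, float],
    cfg: JudgmentSimConfig,
    design: Optional[pd.DataFrame] = None,
    incomplete_pool: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Simulate a full Likert rating experiment.

    Parameters
    ----------
    words : sequence of str
        Stimulus word identifiers; ignored if ``design`` is given.
    scores : mapping word -> float
        The per-word acceptability score driving the fixed effect.
    cfg : JudgmentSimConfig
    design : DataFrame (list, position, word), optional
        Presentation design; by default words are split into
        ``cfg.n_lists`` lists with reversed copies appended.
    incomplete_pool : sequence of participant ids, optional
        If given, incomplete (missing-rating) trials are only planted on
        these participants.

    Returns
    -------
    DataFrame with columns participant, list, position, word, rating
    (rating is NaN for incomplete trials).
    """
    rng = np.random.default_rng(cfg.seed)
    if design is None:
        design = _default_design(words, cfg.n_lists)
    missing = set(design["word"]) - set(scores)
    if missing:
        raise ValueError(f"{len(missing)} designed words lack scores")
    n_total_lists = int(design["list"].max())
    participants = [f"p{i:03d}" for i in range(1, cfg.n_participants + 1)]
    assignment = {p: (i % n_total_lists) + 1 for i, p in enumerate(participants)}

    word_ids = sorted(set(design["word"]))
    positions = sorted(set(design["position"]))
    u_subj = dict(zip(participants, rng.normal(0, cfg.sd_subject, len(participants))))
    u_word = dict(zip(word_ids, rng.normal(0, cfg.sd_word, len(word_ids))))
    u_order = dict(zip(positions, rng.normal(0, cfg.sd_order, len(positions))))

    score_arr = np.array([scores[w] for w in word_ids], dtype=float)
    if cfg.standardize_scores:
        sd = score_arr.std(ddof=1) if len(score_arr) > 1 else 0.0
        if sd > 0:
            score_arr = (score_arr - score_arr.mean()) / sd
        else:
            score_arr = score_arr - score_arr.mean()
    eff = dict(zip(word_ids, score_arr))

    design_by_list = {k: g.sort_values("position") for k, g in design.groupby("list")}
    rows = []
    for p in participants:
        lst = design_by_list[assignment[p]]
        n = len(lst)
        noise = rng.normal(0, cfg.sd_resid, n)
        for (pos, w), e in zip(zip(lst["position"], lst["word"]), noise):
            latent = (
                cfg.intercept
                + cfg.beta * eff[w]
                + u_subj[p]
                + u_word[w]
                + u_order[pos]
                + e
            )
            rating = int(np.digitize(latent, cfg.cutpoints)) + 1
            rows.append((p, assignment[p], pos, w, float(rating)))
    out = pd.DataFrame(
        rows, columns=["participant", "list", "position", "word", "rating"]
    )
    if cfg.n_incomplete:
        if incomplete_pool is not None:
            eligible = out.index[out["participant"].isin(set(incomplete_pool))]
        else:
            eligible = out.index
        drop = rng.choice(eligible, size=cfg.n_incomplete, replace=False)
        out.loc[drop, "rating"] = np.nan
    return out
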