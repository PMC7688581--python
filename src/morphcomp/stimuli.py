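"""Novel trimorphemic stimulus construction.

The pipeline mirrors a productivity-controlled design for building
*potential but unattested* words from an annotated lexicon:

1. :func:`extract_templates` — for each productive outer affix, find
   the best-supported (outer, inner-suffix) combination among attested
   trimorphemic words; keep it if its type frequency clears a
   threshold (defaults: 5 for linear suffix-suffix structures, 2 for
   nested prefix-suffix structures).
2. :func:`candidate_stems` — bimorphemic suffixed words with matching
   inner suffix and categories and token frequency >= 20 are the stems
   a template may be filled with.
3. :func:`generate_stimuli` — alternate between the two structure
   kinds, cycle templates, sample stems without replacement, apply
   orthographic junction rules, and accept the word only if it is
   unattested, not blocklisted, and its root has not been used before.
4. :func:`build_lists` — distribute the stimuli into balanced
   randomized lists and append reversed copies.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .lexicon import EXCLUSION_FLAGS, LexicalEntry, Lexicon
from .trees import MorphTree, Shape, classify_shape

logger = logging.getLogger(__name__)

__all__ = [
    "StructureTemplate",
    "StimulusWord",
    "JunctionRule",
    "DEFAULT_JUNCTION_RULES",
    "PRODUCTIVE_SUFFIXES",
    "PRODUCTIVE_PREFIXES",
    "extract_templates",
    "candidate_stems",
    "orthographic_adjust",
    "generate_stimuli",
    "build_lists",
    "stimuli_to_frame",
    "StimulusGenerationError",
]

# Productive outer affixes (config defaults; replaceable).
PRODUCTIVE_SUFFIXES = frozenset(
    {"al", "ity", "ship", "er", "ize", "ally", "ly", "ness", "ist", "ism"}
)
PRODUCTIVE_PREFIXES = frozenset(
    {"pre", "sub", "super", "inter", "over", "non", "de", "un"}
)


@dataclass(frozen=True)
class StructureTemplate:
    """A trimorphemic structure schema, e.g. ``[A [N [V Root] ion] al]``
    (linear) or ``[A un [A [V Root] able]]`` (nested)."""

    kind: str  # "linear" | "nested"
    outer: str  # outer suffix (linear) or prefix (nested)
    inner: str  # inner suffix
    cats: Tuple[str, str, str]  # (outermost, middle, root category)
    type_freq: int = 0

    @property
    def template_id(self) -> str:
        return f"{self.kind}:{self.outer}+{self.inner}:{'-'.join(self.cats)}"

    def describe(self) -> str:
        o, m, r = self.cats
        if self.kind == "linear":
            return f"[{o} [{m} [{r} Root] {self.inner}] {self.outer}]"
        return f"[{o} {self.outer} [{m} [{r} Root] {self.inner}]]"


@dataclass(frozen=True)
class StimulusWord:
    surface: str
    morphemes: Tuple[str, ...]
    tree: MorphTree
    kind: str
    template_id: str
    root: str
    stem_surface: str


class StimulusGenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Template extraction
# ---------------------------------------------------------------------------


def extract_templates(
    lex: Lexicon,
    kind: str,
    min_type_freq: int,
    productive_affixes: FrozenSet[str],
    exclude_flags: FrozenSet[str] = EXCLUSION_FLAGS,
) -> List[StructureTemplate]:
    """Extract accepted structure templates of one kind from a lexicon.

    For each outer affix found in trimorphemic words of the requested
    kind, the type frequency of every (inner suffix, category triple)
    combination is counted; the best combination per outer affix is
    accepted iff its count clears ``min_type_freq`` and the outer affix
    is in the productive set.  Ties on the count are broken
    lexicographically by inner affix, then category triple, so the
    result is independent of entry order.
    """
    if kind not in ("linear", "nested"):
        raise ValueError(f"kind must be 'linear' or 'nested', got {kind!r}")
    if not productive_affixes:
        logger.warning("empty productive affix set: no %s templates", kind)
        return []
    target = Shape.TRIMORPHEMIC_LINEAR if kind == "linear" else Shape.TRIMORPHEMIC_NESTED
    combos: Dict[str, Counter] = defaultdict(Counter)
    for e in lex.with_trees(exclude_flags):
        if classify_shape(e.tree) is not target:
            continue
        t = e.tree
        mid = t.subtree
        assert mid is not None
        outer = t.suffix if kind == "linear" else t.prefix
        inner = mid.suffix
        root_node = mid.subtree
        assert outer is not None and inner is not None and root_node is not None
        cats = (t.label, mid.label, root_node.label)
        combos[outer][(inner, cats)] += 1
    templates = []
    for outer in sorted(combos):
        if outer not in productive_affixes:
            continue
        best = min(
            combos[outer].items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
        )
        (inner, cats), count = best
        if count >= min_type_freq:
            templates.append(
                StructureTemplate(kind=kind, outer=outer, inner=inner, cats=cats, type_freq=count)
            )
    return templates


# ---------------------------------------------------------------------------
# Stems and orthography
# ---------------------------------------------------------------------------


def candidate_stems(
    lex: Lexicon,
    template: StructureTemplate,
    min_token_freq: int = 20,
    exclude_flags: FrozenSet[str] = EXCLUSION_FLAGS,
) -> List[LexicalEntry]:
    """Bimorphemic suffixed entries that can fill a template's inner slot:
    matching inner suffix, middle and root categories, and token
    frequency at or above the threshold.  Sorted by surface for
    determinism."""
    out = []
    for e in lex.with_trees(exclude_flags):
        if e.token_freq < min_token_freq:
            continue
        t = e.tree
        if classify_shape(t) is not Shape.BIMORPHEMIC_SUFFIXED:
            continue
        root_node = t.subtree
        assert root_node is not None
        if (
            t.suffix == template.inner
            and t.label == template.cats[1]
            and root_node.label == template.cats[2]
        ):
            out.append(e)
    return sorted(out, key=lambda e: e.surface)


@dataclass(frozen=True)
class JunctionRule:
    """A stem-affix junction rewrite: when ``stem_pattern`` matches the
    stem end (suffix side) or start (prefix side) and ``affix_pattern``
    matches the affix, the stem match is replaced by ``replacement``."""

    side: str  # "suffix" | "prefix"
    stem_pattern: str
    affix_pattern: str
    replacement: str


DEFAULT_JUNCTION_RULES: Tuple[JunctionRule, ...] = (
    # final silent e deleted before a vowel-initial suffix: observe + able
    JunctionRule("suffix", r"e$", r"^[aeiou]", ""),
    # final y -> i before a suffix not starting with i: happy + ness
    JunctionRule("suffix", r"y$", r"^[^i]", "i"),
)


def orthographic_adjust(
    stem_surface: str,
    affix: str,
    side: str,
    rules: Sequence[JunctionRule] = DEFAULT_JUNCTION_RULES,
) -> str:
    """Concatenate stem and affix, applying the first matching junction
    rule.  Prefix attachment is plain concatenation unless a prefix-side
    rule fires."""
    if side not in ("prefix", "suffix"):
        raise ValueError("side must be 'prefix' or 'suffix'")
    for rule in rules:
        if rule.side != side:
            continue
        if side == "suffix":
            if re.search(rule.stem_pattern, stem_surface) and re.search(
                rule.affix_pattern, affix
            ):
                return re.sub(rule.stem_pattern, rule.replacement, stem_surface) + affix
        else:
            if re.search(rule.stem_pattern, stem_surface) and re.search(
                rule.affix_pattern, affix
            ):
                return affix + re.sub(rule.stem_pattern, rule.replacement, stem_surface)
    return affix + stem_surface if side == "prefix" else stem_surface + affix


# ---------------------------------------------------------------------------
# Stimulus generation
# ---------------------------------------------------------------------------


def _make_stimulus(
    stem: LexicalEntry, template: StructureTemplate, rules: Sequence[JunctionRule]
) -> StimulusWord:
    side = "suffix" if template.kind == "linear" else "prefix"
    surface = orthographic_adjust(stem.surface, template.outer, side, rules)
    if template.kind == "linear":
        tree = MorphTree(template.cats[0], (stem.tree, template.outer))
    else:
        tree = MorphTree(template.cats[0], (template.outer, stem.tree))
    return StimulusWord(
        surface=surface,
        morphemes=tree.leaves(),
        tree=tree,
        kind=template.kind,
        template_id=template.template_id,
        root=stem.tree.root_morpheme(),
        stem_surface=stem.surface,
    )


def generate_stimuli(
    lex: Lexicon,
    linear_templates: Sequence[StructureTemplate],
    nested_templates: Sequence[StructureTemplate],
    n_per_kind: int = 300,
    blocklist: FrozenSet[str] = frozenset(),
    seed: int = 0,
    min_token_freq: int = 20,
    junction_rules: Sequence[JunctionRule] = DEFAULT_JUNCTION_RULES,
    exclude_flags: FrozenSet[str] = EXCLUSION_FLAGS,
) -> List[StimulusWord]:
    """Generate novel trimorphemic words, ``n_per_kind`` per structure
    kind, alternating word-by-word between kinds.

    Per kind, templates are cycled round-robin; for the current
    template one stem is sampled (without replacement) from its
    remaining candidates, the outer affix attached with orthographic
    adjustment, and the word accepted iff its surface is unattested in
    the lexicon, not blocklisted, and its root morpheme is new across
    the whole stimulus set.  Deterministic given the seed.  Raises
    :class:`StimulusGenerationError` with per-template shortfalls when
    a quota cannot be met.
    """
    if not linear_templates or not nested_templates:
        raise ValueError("need at least one template of each kind")
    rng = np.random.default_rng(seed)
    pools: Dict[str, List[LexicalEntry]] = {}
    for tpl in itertools.chain(linear_templates, nested_templates):
        cand = candidate_stems(lex, tpl, min_token_freq, exclude_flags)
        pools[tpl.template_id] = [cand[i] for i in rng.permutation(len(cand))]
    queues = {
        "linear": list(linear_templates),
        "nested": list(nested_templates),
    }
    counts = {"linear": 0, "nested": 0}
    rejections = Counter()
    used_roots: Set[str] = set()
    used_surfaces: Set[str] = set()
    out: List[StimulusWord] = []
    kind_cycle = itertools.cycle(["linear", "nested"])
    while counts["linear"] < n_per_kind or counts["nested"] < n_per_kind:
        kind = next(kind_cycle)
        if counts[kind] >= n_per_kind:
            continue
        produced = False
        # try each remaining template of this kind once, starting from
        # the head of the rotation
        for _ in range(len(queues[kind])):
            if not queues[kind]:
                break
            tpl = queues[kind].pop(0)
            pool = pools[tpl.template_id]
            while pool:
                stem = pool.pop()
                word = _make_stimulus(stem, tpl, junction_rules)
                if lex.attested(word.surface):
                    rejections["attested"] += 1
                    continue
                if word.surface in blocklist:
                    rejections["blocklisted"] += 1
                    continue
                if word.root in used_roots:
                    rejections["repeated_root"] += 1
                    continue
                if word.surface in used_surfaces:
                    rejections["duplicate_surface"] += 1
                    continue
                used_roots.add(word.root)
                used_surfaces.add(word.surface)
                out.append(word)
                counts[kind] += 1
                produced = True
                break
            if pool or produced:
                queues[kind].append(tpl)  # keep in rotation
            if produced:
                break
        if not produced:
            shortfalls = {
                t.template_id: len(pools[t.template_id])
                for t in (linear_templates if kind == "linear" else nested_templates)
            }
            raise StimulusGenerationError(
                f"quota unreachable: {counts[kind]}/{n_per_kind} {kind} words "
                f"generated, remaining pools {shortfalls}, rejections {dict(rejections)}"
            )
    logger.info(
        "generated %d stimuli (%d rejections: %s)",
        len(out),
        sum(rejections.values()),
        dict(rejections),
    )
    return out


# ---------------------------------------------------------------------------
# List construction
# ---------------------------------------------------------------------------


def build_lists(
    stimuli: Sequence[StimulusWord], n_lists: int = 6, seed: int = 0
) -> pd.DataFrame:
    """Distribute stimuli into ``n_lists`` randomized lists balanced by
    structure kind, then append the reversed copy of each list
    (lists ``n_lists+1 .. 2*n_lists``).

    Returns a DataFrame with columns list, position, word.
    """
    by_kind: Dict[str, List[StimulusWord]] = defaultdict(list)
    for s in stimuli:
        by_kind[s.kind].append(s)
    if len(stimuli) % n_lists:
        raise ValueError("stimulus count must be divisible by n_lists")
    for kind, items in by_kind.items():
        if len(items) % n_lists:
            raise ValueError(f"{kind} count {len(items)} not divisible by n_lists")
    rng = np.random.default_rng(seed)
    lists: List[List[str]] = [[] for _ in range(n_lists)]
    for kind in sorted(by_kind):
        items = by_kind[kind]
        order = rng.permutation(len(items))
        per = len(items) // n_lists
        for k in range(n_lists):
            lists[k].extend(items[i].surface for i in order[k * per : (k + 1) * per])
    rows = []
    for k, words in enumerate(lists, start=1):
        shuffled = [words[i] for i in rng.permutation(len(words))]
        for pos, w in enumerate(shuffled, start=1):
            rows.append((k, pos, w))
        for pos, w in enumerate(reversed(shuffled), start=1):
            rows.append((n_lists + k, pos, w))
    return pd.DataFrame(rows, columns=["list", "position", "word"])


def stimuli_to_frame(stimuli: Sequence[StimulusWord]) -> pd.DataFrame:
    """Tabular view: surface, kind, template id, morphemes, tree, root, stem."""
    return pd.DataFrame(
        {
            "word": [s.surface for s in stimuli],
            "kind": [s.kind for s in stimuli],
            "template_id": [s.template_id for s in stimuli],
            "morphemes": ["-".join(s.morphemes) for s in stimuli],
            "tree": [str(s.tree) for s in stimuli],
            "root": [s.root for s in stimuli],
            "stem": [s.stem_surface for s in stimuli],
            "outer": [s.template_id.split(":")[1].split("+")[0] for s in stimuli],
        }
    )
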