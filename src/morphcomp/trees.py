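"""Morphological derivation trees.

A derivational analysis of a word is a labelled tree over morphemes.
Internal nodes carry syntactic categories (N, V, A, B by default);
leaves are morpheme strings.  Affixes appear as bare terminal children
of the node they head (prefixes on the left, suffixes on the right),
so ``(N (V teach) er)`` reads "the suffix *er* builds a noun from the
verb *teach*".  Unary nodes encode zero conversion, e.g. ``(N (V walk))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence, Tuple, Union

__all__ = [
    "MorphTree",
    "Shape",
    "StruclabParseError",
    "parse_struclab",
    "tree_to_string",
    "tree_to_struclab",
    "classify_shape",
    "flatten_tagged",
    "extract_rules",
    "NT",
    "AFF",
    "ROOT",
    "UNK",
]

# Symbol markers used in grammar rules (see :func:`extract_rules`).
NT = "NT"      # non-terminal category
AFF = "AFF"    # affix terminal (prefix or suffix)
ROOT = "ROOT"  # root-morpheme terminal
UNK = "<unk>"  # unknown-symbol sentinel shared across models

Child = Union["MorphTree", str]


@dataclass(frozen=True)
class MorphTree:
    """Immutable derivation tree node.

    Parameters
    ----------
    label : str
        Syntactic category of the constituent this node dominates.
    children : tuple
        Either a single morpheme string (root node), a single
        :class:`MorphTree` (zero conversion), or a pair in which exactly
        one element is a bare affix string.
    """

    label: str
    children: Tuple[Child, ...]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("node label must be non-empty")
        if len(self.children) not in (1, 2):
            raise ValueError("nodes must have one or two children")
        if len(self.children) == 2:
            n_str = sum(isinstance(c, str) for c in self.children)
            if n_str != 1:
                raise ValueError(
                    "binary nodes must combine one subtree with one affix string"
                )
        for c in self.children:
            if isinstance(c, str) and not c:
                raise ValueError("terminal morphemes must be non-empty")

    # -- structural accessors -------------------------------------------------

    def leaves(self) -> Tuple[str, ...]:
        """Morphemes in left-to-right surface order."""
        out: list[str] = []
        for c in self.children:
            if isinstance(c, str):
                out.append(c)
            else:
                out.extend(c.leaves())
        return tuple(out)

    @property
    def is_root_node(self) -> bool:
        """True for a node that directly dominates a single morpheme."""
        return len(self.children) == 1 and isinstance(self.children[0], str)

    @property
    def suffix(self) -> Optional[str]:
        """The affix string if this node is ``[X subtree affix]``."""
        if len(self.children) == 2 and isinstance(self.children[1], str):
            return self.children[1]
        return None

    @property
    def prefix(self) -> Optional[str]:
        """The affix string if this node is ``[X affix subtree]``."""
        if len(self.children) == 2 and isinstance(self.children[0], str):
            return self.children[0]
        return None

    @property
    def subtree(self) -> Optional["MorphTree"]:
        """The unique MorphTree child of a unary or binary node, if any."""
        for c in self.children:
            if isinstance(c, MorphTree):
                return c
        return None

    def iter_nodes(self) -> Iterator["MorphTree"]:
        yield self
        for c in self.children:
            if isinstance(c, MorphTree):
                yield from c.iter_nodes()

    def root_morpheme(self) -> str:
        """The morpheme at the bottom of the derivation (the root)."""
        node = self
        while not node.is_root_node:
            sub = node.subtree
            if sub is None:  # pragma: no cover - excluded by invariants
                raise ValueError("malformed tree: no subtree child")
            node = sub
        return node.children[0]  # type: ignore[return-value]

    def __str__(self) -> str:
        return tree_to_string(self)


class Shape(str, Enum):
    """Morphological shape of a derivation tree."""

    MONOMORPHEMIC = "monomorphemic"
    BIMORPHEMIC_SUFFIXED = "bimorphemic_suffixed"
    BIMORPHEMIC_PREFIXED = "bimorphemic_prefixed"
    TRIMORPHEMIC_LINEAR = "trimorphemic_linear"
    TRIMORPHEMIC_NESTED = "trimorphemic_nested"
    OTHER = "other"


def classify_shape(t: MorphTree) -> Shape:
    """Classify a tree against the canonical derivational templates.

    * ``[X Root]`` -> monomorphemic
    * ``[X [Y Root] Suffix]`` -> bimorphemic_suffixed
    * ``[X Prefix [Y Root]]`` -> bimorphemic_prefixed
    * ``[X [Y [Z Root] Suffix] Suffix]`` -> trimorphemic_linear
    * ``[X Prefix [Y [Z Root] Suffix]]`` -> trimorphemic_nested

    Anything else — zero-conversion chains, deeper recursion, prefixed
    inner constituents — is ``other``.  Total function: never raises.
    """
    if t.is_root_node:
        return Shape.MONOMORPHEMIC
    sub = t.subtree
    if sub is None or len(t.children) != 2:
        return Shape.OTHER
    if t.suffix is not None:
        if sub.is_root_node:
            return Shape.BIMORPHEMIC_SUFFIXED
        if sub.suffix is not None and sub.subtree is not None and sub.subtree.is_root_node:
            return Shape.TRIMORPHEMIC_LINEAR
        return Shape.OTHER
    # prefixed
    if sub.is_root_node:
        return Shape.BIMORPHEMIC_PREFIXED
    if sub.suffix is not None and sub.subtree is not None and sub.subtree.is_root_node:
        return Shape.TRIMORPHEMIC_NESTED
    return Shape.OTHER


# ---------------------------------------------------------------------------
# Parsing the bracketed-structure dialect
# ---------------------------------------------------------------------------


class StruclabParseError(ValueError):
    """Raised when a structure string does not conform to the dialect."""

    def __init__(self, message: str, position: int, text: str):
        self.position = position
        self.text = text
        super().__init__(f"{message} at position {position} in {text!r}")


@dataclass
class _Constituent:
    category: str
    subcat: Optional[str]
    content: Union[str, list]  # bare morpheme or list of _Constituent


def _parse_constituent(s: str, i: int) -> tuple[_Constituent, int]:
    if i >= len(s) or s[i] != "(":
        raise StruclabParseError("expected '('", i, s)
    i += 1
    if i < len(s) and s[i] == "(":
        children: list[_Constituent] = []
        child, i = _parse_constituent(s, i)
        children.append(child)
        while i < len(s) and s[i] == ",":
            i += 1
            while i < len(s) and s[i] == " ":
                i += 1
            child, i = _parse_constituent(s, i)
            children.append(child)
        content: Union[str, list] = children
    else:
        j = i
        while j < len(s) and s[j] not in "(),[]":
            j += 1
        if j == i:
            raise StruclabParseError("empty constituent", i, s)
        content = s[i:j].strip()
        i = j
    if i >= len(s) or s[i] != ")":
        raise StruclabParseError("expected ')'", i, s)
    i += 1
    if i >= len(s) or s[i] != "[":
        raise StruclabParseError("expected '[' label", i, s)
    j = s.find("]", i)
    if j < 0:
        raise StruclabParseError("unterminated label", i, s)
    label = s[i + 1 : j]
    i = j + 1
    if not label:
        raise StruclabParseError("empty label", j, s)
    if "|" in label:
        category, subcat = label.split("|", 1)
    else:
        category, subcat = label, None
    return _Constituent(category.strip(), subcat, content), i


def _to_tree(c: _Constituent, s: str) -> MorphTree:
    if isinstance(c.content, str):
        # A terminal constituent at tree-building time is a root
        # (affixes — the subcategorized terminals — are flattened by
        # their parent before recursion reaches them).
        return MorphTree(c.category, (c.content,))
    kids = c.content
    if len(kids) == 1:
        return MorphTree(c.category, (_to_tree(kids[0], s),))
    if len(kids) != 2:
        raise StruclabParseError(
            f"constituents must have one or two children, got {len(kids)}", 0, s
        )
    # Exactly one child must be an affix: a terminal carrying a
    # subcategorization label like [N|V.] (suffix) or [A|.A] (prefix).
    def is_affix(k: _Constituent) -> bool:
        return isinstance(k.content, str) and k.subcat is not None

    left, right = kids
    if is_affix(right) and not is_affix(left):
        return MorphTree(c.category, (_to_tree(left, s), right.content))
    if is_affix(left) and not is_affix(right):
        return MorphTree(c.category, (left.content, _to_tree(right, s)))
    raise StruclabParseError(
        "binary constituent must pair one affix with one non-affix", 0, s
    )


def parse_struclab(
    s: str,
    categories: Optional[Sequence[str]] = None,
    on_unknown: str = "pass",
) -> MorphTree:
    """Parse a bracketed structure string into a :class:`MorphTree`.

    The dialect: ``(morpheme)[CAT]`` terminals, optionally subcategorized
    as ``[CAT|SUBCAT]`` for affixes, joined by commas and arbitrarily
    nested, e.g. ``((teach)[V],(er)[N|V.])[N]``.  Subcategorization is
    consumed during parsing (it identifies the affix child) but only the
    category before the ``|`` is kept as a node label.

    Parameters
    ----------
    s : str
        The structure string.
    categories : sequence of str, optional
        If given, the set of admissible category labels.
    on_unknown : {"pass", "reject"}
        What to do with labels outside ``categories``.
    """
    if not s or not s.strip():
        raise StruclabParseError("empty structure string", 0, s)
    s = s.strip()
    c, i = _parse_constituent(s, 0)
    if i != len(s):
        raise StruclabParseError("trailing characters", i, s)
    tree = _to_tree(c, s)
    if categories is not None and on_unknown == "reject":
        allowed = set(categories)
        for node in tree.iter_nodes():
            if node.label not in allowed:
                raise StruclabParseError(
                    f"unknown category label {node.label!r}", 0, s
                )
    return tree


def tree_to_string(t: MorphTree) -> str:
    """Penn-Treebank-style serialization, e.g. ``(N (V teach) er)``."""
    parts = []
    for c in t.children:
        parts.append(c if isinstance(c, str) else tree_to_string(c))
    return "(" + " ".join([t.label] + parts) + ")"


def parse_tree_string(s: str) -> MorphTree:
    """Inverse of :func:`tree_to_string`."""
    tokens = s.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> Union[MorphTree, str]:
        nonlocal pos
        if tokens[pos] != "(":
            tok = tokens[pos]
            pos += 1
            return tok
        pos += 1  # '('
        label = tokens[pos]
        pos += 1
        children: list[Child] = []
        while tokens[pos] != ")":
            children.append(parse())
        pos += 1  # ')'
        return MorphTree(label, tuple(children))

    out = parse()
    if pos != len(tokens) or isinstance(out, str):
        raise StruclabParseError("malformed tree string", pos, s)
    return out


def tree_to_struclab(t: MorphTree) -> str:
    """Serialize back to the bracketed-dialect string.

    Inverse of :func:`parse_struclab` up to subcategorization metadata:
    affixes are emitted with the schematic subcategorization their
    position implies (``[X|Y.]`` suffix, ``[X|.Y]`` prefix).
    """
    if t.is_root_node:
        return f"({t.children[0]})[{t.label}]"
    if len(t.children) == 1:
        return f"({tree_to_struclab(t.subtree)})[{t.label}]"  # type: ignore[arg-type]
    sub = t.subtree
    assert sub is not None
    if t.suffix is not None:
        affix = f"({t.suffix})[{t.label}|{sub.label}.]"
        return f"({tree_to_struclab(sub)},{affix})[{t.label}]"
    affix = f"({t.prefix})[{t.label}|.{sub.label}]"
    return f"({affix},{tree_to_struclab(sub)})[{t.label}]"


# ---------------------------------------------------------------------------
# Tree -> model training views
# ---------------------------------------------------------------------------


def flatten_tagged(t: MorphTree) -> list[tuple[str, str]]:
    """Leaves in surface order with their category tags.

    An affix is tagged with the category of the node it heads; the root
    morpheme keeps the category of its own (innermost) node.  E.g.
    ``(B (A (N accident) al) ly)`` -> ``[(accident, N), (al, A), (ly, B)]``.
    """
    if t.is_root_node:
        return [(t.children[0], t.label)]  # type: ignore[list-item]
    if len(t.children) == 1:
        return flatten_tagged(t.subtree)  # type: ignore[arg-type]
    sub = t.subtree
    assert sub is not None
    if t.suffix is not None:
        return flatten_tagged(sub) + [(t.suffix, t.label)]
    return [(t.prefix, t.label)] + flatten_tagged(sub)  # type: ignore[list-item]


Rule = Tuple[str, Tuple[Tuple[str, str], ...]]


def extract_rules(t: MorphTree) -> list[Rule]:
    """Context-free rules instantiated by a derivation tree.

    Rule right-hand sides are tuples of tagged symbols: ``(NT, cat)``
    for non-terminal categories, ``(AFF, s)`` for affix terminals and
    ``(ROOT, m)`` for root-morpheme terminals.  Affix rules are
    head-lexicalized: ``N -> A ness`` records that *ness* selects
    adjectival bases and yields nouns.
    """
    rules: list[Rule] = []
    for node in t.iter_nodes():
        if node.is_root_node:
            rules.append((node.label, ((ROOT, node.children[0]),)))  # type: ignore[arg-type]
        elif len(node.children) == 1:
            rules.append((node.label, ((NT, node.subtree.label),)))  # type: ignore[union-attr]
        elif node.suffix is not None:
            rules.append(
                (node.label, ((NT, node.subtree.label), (AFF, node.suffix)))  # type: ignore[union-attr]
            )
        else:
            rules.append(
                (node.label, ((AFF, node.prefix), (NT, node.subtree.label)))  # type: ignore[union-attr]
            )
    return rules
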