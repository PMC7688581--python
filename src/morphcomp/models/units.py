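"""Unit tokenization: characters, syllables, morphemes, tagged morphemes."""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

from ..syllables import Syllabifier
from ..trees import MorphTree, flatten_tagged

__all__ = ["tokenize", "UNIT_KINDS"]

UNIT_KINDS = ("character", "syllable", "morpheme")

_default_syllabifier = Syllabifier()


def _surface(item) -> str:
    if isinstance(item, str):
        return item
    return item.surface


def _morphemes(item) -> Tuple[str, ...]:
    morphs = getattr(item, "morphemes", None)
    if morphs is not None:
        return tuple(morphs)
    tree = getattr(item, "tree", None) or (item if isinstance(item, MorphTree) else None)
    if tree is not None:
        return tree.leaves()
    raise ValueError(
        f"no morpheme segmentation available for {item!r}"
    )


def tokenize(
    item,
    kind: str,
    syllabifier: Optional[Callable[[str], List[str]]] = None,
) -> Tuple[str, ...]:
    """Break a word into model units.

    ``item`` may be a bare surface string (characters/syllables), a
    :class:`~morphcomp.trees.MorphTree`, or any object exposing
    ``surface`` and either ``morphemes`` or ``tree`` (lexical entries,
    stimulus words).  Morpheme units are the tree leaves in surface
    order.
    """
    if kind == "character":
        surface = _surface(item) if not isinstance(item, MorphTree) else "".join(item.leaves())
        if not surface:
            raise ValueError("empty word")
        return tuple(surface)
    if kind == "syllable":
        surface = _surface(item) if not isinstance(item, MorphTree) else "".join(item.leaves())
        if not surface:
            raise ValueError("empty word")
        syl = syllabifier or _default_syllabifier
        return tuple(syl(surface))
    if kind == "morpheme":
        return _morphemes(item)
    raise ValueError(f"unknown unit kind {kind!r}; expected one of {UNIT_KINDS}")
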