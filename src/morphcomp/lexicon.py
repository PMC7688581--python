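"""Reading and writing morphologically annotated lexicons.

The on-disk dialect is a UTF-8 TSV with ``#`` comment lines and the
columns ``word  freq  status  flags  struclab``:

* ``word`` — surface form (lemma orthography)
* ``freq`` — non-negative integer token frequency
* ``status`` — morphological status: ``M`` (monomorphemic),
  ``Z`` (zero conversion), ``C`` (morphologically complex)
* ``flags`` — comma-joined exclusion flags (``StrucAllo``,
  ``StrucSubst``, ``StrucOpac``) or ``-`` for none
* ``struclab`` — bracketed structure string
  (e.g. ``((teach)[V],(er)[N|V.])[N]``) or ``-``

A ``column_map`` lets genuine database exports with a different column
order be adapted without rewriting the file.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

from .trees import MorphTree, Shape, StruclabParseError, classify_shape, parse_struclab

logger = logging.getLogger(__name__)

__all__ = [
    "LexicalEntry",
    "Lexicon",
    "LexiconFormatError",
    "read_lexicon",
    "write_lexicon",
    "DEFAULT_COLUMNS",
    "EXCLUSION_FLAGS",
]

DEFAULT_COLUMNS = ("word", "freq", "status", "flags", "struclab")
EXCLUSION_FLAGS = frozenset({"StrucAllo", "StrucSubst", "StrucOpac"})
_STATUSES = frozenset({"M", "Z", "C"})


class LexiconFormatError(ValueError):
    pass


@dataclass
class LexicalEntry:
    surface: str
    token_freq: int
    status: str
    struclab: str = ""
    tree: Optional[MorphTree] = None
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.token_freq < 0:
            raise ValueError(f"negative token frequency for {self.surface!r}")
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r} for {self.surface!r}")

    @property
    def shape(self) -> Shape:
        return classify_shape(self.tree) if self.tree is not None else Shape.OTHER


class Lexicon:
    """Ordered collection of entries with a surface-form index."""

    def __init__(self, entries: Iterable[LexicalEntry] = ()):
        self.entries: List[LexicalEntry] = list(entries)
        self._by_surface: Dict[str, List[LexicalEntry]] = {}
        for e in self.entries:
            self._by_surface.setdefault(e.surface, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexicalEntry]:
        return iter(self.entries)

    def add(self, entry: LexicalEntry) -> None:
        self.entries.append(entry)
        self._by_surface.setdefault(entry.surface, []).append(entry)

    def lookup(self, surface: str) -> List[LexicalEntry]:
        """All entries sharing a surface form (possibly empty)."""
        return list(self._by_surface.get(surface, ()))

    def attested(self, surface: str) -> bool:
        return surface in self._by_surface

    def with_trees(self, exclude_flags: frozenset = frozenset()) -> List[LexicalEntry]:
        """Entries that carry a parsed tree, optionally filtering flagged ones."""
        return [
            e
            for e in self.entries
            if e.tree is not None and not (e.flags & exclude_flags)
        ]

    def shape_counts(self) -> Counter:
        """Distribution of shapes over entries with trees."""
        return Counter(e.shape for e in self.entries if e.tree is not None)

    @property
    def total_tokens(self) -> int:
        return sum(e.token_freq for e in self.entries)


def _resolve_columns(column_map: Optional[Dict[str, int]]) -> Dict[str, int]:
    if column_map is None:
        return {name: i for i, name in enumerate(DEFAULT_COLUMNS)}
    missing = set(DEFAULT_COLUMNS) - set(column_map)
    if missing:
        raise LexiconFormatError(f"column_map missing columns: {sorted(missing)}")
    return dict(column_map)


def read_lexicon(
    path,
    column_map: Optional[Dict[str, int]] = None,
    categories: Optional[Sequence[str]] = None,
    sep: str = "\t",
) -> Lexicon:
    """Read a lexicon file.

    Entries whose structure string fails to parse are retained with
    ``tree=None`` and counted in a single warning, so that a partially
    annotated lexicon still loads.
    """
    cols = _resolve_columns(column_map)
    ncol = max(cols.values()) + 1
    lex = Lexicon()
    n_bad_trees = 0
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < ncol:
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected at least {ncol} columns, got {len(fields)}"
                )
            surface = fields[cols["word"]].strip()
            try:
                freq = int(fields[cols["freq"]])
            except ValueError as exc:
                raise LexiconFormatError(
                    f"{path}:{lineno}: bad frequency {fields[cols['freq']]!r}"
                ) from exc
            status = fields[cols["status"]].strip()
            raw_flags = fields[cols["flags"]].strip()
            flags = (
                frozenset(f for f in raw_flags.split(",") if f)
                if raw_flags not in ("", "-")
                else frozenset()
            )
            struclab = fields[cols["struclab"]].strip()
            tree = None
            if struclab and struclab != "-":
                try:
                    tree = parse_struclab(struclab, categories=categories)
                except StruclabParseError as exc:
                    n_bad_trees += 1
                    logger.warning("%s:%d: unparseable structure: %s", path, lineno, exc)
            lex.add(
                LexicalEntry(
                    surface=surface,
                    token_freq=freq,
                    status=status,
                    struclab=struclab if struclab != "-" else "",
                    tree=tree,
                    flags=flags,
                )
            )
    if n_bad_trees:
        logger.warning("%s: %d entries retained without trees", path, n_bad_trees)
    if not len(lex):
        logger.warning("%s: empty lexicon", path)
    return lex


def write_lexicon(lex: Lexicon, path, sep: str = "\t") -> None:
    """Write a lexicon in the dialect format (round-trips with the reader)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# word\tfreq\tstatus\tflags\tstruclab\n")
        for e in lex:
            flags = ",".join(sorted(e.flags)) if e.flags else "-"
            struclab = e.struclab if e.struclab else "-"
            fh.write(sep.join([e.surface, str(e.token_freq), e.status, flags, struclab]) + "\n")
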