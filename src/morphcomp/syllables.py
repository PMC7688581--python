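"""Orthographic syllabification.

A deliberately simple, rule-based syllabifier over spelling: nuclei are
maximal vowel-letter groups ('y' counts as a vowel when it is not
immediately followed by one), and intervocalic consonant clusters are
split by onset maximization against an inventory of legal word-initial
clusters.  The inventory can be induced from a lexicon's word-initial
clusters or supplied directly, so pre-syllabified input can be emulated
by a custom callable wherever a syllabifier is accepted.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Set

__all__ = ["Syllabifier", "DEFAULT_ONSETS"]

_VOWELS = set("aeiou")

DEFAULT_ONSETS: Set[str] = {
    "",
    *"b c d f g h j k l m n p q r s t v w x y z".split(),
    *(
        "bl br ch cl cr dr dw fl fr gl gr gn kn ph pl pr ps qu rh sc sh sk "
        "sl sm sn sp st sw th tr tw wh wr sch scr shr sph spl spr squ str thr"
    ).split(),
}


def _is_vowel(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return True
    if c == "y":
        nxt = word[i + 1] if i + 1 < len(word) else ""
        return nxt not in _VOWELS
    return False


class Syllabifier:
    """Maximal-onset orthographic syllabifier.

    Parameters
    ----------
    onsets : iterable of str, optional
        Legal word-initial consonant clusters.  Defaults to a stock
        English inventory; the empty cluster is always legal.
    """

    def __init__(self, onsets: Optional[Iterable[str]] = None):
        self.onsets = set(onsets) if onsets is not None else set(DEFAULT_ONSETS)
        self.onsets.add("")

    @classmethod
    def from_lexicon(cls, surfaces: Iterable[str]) -> "Syllabifier":
        """Induce the onset inventory from word-initial clusters."""
        onsets = {""}
        for w in surfaces:
            w = w.lower()
            j = 0
            while j < len(w) and not _is_vowel(w, j):
                j += 1
            cluster = w[:j]
            # every suffix of an attested onset is taken as legal too
            for k in range(len(cluster)):
                onsets.add(cluster[k:])
        return cls(onsets)

    def __call__(self, word: str) -> List[str]:
        w = word.lower()
        if not w:
            raise ValueError("cannot syllabify an empty word")
        # nucleus spans: maximal runs of vowel letters
        nuclei: List[tuple[int, int]] = []
        i = 0
        while i < len(w):
            if _is_vowel(w, i):
                j = i
                while j < len(w) and _is_vowel(w, j):
                    j += 1
                nuclei.append((i, j))
                i = j
            else:
                i += 1
        if not nuclei:
            return [word]
        # split each inter-nucleus cluster: longest legal onset wins
        bounds = [0]
        for (_, end_prev), (start_next, _) in zip(nuclei, nuclei[1:]):
            cluster = w[end_prev:start_next]
            for k in range(len(cluster) + 1):
                if cluster[k:] in self.onsets:
                    bounds.append(end_prev + k)
                    break
        bounds.append(len(w))
        return [word[a:b] for a, b in zip(bounds, bounds[1:])]
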