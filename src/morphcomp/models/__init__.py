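"""The five probability models of morphological competence.

Three surface Markov models (character, syllable, morpheme bigrams), a
hidden Markov model over category-tagged morphemes, and a PCFG over
derivation trees — all trained from a lexicon by token-weighted maximum
likelihood with Lidstone smoothing, plus the morpheme unigram that
serves as the SLOR reference distribution.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Tuple, Union

from ..lexicon import Lexicon
from ..syllables import Syllabifier
from ..trees import flatten_tagged
from .hmm import HMMModel, train_hmm
from .markov import BOS, EOS, BigramModel, UnigramModel, train_bigram, train_unigram
from .pcfg import PCFGModel, train_pcfg
from .smoothing import SmoothingConfig, lidstone_log_prob
from .units import UNIT_KINDS, tokenize

__all__ = [
    "SmoothingConfig",
    "BigramModel",
    "UnigramModel",
    "HMMModel",
    "PCFGModel",
    "train_bigram",
    "train_unigram",
    "train_hmm",
    "train_pcfg",
    "tokenize",
    "token_weight",
    "train_all_models",
    "save_models",
    "load_models",
    "MODEL_NAMES",
    "BOS",
    "EOS",
]

MODEL_NAMES = ("character", "syllable", "morpheme", "hmm", "pcfg")

AnyModel = Union[BigramModel, UnigramModel, HMMModel, PCFGModel]


def token_weight(freq: int, zero_floor: float = 1.0) -> float:
    """Training weight of a word with the given token frequency.

    Zero-frequency types still contribute ``zero_floor`` (default 1)
    so that attested-but-rare words are not erased from the models.
    """
    return float(freq) if freq > 0 else float(zero_floor)


def train_all_models(
    lexicon: Lexicon,
    config: SmoothingConfig = SmoothingConfig(),
    syllabifier: Optional[Callable[[str], List[str]]] = None,
    zero_floor: float = 1.0,
) -> Tuple[Dict[str, AnyModel], UnigramModel]:
    """Train the five models plus the morpheme unigram on a lexicon.

    Character and syllable models use every entry's surface; morpheme,
    HMM and PCFG use the entries that carry derivation trees.  Each
    word's counts are weighted by its token frequency.
    """
    if syllabifier is None:
        syllabifier = Syllabifier.from_lexicon(e.surface for e in lexicon)
    char_seqs, syl_seqs = [], []
    for e in lexicon:
        w = token_weight(e.token_freq, zero_floor)
        char_seqs.append((tokenize(e.surface, "character"), w))
        syl_seqs.append((tokenize(e.surface, "syllable", syllabifier), w))
    treed = [e for e in lexicon if e.tree is not None]
    if not treed:
        raise ValueError("lexicon has no entries with derivation trees")
    morph_seqs = [
        (e.tree.leaves(), token_weight(e.token_freq, zero_floor)) for e in treed
    ]
    tagged = [
        (flatten_tagged(e.tree), token_weight(e.token_freq, zero_floor)) for e in treed
    ]
    trees = [(e.tree, token_weight(e.token_freq, zero_floor)) for e in treed]
    models: Dict[str, AnyModel] = {
        "character": train_bigram(char_seqs, config, unit_kind="character"),
        "syllable": train_bigram(syl_seqs, config, unit_kind="syllable"),
        "morpheme": train_bigram(morph_seqs, config, unit_kind="morpheme"),
        "hmm": train_hmm(tagged, config),
        "pcfg": train_pcfg(trees, config),
    }
    unigram = train_unigram(morph_seqs, config)
    return models, unigram


_CLASSES = {"bigram": BigramModel, "unigram": UnigramModel, "hmm": HMMModel, "pcfg": PCFGModel}


def save_models(models: Dict[str, AnyModel], unigram: UnigramModel, path) -> None:
    payload = {name: m.to_dict() for name, m in models.items()}
    payload["unigram"] = unigram.to_dict()
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_models(path) -> Tuple[Dict[str, AnyModel], UnigramModel]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    uni = UnigramModel.from_dict(payload.pop("unigram"))
    models = {
        name: _CLASSES[d["type"]].from_dict(d) for name, d in payload.items()
    }
    return models, uni
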