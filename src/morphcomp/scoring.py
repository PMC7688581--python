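"""SLOR acceptability scores.

The syntactic log-odds ratio links model probabilities to graded
acceptability::

    SLOR(w) = (log p_model(w) - log p_unigram(w)) / |w|

where ``p_unigram`` is the morpheme-product reference distribution and
``|w|`` the word length.  Subtracting the unigram term removes the
morpheme-frequency confound; dividing by length removes the word-length
confound, leaving the structural contribution of the model.

By default ``|w|`` is the morpheme count for every model, keeping the
normalizer constant across models for the same word (all stimuli here
are trimorphemic); the per-model unit count (characters, syllables) is
available as an alternative convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import UnigramModel, tokenize
from .stimuli import StimulusWord

logger = logging.getLogger(__name__)

__all__ = ["slor", "ModelScore", "score_stimuli", "score_all"]


@dataclass(frozen=True)
class ModelScore:
    word: str
    model: str
    log_pw: float
    log_pm: float
    length: int
    slor: float
    ok: bool = True


def slor(log_pw: float, log_pm: float, length: int, word: str = "?", model: str = "?") -> float:
    """(log_pw - log_pm) / length, with loud failure on non-finite input."""
    if length < 1:
        raise ValueError(f"length must be >= 1 for {word!r}")
    if not (math.isfinite(log_pw) and math.isfinite(log_pm)):
        raise ValueError(
            f"non-finite log probability for word {word!r} under model {model!r}: "
            f"log_pw={log_pw}, log_pm={log_pm}"
        )
    return (log_pw - log_pm) / length


def _unit_count(stim: StimulusWord, model_name: str, model, syllabifier) -> int:
    kind = getattr(model, "unit_kind", "morpheme")
    if kind == "morpheme" or model_name in ("hmm", "pcfg"):
        return len(stim.morphemes)
    return len(tokenize(stim.surface, kind, syllabifier))


def score_stimuli(
    model,
    model_name: str,
    unigram: UnigramModel,
    stimuli: Sequence[StimulusWord],
    length_convention: str = "morphemes",
    syllabifier=None,
) -> List[ModelScore]:
    """Score every stimulus under one model.

    Words the model cannot assign a finite probability (a PCFG whose
    rule skeleton licenses no parse) are flagged ``ok=False`` with
    ``slor = nan`` and counted in a log message; downstream consumers
    drop them explicitly.
    """
    if length_convention not in ("morphemes", "model_units"):
        raise ValueError(f"unknown length convention {length_convention!r}")
    out: List[ModelScore] = []
    n_bad = 0
    for stim in stimuli:
        if getattr(model, "unit_kind", None) in ("character", "syllable"):
            units = tokenize(stim.surface, model.unit_kind, syllabifier)
        else:
            units = stim.morphemes
        log_pw = model.logprob(units)
        log_pm = unigram.logprob(stim.morphemes)
        length = (
            len(stim.morphemes)
            if length_convention == "morphemes"
            else _unit_count(stim, model_name, model, syllabifier)
        )
        if math.isfinite(log_pw) and math.isfinite(log_pm):
            out.append(
                ModelScore(stim.surface, model_name, log_pw, log_pm, length,
                           slor(log_pw, log_pm, length, stim.surface, model_name))
            )
        else:
            n_bad += 1
            out.append(
                ModelScore(stim.surface, model_name, log_pw, log_pm, length,
                           float("nan"), ok=False)
            )
    if n_bad:
        logger.warning("%s: %d unscorable stimuli flagged", model_name, n_bad)
    return out


def score_all(
    models: Mapping[str, object],
    unigram: UnigramModel,
    stimuli: Sequence[StimulusWord],
    length_convention: str = "morphemes",
    syllabifier=None,
) -> pd.DataFrame:
    """Score table over all models: one row per stimulus per model with
    columns word, model, log_pw, log_pm, length, slor, ok."""
    rows: List[ModelScore] = []
    for name, model in models.items():
        rows.extend(
            score_stimuli(model, name, unigram, stimuli, length_convention, syllabifier)
        )
    return pd.DataFrame([r.__dict__ for r in rows])
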