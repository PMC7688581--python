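"""Lidstone (additive) smoothing shared by all models."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SmoothingConfig", "lidstone_log_prob"]


@dataclass(frozen=True)
class SmoothingConfig:
    """Additive-smoothing settings.

    alpha : float
        The pseudo-count added to every event before normalization
        (default 0.1).  ``alpha = 0`` gives plain maximum likelihood,
        in which case unseen events have probability zero.
    include_unknown : bool
        Whether vocabularies reserve a single unknown type that absorbs
        out-of-vocabulary material at test time.
    """

    alpha: float = 0.1
    include_unknown: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def lidstone_log_prob(count: float, total: float, alpha: float, vocab_size: int) -> float:
    """log[(count + alpha) / (total + alpha * vocab_size)].

    Returns ``-inf`` for an unseen event when ``alpha`` is zero.
    """
    num = count + alpha
    den = total + alpha * vocab_size
    if num <= 0.0 or den <= 0.0:
        return float("-inf")
    return math.log(num) - math.log(den)
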