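"""Emotion-dynamics summaries of a continuous rating trace.

Two within-subject variability statistics summarize moment-to-moment emotional
reactivity over the whole task:

* ``STD`` — sqrt(sum((x_i - mu)^2) / n), the population standard deviation of
  the ratings; low values indicate blunted responses.
* ``RMSSD`` — sqrt(sum((x_{i+1} - x_i)^2) / (n - 1)), the root mean square of
  successive differences; low values indicate an inflexible, slowly changing
  emotional response.

Both are in rating units and use exactly these denominators (no Bessel
correction for STD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .schedule import VALENCE_LABELS, ConditionLabels

__all__ = ["EmotionMetrics", "compute_std", "compute_rmssd", "condition_means", "emotion_metrics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmotionMetrics:
    subject_id: str
    std: float
    rmssd: float
    mean_by_condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.std < 0 or self.rmssd < 0:
            raise ValueError("std and rmssd are nonnegative by definition")


def _as_trace(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D rating sequence")
    return x


def compute_std(values) -> float:
    """Within-subject standard deviation with population denominator ``n``."""
    x = _as_trace(values)
    if x.size < 1:
        raise ValueError("compute_std requires at least one sample")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def compute_rmssd(values) -> float:
    """Root mean square of successive differences, denominator ``n - 1``."""
    x = _as_trace(values)
    if x.size < 2:
        raise ValueError("compute_rmssd requires at least two samples")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def condition_means(per_tr_ratings, labels: ConditionLabels) -> dict[str, float]:
    """Mean rating over the volumes of each valence condition (silence excluded).

    A condition with zero volumes is absent from the result (with a logged
    warning), never a NaN.
    """
    x = _as_trace(per_tr_ratings)
    if x.size != labels.n_volumes:
        raise ValueError(
            f"ratings ({x.size}) and labels ({labels.n_volumes}) are not aligned"
        )
    means: dict[str, float] = {}
    for cond in VALENCE_LABELS:
        mask = labels.mask(cond)
        if not mask.any():
            logger.warning("condition %r has no volumes; mean omitted", cond)
            continue
        means[cond] = float(x[mask].mean())
    return means


def emotion_metrics(
    subject_id: str,
    per_tr_ratings,
    labels: ConditionLabels,
    exclude_silence: bool = False,
) -> EmotionMetrics:
    """STD, RMSSD and per-condition means for one subject's TR-grid ratings.

    By default the variability statistics run over the entire task including
    silence volumes; ``exclude_silence=True`` restricts them to music volumes.
    """
    x = _as_trace(per_tr_ratings)
    if exclude_silence:
        keep = np.asarray(labels.labels) != "silence"
        stat_trace = x[keep]
    else:
        stat_trace = x
    return EmotionMetrics(
        subject_id=subject_id,
        std=compute_std(stat_trace),
        rmssd=compute_rmssd(stat_trace),
        mean_by_condition=condition_means(x, labels),
    )
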