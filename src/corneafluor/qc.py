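"""Eyelid-reference artifact rejection for corneal fluorescence recordings.

Corneal fluorescence is weak, so ambient and reflected light corrupt the
corneal channel.  The eyelid channel sees the same illumination but a much
stronger fluorescence signal, making it a robust reference: over a clean
stretch the two channels drift together, while during an interference
episode the corneal channel trends *against* the eyelid channel.

The filter slides a window along both channels, computes a per-window
trend-consistency statistic, rejects windows below a threshold, and
averages the surviving corneal samples into one corrected intensity per
subject (pooling repeated recordings).  Two statistics are supported:

``correlation``
    Pearson correlation between the two channels inside the window
    (default; threshold 0 rejects anti-correlated windows).
``slope_sign``
    +1 when the least-squares slopes of the two channels share a sign,
    -1 otherwise.

Zero-variance (flat) windows get statistic +1: a flat corneal signal
cannot oppose the eyelid trend, so there is no evidence of interference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigurationError, ConsistencyError, InputError
from .simulate import RawRecording

__all__ = [
    "QcConfig",
    "WindowTrends",
    "ValidityMask",
    "CorrectedMeasurement",
    "window_starts",
    "windowed_trends",
    "build_mask",
    "summarize_valid",
    "qc_recording",
    "mask_to_sample_keep",
    "confusion_counts",
]


@dataclass(frozen=True)
class QcConfig:
    window_length: int = 50  # samples
    window_step: int = 25  # 50% overlap by default
    trend_statistic: str = "correlation"  # or "slope_sign"
    consistency_threshold: float = 0.0
    min_valid_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.window_step <= self.window_length:
            raise ConfigurationError("need 0 < window_step <= window_length")
        if self.trend_statistic not in ("correlation", "slope_sign"):
            raise ConfigurationError(
                "trend_statistic must be 'correlation' or 'slope_sign'"
            )
        if not -1.0 <= self.consistency_threshold <= 1.0:
            raise ConfigurationError("consistency_threshold must lie in [-1, 1]")
        if not 0.0 < self.min_valid_fraction <= 1.0:
            raise ConfigurationError("min_valid_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class WindowTrends:
    """Per-window slopes of both channels and the consistency statistic."""

    window_starts: np.ndarray
    corneal_slope: np.ndarray
    eyelid_slope: np.ndarray
    consistency: np.ndarray
    window_length: int


@dataclass(frozen=True)
class ValidityMask:
    """Keep/reject decision per window."""

    window_starts: np.ndarray
    keep: np.ndarray
    per_window_statistic: np.ndarray
    window_length: int

    def __post_init__(self) -> None:
        if not (
            len(self.window_starts) == len(self.keep) == len(self.per_window_statistic)
        ):
            raise ConsistencyError("mask field lengths differ")

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.keep)) if len(self.keep) else 0.0


@dataclass(frozen=True)
class CorrectedMeasurement:
    """Per-subject corrected fluorescence summary."""

    subject_id: str
    corrected_intensity: float  # NaN when unusable
    eyelid_reference: float
    valid_fraction: float
    n_repeats_used: int
    usable: bool


def window_starts(n_samples: int, cfg: QcConfig) -> np.ndarray:
    """Start indices tiling the series; the final window is anchored to the
    series end so every sample is covered when ``window_step <= window_length``."""
    if n_samples < cfg.window_length:
        raise InputError(
            f"recording of {n_samples} samples is shorter than one "
            f"window ({cfg.window_length})"
        )
    starts = list(range(0, n_samples - cfg.window_length + 1, cfg.window_step))
    if starts[-1] + cfg.window_length < n_samples:
        starts.append(n_samples - cfg.window_length)
    return np.asarray(starts, dtype=int)


def _slope(y: np.ndarray) -> float:
    x = np.arange(len(y), dtype=float)
    x -= x.mean()
    denom = np.dot(x, x)
    return float(np.dot(x, y - y.mean()) / denom) if denom > 0 else 0.0


def _consistency(c: np.ndarray, e: np.ndarray, statistic: str) -> float:
    if statistic == "correlation":
        sc, se = np.std(c), np.std(e)
        if sc == 0.0 or se == 0.0:
            return 1.0  # flat window: no evidence of opposition
        return float(np.corrcoef(c, e)[0, 1])
    # slope_sign: +1 on agreement (a zero slope never disagrees)
    sc, se = _slope(c), _slope(e)
    return -1.0 if sc * se < 0 else 1.0


def windowed_trends(recording: RawRecording, cfg: QcConfig) -> WindowTrends:
    """Channel slopes and trend-consistency statistic per window."""
    starts = window_starts(recording.n_samples, cfg)
    wl = cfg.window_length
    corneal_slope = np.empty(len(starts))
    eyelid_slope = np.empty(len(starts))
    consistency = np.empty(len(starts))
    for i, s in enumerate(starts):
        c = recording.corneal[s : s + wl]
        e = recording.eyelid[s : s + wl]
        corneal_slope[i] = _slope(c)
        eyelid_slope[i] = _slope(e)
        consistency[i] = _consistency(c, e, cfg.trend_statistic)
    return WindowTrends(starts, corneal_slope, eyelid_slope, consistency, wl)


def build_mask(trends: WindowTrends, cfg: QcConfig) -> ValidityMask:
    """Keep a window iff its consistency statistic meets the threshold."""
    if len(trends.window_starts) == 0:
        raise InputError("no windows to mask")
    keep = trends.consistency >= cfg.consistency_threshold
    return ValidityMask(
        window_starts=trends.window_starts,
        keep=keep,
        per_window_statistic=trends.consistency,
        window_length=trends.window_length,
    )


def qc_recording(recording: RawRecording, cfg: QcConfig) -> ValidityMask:
    """Convenience: trends + mask in one call."""
    return build_mask(windowed_trends(recording, cfg), cfg)


def mask_to_sample_keep(mask: ValidityMask, n_samples: int) -> np.ndarray:
    """Per-sample boolean: sample belongs to at least one kept window."""
    keep = np.zeros(n_samples, dtype=bool)
    for s, k in zip(mask.window_starts, mask.keep):
        if k:
            keep[s : s + mask.window_length] = True
    return keep


def summarize_valid(
    recordings: Sequence[RawRecording],
    masks: Sequence[ValidityMask],
    cfg: QcConfig,
) -> CorrectedMeasurement:
    """Pool kept-window samples across repeats into one corrected value.

    Repeats whose per-recording valid fraction falls below
    ``min_valid_fraction`` are dropped entirely; if none survive, the
    measurement is flagged unusable (NaN intensity).
    """
    if len(recordings) != len(masks):
        raise ConsistencyError(
            f"{len(recordings)} recordings but {len(masks)} masks"
        )
    if not recordings:
        raise InputError("no recordings to summarize")
    subject_ids = {r.subject_id for r in recordings}
    if len(subject_ids) != 1:
        raise ConsistencyError(f"mixed subjects in one summary: {subject_ids}")
    subject_id = recordings[0].subject_id

    corneal_pool: list[np.ndarray] = []
    eyelid_pool: list[np.ndarray] = []
    n_used = 0
    kept_windows = 0
    total_windows = 0
    for rec, mask in zip(recordings, masks):
        total_windows += len(mask.keep)
        kept_windows += int(np.sum(mask.keep))
        if mask.valid_fraction < cfg.min_valid_fraction:
            continue
        sample_keep = mask_to_sample_keep(mask, rec.n_samples)
        corneal_pool.append(rec.corneal[sample_keep])
        eyelid_pool.append(rec.eyelid[sample_keep])
        n_used += 1

    valid_fraction = kept_windows / total_windows if total_windows else 0.0
    if n_used == 0:
        return CorrectedMeasurement(
            subject_id, float("nan"), float("nan"), valid_fraction, 0, False
        )
    corneal_all = np.concatenate(corneal_pool)
    eyelid_all = np.concatenate(eyelid_pool)
    return CorrectedMeasurement(
        subject_id,
        float(corneal_all.mean()),
        float(eyelid_all.mean()),
        valid_fraction,
        n_used,
        True,
    )


def confusion_counts(
    masks: Iterable[ValidityMask],
    truth_masks: Iterable[np.ndarray],
    min_overlap: float = 0.5,
) -> dict[str, int]:
    """Score keep/reject decisions against the simulator truth mask.

    A window counts as *contaminated* when at least ``min_overlap`` of its
    samples are truth-masked and *clean* when none are; windows in between
    are ambiguous at the filter's one-window resolution and are excluded.
    Returns counts of true/false positives/negatives where "positive"
    means rejected-as-interference.
    """
    tp = fp = tn = fn = 0
    for mask, truth in zip(masks, truth_masks):
        wl = mask.window_length
        for s, k in zip(mask.window_starts, mask.keep):
            overlap = int(np.sum(truth[s : s + wl]))
            if overlap >= min_overlap * wl:
                if k:
                    fn += 1
                else:
                    tp += 1
            elif overlap == 0:
                if k:
                    tn += 1
                else:
                    fp += 1
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
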