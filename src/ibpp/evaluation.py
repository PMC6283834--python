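"""Performance metrics for short-window classification and long-sequence scans.

Short sequences use the standard confusion-matrix ratios

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

For long sequences the unit of truth differs: a sequence counts as a
true positive when any merged hit lands within ±50 nt of its TSS, and
sensitivity is TP over the number of sequences.  Specificity needs a
notion of "negative opportunity" along the rest of the sequence: the
region outside the ±50 TSS window is tiled into 101-nt bins; a bin
containing a hit is an FP, an empty bin a TN, and specificity is
TN / (TN + FP).  (A literal per-hit variant of the FP count is kept
behind ``literal_fp`` for comparison; see the methods note.)

Undefined ratios (zero denominators) are returned as NaN rather than
silently clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .scanner import Hit


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(
        cls, y_true: Iterable[int], y_pred: Iterable[int]
    ) -> "ConfusionCounts":
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred, strict=True):
            if t and p:
                tp += 1
            elif t and not p:
                fn += 1
            elif not t and p:
                fp += 1
            else:
                tn += 1
        return cls(tp, fp, tn, fn)


class ShortMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    f1: float


class LongMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    tp: int
    fp: float
    tn: int


def short_metrics(c: ConfusionCounts) -> ShortMetrics:
    """Sensitivity, specificity and F1 from a confusion matrix.

    Any ratio with a zero denominator comes back as NaN.
    """
    sn = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else math.nan
    sp = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else math.nan
    denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / denom if denom > 0 else math.nan
    return ShortMetrics(sn, sp, f1)


@dataclass(frozen=True)
class LongSeqEvalConfig:
    hit_window: tuple[int, int] = (-50, 50)
    bin_width: int = 101
    literal_fp: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.hit_window
        if lo > 0 or hi < 0 or -lo != hi:
            raise ValueError("hit_window must be symmetric around 0")
        if self.bin_width != hi - lo + 1:
            raise ValueError("bin_width must equal the hit-window length")


def _off_window_bins(
    length: int, tss: int, config: LongSeqEvalConfig
) -> list[tuple[int, int]]:
    """Half-open bins tiling the sequence outside the TSS hit window.

    Bins are laid outward from the window edges so the bins adjacent to
    the TSS are full-width; partial bins at the sequence ends count.
    """
    lo, hi = config.hit_window
    w = config.bin_width
    bins = []
    # leftward from tss + lo (exclusive)
    right = tss + lo
    while right > 0:
        left = max(0, right - w)
        bins.append((left, right))
        right = left
    # rightward from tss + hi (exclusive)
    left = tss + hi + 1
    while left < length:
        right = min(length, left + w)
        bins.append((left, right))
        left = right
    return bins


def long_metrics(
    hit_lists: list[list[Hit]],
    true_tss: list[int],
    seq_lengths: list[int],
    config: LongSeqEvalConfig | None = None,
) -> LongMetrics:
    """Scan-level sensitivity and specificity over a set of long sequences.

    ``hit_lists[i]`` holds the merged hits of sequence ``i`` whose true
    TSS is ``true_tss[i]`` and whose length is ``seq_lengths[i]``.
    """
    config = config or LongSeqEvalConfig()
    if not (len(hit_lists) == len(true_tss) == len(seq_lengths)):
        raise ValueError("hit_lists, true_tss and seq_lengths must align")
    lo, hi = config.hit_window
    tp = 0
    fp: float = 0
    tn = 0
    for hits, tss, length in zip(hit_lists, true_tss, seq_lengths):
        if tss + lo < 0 or tss + hi >= length:
            raise ValueError(
                f"TSS window [{tss + lo}, {tss + hi}] extends past the sequence"
            )
        positions = [h.tss_position for h in hits]
        if any(tss + lo <= p <= tss + hi for p in positions):
            tp += 1
        off_positions = [p for p in positions if not tss + lo <= p <= tss + hi]
        for left, right in _off_window_bins(length, tss, config):
            occupied = any(left <= p < right for p in off_positions)
            if occupied:
                if not config.literal_fp:
                    fp += 1
            else:
                tn += 1
        if config.literal_fp:
            # paper-literal reading: hits near the TSS, per window length
            n_in = sum(1 for p in positions if tss + lo <= p <= tss + hi)
            fp += n_in / config.bin_width
    sensitivity = tp / len(hit_lists) if hit_lists else math.nan
    specificity = tn / (tn + fp) if tn + fp > 0 else math.nan
    return LongMetrics(sensitivity, specificity, tp, fp, tn)
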